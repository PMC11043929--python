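import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strooprel._errors import ParameterError
from strooprel.performance_summaries import participant_scores
from strooprel.reliability import (
    test_retest_pearson as retest_pearson,
    SplitHalfConfig,
    compare_correlations_fisher,
    icc,
    permutation_split_half,
    reliability_curve,
    spearman_brown,
)
from strooprel.synthetic_cohort import GeneratorParams, generate_cohort
from strooprel.trial_data import CohortData, SessionPlan

from conftest import make_trials

NO_LAPSE = {"basic": 0.0, "game": 0.0}
NO_ERR = {"congruent": 0.0, "neutral": 0.0, "incongruent": 0.0}


def brute_force_icc(x: np.ndarray, kind: str) -> float:
    """Independent two-way ANOVA decomposition, cell by cell."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if kind == "icc31":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestSpearmanBrown:
    @pytest.mark.parametrize("r,expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3)])
    def test_values(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    def test_undefined_at_minus_one(self):
        with pytest.raises(ParameterError):
            spearman_brown(-1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        st.tuples(
            st.floats(min_value=-0.999, max_value=1.0),
            st.floats(min_value=-0.999, max_value=1.0),
        ).filter(lambda t: abs(t[0] - t[1]) > 1e-12)
    )
    def test_monotone_increasing(self, pair):
        lo, hi = sorted(pair)
        assert spearman_brown(lo) < spearman_brown(hi)


class TestFisherComparison:
    def test_equal_correlations(self):
        z, p = compare_correlations_fisher(0.5, 30, 0.5, 40)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, _ = compare_correlations_fisher(0.78, 31, 0.83, 34)
        z2, _ = compare_correlations_fisher(0.83, 34, 0.78, 31)
        assert z1 == pytest.approx(-z2)

    def test_reported_group_pair_nonsignificant(self):
        # the two arms' split-half coefficients do not differ significantly
        z, p = compare_correlations_fisher(0.78, 31, 0.83, 34)
        assert abs(z) < 1.96 and p > 0.05

    def test_small_n_errors(self):
        with pytest.raises(ParameterError):
            compare_correlations_fisher(0.5, 3, 0.5, 40)

    def test_extreme_r_errors(self):
        with pytest.raises(ParameterError):
            compare_correlations_fisher(1.0, 30, 0.5, 40)


class TestTestRetestPearson:
    def test_perfect_correlation_degenerate_ci(self):
        x = np.arange(10.0)
        est, t = retest_pearson(x, x)
        assert est.point == 1.0
        assert est.ci_low == est.ci_high == 1.0
        assert math.isinf(t)

    def test_reported_t_statistic(self):
        # r = 0.68 at n = 31 gives t ~ 5.0 on 29 df
        rng = np.random.default_rng(0)
        n = 31
        r_target = 0.68
        t_expected = r_target * math.sqrt(n - 2) / math.sqrt(1 - r_target**2)
        assert t_expected == pytest.approx(5.0, abs=0.01)
        x = rng.normal(size=n)
        y = r_target * x + math.sqrt(1 - r_target**2) * rng.normal(size=n)
        est, t = retest_pearson(x, y)
        assert est.df == n - 2
        assert t == pytest.approx(
            est.point * math.sqrt(n - 2) / math.sqrt(1 - est.point**2)
        )

    def test_ci_matches_fisher_construction(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        est, _ = retest_pearson(x, y)
        half = 1.959963984540054 / math.sqrt(40 - 3)
        assert est.ci_low == pytest.approx(math.tanh(math.atanh(est.point) - half))
        assert est.ci_high == pytest.approx(math.tanh(math.atanh(est.point) + half))

    def test_independent_sessions_near_zero(self):
        rng = np.random.default_rng(5)
        est, _ = retest_pearson(rng.normal(size=5000), rng.normal(size=5000))
        assert est.point == pytest.approx(0.0, abs=0.05)

    def test_zero_variance_errors(self):
        with pytest.raises(ParameterError, match="variance"):
            retest_pearson(np.ones(10), np.arange(10.0))

    def test_too_few_pairs(self):
        with pytest.raises(ParameterError):
            retest_pearson(np.arange(3.0), np.arange(3.0))


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.array([[1.0, 1.0], [3.0, 3.0], [7.0, 7.0], [2.0, 2.0]])
        assert icc(x, "icc31").icc == pytest.approx(1.0)
        assert icc(x, "icc21").icc == pytest.approx(1.0)

    def test_column_shift_consistency_vs_agreement(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc(x, "icc31").icc == pytest.approx(1.0)
        assert icc(x, "icc21").icc < 1.0

    def test_4x2_matrix_against_oracle(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [8.0, 7.0]])
        for kind in ("icc21", "icc31"):
            assert icc(x, kind).icc == pytest.approx(brute_force_icc(x, kind), abs=1e-12)

    def test_random_matrices_against_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            x = rng.normal(size=(5, 2)) + rng.normal(size=(5, 1))
            for kind in ("icc21", "icc31"):
                assert icc(x, kind).icc == pytest.approx(
                    brute_force_icc(x, kind), abs=1e-10
                )

    def test_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 2)) + 2 * rng.normal(size=(15, 1))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(15), 2),
                "raters": np.tile([1, 2], 15),
                "scores": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        labels = {"icc21": ("ICC2", "ICC(A,1)"), "icc31": ("ICC3", "ICC(C,1)")}
        ci_col = next(c for c in ref.columns if c.startswith("CI95"))
        for kind in ("icc21", "icc31"):
            mine = icc(x, kind)
            row = ref[ref["Type"].isin(labels[kind])]
            assert mine.icc == pytest.approx(float(row["ICC"].iloc[0]), abs=1e-9)
            lo, hi = row[ci_col].iloc[0]
            assert mine.ci_low == pytest.approx(lo, abs=0.01)
            assert mine.ci_high == pytest.approx(hi, abs=0.01)

    def test_incomplete_matrix_errors(self):
        x = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
        with pytest.raises(ParameterError, match="complete"):
            icc(x)

    def test_too_small_errors(self):
        with pytest.raises(ParameterError):
            icc(np.array([[1.0, 2.0], [3.0, 4.0]]))


@pytest.fixture(scope="module")
def midsize_cohort():
    params = GeneratorParams(
        n_participants=60,
        seed=3,
        arms=("basic",),
        lapse_prob=NO_LAPSE,
    )
    return params, generate_cohort(params)


class TestPermutationSplitHalf:
    def test_noise_free_cohort_exactly_one(self):
        params = GeneratorParams(
            n_participants=6,
            seed=1,
            arms=("basic",),
            sigma_trial=0.0,
            lapse_prob=NO_LAPSE,
            error_rates=NO_ERR,
            plan=SessionPlan(n_per_condition=8),
        )
        cohort = generate_cohort(params)
        s1 = cohort.trials[cohort.trials["session"] == 1]
        est = permutation_split_half(s1, SplitHalfConfig(n_permutations=50, seed=2))
        assert est.point == pytest.approx(1.0, abs=1e-12)

    def test_no_true_variance_near_zero(self):
        params = GeneratorParams(
            n_participants=100,
            seed=6,
            arms=("basic",),
            sigma_effect=0.0,
            lapse_prob=NO_LAPSE,
            plan=SessionPlan(n_per_condition=60),
        )
        cohort = generate_cohort(params)
        s1 = cohort.trials[cohort.trials["session"] == 1]
        est = permutation_split_half(s1, SplitHalfConfig(n_permutations=300, seed=2))
        assert est.point == pytest.approx(0.0, abs=0.1)

    def test_seed_reproducible_and_order_invariant(self, midsize_cohort):
        _, cohort = midsize_cohort
        s1 = cohort.trials[cohort.trials["session"] == 1]
        cfg = SplitHalfConfig(n_permutations=100, seed=11)
        a = permutation_split_half(s1, cfg)
        b = permutation_split_half(s1.sample(frac=1.0, random_state=4), cfg)
        assert a == b
        c = permutation_split_half(s1, SplitHalfConfig(n_permutations=100, seed=12))
        assert a.point != c.point

    def test_ci_brackets_point(self, midsize_cohort):
        _, cohort = midsize_cohort
        s1 = cohort.trials[cohort.trials["session"] == 1]
        est = permutation_split_half(s1, SplitHalfConfig(n_permutations=200, seed=0))
        assert est.ci_low <= est.point <= est.ci_high
        assert est.n_splits == 200
        assert est.n_participants == 60

    def test_error_cost_score(self, midsize_cohort):
        _, cohort = midsize_cohort
        s1 = cohort.trials[cohort.trials["session"] == 1]
        est = permutation_split_half(
            s1, SplitHalfConfig(n_permutations=100, seed=0, score="error_cost")
        )
        assert -1.0 <= est.point <= 1.0

    def test_sparse_participant_dropped_with_warning(self):
        blocks = []
        for i in range(4):
            rng = np.random.default_rng(i)
            blocks.append(
                make_trials(
                    f"p{i}",
                    1,
                    "basic",
                    rng.uniform(400, 800, 30),
                    ["congruent", "incongruent"] * 15,
                )
            )
        blocks.append(
            make_trials("sparse", 1, "basic", [500.0, 600.0],
                        ["congruent", "incongruent"])
        )
        trials = pd.concat(blocks, ignore_index=True)
        with pytest.warns(UserWarning, match="sparse"):
            est = permutation_split_half(trials, SplitHalfConfig(n_permutations=20, seed=0))
        assert est.n_participants == 4

    def test_too_few_participants_errors(self):
        trials = pd.concat(
            [
                make_trials("p1", 1, "basic", [500.0] * 10,
                            ["congruent", "incongruent"] * 5),
                make_trials("p2", 1, "basic", [520.0] * 10,
                            ["congruent", "incongruent"] * 5),
            ],
            ignore_index=True,
        )
        with pytest.raises(ParameterError, match="at least 3"):
            permutation_split_half(trials, SplitHalfConfig(n_permutations=10, seed=0))

    def test_multi_session_input_rejected(self, midsize_cohort):
        _, cohort = midsize_cohort
        with pytest.raises(ParameterError, match="single session"):
            permutation_split_half(cohort.trials, SplitHalfConfig(n_permutations=10))


class TestReliabilityCurve:
    def test_final_point_equals_full_data_icc(self, midsize_cohort):
        _, cohort = midsize_cohort
        curve = reliability_curve(cohort, step=120)
        scores = participant_scores(cohort)
        wide = scores.pivot(index="participant_id", columns="session", values="rt_cost")
        full = icc(wide.to_numpy(), "icc31").icc
        final = curve.loc[curve["t"] == 240, "icc"].iloc[0]
        assert final == pytest.approx(full, abs=1e-12)

    def test_noise_free_curve_constant_one(self):
        params = GeneratorParams(
            n_participants=6,
            seed=2,
            arms=("basic",),
            sigma_trial=0.0,
            rho_effect=1.0,
            lapse_prob=NO_LAPSE,
            error_rates=NO_ERR,
            plan=SessionPlan(n_per_condition=12),
        )
        cohort = generate_cohort(params)
        curve = reliability_curve(cohort, step=4)
        assert np.allclose(curve["icc"], 1.0)

    def test_tracks_analytic_attenuation(self):
        from strooprel.synthetic_cohort import analytic_retest_icc

        params = GeneratorParams(
            n_participants=400,
            seed=17,
            arms=("basic",),
            lapse_prob=NO_LAPSE,
            error_rates=NO_ERR,
        )
        cohort = generate_cohort(params)
        curve = reliability_curve(cohort, step=60)
        for _, row in curve.iterrows():
            assert row["icc"] == pytest.approx(
                analytic_retest_icc(params, int(row["t"])), abs=0.1
            )

    def test_expected_monotonicity_over_seeds(self):
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(12):
            params = GeneratorParams(
                n_participants=150,
                seed=seed,
                arms=("basic",),
                lapse_prob=NO_LAPSE,
                plan=SessionPlan(n_per_condition=120),
            )
            cohort = generate_cohort(params)
            curve = reliability_curve(cohort, step=24)
            rhos.append(spearmanr(curve["t"], curve["icc"]).statistic)
        assert np.mean(rhos) > 0.9

    def test_per_type_metric_shape(self, midsize_cohort):
        _, cohort = midsize_cohort
        curve = reliability_curve(cohort, metric="per_type_icc31", step=120)
        assert set(curve["trial_type"]) == {"congruent", "neutral", "incongruent"}
        assert set(curve["t"]) == {120, 240}

    def test_pearson_estimator_switch(self, midsize_cohort):
        _, cohort = midsize_cohort
        a = reliability_curve(cohort, step=240, estimator="icc31")
        b = reliability_curve(cohort, step=240, estimator="pearson")
        assert a.loc[0, "icc"] != b.loc[0, "icc"]
        assert abs(a.loc[0, "icc"] - b.loc[0, "icc"]) < 0.05

    def test_short_participants_contribute_available_trials(self, midsize_cohort):
        _, cohort = midsize_cohort
        # truncate one participant's incongruent trials to 100
        t = cohort.trials
        pid = "basic_0001"
        mask = (
            (t["participant_id"] == pid)
            & (t["trial_type"] == "incongruent")
            & (t.groupby(["participant_id", "session", "trial_type"]).cumcount() >= 100)
        )
        truncated = CohortData(t[~mask], cohort.plan)
        curve = reliability_curve(truncated, step=240)
        assert (curve["n_participants"] == 60).all()

    def test_single_session_errors(self, midsize_cohort):
        _, cohort = midsize_cohort
        s1 = cohort.trials[cohort.trials["session"] == 1]
        with pytest.raises(ParameterError, match="both sessions"):
            reliability_curve(s1)
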