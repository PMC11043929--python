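"""Reliability estimators for interference-cost scores.

- :func:`spearman_brown` — full-length projection of a half-test correlation.
- :func:`permutation_split_half` — repeated random within-condition splits of
  one session, Pearson correlation of half scores across participants,
  Spearman-Brown corrected, averaged, with a percentile CI over splits.
- :func:`compare_correlations_fisher` — z test for two independent r's.
- :func:`test_retest_pearson` — paired-session correlation with t statistic
  and Fisher-z CI.
- :func:`icc` — single-rater intraclass correlations ICC(2,1) / ICC(3,1)
  from the two-way mean-squares decomposition, with F-based CIs.
- :func:`reliability_curve` — test-retest reliability of scores built from
  the first *t* kept trials per condition, on a grid of *t*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from strooprel._errors import ParameterError
from strooprel.screening import ScreenedCohort
from strooprel.trial_data import CohortData

SCORES = ("rt_cost", "error_cost")
_COST_TYPES = ("congruent", "incongruent")


@dataclass(frozen=True)
class SplitHalfConfig:
    n_permutations: int = 5000
    seed: int = 0
    score: str = "rt_cost"  # or "error_cost"
    #: correct per split then average (True) or average raw r's then correct
    correct_each_split: bool = True
    rt_on_correct_only: bool = True

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")
        if self.score not in SCORES:
            raise ParameterError(f"score must be one of {SCORES}")


@dataclass(frozen=True)
class ReliabilityEstimate:
    point: float
    ci_low: float
    ci_high: float
    method: str  # splithalf_sb | pearson | icc21 | icc31
    n_participants: int
    n_splits: int | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if not (
            math.isnan(self.ci_low)
            or self.ci_low <= self.point <= self.ci_high
        ):
            raise ValueError("CI must bracket the point estimate")

    def to_dict(self) -> dict:
        out = {
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "n_participants": self.n_participants,
        }
        if self.n_splits is not None:
            out["n_splits"] = self.n_splits
        if self.df is not None:
            out["df"] = self.df
        return out


@dataclass(frozen=True)
class ICCResult:
    icc: float
    kind: str  # "icc21" (absolute agreement) | "icc31" (consistency)
    msr: float
    msc: float
    mse: float
    f_stat: float
    ci_low: float
    ci_high: float

    def to_estimate(self, n_participants: int) -> ReliabilityEstimate:
        return ReliabilityEstimate(
            point=self.icc,
            ci_low=min(self.ci_low, self.icc),
            ci_high=max(self.ci_high, self.icc),
            method=self.kind,
            n_participants=n_participants,
        )


def spearman_brown(r: float) -> float:
    """Project a half-test correlation to full length: ``2r / (1 + r)``."""
    if not -1.0 <= r <= 1.0:
        raise ParameterError("r must be in [-1, 1]")
    if r == -1.0:
        raise ParameterError("Spearman-Brown undefined at r = -1")
    return 2.0 * r / (1.0 + r)


def compare_correlations_fisher(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """z statistic and two-sided p for two independent correlations."""
    if n1 <= 3 or n2 <= 3:
        raise ParameterError("both sample sizes must exceed 3")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ParameterError("correlations must lie strictly inside (-1, 1)")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


# ---------------------------------------------------------------------------
# permutation split-half
# ---------------------------------------------------------------------------


def _random_half_assignments(
    rng: np.random.Generator, n_perm: int, n_trials: int
) -> np.ndarray:
    """Boolean (n_perm, n_trials) matrix; True marks half 1.

    Halves are balanced; for odd counts the extra trial lands in a random
    half per permutation.
    """
    perm = np.argsort(rng.random((n_perm, n_trials)), axis=1)
    k = np.full(n_perm, n_trials // 2)
    if n_trials % 2 == 1:
        k += rng.integers(0, 2, size=n_perm)
    mask = np.arange(n_trials)[None, :] < k[:, None]
    out = np.zeros((n_perm, n_trials), dtype=bool)
    np.put_along_axis(out, perm, mask, axis=1)
    return out


def _half_scores(
    rt: np.ndarray,
    correct: np.ndarray,
    assign: np.ndarray,
    score: str,
    rt_on_correct_only: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-permutation condition scores for each half.

    For ``rt_cost`` the condition score is the mean RT (correct trials only
    by default); for ``error_cost`` it is the error percentage of the half.
    """
    a1 = assign.astype(float)
    a2 = (~assign).astype(float)
    if score == "rt_cost":
        w = correct.astype(float) if rt_on_correct_only else np.ones_like(rt)
        with np.errstate(invalid="ignore", divide="ignore"):
            s1 = (a1 @ (rt * w)) / (a1 @ w)
            s2 = (a2 @ (rt * w)) / (a2 @ w)
    else:
        err = (~correct).astype(float)
        s1 = 100.0 * (a1 @ err) / a1.sum(axis=1)
        s2 = 100.0 * (a2 @ err) / a2.sum(axis=1)
    return s1, s2


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r along axis 1, NaN-aware (pairs with NaN are dropped per row)."""
    nan = np.isnan(x) | np.isnan(y)
    if nan.any():
        x = np.ma.masked_array(x, nan)
        y = np.ma.masked_array(y, nan)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        num = (xc * yc).sum(axis=1)
        den = np.ma.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        return np.asarray((num / den).filled(np.nan))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def permutation_split_half(
    trials: pd.DataFrame | ScreenedCohort | CohortData,
    cfg: SplitHalfConfig = SplitHalfConfig(),
) -> ReliabilityEstimate:
    """Permutation-based split-half internal consistency of the cost score.

    ``trials`` must hold a single session (one arm).  For each permutation,
    every participant's congruent and incongruent trials are independently
    split into random halves; the cost is computed per half; half-1 and
    half-2 costs are Pearson-correlated across participants and
    Spearman-Brown corrected.  The point estimate is the mean over
    permutations and the CI the 2.5th/97.5th percentile of the per-split
    values.  Deterministic given ``cfg.seed`` and invariant to row order.
    """
    cfg.validate()
    if not isinstance(trials, pd.DataFrame):
        trials = trials.trials
    if trials["session"].nunique() > 1:
        raise ParameterError("split-half expects trials from a single session")

    rng = np.random.default_rng(cfg.seed)
    B = cfg.n_permutations

    sorted_trials = trials.sort_values("trial_index", kind="stable")
    by_pid_cond: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for (pid, tt), grp in sorted_trials.groupby(["participant_id", "trial_type"]):
        if tt in _COST_TYPES:
            by_pid_cond.setdefault(str(pid), {})[str(tt)] = (
                grp["rt_ms"].to_numpy(),
                grp["correct"].to_numpy(),
            )
    data: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for pid in sorted(by_pid_cond):
        per_cond = by_pid_cond[pid]
        if any(
            tt not in per_cond or len(per_cond[tt][0]) < 2 for tt in _COST_TYPES
        ):
            warnings.warn(
                f"participant {pid} has < 2 trials in a cost condition; "
                "dropped from split-half",
                stacklevel=2,
            )
            continue
        data[pid] = per_cond
    if len(data) < 3:
        raise ParameterError("split-half needs at least 3 usable participants")

    n = len(data)
    h1 = np.empty((B, n))
    h2 = np.empty((B, n))
    for j, pid in enumerate(data):
        cost1 = np.zeros(B)
        cost2 = np.zeros(B)
        for tt, sign in (("congruent", -1.0), ("incongruent", 1.0)):
            rt, correct = data[pid][tt]
            assign = _random_half_assignments(rng, B, len(rt))
            s1, s2 = _half_scores(rt, correct, assign, cfg.score, cfg.rt_on_correct_only)
            cost1 += sign * s1
            cost2 += sign * s2
        h1[:, j] = cost1
        h2[:, j] = cost2

    r = _rowwise_pearson(h1, h2)
    r = np.clip(r, -1.0, 1.0)
    sb = 2.0 * r / (1.0 + r)
    sb[r == -1.0] = np.nan
    valid = sb[np.isfinite(sb)]
    if len(valid) == 0:
        raise ParameterError("no valid splits (degenerate data)")
    if cfg.correct_each_split:
        point = float(valid.mean())
        lo, hi = np.percentile(valid, [2.5, 97.5])
    else:
        rbar = float(np.nanmean(r))
        point = spearman_brown(rbar)
        lo, hi = (spearman_brown(float(q)) for q in np.percentile(r[np.isfinite(r)], [2.5, 97.5]))
    return ReliabilityEstimate(
        point=point,
        ci_low=min(float(lo), point),
        ci_high=max(float(hi), point),
        method="splithalf_sb",
        n_participants=n,
        n_splits=B,
    )


# ---------------------------------------------------------------------------
# test-retest
# ---------------------------------------------------------------------------


def test_retest_pearson(
    score_t1: np.ndarray | pd.Series, score_t2: np.ndarray | pd.Series
) -> tuple[ReliabilityEstimate, float]:
    """Pearson test-retest correlation of paired session scores.

    Returns ``(estimate, t_statistic)`` with ``t = r sqrt(n-2)/sqrt(1-r^2)``
    on ``n - 2`` df, and a 95% CI via Fisher z +/- 1.96/sqrt(n-3).  For
    |r| = 1 the CI degenerates to the point and t is infinite.
    """
    x = np.asarray(score_t1, dtype=float)
    y = np.asarray(score_t2, dtype=float)
    if len(x) != len(y):
        raise ParameterError("sessions must have paired scores")
    n = len(x)
    if n < 4:
        raise ParameterError("test-retest needs >= 4 paired observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ParameterError("zero variance in a session's scores")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) > 1.0 - 1e-12:  # snap numerically-perfect correlations
        r = 1.0 if r > 0 else -1.0
        est = ReliabilityEstimate(
            point=r, ci_low=r, ci_high=r, method="pearson", n_participants=n, df=n - 2
        )
        return est, math.inf * (1 if r > 0 else -1)
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r**2)
    half = 1.959963984540054 / math.sqrt(n - 3)
    lo, hi = math.tanh(math.atanh(r) - half), math.tanh(math.atanh(r) + half)
    est = ReliabilityEstimate(
        point=r, ci_low=lo, ci_high=hi, method="pearson", n_participants=n, df=n - 2
    )
    return est, t


def icc(matrix: np.ndarray | pd.DataFrame, kind: str = "icc31", alpha: float = 0.05) -> ICCResult:
    """Single-rater intraclass correlation from an n x k two-way layout.

    ``kind="icc31"`` is the consistency coefficient (session mean shifts
    ignored); ``kind="icc21"`` is absolute agreement.  Confidence intervals
    use the F-based constructions for the two-way decomposition.
    Requires a complete matrix with n >= 3 rows and k >= 2 columns.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ParameterError("matrix must be 2-dimensional")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ParameterError("need n >= 3 participants and k >= 2 sessions")
    if np.isnan(x).any():
        raise ParameterError("matrix must be complete (no missing cells)")
    if kind not in ("icc21", "icc31"):
        raise ParameterError("kind must be 'icc21' or 'icc31'")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if kind == "icc31":
        denom = msr + (k - 1) * mse
        val = (msr - mse) / denom if denom > 0 else math.nan
        f = msr / mse if mse > 0 else math.inf
        if not math.isfinite(f):
            return ICCResult(val, "icc31", msr, msc, mse, f, val, val)
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1.0) / (fl + k - 1.0)
        hi = (fu - 1.0) / (fu + k - 1.0) if math.isfinite(fu) else 1.0
        return ICCResult(val, "icc31", msr, msc, mse, f, lo, hi)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    val = (msr - mse) / denom if denom > 0 else math.nan
    f = msr / mse if mse > 0 else math.inf
    if mse > 0 and math.isfinite(val) and abs(val) < 1.0:
        # Satterthwaite df, then the F-based agreement interval
        fj = msc / mse
        vn = (k - 1.0) * (n - 1.0) * (
            k * val * fj + n * (1.0 + (k - 1.0) * val) - k * val
        ) ** 2
        vd = (n - 1.0) * k**2 * val**2 * fj**2 + (
            n * (1.0 + (k - 1.0) * val) - k * val
        ) ** 2
        v = vn / vd if vd > 0 else n - 1.0
        f_l = stats.f.ppf(1 - alpha / 2, n - 1.0, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1.0)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lo, hi = val, val
    return ICCResult(val, "icc21", msr, msc, mse, f, lo, hi)


# ---------------------------------------------------------------------------
# trial-count reliability curves
# ---------------------------------------------------------------------------


def _cumulative_condition_stats(
    trials: pd.DataFrame, rt_on_correct_only: bool
) -> dict[tuple[str, int, str], tuple[np.ndarray, np.ndarray]]:
    """(pid, session, trial_type) -> (mean_rt_at_t, err_pct_at_t) arrays.

    Entry ``t-1`` of each array is the statistic over the first ``t`` kept
    trials of that condition in presentation order.
    """
    out = {}
    sorted_trials = trials.sort_values("trial_index", kind="stable")
    for (pid, s, tt), grp in sorted_trials.groupby(
        ["participant_id", "session", "trial_type"]
    ):
        rt = grp["rt_ms"].to_numpy()
        c = grp["correct"].to_numpy().astype(float)
        t = np.arange(1, len(rt) + 1)
        if rt_on_correct_only:
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_rt = np.cumsum(rt * c) / np.cumsum(c)
        else:
            mean_rt = np.cumsum(rt) / t
        err_pct = 100.0 * (t - np.cumsum(c)) / t
        out[(pid, int(s), tt)] = (mean_rt, err_pct)
    return out


def _score_at(
    stats_map, pid: str, s: int, tt: str, t: int, which: int
) -> float:
    arr = stats_map.get((pid, s, tt))
    if arr is None:
        return math.nan
    vec = arr[which]
    return float(vec[min(t, len(vec)) - 1])


def reliability_curve(
    cohort: ScreenedCohort | CohortData | pd.DataFrame,
    metric: str = "cost_icc31",
    step: int = 10,
    score: str = "rt_cost",
    estimator: str = "icc31",
    rt_on_correct_only: bool = True,
) -> pd.DataFrame:
    """Test-retest reliability as a function of trials per condition.

    For each grid point ``t`` (multiples of ``step`` up to the plan's
    per-condition count), each participant-session score is computed from the
    first ``t`` kept trials of each relevant condition in presentation order;
    reliability across sessions 1 and 2 is then estimated per arm.
    Participants with fewer than ``t`` kept trials contribute all their kept
    trials, keeping n constant across the grid.

    ``metric="cost_icc31"`` yields one curve per arm for the chosen cost
    ``score``; ``metric="per_type_icc31"`` yields one curve per (arm,
    trial type) of the per-type mean RT.  Tidy output columns:
    arm, metric, trial_type, t, icc, n_participants.
    """
    if metric not in ("cost_icc31", "per_type_icc31"):
        raise ParameterError("metric must be 'cost_icc31' or 'per_type_icc31'")
    if estimator not in ("icc31", "pearson"):
        raise ParameterError("estimator must be 'icc31' or 'pearson'")
    if step < 1:
        raise ParameterError("step must be >= 1")

    if isinstance(cohort, pd.DataFrame):
        trials, n_max = cohort, None
    else:
        trials = cohort.trials
        n_max = cohort.plan.n_per_condition
    if n_max is None:
        n_max = int(
            trials.groupby(["participant_id", "session", "trial_type"]).size().max()
        )
    if not {1, 2}.issubset(set(trials["session"].unique())):
        raise ParameterError("curve needs both sessions")

    which = 0 if score == "rt_cost" else 1
    stats_map = _cumulative_condition_stats(trials, rt_on_correct_only)
    arm_of = trials.groupby("participant_id")["arm"].first()
    grid = list(range(step, n_max + 1, step))
    if grid and grid[-1] != n_max:
        grid.append(n_max)

    trial_types = (
        [None] if metric == "cost_icc31" else sorted(trials["trial_type"].unique())
    )
    rows = []
    for arm in sorted(arm_of.unique()):
        pids = sorted(arm_of.index[arm_of == arm])
        for tt in trial_types:
            for t in grid:
                pairs = []
                for pid in pids:
                    if tt is None:
                        v1 = _score_at(stats_map, pid, 1, "incongruent", t, which) - (
                            _score_at(stats_map, pid, 1, "congruent", t, which)
                        )
                        v2 = _score_at(stats_map, pid, 2, "incongruent", t, which) - (
                            _score_at(stats_map, pid, 2, "congruent", t, which)
                        )
                    else:
                        v1 = _score_at(stats_map, pid, 1, tt, t, which)
                        v2 = _score_at(stats_map, pid, 2, tt, t, which)
                    if math.isfinite(v1) and math.isfinite(v2):
                        pairs.append((v1, v2))
                if len(pairs) < 2:
                    continue
                mat = np.array(pairs)
                if estimator == "icc31":
                    try:
                        val = icc(mat, "icc31").icc
                    except ParameterError:
                        continue
                else:
                    val = float(np.corrcoef(mat[:, 0], mat[:, 1])[0, 1])
                rows.append(
                    {
                        "arm": arm,
                        "metric": metric if tt is None else "per_type_icc31",
                        "trial_type": score if tt is None else tt,
                        "t": t,
                        "icc": val,
                        "n_participants": len(pairs),
                    }
                )
    return pd.DataFrame(rows, columns=["arm", "metric", "trial_type", "t", "icc", "n_participants"])
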