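"""Two-arm, two-session synthetic interference-task cohorts with known truth.

The generative model is hierarchical.  For subject *i*:

- baseline speed ``(a_i1, a_i2)`` is bivariate normal with SD
  ``sigma_subject`` and cross-session correlation ``rho_baseline``;
- interference effect deviation ``(u_i1, u_i2)`` is bivariate normal with SD
  ``sigma_effect`` and correlation ``rho_effect``.

The session-*s* mean RT for a given condition is::

    m = mu_congruent + a_is
        + delta_neutral        (neutral trials)
        + beta_stroop + u_is   (incongruent trials)
        - game_speed_shift_t1  (game arm, session 1 only)

Each trial is, with probability ``lapse_prob[arm]``, a slow contaminant drawn
uniformly on ``lapse_range``; otherwise it is drawn from a lognormal (or,
optionally, normal) distribution moment-matched to mean ``m`` and SD
``sigma_trial``.  Correctness is Bernoulli with a per-condition error rate,
independent of RT.

Because every draw flows through one seeded generator, a cohort is a pure
function of its :class:`GeneratorParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from strooprel._errors import ParameterError
from strooprel.trial_data import ARMS, CSV_COLUMNS, CohortData, SessionPlan


def _default_lapse_prob() -> dict[str, float]:
    return {"basic": 0.03, "game": 0.015}


def _default_error_rates() -> dict[str, float]:
    return {"congruent": 0.045, "neutral": 0.035, "incongruent": 0.07}


@dataclass
class GeneratorParams:
    """Full parameterization of the synthetic two-session cohort."""

    n_participants: int = 50  # per arm
    plan: SessionPlan = field(default_factory=SessionPlan)
    arms: tuple[str, ...] = ARMS
    mu_congruent: float = 660.0
    delta_neutral: float = -8.0
    beta_stroop: float = 110.0
    sigma_subject: float = 90.0
    sigma_effect: float = 45.0
    rho_baseline: float = 0.8
    rho_effect: float = 0.7
    sigma_trial: float = 150.0
    lapse_prob: dict[str, float] = field(default_factory=_default_lapse_prob)
    lapse_range: tuple[float, float] = (1400.0, 2600.0)
    error_rates: dict[str, float] = field(default_factory=_default_error_rates)
    game_speed_shift_t1: float = 30.0
    trial_dist: str = "lognormal"  # or "normal" for closed-form checks
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        for name in ("sigma_subject", "sigma_effect", "sigma_trial"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("rho_baseline", "rho_effect"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must be in [-1, 1]")
        for arm in self.arms:
            if arm not in ARMS:
                raise ParameterError(f"unknown arm {arm!r}")
            p = self.lapse_prob.get(arm, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"lapse_prob[{arm}] must be in [0, 1]")
        for tt in self.plan.conditions:
            p = self.error_rates.get(tt, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"error_rates[{tt}] must be in [0, 1]")
        lo, hi = self.lapse_range
        if not (lo > 0 and hi > lo):
            raise ParameterError("lapse_range must satisfy 0 < low < high")
        if self.trial_dist not in ("lognormal", "normal"):
            raise ParameterError("trial_dist must be 'lognormal' or 'normal'")

    def with_(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PointsRules:
    """Points awarded per response in the gamified task variant."""

    gain_correct: int = 5
    loss_incorrect: int = -5
    bonus_record: int = 25


def _bivariate(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """n x 2 draws, each column marginal N(0, sd^2), correlation rho."""
    if sd == 0.0:
        return np.zeros((n, 2))
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    x2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2
    return sd * np.column_stack([z1, x2])


def _lognormal_mm(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Lognormal draws moment-matched to (mean, sd); degenerates to mean at sd=0."""
    if np.any(mean <= 0):
        raise ParameterError("implied trial mean RT is non-positive")
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(s2)))


def generate_cohort(params: GeneratorParams) -> CohortData:
    """Simulate a full cohort; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    plan = params.plan
    npc = plan.n_per_condition
    per_session = plan.trials_per_session

    frames = []
    for arm in params.arms:
        a = _bivariate(rng, params.n_participants, params.sigma_subject, params.rho_baseline)
        u = _bivariate(rng, params.n_participants, params.sigma_effect, params.rho_effect)
        lapse_p = params.lapse_prob.get(arm, 0.0)
        for i in range(params.n_participants):
            pid = f"{arm}_{i + 1:04d}"
            for s in range(1, plan.n_sessions + 1):
                types = np.repeat(np.arange(len(plan.conditions)), npc)
                rng.shuffle(types)
                shift = (
                    params.game_speed_shift_t1 if (arm == "game" and s == 1) else 0.0
                )
                base = params.mu_congruent + a[i, s - 1] - shift
                cond_means = np.empty(len(plan.conditions))
                for j, tt in enumerate(plan.conditions):
                    m = base
                    if tt == "neutral":
                        m += params.delta_neutral
                    elif tt == "incongruent":
                        m += params.beta_stroop + u[i, s - 1]
                    cond_means[j] = m
                if np.any(cond_means <= 0):
                    raise ParameterError(
                        f"implied mean RT non-positive for {pid} session {s}"
                    )
                means = cond_means[types]
                if params.trial_dist == "lognormal":
                    rt = _lognormal_mm(rng, means, params.sigma_trial)
                else:
                    rt = rng.normal(means, params.sigma_trial)
                    if np.any(rt <= 0):
                        raise ParameterError(
                            "normal trial model produced non-positive RT; "
                            "reduce sigma_trial or use lognormal"
                        )
                if lapse_p > 0:
                    is_lapse = rng.random(per_session) < lapse_p
                    rt = np.where(
                        is_lapse,
                        rng.uniform(*params.lapse_range, size=per_session),
                        rt,
                    )
                err = np.array(
                    [params.error_rates.get(tt, 0.0) for tt in plan.conditions]
                )[types]
                correct = rng.random(per_session) >= err
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "session": s,
                            "arm": arm,
                            "trial_index": np.arange(per_session),
                            "trial_type": np.asarray(plan.conditions)[types],
                            "correct": correct,
                            "rt_ms": rt,
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True)[list(CSV_COLUMNS)]
    return CohortData(df, plan)


def score_points(
    trials: pd.DataFrame | Iterable, rules: PointsRules = PointsRules()
) -> tuple[int, list[int]]:
    """Score one session's trials under the points rules.

    The running record is the fastest *correct* RT seen so far.  The first
    correct response sets the record without earning the bonus; each later
    correct response earns ``gain_correct`` plus ``bonus_record`` if its RT
    strictly beats the record (which then updates).  Incorrect responses earn
    ``loss_incorrect`` and never touch the record.

    Returns ``(total, per_trial_deltas)``.
    """
    if isinstance(trials, pd.DataFrame):
        trials = trials.sort_values("trial_index", kind="stable")
        pairs = list(zip(trials["correct"].tolist(), trials["rt_ms"].tolist()))
    else:
        pairs = [(bool(t.correct), float(t.rt_ms)) for t in trials]

    record: float | None = None
    deltas: list[int] = []
    for correct, rt in pairs:
        if not correct:
            deltas.append(rules.loss_incorrect)
            continue
        delta = rules.gain_correct
        if record is None:
            record = rt
        elif rt < record:
            delta += rules.bonus_record
            record = rt
        deltas.append(delta)
    return sum(deltas), deltas


def _require_no_lapses(params: GeneratorParams) -> None:
    if any(params.lapse_prob.get(a, 0.0) > 0 for a in params.arms):
        raise ParameterError("closed form requires lapse_prob = 0 for all arms")


def analytic_split_half_r(params: GeneratorParams, m: int) -> float:
    """Expected half-half correlation of the RT cost at ``m`` trials per
    condition per half, treating halves as independent replicates.

    Equals ``sigma_effect^2 / (sigma_effect^2 + 2 sigma_trial^2 / m)``.
    """
    if m <= 0:
        raise ParameterError("m must be positive")
    _require_no_lapses(params)
    true_var = params.sigma_effect**2
    if true_var == 0.0:
        return 0.0
    noise = 2.0 * params.sigma_trial**2 / m
    return true_var / (true_var + noise)


def analytic_retest_icc(params: GeneratorParams, n: int) -> float:
    """Expected session-1 vs session-2 cost consistency (ICC(3,1)) at ``n``
    trials per condition:
    ``rho_effect * sigma_effect^2 / (sigma_effect^2 + 2 sigma_trial^2 / n)``.
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    _require_no_lapses(params)
    true_var = params.sigma_effect**2
    if true_var == 0.0:
        return 0.0
    noise = 2.0 * params.sigma_trial**2 / n
    return params.rho_effect * true_var / (true_var + noise)
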