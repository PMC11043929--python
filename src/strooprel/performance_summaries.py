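"""Per-participant-session condition summaries, interference costs, and
RT distribution shape."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from strooprel._errors import ParameterError
from strooprel.screening import ScreenedCohort
from strooprel.trial_data import CohortData


@dataclass(frozen=True)
class ConditionStats:
    mean_rt_ms: float  # NaN when no correct trial of the type
    pct_correct: float
    n_trials: int


@dataclass
class ConditionSummary:
    """Per-trial-type statistics for one participant-session."""

    by_type: dict[str, ConditionStats] = field(default_factory=dict)

    def __getitem__(self, trial_type: str) -> ConditionStats:
        return self.by_type[trial_type]

    def __contains__(self, trial_type: str) -> bool:
        return trial_type in self.by_type


@dataclass(frozen=True)
class CostScore:
    """Interference costs: incongruent minus congruent."""

    rt_cost: float  # milliseconds
    error_cost: float  # percentage points


@dataclass(frozen=True)
class ShapeStats:
    skewness: float
    excess_kurtosis: float  # NaN for n < 4 (adjusted estimator undefined)


def summarize_conditions(
    session_trials: pd.DataFrame, rt_on_correct_only: bool = True
) -> ConditionSummary:
    """Summarize one participant-session's (screened) trials per trial type.

    Mean RT is over correct trials only by default (configurable); percent
    correct is over all kept trials of the type.  A type with zero correct
    trials gets a NaN mean RT.
    """
    out = ConditionSummary()
    for tt, grp in session_trials.groupby("trial_type"):
        n = len(grp)
        correct = grp["correct"].to_numpy()
        rts = grp["rt_ms"].to_numpy()
        if rt_on_correct_only:
            rts = rts[correct]
        mean_rt = float(rts.mean()) if len(rts) else math.nan
        out.by_type[str(tt)] = ConditionStats(
            mean_rt_ms=mean_rt,
            pct_correct=100.0 * float(correct.mean()),
            n_trials=n,
        )
    return out


def cost_scores(summary: ConditionSummary) -> CostScore:
    """Interference costs from a condition summary (incongruent - congruent)."""
    for needed in ("congruent", "incongruent"):
        if needed not in summary:
            raise ParameterError(f"cost requires a {needed!r} summary")
    con, inc = summary["congruent"], summary["incongruent"]
    return CostScore(
        rt_cost=inc.mean_rt_ms - con.mean_rt_ms,
        error_cost=(100.0 - inc.pct_correct) - (100.0 - con.pct_correct),
    )


def shape_stats(rts: np.ndarray | pd.Series) -> ShapeStats:
    """Adjusted Fisher-Pearson skewness and excess kurtosis of a participant's
    RT distribution.  Requires >= 3 values with positive SD; the adjusted
    kurtosis additionally needs n >= 4 and is NaN below that.
    """
    x = np.asarray(rts, dtype=float)
    if len(x) < 3:
        raise ParameterError("shape statistics need at least 3 values")
    if x.std(ddof=1) == 0.0:
        raise ParameterError("shape statistics undefined for zero-variance data")
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False)) if len(x) >= 4 else math.nan
    return ShapeStats(skewness=skew, excess_kurtosis=kurt)


def participant_scores(
    screened: ScreenedCohort | CohortData, rt_on_correct_only: bool = True
) -> pd.DataFrame:
    """Tidy per-participant-session scores for the whole cohort.

    Columns: participant_id, arm, session, rt_cost, error_cost, plus
    ``<type>_rt`` / ``<type>_pct_correct`` / ``<type>_n`` per trial type.
    """
    trials = screened.trials if hasattr(screened, "trials") else screened
    rows = []
    for (pid, s), grp in trials.groupby(["participant_id", "session"]):
        summary = summarize_conditions(grp, rt_on_correct_only)
        row: dict = {
            "participant_id": pid,
            "arm": grp["arm"].iloc[0],
            "session": int(s),
        }
        try:
            cost = cost_scores(summary)
            row["rt_cost"] = cost.rt_cost
            row["error_cost"] = cost.error_cost
        except ParameterError:
            row["rt_cost"] = math.nan
            row["error_cost"] = math.nan
        for tt, st in summary.by_type.items():
            row[f"{tt}_rt"] = st.mean_rt_ms
            row[f"{tt}_pct_correct"] = st.pct_correct
            row[f"{tt}_n"] = st.n_trials
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_cost_table(
    screened: ScreenedCohort | CohortData, rt_on_correct_only: bool = True
) -> pd.DataFrame:
    """Per-arm, per-session means and SDs of costs and condition summaries,
    mirroring a descriptive-statistics table.  Indexed by (arm, session).
    """
    scores = participant_scores(screened, rt_on_correct_only)
    if scores.empty:
        return pd.DataFrame()
    value_cols = [
        c
        for c in scores.columns
        if c not in ("participant_id", "arm", "session") and not c.endswith("_n")
    ]
    parts = []
    for (arm, s), grp in scores.groupby(["arm", "session"]):
        if grp.empty:
            warnings.warn(f"empty arm/session cell ({arm}, {s}) omitted", stacklevel=2)
            continue
        row: dict = {"arm": arm, "session": int(s), "n_participants": len(grp)}
        for c in value_cols:
            row[f"{c}_mean"] = float(grp[c].mean())
            row[f"{c}_sd"] = float(grp[c].std(ddof=1)) if len(grp) > 1 else math.nan
        parts.append(row)
    return pd.DataFrame(parts).set_index(["arm", "session"]).sort_index()
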