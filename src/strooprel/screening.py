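"""Trial trimming and participant exclusion cascade with an audit ledger.

Cascade order (fixed):

1. drop participants missing a session (when ``require_both_sessions``);
2. per participant-session, remove trials with
   ``rt > mean + trial_sd_k * SD`` (mean/SD over that participant-session's
   own trials, sample SD);
3. remove remaining trials slower than ``rt_cap_ms``;
4. on the trimmed data, per session, flag participants whose total incorrect
   count exceeds the group mean by more than ``error_sd_k`` SDs, or whose
   mean RT exceeds the group mean-of-means by more than
   ``slow_participant_sd_k`` SDs; a participant flagged at either session is
   excluded entirely.

Screening is one-shot: thresholds are not recomputed after exclusions, so
re-screening a screened cohort can remove further data and idempotence is
*not* guaranteed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from strooprel._errors import ParameterError
from strooprel.trial_data import CohortData, SessionPlan

RULE_TRIAL_SD = "trial_sd"
RULE_RT_CAP = "rt_cap"
RULE_ERRORS = "participant_errors"
RULE_SLOW = "participant_slow"
RULE_INCOMPLETE = "incomplete_sessions"


@dataclass(frozen=True)
class ScreeningConfig:
    trial_sd_k: float = 3.0
    rt_cap_ms: float = 2000.0
    error_sd_k: float = 1.0
    slow_participant_sd_k: float = 3.0
    require_both_sessions: bool = True
    #: compute the participant error/slow screens on trimmed (True) or raw data
    flags_on_trimmed: bool = True

    def validate(self) -> None:
        for name in ("trial_sd_k", "rt_cap_ms", "error_sd_k", "slow_participant_sd_k"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass
class ScreeningReport:
    """Audit ledger: what was removed, by which rule, and totals."""

    n_trials_input: int = 0
    n_trials_kept: int = 0
    #: (participant_id, session, rule) -> count of removed trials
    removed_trials: dict[tuple[str, int, str], int] = field(default_factory=dict)
    #: participant_id -> sorted list of triggering rules
    excluded_participants: dict[str, list[str]] = field(default_factory=dict)
    n_participants_input: int = 0
    n_participants_kept: int = 0

    @property
    def n_trials_removed(self) -> int:
        return self.n_trials_input - self.n_trials_kept

    def removed_by_rule(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_, _, rule), k in self.removed_trials.items():
            out[rule] = out.get(rule, 0) + k
        return out

    def to_dict(self) -> dict:
        return {
            "n_trials_input": self.n_trials_input,
            "n_trials_kept": self.n_trials_kept,
            "n_trials_removed": self.n_trials_removed,
            "removed_by_rule": self.removed_by_rule(),
            "removed_trials": [
                {"participant_id": p, "session": s, "rule": r, "count": k}
                for (p, s, r), k in sorted(self.removed_trials.items())
            ],
            "excluded_participants": {
                p: rules for p, rules in sorted(self.excluded_participants.items())
            },
            "n_participants_input": self.n_participants_input,
            "n_participants_kept": self.n_participants_kept,
        }


@dataclass
class ScreenedCohort:
    """Cohort surviving the cascade, with its ledger attached."""

    cohort: CohortData
    report: ScreeningReport

    @property
    def trials(self) -> pd.DataFrame:
        return self.cohort.trials

    @property
    def plan(self) -> SessionPlan:
        return self.cohort.plan


def trim_trials(
    session_trials: pd.DataFrame, cfg: ScreeningConfig = ScreeningConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trim one participant-session's trials.

    Returns ``(kept, removed)`` where ``removed`` carries a ``rule`` column.
    Step 1 removes trials above ``mean + trial_sd_k * SD`` of this
    participant-session; step 2 removes *remaining* trials above
    ``rt_cap_ms``.  With fewer than 2 trials the SD is undefined and the
    input passes through with a warning.
    """
    cfg.validate()
    df = session_trials
    if len(df) < 2:
        warnings.warn(
            "fewer than 2 trials: SD undefined, passing trials through unscreened",
            stacklevel=2,
        )
        removed = df.iloc[0:0].copy()
        removed["rule"] = pd.Series(dtype=str)
        return df, removed

    rt = df["rt_ms"].to_numpy()
    thresh = rt.mean() + cfg.trial_sd_k * rt.std(ddof=1)
    sd_mask = rt > thresh
    cap_mask = ~sd_mask & (rt > cfg.rt_cap_ms)

    removed = df[sd_mask | cap_mask].copy()
    removed["rule"] = np.where(sd_mask[sd_mask | cap_mask], RULE_TRIAL_SD, RULE_RT_CAP)
    kept = df[~(sd_mask | cap_mask)]
    return kept, removed


def flag_participants(
    trials: pd.DataFrame, cfg: ScreeningConfig = ScreeningConfig()
) -> dict[str, list[str]]:
    """Flag participants on (trimmed) trials; returns pid -> triggering rules.

    Per session: a participant is flagged if their total incorrect count
    exceeds the group mean by more than ``error_sd_k`` sample SDs, or their
    mean RT exceeds the group mean-of-means by more than
    ``slow_participant_sd_k`` sample SDs.  Flagged at either session =>
    excluded entirely.
    """
    cfg.validate()
    flags: dict[str, set[str]] = {}
    for _, sess in trials.groupby("session"):
        per = sess.groupby("participant_id").agg(
            n_incorrect=("correct", lambda c: int((~c).sum())),
            mean_rt=("rt_ms", "mean"),
        )
        if len(per) < 2:
            warnings.warn(
                "fewer than 2 participants in a session: no group-level exclusions",
                stacklevel=2,
            )
            continue
        err_thresh = per["n_incorrect"].mean() + cfg.error_sd_k * per["n_incorrect"].std(
            ddof=1
        )
        rt_thresh = per["mean_rt"].mean() + cfg.slow_participant_sd_k * per[
            "mean_rt"
        ].std(ddof=1)
        for pid in per.index[per["n_incorrect"] > err_thresh]:
            flags.setdefault(pid, set()).add(RULE_ERRORS)
        for pid in per.index[per["mean_rt"] > rt_thresh]:
            flags.setdefault(pid, set()).add(RULE_SLOW)
    return {pid: sorted(rules) for pid, rules in flags.items()}


def apply_screening(
    cohort: CohortData, cfg: ScreeningConfig = ScreeningConfig()
) -> tuple[ScreenedCohort, ScreeningReport]:
    """Run the full cascade; kept + removed trial counts always reconcile."""
    cfg.validate()
    report = ScreeningReport(
        n_trials_input=cohort.n_trials,
        n_participants_input=len(cohort.participants()),
    )
    df = cohort.trials
    if df.empty:
        screened = ScreenedCohort(CohortData(df, cohort.plan), report)
        return screened, report

    # stage 1: both-sessions filter
    if cfg.require_both_sessions:
        complete = set(cohort.complete_participants())
        incomplete = [p for p in cohort.participants() if p not in complete]
        for pid in incomplete:
            report.excluded_participants[pid] = [RULE_INCOMPLETE]
            sub = df[df["participant_id"] == pid]
            for s, grp in sub.groupby("session"):
                report.removed_trials[(pid, int(s), RULE_INCOMPLETE)] = len(grp)
        df = df[df["participant_id"].isin(complete)]

    # stage 2+3: per participant-session trial trimming
    kept_parts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny sessions pass through silently here
        for (pid, s), grp in df.groupby(["participant_id", "session"]):
            kept, removed = trim_trials(grp, cfg)
            kept_parts.append(kept)
            for rule, cnt in removed["rule"].value_counts().items():
                report.removed_trials[(pid, int(s), rule)] = int(cnt)
    trimmed = (
        pd.concat(kept_parts, ignore_index=True) if kept_parts else df.iloc[0:0]
    )

    # stage 4: participant-level flags on trimmed (or raw) data
    flag_input = trimmed if cfg.flags_on_trimmed else df
    flags = flag_participants(flag_input, cfg) if not flag_input.empty else {}
    for pid, rules in flags.items():
        report.excluded_participants[pid] = rules
        sub = trimmed[trimmed["participant_id"] == pid]
        for s, grp in sub.groupby("session"):
            key = (pid, int(s), "+".join(rules))
            report.removed_trials[key] = report.removed_trials.get(key, 0) + len(grp)
    kept_df = trimmed[~trimmed["participant_id"].isin(flags)].reset_index(drop=True)

    report.n_trials_kept = len(kept_df)
    report.n_participants_kept = kept_df["participant_id"].nunique()
    assert report.n_trials_kept + sum(report.removed_trials.values()) == (
        report.n_trials_input
    ), "screening ledger does not reconcile"
    screened = ScreenedCohort(CohortData(kept_df, cohort.plan), report)
    return screened, report
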