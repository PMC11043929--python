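"""Trial-level data model and CSV I/O for two-session interference-task cohorts.

The canonical on-disk format is a UTF-8, comma-separated file with header::

    participant_id,session,arm,trial_index,trial_type,correct,rt_ms

``correct`` is encoded 0/1 and ``rt_ms`` is serialized with at most three
decimals.  ``trial_index`` is 0-based presentation order within a
(participant, session); when absent from an input file it is assigned from
file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from strooprel._errors import RowError, SchemaError

logger = logging.getLogger(__name__)

ARMS: tuple[str, ...] = ("basic", "game")
TRIAL_TYPES: tuple[str, ...] = ("congruent", "neutral", "incongruent")

#: Exact column names of the interchange CSV, in order.
CSV_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "session",
    "arm",
    "trial_index",
    "trial_type",
    "correct",
    "rt_ms",
)

_REQUIRED_COLUMNS = tuple(c for c in CSV_COLUMNS if c != "trial_index")


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus-response event."""

    participant_id: str
    session: int
    arm: str
    trial_index: int
    trial_type: str
    correct: bool
    rt_ms: float

    def __post_init__(self) -> None:
        if self.rt_ms <= 0:
            raise ValueError(f"rt_ms must be positive, got {self.rt_ms}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")


@dataclass(frozen=True)
class SessionPlan:
    """Per-session trial composition."""

    n_per_condition: int = 240
    conditions: tuple[str, ...] = TRIAL_TYPES
    n_sessions: int = 2

    @property
    def trials_per_session(self) -> int:
        return self.n_per_condition * len(self.conditions)


@dataclass
class CohortData:
    """A cohort of trials plus the session plan it was collected under.

    ``trials`` is a DataFrame with the columns of :data:`CSV_COLUMNS`,
    sorted by (participant_id, session, trial_index).
    """

    trials: pd.DataFrame
    plan: SessionPlan = field(default_factory=SessionPlan)

    def __post_init__(self) -> None:
        self.trials = _canonicalize(self.trials)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def participants(self) -> list[str]:
        return sorted(self.trials["participant_id"].unique())

    def sessions(self) -> list[int]:
        return sorted(self.trials["session"].unique())

    def complete_participants(self) -> list[str]:
        """Participants observed in every session of the plan."""
        counts = self.trials.groupby("participant_id")["session"].nunique()
        return sorted(counts.index[counts >= self.plan.n_sessions])

    def arm_of(self) -> pd.Series:
        """participant_id -> arm (constant per participant by invariant)."""
        return self.trials.groupby("participant_id")["arm"].first()

    def session_trials(self, participant_id: str, session: int) -> pd.DataFrame:
        t = self.trials
        return t[(t["participant_id"] == participant_id) & (t["session"] == session)]

    def to_records(self) -> list[TrialRecord]:
        return [
            TrialRecord(
                participant_id=r.participant_id,
                session=int(r.session),
                arm=r.arm,
                trial_index=int(r.trial_index),
                trial_type=r.trial_type,
                correct=bool(r.correct),
                rt_ms=float(r.rt_ms),
            )
            for r in self.trials.itertuples(index=False)
        ]

    @classmethod
    def from_records(
        cls, records: Iterable[TrialRecord], plan: SessionPlan | None = None
    ) -> "CohortData":
        df = pd.DataFrame([vars(r) for r in records], columns=list(CSV_COLUMNS))
        return cls(df, plan or SessionPlan())


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes, enforce cross-row invariants, sort by presentation order."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(CSV_COLUMNS)].copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["session"] = df["session"].astype(np.int64)
    df["arm"] = df["arm"].astype(str)
    df["trial_index"] = df["trial_index"].astype(np.int64)
    df["trial_type"] = df["trial_type"].astype(str)
    df["correct"] = df["correct"].astype(bool)
    df["rt_ms"] = df["rt_ms"].astype(np.float64)

    arms = df.groupby("participant_id")["arm"].nunique()
    bad = arms.index[arms > 1].tolist()
    if bad:
        raise SchemaError(f"conflicting arm values for participant(s): {bad}")

    dup = df.duplicated(subset=["participant_id", "session", "trial_index"])
    if dup.any():
        raise SchemaError(
            f"duplicate trial_index within a participant-session "
            f"({int(dup.sum())} duplicate row(s))"
        )

    df = df.sort_values(
        ["participant_id", "session", "trial_index"], kind="stable"
    ).reset_index(drop=True)
    return df


def read_trials(
    path: str | Path,
    strict: bool = True,
    plan: SessionPlan | None = None,
) -> CohortData:
    """Read a trial CSV into a :class:`CohortData`.

    Parameters
    ----------
    path:
        CSV file with a header row.  ``trial_index`` may be omitted, in which
        case presentation order is taken from file order.
    strict:
        If True, any invalid row (non-positive RT, unknown trial type,
        non-0/1 correctness) raises :class:`RowError` naming the row.
        If False, invalid rows are dropped with a log message.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    bad = pd.Series(False, index=df.index)
    reasons: dict[int, str] = {}

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    m = ~(rt > 0)
    for i in df.index[m]:
        reasons.setdefault(i, f"non-positive or non-numeric rt_ms ({df.at[i, 'rt_ms']!r})")
    bad |= m

    m = ~df["trial_type"].isin(TRIAL_TYPES)
    for i in df.index[m]:
        reasons.setdefault(i, f"unknown trial_type ({df.at[i, 'trial_type']!r})")
    bad |= m

    corr = pd.to_numeric(df["correct"], errors="coerce")
    m = ~corr.isin([0, 1])
    for i in df.index[m]:
        reasons.setdefault(i, f"correct must be 0/1 ({df.at[i, 'correct']!r})")
    bad |= m

    m = ~df["arm"].isin(ARMS)
    for i in df.index[m]:
        reasons.setdefault(i, f"unknown arm ({df.at[i, 'arm']!r})")
    bad |= m

    if bad.any():
        if strict:
            i = int(df.index[bad][0])
            # +2: header line plus 1-based numbering
            raise RowError(f"{path}, row {i + 2}: {reasons[i]}")
        logger.warning(
            "%s: dropping %d invalid row(s) in lenient mode", path, int(bad.sum())
        )
        df = df[~bad]

    df = df.copy()
    df["rt_ms"] = pd.to_numeric(df["rt_ms"])
    df["correct"] = pd.to_numeric(df["correct"]).astype(bool)
    df["session"] = pd.to_numeric(df["session"]).astype(np.int64)
    if "trial_index" not in df.columns:
        df["trial_index"] = df.groupby(["participant_id", "session"]).cumcount()
    return CohortData(df, plan or SessionPlan())


def write_trials(cohort: CohortData, path: str | Path) -> Path:
    """Write a cohort to the canonical CSV; inverse of :func:`read_trials`."""
    path = Path(path)
    out = cohort.trials.copy()
    out["correct"] = out["correct"].astype(int)
    out["rt_ms"] = out["rt_ms"].round(3)
    out.to_csv(path, index=False, columns=list(CSV_COLUMNS))
    return path


def concat_cohorts(cohorts: Sequence[CohortData]) -> CohortData:
    """Concatenate cohorts sharing a session plan."""
    if not cohorts:
        raise ValueError("no cohorts to concatenate")
    return CohortData(
        pd.concat([c.trials for c in cohorts], ignore_index=True), cohorts[0].plan
    )
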