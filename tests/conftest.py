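import numpy as np
import pandas as pd
import pytest

from strooprel.trial_data import CSV_COLUMNS, CohortData, SessionPlan


def make_trials(
    participant_id: str,
    session: int,
    arm: str,
    rts,
    trial_types=None,
    correct=None,
    start_index: int = 0,
) -> pd.DataFrame:
    """Build one participant-session block of trials from explicit RTs."""
    rts = list(rts)
    n = len(rts)
    if trial_types is None:
        trial_types = ["congruent", "neutral", "incongruent"] * (n // 3 + 1)
    if correct is None:
        correct = [True] * n
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "session": session,
            "arm": arm,
            "trial_index": np.arange(start_index, start_index + n),
            "trial_type": list(trial_types)[:n],
            "correct": list(correct)[:n],
            "rt_ms": rts,
        }
    )[list(CSV_COLUMNS)]


def make_cohort(blocks, plan: SessionPlan | None = None) -> CohortData:
    return CohortData(pd.concat(blocks, ignore_index=True), plan or SessionPlan())


@pytest.fixture
def tiny_cohort() -> CohortData:
    """Two participants, two sessions, 6 trials each: minimal valid cohort."""
    blocks = []
    for pid, arm in (("p1", "basic"), ("p2", "game")):
        for s in (1, 2):
            blocks.append(
                make_trials(
                    pid,
                    s,
                    arm,
                    [500.0, 510.5, 620.25, 498.0, 505.125, 633.0],
                    trial_types=[
                        "congruent",
                        "neutral",
                        "incongruent",
                        "congruent",
                        "neutral",
                        "incongruent",
                    ],
                    correct=[True, True, False, True, True, True],
                )
            )
    return make_cohort(blocks, SessionPlan(n_per_condition=2))


@pytest.fixture
def planted_cohort() -> CohortData:
    """Eight participants with three planted screening violations.

    - p1 session 1: bimodal RTs (300/1700) plus one 2500 ms trial that
      survives the per-participant 3-SD rule but exceeds the 2000 ms cap.
    - p2 session 1: tight RTs around 500 plus one 1500 ms trial that exceeds
      mean + 3 SD.
    - p3: 30 incorrect responses at session 1 (everyone else has 2),
      exceeding the 1-SD group error screen.
    """
    n = 90  # 30 per condition
    types = ["congruent", "neutral", "incongruent"] * 30
    blocks = []
    for i in range(1, 9):
        pid = f"p{i}"
        arm = "basic" if i <= 4 else "game"
        for s in (1, 2):
            if pid == "p1" and s == 1:
                rts = [300.0] * 45 + [1700.0] * 44 + [2500.0]
                correct = [True] * n
            elif pid == "p2" and s == 1:
                rts = [495.0, 505.0] * 44 + [500.0, 1500.0]
                correct = [True] * n
            else:
                rts = [480.0 + 2 * j % 60 for j in range(n)]
                n_bad = 30 if (pid == "p3" and s == 1) else 2
                correct = [False] * n_bad + [True] * (n - n_bad)
            blocks.append(make_trials(pid, s, arm, rts, types, correct))
    return make_cohort(blocks, SessionPlan(n_per_condition=30))
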