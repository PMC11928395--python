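import numpy as np
import pandas as pd
import pytest

from relistab import task


@pytest.fixture(scope="session")
def default_schedule():
    return task.generate_schedule(task.TaskConfig(seed=101))


@pytest.fixture(scope="session")
def small_cohort():
    """Two-session cohort of 20 heterogeneous agents, screened sizes kept small."""
    rng = np.random.default_rng(2024)
    return task.simulate_cohort(task.PopulationSpec(), 20, rng=rng)


@pytest.fixture(scope="session")
def stable_cohort():
    """Two-session cohort with no session drift (stable true parameters)."""
    pop = task.PopulationSpec(session2_gain=0.0)
    rng = np.random.default_rng(77)
    return task.simulate_cohort(pop, 30, rng=rng)


def make_trials(choices, outcomes, correct=None, reversals=None, rts=None,
                subject_id="t1", session=1):
    """Build a trial table from explicit per-trial values.

    ``choices`` uses 'A'/'B'/None; ``outcomes`` ±1 (ignored where choice is
    None); ``correct`` defaults to all-'A'.
    """
    n = len(choices)
    correct = ["A"] * n if correct is None else list(correct)
    reversals = [False] * n if reversals is None else list(reversals)
    rts = [500.0] * n if rts is None else list(rts)
    rows = []
    for i in range(n):
        missing = choices[i] is None
        rows.append({
            "subject_id": subject_id, "session": session, "trial": i + 1,
            "correct_stimulus": correct[i],
            "choice": None if missing else choices[i],
            "chose_best": None if missing else choices[i] == correct[i],
            "outcome": None if missing else outcomes[i],
            "rt_ms": None if missing else rts[i],
            "is_reversal": reversals[i],
        })
    return pd.DataFrame(rows)
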