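import numpy as np
import pandas as pd
import pytest

from spinesurvival import SimulationConfig, simulate_population


def make_table(trajectories, days=(-1, 0, 3, 6, 9, 12), group="g"):
    """Build a longitudinal table from explicit per-spine trajectories.

    ``trajectories`` maps spine_id -> sequence over ``days`` with entries
    True (present SP+), False (present SP-), or None (absent).  Head areas
    default to 0.5 µm² where present.
    """
    rows = []
    for spine_id, states in trajectories.items():
        assert len(states) == len(days)
        for day, state in zip(days, states):
            present = state is not None
            rows.append(
                {
                    "spine_id": spine_id,
                    "segment_id": "seg000",
                    "group": group,
                    "day": day,
                    "present": present,
                    "sp_positive": bool(state) if present else pd.NA,
                    "head_area": 0.5 if present else np.nan,
                }
            )
    t = pd.DataFrame(rows)
    t["day"] = t["day"].astype("int64")
    t["sp_positive"] = t["sp_positive"].astype("boolean")
    return t


@pytest.fixture(scope="session")
def default_table():
    """One simulated cohort at the default study conditions."""
    return simulate_population(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def big_sp_neg_table():
    """Large pure SP- cohort observed from day 0, for closed-form checks."""
    config = SimulationConfig(
        n_spines_sp_pos=0,
        n_spines_sp_neg=20000,
        observation_days=(0, 3, 6, 9, 12),
        seed=11,
    )
    return simulate_population(config)
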