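import numpy as np
import pandas as pd
import pytest

from enterodyn import synth


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject default-structure cohort shared across tests."""
    cfg = synth.CohortConfig(n_subjects=60, seed=11)
    profiles = synth.make_profiles(G=30, K=4, dominance=0.45, concentration=150.0)
    traj = synth.simulate_trajectories(cfg)
    counts, meta = synth.simulate_counts(traj, profiles, cfg)
    return cfg, profiles, traj, counts, meta


@pytest.fixture()
def toy_counts():
    """A tiny deterministic 3-taxa x 4-sample count table."""
    return pd.DataFrame(
        [[10, 0, 5, 1], [10, 4, 5, 1], [0, 16, 10, 2]],
        index=["taxA", "taxB", "taxC"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture()
def line_distance():
    """Euclidean distances of 1-D points {0, 1, 10, 11}."""
    pts = np.array([0.0, 1.0, 10.0, 11.0])
    return np.abs(pts[:, None] - pts[None, :])
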