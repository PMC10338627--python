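import numpy as np
import pytest

from paccquant import MigrationSimConfig, Trajectory, simulate_trajectories


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(points, cell_id="c0", area=None, flags=(), dt=30.0):
    """Trajectory from a plain list of (x, y) pairs, sampled every dt minutes."""
    xy = np.asarray(points, dtype=float)
    times = dt * np.arange(len(points))
    return Trajectory(cell_id=cell_id, times=times, xy=xy, area=area, flags=frozenset(flags))


@pytest.fixture
def random_cohort():
    """A moderate unbiased synthetic cohort used by several property tests."""
    cfg = MigrationSimConfig(n_cells=50, drift_bias=0.0, persistence=0.4, seed=99)
    return simulate_trajectories(cfg)
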