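import numpy as np
import pytest

from rangeselect import ReferenceGrid, Trajectory, UtilizationDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def grid_3x3():
    return ReferenceGrid(x0=0.0, y0=0.0, grain=100.0, ncols=3, nrows=3)


@pytest.fixture
def small_ud():
    """UD with masses 0.5 / 0.3 / 0.2 on a 1x3 grid."""
    grid = ReferenceGrid(x0=0.0, y0=0.0, grain=1.0, ncols=3, nrows=1)
    return UtilizationDistribution(grid=grid, score=np.array([[0.5, 0.3, 0.2]]))


def make_traj(x, y, t=None, animal="a", **kw):
    x = np.asarray(x, dtype=float)
    if t is None:
        t = np.arange(x.size) * 3600.0
    return Trajectory(animal_id=animal, t=t, x=x, y=np.asarray(y, dtype=float), **kw)


@pytest.fixture
def traj_factory():
    return make_traj
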