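import numpy as np
import pytest

from corticowalk import sim
from corticowalk.laminar import BoundaryPolyline
from corticowalk.trackstats import Track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def l_track():
    # (0,0) -> (3,0) -> (3,4): d_tot = 7, d_net = 5, over 70 min
    return Track("L", [[0.0, 0.0, 0.0], [30.0, 3.0, 0.0], [70.0, 3.0, 4.0]])


@pytest.fixture
def loop_track():
    return Track("loop", [[0.0, 0.0, 0.0], [30.0, 1.0, 1.0], [60.0, 0.0, 0.0]])


@pytest.fixture
def straight_track():
    return Track("straight", [[0.0, 0.0, 0.0], [5.0, 0.0, 10.0]])


@pytest.fixture
def flat_boundaries():
    vent = BoundaryPolyline([[-100.0, 0.0], [600.0, 0.0]], role="ventricular")
    pial = BoundaryPolyline([[-100.0, 200.0], [600.0, 200.0]], role="pial")
    return vent, pial


@pytest.fixture
def small_control_spec():
    return sim.PopulationSpec(
        n_control=30,
        n_mutant=0,
        params_control=sim.control_params(),
        params_mutant_pure_ko=sim.ko_params(),
        field=sim.control_field(),
    )


def random_tracks(rng, n=100, max_len=30):
    tracks = []
    for i in range(n):
        m = rng.integers(2, max_len)
        t = np.sort(rng.choice(np.arange(1, 400), size=m, replace=False)).astype(float)
        xy = rng.normal(0.0, 20.0, size=(m, 2))
        tracks.append(Track(f"r{i}", np.column_stack([t, xy])))
    return tracks
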