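import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_params():
    from malustar.synthetic import default_markov_params

    return default_markov_params()


@pytest.fixture(scope="session")
def small_dome():
    """Reduced sky dome for experiment-level tests where per-direction
    resolution is not the quantity under test."""
    from malustar.light import soc_weights, turtle_sky

    return soc_weights(turtle_sky(46))


def flat_leaf(area, center=(0.0, 0.0, 0.0)):
    from malustar.geometry import Leaf, _leaf_polygon

    c = np.asarray(center, dtype=float)
    poly = _leaf_polygon(
        area, c, np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    )
    return Leaf(area, c, np.array([0.0, 0.0, 1.0]), poly)


def random_canopy(rng, n=120, extent=0.4, area_range=(1e-3, 4e-3)):
    """Random oriented leaf cloud used by projection tests."""
    from malustar.geometry import Leaf, _leaf_polygon

    leaves = []
    for _ in range(n):
        c = rng.uniform(-extent, extent, 3)
        a = rng.uniform(*area_range)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        u = np.cross(v, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(v, [1.0, 0.0, 0.0])
        u /= np.linalg.norm(u)
        w = np.cross(v, u)
        leaves.append(Leaf(a, c, v, _leaf_polygon(a, c, u, w)))
    return leaves
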