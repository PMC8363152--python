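import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ccpkit", deadline=None, derandomize=True)
settings.load_profile("ccpkit")

from ccpkit.energy import ModelParams
from ccpkit.geometry import SphericalCap
from ccpkit.morphometry import level_background
from ccpkit.synthetic import SyntheticTruth, build_flat_honeycomb, render_topograph


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def honeycomb19():
    """Flat 19-hexagon honeycomb patch (edge 18 nm)."""
    return build_flat_honeycomb(n_rings=2, edge_length=18.0)


@pytest.fixture(scope="session")
def honeycomb_topograph(honeycomb19):
    """Rendered AFM-like image of the 19-hexagon patch (ridge 2 nm, tip 2 nm)."""
    truth = SyntheticTruth(cap=None, mesh=honeycomb19, ridge_height=2.0,
                           tip_radius=2.0, noise_sd=0.1, pixel_size=2.0,
                           shape=(300, 300), seed=7)
    return level_background(render_topograph(truth))


@pytest.fixture(scope="session")
def cap_topograph():
    """Clean rendered spherical cap R=100, h=40 nm (no ridges/tip/noise)."""
    truth = SyntheticTruth(cap=SphericalCap(R=100.0, h=40.0), mesh=None,
                           ridge_height=0.0, tip_radius=0.0, noise_sd=0.0,
                           pixel_size=2.0, shape=(300, 300), seed=0)
    return level_background(render_topograph(truth))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
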