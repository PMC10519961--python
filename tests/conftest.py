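import numpy as np
import pytest

from virthist import phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 256x256 phantom with well-separated in-range nuclei."""
    spec = phantom.PhantomSpec(width=256, height=256, n_nuclei=12,
                               noise_sd=0.0, edge_softness=0.0, seed=3)
    dual, truth = phantom.make_dual_channel(spec)
    return spec, dual, truth


@pytest.fixture(scope="session")
def textured_image():
    """Pseudo-H&E rendering of a noisy phantom, used as registration target."""
    spec = phantom.PhantomSpec(width=128, height=128, n_nuclei=10,
                               noise_sd=0.01, seed=7)
    dual, _ = phantom.make_dual_channel(spec)
    return phantom.make_pseudo_he(dual).rgb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
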