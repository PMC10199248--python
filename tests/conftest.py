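import numpy as np
import pytest

from dotfrac.scheme import build_scheme
from dotfrac.signal_model import CompartmentMixture
from dotfrac.synthetic import default_phantom, generate_phantom


@pytest.fixture(scope="session")
def fig_mixture():
    """Three-compartment grey-matter mixture: free water, tissue, sphere."""
    return CompartmentMixture((0.2, 0.72, 0.08), (3.0, 1.0, 0.1))


@pytest.fixture(scope="session")
def scheme():
    """Default full STE scheme, randomised order, interleaved b0s."""
    return build_scheme(order_seed=1)


@pytest.fixture(scope="session")
def clean_phantom(scheme):
    """Noiseless, drift-free phantom with its truth maps (12^3 grid)."""
    spec = default_phantom(shape=12, sigma=0.0, drift=(1.0,), seed=0)
    dataset, truth = generate_phantom(spec, scheme)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def noisy_phantom(scheme):
    """Default-noise phantom (sigma = S0/50) with drift, 16^3 grid."""
    spec = default_phantom(shape=16, sigma=0.02, seed=0)
    dataset, truth = generate_phantom(spec, scheme)
    return spec, dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
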