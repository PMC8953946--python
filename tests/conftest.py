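import numpy as np
import pytest

from skinetc.fractal import PoreNetworkSpec, rev_geometry


@pytest.fixture(scope="session")
def validation_spec() -> PoreNetworkSpec:
    """Pore network of the validation preset: phi=0.05, straight capillaries."""
    return PoreNetworkSpec.from_porosity(0.05, 5e-6, 5e-4, tortuosity_dim=1.0)


@pytest.fixture(scope="session")
def validation_L0(validation_spec) -> float:
    return rev_geometry(validation_spec).side_length


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240311)


def random_spec(rng: np.random.Generator) -> PoreNetworkSpec:
    """A random valid pore-network spec with well-separated scales."""
    phi = rng.uniform(0.02, 0.95)
    lam_min = 10.0 ** rng.uniform(-6.5, -5.5)
    ratio = 10.0 ** rng.uniform(-3.5, -1.5)
    dt = rng.uniform(1.0, 1.5)
    return PoreNetworkSpec.from_porosity(
        phi, lam_min, lam_min / ratio, tortuosity_dim=dt, criterion_threshold=1.0
    )
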