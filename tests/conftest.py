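import numpy as np
import pytest

from dwiphasor import (
    IVIM_BVALUES,
    PHANTOM_DIFFUSIVITIES,
    SamplingScheme,
    make_equidistant_scheme,
)


@pytest.fixture(scope="session")
def scheme21() -> SamplingScheme:
    """The 21-point equidistant 0-2500 s/mm2 unmixing scheme."""
    return make_equidistant_scheme(21, 2500)


@pytest.fixture(scope="session")
def ivim_scheme() -> SamplingScheme:
    """The 15-b-value clinical IVIM scheme (0-1000 s/mm2)."""
    return SamplingScheme(IVIM_BVALUES)


@pytest.fixture(scope="session")
def phantom_diffusivities() -> tuple[float, float, float]:
    return PHANTOM_DIFFUSIVITIES


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)
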