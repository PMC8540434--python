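import numpy as np
import pytest

from pulsewave import FirSpec, design_fir, default_fir_spec


@pytest.fixture(scope="session")
def resolved_spec() -> FirSpec:
    """Band-pass spec whose tap count resolves 0.7-9.5 Hz at 5 kHz."""
    return default_fir_spec(5000.0)


@pytest.fixture(scope="session")
def resolved_taps(resolved_spec) -> np.ndarray:
    return design_fir(resolved_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
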