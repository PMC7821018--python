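import numpy as np
import pytest

from mworient import PhantomSpec, SequenceParams, T2Grid, generate_dataset


@pytest.fixture(scope="session")
def seq48():
    """Standard 48-echo CPMG timing (TE = 8 ms)."""
    return SequenceParams(n_echoes=48, te_ms=8.0, tr_ms=1073.0)


@pytest.fixture(scope="session")
def grid40():
    return T2Grid.log_spaced(8.0, 2000.0, 40)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Small noiseless phantom: 16 interior angle columns, one TR."""
    spec = PhantomSpec(shape=(18, 4, 4), tr_list_ms=(1073.0,), noise="none", seed=3)
    return generate_dataset(spec)
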