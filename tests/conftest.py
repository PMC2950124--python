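import numpy as np
import pytest

from microtem.synthetic_data import vnc_fixture


@pytest.fixture(scope="session")
def vnc():
    """The deterministic VNC-like dense microvolume (85 µm³, 170 elements)."""
    return vnc_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
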