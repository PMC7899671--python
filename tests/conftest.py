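import numpy as np
import pytest

import chanlink as cl


@pytest.fixture
def l9t_params() -> cl.MWCParams:
    """Fitted MWC parameters of the spontaneously active L9'T background."""
    return cl.reference_data.fitted_mwc_params("L9'T")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
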