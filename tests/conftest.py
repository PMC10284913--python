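import numpy as np
import pytest

from fractumor.reference import REFERENCE_PARAMS, reference_spec


@pytest.fixture(scope="session")
def day_grid_coarse():
    """Uniform 0.1-day grid over the 18-day observation window."""
    return np.round(np.arange(0, 18.0001, 0.1), 10)


@pytest.fixture(scope="session")
def day_grid_fine():
    """Uniform 0.01-day grid over the 18-day observation window."""
    return np.round(np.arange(0, 18.0001, 0.01), 10)


@pytest.fixture(params=sorted({k for k, _ in REFERENCE_PARAMS}, key=lambda k: k.value))
def reference_model_treated(request):
    return reference_spec(request.param, "treated")


@pytest.fixture(params=sorted({k for k, _ in REFERENCE_PARAMS}, key=lambda k: k.value))
def reference_model_untreated(request):
    return reference_spec(request.param, "untreated")
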