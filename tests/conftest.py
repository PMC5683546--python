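import pytest

from ubt_impact import load_fitted_hidden, reference_config
from ubt_impact.calibration import load_targets


@pytest.fixture(scope="session")
def fitted_hidden():
    return load_fitted_hidden()


@pytest.fixture(scope="session")
def ref_config(fitted_hidden):
    """Published cohort and UBT inputs with the reference calibrated internals."""
    return reference_config(hidden=fitted_hidden)


@pytest.fixture(scope="session")
def default_config():
    """Published inputs with the pre-calibration placeholder internals."""
    return reference_config()


@pytest.fixture(scope="session")
def printed_targets():
    return load_targets()
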