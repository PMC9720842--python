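import numpy as np
import pytest

from liquidhcc.reproduce import reconstruct_control_gnb4
from liquidhcc.synthetic import default_ct_params


@pytest.fixture(scope="session")
def control_gnb4_vector() -> np.ndarray:
    """The 11 control-group GNB4 Ct values reconstructed from the printed
    summary row (mean 44.46, SD 1.78, median 45, ceiling 45)."""
    return reconstruct_control_gnb4().values


@pytest.fixture(scope="session")
def hcc_ct_params():
    return default_ct_params("hcc")


@pytest.fixture(scope="session")
def control_ct_params():
    return default_ct_params("control")
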