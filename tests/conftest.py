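import numpy as np
import pytest

from linlogfit import DoseResponseTable, LinLogParams, SyntheticDesign, linlog_eval


@pytest.fixture
def ref_params():
    """The reference parameter set with a well-separated rise-dip-rise."""
    return LinLogParams(a=0.0, b=1.0, c=10.0, d=100.0, f=1.0)


@pytest.fixture
def noiseless_table(ref_params):
    """12 exact points on the reference curve over [0.5, 6]."""
    x = np.arange(0.5, 6.01, 0.5)
    return DoseResponseTable(x, linlog_eval(ref_params, x))


@pytest.fixture
def default_design():
    return SyntheticDesign()  # 6 levels over 77-127, 8 reps, 3% noise
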