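import pytest

from aortafrac.constitutive import gent, neo_hookean
from aortafrac.geometry import AortaGeometry


@pytest.fixture
def op_geom():
    """The trend-study operating point: H2/R=0.2, H1/H2=0.5, alpha=30 deg."""
    return AortaGeometry.from_ratios(0.2, 0.5, 30.0)


@pytest.fixture
def nh():
    return neo_hookean()


@pytest.fixture
def gent1():
    return gent(1.0)
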