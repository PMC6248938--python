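import pytest
from hypothesis import settings

from mkmrbe import builtin_parameters

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

# printed iso-survival RBE values for the NCI-H460 FF/FFF study conditions:
# (beam, dose Gy, delivery time min) -> RBE
HEADLINE_RBE = {
    ("FF", 2.0, 5.0): 0.998,
    ("FF", 2.0, 60.0): 0.974,
    ("FF", 8.0, 5.0): 0.996,
    ("FF", 8.0, 60.0): 0.951,
    ("FFF", 2.0, 5.0): 0.997,
    ("FFF", 2.0, 60.0): 0.972,
    ("FFF", 8.0, 5.0): 0.995,
    ("FFF", 8.0, 60.0): 0.949,
}


@pytest.fixture(scope="session")
def headline_rbe():
    return HEADLINE_RBE


@pytest.fixture(scope="session")
def beams():
    return builtin_parameters()


@pytest.fixture(scope="session")
def ff(beams):
    return beams["FF"]


@pytest.fixture(scope="session")
def fff(beams):
    return beams["FFF"]
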