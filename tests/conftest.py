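import pytest

from smokekin import ArrheniusParameters, ConsecutiveModel


@pytest.fixture
def es1_arrhenius() -> ArrheniusParameters:
    """Destruction Arrhenius parameters of the ES1 cigarette (kJ -> J)."""
    return ArrheniusParameters(Ea=108_850.0, A=2.1e6)


@pytest.fixture
def sm1_arrhenius() -> ArrheniusParameters:
    """Destruction Arrhenius parameters of the SM1 cigarette."""
    return ArrheniusParameters(Ea=136_520.0, A=3.0e7)


@pytest.fixture
def es1_model() -> ConsecutiveModel:
    """Series-reaction model with the printed ES1 rate constants."""
    return ConsecutiveModel(k1=1.11, k2=0.13, nic0=8.0e8, t=2.0)
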