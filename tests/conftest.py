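import pytest

from timerr import TimeNoiseParams, TimerrParams


@pytest.fixture
def env():
    """Reference environment: 10-unit lookback, experienced rate 0.5."""
    return TimerrParams(T_ime=10.0, a_est=0.5)


@pytest.fixture
def noise():
    """Reference noise: scalar-timing slope 0.1, read-out 0.05, magnitude Weber 0.05."""
    return TimeNoiseParams(k=0.1, c=0.05, l=0.05)
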