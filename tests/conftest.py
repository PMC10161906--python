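import numpy as np
import pytest

from dscqc import SignalTimeCourse


@pytest.fixture
def example_signal():
    """Plateau-bolus-plateau course: baseline 100 (5 dyn), dip to 60, back."""
    values = [100.0] * 5 + [90, 70, 60, 70, 90] + [100.0] * 5
    return SignalTimeCourse(np.array(values), tr_seconds=1.0)


@pytest.fixture
def noisy_baseline_signal():
    """Same morphology with baseline [101,99,101,99,100] (sample SD = 1)."""
    values = [101.0, 99, 101, 99, 100] + [90, 70, 60, 70, 90] + [100.0] * 5
    return SignalTimeCourse(np.array(values), tr_seconds=1.0)


@pytest.fixture
def plateau90_signal():
    """Post-bolus plateau at 90 instead of 100."""
    values = [100.0] * 5 + [90, 70, 60, 70] + [90.0] * 6
    return SignalTimeCourse(np.array(values), tr_seconds=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
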