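import numpy as np
import pytest
from scipy import signal

from audiomotor import EnvelopeSignal, make_accelerating_schedule
from audiomotor.simulate import render_stimulus_envelope


@pytest.fixture(scope="session")
def slow_schedule_short():
    """A 60-token slow accelerating sequence (~30 s), cheap to analyze."""
    return make_accelerating_schedule(1.92, 2.08, 0.04, 12)


@pytest.fixture(scope="session")
def slow_stim_env(slow_schedule_short):
    return render_stimulus_envelope(slow_schedule_short, "syllable")


def noise_envelope(rng, duration=45.0, fs=100.0):
    """Independent white-noise-modulated envelope (rectified low-passed noise)."""
    x = rng.standard_normal(int(duration * fs))
    sos = signal.butter(4, 10, "low", fs=fs, output="sos")
    return EnvelopeSignal(np.abs(signal.sosfiltfilt(sos, x)), fs)
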