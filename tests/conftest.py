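import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from spikefield.session import LfpSignal, SpikeUnit
from spikefield.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def vehicle_session():
    """One short synthetic vehicle session shared across read-only tests."""
    return generate_session("VEHICLE", seed=11, base=SynthConfig(duration_s=60))


@pytest.fixture
def sine_lfp():
    """Noiseless 8 Hz, 50 µV sinusoid at 1 kHz for 60 s."""
    fs = 1000.0
    t = np.arange(int(60 * fs)) / fs
    return LfpSignal(50.0 * np.sin(2 * np.pi * 8.0 * t), fs=fs, band="lfp")


def make_unit(times, width_ms=0.8, fs_wf=25000.0):
    n = max(8, int(round(4 * width_ms / 1000 * fs_wf)))
    wf = -np.hanning(n)
    return SpikeUnit(spike_times=np.asarray(times, dtype=float), waveform=wf,
                     waveform_fs=fs_wf, trough_to_peak_ms=width_ms,
                     unit_id="test")


@pytest.fixture
def unit_factory():
    return make_unit
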