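import numpy as np
import pytest

import pulsereplay as pr
from pulsereplay.benchmark import run_benchmark


@pytest.fixture(scope="session")
def bench_result():
    """One full benchmark run (10 training / 8 held-out sets per force
    range, linear and ANN models) shared by the end-to-end tests."""
    return run_benchmark(seed=1, compare=True)


@pytest.fixture
def moderate_pulse():
    """Noiseless, jitter-free 8 s moderate-force pulse at 1 kHz."""
    params = pr.PulseParams.for_force_level("moderate", seed=0,
                                            beat_jitter=0.0, noise_sd=0.0)
    return pr.generate_pulse(params, duration=8.0, fs=1000.0)


@pytest.fixture
def noisy_pulse():
    """Default moderate-force pulse (noise and jitter on) at 1 kHz."""
    params = pr.PulseParams.for_force_level("moderate", seed=3)
    return pr.generate_pulse(params, duration=8.0, fs=1000.0)


@pytest.fixture
def pulse_wave_250(noisy_pulse):
    """Recorded, downsampled and integrated pulse waveform at 250 Hz."""
    rec = pr.pvdf_record(noisy_pulse, pr.SensorConfig())
    down = pr.mean_filter_downsample(rec, 250.0)
    return pr.integrate_signal(down, detrend=True)
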