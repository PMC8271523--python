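"""Simulated PVDF vibration recorder and the recorder-side utilities.

A PVDF film outputs a voltage proportional to its strain *rate*, so the
simulated recorder differentiates the displacement applied to it; the
displacement waveform is recovered downstream by numerical integration.
This module also provides the mean-filter downsampler used to go from
the 1 kHz acquisition rate to the 250 Hz working rate, the scalar
design score used for the recorder's structure screening (R^2 plus
normalized peak voltage), and the rotating-cam verification protocol
that characterizes recorder fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
from scipy.integrate import cumulative_trapezoid

from . import pulse_synth
from .metrics import align_offset, nrmse, r_squared
from .reports import EvalReport
from .signals import DISPLACEMENT, VOLT, Signal


@dataclass
class SensorConfig:
    """PVDF recorder model: output = sensitivity x displacement rate + noise."""

    sensitivity: float = 1.0   # volts per (displacement unit / s)
    noise_sd: float = 0.0      # volts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def pvdf_record(displacement: Signal, cfg: SensorConfig,
                rng: np.random.Generator | None = None) -> Signal:
    """Record a displacement waveform through the rate-sensing film.

    The voltage is the first-difference derivative (x fs) scaled by the
    sensitivity, with the first sample padded so input and output have
    equal length, plus white Gaussian voltage noise.
    """
    if displacement.unit != DISPLACEMENT:
        raise ValueError("pvdf_record expects a displacement signal")
    d = np.diff(displacement.samples) * displacement.fs
    d = np.concatenate(([d[0]], d))
    v = cfg.sensitivity * d
    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        v = v + rng.normal(0.0, cfg.noise_sd, size=v.size)
    return Signal(v, fs=displacement.fs, unit=VOLT)


def integrate_signal(signal: Signal, detrend: bool = False) -> Signal:
    """Cumulative trapezoidal integral; voltage in, displacement out.

    The first output sample is 0 (the constant of integration is
    unobservable through a rate sensor).  ``detrend=True`` removes the
    best-fit line afterwards, suppressing the random-walk drift that
    integrating voltage noise produces.
    """
    if signal.n < 2:
        raise ValueError("need at least 2 samples to integrate")
    y = cumulative_trapezoid(signal.samples, dx=1.0 / signal.fs, initial=0.0)
    if detrend:
        y = scipy.signal.detrend(y, type="linear")
    return Signal(y, fs=signal.fs, unit=DISPLACEMENT)


def mean_filter_downsample(signal: Signal, target_fs: float) -> Signal:
    """Decimate by averaging non-overlapping windows of fs/target_fs samples."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    ratio = signal.fs / target_fs
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9 * ratio:
        raise ValueError(
            f"fs {signal.fs} is not an integer multiple of target_fs {target_fs}")
    n_out = signal.n // factor
    if n_out < 2:
        raise ValueError("signal too short for this decimation factor")
    trimmed = signal.samples[: n_out * factor]
    out = trimmed.reshape(n_out, factor).mean(axis=1)
    return Signal(out, fs=target_fs, unit=signal.unit)


def taguchi_score(r_squared_value: float, norm_peak_volt: float) -> float:
    """Design score = R^2 of the measured-vs-cam fit + normalized peak voltage."""
    if not (0.0 <= r_squared_value <= 1.0):
        raise ValueError("r_squared must lie in [0, 1]")
    if not (0.0 <= norm_peak_volt <= 1.0):
        raise ValueError("norm_peak_volt must lie in [0, 1]")
    return float(r_squared_value + norm_peak_volt)


def cam_profile(fs: float = 1000.0) -> Signal:
    """One noiseless synthetic beat over 1 s: the 60 rpm cam's lift profile."""
    params = pulse_synth.PulseParams(
        heart_rate=1.0, beat_jitter=0.0, noise_sd=0.0, seed=0)
    return pulse_synth.generate_pulse(params, duration=1.0, fs=fs)


def default_cam_sensor(profile: Signal, noise_fraction: float = 0.02,
                       seed: int = 0) -> SensorConfig:
    """Sensor config whose noise is a fraction of the noiseless peak voltage."""
    clean = pvdf_record(profile, SensorConfig())
    peak = float(np.max(np.abs(clean.samples)))
    return SensorConfig(sensitivity=1.0, noise_sd=noise_fraction * peak, seed=seed)


def cam_verification(cam: Signal, cfg: SensorConfig | None = None,
                     repeats: int = 10,
                     seed: int | None = None) -> EvalReport:
    """Record the rotating cam ``repeats`` times and score each recovery.

    Each repeat records the cam profile through the sensor, integrates
    (with linear detrend) and compares the recovered waveform with the
    cam profile after offset alignment.  Rows mirror the recorder
    verification table: one row per repeat, then Average and S.D.
    available through the report summary.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if cfg is None:
        cfg = default_cam_sensor(cam)
    base_seed = cfg.seed if seed is None else seed
    streams = np.random.SeedSequence(base_seed).spawn(repeats)
    rows = []
    for i, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        rec = pvdf_record(cam, cfg, rng=rng)
        # no detrend: a linear fit to a single-beat record would remove
        # signal, and the integrated-noise drift over 1 s is negligible
        recovered = integrate_signal(rec)
        aligned = align_offset(cam.samples, recovered.samples)
        rows.append(
            {
                "subject": i,
                "force": "cam",
                "nrmse": nrmse(cam.samples, aligned),
                "r_squared": r_squared(cam.samples, aligned),
            }
        )
    return EvalReport(pd.DataFrame(rows))
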