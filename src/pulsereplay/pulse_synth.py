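"""Synthetic radial-pulse displacement waveforms.

A single beat is modelled as a baseline plus three raised-cosine bumps:
the percussion wave (early systolic peak, the largest), the tidal wave
(late systolic shoulder) and the dicrotic bump after the notch.  Beats
are laid end to end with an optional beat-period jitter; additive white
Gaussian noise models measurement roughness.  Amplitude and noise
presets for the three palpation-force regimes follow the clinical
pattern that lightly palpated pulses are faint and noisy while firmer
palpation gives cleaner, larger deflections.

All displacement is in arbitrary units; absolute physical scale is not
meaningful for the record/replay fidelity question this package studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signals import DISPLACEMENT, Signal

#: palpation force ranges in newtons: light (<0.9), moderate (0.9-1.5), heavy (>1.5)
FORCE_RANGES: dict[str, tuple[float, float]] = {
    "light": (0.0, 0.9),
    "moderate": (0.9, 1.5),
    "heavy": (1.5, float("inf")),
}

#: per-regime (percussion amplitude, relative noise sd) presets;
#: light pulses are the faintest and noisiest, heavy the cleanest.
FORCE_PRESETS: dict[str, tuple[float, float]] = {
    "light": (0.4, 0.05),
    "moderate": (1.0, 0.02),
    "heavy": (1.3, 0.01),
}

#: raised-cosine half-widths of the three bumps, as fractions of the beat
_WIDTHS = (0.11, 0.16, 0.10)


def force_level_of(force_newtons: float) -> str:
    """Map a palpation force in newtons to its regime label."""
    if force_newtons <= 0:
        raise ValueError("force must be positive")
    if force_newtons < 0.9:
        return "light"
    if force_newtons <= 1.5:
        return "moderate"
    return "heavy"


@dataclass(frozen=True)
class ForceLevel:
    label: str
    range_newtons: tuple[float, float]

    @classmethod
    def from_label(cls, label: str) -> "ForceLevel":
        return cls(label, FORCE_RANGES[label])


@dataclass
class PulseParams:
    """Morphology, rate and noise parameters of a synthetic pulse train.

    Amplitudes are relative displacement units (percussion largest);
    timing offsets are fractions of the beat period; ``noise_sd`` is the
    additive noise standard deviation relative to ``percussion_amp``.
    """

    heart_rate: float = 1.2            # beats per second, physiologic 0.6-2
    percussion_amp: float = 1.0
    tidal_amp: float = 0.5
    dicrotic_amp: float = 0.25
    percussion_t: float = 0.15
    tidal_t: float = 0.40
    dicrotic_t: float = 0.62
    beat_jitter: float = 0.02          # CV of the beat period
    noise_sd: float = 0.02
    force_level: str = "moderate"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.6 <= self.heart_rate <= 2.0):
            raise ValueError("heart_rate must lie in the physiologic band 0.6-2 Hz")
        if not (self.percussion_amp > self.tidal_amp > self.dicrotic_amp > 0):
            raise ValueError("amplitudes must satisfy percussion > tidal > dicrotic > 0")
        if not (0 <= self.percussion_t < self.tidal_t < self.dicrotic_t < 1):
            raise ValueError("timing offsets must be ordered within the beat")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.beat_jitter < 0:
            raise ValueError("beat_jitter must be non-negative")
        if self.force_level not in FORCE_RANGES:
            raise ValueError(f"unknown force_level {self.force_level!r}")

    @classmethod
    def for_force_level(cls, label: str, seed: int = 0, **overrides) -> "PulseParams":
        """Preset parameters for a palpation-force regime."""
        amp, noise = FORCE_PRESETS[label]
        base = dict(
            percussion_amp=amp,
            tidal_amp=0.5 * amp,
            dicrotic_amp=0.25 * amp,
            noise_sd=noise,
            force_level=label,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


def _bump(phase: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Raised-cosine bump of unit height on the beat phase in [0, 1)."""
    u = (phase - center) / half_width
    out = np.zeros_like(phase)
    mask = np.abs(u) < 1.0
    out[mask] = 0.5 * (1.0 + np.cos(np.pi * u[mask]))
    return out


def beat_template(params: PulseParams, phase: np.ndarray) -> np.ndarray:
    """Noiseless single-beat displacement evaluated at beat phase in [0, 1)."""
    amps = (params.percussion_amp, params.tidal_amp, params.dicrotic_amp)
    centers = (params.percussion_t, params.tidal_t, params.dicrotic_t)
    y = np.zeros_like(phase)
    for a, c, w in zip(amps, centers, _WIDTHS):
        y += a * _bump(phase, c, w)
    return y


def generate_pulse(params: PulseParams, duration: float, fs: float) -> Signal:
    """Generate a pulse displacement waveform.

    Parameters
    ----------
    params
        Morphology/rate/noise parameters; ``params.seed`` makes the
        output deterministic.
    duration
        Record length in seconds (> 0).
    fs
        Sampling rate in Hz; must be at least twice the heart rate.

    Returns
    -------
    Signal
        ``duration * fs`` displacement samples, non-negative relative to
        the zero baseline when ``noise_sd`` is 0.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if fs < 2 * params.heart_rate:
        raise ValueError("fs below the Nyquist bound for the heart rate")

    rng = np.random.default_rng(params.seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # lay down beat onsets with jittered periods until the record is covered
    mean_period = 1.0 / params.heart_rate
    onsets = [0.0]
    periods = []
    while onsets[-1] < duration:
        factor = 1.0 + params.beat_jitter * rng.standard_normal()
        period = mean_period * max(0.5, factor)
        periods.append(period)
        onsets.append(onsets[-1] + period)

    y = np.zeros(n)
    for onset, period in zip(onsets, periods):
        lo = int(np.ceil(onset * fs))
        hi = min(n, int(np.ceil((onset + period) * fs)))
        if lo >= hi:
            continue
        phase = (t[lo:hi] - onset) / period
        y[lo:hi] = beat_template(params, phase)

    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd * params.percussion_amp, size=n)
    return Signal(y, fs=fs, unit=DISPLACEMENT)
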