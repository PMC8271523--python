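"""Simulated piezoelectric-bender stack (the "plant" being driven).

The physical player drives a stack of bimorph benders at up to +/-48 V;
finger pressure on the contact skin suppresses the vibration, and the
voltage-to-displacement map is not perfectly linear.  The simulated
plant captures exactly those features: hard voltage clipping at the
drive limit, a memoryless cubic softening/stiffening term, a
force-dependent gain attenuation, an optional rate-lag hysteresis term
and optional output noise.  The default plant is memoryless, which is
the regime a pointwise (sample-to-sample) inverse model can invert;
hysteresis exists to probe the method's limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensor_sim import SensorConfig, pvdf_record
from .signals import DISPLACEMENT, VOLT, Signal


@dataclass
class PlantConfig:
    linear_gain: float = 0.04        # displacement units per volt
    cubic_coeff: float = 1.0         # relative cubic deviation at v = v_limit
    hysteresis_strength: float = 0.0
    force_damping: float = 0.08      # gain attenuation per newton
    v_limit: float = 48.0            # drive voltage limit (volts)
    output_noise_sd: float = 0.0     # displacement units
    hysteresis_tau: float = 0.02     # lag time constant (s) when hysteresis is on
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linear_gain <= 0:
            raise ValueError("linear_gain must be positive")
        if self.v_limit <= 0:
            raise ValueError("v_limit must be positive")
        if self.force_damping < 0:
            raise ValueError("force_damping must be non-negative")
        if self.output_noise_sd < 0:
            raise ValueError("output_noise_sd must be non-negative")


def apply_drive(voltage: Signal, force: float, cfg: PlantConfig,
                rng: np.random.Generator | None = None) -> Signal:
    """Displacement response of the bender stack to a driving voltage.

    The drive is clipped to +/-v_limit, passed through the memoryless
    core  g * (v + c * v^3 / v_limit^2)  and attenuated by
    (1 - force_damping * force).  With ``hysteresis_strength`` > 0 a
    rate-dependent lag term is added, making the plant non-memoryless.
    """
    if voltage.unit != VOLT:
        raise ValueError("apply_drive expects a voltage signal")
    if force <= 0:
        raise ValueError("force must be positive")
    damping = 1.0 - cfg.force_damping * force
    if damping <= 0:
        raise ValueError("force_damping * force must be < 1")
    v = np.clip(voltage.samples, -cfg.v_limit, cfg.v_limit)
    y = cfg.linear_gain * (v + cfg.cubic_coeff * v ** 3 / cfg.v_limit ** 2)
    if cfg.hysteresis_strength > 0:
        # single-pole lag of the drive; its excess over v adds a
        # loop-opening, rate-sign-dependent offset
        alpha = float(np.exp(-1.0 / (cfg.hysteresis_tau * voltage.fs)))
        lagged = np.empty_like(v)
        acc = v[0]
        for i, vi in enumerate(v):
            acc = alpha * acc + (1.0 - alpha) * vi
            lagged[i] = acc
        y = y + cfg.hysteresis_strength * cfg.linear_gain * (lagged - v)
    y = y * damping
    if cfg.output_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        y = y + rng.normal(0.0, cfg.output_noise_sd, size=y.size)
    return Signal(y, fs=voltage.fs, unit=DISPLACEMENT)


def record_playback(voltage: Signal, force: float, plant: PlantConfig,
                    sensor: SensorConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[Signal, Signal]:
    """Drive the plant and re-record the resulting vibration.

    Mirrors placing the recorder on the player's skin: returns the
    plant displacement and the PVDF voltage it induces.
    """
    displacement = apply_drive(voltage, force, plant, rng=rng)
    recorded = pvdf_record(displacement, sensor, rng=rng)
    return displacement, recorded
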