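"""Waveform fidelity metrics: NRMSE and the coefficient of determination.

NRMSE is the root-mean-square pointwise error divided by the range
(max - min) of the *original* waveform, so 0 is a perfect reproduction
and values are comparable across amplitudes.  R^2 is computed as the
coefficient of determination with the original as reference
(1 - SS_res/SS_tot); the squared-Pearson-correlation variant is
available via ``mode="correlation"`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import as_array


@dataclass(frozen=True)
class MetricPair:
    nrmse: float
    r_squared: float


def _paired(original, reproduced) -> tuple[np.ndarray, np.ndarray]:
    x = as_array(original)
    y = as_array(reproduced)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return x, y


def nrmse(original, reproduced) -> float:
    """RMSE between the two series divided by the original's range."""
    x, y = _paired(original, reproduced)
    rng = float(np.max(x) - np.min(x))
    if rng == 0.0:
        raise ValueError("original signal is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((x - y) ** 2)) / rng)


def r_squared(original, reproduced, mode: str = "determination") -> float:
    """Coefficient of determination of ``reproduced`` against ``original``."""
    x, y = _paired(original, reproduced)
    if x.size < 3:
        raise ValueError("need at least 3 samples for R^2")
    ss_tot = float(np.sum((x - np.mean(x)) ** 2))
    if ss_tot == 0.0:
        raise ValueError("original signal is constant; R^2 undefined")
    if mode == "determination":
        ss_res = float(np.sum((x - y) ** 2))
        return 1.0 - ss_res / ss_tot
    if mode == "correlation":
        sy = float(np.std(y))
        if sy == 0.0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)
    raise ValueError(f"unknown mode {mode!r}")


def align_offset(original, reproduced) -> np.ndarray:
    """Shift ``reproduced`` by a constant so its mean matches the original's.

    A rate sensor is blind to the DC level, so a waveform recovered by
    integration carries an arbitrary additive constant; comparisons
    remove it before scoring.
    """
    x, y = _paired(original, reproduced)
    return y + (np.mean(x) - np.mean(y))


def metric_pair(original, reproduced, align: bool = False) -> MetricPair:
    """NRMSE and R^2 in one call, optionally after offset alignment."""
    y = align_offset(original, reproduced) if align else as_array(reproduced)
    x = as_array(original)
    return MetricPair(nrmse=nrmse(x, y), r_squared=r_squared(x, y))
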