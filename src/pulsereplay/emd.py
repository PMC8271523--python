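"""Empirical mode decomposition with a Cauchy-type sifting stop.

Sifting repeatedly subtracts the mean of the cubic-spline upper and
lower envelopes from the current iterate h_k until the normalized
squared change between consecutive iterates,

    SD_k = sum |h_{k-1} - h_k|^2 / sum |h_{k-1}|^2,

falls below a threshold (0.1 by default).  Each extracted component is
an intrinsic mode function (IMF): its extrema and zero-crossing counts
differ by at most one and its local envelope mean is near zero.  IMFs
are peeled off in order of decreasing characteristic frequency until
the residue is extrema-poor (covers "monotonic") or a maximum count is
reached; an 8 s pulse waveform decomposes into at most seven IMFs.

The decomposition is exactly telescoping, so the IMFs plus the residue
reconstruct the input to floating-point accuracy by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .signals import Signal


class NoEnvelopeError(ValueError):
    """Raised when a signal has too few extrema to build spline envelopes."""


@dataclass
class SiftConfig:
    sd_threshold: float = 0.1
    max_sift_iters: int = 50
    max_imfs: int = 7
    boundary_mode: str = "mirror"   # mirror the two extrema nearest each end

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sift_iters < 1 or self.max_imfs < 1:
            raise ValueError("iteration and IMF caps must be >= 1")
        if self.boundary_mode != "mirror":
            raise ValueError("only 'mirror' boundary handling is implemented")


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    An extremum is a sign change of the first difference; a plateau
    between opposite slopes contributes its midpoint, which keeps the
    detection deterministic on flat-topped data.
    """
    d = np.diff(x)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    maxima, minima = [], []
    for k in range(len(nz) - 1):
        if s[nz[k]] != s[nz[k + 1]]:
            # plateau spans samples nz[k]+1 .. nz[k+1]; take its midpoint
            idx = (nz[k] + 1 + nz[k + 1]) // 2
            (maxima if s[nz[k]] > 0 else minima).append(idx)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def zero_crossings(x: np.ndarray) -> int:
    """Number of sign changes, ignoring exact zeros."""
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _mirrored_knots(idx: np.ndarray, vals: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema knots by mirroring the two nearest each end.

    Mirroring about the first and last samples anchors the splines
    outside the record and tames end swings.
    """
    t = idx.astype(float)
    left_t = 2 * 0.0 - t[:2][::-1]
    left_v = vals[:2][::-1]
    right_t = 2 * (n - 1.0) - t[-2:][::-1]
    right_v = vals[-2:][::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, vals, right_v])
    # drop duplicate knot positions (extremum exactly at an endpoint)
    tt, keep = np.unique(tt, return_index=True)
    return tt, vv[keep]


def envelope_mean(signal: Signal) -> Signal:
    """Mean of the cubic-spline upper and lower envelopes.

    The upper spline interpolates the local maxima and the lower the
    local minima, each extended by mirrored boundary extrema.  Raises
    :class:`NoEnvelopeError` when fewer than two maxima or two minima
    exist; the sifter treats that as termination, not failure.
    """
    x = signal.samples
    maxima, minima = local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise NoEnvelopeError("fewer than two maxima or two minima")
    grid = np.arange(x.size, dtype=float)
    tt, vv = _mirrored_knots(maxima, x[maxima], x.size)
    upper = CubicSpline(tt, vv)(grid)
    tt, vv = _mirrored_knots(minima, x[minima], x.size)
    lower = CubicSpline(tt, vv)(grid)
    return signal.with_samples(0.5 * (upper + lower))


def sift(signal: Signal, cfg: SiftConfig | None = None) -> Signal:
    """Extract one IMF from ``signal`` by iterative envelope-mean removal.

    Iterates h <- h - envelope_mean(h) until the Cauchy-type SD falls
    below ``cfg.sd_threshold`` *and* the component satisfies the two
    defining IMF conditions (the SD rule alone can stop after a pass or
    two on noisy data while the candidate still has badly unbalanced
    extrema), or until the envelope becomes undefined or
    ``cfg.max_sift_iters`` is reached.  Raises :class:`NoEnvelopeError`
    if even the first envelope cannot be built.
    """
    cfg = cfg or SiftConfig()
    h = signal.samples.copy()
    m = envelope_mean(signal).samples   # NoEnvelopeError propagates: no IMF here
    for _ in range(cfg.max_sift_iters):
        h_next = h - m
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_next) ** 2)) / denom if denom > 0 else 0.0
        h = h_next
        if sd < cfg.sd_threshold and is_imf(h):
            break
        try:
            m = envelope_mean(signal.with_samples(h)).samples
        except NoEnvelopeError:
            break
    return signal.with_samples(h)


def is_imf(x: np.ndarray, envelope_tol: float = 0.05,
           boundary_fraction: float = 0.05) -> bool:
    """Check the two IMF conditions with tolerance.

    (1) extrema and zero-crossing counts differ by at most one;
    (2) the local envelope mean, excluding a boundary margin, stays
    within ``envelope_tol`` of the component's amplitude.
    """
    maxima, minima = local_extrema(x)
    n_ext = maxima.size + minima.size
    if abs(n_ext - zero_crossings(x)) > 1:
        return False
    amp = float(np.max(np.abs(x)))
    if amp == 0:
        return True
    try:
        m = envelope_mean(Signal(x, fs=1.0)).samples
    except NoEnvelopeError:
        return True    # too few extrema to define an envelope; nothing to violate
    margin = int(boundary_fraction * x.size)
    core = m[margin: x.size - margin] if x.size > 2 * margin else m
    return bool(np.max(np.abs(core)) <= envelope_tol * amp)


@dataclass
class IMFSet:
    """Ordered IMFs, the residue, per-IMF energy weights and (after
    normalization) the amplitude scales needed to undo it.

    ``weights`` are the per-IMF energies (sum of squared samples)
    normalized to sum to 1; they rank the IMFs by energy intensity.
    ``scales`` is None for a raw decomposition; :func:`normalize_imfs`
    fills it with each IMF's original max-abs value so the weighted
    recombination sum(scales[i] * imfs[i]) restores sum of the original
    IMFs exactly.
    """

    imfs: list[Signal]
    residue: Signal
    weights: np.ndarray
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.residue.n
        if any(imf.n != n or imf.fs != self.residue.fs for imf in self.imfs):
            raise ValueError("all components must share fs and length")
        if self.weights.size != len(self.imfs):
            raise ValueError("one weight per IMF required")
        if self.weights.size and (np.any(self.weights < 0)
                                  or abs(self.weights.sum() - 1.0) > 1e-9):
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> Signal:
        """Element-wise sum of IMFs (undoing any normalization) + residue."""
        total = self.residue.samples.copy()
        scales = self.scales if self.scales is not None else np.ones(self.n_imfs)
        for s, imf in zip(scales, self.imfs):
            total += s * imf.samples
        return self.residue.with_samples(total)

    def detail(self) -> Signal:
        """Sum of the IMFs only (the residue-removed, drivable part)."""
        rec = self.reconstruct()
        return rec.with_samples(rec.samples - self.residue.samples)

    def write_csv(self, path) -> None:
        cols = {f"imf{i + 1}": imf.samples for i, imf in enumerate(self.imfs)}
        cols["residue"] = self.residue.samples
        pd.DataFrame(cols).to_csv(path, index=False)

    def write_weights_json(self, path) -> None:
        payload = {"weights": self.weights.tolist()}
        if self.scales is not None:
            payload["scales"] = self.scales.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _energy_weights(imfs: list[Signal]) -> np.ndarray:
    if not imfs:
        return np.zeros(0)
    e = np.array([float(np.sum(imf.samples ** 2)) for imf in imfs])
    total = e.sum()
    return e / total if total > 0 else e


def decompose(signal: Signal, cfg: SiftConfig | None = None) -> IMFSet:
    """Full decomposition into IMFs plus a monotonic (extrema-poor) residue."""
    cfg = cfg or SiftConfig()
    if signal.n < 16:
        raise ValueError("signal too short to decompose (need >= 16 samples)")
    residue = signal.samples.copy()
    imfs: list[Signal] = []
    while len(imfs) < cfg.max_imfs:
        maxima, minima = local_extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break   # residue is monotonic or extrema-poor: stop
        try:
            imf = sift(signal.with_samples(residue), cfg)
        except NoEnvelopeError:
            break
        imfs.append(imf)
        residue = residue - imf.samples
    return IMFSet(imfs=imfs, residue=signal.with_samples(residue),
                  weights=_energy_weights(imfs))


def normalize_imfs(imfset: IMFSet) -> IMFSet:
    """Scale each IMF to unit maximum absolute value.

    The original max-abs values are kept in ``scales`` so recombination
    can restore amplitude; an all-zero IMF is left unchanged with scale
    and weight 0.
    """
    if imfset.n_imfs == 0:
        raise ValueError("cannot normalize an empty IMF set")
    scales = np.array([float(np.max(np.abs(imf.samples))) for imf in imfset.imfs])
    normed = [
        imf.with_samples(imf.samples / s if s > 0 else imf.samples)
        for imf, s in zip(imfset.imfs, scales)
    ]
    return IMFSet(imfs=normed, residue=imfset.residue,
                  weights=imfset.weights, scales=scales)
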