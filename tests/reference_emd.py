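"""Independent reference empirical mode decomposition.

A deliberately separate, straight-line implementation of sifting with
the same Cauchy-type stop rule (SD < 0.1) used as a cross-check oracle
in the tests.  It shares no code with the package: extrema come from
``scipy.signal.argrelextrema``, envelopes from ``CubicSpline`` over
end-mirrored extrema, and the loop structure is written independently.
"""

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema


def _envelope(x, idx, n):
    t = idx.astype(float)
    v = x[idx]
    # mirror the two extrema nearest each end about the record endpoints
    t_ext = np.concatenate([-t[1::-1], t, 2 * (n - 1) - t[:-3:-1]])
    v_ext = np.concatenate([v[1::-1], v, v[:-3:-1]])
    order = np.argsort(t_ext)
    t_ext, v_ext = t_ext[order], v_ext[order]
    keep = np.concatenate([[True], np.diff(t_ext) > 0])
    return CubicSpline(t_ext[keep], v_ext[keep])(np.arange(n))


def _is_mode(h, n, tol=0.05, margin_frac=0.05):
    """The two IMF conditions, checked with this module's own primitives."""
    maxima = argrelextrema(h, np.greater)[0]
    minima = argrelextrema(h, np.less)[0]
    signs = np.sign(h)
    signs = signs[signs != 0]
    crossings = int(np.count_nonzero(np.diff(signs))) if signs.size > 1 else 0
    if abs((maxima.size + minima.size) - crossings) > 1:
        return False
    amp = np.max(np.abs(h))
    if amp == 0 or maxima.size < 2 or minima.size < 2:
        return True
    mean_env = 0.5 * (_envelope(h, maxima, n) + _envelope(h, minima, n))
    margin = int(margin_frac * n)
    core = mean_env[margin:n - margin] if n > 2 * margin else mean_env
    return bool(np.max(np.abs(core)) <= tol * amp)


def reference_emd(x, sd_threshold=0.1, max_imfs=7, max_iters=50):
    """Decompose ``x`` into (imfs, residue) with plain sifting.

    Stops each sift when the Cauchy SD is below threshold and the
    candidate satisfies the IMF conditions, matching the package's
    documented stop rule.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    residue = x.copy()
    imfs = []
    while len(imfs) < max_imfs:
        maxima = argrelextrema(residue, np.greater)[0]
        minima = argrelextrema(residue, np.less)[0]
        if maxima.size < 2 or minima.size < 2:
            break
        h = residue.copy()
        for _ in range(max_iters):
            maxima = argrelextrema(h, np.greater)[0]
            minima = argrelextrema(h, np.less)[0]
            if maxima.size < 2 or minima.size < 2:
                break
            mean_env = 0.5 * (_envelope(h, maxima, n) + _envelope(h, minima, n))
            h_new = h - mean_env
            denom = np.sum(h ** 2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold and _is_mode(h, n):
                break
        imfs.append(h)
        residue = residue - h
    return imfs, residue
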