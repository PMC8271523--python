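"""Uniformly sampled time series with a sampling rate and a unit tag.

``Signal`` is the currency of the whole pipeline: synthetic pulse
displacements, PVDF sensor voltages, driving voltages and replayed
waveforms are all carried in this container.  Displacement is kept in
arbitrary units throughout (the physical system's absolute scale is
irrelevant to the record/replay fidelity question), voltages are in
volts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: unit tag for voltage-valued series
VOLT = "volt"
#: unit tag for displacement-valued series (arbitrary units)
DISPLACEMENT = "displacement"

_UNITS = (VOLT, DISPLACEMENT)


@dataclass
class Signal:
    """A finite, uniformly sampled real-valued time series.

    Parameters
    ----------
    samples
        1-D array of at least two finite values.
    fs
        Sampling rate in Hz, strictly positive.
    unit
        Either :data:`VOLT` or :data:`DISPLACEMENT`.
    """

    samples: np.ndarray
    fs: float
    unit: str = DISPLACEMENT

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a Signal needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {_UNITS}")

    # -- basic views ---------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.samples.size)

    def __len__(self) -> int:
        return self.n

    @property
    def duration(self) -> float:
        """Length of the record in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, unit: str | None = None) -> "Signal":
        """A new Signal sharing fs (and unit unless overridden)."""
        return Signal(np.asarray(samples, dtype=float), self.fs,
                      self.unit if unit is None else unit)

    # -- CSV round trip ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.samples})

    def write_csv(self, path) -> None:
        """Write the two-column ``time_s,value`` CSV format."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, unit: str = DISPLACEMENT) -> "Signal":
        """Read a two-column ``time_s,value`` CSV.

        The sampling rate is recovered from the median spacing of the
        time column; the grid must be uniform to 1 part in 10^3.
        """
        df = pd.read_csv(path)
        if not {"time_s", "value"}.issubset(df.columns):
            raise ValueError("CSV must have columns time_s,value")
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError("time column must be strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > 1e-3 * step:
            raise ValueError("time grid is not uniform")
        return cls(df["value"].to_numpy(dtype=float), fs=1.0 / step, unit=unit)


def as_array(x) -> np.ndarray:
    """Samples of a Signal, or ``x`` itself coerced to a float array."""
    if isinstance(x, Signal):
        return x.samples
    return np.asarray(x, dtype=float)
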