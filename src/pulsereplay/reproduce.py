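"""End-to-end pulse reproduction pipeline and its verification.

Reproduction of a recorded pulse proceeds: downsample the 1 kHz
recording to 250 Hz with a mean filter, integrate (with detrend) to the
pulse waveform, decompose into IMFs, normalize them, map each
normalized IMF through the force range's inverse model to a driving
signal, recombine the driving signals weighted by the IMF amplitude
scales, upsample the combined drive to 1 kHz, play it through the
plant, re-record through the PVDF sensor and integrate — yielding the
replayed waveform.  The residue (the slow trend) is never driven, so
verification compares the replayed waveform against the residue-removed
original on the 250 Hz grid after removing the unobservable DC offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .emd import SiftConfig, decompose, normalize_imfs
from .inverse_model import InverseModel, predict_drive
from .metrics import align_offset, nrmse, r_squared
from .plant_sim import PlantConfig, apply_drive
from .pulse_synth import force_level_of
from .reports import ComparisonReport, EvalReport
from .sensor_sim import SensorConfig, integrate_signal, mean_filter_downsample, pvdf_record
from .signals import DISPLACEMENT, VOLT, Signal


def upsample_linear(signal: Signal, target_fs: float) -> Signal:
    """Linear-interpolation upsampling to an integer multiple of fs."""
    ratio = target_fs / signal.fs
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9 * ratio:
        raise ValueError("target_fs must be an integer multiple of fs")
    t_in = np.arange(signal.n) / signal.fs
    t_out = np.arange(signal.n * factor) / target_fs
    out = np.interp(t_out, t_in, signal.samples)
    return Signal(out, fs=target_fs, unit=signal.unit)


def reproduce_pulse(recorded: Signal, force: float,
                    models: dict[str, InverseModel],
                    plant: PlantConfig, sensor: SensorConfig,
                    sift_cfg: SiftConfig | None = None,
                    native_fs: float = 1000.0,
                    working_fs: float = 250.0,
                    rng: np.random.Generator | None = None,
                    return_details: bool = False):
    """Reproduce one recorded pulse through the full replay chain.

    Parameters
    ----------
    recorded
        Voltage signal from the recorder at ``native_fs``.
    force
        Palpation force in newtons; selects the inverse model.
    models
        Mapping from force-level label to a trained inverse model.

    Returns
    -------
    (drive, replayed)
        The combined driving voltage and the replayed displacement
        waveform, both at ``native_fs``.  With ``return_details=True`` a
        third element carries the intermediate products, including the
        residue-removed original waveform on the working grid.
    """
    if recorded.unit != VOLT:
        raise ValueError("reproduce_pulse expects a recorded voltage signal")
    if abs(recorded.fs - native_fs) > 1e-9 * native_fs:
        raise ValueError(f"recorded signal must be sampled at {native_fs} Hz")
    sift_cfg = sift_cfg or SiftConfig()
    level = force_level_of(force)
    if level not in models:
        raise KeyError(f"no inverse model for force level {level!r}")
    model = models[level]

    down = mean_filter_downsample(recorded, working_fs)
    wave = integrate_signal(down, detrend=True)
    bank = normalize_imfs(decompose(wave, sift_cfg))

    combined = np.zeros(wave.n)
    for scale, imf in zip(bank.scales, bank.imfs):
        drive_i = predict_drive(model, imf)
        combined += scale * drive_i.samples
    combined = np.clip(combined, -plant.v_limit, plant.v_limit)

    drive = upsample_linear(Signal(combined, fs=working_fs, unit=VOLT), native_fs)
    played = apply_drive(drive, force, plant, rng=rng)
    re_recorded = pvdf_record(played, sensor, rng=rng)
    # mean-filter the re-recording to the working rate, then integrate;
    # no detrend here — it would distort the slow IMF content, and the
    # unobservable offset is removed at comparison time anyway
    replayed = integrate_signal(mean_filter_downsample(re_recorded, working_fs))

    if return_details:
        details = {
            "waveform": wave,
            "imfset": bank,
            "original_detail": bank.detail(),   # residue-removed original
            "played": played,
        }
        return drive, replayed, details
    return drive, replayed


def verify(originals: list[Signal], replayed: list[Signal],
           force_levels: list[str] | None = None,
           subjects: list | None = None) -> EvalReport:
    """Score each replayed waveform against its original.

    Replayed waveforms at a higher rate are mean-filter downsampled to
    the original's grid; the unobservable DC offset is removed before
    computing NRMSE and R^2.
    """
    if len(originals) != len(replayed):
        raise ValueError("originals and replayed must have equal counts")
    if force_levels is None:
        force_levels = ["all"] * len(originals)
    if subjects is None:
        subjects = list(range(1, len(originals) + 1))
    rows = []
    for subject, level, orig, rep in zip(subjects, force_levels, originals, replayed):
        if rep.fs != orig.fs:
            rep = mean_filter_downsample(rep, orig.fs)
        if rep.n != orig.n:
            raise ValueError("length mismatch after alignment to the working grid")
        aligned = align_offset(orig.samples, rep.samples)
        rows.append({
            "subject": subject,
            "force": level,
            "nrmse": nrmse(orig.samples, aligned),
            "r_squared": r_squared(orig.samples, aligned),
        })
    return EvalReport(pd.DataFrame(rows))


def compare_models(linear_report: EvalReport, ann_report: EvalReport,
                   alpha: float = 0.05, equal_var: bool = True) -> ComparisonReport:
    """Independent two-sample t-tests between two models' metrics.

    Pooled-variance t-tests (Welch via ``equal_var=False``) on NRMSE
    and on R^2, per force level and over all trials.
    """
    if linear_report.n_trials != ann_report.n_trials:
        raise ValueError("reports must cover the same trials")
    groups = list(dict.fromkeys(linear_report.per_trial["force"])) + ["all"]
    rows = []
    for metric in ("nrmse", "r_squared"):
        for group in groups:
            def pick(report):
                df = report.per_trial
                if group != "all":
                    df = df[df["force"] == group]
                return df[metric].to_numpy()
            a, b = pick(linear_report), pick(ann_report)
            if a.size < 2 or b.size < 2:
                raise ValueError("need at least 2 trials per group for a t-test")
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append({
                "metric": metric,
                "group": group,
                "t_statistic": float(t),
                "p_value": float(p),
                "significant": bool(p < alpha),
                "linear_mean": float(np.mean(a)),
                "ann_mean": float(np.mean(b)),
            })
    return ComparisonReport(pd.DataFrame(rows), alpha=alpha)
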