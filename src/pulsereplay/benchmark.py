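"""The default simulated record/replay benchmark.

This module freezes the study conditions everything else reports
against: three palpation-force regimes (0.5, 1.2 and 1.8 N — one
representative force per range), ten 8 s training pulse sets and eight
held-out verification sets per regime, all sampled at 1 kHz and
processed at 250 Hz; a memoryless mildly-cubic plant; a recorder whose
voltage noise is 2% of the peak voltage of a noiseless reference
moderate-force recording.  One inverse model (linear baseline and
1-10-1 ANN) is trained per force regime on the pooled per-IMF data and
verified on the held-out sets via the full reproduction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emd import SiftConfig
from .inverse_model import (FAST_TRAIN, InverseModel, TrainConfig,
                            collect_training_data, fit_ann, fit_linear)
from .plant_sim import PlantConfig
from .pulse_synth import PulseParams, generate_pulse
from .reports import ComparisonReport, EvalReport
from .reproduce import compare_models, reproduce_pulse, verify
from .sensor_sim import SensorConfig, pvdf_record
from .signals import Signal

#: representative palpation force (newtons) for each regime
BENCH_FORCES: dict[str, float] = {"light": 0.5, "moderate": 1.2, "heavy": 1.8}

#: full-scale drive voltage given to a normalized (unit max-abs) IMF
DRIVE_SCALE = 40.0

NATIVE_FS = 1000.0
WORKING_FS = 250.0
DURATION = 8.0
N_TRAIN = 10
N_TEST = 8


def default_plant() -> PlantConfig:
    return PlantConfig()


def default_sift() -> SiftConfig:
    return SiftConfig()


def reference_sensor_noise(noise_fraction: float = 0.02) -> float:
    """Recorder noise in volts: a fraction of the peak voltage of a
    noiseless reference moderate-force recording."""
    params = PulseParams.for_force_level("moderate", seed=0,
                                         beat_jitter=0.0, noise_sd=0.0)
    pulse = generate_pulse(params, DURATION, NATIVE_FS)
    clean = pvdf_record(pulse, SensorConfig())
    return noise_fraction * float(np.max(np.abs(clean.samples)))


def default_sensor(seed: int = 0) -> SensorConfig:
    return SensorConfig(sensitivity=1.0, noise_sd=reference_sensor_noise(), seed=seed)


@dataclass
class BenchmarkResult:
    models: dict[str, dict[str, InverseModel]]    # kind -> level -> model
    reports: dict[str, EvalReport]                # kind -> evaluation report
    comparison: ComparisonReport | None
    training_sets: dict = field(default_factory=dict)

    def mean_nrmse(self, kind: str = "ann") -> float:
        return self.reports[kind].mean("nrmse")

    def mean_r_squared(self, kind: str = "ann") -> float:
        return self.reports[kind].mean("r_squared")


def _subject_pulse(level: str, seed: int, rng: np.random.Generator) -> Signal:
    """One subject's 8 s pulse: regime preset with physiologic variation."""
    hr = float(rng.uniform(0.9, 1.4))
    amp_factor = float(rng.uniform(0.9, 1.1))
    base = PulseParams.for_force_level(level, seed=seed)
    params = PulseParams.for_force_level(
        level, seed=seed, heart_rate=hr,
        percussion_amp=base.percussion_amp * amp_factor,
        tidal_amp=base.tidal_amp * amp_factor,
        dicrotic_amp=base.dicrotic_amp * amp_factor,
    )
    return generate_pulse(params, DURATION, NATIVE_FS)


def run_benchmark(seed: int = 0,
                  kinds: tuple[str, ...] = ("ann",),
                  n_train: int = N_TRAIN,
                  n_test: int = N_TEST,
                  plant: PlantConfig | None = None,
                  sensor: SensorConfig | None = None,
                  sift_cfg: SiftConfig | None = None,
                  train_cfg: TrainConfig | None = None,
                  compare: bool = False) -> BenchmarkResult:
    """Train per-regime inverse models and verify on held-out pulse sets.

    ``kinds`` selects which model families to train ("linear", "ann");
    with ``compare=True`` both are trained and their held-out metrics
    are compared by t-tests.
    """
    if compare:
        kinds = ("linear", "ann")
    plant = plant or default_plant()
    sensor = sensor or default_sensor()
    sift_cfg = sift_cfg or default_sift()
    train_cfg = train_cfg or FAST_TRAIN

    master = np.random.SeedSequence(seed)
    models: dict[str, dict[str, InverseModel]] = {k: {} for k in kinds}
    trials: dict[str, dict] = {k: {"orig": [], "rep": [], "levels": [], "subjects": []}
                               for k in kinds}
    training_sets = {}

    for level_idx, (level, force) in enumerate(BENCH_FORCES.items()):
        level_seq = np.random.SeedSequence((seed, level_idx))
        gen_rng = np.random.default_rng(level_seq.spawn(1)[0])
        noise_rng = np.random.default_rng(level_seq.spawn(1)[0])

        # --- data: record n_train + n_test synthetic pulses at 1 kHz
        recordings = []
        for j in range(n_train + n_test):
            pulse_seed = int(gen_rng.integers(2 ** 31))
            pulse = _subject_pulse(level, pulse_seed, gen_rng)
            recordings.append(pvdf_record(pulse, sensor, rng=noise_rng))
        train_recs, test_recs = recordings[:n_train], recordings[n_train:]

        # --- training data and model fits
        train = collect_training_data(train_recs, force, plant, sensor,
                                      sift_cfg, drive_scale=DRIVE_SCALE,
                                      target_fs=WORKING_FS, rng=noise_rng)
        training_sets[level] = train
        for kind in kinds:
            if kind == "linear":
                models[kind][level] = fit_linear(train)
            elif kind == "ann":
                cfg = TrainConfig(epochs=train_cfg.epochs,
                                  learning_rate=train_cfg.learning_rate,
                                  hidden_neurons=train_cfg.hidden_neurons,
                                  batch_size=train_cfg.batch_size,
                                  seed=int(level_seq.generate_state(1)[0] % (2 ** 31)),
                                  max_points=train_cfg.max_points)
                models[kind][level] = fit_ann(train, cfg)
            else:
                raise ValueError(f"unknown model kind {kind!r}")

        # --- held-out verification through the full replay chain
        for subj, rec in enumerate(test_recs, start=1):
            for kind in kinds:
                _, replayed, details = reproduce_pulse(
                    rec, force, models[kind], plant, sensor,
                    sift_cfg=sift_cfg, native_fs=NATIVE_FS,
                    working_fs=WORKING_FS, rng=noise_rng,
                    return_details=True)
                t = trials[kind]
                t["orig"].append(details["original_detail"])
                t["rep"].append(replayed)
                t["levels"].append(level)
                t["subjects"].append(subj)

    reports = {
        kind: verify(t["orig"], t["rep"], force_levels=t["levels"],
                     subjects=t["subjects"])
        for kind, t in trials.items()
    }
    comparison = None
    if compare:
        comparison = compare_models(reports["linear"], reports["ann"])
    return BenchmarkResult(models=models, reports=reports,
                           comparison=comparison, training_sets=training_sets)
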