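import numpy as np
import pytest

import pulsereplay as pr
from pulsereplay.emd import SiftConfig
from pulsereplay.inverse_model import (FAST_TRAIN, InverseModel, SeriesRecord,
                                       TrainConfig, TrainingSet,
                                       collect_training_data, fit_ann,
                                       fit_linear, predict_drive,
                                       training_error_table)
from pulsereplay.plant_sim import PlantConfig, apply_drive
from pulsereplay.sensor_sim import SensorConfig
from pulsereplay.signals import DISPLACEMENT, VOLT, Signal


def _identity_plant():
    return PlantConfig(linear_gain=1.0, cubic_coeff=0.0, force_damping=0.0)


def _recorded_pulses(n, level="moderate", seed0=100):
    out = []
    for k in range(n):
        params = pr.PulseParams.for_force_level(level, seed=seed0 + k)
        pulse = pr.generate_pulse(params, 8.0, 1000.0)
        out.append(pr.pvdf_record(pulse, SensorConfig()))
    return out


def _pairs_set(P, U, level="moderate"):
    return TrainingSet(level, [SeriesRecord(level, 1, 1, P, U)])


class TestCollectTrainingData:
    def test_protocol_pair_count(self):
        """10 pulse sets x 7 IMF slots x 2000 points = 140,000 pairs."""
        pulses = _recorded_pulses(10)
        train = collect_training_data(pulses, 1.2, _identity_plant(),
                                      SensorConfig(), SiftConfig(max_imfs=7))
        assert len(train.series) == 70
        assert train.n_pairs == 140_000

    def test_single_pulse_single_imf_count(self):
        pulses = _recorded_pulses(1)
        train = collect_training_data(pulses, 1.2, _identity_plant(),
                                      SensorConfig(), SiftConfig(max_imfs=1))
        assert train.n_pairs == 2000

    def test_identity_plant_pairs_are_proportional(self):
        """With a unit-gain plant and noiseless sensor, P tracks U up to
        the linear gain.  The first IMF rides near the Nyquist band of
        the working rate, where the 1 kHz record-and-average chain
        attenuates it, so only correlation is required there; the
        sub-Nyquist IMFs must match almost exactly."""
        pulses = _recorded_pulses(2)
        train = collect_training_data(pulses, 1.2, _identity_plant(),
                                      SensorConfig(), SiftConfig())
        for rec in train.series:
            if np.max(rec.U) == np.min(rec.U):
                continue
            u = rec.U - np.mean(rec.U)
            if rec.imf_index == 1:
                assert np.corrcoef(rec.P, u)[0, 1] > 0.85
            else:
                err = np.sqrt(np.mean((rec.P - u) ** 2))
                assert err < 0.02 * np.max(np.abs(u))

    def test_non_voltage_input_rejected(self):
        bad = Signal(np.zeros(8000) + 1, fs=1000.0, unit=DISPLACEMENT)
        with pytest.raises(ValueError):
            collect_training_data([bad], 1.2, _identity_plant(),
                                  SensorConfig(), SiftConfig())


class TestFitLinear:
    def test_exact_recovery_of_synthetic_line(self):
        P = np.linspace(-2, 2, 500)
        model = fit_linear(_pairs_set(P, 2.0 * P + 1.0))
        assert model.params["gain"] == pytest.approx(2.0, rel=1e-9)
        assert model.params["offset"] == pytest.approx(1.0, rel=1e-9)

    def test_recovers_plant_inverse_gain(self):
        """Noiseless linear-plant data yields the inverse gain to 1e-6."""
        plant = PlantConfig(cubic_coeff=0.0, force_damping=0.0)
        U = np.linspace(-40, 40, 2000)
        P = plant.linear_gain * U
        model = fit_linear(_pairs_set(P, U))
        assert model.params["gain"] == pytest.approx(1.0 / plant.linear_gain,
                                                     rel=1e-6)

    def test_cubic_plant_leaves_residual(self):
        plant = PlantConfig(force_damping=0.0)
        U = np.linspace(-45, 45, 2000)
        P = plant.linear_gain * (U + plant.cubic_coeff * U ** 3 / plant.v_limit ** 2)
        model = fit_linear(_pairs_set(P, U))
        resid = U - model.predict(P)
        assert np.std(resid) > 0.5   # volts; the curvature is real

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(_pairs_set(np.ones(100), np.arange(100.0)))


class TestFitAnn:
    def test_learns_identity_map(self):
        rng = np.random.default_rng(0)
        P = rng.uniform(-1, 1, 4000)
        train = _pairs_set(P, P.copy())
        model = fit_ann(train, TrainConfig(epochs=200, optimizer="lbfgs",
                                           restarts=2, seed=0))
        held = np.linspace(-0.95, 0.95, 200)
        assert pr.nrmse(held, model.predict(held)) < 0.05

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(-1, 1, 2000)
        train = _pairs_set(P, np.tanh(P))
        cfg = TrainConfig(epochs=50, optimizer="lbfgs", seed=7)
        a = fit_ann(train, cfg)
        b = fit_ann(train, cfg)
        for key in ("w1", "b1", "w2"):
            assert np.array_equal(a.params[key], b.params[key])
        assert a.params["b2"] == b.params["b2"]

    def test_closed_loop_inversion_of_cubic_plant(self):
        """Drive predicted from a held-out first-IMF-like target, played
        back through the generating plant, reproduces the target with
        NRMSE < 0.1."""
        plant = PlantConfig(force_damping=0.0)
        rng = np.random.default_rng(2)
        U = rng.uniform(-40, 40, 8000)
        P = plant.linear_gain * (U + plant.cubic_coeff * U ** 3 / plant.v_limit ** 2)
        model = fit_ann(_pairs_set(P, U), FAST_TRAIN)
        t = np.arange(2000) / 250.0
        target = Signal(np.sin(2 * np.pi * 7.0 * t), fs=250.0, unit=DISPLACEMENT)
        drive = predict_drive(model, target)
        replay = apply_drive(drive, force=1e-9 + 1.0, cfg=plant)
        assert pr.nrmse(target.samples, replay.samples) < 0.1

    def test_sgd_path_learns_smooth_map(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(-1, 1, 3000)
        train = _pairs_set(P, 0.5 * P + 0.2 * P ** 3)
        model = fit_ann(train, TrainConfig(epochs=200, optimizer="sgd", seed=1))
        held = np.linspace(-0.9, 0.9, 100)
        assert pr.nrmse(0.5 * held + 0.2 * held ** 3, model.predict(held)) < 0.1

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_ann(TrainingSet("light", []), FAST_TRAIN)


class TestPredictDrive:
    def test_linear_model_is_exact_affine_map(self):
        model = InverseModel(kind="linear", force_level="moderate",
                             params={"gain": 3.0, "offset": -1.0}, trained=True)
        target = Signal(np.array([0.0, 1.0, 2.0]), fs=10.0, unit=DISPLACEMENT)
        out = predict_drive(model, target)
        assert out.unit == VOLT
        assert np.allclose(out.samples, [-1.0, 2.0, 5.0])

    def test_ann_on_zero_signal_is_constant(self):
        rng = np.random.default_rng(4)
        P = rng.uniform(-1, 1, 2000)
        model = fit_ann(_pairs_set(P, 2 * P), TrainConfig(epochs=50,
                                                          optimizer="lbfgs",
                                                          seed=0))
        zero = Signal(np.zeros(50), fs=10.0, unit=DISPLACEMENT)
        out = predict_drive(model, zero)
        assert np.allclose(out.samples, out.samples[0])

    def test_pointwise_map_commutes_with_permutation(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(-1, 1, 2000)
        model = fit_ann(_pairs_set(P, np.sin(P)), TrainConfig(epochs=50,
                                                              optimizer="lbfgs",
                                                              seed=0))
        x = rng.uniform(-1, 1, 100)
        perm = rng.permutation(100)
        direct = model.predict(x)
        assert np.allclose(model.predict(x[perm]), direct[perm])

    def test_untrained_model_rejected(self):
        model = InverseModel(kind="linear", force_level="light",
                             params={"gain": 1.0, "offset": 0.0})
        target = Signal(np.zeros(10) + 1, fs=10.0, unit=DISPLACEMENT)
        with pytest.raises(RuntimeError):
            predict_drive(model, target)

    def test_voltage_clipping_option(self):
        model = InverseModel(kind="linear", force_level="heavy",
                             params={"gain": 100.0, "offset": 0.0}, trained=True)
        target = Signal(np.array([0.0, 1.0]), fs=10.0, unit=DISPLACEMENT)
        out = predict_drive(model, target, v_limit=48.0)
        assert out.samples.max() <= 48.0


class TestModelSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(6)
        P = rng.uniform(-1, 1, 2000)
        model = fit_ann(_pairs_set(P, 0.7 * P), TrainConfig(epochs=50,
                                                            optimizer="lbfgs",
                                                            seed=0))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = InverseModel.from_json(path)
        x = np.linspace(-1, 1, 50)
        assert np.allclose(back.predict(x), model.predict(x))
        assert back.kind == "ann" and back.force_level == "moderate"


class TestTrainingErrorTable:
    def test_per_imf_ordering_on_benchmark(self, bench_result):
        """Average training NRMSE of the high-energy leading IMFs
        (1-3) does not exceed that of IMFs 4-7."""
        for level, train in bench_result.training_sets.items():
            model = bench_result.models["ann"][level]
            table = training_error_table(model, train)
            lead = table[table["imf"] <= 3]["nrmse"].mean()
            tail = table[table["imf"] >= 4]["nrmse"].mean()
            assert lead <= tail

    def test_zero_range_series_skipped(self):
        train = TrainingSet("light", [
            SeriesRecord("light", 1, 1, np.linspace(-1, 1, 50),
                         np.linspace(-2, 2, 50)),
            SeriesRecord("light", 1, 2, np.zeros(50), np.zeros(50)),
        ])
        model = fit_linear(train)
        table = training_error_table(model, train)
        assert table["imf"].tolist() == [1]
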