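"""FCNN training, periodic loss, schedule, routing, and persistence."""

import numpy as np
import pytest

from ssangles.features import Ahiw, NormalizationStats
from ssangles.geometry import wrap_angle
from ssangles.model import (
    DEFAULT_SETTINGS,
    EmptyClassError,
    Fcnn,
    FcnnConfig,
    ModelBundle,
    TrainingSchedule,
    periodic_mae_loss,
    predict_angles,
    train_bundle,
    train_model,
)
from ssangles.ss_router import SS3_CLASSES, map_ss8_to_ss3


class TestPeriodicMaeLoss:
    def test_zero_when_equal(self, rng):
        y = rng.uniform(-180, 180, 50)
        assert periodic_mae_loss(y, y) == 0.0

    def test_wrap_example(self):
        assert periodic_mae_loss([179.0], [-179.0]) == pytest.approx(2.0)

    def test_elementwise_scalar_oracle(self, rng):
        p = rng.uniform(-180, 180, 300)
        a = rng.uniform(-180, 180, 300)
        expected = np.mean(
            [min(abs(x - y), abs(360 - abs(x - y))) for x, y in zip(p, a)]
        )
        assert periodic_mae_loss(p, a) == pytest.approx(expected, abs=1e-9)
        # far outside the principal range, the circular distance still applies
        p2 = rng.uniform(-720, 720, 300)
        a2 = rng.uniform(-720, 720, 300)
        shifts = np.min(
            [np.abs(p2 - a2 + 360 * k) for k in range(-4, 5)], axis=0
        )
        assert periodic_mae_loss(p2, a2) == pytest.approx(shifts.mean(), abs=1e-9)

    def test_symmetry_bounds_and_period(self, rng):
        p = rng.uniform(-180, 180, 100)
        a = rng.uniform(-180, 180, 100)
        assert periodic_mae_loss(p, a) == pytest.approx(periodic_mae_loss(a, p))
        assert 0 <= periodic_mae_loss(p, a) <= 180
        k = rng.integers(-3, 4, 100)
        assert periodic_mae_loss(p + 360 * k, a) == pytest.approx(
            periodic_mae_loss(p, a), abs=1e-9
        )

    def test_defined_mask_excludes(self):
        loss = periodic_mae_loss([0.0, 90.0], [0.0, 0.0], defined=[True, False])
        assert loss == 0.0

    def test_no_defined_entries_raises(self):
        with pytest.raises(ValueError):
            periodic_mae_loss([1.0], [np.nan])


class TestTrainModel:
    def test_fits_constant_target(self, rng):
        X = rng.random((300, 30))
        y = np.full(300, 42.0)
        _, h = train_model(
            (X, y), (rng.random((60, 30)), np.full(60, 42.0)),
            FcnnConfig(), TrainingSchedule(seed=1, max_epochs=30),
        )
        assert min(h["val_loss"]) < 0.5

    def test_same_seed_bit_identical_history(self, rng):
        X = rng.random((200, 20))
        y = rng.uniform(-180, 180, 200)
        val = (rng.random((40, 20)), rng.uniform(-180, 180, 40))
        sched = TrainingSchedule(seed=9, max_epochs=8)
        _, h1 = train_model((X, y), val, None, sched)
        _, h2 = train_model((X, y), val, None, sched)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]
        assert h1["lr"] == h2["lr"]

    def test_lr_trace_halving_contract(self, rng):
        X = rng.random((150, 10))
        y = rng.uniform(-180, 180, 150)
        # deliberately unlearnable noise so the schedule anneals
        _, h = train_model(
            (X, y), (rng.random((40, 10)), rng.uniform(-180, 180, 40)),
            None, TrainingSchedule(seed=2, max_epochs=120),
        )
        lr = np.array(h["lr"])
        assert (np.diff(lr) <= 0).all()
        changes = lr[1:][np.diff(lr) < 0] / lr[:-1][np.diff(lr) < 0]
        assert np.allclose(changes, 0.5)
        assert (lr >= TrainingSchedule().lr_floor).all()

    def test_nan_targets_dropped_and_empty_raises(self, rng):
        X = rng.random((10, 4))
        y = np.full(10, np.nan)
        with pytest.raises(EmptyClassError):
            train_model((X, y), (X, y), None, TrainingSchedule(max_epochs=1))


class TestBundle:
    def test_default_settings_match_best_published(self):
        assert DEFAULT_SETTINGS[("helix", "phi")] == "YYR9"
        assert DEFAULT_SETTINGS[("sheet", "psi")] == "YYZ9"
        assert DEFAULT_SETTINGS[("sheet", "tau")] == "YYR9"
        assert DEFAULT_SETTINGS[("coil", "phi")] == "YYR5"
        assert DEFAULT_SETTINGS[("coil", "theta")] == "YYR5"
        assert DEFAULT_SETTINGS[("coil", "psi")] == "YYR9"
        assert len(DEFAULT_SETTINGS) == 12

    def test_twelve_models_with_matching_widths(self, micro_bundle):
        assert len(micro_bundle.models) == 12
        for key, model in micro_bundle.models.items():
            setting = micro_bundle.settings[key]
            assert model.input_width == setting.residue_width * setting.window

    def test_empty_class_error_names_class(self, small_splits):
        recs = [r for r in small_splits["train"][:2]]
        # forge predictions with no sheet residues at all
        for r in recs:
            r = r
        import copy

        no_sheet = []
        for r in recs:
            r2 = copy.copy(r)
            r2.ss8_pred = r.ss8_pred.replace("E", "H").replace("B", "H")
            no_sheet.append(r2)
        with pytest.raises(EmptyClassError, match="sheet"):
            train_bundle(no_sheet, no_sheet, sched=TrainingSchedule(max_epochs=1))

    def test_save_load_round_trip(self, tmp_path, micro_bundle, small_splits):
        micro_bundle.save(tmp_path / "b")
        loaded = ModelBundle.load(tmp_path / "b")
        rec = small_splits["val"][0]
        t1 = predict_angles(micro_bundle, rec)
        t2 = predict_angles(loaded, rec)
        for a in ("phi", "psi", "theta", "tau"):
            assert np.array_equal(t1.angle(a), t2.angle(a), equal_nan=True)


class TestPredictAngles:
    def test_wrap_and_theta_clamp(self, micro_bundle, small_splits):
        rec = small_splits["val"][0]
        # force one routed model to emit a constant raw 190 degrees
        cls0 = map_ss8_to_ss3(rec.ss8_pred[1])
        key = (cls0, "phi")
        model = micro_bundle.models[key]
        state = model.state()
        for k in state:
            state[k] = np.zeros_like(state[k])
        state["b3"] = np.array([190.0], dtype=np.float32)
        micro_bundle.models[key] = Fcnn.from_state(state)
        out = predict_angles(micro_bundle, rec)
        assert out.phi[1] == pytest.approx(-170.0)
        assert np.all((out.theta[np.isfinite(out.theta)] >= 0)
                      & (out.theta[np.isfinite(out.theta)] <= 180))

    def test_terminus_flags(self, micro_bundle, small_splits):
        rec = small_splits["val"][1]
        out = predict_angles(micro_bundle, rec)
        L = len(rec)
        assert np.isnan(out.phi[0]) and np.isnan(out.psi[L - 1])
        assert np.isnan(out.theta[0]) and np.isnan(out.theta[L - 1])
        assert np.isnan(out.tau[0]) and np.isnan(out.tau[L - 1]) and np.isnan(out.tau[L - 2])

    def test_row_level_oracle(self, micro_bundle, small_splits):
        from ssangles.features import apply_normalization, build_feature_matrix

        rec = small_splits["val"][0]
        out = predict_angles(micro_bundle, rec)
        i = 3
        cls = map_ss8_to_ss3(rec.ss8_pred[i])
        key = (cls, "psi")
        setting = micro_bundle.settings[key]
        m = build_feature_matrix([rec], setting)
        X = apply_normalization(m.X[[i]], micro_bundle.stats[key])
        direct = wrap_angle(micro_bundle.models[key].predict(X))[0]
        assert out.psi[i] == pytest.approx(direct)

    def test_routing_consults_only_own_class(self, small_splits):
        sched = TrainingSchedule(seed=7, max_epochs=1)
        bundle = train_bundle(small_splits["train"], small_splits["val"], sched=sched)
        import copy

        rec = copy.copy(small_splits["val"][0])
        rec.ss8_pred = "H" * len(rec)
        for k in bundle.call_counts:
            bundle.call_counts[k] = 0
        predict_angles(bundle, rec)
        for (cls, angle), count in bundle.call_counts.items():
            if cls == "helix":
                assert count > 0
            else:
                assert count == 0
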