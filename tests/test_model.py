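"""Student classifier: fitting, tuning, calibration, prediction
tie-breaks, confusion reporting, importance, and persistence."""

from __future__ import annotations

import numpy as np
import pytest

from ncfet import (CLASS_ORDER, OvulationClass, StudentModel,
                   calibrate_one_vs_rest, confusion_report, feature_importance,
                   fit_student, tune_hyperparameters)
from ncfet.instances import labels_vector
from ncfet.model import (argmax_class, assert_patient_disjoint,
                         expected_calibration_error)
from ncfet.records import Instance

QUICK = {"learning_rate": 0.3, "max_depth": 3, "n_estimators": 40}


def separable_instances(n_per_class=30, n_classes=9, noise=0.0, seed=0):
    """Toy fixture: the class is encoded in lh_d2 alone."""
    rng = np.random.default_rng(seed)
    out = []
    for c in range(n_classes):
        for k in range(n_per_class):
            out.append(Instance(
                patient_id=f"p{c}_{k}", cycle_id="1", first_day=8, second_day=8,
                features={"lh_d2": 10.0 * c + noise * rng.normal(),
                          "e2_d2": 500.0},
                label=OvulationClass(c)))
    return out


class TestArgmaxTieBreaks:
    def test_concentrated_probability_wins(self):
        p = np.zeros(9)
        p[int(OvulationClass.M1)] = 1.0
        assert argmax_class(p) == OvulationClass.M1

    def test_tie_goes_to_bin_nearest_zero(self):
        p = np.zeros(9)
        p[int(OvulationClass.M3)] = 0.5
        p[int(OvulationClass.ZERO)] = 0.5
        assert argmax_class(p) == OvulationClass.ZERO

    def test_uniform_vector_gives_zero(self):
        assert argmax_class(np.full(9, 1 / 9)) == OvulationClass.ZERO

    def test_equal_distance_tie_goes_to_later_bin(self):
        p = np.zeros(9)
        p[int(OvulationClass.M1)] = 0.5
        p[int(OvulationClass.P1)] = 0.5
        assert argmax_class(p) == OvulationClass.P1


class TestFitStudent:
    def test_predict_proba_interface(self):
        instances = separable_instances(10)
        model = fit_student(instances, QUICK, seed=0)
        proba = model.predict_proba(instances[:3])
        assert proba.shape == (3, 9)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba >= 0).all()

    def test_all_ultrasound_missing_still_fits(self, small_synthetic_splits):
        train = small_synthetic_splits[0][:400]
        stripped = []
        for inst in train:
            feats = dict(inst.features)
            for name in ("follicle_mm_d1", "follicle_mm_d2", "endometrium_mm_d1",
                         "endometrium_mm_d2", "follicle_slope_per_day"):
                feats[name] = float("nan")
            stripped.append(Instance(inst.patient_id, inst.cycle_id,
                                     inst.first_day, inst.second_day, feats,
                                     inst.label))
        model = fit_student(stripped, QUICK, seed=1)
        assert model.predict_proba(stripped[:2]).shape == (2, 9)

    def test_single_class_rejected(self):
        instances = separable_instances(5, n_classes=1)
        with pytest.raises(ValueError, match="single class"):
            fit_student(instances, QUICK, seed=0)

    def test_separable_toy_is_learned_perfectly(self):
        instances = separable_instances(30)
        model = fit_student(instances, QUICK, seed=0)
        pred = model.predict_classes(instances)
        assert all(p == i.label for p, i in zip(pred, instances))


class TestTuneHyperparameters:
    def test_singleton_grid_returned(self):
        train = separable_instances(10, seed=1)
        val = separable_instances(5, seed=2)
        grid = [QUICK]
        assert tune_hyperparameters(train, val, grid) == QUICK

    def test_separable_toy_reaches_perfect_validation_accuracy(self):
        train = separable_instances(20, seed=1)
        val = separable_instances(8, seed=2)
        grid = [dict(QUICK, max_depth=2), dict(QUICK, max_depth=4)]
        best = tune_hyperparameters(train, val, grid, seed=0)
        model = fit_student(train, best, seed=0)
        pred = model.predict_classes(val)
        assert np.mean([p == i.label for p, i in zip(pred, val)]) == 1.0
        # tie on accuracy resolves toward the smaller depth
        assert best["max_depth"] == 2

    def test_deterministic_choice(self):
        train = separable_instances(10, noise=3.0, seed=1)
        val = separable_instances(5, noise=3.0, seed=2)
        grid = [dict(QUICK, max_depth=d) for d in (2, 3)]
        a = tune_hyperparameters(train, val, grid, seed=5)
        b = tune_hyperparameters(train, val, grid, seed=5)
        assert a == b

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters([], separable_instances(2), [QUICK])


class TestCalibration:
    def test_probabilities_still_normalized(self, small_student,
                                            small_synthetic_splits):
        test = small_synthetic_splits[2]
        proba = small_student.predict_proba(test[:50])
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_ece_does_not_increase_on_calibration_set(self, small_synthetic_splits):
        train, valcal, _ = small_synthetic_splits
        patients = sorted({i.patient_id for i in valcal})
        cal_ids = set(patients[len(patients) // 2:])
        cal = [i for i in valcal if i.patient_id in cal_ids]
        model = fit_student(train, QUICK, seed=7)
        y_cal = labels_vector(cal)
        before = expected_calibration_error(model.predict_proba(cal), y_cal)
        calibrated = calibrate_one_vs_rest(model, cal)
        after = expected_calibration_error(calibrated.predict_proba(cal), y_cal)
        assert after <= before + 1e-9

    def test_recalibration_is_idempotent_on_calibration_set(
            self, small_student, small_synthetic_splits):
        _, valcal, _ = small_synthetic_splits
        patients = sorted({i.patient_id for i in valcal})
        cal_ids = set(patients[len(patients) // 2:])
        cal = [i for i in valcal if i.patient_id in cal_ids]
        # small_student was calibrated on exactly this set
        twice = calibrate_one_vs_rest(small_student, cal)
        np.testing.assert_allclose(twice.predict_proba(cal),
                                   small_student.predict_proba(cal), atol=1e-6)

    def test_absent_class_skipped_with_warning(self):
        train = separable_instances(20)
        model = fit_student(train, QUICK, seed=0)
        cal = [i for i in separable_instances(10, seed=3)
               if i.label != OvulationClass.GE_P2]
        with pytest.warns(UserWarning, match="absent from calibration"):
            calibrated = calibrate_one_vs_rest(model, cal)
        assert calibrated.calibration_stages[-1].maps[int(OvulationClass.GE_P2)] is None

    def test_calibrated_and_raw_argmax_mostly_agree(self, small_student,
                                                    small_synthetic_splits):
        test = small_synthetic_splits[2]
        raw = StudentModel(booster=small_student.booster,
                           present_classes=small_student.present_classes)
        agree = np.mean([a == b for a, b in zip(
            raw.predict_classes(test), small_student.predict_classes(test))])
        assert agree >= 0.90

    def test_unknown_method_rejected(self, small_student):
        with pytest.raises(ValueError, match="unknown calibration method"):
            calibrate_one_vs_rest(small_student, separable_instances(2), "beta")


class _StubModel:
    """Fixed-prediction stand-in for confusion-report mechanics."""

    class_order = CLASS_ORDER

    def __init__(self, fn):
        self.fn = fn

    def predict_classes(self, instances):
        return [self.fn(i) for i in instances]


class TestConfusionReport:
    def test_perfect_predictor_identity_matrix(self):
        instances = separable_instances(5)
        report = confusion_report(_StubModel(lambda i: i.label), instances)
        assert report.overall_accuracy == 1.0
        assert np.all(np.diag(report.counts) == 5)
        assert report.counts.sum() == len(instances)

    def test_column_sums_match_class_totals(self, small_student,
                                            small_synthetic_splits):
        test = small_synthetic_splits[2]
        report = confusion_report(small_student, test)
        y = labels_vector(test)
        np.testing.assert_array_equal(report.counts.sum(axis=0),
                                      np.bincount(y, minlength=9))
        pct = report.column_percentages
        nonzero = report.counts.sum(axis=0) > 0
        assert np.allclose(pct[:, nonzero].sum(axis=0), 100.0)

    def test_random_predictor_near_chance(self):
        rng = np.random.default_rng(0)
        instances = separable_instances(1000)  # 9,000 balanced instances
        stub = _StubModel(lambda i: OvulationClass(int(rng.integers(9))))
        report = confusion_report(stub, instances)
        assert 0.09 <= report.overall_accuracy <= 0.13

    def test_single_day_window_filter(self, small_student, small_synthetic_splits):
        test = small_synthetic_splits[2]
        report = confusion_report(small_student, test, filters="single_day_6_10")
        assert report.counts.sum() <= len(test)

    def test_empty_test_set_rejected(self, small_student):
        with pytest.raises(ValueError, match="no test instances"):
            confusion_report(small_student, [])


class TestFeatureImportance:
    def test_signal_feature_ranked_first(self):
        model = fit_student(separable_instances(30), QUICK, seed=0)
        ranking = feature_importance(model)
        assert ranking[0][0] == "lh_d2"
        assert all(gain >= 0 for _, gain in ranking)

    def test_gain_conservation(self):
        model = fit_student(separable_instances(30), QUICK, seed=0)
        ranking = feature_importance(model)
        booster_total = sum(
            model.booster.get_score(importance_type="total_gain").values())
        assert sum(g for _, g in ranking) == pytest.approx(booster_total, rel=1e-6)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, small_student,
                                  small_synthetic_splits):
        test = small_synthetic_splits[2][:40]
        path = tmp_path / "student.zip"
        small_student.save(path)
        loaded = StudentModel.load(path)
        np.testing.assert_allclose(loaded.predict_proba(test),
                                   small_student.predict_proba(test), atol=1e-12)
        assert loaded.class_order == small_student.class_order
        assert loaded.metadata["hyperparameters"] == \
            small_student.metadata["hyperparameters"]


class TestPatientDisjointness:
    def test_overlap_detected(self):
        a = separable_instances(3, seed=0)
        assert_patient_disjoint(a[:10], a[30:40])  # different patients
        with pytest.raises(ValueError, match="appears in splits"):
            assert_patient_disjoint(a, a)
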