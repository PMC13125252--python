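"""Shared fixtures: deterministic RNGs, a worked-example cycle, and a
small trained model reused across classifier tests."""

from __future__ import annotations

import numpy as np
import pytest

from ncfet import (Baseline, CycleRecord, SimulationConfig, TestDayRecord,
                   build_instances_many, calibrate_one_vs_rest, fit_student,
                   generate_dataset, split_by_patient)

QUICK_PARAMS = {"learning_rate": 0.3, "max_depth": 3, "n_estimators": 60}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def worked_example_cycle():
    """Ovulation on day 13; blood tests on days 3, 10, 12, and 14."""
    baseline = Baseline(patient_id="pA", age_years=34.0, bmi_kg_m2=23.0,
                        smoker=False)
    tests = [
        TestDayRecord(cycle_day=3, lh_iu_l=4.0, e2=160.0, p4=1.2,
                      follicle_mm=5.0, endometrium_mm=4.5),
        TestDayRecord(cycle_day=10, lh_iu_l=8.0, e2=600.0, p4=1.5,
                      follicle_mm=13.0, endometrium_mm=7.0),
        TestDayRecord(cycle_day=12, lh_iu_l=30.0, e2=1100.0, p4=1.8,
                      follicle_mm=17.5, endometrium_mm=8.5),
        TestDayRecord(cycle_day=14, lh_iu_l=10.0, e2=700.0, p4=8.0,
                      follicle_mm=None, endometrium_mm=9.0),
    ]
    return CycleRecord(baseline=baseline, tests=tests, cycle_id="c1",
                       ovulation_day=13, label_source="retro_label")


@pytest.fixture(scope="session")
def small_synthetic_splits():
    """Patient-disjoint splits from 300 observed synthetic cycles."""
    rng = np.random.default_rng(1234)
    cycles = generate_dataset(rng, 300, SimulationConfig())
    instances = build_instances_many(cycles)
    return split_by_patient(instances, rng=np.random.default_rng(99))


@pytest.fixture(scope="session")
def small_student(small_synthetic_splits):
    """A quickly trained, calibrated student model on the small dataset."""
    train, valcal, _test = small_synthetic_splits
    patients = sorted({i.patient_id for i in valcal})
    val_ids = set(patients[: len(patients) // 2])
    val = [i for i in valcal if i.patient_id in val_ids]
    cal = [i for i in valcal if i.patient_id not in val_ids]
    model = fit_student(train + val, QUICK_PARAMS, seed=7)
    return calibrate_one_vs_rest(model, cal)
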