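"""End-to-end synthetic workflow: simulate, label, train, evaluate.

This is the programmatic counterpart of chaining the CLI commands
``simulate -> label -> build-instances -> train -> evaluate`` on one
seed, used for benchmarking the whole stack on synthetic cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import NTMAConfig
from .evaluate import (ErrorModel, EvaluationReport, OvulationPMF,
                       error_model_from_confusion, evaluate_monte_carlo)
from .instances import build_instances_many, split_by_patient
from .io import forked_rng
from .labeling import LabelingConfig, filter_uncertain
from .model import (ConfusionReport, StudentModel, assert_patient_disjoint,
                    calibrate_one_vs_rest, confusion_report, fit_student)
from .records import CycleRecord, Instance
from .simulate import SimulationConfig, generate_dataset, sample_observation_schedule

DEFAULT_BENCHMARK_PARAMS = {"learning_rate": 0.1, "max_depth": 5,
                            "n_estimators": 300}


@dataclass
class BenchmarkResult:
    model: StudentModel
    report: ConfusionReport
    labeled_cycles: list[CycleRecord]
    n_excluded: int
    train: list[Instance] = field(repr=False, default_factory=list)
    test: list[Instance] = field(repr=False, default_factory=list)

    @property
    def holdout_accuracy(self) -> float:
        return self.report.overall_accuracy

    def ovulation_pmf(self) -> OvulationPMF:
        return OvulationPMF.from_observed_days(
            [c.ovulation_day for c in self.labeled_cycles])

    def error_model(self) -> ErrorModel:
        return error_model_from_confusion(self.report)


def synthetic_benchmark(seed: int, n_cycles: int = 2000,
                        sim_config: SimulationConfig = SimulationConfig(),
                        hyperparameters: Optional[dict] = None,
                        labeling_config: LabelingConfig = LabelingConfig(),
                        ) -> BenchmarkResult:
    """Simulate cycles, retro-label them, train and score the student.

    Full daily grids are labeled retrospectively (strict surge+rupture
    agreement; uncertain cycles dropped), physician-like observation
    schedules are drawn, instances are built and split patient-disjointly
    60/25/15, the model is fitted on train+validation and calibrated on
    the calibration block, and the confusion report comes from the
    held-out test split.
    """
    rng = forked_rng(seed, "benchmark")
    full = generate_dataset(rng, n_cycles, sim_config, keep_full_grid=True)
    labeled, n_excluded = filter_uncertain(full, labeling_config)
    observed = []
    for c in labeled:
        days = set(sample_observation_schedule(rng, c))
        observed.append(CycleRecord(
            baseline=c.baseline,
            tests=[t for t in c.tests if t.cycle_day in days],
            cycle_id=c.cycle_id, ovulation_day=c.ovulation_day,
            label_source="retro_label"))
    instances = build_instances_many(observed)
    train, valcal, test = split_by_patient(instances,
                                           rng=forked_rng(seed, "split"))
    assert_patient_disjoint(train, valcal, test)
    patients = sorted({i.patient_id for i in valcal})
    val_ids = set(patients[: int(round(0.6 * len(patients)))])
    val = [i for i in valcal if i.patient_id in val_ids]
    cal = [i for i in valcal if i.patient_id not in val_ids]
    model = fit_student(train + val,
                        hyperparameters or DEFAULT_BENCHMARK_PARAMS, seed=seed)
    model = calibrate_one_vs_rest(model, cal)
    report = confusion_report(model, test)
    return BenchmarkResult(model=model, report=report, labeled_cycles=observed,
                           n_excluded=n_excluded, train=train, test=test)


def evaluate_benchmark_policy(result: BenchmarkResult, seed: int,
                              config: NTMAConfig = NTMAConfig(),
                              n_samples: int = 10_000, n_repeats: int = 30,
                              ) -> EvaluationReport:
    """Plug the benchmark's empirical pmf and error model into the
    Monte Carlo policy evaluation."""
    return evaluate_monte_carlo(
        result.ovulation_pmf(), result.error_model(), config,
        n_samples=n_samples, n_repeats=n_repeats,
        rng=forked_rng(seed, "policy_eval"))
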