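"""Treatment-management state machine for natural-cycle FET monitoring.

Given the classifier's relative-to-ovulation class after each monitoring
visit, the rule set decides what happens next:

* ovulation six or more days away -> retest in four days;
* ovulation predicted for yesterday, today, or tomorrow -> schedule the
  embryo transfer at predicted ovulation day + embryo developmental stage;
* ovulation two or more days past -> cancel the cycle (the exact day can
  no longer be recovered);
* otherwise -> retest one day before the predicted ovulation day.

Monitoring starts on cycle day 8.  A retest that would land past the
configured horizon cancels the cycle (max-day abort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Union

from .instances import build_features
from .records import Baseline, CycleRecord, Instance, OvulationClass, TestDayRecord


@dataclass(frozen=True)
class NTMAConfig:
    initial_test_day: int = 8
    far_retest_interval_days: int = 4
    embryo_stage_days: int = 5
    max_cycle_day: int = 35
    transfer_classes: frozenset[OvulationClass] = frozenset(
        {OvulationClass.M1, OvulationClass.ZERO, OvulationClass.P1})
    cancel_class: OvulationClass = OvulationClass.GE_P2

    def __post_init__(self) -> None:
        if self.initial_test_day < 1:
            raise ValueError("initial_test_day must be >= 1")
        if self.far_retest_interval_days < 1:
            raise ValueError("far_retest_interval_days must be >= 1")


@dataclass(frozen=True)
class NTMARecommendation:
    action: str  # NEXT_TEST | TRANSFER | CANCEL
    reason: str
    next_test_day: Optional[int] = None
    predicted_ovulation_day: Optional[int] = None
    transfer_day: Optional[int] = None

    def __post_init__(self) -> None:
        by_action = {
            "NEXT_TEST": self.next_test_day is not None
                         and self.predicted_ovulation_day is None
                         and self.transfer_day is None,
            "TRANSFER": self.next_test_day is None
                        and self.predicted_ovulation_day is not None
                        and self.transfer_day is not None,
            "CANCEL": self.next_test_day is None
                      and self.predicted_ovulation_day is None
                      and self.transfer_day is None,
        }
        if self.action not in by_action:
            raise ValueError(f"unknown action {self.action!r}")
        if not by_action[self.action]:
            raise ValueError(f"fields inconsistent with action {self.action}")


@dataclass
class CycleTrajectory:
    steps: list[tuple[int, OvulationClass, NTMARecommendation]] = field(
        default_factory=list)
    outcome: str = ""  # TRANSFER_SCHEDULED | CANCELLED | ABORTED_MAX_DAY

    @property
    def n_tests(self) -> int:
        return len(self.steps)

    @property
    def final(self) -> NTMARecommendation:
        return self.steps[-1][2]

    def to_jsonable(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_tests": self.n_tests,
            "steps": [
                {"test_day": d, "predicted_class": c.name,
                 "action": r.action, "reason": r.reason,
                 "next_test_day": r.next_test_day,
                 "predicted_ovulation_day": r.predicted_ovulation_day,
                 "transfer_day": r.transfer_day}
                for d, c, r in self.steps
            ],
        }


def predicted_ovulation_day(test_day: int, cls: OvulationClass) -> Optional[int]:
    """Invert the labeling rule: O = test day - class offset.

    The open bins (<= -6, >= +2) pin no single day, so they yield None.
    """
    if cls.is_open:
        return None
    return test_day - cls.representative_int


def step(current_test_day: int, predicted_class: OvulationClass,
         config: NTMAConfig = NTMAConfig()) -> NTMARecommendation:
    """Map one (test day, predicted class) to the next recommendation.

    Pure function; the same inputs always give the same recommendation.
    """
    if current_test_day > config.max_cycle_day:
        raise ValueError(f"test day {current_test_day} beyond max_cycle_day")
    if predicted_class == config.cancel_class:
        return NTMARecommendation(action="CANCEL", reason="no_prediction")
    if predicted_class in config.transfer_classes:
        o = predicted_ovulation_day(current_test_day, predicted_class)
        assert o is not None
        return NTMARecommendation(
            action="TRANSFER", reason="ovulation_identified",
            predicted_ovulation_day=o,
            transfer_day=o + config.embryo_stage_days)
    if predicted_class == OvulationClass.LE_M6:
        next_day = current_test_day + config.far_retest_interval_days
        reason = "far_from_ovulation"
    else:  # -5 .. -2: retest one day before the predicted ovulation day
        o = predicted_ovulation_day(current_test_day, predicted_class)
        assert o is not None
        next_day = o - 1
        reason = "approaching_ovulation"
    if next_day > config.max_cycle_day:
        return NTMARecommendation(action="CANCEL", reason="max_day")
    return NTMARecommendation(action="NEXT_TEST", reason=reason,
                              next_test_day=next_day)


class ClassPredictor(Protocol):
    def predict_class(self, instance: Instance) -> OvulationClass: ...


@dataclass(frozen=True)
class PerfectOracle:
    """Predictor that knows the true ovulation day (analytic limit)."""

    ovulation_day: int

    def predict_class(self, instance: Instance) -> OvulationClass:
        return OvulationClass.from_difference(
            instance.second_day - self.ovulation_day)


MeasurementSource = Callable[[int], TestDayRecord]


def replay_source(cycle: CycleRecord) -> MeasurementSource:
    """Measurement source backed by a fully simulated / recorded cycle grid."""

    def source(day: int) -> TestDayRecord:
        return cycle.test_on(day)

    return source


_PLACEHOLDER = Baseline(patient_id="live", age_years=36.44, bmi_kg_m2=24.27,
                        smoker=False)


def _live_instance(tested: list[TestDayRecord], day: int,
                   baseline: Optional[Baseline]) -> Instance:
    """Real-time instance: current day paired with the latest prior test
    within four days, else a single-day instance."""
    prior = None
    for t in tested:
        if t.cycle_day < day and day - t.cycle_day <= 4:
            prior = t.cycle_day
    first = prior if prior is not None else day
    cycle = CycleRecord(baseline=baseline or _PLACEHOLDER, tests=list(tested),
                        cycle_id="live")
    feats = build_features(cycle, first, day)
    if baseline is None:
        for name in ("age_years", "bmi_kg_m2", "smoker"):
            feats[name] = float("nan")
    pid = baseline.patient_id if baseline else "live"
    return Instance(patient_id=pid, cycle_id="live", first_day=first,
                    second_day=day, features=feats)


def run_cycle(predictor: Union[ClassPredictor, Callable[[Instance], OvulationClass]],
              measurement_source: MeasurementSource,
              config: NTMAConfig = NTMAConfig(),
              baseline: Optional[Baseline] = None) -> CycleTrajectory:
    """Drive one monitored cycle from the initial test to its outcome.

    ``measurement_source`` must return a TestDayRecord for any requested
    day (a simulator in closed-loop mode, or recorded data in replay
    mode); its failure aborts with a diagnostic.
    """
    predict = (predictor.predict_class if hasattr(predictor, "predict_class")
               else predictor)
    traj = CycleTrajectory()
    tested: list[TestDayRecord] = []
    day = config.initial_test_day
    while True:
        try:
            record = measurement_source(day)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(f"measurement source failed on day {day}: {exc}"
                               ) from exc
        if record.cycle_day != day:
            raise RuntimeError(
                f"measurement source returned day {record.cycle_day} "
                f"for requested day {day}")
        tested.append(record)
        instance = _live_instance(tested, day, baseline)
        cls = predict(instance)
        rec = step(day, cls, config)
        traj.steps.append((day, cls, rec))
        if rec.action == "TRANSFER":
            traj.outcome = "TRANSFER_SCHEDULED"
            return traj
        if rec.action == "CANCEL":
            traj.outcome = ("ABORTED_MAX_DAY" if rec.reason == "max_day"
                            else "CANCELLED")
            return traj
        assert rec.next_test_day is not None and rec.next_test_day > day
        day = rec.next_test_day
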