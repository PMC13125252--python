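"""Core domain records for natural-cycle FET monitoring.

Cycle days are 1-based with day 1 = first day of menses.  "Ovulation day"
(O) is the cycle day of follicular rupture; the LH surge day is O - 1.
Units: LH in IU/L, estradiol (E2) in pmol/L, progesterone (P4) in nmol/L,
ultrasound measurements in mm.  Missing measurements are ``None`` in
records and NaN in feature vectors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


class OvulationClass(enum.IntEnum):
    """The nine bins of (last test day - ovulation day).

    Open bins at the ends: ``LE_M6`` collects differences <= -6 and
    ``GE_P2`` differences >= +2; the rest are exact offsets.  The enum
    ordering matches chronological ordering of the offsets.
    """

    LE_M6 = 0
    M5 = 1
    M4 = 2
    M3 = 3
    M2 = 4
    M1 = 5
    ZERO = 6
    P1 = 7
    GE_P2 = 8

    @property
    def representative_int(self) -> int:
        return _REPRESENTATIVE[self]

    @property
    def is_open(self) -> bool:
        """True for the unbounded bins (<= -6 and >= +2)."""
        return self in (OvulationClass.LE_M6, OvulationClass.GE_P2)

    @classmethod
    def from_difference(cls, diff: int) -> "OvulationClass":
        """Clip an integer day difference into its bin."""
        if diff <= -6:
            return cls.LE_M6
        if diff >= 2:
            return cls.GE_P2
        return _BY_REP[diff]


_REPRESENTATIVE = {
    OvulationClass.LE_M6: -6,
    OvulationClass.M5: -5,
    OvulationClass.M4: -4,
    OvulationClass.M3: -3,
    OvulationClass.M2: -2,
    OvulationClass.M1: -1,
    OvulationClass.ZERO: 0,
    OvulationClass.P1: 1,
    OvulationClass.GE_P2: 2,
}
_BY_REP = {v: k for k, v in _REPRESENTATIVE.items()}

#: Fixed class order used everywhere a 9-vector or 9x9 matrix appears.
CLASS_ORDER: tuple[OvulationClass, ...] = tuple(OvulationClass)


@dataclass(frozen=True)
class Baseline:
    """Per-patient baseline covariates."""

    patient_id: str
    age_years: float
    bmi_kg_m2: float
    smoker: bool

    def __post_init__(self) -> None:
        if not 18.0 <= self.age_years <= 55.0:
            raise ValueError(f"age_years {self.age_years} outside [18, 55]")
        if not 14.0 <= self.bmi_kg_m2 <= 60.0:
            raise ValueError(f"bmi_kg_m2 {self.bmi_kg_m2} outside [14, 60]")


@dataclass(frozen=True)
class TestDayRecord:
    """One monitoring visit: blood panel plus optional ultrasound."""

    __test__ = False  # not a pytest class despite the name

    cycle_day: int
    lh_iu_l: float
    e2: float
    p4: float
    follicle_mm: Optional[float] = None
    endometrium_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cycle_day < 1:
            raise ValueError(f"cycle_day must be >= 1, got {self.cycle_day}")
        for name in ("lh_iu_l", "e2", "p4"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(f"hormone field {name} may not be missing")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for name in ("follicle_mm", "endometrium_mm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class CycleRecord:
    """A patient-cycle: baseline covariates plus ordered monitoring days."""

    baseline: Baseline
    tests: list[TestDayRecord]
    cycle_id: str = "1"
    ovulation_day: Optional[int] = None
    label_source: str = "none"  # simulated_truth | retro_label | none

    def __post_init__(self) -> None:
        days = [t.cycle_day for t in self.tests]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("test cycle_days must be strictly increasing")
        if self.ovulation_day is not None and self.ovulation_day < 5:
            raise ValueError(f"ovulation_day {self.ovulation_day} < 5")
        if self.label_source not in ("simulated_truth", "retro_label", "none"):
            raise ValueError(f"unknown label_source {self.label_source!r}")

    @property
    def test_days(self) -> list[int]:
        return [t.cycle_day for t in self.tests]

    def test_on(self, day: int) -> TestDayRecord:
        for t in self.tests:
            if t.cycle_day == day:
                return t
        raise KeyError(f"no test on cycle day {day}")

    def has_test_on(self, day: int) -> bool:
        return any(t.cycle_day == day for t in self.tests)


@dataclass
class Instance:
    """A model input built from one or two test days of a cycle.

    Single-day instances use the same day as both first and second day
    (``day_gap`` 0).  ``features`` maps registry names to floats, with NaN
    marking a missing value.
    """

    patient_id: str
    cycle_id: str
    first_day: int
    second_day: int
    features: dict[str, float]
    label: Optional[OvulationClass] = None

    def __post_init__(self) -> None:
        if self.second_day < self.first_day:
            raise ValueError("second_day must be >= first_day")
        if self.second_day - self.first_day > 4:
            raise ValueError("test days more than 4 days apart")


@dataclass(frozen=True)
class LabelResult:
    """Outcome of retrospective ovulation labeling for one cycle."""

    ovulation_day: Optional[int]
    status: str  # labeled | uncertain
    evidence: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.status == "labeled" and (self.ovulation_day is None or not self.evidence):
            raise ValueError("labeled result requires an ovulation day and evidence")


def require_unique_days(days: Sequence[int]) -> None:
    if len(set(days)) != len(days):
        raise ValueError(f"duplicate test days in {list(days)}")
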