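"""Build model instances from a cycle's observed test days.

An instance is one test day, or a pair of test days at most four days
apart; its class label is the offset of the last test day from the
ovulation day, clipped into the nine ovulation bins.  For a single-day
instance the day serves as both the first and the second day, so every
"first-day" feature equals its "second-day" counterpart and the slope
features are undefined.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np

from .records import CycleRecord, Instance, OvulationClass, require_unique_days

#: Fixed feature registry.  Slope features are per-day differences between
#: the pair's two test days and are missing for single-day instances;
#: ``e2_over_p4_d2`` is missing when P4 on the second day is zero.
FEATURE_REGISTRY: tuple[str, ...] = (
    "lh_d2",
    "e2_over_p4_d2",
    "p4_d2",
    "e2_d2",
    "e2_d1",
    "follicle_mm_d2",
    "lh_d1",
    "lh_slope_per_day",
    "endometrium_mm_d2",
    "p4_d1",
    "follicle_mm_d1",
    "endometrium_mm_d1",
    "e2_slope_per_day",
    "p4_slope_per_day",
    "follicle_slope_per_day",
    "first_day",
    "second_day",
    "day_gap",
    "age_years",
    "bmi_kg_m2",
    "smoker",
)

MAX_PAIR_GAP_DAYS = 4


def enumerate_combinations(test_days: Sequence[int]) -> list[tuple[int, int]]:
    """All single days plus pairs at most four days apart.

    Deterministic order: by second day, singles before pairs sharing that
    second day, then by first day.
    """
    days = list(test_days)
    require_unique_days(days)
    if not days:
        raise ValueError("test_days must be non-empty")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("test_days must be strictly increasing")
    combos: list[tuple[int, int]] = []
    for j, d2 in enumerate(days):
        combos.append((d2, d2))
        for d1 in days[:j]:
            if d2 - d1 <= MAX_PAIR_GAP_DAYS:
                combos.append((d1, d2))
    return combos


def relative_day_class(last_test_day: int, ovulation_day: int) -> OvulationClass:
    """Bin (last test day - ovulation day) into the nine ovulation classes."""
    return OvulationClass.from_difference(last_test_day - ovulation_day)


def _opt(value: Optional[float]) -> float:
    return float("nan") if value is None else float(value)


def _slope(v1: Optional[float], v2: Optional[float], gap: int) -> float:
    if gap == 0 or v1 is None or v2 is None:
        return float("nan")
    return (v2 - v1) / gap


def build_features(cycle: CycleRecord, first_day: int, second_day: int) -> dict[str, float]:
    """Compute the full registry feature map for one day combination."""
    t1 = cycle.test_on(first_day)
    t2 = cycle.test_on(second_day)
    gap = second_day - first_day
    if t2.p4 > 0:
        e2_over_p4 = t2.e2 / t2.p4
    else:
        e2_over_p4 = float("nan")
    b = cycle.baseline
    return {
        "lh_d2": t2.lh_iu_l,
        "e2_over_p4_d2": e2_over_p4,
        "p4_d2": t2.p4,
        "e2_d2": t2.e2,
        "e2_d1": t1.e2,
        "follicle_mm_d2": _opt(t2.follicle_mm),
        "lh_d1": t1.lh_iu_l,
        "lh_slope_per_day": _slope(t1.lh_iu_l, t2.lh_iu_l, gap),
        "endometrium_mm_d2": _opt(t2.endometrium_mm),
        "p4_d1": t1.p4,
        "follicle_mm_d1": _opt(t1.follicle_mm),
        "endometrium_mm_d1": _opt(t1.endometrium_mm),
        "e2_slope_per_day": _slope(t1.e2, t2.e2, gap),
        "p4_slope_per_day": _slope(t1.p4, t2.p4, gap),
        "follicle_slope_per_day": _slope(t1.follicle_mm, t2.follicle_mm, gap),
        "first_day": float(first_day),
        "second_day": float(second_day),
        "day_gap": float(gap),
        "age_years": b.age_years,
        "bmi_kg_m2": b.bmi_kg_m2,
        "smoker": float(b.smoker),
    }


def build_instances(cycle: CycleRecord) -> list[Instance]:
    """One instance per day combination; labeled iff ovulation day is known."""
    combos = enumerate_combinations(cycle.test_days)
    out = []
    for d1, d2 in combos:
        label = (relative_day_class(d2, cycle.ovulation_day)
                 if cycle.ovulation_day is not None else None)
        out.append(Instance(
            patient_id=cycle.baseline.patient_id, cycle_id=cycle.cycle_id,
            first_day=d1, second_day=d2,
            features=build_features(cycle, d1, d2), label=label))
    return out


def build_instances_many(cycles: Sequence[CycleRecord]) -> list[Instance]:
    out: list[Instance] = []
    for c in cycles:
        out.extend(build_instances(c))
    return out


def _class_distribution(instances: Sequence[Instance]) -> np.ndarray:
    counts = np.zeros(len(OvulationClass))
    for inst in instances:
        if inst.label is not None:
            counts[int(inst.label)] += 1
    total = counts.sum()
    return counts / total if total else counts


def split_by_patient(instances: Sequence[Instance],
                     fractions: tuple[float, float, float] = (0.60, 0.25, 0.15),
                     rng: Optional[np.random.Generator] = None,
                     max_resamples: int = 20,
                     distribution_tol: float = 0.10,
                     ) -> tuple[list[Instance], list[Instance], list[Instance]]:
    """Patient-disjoint train / validation+calibration / test split.

    Patients are shuffled and cut at the cumulative fractions, so split
    sizes by patient count are within rounding of the requested 60/25/15.
    The assignment is redrawn (up to ``max_resamples`` times) until each
    split's class distribution is within ``distribution_tol`` total
    variation of the global one; if that never happens a warning is
    emitted and the last assignment is returned.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    if rng is None:
        rng = np.random.default_rng()
    patients = sorted({inst.patient_id for inst in instances})
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to split")
    by_patient: dict[str, list[Instance]] = {p: [] for p in patients}
    for inst in instances:
        by_patient[inst.patient_id].append(inst)
    global_dist = _class_distribution(instances)

    n = len(patients)
    cut1 = int(round(fractions[0] * n))
    cut2 = int(round((fractions[0] + fractions[1]) * n))
    cut1 = min(max(cut1, 1), n - 2)
    cut2 = min(max(cut2, cut1 + 1), n - 1)

    splits: tuple[list[Instance], ...] = ([], [], [])
    for attempt in range(max_resamples):
        order = list(patients)
        rng.shuffle(order)
        groups = (order[:cut1], order[cut1:cut2], order[cut2:])
        splits = tuple([inst for p in g for inst in by_patient[p]] for g in groups)
        if all(
            np.abs(_class_distribution(s) - global_dist).sum() / 2 <= distribution_tol
            for s in splits if s
        ):
            break
    else:
        warnings.warn(
            f"class distributions still differ by more than {distribution_tol} "
            f"total variation after {max_resamples} reshuffles", stacklevel=2)
    return splits  # type: ignore[return-value]


def features_matrix(instances: Sequence[Instance]) -> np.ndarray:
    """Stack instances into an (n, len(registry)) float matrix (NaN = missing)."""
    X = np.empty((len(instances), len(FEATURE_REGISTRY)))
    for i, inst in enumerate(instances):
        unknown = set(inst.features) - set(FEATURE_REGISTRY)
        if unknown:
            raise ValueError(f"unknown feature names {sorted(unknown)}")
        for j, name in enumerate(FEATURE_REGISTRY):
            X[i, j] = inst.features.get(name, float("nan"))
    return X


def labels_vector(instances: Sequence[Instance]) -> np.ndarray:
    labels = []
    for inst in instances:
        if inst.label is None:
            raise ValueError("instance without a label")
        labels.append(int(inst.label))
    return np.asarray(labels, dtype=int)
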