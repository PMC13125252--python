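"""Retrospective ovulation labeling from gold-standard criteria.

A fully observed cycle is labeled from two pieces of evidence:

* an LH surge — LH >= 17 IU/L on some day with a lower measurement on the
  next observed calendar day;
* follicular rupture — the leading follicle reaches >= 17 mm and then
  collapses (disappears from ultrasound after being seen, or shrinks
  below a collapse threshold) within two days.

In strict mode both criteria must fire consistently (rupture the day
after the surge); the rupture day is the ovulation day.  Cycles where the
evidence is absent or inconsistent are marked uncertain and can be
filtered out before training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .records import CycleRecord, LabelResult, TestDayRecord


@dataclass(frozen=True)
class LabelingConfig:
    lh_surge_threshold: float = 17.0
    follicle_rupture_mm: float = 17.0
    follicle_collapse_mm: float = 12.0
    rupture_window_days: int = 2
    mode: str = "strict"  # strict | either

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "either"):
            raise ValueError(f"unknown labeling mode {self.mode!r}")


def _sorted(tests: Sequence[TestDayRecord]) -> list[TestDayRecord]:
    return sorted(tests, key=lambda t: t.cycle_day)


def detect_lh_surge(tests: Sequence[TestDayRecord],
                    config: LabelingConfig = LabelingConfig()) -> Optional[int]:
    """Earliest day s with LH(s) >= threshold and LH(s+1) < LH(s).

    Requires a measurement on the next calendar day; a high LH with no
    next-day confirmation does not count.
    """
    ordered = _sorted(tests)
    by_day = {t.cycle_day: t for t in ordered}
    for t in ordered:
        if t.lh_iu_l >= config.lh_surge_threshold:
            nxt = by_day.get(t.cycle_day + 1)
            if nxt is not None and nxt.lh_iu_l < t.lh_iu_l:
                return t.cycle_day
    return None


def detect_follicle_rupture(tests: Sequence[TestDayRecord],
                            config: LabelingConfig = LabelingConfig()) -> Optional[int]:
    """Earliest day where a >= 17 mm leading follicle has collapsed.

    A day r counts if some earlier day p (r - p <= window) showed the
    follicle at >= ``follicle_rupture_mm`` and on day r the follicle is
    either absent from an otherwise ultrasound-covered visit after having
    been seen, or measured below ``follicle_collapse_mm``.
    """
    ordered = _sorted(tests)
    seen_any = False
    for i, t in enumerate(ordered):
        collapsed = False
        if t.follicle_mm is not None and t.follicle_mm < config.follicle_collapse_mm:
            collapsed = True
        elif t.follicle_mm is None and seen_any:
            collapsed = True
        if collapsed:
            for prev in ordered[:i]:
                if (prev.follicle_mm is not None
                        and prev.follicle_mm >= config.follicle_rupture_mm
                        and t.cycle_day - prev.cycle_day <= config.rupture_window_days):
                    return t.cycle_day
        if t.follicle_mm is not None:
            seen_any = True
    return None


def label_ovulation(cycle: CycleRecord,
                    config: LabelingConfig = LabelingConfig()) -> LabelResult:
    """Determine the ovulation day of a fully observed cycle.

    strict: labeled iff both criteria fire and rupture = surge + 1.
    either: labeled from whichever criterion fires (rupture day preferred,
    else surge day + 1).
    """
    surge = detect_lh_surge(cycle.tests, config)
    rupture = detect_follicle_rupture(cycle.tests, config)
    if config.mode == "strict":
        if surge is not None and rupture is not None and rupture == surge + 1:
            return LabelResult(ovulation_day=rupture, status="labeled",
                               evidence=frozenset({"lh_surge", "follicle_rupture"}))
        return LabelResult(ovulation_day=None, status="uncertain")
    # either
    if rupture is not None:
        evidence = {"follicle_rupture"}
        if surge is not None and rupture == surge + 1:
            evidence.add("lh_surge")
        return LabelResult(ovulation_day=rupture, status="labeled",
                           evidence=frozenset(evidence))
    if surge is not None:
        return LabelResult(ovulation_day=surge + 1, status="labeled",
                           evidence=frozenset({"lh_surge"}))
    return LabelResult(ovulation_day=None, status="uncertain")


def filter_uncertain(cycles: Sequence[CycleRecord],
                     config: LabelingConfig = LabelingConfig(),
                     ) -> tuple[list[CycleRecord], int]:
    """Relabel cycles retrospectively and drop the uncertain ones.

    Returns the labeled cycles (ovulation day replaced by the retro label,
    ``label_source='retro_label'``) and the number excluded.
    """
    labeled: list[CycleRecord] = []
    n_excluded = 0
    for cycle in cycles:
        result = label_ovulation(cycle, config)
        if result.status == "labeled":
            labeled.append(CycleRecord(
                baseline=cycle.baseline, tests=list(cycle.tests),
                cycle_id=cycle.cycle_id, ovulation_day=result.ovulation_day,
                label_source="retro_label"))
        else:
            n_excluded += 1
    return labeled, n_excluded
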