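"""Synthetic natural-cycle generator.

Produces seeded menstrual cycles with the endocrine and ultrasound
structure that retrospective ovulation labeling assumes: an LH surge the
day before follicular rupture (LH >= 17 IU/L with a decrease by the day
after rupture), a leading follicle growing roughly 1.5 mm/day to >= 17 mm
and collapsing on the ovulation day, estradiol peaking the day before
ovulation, progesterone staying low (< 3 nmol/L) until ovulation and
rising for several days after, and an endometrium thickening toward a
per-cycle target.

Trajectory shapes are deliberately phenomenological (piecewise analytic
curves with multiplicative log-normal noise), not mechanistic endocrine
feedback models; every shape parameter lives in :class:`SimulationConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import Baseline, CycleRecord, TestDayRecord


class SurgeInvariantError(RuntimeError):
    """Raised when noise keeps breaking the LH-surge/rupture invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of the synthetic cycle generator.

    Population parameters (ovulation day 16.00 +- 5.08, endometrium
    9.55 +- 1.99 mm at the last test, age 36.44 +- 5.80 y, BMI
    24.27 +- 5.66 kg/m^2, 7.66% smokers) default to the clinical cohort
    the generator emulates.
    """

    # ovulation day distribution (discretized truncated normal)
    ovulation_day_mean: float = 16.00
    ovulation_day_sd: float = 5.08
    ovulation_day_min: int = 8
    ovulation_day_max: int = 35
    # baseline covariates
    age_mean: float = 36.44
    age_sd: float = 5.80
    age_min: float = 18.0
    age_max: float = 55.0
    bmi_mean: float = 24.27
    bmi_sd: float = 5.66
    bmi_min: float = 14.0
    bmi_max: float = 60.0
    smoker_prob: float = 0.0766
    # labeling-relevant thresholds
    lh_surge_threshold: float = 17.0
    follicle_rupture_mm: float = 17.0
    # hormone trajectory shapes
    lh_base: float = 5.0
    lh_peak: float = 45.0
    lh_surge_width_days: float = 0.75
    e2_base: float = 150.0
    e2_peak: float = 1200.0
    e2_luteal: float = 500.0
    e2_rise_days: float = 9.0
    e2_fall_tau_days: float = 1.2
    p4_base: float = 1.5
    p4_luteal_slope: float = 6.0
    p4_luteal_max: float = 35.0
    # ultrasound trajectory shapes
    follicle_peak_mm: float = 18.4
    follicle_growth_mm_per_day: float = 1.5
    follicle_start_mm: float = 4.0
    follicle_collapsed_mm: float = 8.0
    endometrium_target_mean: float = 9.55
    endometrium_target_sd: float = 1.99
    endometrium_start_mm: float = 4.0
    endometrium_tau_days: float = 5.0
    # noise and missingness
    hormone_noise_scale: float = 0.15
    ultrasound_noise_scale: float = 0.05
    ultrasound_missing_prob: float = 0.10
    # grid / termination
    days_after_ovulation: int = 5
    max_cycle_day: int = 45
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.ovulation_day_min > self.ovulation_day_max:
            raise ValueError("ovulation_day_min must be <= ovulation_day_max")
        for name in ("ovulation_day_sd", "age_sd", "bmi_sd", "endometrium_target_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ultrasound_missing_prob <= 1.0:
            raise ValueError("ultrasound_missing_prob must be in [0, 1]")

    def noise_free(self) -> "SimulationConfig":
        """A copy with all stochastic perturbations switched off."""
        return replace(
            self,
            hormone_noise_scale=0.0,
            ultrasound_noise_scale=0.0,
            ultrasound_missing_prob=0.0,
            endometrium_target_sd=0.0,
        )


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    if sd == 0:
        return None
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    dist = _truncnorm(mean, sd, lo, hi)
    if dist is None:
        return float(min(max(mean, lo), hi))
    return float(dist.ppf(rng.uniform()))


def ovulation_day_pmf(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Discretized truncated-normal pmf over integer ovulation days.

    Integer day k receives the truncated-normal mass of [k-0.5, k+0.5]
    (support extended half a day past the integer bounds), renormalized.
    """
    lo, hi = config.ovulation_day_min, config.ovulation_day_max
    days = np.arange(lo, hi + 1)
    if config.ovulation_day_sd == 0:
        target = int(round(min(max(config.ovulation_day_mean, lo), hi)))
        probs = (days == target).astype(float)
        return days, probs
    dist = _truncnorm(config.ovulation_day_mean, config.ovulation_day_sd,
                      lo - 0.5, hi + 0.5)
    probs = dist.cdf(days + 0.5) - dist.cdf(days - 0.5)
    return days, probs / probs.sum()


def sample_baseline(rng: np.random.Generator, config: SimulationConfig,
                    patient_id: str = "p0") -> Baseline:
    """Draw baseline covariates from truncated normals / Bernoulli."""
    age = _sample_truncnorm(rng, config.age_mean, config.age_sd,
                            config.age_min, config.age_max)
    bmi = _sample_truncnorm(rng, config.bmi_mean, config.bmi_sd,
                            config.bmi_min, config.bmi_max)
    smoker = bool(rng.uniform() < config.smoker_prob)
    return Baseline(patient_id=patient_id, age_years=age, bmi_kg_m2=bmi, smoker=smoker)


def sample_ovulation_day(rng: np.random.Generator, config: SimulationConfig) -> int:
    """Draw an integer ovulation day from the discretized truncated normal."""
    days, probs = ovulation_day_pmf(config)
    return int(rng.choice(days, p=probs))


# ---------------------------------------------------------------------------
# noise-free trajectory shapes


def _lh_shape(day: int, o: int, c: SimulationConfig) -> float:
    return c.lh_base + (c.lh_peak - c.lh_base) * math.exp(
        -(((day - (o - 1)) / c.lh_surge_width_days) ** 2))


def _e2_shape(day: int, o: int, c: SimulationConfig) -> float:
    peak_day = o - 1
    if day <= peak_day:
        progress = min(max((day - (peak_day - c.e2_rise_days)) / c.e2_rise_days, 0.0), 1.0)
        return c.e2_base * (c.e2_peak / c.e2_base) ** progress
    return c.e2_luteal + (c.e2_peak - c.e2_luteal) * math.exp(
        -(day - peak_day) / c.e2_fall_tau_days)


def _p4_shape(day: int, o: int, c: SimulationConfig) -> float:
    if day < o:
        return c.p4_base
    return min(c.p4_base + c.p4_luteal_slope * (day - o + 1), c.p4_luteal_max)


def _follicle_shape(day: int, o: int, c: SimulationConfig) -> Optional[float]:
    """Pre-rupture growth at ~growth mm/day peaking the day before O; None after."""
    if day >= o:
        return None  # collapsed; the collapsed remnant size is applied separately
    size = c.follicle_peak_mm + c.follicle_growth_mm_per_day * (day - (o - 1))
    return max(size, c.follicle_start_mm)


def _endometrium_shape(day: int, target: float, c: SimulationConfig) -> float:
    return target - (target - c.endometrium_start_mm) * math.exp(
        -(day - 1) / c.endometrium_tau_days)


def _lognoise(rng: np.random.Generator, scale: float) -> float:
    return math.exp(rng.normal(0.0, scale)) if scale > 0 else 1.0


def simulate_cycle(rng: np.random.Generator, baseline: Baseline, ovulation_day: int,
                   config: SimulationConfig, cycle_id: str = "1") -> CycleRecord:
    """Simulate a full daily grid of monitoring days for one cycle.

    The grid runs from day 1 to ``ovulation_day + days_after_ovulation``
    (capped at ``max_cycle_day``).  Noise realizations that break the
    surge/rupture invariant (LH(O-1) >= threshold, LH falling through
    O..O+1, follicle(O-1) >= rupture size) are rejected and resampled up
    to ``max_retries`` times.
    """
    o = ovulation_day
    if not config.ovulation_day_min <= o <= config.ovulation_day_max:
        raise ValueError(
            f"ovulation_day {o} outside configured support "
            f"[{config.ovulation_day_min}, {config.ovulation_day_max}]")
    last_day = min(o + config.days_after_ovulation, config.max_cycle_day)
    em_target = max(
        config.endometrium_start_mm,
        rng.normal(config.endometrium_target_mean, config.endometrium_target_sd)
        if config.endometrium_target_sd > 0 else config.endometrium_target_mean,
    )

    for _ in range(config.max_retries):
        tests: list[TestDayRecord] = []
        lh_by_day: dict[int, float] = {}
        foll_pre_missing: dict[int, Optional[float]] = {}
        for day in range(1, last_day + 1):
            lh = _lh_shape(day, o, config) * _lognoise(rng, config.hormone_noise_scale)
            e2 = _e2_shape(day, o, config) * _lognoise(rng, config.hormone_noise_scale)
            p4 = _p4_shape(day, o, config) * _lognoise(rng, config.hormone_noise_scale)
            foll = _follicle_shape(day, o, config)
            if foll is None:
                foll_val = config.follicle_collapsed_mm * _lognoise(
                    rng, config.ultrasound_noise_scale)
            else:
                foll_val = foll * _lognoise(rng, config.ultrasound_noise_scale)
            em = _endometrium_shape(day, em_target, config) * _lognoise(
                rng, config.ultrasound_noise_scale)
            lh_by_day[day] = lh
            foll_pre_missing[day] = foll_val if day < o else None

            follicle_out: Optional[float] = foll_val
            endometrium_out: Optional[float] = em
            if config.ultrasound_missing_prob > 0:
                if rng.uniform() < config.ultrasound_missing_prob:
                    follicle_out = None
                if rng.uniform() < config.ultrasound_missing_prob:
                    endometrium_out = None
            if day >= o:
                # collapsed follicle may read as a small remnant or be absent
                if config.ultrasound_missing_prob > 0 and rng.uniform() < 0.5:
                    follicle_out = None
            tests.append(TestDayRecord(
                cycle_day=day, lh_iu_l=lh, e2=e2, p4=p4,
                follicle_mm=follicle_out, endometrium_mm=endometrium_out))

        surge_ok = lh_by_day.get(o - 1, 0.0) >= config.lh_surge_threshold
        if surge_ok and o in lh_by_day:
            surge_ok = lh_by_day[o] < lh_by_day[o - 1]
        if surge_ok and o + 1 in lh_by_day:
            surge_ok = lh_by_day[o + 1] < lh_by_day[o - 1]
        pre_rupture = foll_pre_missing.get(o - 1)
        foll_ok = pre_rupture is not None and pre_rupture >= config.follicle_rupture_mm
        if surge_ok and foll_ok:
            return CycleRecord(baseline=baseline, tests=tests, cycle_id=cycle_id,
                               ovulation_day=o, label_source="simulated_truth")
    raise SurgeInvariantError(
        f"could not satisfy surge/rupture invariant for O={o} after "
        f"{config.max_retries} retries")


OBSERVATION_POLICIES = ("sparse_then_dense", "daily_window", "fixed_days")


def sample_observation_schedule(rng: np.random.Generator, cycle: CycleRecord,
                                policy: str = "sparse_then_dense",
                                fixed_days: Optional[Sequence[int]] = None,
                                ) -> list[int]:
    """Pick physician-like monitoring days from a fully simulated cycle.

    ``sparse_then_dense`` (default) starts with one early-follicular visit
    on day 6-10 (never after ovulation) and revisits every 1-3 days until
    the day after ovulation.  ``daily_window`` observes every day from day
    6 through O+1.  ``fixed_days`` returns the given days restricted to
    the cycle grid.
    """
    grid = cycle.test_days
    if not grid:
        return []
    last = grid[-1]
    o = cycle.ovulation_day if cycle.ovulation_day is not None else last
    if policy == "fixed_days":
        if fixed_days is None:
            raise ValueError("fixed_days policy requires a day list")
        days = sorted(set(int(d) for d in fixed_days))
        missing = [d for d in days if d not in set(grid)]
        if missing:
            raise ValueError(f"fixed days {missing} not on the cycle grid")
        return days
    if policy == "daily_window":
        start = min(6, last)
        return [d for d in grid if start <= d <= min(o + 1, last)] or [grid[0]]
    if policy == "sparse_then_dense":
        hi = min(10, o, last)
        lo = min(6, hi)
        day = int(rng.integers(lo, hi + 1))
        days = [day]
        while day < min(o + 1, last):
            day = min(day + int(rng.integers(1, 4)), last)
            days.append(day)
        return days
    raise ValueError(f"unknown observation policy {policy!r}; "
                     f"expected one of {OBSERVATION_POLICIES}")


def generate_dataset(rng: np.random.Generator, n_cycles: int,
                     config: SimulationConfig = SimulationConfig(),
                     policy: str = "sparse_then_dense",
                     fixed_days: Optional[Sequence[int]] = None,
                     keep_full_grid: bool = False) -> list[CycleRecord]:
    """Generate ``n_cycles`` observed synthetic cycles (one per patient).

    Each cycle is built baseline -> ovulation day -> daily simulation ->
    observation schedule; unless ``keep_full_grid`` the returned record
    retains only the observed test days.  Ovulation day carries the
    simulated truth (``label_source='simulated_truth'``).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    cycles = []
    width = len(str(n_cycles))
    for i in range(n_cycles):
        baseline = sample_baseline(rng, config, patient_id=f"p{i:0{width}d}")
        o = sample_ovulation_day(rng, config)
        full = simulate_cycle(rng, baseline, o, config, cycle_id="1")
        if keep_full_grid:
            cycles.append(full)
            continue
        days = set(sample_observation_schedule(rng, full, policy, fixed_days))
        observed = [t for t in full.tests if t.cycle_day in days]
        cycles.append(CycleRecord(
            baseline=baseline, tests=observed, cycle_id="1",
            ovulation_day=o, label_source="simulated_truth"))
    return cycles
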