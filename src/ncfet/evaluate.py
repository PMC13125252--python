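"""Simulation-based statistical evaluation of the treatment scheduler.

The evaluation combines three ingredients: the probability of ovulating
on each cycle day (an integer pmf), the classifier's class-conditional
error matrix P(predicted class | actual class), and the scheduling rules.
For a drawn ovulation day, each simulated monitoring visit has a
deterministic actual class (the clipped day offset) and a predicted class
sampled from the error matrix; the rules then decide the next visit,
transfer, or cancellation.  Outcomes:

* correct    - transfer scheduled with the true ovulation day;
* incorrect  - transfer scheduled with a wrong ovulation day;
* no_prediction - cancelled because monitoring started two or more days
  after ovulation;
* aborted    - cancelled at the cycle-day horizon.

Rates come either from Monte Carlo (repeated batches; Wilson score
intervals on the pooled counts, normal-theory interval for the mean test
count across repeats) or from exact enumeration of the finite trajectory
tree, which serves as a brute-force oracle for the Monte Carlo path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .engine import NTMAConfig, step
from .records import CLASS_ORDER, OvulationClass

_REPS = np.array([c.representative_int for c in CLASS_ORDER])
_TRANSFER_IDX = np.array([int(OvulationClass.M1), int(OvulationClass.ZERO),
                          int(OvulationClass.P1)])
_N_CLASSES = len(CLASS_ORDER)

OUTCOMES = ("correct", "incorrect", "no_prediction", "aborted")


@dataclass(frozen=True)
class ErrorModel:
    """Row-stochastic matrix P(predicted class | actual class)."""

    matrix: np.ndarray  # (9, 9), rows = actual, columns = predicted

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (_N_CLASSES, _N_CLASSES):
            raise ValueError(f"error matrix must be 9x9, got {m.shape}")
        if (m < 0).any():
            raise ValueError("error matrix entries must be >= 0")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("error matrix rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "ErrorModel":
        return cls(np.eye(_N_CLASSES))

    @classmethod
    def uniform(cls) -> "ErrorModel":
        return cls(np.full((_N_CLASSES, _N_CLASSES), 1.0 / _N_CLASSES))

    def mix_with_uniform(self, lam: float) -> "ErrorModel":
        """Degrade the model: (1 - lam) * self + lam * uniform."""
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        return ErrorModel((1 - lam) * self.matrix
                          + lam * np.full_like(self.matrix, 1.0 / _N_CLASSES))


def error_model_from_confusion(report) -> ErrorModel:
    """Column-normalize a predicted-by-actual confusion into P(pred | actual).

    Actual classes never seen in the test data fall back to an identity
    row (predict the true class) with a warning.
    """
    import warnings

    counts = np.asarray(report.counts, dtype=float)  # [predicted, actual]
    matrix = np.zeros((_N_CLASSES, _N_CLASSES))
    col_tot = counts.sum(axis=0)
    for actual in range(_N_CLASSES):
        if col_tot[actual] > 0:
            matrix[actual, :] = counts[:, actual] / col_tot[actual]
        else:
            warnings.warn(
                f"actual class {CLASS_ORDER[actual].name} absent from the "
                f"confusion report; using an identity row", stacklevel=2)
            matrix[actual, actual] = 1.0
    return ErrorModel(matrix)


@dataclass(frozen=True)
class OvulationPMF:
    """Probability of ovulating on each integer cycle day (finite support)."""

    days: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        probs = np.asarray(self.probs, dtype=float)
        if days.shape != probs.shape or days.ndim != 1:
            raise ValueError("days and probs must be matching 1-d arrays")
        if (np.diff(days) <= 0).any():
            raise ValueError("days must be strictly increasing")
        if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("probs must be non-negative and sum to 1")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def from_truncated_normal(cls, mean: float = 16.00, sd: float = 5.08,
                              day_min: int = 8, day_max: int = 35) -> "OvulationPMF":
        """Discretized truncated normal: integer day k gets the [k-.5, k+.5] mass."""
        days = np.arange(day_min, day_max + 1)
        a = (day_min - 0.5 - mean) / sd
        b = (day_max + 0.5 - mean) / sd
        dist = stats.truncnorm(a, b, loc=mean, scale=sd)
        probs = dist.cdf(days + 0.5) - dist.cdf(days - 0.5)
        return cls(days, probs / probs.sum())

    @classmethod
    def from_observed_days(cls, ovulation_days: Sequence[int]) -> "OvulationPMF":
        """Empirical pmf from a list of labeled ovulation days."""
        if not len(ovulation_days):
            raise ValueError("no ovulation days supplied")
        vals, counts = np.unique(np.asarray(ovulation_days, dtype=int),
                                 return_counts=True)
        return cls(vals, counts / counts.sum())

    def mass_at_most(self, day: int) -> float:
        return float(self.probs[self.days <= day].sum())

    def mean(self) -> float:
        return float((self.days * self.probs).sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.days, size=n, p=self.probs)


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    return (center - half, center + half)


@dataclass
class EvaluationReport:
    """Outcome rates and monitoring burden with 95% confidence intervals."""

    correct_rate: float
    incorrect_rate: float
    no_prediction_rate: float
    aborted_rate: float
    mean_tests: float
    correct_within_1_rate: float
    ci: dict[str, tuple[float, float]]
    n_samples: int
    n_repeats: int
    method: str
    per_repeat: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.correct_rate + self.incorrect_rate
                 + self.no_prediction_rate + self.aborted_rate)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"outcome rates sum to {total}, not 1")

    def to_jsonable(self) -> dict:
        return {
            "method": self.method,
            "correct_rate": self.correct_rate,
            "incorrect_rate": self.incorrect_rate,
            "no_prediction_rate": self.no_prediction_rate,
            "aborted_rate": self.aborted_rate,
            "correct_within_1_rate": self.correct_within_1_rate,
            "mean_tests": self.mean_tests,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_samples": self.n_samples,
            "n_repeats": self.n_repeats,
            "per_repeat": self.per_repeat,
        }

    def summary(self) -> str:
        def pct(name: str, value: float) -> str:
            lo, hi = self.ci[name]
            return f"{100 * value:.2f} [{100 * lo:.2f}-{100 * hi:.2f}]"

        lo, hi = self.ci["mean_tests"]
        lines = [
            f"Correct prediction rate (%)     {pct('correct_rate', self.correct_rate)}",
            f"Incorrect prediction rate (%)   {pct('incorrect_rate', self.incorrect_rate)}",
            f"No prediction rate (%)          {pct('no_prediction_rate', self.no_prediction_rate)}",
            f"Average number of tests         {self.mean_tests:.2f} [{lo:.2f}-{hi:.2f}]",
        ]
        if self.aborted_rate > 0:
            lines.append(f"Aborted at horizon (%)          "
                         f"{pct('aborted_rate', self.aborted_rate)}")
        return "\n".join(lines)


def simulate_outcome(ovulation_day: int, error_model: ErrorModel,
                     config: NTMAConfig, rng: np.random.Generator,
                     ) -> tuple[str, int]:
    """Walk one cycle through the rules with sampled class predictions."""
    day = config.initial_test_day
    n_tests = 0
    while True:
        n_tests += 1
        actual = OvulationClass.from_difference(day - ovulation_day)
        pred_idx = int(rng.choice(_N_CLASSES, p=error_model.matrix[int(actual)]))
        rec = step(day, CLASS_ORDER[pred_idx], config)
        if rec.action == "TRANSFER":
            outcome = ("correct" if rec.predicted_ovulation_day == ovulation_day
                       else "incorrect")
            return outcome, n_tests
        if rec.action == "CANCEL":
            return ("aborted" if rec.reason == "max_day" else "no_prediction",
                    n_tests)
        day = rec.next_test_day


def _next_day_for_class(day: int, pred: int, config: NTMAConfig) -> int:
    """Next test day implied by a non-terminal predicted class index."""
    if pred == int(OvulationClass.LE_M6):
        return day + config.far_retest_interval_days
    return day - _REPS[pred] - 1


def _simulate_batch(ovulation_days: np.ndarray, error_model: ErrorModel,
                    config: NTMAConfig, rng: np.random.Generator,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized trajectory sampling.

    Returns (outcome codes 0..3 per OUTCOMES order, test counts,
    within-1-day correctness flags).
    """
    n = len(ovulation_days)
    cum = np.cumsum(error_model.matrix, axis=1)
    day = np.full(n, config.initial_test_day, dtype=int)
    active = np.ones(n, dtype=bool)
    outcome = np.full(n, -1, dtype=int)
    n_tests = np.zeros(n, dtype=int)
    within1 = np.zeros(n, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        d = day[idx]
        o = ovulation_days[idx]
        n_tests[idx] += 1
        actual = np.clip(d - o, -6, 2) + 6  # class index 0..8
        u = rng.uniform(size=len(idx))
        pred = np.minimum((u[:, None] > cum[actual]).sum(axis=1), _N_CLASSES - 1)
        is_transfer = np.isin(pred, _TRANSFER_IDX)
        is_cancel = pred == int(OvulationClass.GE_P2)
        pred_o = d - _REPS[pred]
        # transfers
        t = idx[is_transfer]
        outcome[t] = np.where(pred_o[is_transfer] == o[is_transfer], 0, 1)
        within1[t] = np.abs(pred_o[is_transfer] - o[is_transfer]) <= 1
        # cancellations (monitoring started too late)
        outcome[idx[is_cancel]] = 2
        # continuing samples
        cont = ~(is_transfer | is_cancel)
        nxt = np.where(pred[cont] == int(OvulationClass.LE_M6),
                       d[cont] + config.far_retest_interval_days,
                       d[cont] - _REPS[pred[cont]] - 1)
        over = nxt > config.max_cycle_day
        outcome[idx[cont][over]] = 3
        day[idx[cont][~over]] = nxt[~over]
        active[idx] = False
        active[idx[cont][~over]] = True
    return outcome, n_tests, within1


def evaluate_monte_carlo(pmf: OvulationPMF, error_model: ErrorModel,
                         config: NTMAConfig = NTMAConfig(),
                         n_samples: int = 10_000, n_repeats: int = 30,
                         rng: Optional[np.random.Generator] = None,
                         ) -> EvaluationReport:
    """Monte Carlo evaluation: ``n_repeats`` batches of ``n_samples`` cycles.

    Proportion CIs are Wilson intervals on the pooled outcome counts; the
    mean-test-count CI is the normal-theory interval on the across-repeat
    means.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    pooled = np.zeros(4, dtype=int)
    pooled_within1 = 0
    per_repeat: dict[str, list[float]] = {k: [] for k in OUTCOMES}
    per_repeat["mean_tests"] = []
    per_repeat["tests_sd"] = []
    for _ in range(n_repeats):
        o_days = pmf.sample(rng, n_samples)
        outcome, n_tests, within1 = _simulate_batch(o_days, error_model, config, rng)
        counts = np.bincount(outcome, minlength=4)
        pooled += counts
        pooled_within1 += int(within1.sum())
        for k, c in zip(OUTCOMES, counts):
            per_repeat[k].append(float(c / n_samples))
        per_repeat["mean_tests"].append(float(n_tests.mean()))
        per_repeat["tests_sd"].append(float(n_tests.std(ddof=1)) if n_samples > 1
                                      else 0.0)
    total = int(pooled.sum())
    rates = pooled / total
    ci = {f"{k}_rate": wilson_ci(int(c), total) for k, c in zip(OUTCOMES, pooled)}
    ci["correct_within_1_rate"] = wilson_ci(pooled_within1, total)
    means = np.asarray(per_repeat["mean_tests"])
    if n_repeats > 1:
        half = 1.959963984540054 * means.std(ddof=1) / math.sqrt(n_repeats)
    else:
        half = 0.0
    ci["mean_tests"] = (float(means.mean() - half), float(means.mean() + half))
    return EvaluationReport(
        correct_rate=float(rates[0]), incorrect_rate=float(rates[1]),
        no_prediction_rate=float(rates[2]), aborted_rate=float(rates[3]),
        mean_tests=float(means.mean()),
        correct_within_1_rate=float(pooled_within1 / total),
        ci=ci, n_samples=n_samples, n_repeats=n_repeats,
        method="monte_carlo", per_repeat=per_repeat)


def evaluate_exact(pmf: OvulationPMF, error_model: ErrorModel,
                   config: NTMAConfig = NTMAConfig(),
                   node_budget: int = 2_000_000) -> EvaluationReport:
    """Exact outcome probabilities by enumerating the finite trajectory tree.

    For each ovulation day the reachable test days carry probability
    mass; each visit splits that mass across the nine predicted classes.
    Branches that revisit the same next test day merge, so the tree
    collapses to at most one state per (ovulation day, test day).
    """
    n_nodes = len(pmf.days) * (config.max_cycle_day + 1) * _N_CLASSES
    if n_nodes > node_budget:
        raise ValueError(
            f"exact enumeration needs ~{n_nodes} nodes (> budget {node_budget}); "
            f"use evaluate_monte_carlo")
    m = error_model.matrix
    p_outcome = np.zeros(4)
    p_within1 = 0.0
    exp_tests = 0.0
    for o, p_o in zip(pmf.days, pmf.probs):
        mass: dict[int, float] = {config.initial_test_day: 1.0}
        while mass:
            new_mass: dict[int, float] = {}
            for day, p_day in mass.items():
                exp_tests += p_o * p_day
                actual = min(max(day - o, -6), 2) + 6
                for pred in range(_N_CLASSES):
                    p_branch = p_day * m[actual, pred]
                    if p_branch == 0.0:
                        continue
                    cls = CLASS_ORDER[pred]
                    if cls in config.transfer_classes:
                        pred_o = day - cls.representative_int
                        p_outcome[0 if pred_o == o else 1] += p_o * p_branch
                        if abs(pred_o - o) <= 1:
                            p_within1 += p_o * p_branch
                    elif cls == config.cancel_class:
                        p_outcome[2] += p_o * p_branch
                    else:
                        nxt = _next_day_for_class(day, pred, config)
                        if nxt > config.max_cycle_day:
                            p_outcome[3] += p_o * p_branch
                        else:
                            new_mass[nxt] = new_mass.get(nxt, 0.0) + p_branch
            mass = new_mass
    ci = {f"{k}_rate": (float(p), float(p)) for k, p in zip(OUTCOMES, p_outcome)}
    ci["correct_within_1_rate"] = (p_within1, p_within1)
    ci["mean_tests"] = (exp_tests, exp_tests)
    return EvaluationReport(
        correct_rate=float(p_outcome[0]), incorrect_rate=float(p_outcome[1]),
        no_prediction_rate=float(p_outcome[2]), aborted_rate=float(p_outcome[3]),
        mean_tests=float(exp_tests), correct_within_1_rate=float(p_within1),
        ci=ci, n_samples=0, n_repeats=0, method="exact")
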