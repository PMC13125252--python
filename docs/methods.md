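# Methods

This note documents the models, parameters, numerical choices, and known
limitations of the `ncfet` package: what each layer computes, why its
defaults are what they are, and what the synthetic results do and do not
say about clinical data.

## Conventions and units

Cycle days are 1-based; day 1 is the first day of menses. The ovulation
day *O* is the day of follicular rupture; the LH surge day is *O*−1.
LH is in IU/L, estradiol (E2) in pmol/L, progesterone (P4) in nmol/L,
ultrasound measurements in mm. Any consistent unit convention works —
the classifier consumes raw values — but the simulator and documentation
use this one throughout. Missing measurements are `None` in records, NaN
in feature vectors, and the empty string in CSV files.

## Synthetic cycle simulator

The simulator is phenomenological, not mechanistic: each quantity follows
a deterministic analytic shape in the distance to ovulation, multiplied
by log-normal noise. This is a deliberate choice — the downstream
algorithms depend only on a handful of qualitative facts (surge timing,
rupture, the luteal P4 rise, the E2 peak), so a feedback ODE model of the
hypothalamic–pituitary–ovarian axis would add parameters without adding
test power. The facts the simulator guarantees:

* **LH**: baseline ≈ 5 IU/L with a Gaussian-bump surge peaking at
  ≈ 45 IU/L on day *O*−1 (width 0.75 d), so LH(*O*−1) ≥ 17 IU/L and
  LH declines through *O* and *O*+1.
* **Leading follicle**: grows 1.5 mm/day to ≈ 18.4 mm on day *O*−1
  (≥ 17 mm even under ultrasound noise), then collapses to a small
  remnant (or disappears from the scan) from day *O*.
* **E2**: geometric rise across the follicular phase, peak on *O*−1
  (≈ 1200 pmol/L), exponential fall toward a luteal plateau.
* **P4**: < 3 nmol/L before *O*, then rising ≈ 6 nmol/L/day for at least
  four days, capped at 35 nmol/L.
* **Endometrium**: saturating growth toward a per-cycle target drawn from
  N(9.55, 1.99²) mm, so the last-test thickness matches the cohort value.

Noise scales default to 0.15 (log-sd) for hormones and 0.05 for
ultrasound; ultrasound fields are additionally missing with probability
0.10 per visit, emulating visits without a scan. A noise draw that breaks
the surge/rupture invariant is rejected and resampled, up to 100 times
per cycle before a hard error; rejection keeps the invariant exact
without silently biasing the hormone levels more than necessary.

Population parameters default to a realistic NC-FET cohort: ovulation day
from a truncated normal (mean 16.00, sd 5.08) discretized onto integer
days 8–35 (each integer day takes the mass of its ±0.5 interval), age
36.44 ± 5.80 y on [18, 55], BMI 24.27 ± 5.66 kg/m² on [14, 60], 7.66%
smokers. Note that truncation shifts sampled means away from the location
parameter where the support is asymmetric (BMI mean ≈ 24.66); tests
compare against the truncated-normal mean, not the location.

Observation schedules emulate physician-chosen monitoring: the default
`sparse_then_dense` policy starts with one early-follicular visit on day
6–10 and revisits every 1–3 days until the day after ovulation. The
first visit is drawn from [6, min(10, *O*)] so that every schedule
contains at least one pre-ovulatory day — a convenience for building
labeled retrospective datasets, not a claim about clinical practice.

## Retrospective labeling (teacher surrogate)

Cycles are labeled from full-cycle evidence: the LH surge day is the
earliest day with LH ≥ 17 IU/L and a lower value on the next calendar
day; follicular rupture is the earliest day on which a follicle
previously measured ≥ 17 mm (within the last 2 days) is collapsed —
below 12 mm, or absent from a scan after having been seen. In `strict`
mode (default) a cycle is labeled only when both criteria fire and
rupture = surge + 1; the rupture day is the ovulation day. `either` mode
accepts single-criterion evidence (rupture preferred, else surge + 1).
The collapse threshold (12 mm) and 2-day rupture window are configurable
choices; only the ≥ 17 mm size and next-day-decrease rules are anchored
in monitoring practice. On noise-free, daily-observed simulated cycles
the strict label provably equals the simulated truth; under default noise
about 10% of cycles are filtered as uncertain and essentially all kept
labels are exact.

## Instances and features

From a cycle's observed test days, instances are all single days plus all
ordered pairs at most 4 days apart (wider pairs add nothing). The class
label is last test day − ovulation day, clipped into nine bins
(≤ −6, −5, −4, −3, −2, −1, 0, +1, ≥ +2). A single-day instance treats its
day as both first and second day, so d1 features duplicate d2 features
and slope features are undefined.

The feature registry is fixed and data-driven: per-day LH, E2, P4,
follicle size and endometrial thickness for both days; the E2/P4 ratio on
the second day (missing when P4 = 0); per-day slopes ((v2−v1)/gap,
missing for single days); the day indices and gap; and age, BMI, smoking.
Cycle-day indices are genuinely informative (the ovulation-day prior is
concentrated), which is part of why far-from-ovulation instances classify
so well; they are ordinary registry entries and can be dropped without
code changes.

Splits are by patient — every instance of a patient lands in exactly one
of train (60%), validation+calibration (25%), test (15%) — preventing
leakage of within-cycle correlation. Patients are shuffled and cut at the
cumulative fractions; the shuffle is redrawn (≤ 20 times) until each
split's class distribution is within 0.10 total variation of the global
one. The 25% block is further split 60/40 by patient into a validation
set (hyperparameter selection) and a calibration set.

## Student classifier

A multiclass XGBoost ensemble (`multi:softprob`, `hist`, single thread
for reproducibility) maps the 21-feature vector to nine class
probabilities; tree splits route missing values natively, so instances
with no ultrasound need no imputation. Grid search (learning rate
{0.05, 0.1, 0.3} × depth {3, 5, 7} × trees {100, 300}) maximizes
validation accuracy, breaking ties toward the simpler model (smaller
depth, then smaller learning rate, then fewer trees). The benchmark
pipeline uses fixed mid-grid settings (0.1 / 5 / 300) as its default.

Calibration is one-vs-rest and monotone: for each class, isotonic
regression of the binary indicator on the class score, fitted on the
calibration block (classes absent there are skipped with a warning;
Platt sigmoid is available as an option). Calibrated per-class scores are
renormalized to a probability vector only at prediction time; a repeated
calibration pass fits on the current calibrated scores, which makes
recalibration on the same data an exact fixed point of the isotonic map.
Prediction is the argmax with a clinically conservative tie-break: ties
go to the bin closest to the same-day class 0, and on equal distance to
the later bin (a transfer one day after ovulation is still viable; one
day early is not).

Reports: the confusion matrix is predicted × actual with columns
normalized to 100% per actual class (one of two readings of cumulative
column percentages; fixed here as column normalization), per-class and
overall accuracy, and optional reporting subsets (e.g. single test days
on cycle days 6–10). Feature importance is XGBoost total gain, ranked
descending with name tie-breaks.

## Treatment-management rules (NTMA)

The deployed rule set is class-driven (the probability vector is reduced
to its argmax):

| predicted class | action |
| --- | --- |
| ≤ −6 | next test in 4 days |
| −5 … −2 | next test on predicted *O* − 1, where *O* = day − offset |
| −1, 0, +1 | transfer on *O* + embryo stage (default 5 days) |
| ≥ +2 | cancel: ovulation passed ≥ 2 days ago, day unrecoverable |

Monitoring starts on cycle day 8. In closed loop, each visit's instance
pairs the current day with the most recent prior test if it is within 4
days (mirroring the training-instance constraint), else it is a
single-day instance. A retest that would land beyond `max_cycle_day`
(default 35) cancels the cycle; without this invented horizon the state
machine need not terminate. With a perfect predictor the rules transfer
on the true ovulation day for every *O* ≥ 7 and cancel exactly when
*O* ≤ initial day − 2 — both verified by exhaustive sweep.

## Policy evaluation

The evaluation needs only three ingredients: the ovulation-day pmf, the
error matrix P(predicted | actual) (obtained by column-normalizing a
confusion report; never-observed actual classes fall back to an identity
row with a warning), and the rules. Given *O*, a visit's actual class is
deterministic (clipped day offset); the predicted class is sampled from
the error matrix row; the rules advance the day. Outcomes partition into
correct / incorrect / no-prediction / aborted-at-horizon, and the visit
count includes the initial day-8 test. A transfer within ±1 day of the
true ovulation day is reported separately (`correct_within_1_rate`) and
never mixed into the headline correct rate.

*Monte Carlo*: `n_repeats` (default 30) batches of `n_samples` cycles,
vectorized over samples. Proportion CIs are Wilson score intervals on the
pooled outcome counts; the mean-test-count CI is the normal-theory
interval over the per-repeat means. Both the pooled-count and the
across-repeat views are reported because they answer slightly different
questions (binomial uncertainty vs repeat-to-repeat spread).

*Exact enumeration*: for each *O*, probability mass flows through the
finite trajectory tree; branches reaching the same next test day merge,
so the state space is at most (support × horizon) and the computation is
exact to float precision. It exists as the internal oracle for the Monte
Carlo path (equivalence within 3 binomial SE is tested on random
scenarios) and as a fast deterministic evaluator; a node budget guards
against pathological configurations.

The Wilson interval is implemented directly from its closed form
(centre (p̂ + z²/2n)/(1 + z²/n), half-width z√(p̂(1−p̂)/n + z²/4n²)/(1 +
z²/n)) and tested against an independent library implementation.

## Benchmark scale and what it shows

The default end-to-end benchmark simulates 2,000 cycles (≈ 1,780 survive
strict labeling, ≈ 26,000 instances), trains on the 60% split, and
evaluates the policy with 30 × 10,000 Monte Carlo draws; it completes in
well under a minute on one CPU, and all test-suite simulations are scaled
to the same order. On this synthetic cohort the student reaches ≈ 94–96%
held-out bin accuracy, with the characteristic profile — near-perfect far
from ovulation (≤ −6) and around it (−1/0), weakest at −4/−3 where
follicular trajectories are least distinctive — and the policy evaluation
yields a correct-transfer rate near 100% at ≈ 3.3 visits per cycle.

These numbers validate the machinery, not the clinic. The simulator's
trajectories are cleaner and more stereotyped than real monitoring data:
no anovulatory or biphasic-LH cycles, no assay noise beyond log-normal
perturbation, no inter-lab unit drift, missingness completely at random,
one cycle per patient, and a cycle-day prior that the model can exploit
more than it could in a heterogeneous population. Real-data rates for an
equivalent stack are necessarily lower, and the package makes no claim
about them.

## Degenerate inputs and numerical details

* Zero-probability rows/columns: empty actual classes in a confusion
  report warn and fall back to identity rows; an all-zero probability
  vector renormalizes to uniform before argmax.
* `sd = 0` anywhere degenerates to the point mass at the (clipped) mean.
* Probability vectors are validated to sum to 1 within 1e-9; outcome
  rates partition to 1 within 1e-9.
* All randomness flows through `numpy` generators forked from one global
  seed via named `SeedSequence` streams, so every artifact is
  reproducible from (config, seed, inputs); XGBoost runs single-threaded
  with a fixed seed for bit-stable fits.

## Known limitations

* The retrospective labeler is a rule-based surrogate for a learned
  full-cycle labeling model; its "uncertain" filter approximates a model
  confidence filter with hard evidence criteria.
* The NTMA implements only the published simplified rule set; it uses the
  class argmax, not the full probability vector, and has no
  clinic-constraint (weekend, capacity) rescheduling.
* Instances of three or more test days are out of scope by design.
* The exact evaluator assumes the actual class of a visit is a
  deterministic function of (day, *O*), i.e. labeling noise enters only
  through the error matrix.
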