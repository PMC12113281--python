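# Methods

## The problem

A visual agent's head and body orientations are independent social cues;
the question the analysis chain addresses is whether a neural population
encodes their *conjunction* — the signed head–body angle — rather than the
two orientations separately.  The design crosses 8 head × 8 body
orientations (45° steps) of a monkey avatar in two poses (sitting P1,
standing P2), two image centerings (monkey-centered MC, head-centered HC),
with isolated heads and headless bodies at matched locations, and an
upright/inverted manipulation.  Signed angles live in (−180°, 180°], with
180° (never −180°) for the straight, anatomically impossible configuration.
Isolated parts carry an `anchor_orientation` — the matched configuration's
other-part orientation — because the same head orientation shown at two
different locations is two different images.

## Synthetic units

Each unit's expected response-window rate is

```
rate = baseline + part_weight · a · gain · core
core(monkey)  = (1 − w_conj) · (f_H(h) + f_B(b)) / 2 + w_conj · f_H(h) · f_B(b)
core(head)    = f_H(h);   core(body) = f_B(b)
f_X(θ)        = (1 − m) · vm(θ; μ_X, κ_X) + m · (vm(θ) + vm(−θ)) / 2
```

with von Mises bumps `vm` peak-normalized to 1 so `gain` carries spikes/s
and additive and conjunctive components are commensurable.  `w_conj = 0`
makes the 8 × 8 expected-rate matrix exactly additive (zero double-centered
residuals); `m_mirror = 1` makes the rate invariant under joint reflection
`(h, b) → (−h, −b)`, which exchanges the +90° and −90° angle classes and
therefore predicts chance decoding of the angle's sign.  Away from the
reference centering (MC) the tuned core is mixed as
`c_tol · core + (1 − c_tol) · pattern`, where `pattern` is a fixed
per-unit pseudo-random value per condition — this reproduces graded MC↔HC
tuning correlations without modeling retinotopy.  Inversion multiplies the
driven component by `a_inv` (attenuation only; no tuning re-draw — the
phenomena of interest are reduced responses and reduced decodability, and
attenuation produces both).  Counts are Poisson per trial and window
(100 ms and 200 ms baselines at the baseline rate; 250 ms response window
at the condition rate), units independent — harmless here because
pseudo-population assembly discards inter-unit noise correlations by
construction.  What the generator does *not* emulate: latency dynamics and
PSTH shape, non-Poisson dispersion, noise correlations, eye-position
artifacts.  Passing tests therefore validate the analysis chain's logic
and calibration, not those aspects of real recordings.

Default study conditions (fixed once in `headbody.studies`): baseline
10 spikes/s; decoding populations gain 60 spikes/s with κ ∈ [1.5, 3]
(strongly driven, the regime where the contrasts of interest are clearly
expressed at 60 units × 8 trials); ANOVA calibration gain 20 spikes/s (see
below); `part_weights = (1, 0.5, 0.5)` so that with `w_conj = 0` the net
monkey response equals the summed net part responses exactly; 8 trials per
stimulus, 60-unit pseudo-populations balanced 30/30 across two subjects,
mirroring the experimental design.

## Screening

Experiment-1-style screening: split-plot ANOVA (within-trial factor
baseline-200 ms vs response window, between-trial factor stimulus; trials
are the error stratum), passing if the window main effect or the
interaction is significant and the best-stimulus mean net rate is positive
("excitatory").  Probe-style screening adds a Kruskal–Wallis test on raw
response rates across stimuli and the z-score criterion, with
`stdBaseAll` computed across per-stimulus mean baseline rates (the wording
is followed literally, not pooled trials).  The three criteria are
conjunctive, so screening order cannot change the pass set.  Degenerate
data (zero variance) yield NaN statistics and the unit fails.

## Tuning statistics

* MSI is computed per orientation/pose/centering case on mean net rates,
  only for cases where the monkey, head or body image drives a significant
  excitatory response (Wilcoxon rank-sum between per-trial baseline-100 ms
  and response rates, α = 0.05).  The rank-sum form is used as stated even
  though the windows are paired; with three independent tests the null
  selection rate is at most 1 − 0.95³ ≈ 0.14, and the additional
  excitatory requirement makes it conservative.  The 100-ms baseline is
  the netting convention throughout.
* The head × body ANOVA is a balanced fixed-effects two-way ANOVA on
  per-trial response counts, by default `sqrt(count + 3/8)`-transformed
  (the reported variant; raw counts behind a flag).  It is computed in
  closed form from the balanced-design sums of squares — identical to an
  OLS/anova_lm fit, which the test suite verifies — because hundreds of
  units are screened per run.
* Calibration caveat: the generator is additive on the *rate* scale and
  the square-root transform is concave, so strongly modulated additive
  units acquire a small genuine interaction on the transformed scale
  (rejection ≈ 0.10 at gain 4× baseline), while at moderate modulation
  (gain ≤ 2× baseline) both the transformed and raw ANOVAs calibrate at
  0.04–0.06.  The calibration study therefore uses gain 20 / baseline 10,
  i.e. the regime in which the transform's additive null holds to first
  order; this is a property of the statistic, not of the implementation.
* Residuals use the double-centering identity; the operator is idempotent
  and its row/column means vanish to machine precision.  Residual and
  centering correlations are plain Pearson correlations over the 64
  conditions, dropped when either vector is constant.
* Split-half reliability averages Spearman–Brown-corrected Pearson
  correlations over 100 random 4/4 trial splits; attenuation correction
  divides by the geometric mean of two reliabilities and is deliberately
  not clipped at 1.

## Decoding

Pseudo-population vectors: per stimulus, each unit's 8 trials are permuted
independently and stacked, giving 8 vectors per stimulus; fresh
permutations per resampling.  Permutations are counter-based (keyed by
seed, resampling index, condition and full-roster unit position), so
analyses on unit subsets — neuron-dropping leave-one-out rosters in
particular — reuse exactly the same trial assembly as the full roster and
differ only in the units present, which makes each leave-one-out accuracy
delta isolate the removed unit's effect.  Classification uses a linear SVM with C = 1
(libsvm with a 3000-iteration cap — chance-level non-separable problems
otherwise iterate pathologically; capped and fully converged solutions
agree to < 0.002 in accuracy on marginal-signal populations).  Multiclass
decoding uses the SVM's native one-vs-one majority vote.

Cross-validation is eightfold and *orientation balanced*: per condition a
random slot permutation is drawn; fold k trains on 7 slots per condition
per class (56 trials/class with 8 orientations, 28 with 4) and tests on
the held-out slot, so both classes always contain identical multisets of
head and of body orientations and every trial is tested exactly once.  A
guard (`BalanceError`) rejects any unbalanced class construction.
Conditions assembled from shared recordings — the head–body sums of two
angle classes at one orientation share the isolated-body trials — are
placed in one *fold group* with a common slot permutation, so a shared
trial is held out of training everywhere at once (otherwise the leak
produces artifactual below-chance accuracy).  Sum decoding uses net rates
(baseline-subtracted) to avoid inflating sums; within-experiment-2
configuration decoding uses net rates likewise.

Permutation nulls shuffle the pseudo-population vectors across the
contrast's condition/slot grid within each centering source ("permuting
the stimulus labels") and rerun the identical pipeline, by default 200
runs; the min–max of the run means is the null band.  Note that label
permutation destroys orientation balance, so on an orientation-tuned
population the null band is wide — this is exactly why balanced true-label
accuracies sit well inside it while deliberately confounded folds (each
class holding out a *different* orientation per fold) fall far below it.
Two fine points about chance-level decoding: (i) true-label
cross-validation at chance carries the standard small-sample pessimistic
bias (a few percent below the nominal chance level), which label-shuffled
nulls largely lack because shuffling breaks the condition-cluster
structure the bias comes from; (ii) a finite null band is itself a random
object, so a handful of chance-level accuracies per hundred falling below
its minimum is tail coincidence, not an artifact — the confounded-fold
artifact exceeds that coincidence rate by two orders of magnitude.
Paired comparisons share per-resampling unit draws through a common seed;
the p-value is the percentile of zero in the per-resampling difference
distribution, two-tailed significance at p < 0.025 / p > 0.975.  The
upright-vs-inverted contrast uses the distribution of differences between
means of 10 consecutive resamplings.

Neuron dropping ranks units by leave-one-out accuracy delta (the
procedure is a documented stand-in — no canonical definition exists) and
re-decodes with the top-k roster; the report includes the fraction of top
units with a significant head × body interaction and with a significant
one-way head–body-angle effect.

## Desk-scale problem sizes

Decoding runs default to 100 resamplings (as in the experimental
analyses), but the validation studies use 10–100 resamplings, null bands
of 200 runs × 1 resampling, 30 permutation runs for the 8-way chance
check, and mean-of-10 blocks over 100 resamplings for the inversion
distribution — sizes chosen so the full validation suite runs on a single
CPU in minutes while keeping Monte Carlo error an order of magnitude
smaller than the effects being demonstrated.  The ANOVA calibration uses
500–1500 units (binomial SE 0.6–1% around the nominal 5%).

## Numerical and degenerate-input conventions

Zero-variance inputs yield NaN correlations/statistics and the case is
dropped (reliability splits skipped, distance-matrix entries flagged);
MSI is undefined (case dropped) when `|M| + |B + H| = 0`; a degenerate SVM
fit predicts the first class, keeping accuracy at chance by symmetry of
fold construction; orientations are validated against the 45° grid
everywhere; inversion is an explicit flag, never encoded by negating
orientations.  All randomness flows through `numpy` Generators seeded from
explicit integers; identical seeds reproduce identical results bit for bit
(the pipeline manifest records config hash, versions and seed).

## Known limitations

The generator's independence and Poisson assumptions are idealizations;
real STS populations show correlated variability and non-stationarity.
The centering-tolerance mixture is a statistical surrogate for retinotopic
position effects.  Real-data quantitative values (median correlations,
absolute decoding accuracies) depend on recorded-population properties the
generator does not calibrate to, so the validation studies demonstrate
qualitative signatures and statistical calibration, not numerical
reproduction of recorded results.
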