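# Methods

## The features

Both features score the *spatial complexity* of a reading scanpath directly
from the cleaned (t, x, y) gaze sequence, with no fixation/saccade parsing.
They share one template — a trigger condition evaluated on every sliding
window of four consecutive points (stride 1), and a scoring window of
250 ms (about one average fixation) opened at each trigger:

* **SI trigger** — the polyline p1→p2→p3→p4 self-intersects, i.e. the closed
  segment (p1, p2) meets the closed segment (p3, p4).  Adjacent segment
  pairs always share an endpoint, so only this non-adjacent pair is tested.
  Touching configurations (shared point, endpoint on a segment, collinear
  overlap) count as intersection and zero-length segments are treated as
  points: the predicate stays purely combinatorial-geometric, with no
  epsilon thresholds to tune.
* **VAS trigger** — the four points contain exactly two changes of vertical
  movement direction, the maximum possible over their three deltas (so
  "exactly 2" and "at least 2" coincide).

The **vertical alteration score** of a point sequence counts strict sign
flips of the *effective* vertical direction: each delta's sign, with a zero
delta inheriting the last known direction.  A stationary gaze therefore
neither manufactures nor erases direction changes.  The window after a
trigger consists of the quadruple's 4th point (the anchor) plus all points
with t ∈ (t_anchor, t_anchor + 250 ms], and the effective direction at the
end of the triggering quadruple is carried into the window, so a flip at
the boundary is counted exactly once.

A trial's feature value starts at 0 and accumulates every trigger's window
score.  Each trigger event retains its anchor coordinates and its
contribution, so `total = Σ contributions` holds by construction (and is
asserted), and the anchors localize where in the text the score accrued —
the interpretability that motivates the design.  By default every trigger
opens its own window even if windows overlap; `suppress_overlap=True`
skips triggers landing inside an open window, for the alternative reading.
Both behaviours are tested; the default is the literal "each trigger can
add" accumulation.

Because only direction *changes* are scored, the features are invariant to
the screen coordinate convention: SI trigger sets are invariant under
similarity transforms of the plane, and all VAS quantities are invariant
under strictly increasing transforms of y and arbitrary transforms of x.
Both invariances are asserted on simulated trials.

## Preprocessing

Samples where both eyes are invalid are removed; with both eyes valid the
gaze point is the arithmetic mean of the two eyes (no laterality
assumption), with one valid eye that eye is used.  Timestamps are
preserved through removal — scoring windows are defined in *time*, so gaps
must remain gaps.  Downsampling 60 → 30 Hz keeps every 2nd sample starting
at index 0, emulating a slower sampler; averaging would smooth away the
very direction changes being scored.  Trials with reading time (last t −
first t) strictly below 5 s are excluded as insufficient engagement with
the text; exactly 5.0 s is retained.

Numerical choice: timestamps are float milliseconds and a 60 Hz step
(1000/60 ms) is not exactly representable, so window membership uses
`t − t_anchor ≤ 250 ms + 1e-6 ms`.  This makes a full window at 60 Hz
contain exactly 15 subsequent samples (7 at 30 Hz), as the ⌊0.25·rate⌋
spacing implies, independent of accumulated rounding.

## Synthetic cohort

The simulator emulates the study design the pipeline assumes: 30 subjects
(15 dyslexic, 15 control) × 13 color configurations (CC), recorded
binocularly at 60 Hz.  A trial is line-by-line reading of a short segment
(default 4 lines × 8 word anchors, 100 px spacing): fixations with
Gaussian-distributed durations, 33 ms forward saccades, leftward
regressions with probability `p_regress`, and 50 ms return sweeps.  On top
of the ideal scanpath rides Gaussian-filtered (smoothed) horizontal and
vertical wander.

Smoothness is essential, not cosmetic: independent per-sample noise flips
the sign of successive deltas ≈ 50% of the time *regardless of amplitude*,
which would make the direction-change rate — the quantity the features
measure — insensitive to the noise parameters.  With smoothed wander the
flip rate is governed by amplitude and filter width together, so the group
effect has the intended mechanism.

Group defaults (the simulated study conditions):

| parameter | control | dyslexic | unit |
|---|---|---|---|
| fixation duration | 210 ± 40 | 290 ± 60 | ms |
| regression probability | 0.08 | 0.28 | per word |
| vertical wander SD | 1.0 | 3.5 | px |
| horizontal wander SD | 0.8 | 2.5 | px |
| wander smoothing σ | 4.0 | 1.0 | samples @60 Hz |
| both-eye dropout | 2.5% | 4.5% | per sample |

Per-subject parameters are drawn around these (log-normal factors for
rates/amplitudes, Gaussian for fixation means), and each subject gets
per-CC multiplicative modifiers (`exp(N(0, 0.18))`) on regression rate and
wander amplitude.  CC effects are deliberately subject-specific with no
population-level component: no CC is uniformly best or worst, only
individually so.  Wander magnitudes were set so that the dyslexic/control
separation of the feature totals at 15 vs 15 subjects is decisive
(Mann-Whitney p < 0.001 pooled and per CC) — that calibration is part of
the simulated conditions, stated here once.

What the simulator does **not** model: oculomotor main-sequence dynamics,
microsaccades, tracker-specific noise spectra, text rendering or word
length/frequency effects, vergence dynamics (the binocular offset is a
per-trial constant), blinks as structured gaps.  Passing tests therefore
demonstrate internal correctness of the pipeline and the designed
direction of the group effect — not clinical effect sizes.  Real-cohort
accuracies are expected to be far from the near-perfect separation seen on
these synthetic defaults.

## Classification

LOSO evaluation: one fold per subject, every trial of the held-out subject
in test, the rest in training; predictions of all folds are concatenated
before computing ACC, Se (dyslexic recall), Sp (control recall), F1
(dyslexic class) and AUROC.  AUROC always comes from continuous decision
scores via the rank (Mann-Whitney) statistic.  Per fold, the single
feature is standardized on training data and hyperparameters are chosen by
grid search with fivefold CV on training only (grids: LR/SVM C over
10⁻³…10³, SVM kernels linear/RBF, KNN k ∈ {1,…,11} odd, RF 50–200 trees ×
depth {2, 3, 5, ∞}; ties break to the first grid point, deterministically;
stochastic learners are seeded from the run seed).

A leakage canary is part of the suite: perturbing a single held-out trial
must leave the same fold's other predictions unchanged — any change could
only come from test data reaching the scaler or the search.

Permutation nulls are run with *trial-level* label permutation.
Subject-level permutation under LOSO with a separable feature collapses to
ACC ≈ 0 through the balanced-design anti-learning artifact (removing the
held-out subject tilts the training majority against its label); even
trial-level permuted CV runs are mildly anti-biased below 0.5, so the mean
over 20 permutations is used as the chance-level summary.

## Statistics

Mann-Whitney U, two-sided, on trial-level values.  The exact enumerated
null is used when the pooled sample size is ≤ 20 and the data are
tie-free; otherwise the normal approximation with tie and continuity
correction (the exact method does not correct for ties).  The exact branch
is verified against full enumeration of group assignments in the tests.
Per-CC and pairwise-CC families are reported raw by default; Bonferroni
and Holm corrections are available by flag.

Best/worst CC per subject = argmin/argmax of the subject's trial values
for the feature (lower value = less struggle); ties break to the first CC
in canonical label order.  The summary emits the four contrast
distributions (control-best vs dyslexic-worst = maximally separated;
dyslexic-best vs control-worst = brought together) and the CC frequency
tables, as tidy CSV for any plotting layer.

## Problem sizes and determinism

The test suite and the acceptance script run everything at full study
scale (390-trial cohorts); the geometry oracle check uses 10⁵ random
quadruples (drawn from integer and eighth grids, where double-precision
orientation arithmetic is exact, so agreement with the rational-arithmetic
oracle must be 100%) plus 10³ constructed degenerate ones; the trigger
invariance suite uses 100 simulated trials; the within-dyslexic pairwise
CC fraction is the median over 3 cohort seeds; permutation nulls use 20
shuffles.  All randomness flows from explicit seeds; identical inputs give
identical outputs on any platform (`float_precision="round_trip"` CSV
parsing keeps write→read bit-exact).

## Known limitations

* The carry rule for zero deltas and the carry-in from the triggering
  quadruple into its window are this package's resolution of an
  under-determined corner of the feature definition; both are frozen in
  tests and documented above.
* With heavy ties the Mann-Whitney p is approximate (corrected normal),
  which is the standard treatment.
* Feature totals are duration-sensitive (longer reading offers more
  trigger opportunities); no normalization by reading time is applied, by
  design — reading time itself is carried as the explicit baseline feature.
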