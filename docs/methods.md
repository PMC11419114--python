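# Methods

This note documents the models, conventions, and numerical choices behind
`fearetho`, in the spirit of a statistics package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A trial is 87 frames at 5 frames/s: frames 1–25 baseline (5 s), 26–75 cue
(10 s), 76–87 post-cue (2.5 s). Frame indexing is 1-based and inclusive;
frame 26 begins at cue onset t = 0 s and each frame spans 200 ms. Each
frame carries exactly one label from a closed 13-letter alphabet: 12
scored behaviors plus `background`, which is a first-class label (the
scoring procedure assigns it explicitly) and is excluded only from the
classification features. Files that violate the 87-frame or
closed-alphabet invariants raise; nothing is padded or truncated.

Behavior categories for feature subsets: Immobile = {freeze, stretch},
Horizontal = {locomote, backpedal}, Vertical = {rear, scale, jump,
light_rear, light_scale}, Reward = {cup, port}; groom belongs to no
category.

## Suppression ratio

ratio = (b − c)/(b + c), with b = pokes in the 20-s pre-cue window × 3 and
c = pokes in the 10-s cue × 6 (both pokes/min). Conventions:

* Windows are half-open `[start, end)`; a poke at exactly cue onset counts
  toward the cue. One consistent rule, stated bit-exactly.
* A 0/0 trial is undefined (NaN) and excluded from session means. Imputing
  0 or 1 would bias paired and unpaired group means in opposite
  directions.
* At equal underlying Poisson rates the *expected* ratio is not 0: the
  10-s cue count has higher relative variance than the 20-s baseline
  count, giving a Jensen bias of about +0.04 at 20 pokes/min. The test
  suite checks the sample mean against this Monte-Carlo expectation, not
  against zero.

## Ethograms and features

The 1044-element session feature vector is the across-trial mean of the 4
one-hot trial indicators (12 behavior rows × 87 frames), flattened
behavior-major (behavior 1 frames 1–87, then behavior 2, …). With 4 trials
every cell lies on the quarter grid {0, 0.25, 0.5, 0.75, 1}. The mean is
the only 4-trial reduction consistent with a 12 × 87 array of bounded
values; it is fixed here as the canonical feature map. Group ethograms
(% behavior per 200-ms bin) retain the background row so every bin sums to
100; aggregation from trials and from session arrays commutes on balanced
selections (tested to 1e−12).

## Inter-rater reliability

Raw % identical observations per unordered observer pair (no chance
correction — that is the quantity the scoring procedure reports). Within a
pair the lexicographically lower observer id is "observer 1" (the
confusion-matrix row); the rule is arbitrary but deterministic, making
outputs bit-exact. The per-trial behavior count used for stratification is
the number of distinct non-background behaviors in the *union* of the
observers' labels — observer-independent, where a per-observer count would
make the stratum depend on who scored the trial.

## Statistics

* Per-window group tests: pooled-variance (Student) two-tailed t on
  per-rat % behavior (mean over the rat's trials × window frames). The
  87 frames tile into 5-frame (1-s) windows 1–5, …, 81–85 plus a trailing
  2-frame window 86–87, which is retained and flagged `partial_window`.
  The rat, not the trial, is the unit of analysis.
* Zero-variance conventions: equal means → t = 0, p = 1; unequal means →
  p = 0 (with a warning for the one-sample test).
* Split-plot ANOVA: classical sums-of-squares decomposition for a fully
  balanced design — one within factor, up to three crossed between
  factors, subjects nested in between cells. Between effects are tested
  against subjects-within-groups, within-involving effects against the
  subject × within residual; no sphericity correction. Unbalanced input
  raises rather than approximating. Effect sums of squares are computed by
  inclusion–exclusion over cell means and must add to the total (checked
  to 1e−9); the implementation matches pingouin's mixed ANOVA on
  one-between designs to 1e−8 in the tests.
* Bonferroni: α/m; for the 12-behavior screen, 0.05/12 = 0.004167.

## Classification

* Discriminant: two-class LDA with pooled within-class covariance S
  (denominator n − 2) and equal priors. With 64 sessions and 1044 features
  S is singular; the default uses the Moore–Penrose pseudo-inverse,
  computed in the low-rank basis via SVD of the centered data (exactly
  equal to pinv(S)·d, verified against the dense route). Shrinkage
  ((1−γ)S + γ(tr S/p)I) and diagonal modes are available and recorded on
  the model.
* A consequence worth knowing: w = S⁺d lies in the range of S, so the part
  of the mean difference in the null space of the within-class scatter is
  discarded. Training accuracy is therefore *not* 1 even though n ≪ p, and
  held-out accuracy can exceed training accuracy on these quantized
  features. This matches the reference behavior of pseudo-inverse
  discriminants (sklearn's svd-solver LDA trains at a similar level on the
  same data) and is asserted as such in the tests.
* Cross-validation: 100 repetitions of stratified 10-fold CV, fresh random
  partition per repetition; per-repetition accuracy is the unweighted mean
  over folds of the held-out fraction correct; results report mean ± SEM
  (SD/√100) over repetitions. Fold partitions depend only on (seed,
  labels), so runs at the same seed share partitions across feature
  subsets — matched-fold comparisons come for free.
* Session-shuffle null: each of the 100 models receives a fresh uniform
  permutation of the labels. A single fixed permutation is not used
  because its chance overlap with the true labels is itself learnable
  (measured means ranged 0.39–0.65 across permutations); the per-model
  permutation null converges to chance.
* Temporal shuffle: one random permutation of the frame columns per
  session, applied jointly to all behavior rows (per-behavior totals and
  per-frame mutual exclusivity preserved). In the analysis grid the
  shuffle is applied *after* period segmentation, so a period cell tests
  loss of temporal order within the analyzed window rather than leakage of
  frames from other periods.
* All randomness descends from one root seed via `SeedSequence` spawning;
  any grid cell is independently reproducible.

## Synthetic data generator

The generator emulates the stated experimental design: 32 rats split
16/16 into paired and unpaired, balanced over sex and two shock
intensities (0.35/0.5 mA), two scored sessions (conditioning, extinction)
of 4 trials × 87 frames — 22,272 frames and 64 session arrays — plus one
operant event log per session.

Behavior is semi-Markov: per-behavior geometric dwell (freeze mean dwell 4
frames, honoring the ≥3-frame/600-ms definition of a freezing bout), then
a jump drawn from the active period's distribution. Period distributions
are a shared base (baseline behavior: mostly rear/cup/port, little
freezing or locomotion) plus zero-sum group deltas packaged in
`data/kinetics.yaml`: paired-cue freeze/locomote up and reward/rear down;
unpaired-cue light-directed rear/scale up with reward preserved;
paired-conditioning frames 76–87 use a shock burst (locomote/jump/
backpedal); extinction and unpaired trials use the group's post kinetics
instead. The effect-size setting scales the deltas (none = 0 makes the
groups generatively identical; moderate = 1; strong = 1.75, clipped at
zero and renormalized). At a period boundary the state is redrawn from
the new period's distribution — cue onset and shock are salient events;
the cost is that the generator has no cross-boundary bout carryover.
Parameters were tuned only to qualitative ethogram shape; no claim is made
of matching any real percentages.

Nose pokes are a piecewise-homogeneous Poisson process: 20 pokes/min
baseline (a plausible VI-60 operant rate), rate × (1 − s) inside cues,
with s = 0.8 for paired and 0 for unpaired in both scored sessions.
Event-log timing is schematic (4 cue onsets 600 s apart in a 43-min
session); only the poke/cue structure feeds the analysis.

Synthetic observers for reliability testing relabel each frame with
probability 0.15, mostly (70%) to `background` — mirroring the real
finding that disagreement is behavior-vs-background, not
behavior-vs-behavior.

What a green test does and does not establish: the generator reproduces
the design cardinalities, the direction and rough shape of the group
divergence, and the statistical structure the pipeline assumes
(exclusivity, bouts, Poisson poking, suppressed cue responding). It does
not model cross-boundary bout dynamics, sex- or intensity-dependent
kinetics (carried as metadata only), within-session learning curves, or
reinforcement scheduling; green tests certify the pipeline's arithmetic
and inferential behavior on this stated world, not fidelity to any real
rat.

## Known limitations

* The split-plot ANOVA requires exact balance; real datasets with dropped
  trials need a mixed-model treatment that is out of scope here.
* The pseudo-inverse discriminant is one of several defensible choices for
  a singular pooled covariance; real-data accuracies depend on that choice
  and are not reproduction targets.
* The blinded-scoring codec is a keyed format-preserving scheme
  (Feistel permutation + HMAC tag over the identifier digits, wordlist
  word chosen by keyed hash). It reproduces the *format* and the blinding
  guarantees, not any particular historical mapping.
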