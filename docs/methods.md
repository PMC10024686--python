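# Methods

## Coordinate conventions

All coordinates are image pixels with the origin at the top-left and y
increasing downward.  Sequences are assumed normalized so cows travel
toward +x (the simulator generates them that way; real input filmed in the
opposite direction should be mirrored in x before analysis), which fixes
the sign of the neck-gradient features.  The head-elevation and neck-angle
features are frame-dependent by definition and documented as such; the back
RMSE and all areas are invariant to translation and rotation.

## Per-frame kinematics

**Back line and RMSE.**  The topline is the ordered five dorsal key-points
tail setting → hook bone → back centre → withers → scapula.  The line of
best fit is ordinary least squares of y on x (not orthogonal regression):
the residuals entering the RMSE are vertical offsets, which is what a
y-on-x fit minimises.  A topline with zero x-spread has no function-form
fit and is a geometry error.

**Back area.**  The baseline is the tail-to-scapula chord.  The three
intermediate points are projected onto the chord; their signed
perpendicular heights are integrated by the trapezoid rule along the chord
coordinate.  Because both end heights are zero this equals the
triangle-plus-rectangle decomposition of the same region.  Sections: the
rear section spans the two trapezoids tail → hook bone → back centre, the
front section back centre → withers, the neck section withers → scapula;
their sum is the total by construction, including when a segment dips below
the chord.  The global sign is chosen so the side of the chord on which the
back centre lies counts positive (falling back to the largest-magnitude
height if the centre sits exactly on the chord).  This makes an arched back
positive in image convention (+y down) and mathematical convention (+y up)
alike, keeps sway-backed segments negative rather than clamped, and
preserves rigid-motion invariance.

**Head/nose elevation.**  The back regression line is extended forward past
the head; for the head and nose key-points the value is
`(y_line − y_point)²`, multiplied by −1 when the line lies above the point
in image coordinates (head hanging below the back line).  The per-frame
scalar is the mean of the head and nose values — the least-structured
combiner for a single reported series; the two components are also exposed
separately.

**Neck angle.**  `m₁` is the gradient of withers → scapula, `m₂` of
scapula → head; the angle is `atan((m₁ − m₂)/(1 + m₁·m₂))`, the standard
angle-between-lines identity (the unit constant in the denominator is
required for the identity `m₁ = m₂ ⇒ 0` to hold).  The perpendicular case
`1 + m₁m₂ = 0` returns ±π/2 by the sign of `m₁ − m₂`; vertical segments
are geometry errors naming the offending segment.  Whether the first
segment should start at the withers or elsewhere on the shoulder is
anatomically ambiguous; withers → scapula is used and documented.

A feature is computed only when all its key-points are visible (COCO
ternary visibility); missing points yield unset features, never failures.

## Tracking

Tracking-by-detection in the original SORT parameterization: a 7-state
constant-velocity Kalman filter on (centre x, centre y, box area, aspect
ratio) with SORT's published noise covariances, association by Hungarian
assignment on 1 − IoU with a 0.3 IoU gate, tracks confirmed after 3 hits
and retired after 5 consecutive misses.  All thresholds are configuration
with these defaults.  Appearance models are deliberately out of scope: the
walkway holds cows in single file, so boxes of different cows essentially
never overlap and geometric association suffices.  Tentative tracks
contribute no features.  Pre-assigned input ids can be trusted via a
configuration flag, letting annotated data bypass the tracker.

## Aggregation and screening

Each per-frame series is summarised by min, max, mean, median, standard
deviation (ddof = 1), and the biased (population) skewness and excess
kurtosis.  A numerically constant series gets skew = kurtosis = 0 rather
than NaN so tables stay numeric.  The default table is 48 columns: 7 series
× 7 statistics minus the head/nose-elevation median, which the default
column set omits; `full_stats` restores it.  Cows with fewer than
`min_frames` (default 10) valid frames in any series are excluded with a
warning.

Screening is the Pearson correlation of each column against the
consolidated score with two-sided p-values, banded † p<0.10, * p<0.05,
** p<0.01, **** p<0.001.  No multiple-testing correction is applied, by
design: the screen is descriptive, and the classifier — not the p-values —
carries the inferential weight.  Rater scores are consolidated by
arithmetic mean rounded half away from zero (three raters on an integer
scale can only produce halves with even rater counts, but the rule is fixed
for those too).  Inter-rater agreement is Kendall's coefficient of
concordance with the average-rank tie correction — integer 0–3 scores are
heavily tied — and a chi-square approximation `χ² = m(n−1)W` for the
p-value.

## Classification protocol

The learner is gradient-boosted decision trees
(scikit-learn `GradientBoostingClassifier`; 300 trees, learning rate 0.1,
depth 3 by default, all overridable).  "Threefold cross-validation" is
implemented as the protocol it names here: three *independent* stratified
80/20 shuffle-splits — not disjoint k-fold partitions — each fold training
on its 80% with early stopping (patience 20) monitored on a stratified 20%
carve-out of the training portion, and scored on its 20% hold-out.
Hold-outs may therefore overlap across folds; accuracies are averaged and
hold-out predictions pooled into one confusion matrix.  Splits are
stratified because the severe class is rare (~6%); stratification can be
disabled, falls back to plain shuffles with bounded re-draws when a class
is too small to stratify, and early stopping is skipped when the carve-out
cannot hold every class (tiny tables).

Cohen's kappa is computed from the pooled confusion matrix with the
large-sample standard error under the alternative (Fleiss–Cohen–Everitt
form, cross-checked against statsmodels in the test suite), a 95% CI of
κ ± 1.96·ASE, and the κ = 0 z-test from the null variance.  A single-cell
matrix (chance agreement 1) is reported as undefined rather than raised.
Precision and recall are macro-averaged over classes, with empty classes
excluded under a warning; a binary positive-class reduction is available by
flag.  Importances are impurity-based, averaged over folds, normalized to
sum 1 and reported with their running (cumulative) sum; all-zero
importances are reported uniform with a degenerate flag.  Recursive feature
elimination trains on a fresh stratified split per step, records hold-out
error, and drops the single lowest-importance feature until one remains,
returning the error curve, removal order and the error-minimising feature
count.  The per-scorer validation mode repeats the full CV against each
individual rater's scores under every label scheme.

## Synthetic gait simulator

The simulator emulates the measurement situation the pipeline assumes — a
fixed side-on camera over a single-file walkway — not cow biomechanics.
Per frame, the topline is a parabola through the chord endpoints (tail
setting and scapula on the baseline row, chord = body length 400 px) with
peak height `arch + flex·sin(2π·f·t)` at the back centre; hook bone and
withers sit at the 25%/75% chord positions on the parabola.  Head and nose
ride ahead of the scapula at a score-dependent mean elevation with a
stride-locked bob; knees and hooves are placed schematically below the body
(features never use them).  Every coordinate receives i.i.d. Gaussian
jitter (sd 1 px) emulating pose-estimation noise.

Score-dependent defaults (score 0→3): static arch 0/3/7/12 px, flex
amplitude 0.5/1.5/3/6 px, mean head elevation +25/+10/−5/−25 px, head bob
1/3/7/14 px, speed 6/5/4/2.5 px/frame; stride frequency 1.2 Hz at 30 fps.
These are free parameters chosen once to preserve the qualitative orderings
the analysis exploits (more arch, more flexing, lower head, slower walk
with worse mobility) with margins well above the key-point noise; they make
no claim to metric realism.  `scale_effects(k)` interpolates every
score-dependent parameter toward its score-0 value, with k = 0 the
no-signal control used for chance-level checks.  Cows enter staggered,
fastest first, and a follower slows to hold a minimum gap behind its
leader, so single-file order is preserved and bodies never overlap.  True
scores are drawn from the observed herd distribution
(25.2/43.2/25.6/6.0%); three simulated raters independently report the
truth perturbed ±1 with probability 0.15 (clamped to 0–3, optional
per-rater bias), and the consolidated score is their rounded mean.

What the simulator does *not* model — occlusion, missed detections,
perspective and lens distortion, gait asymmetries, hoof-placement timing,
rater drift — bounds what passing tests show: they validate the geometry,
tracking, statistics and protocol machinery, and parameter recovery under
the stated correlational structure, not field performance on real video.
Classification accuracies on these cohorts are correspondingly near-ceiling
and should not be read as expected on-farm accuracy.

## Problem sizes and numerical choices

Tests and the acceptance script use cohorts of 40–250 cows at 30–60 frames
per cow — the scale at which all statistics are stable while the whole
suite stays fast.  Geometry oracles run at 1e-12 (RMSE vs brute-force OLS)
and 1e-9 (area vs shoelace polygon) tolerances; statistics oracles at
1e-9–1e-12.  Randomness everywhere flows from explicit integer seeds
through `numpy.random.default_rng`; fixed seeds give bit-identical
simulator output, CV reports and demo artifacts.
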