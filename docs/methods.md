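# Methods

## Coordinate conventions

All keypoints live in image coordinates: origin top-left, x rightward, y
downward, nominally a 1280x720 frame at 30 fps.  Orientation angles are
reported in the physical convention: the y axis is negated before the
quadrant-aware arctangent, so a segment pointing up on screen reads +90
degrees and results lie in (-180, 180].  Joint angles are interior angles
in [0, 180] degrees; the cosine is clamped to [-1, 1] before the arccos so
collinear configurations cannot overshoot through floating-point error.
Angles are degrees at every public surface and radians internally.

A quadrant-aware arctangent is used for pair orientations rather than the
plain ratio arctangent: the plain form cannot distinguish the direction of
a lean, while the magnitudes agree wherever both are defined.

## Missing data

A keypoint is *missing* when its confidence falls below 0.1 or its
coordinates are exactly (0, 0) — the value the OpenPose detector emits for
joints it cannot place.  Missing coordinates are never consumed: any frame
in which a contributing keypoint is missing is masked out of the signal
and of every feature computed from it.  Gap filling interpolates linearly
across dropouts of at most 5 frames (~167 ms at 30 fps) bounded by
observations on both sides; longer or boundary gaps stay missing and are
reported.  The limit is short enough not to fabricate motion and is
configurable (`pose.max_gap_frames`).

## The signal catalogue

Fifteen signals are computed per recording: 3 pair orientations (hip
line, shoulder line, spine), 7 joint angles (shoulders, hips, knees,
trunk) and 5 relative distances.  The catalogue ships with the published
keypoint index tuples kept verbatim, including the rows whose names read
loosely against the BODY_25 map (e.g. "RWristMidHip" indexing the two
wrists (4, 7), "MidHipLSmallToe" indexing mid-hip and left knee (8, 13)).
The printed indices are treated as authoritative because the intended
anatomy cannot be reconstructed from the names alone; a YAML override
(`catalogue:` config key) lets users substitute corrected definitions
without touching code.

Relative distances are normalised by the same frame's trunk length
(neck to mid-hip).  No averaging is involved by default; a sequence-median
normaliser (`trunk_normalizer="median"`) is available as a fallback for
frames whose trunk estimate is degenerate or noisy.  An optional width-5
median smoother exists but defaults off — no temporal filtering is part of
the standard pipeline.

## Features

The feature of record is the range of movement, ROM = max − min over the
valid frames of a signal, one value per signal per recording: a
15-dimensional vector in mixed units (degrees and dimensionless ratios).
One vector summarises the whole clip, spanning all repetitions — labels
are given per recording, and no per-repetition segmentation is defined.
An extended mode appends min, max, median and mean per signal (75
columns).  Features are not standardised: the downstream tree ensemble is
scale-invariant, so units are left interpretable.

## Label gating by inter-rater agreement

Each of three raters answers 15 binary error parameters per subject and
test.  Per parameter, Fleiss's kappa is computed over the complete
subjects x raters table (the generic statistic is delegated to
statsmodels), and consensus labels come from the per-subject majority
vote; an even rater panel requires an explicit tie rule.  When every
rating in a table is identical both observed and chance agreement equal
one and the formula degenerates to 0/0; the implementation returns 1.0,
the complete-agreement convention, which is also what the reference
summary prints for its unanimous rows.

A parameter is *eligible* for classification when kappa >= 0.41 —
inclusive, the conventional lower bound of moderate agreement — and its
consensus minority class holds at least `min_minority = 8` subjects.  The
reference study states the kappa gate and an unspecified minimum sample
size; 8 is the smallest minority bound that exactly reproduces its
selected parameter sets (five SDT, two SLST) from the printed summary,
and it is configurable.  The bundled
`data/expert_agreement.tsv` transcribes that summary in its original
typography (decimal commas, `kappa (faulty, non_faulty)` cells),
normalised at ingest.

## The boosted classifier

Discrete two-class AdaBoost over depth-bounded CART trees, authored
in-package (the per-round feature subsampling is not expressible with
stock ensemble implementations; single trees are fitted by scikit-learn):

* sample weights start uniform at 1/n;
* round *t* draws floor(sqrt(d)) features with a generator seeded by
  (seed, round) — keyed to the round, not the data order, so permuting
  rows with their labels leaves the fitted predictions unchanged;
* the weak learner is fitted by weighted Gini on that subset, its
  weighted error e computed on all training rows;
* alpha_t = learning_rate * ln((1 - e) / e); misclassified rows are
  multiplied by exp(alpha_t) and weights renormalised;
* e = 0 keeps the learner and stops; e >= 0.5 redraws the subset once and
  stops after the retry if still no better than chance (this keeps every
  alpha positive; the behaviour in this regime is otherwise unspecified);
* prediction is the sign of sum(alpha_t * (2 h_t(x) - 1)), ties resolved
  to the non-faulty class.

Defaults: 50 learners, learning rate 0.1, max depth 3, seed 42, split
80/15/5.  An exhaustive minimum-weighted-error stump (`base_learner=
"stump"`) with fully deterministic tie-breaks (features ascending,
thresholds ascending, left-class 0 first) backs brute-force equivalence
testing.  Models serialise to JSON as nested node records and evaluate
identically after a round trip.

Splitting is stratified: within each class, indices are shuffled by the
seed and allocated to train/validation/test by largest-remainder rounding
(remainder ties to the larger-fraction split).  If a split would receive
zero members of a class, a warning is issued and validation absorbs the
test split.  Because a 5% test split of a 46-subject cohort is two
subjects, per-parameter metrics are reported from stratified 5-fold
cross-validation with pooled out-of-fold predictions; the 80/15/5 split
remains available and is used for reporting only — no tuning loop exists.

Metrics are sensitivity TP/(TP+FN), specificity TN/(TN+FP) and accuracy,
with the faulty class positive.  Zero-denominator ratios are NaN with an
explicit flag, never silently zero.

## The synthetic cohort generator

The simulator emulates the acquisition protocol: 46 subjects per cohort,
one ~15 s clip per subject and test at 30 fps, three squat repetitions on
the stance limb, a 20 cm step (0.4 trunk units) for the SDT, and 1 px
Gaussian keypoint jitter standing in for detector noise.  Subject
geometry scales from a trunk length of 150 +/- 8.5 px (the cohort's
height spread, ~5.7% relative, seen from 4 m); squat depth varies as
100 +/- 3 degrees of knee angle.

It is a signal-level simulation, not biomechanics: the squat follows a
raised-cosine depth envelope (the middle 80% of each repetition slot),
and the stance leg is posed as a symmetric two-segment linkage so the 2D
knee angle equals the commanded value exactly.  Six error modes perturb
the signal family an expert would watch: trunk rotation about the mid-hip
(forward lean, 15 deg default), hip-line tilt (hip drop, 12 deg), outward
wrist displacement (gross arm deviation, 60 px), a Gaussian-bump lateral
sway of the upper body over planted feet (loss of balance, 40 px),
re-posing of the stance linkage to a shallower depth (shallow squat,
30 deg), and band-limited 8-12 Hz oscillation of knees and ankles
(tremor, 8 px; the physiological tremor band, below the 15 Hz Nyquist
limit of 30 fps capture).  Magnitude zero is an exact identity, each
targeted ROM responds monotonically to magnitude, and every default
magnitude shifts its target feature by at least 3 pooled standard
deviations in a protocol-scale cohort (verified by test).  Angular
magnitudes are in the units of the signal they perturb, so thresholds
stay interpretable.

One error mode at most is injected per recording, matching the one-label-
per-parameter design; prevalences default to 0.1 per mode.  Simulated
raters flip the true label of each cell independently — a faulty cell is
seen with the rater's sensitivity, a clean one with their specificity
(defaults 0.90/0.95 per rater; perfect raters reproduce truth exactly).

What passing tests on simulated cohorts do **not** show: robustness to
real detector failure modes (occlusion, left/right swaps, identity
switches), to camera misalignment, or to the biomechanical coupling of
real compensatory movement.  The simulation validates the pipeline's
machinery — signal extraction, gating, classification — not clinical
performance.

## Problem sizes in the test suite

Recovery studies run six balanced single-mode cohorts of 200 subjects at
full protocol scale (15 s, 30 fps) with perfect raters and 5-fold
cross-validation, plus a zero-magnitude control; kinematic invariances
use 1,000 random configurations against longhand trigonometric oracles
at 1e-9; the kappa implementation is checked against a longhand Fleiss
evaluation on all 4,096 binary 4-subject x 3-rater tables; boosting is
checked label-for-label against a loop-based exhaustive-stump reference
on random datasets of at most 8 points x 2 features.  Pipeline tests use
smaller cohorts (8-24 subjects, 3-5 s clips), chosen to exercise every
stage while keeping the default suite fast.

## Known limitations

* 2D frontal-plane only: sagittal-plane information (true forward lean,
  squat depth along the optical axis) is observable only through its
  frontal projection, both in the simulation and in the intended use.
* The printed catalogue's name/index mismatches are preserved by design;
  anatomical reinterpretation is the user's responsibility via the
  catalogue override.
* The agreement gate assumes complete rating tables; missing ratings are
  an error, not imputed.
* `fill_missing` interpolates linearly; fast motion across a dropout is
  under-modelled (bounded by the 5-frame default gap limit).
* Consensus counts treat the majority vote as the reference; with three
  raters no tie handling is needed, and no weighting by rater reliability
  is attempted.
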