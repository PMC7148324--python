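# Methods

This note documents the models, conventions and numerical choices behind
`emokin`, and what its synthetic benchmarks do and do not establish.

## Input model and canonicalization

Input is the OpenPose COCO-18 dialect: per frame, 18 keypoints × (x, y,
confidence), image coordinates with y increasing downward. Eye and ear
keypoints are unreliable when faces are blurred (standard practice in
body-expression stimuli) and are dropped; the nose is kept as a head
reference, leaving 14 canonical joints. A detection with confidence
below 0.1 counts as missing and is repaired by per-coordinate linear
interpolation over frames (nearest-value extrapolation at the ends).
Interpolation is a reproducible stand-in for the manual frame-by-frame
correction used in practice on real pose tracks; it reconstructs smooth
trajectories but cannot recover systematic occlusion errors. Confident
detections pass through bit-exactly, and coordinates stay in image
convention at I/O so files remain faithful to the pose estimator's
output; sign conventions are applied only inside the features module.
`validate_sequence` flags frames whose bone lengths deviate from the
sequence median by more than a tolerance fraction (default 0.5) — a
screening report, never a mutation.

## Feature definitions and conventions

Kinematic features (per keypoint, per frame transition):

* **velocity** = ‖p(t+1) − p(t)‖, px/frame. The full 2D displacement
  magnitude, the common reading of pose kinematics; per-axis variants are
  out of scope.
* **acceleration** = ‖v(t+1) − v(t)‖, px/frame², the magnitude of the
  change of the 2D velocity vector (not the change of speed).
* **vertical movement** = −Δy, px/frame, *signed and up-positive*. The
  sign is kept because net upward vs downward drift is the discriminative
  quantity (approach-postures rise, retreat-postures sink); an absolute
  version would erase that contrast.

Postural features (per frame):

* **limb angles**: interior angles at elbows, knees, shoulders and hips,
  degrees in [0, 180], via arccos of the normalized dot product, clipped
  to [−1, 1] before arccos for numerical safety. The torso reference for
  shoulder and hip angles is the neck keypoint, keeping every angle an
  angle between two adjacent body segments. Coincident adjacent joints
  make an angle undefined and raise an error naming the site.
* **symmetry**: for each left/right joint pair, with d = |x − x_nose|,
  the asymmetry distance |d_L − d_R| in px; 0 means mirror-symmetric
  about the vertical axis through the nose. Note the direction: *larger
  = less symmetric*. Published mean tables in this literature sometimes
  run in the opposite direction (a "symmetry score" where larger = more
  symmetric, implying an undocumented supplementary transform); this
  package fixes the asymmetry-distance formula, calibrates its synthetic
  generator to it, and uses the values only relationally downstream.
* **shoulder ratio**: ‖shoulder_L − shoulder_R‖ / (max x − min x over the
  14 joints), dimensionless; smaller = more extended beyond the
  shoulders.
* **surface**: bounding-box area (max x − min x)(max y − min y), px².
* **limb contraction**: mean Euclidean distance of the two wrists and
  two ankles to the nose, px; larger = more extended.

Aggregation is the arithmetic mean over the time and/or component axes
(means commute, and re-aggregating an averaged axis is a no-op). The
time-preserving feature table averages components but keeps the frame
axis; because velocity loses one frame and acceleration two, all
features are truncated to the acceleration axis (n_frames − 2) so every
column is defined for every stimulus — at 25 frames, 8 × 23 = 184
columns.

## RSA

First-level RDMs are pairwise Euclidean distances between per-stimulus
descriptors (time- and component-averaged scalars by default, so scalar
distances are absolute differences); category RDMs are dummy-coded
(0 within, √2 between — the distance between distinct one-hot vectors);
rating RDMs are built per participant and averaged entrywise, with
missing responses an error rather than an imputation. Second-level
comparisons are Spearman rank correlations over the strictly-lower
triangles (the zero diagonal carries no information and would inflate
rho), df = n(n−1)/2 − 2, two-sided p from the t approximation (with
n = 56 stimuli there are 1540 pairs, far beyond the small-sample
regime). The Bonferroni divisor is a caller-supplied parameter —
9 for the computed-feature analysis and 12 for the behavioural one by
default, matching the conventions of the analyses this pipeline
replicates; the counting rule behind those divisors is not derivable
from the matrix sizes, so they are deliberately parameters rather than
computed values.

## Repeated-measures ANOVA and ICC

Each feature's category effect is tested with a one-way repeated-measures
ANOVA: the repeated-measure unit is the exemplar index (videos are paired
across the four categories by their within-category index, the only
convention available when the original cross-category pairing is
unknown), k = 4 emotion levels, so uncorrected dfs are (3, 3(n−1)) —
(3, 39) at n = 14. Sphericity is assessed by Mauchly's test at α = 0.05
(the conventional threshold); when it rejects, Greenhouse–Geisser
ε rescales both dfs (ε ∈ [1/(k−1), 1]). Effect size is partial
η² = SS_effect/(SS_effect + SS_error). Post-hocs are paired t-tests
(df = n − 1) with p multiplied by C(k,2) = 6 and capped at 1. The
degenerate all-equal table returns F = 0, p = 1 rather than 0/0.
Computation is delegated to pingouin; the test suite cross-checks it
against a hand-coded sums-of-squares decomposition, including the GG ε
formula from the condition covariance matrix.

Inter-rater reliability is the two-way random-effects, absolute-agreement
intraclass correlation. Both ICC(2,1) (single rater) and ICC(2,k)
(average of k raters) are reported, because "consistency above 90%" style
statements in the literature do not say which definition they use.

## Bagged classification trees

Each tree is an entropy-split (information-gain) CART grown without depth
limit on a bootstrap resample of the stimuli; a resample missing a class
is redrawn (at most 100 attempts). Prediction is by unweighted majority
vote — the standard bagging rule; an in-bag-accuracy-weighted vote is
available behind a flag but is a no-op for purity-grown trees. Accuracy
and the confusion matrix are computed out-of-bag: each stimulus is
predicted only by trees whose bootstrap missed it. OOB evaluation is the
principled accuracy protocol for bagging when no held-out set exists,
but it is *slightly pessimistic*: a stimulus that is out of bag for a
tree is necessarily underrepresented in that tree's bootstrap, biasing
the tree against the stimulus's class. On label-permuted 4-class data
(56 stimuli) this depresses the mean OOB accuracy to ≈ 22–23% rather
than the nominal 25% — a property of the protocol, not an information
leak, and the reason the chance-level benchmark uses a ±5-percentage-
point band around 25%.

Importances come from a single tree fit to the full data (total impurity
decrease, normalized to sum to 1), the convention of the MATLAB-era
analyses this mirrors; for grouped predictor sets (x and y per joint or
body side) importances are summed within groups so a "descriptor" is a
joint or a side, not a coordinate. Ratings-based predictor sets use
stimulus-level across-participant means (the classified objects are the
56 stimuli, not single trials). n_trees defaults to 100.

## Synthetic data generator

The generator emulates the reference study design: 4 categories × 14
exemplars × 7 actor identities, 25 frames at 25 fps, 14 keypoints,
30 rating participants, 11 questions. It is two-tier because no
parametric skeleton can hit eight arbitrary feature targets at once:

* The **feature-level** simulator draws each stimulus's eight feature
  values independently from per-emotion Normal profiles whose means are
  the reference per-emotion values (e.g. fear limb angle 121.27°,
  neutral shoulder ratio 0.69, anger vertical drift +0.39 px/frame).
  Four cells have no published value (vertical movement for
  happiness/neutral, symmetry for fear, surface for anger/fear) and are
  filled with values inside the envelope of the published ones
  (0.1/0.0 px/frame, 40 px, 41 000 px²). Default sds are 25% of each
  feature's between-category mean range — large enough that recovery at
  n = 14 is non-trivial, small enough that the reference contrasts are
  recoverable. With sds of zero the rows equal the profile means
  exactly.
* The **skeleton-level** simulator animates a template standing skeleton
  (neck–hip 0.3 H, shoulder width 0.22 H, arm segments 0.17 H, leg
  segments 0.24 H, nose 0.15 H above the neck, H = 300 px by default;
  rounded anthropometric ratios) with antiphase sinusoidal arm swings,
  gait translation, vertical drift, per-emotion limb flexion and a
  left-arm asymmetry offset, plus 0.8 px Gaussian keypoint jitter; actor
  identity scales the skeleton ±10%, and swing phase plus 10% parameter
  scatter differentiate exemplars. Its *computed* features are
  ordering-faithful (fear most flexed and contracted, neutral most
  static and least extended, anger drifting up more than fear) but not
  mean-exact — pixel magnitudes depend on the arbitrary 300 px height,
  since the original videos' resolution is unknown.

The rating simulator maps each stimulus's true feature values affinely
onto the 7-point scale for the six feature-linked questions (contraction
inverted: the question asks how contracted, the feature measures how
extended), uses category anchors for approach/intensity/valence/
familiarity, adds a per-participant bias (sd = half the response-noise
sd) and response noise, clips to [1, 7], and draws forced-choice emotion
and action responses from a confusion matrix (happiness 78% correct with
spill mostly to neutral; neutral/fear near ceiling at 97/98%; anger,
for which no published rate exists, set to 88%). With zero noise and an
identity confusion every participant responds identically and all ICCs
equal 1.

**What passing tests show — and do not.** The synthetic benchmarks
establish that the pipeline recovers effect structure that is truly
present, stays at chance when labels carry no information, and matches
independent oracles numerically. They do not establish real-data effect
sizes: the feature-level generator draws features independently, whereas
real kinematic features are strongly inter-correlated and relatively
noisier than postural ones. One visible consequence: with every feature
given the same relative noise (25% of range), surface, acceleration and
vertical displacement carry category signal comparable to limb angles
and symmetry, so the full-data-tree importance ranking puts limb angles
or symmetry in the top three in ≈ 75% of simulated datasets — a genuine
competition between predictors, not an analysis failure; real data, with
noisier kinematics, favour the postural features more strongly. For the
same reason synthetic classification accuracies (often 100%) exceed what
real video data yield.

## Pipeline and reproducibility

`run_pipeline` sequences simulate → extract → RSA → ANOVA/ICC → classify
from a single config; every random stage receives a subseed drawn
deterministically from the master seed, so identical configs produce
byte-identical CSV artifacts. A completed run (matching config hash in
`manifest.json`) is a no-op unless forced. Stages whose inputs are
absent (e.g. ratings in pose-directory mode) are skipped with a logged
warning. Exit codes at the CLI: 0 success, 2 invalid config, 3 data
error.

The acceptance script and the heavier tests size their simulations at
200 datasets for contrast recovery, 100 for importance rankings and 200
label permutations — enough that the reported rates have standard errors
of a few percentage points while the whole suite stays interactive.

## Known limitations

* The skeleton generator is planar and sinusoidal; it does not model
  3D pose, self-occlusion, or realistic gait dynamics.
* Exemplar pairing across categories (the repeated-measures unit) is by
  index; with real stimuli an actor-matched pairing would be preferable
  when available.
* The symmetry feature's direction conflicts with published mean tables
  (see above); cross-study magnitude comparisons of symmetry values are
  therefore not meaningful, only within-pipeline relational uses.
* Absolute pixel-unit features (surface, limb contraction) are only
  meaningful relative to a known image scale.
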