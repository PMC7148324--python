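# emokin

Postural and kinematic analysis of emotional whole-body movement from 2D
pose keypoints.

People read emotion from body movement with striking ease, yet which
measurable properties of posture and motion carry that signal is an open
question in affective science. `emokin` implements a complete quantitative
pipeline for the problem: it consumes OpenPose-style COCO-18 keypoint
sequences of short whole-body clips (four categories — anger, happiness,
neutral, fear — acted by several identities), computes interpretable
per-frame descriptors, and relates them to emotion categories and to
observers' subjective ratings with three complementary analyses.

**Features.** Three kinematic descriptors — per-keypoint speed
‖p(t+1) − p(t)‖ (px/frame), acceleration magnitude ‖v(t+1) − v(t)‖
(px/frame²), and signed up-positive vertical displacement — and five
postural ones: interior limb angles at elbows/knees/shoulders/hips
(degrees), left–right asymmetry about the vertical nose axis (px),
shoulder-width-to-body-extent ratio, bounding-box surface (px²), and limb
contraction (mean wrist/ankle distance to the head, px).

**Analyses.**

* *Representational similarity analysis (RSA).* Per descriptor, a 56×56
  representational dissimilarity matrix (RDM) of pairwise Euclidean
  distances; emotion categories enter as a dummy-coded RDM (0 within a
  category, √2 between). Second-level Spearman rank correlations over RDM
  lower triangles, df = n(n−1)/2 − 2 = 1538, Bonferroni-controlled.
* *Repeated-measures ANOVA.* Per feature, a one-way ANOVA with a
  four-level emotion factor over the 14 exemplar pairings
  (F(3, 39) uncorrected; Greenhouse–Geisser correction when Mauchly's test
  rejects sphericity), with partial η² and Bonferroni-corrected paired
  post-hocs. Inter-rater reliability of ratings via ICC(2,1)/ICC(2,k)
  (two-way random, absolute agreement).
* *Bagged classification trees.* Entropy-split trees grown on bootstrap
  resamples, majority vote, out-of-bag accuracy and confusion, and
  predictor importances from a full-data tree — for six predictor sets
  (time-averaged features, time-preserving features, nine or six
  behavioural ratings, and centre/left/right or 14-joint position
  descriptors).

Because the original video stimuli and ratings of such studies are rarely
deposited, the package ships a first-class synthetic generator: a
parametric skeleton animator (sinusoidal limb swings, gait translation,
vertical drift, per-emotion flexion and asymmetry) plus a feature-level
simulator with per-emotion Normal profiles, and a simulated 30-participant
rating experiment with a forced-choice confusion structure. Every
downstream stage is tested against these generators.

## Worked example

```python
from emokin import rsa, stats, classify
from emokin.evaluation import anova_by_emotion
from emokin.features import build_feature_table
from emokin.synthetic import GeneratorConfig, default_profiles, generate_stimulus_set

stimuli = generate_stimulus_set(default_profiles(), GeneratorConfig(seed=0))
table = build_feature_table(stimuli, mode="averaged")

res = stats.rm_anova(anova_by_emotion(table, "limb_angles"))
print(res.summary())

emotion_rdm = rsa.dummy_rdm(table.emotions, source="emotion")
angle_rdm = rsa.euclidean_rdm(table.data["limb_angles"],
                              table.stimulus_ids, "limb_angles")
comp = rsa.compare_rdms(angle_rdm, emotion_rdm, m_comparisons=9)
print(f"limb angles vs emotion: rho({comp.df}) = {comp.rho:.3f}")

pset = classify.build_predictor_set(table, "features_averaged")
report = classify.fit_bagged_trees(pset, n_trees=100, seed=0)
print(f"OOB accuracy: {report.oob_accuracy:.2f}")
```

prints

```
F(3, 39) = 595.544, p = 1.347e-32, partial eta^2 = 0.979
limb angles vs emotion: rho(1538) = 0.587
OOB accuracy: 1.00
```

The ANOVA says the emotion factor explains nearly all exemplar-level
variance in mean limb angle on this synthetic set (the generator gives
fear a sharply flexed profile); the second-level rho of 0.587 means the
limb-angle dissimilarity structure tracks category membership; and the
out-of-bag accuracy of 1.00 shows the eight averaged features separate
the four synthetic categories completely (real video data are far
noisier — see `docs/methods.md`).

The same pipeline runs from the shell:

```bash
emokin all --seed 11 --out run1          # synthetic end-to-end run
emokin all --mode pose_dir --config cfg.yaml   # your own OpenPose JSON
```

which writes feature tables, all RDMs, second-level comparisons, ANOVA and
post-hoc tables, ICC values, six classifier reports and a `manifest.json`
with seeds and versions into the run directory.

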