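"""Synthetic emotion-labelled skeleton motion and behavioural ratings.

The study design this emulates: 4 emotion categories (anger, happiness,
neutral, fear) x 14 exemplars each, performed by 7 actor identities, as
one-second clips of 25 frames x 14 canonical keypoints; 30 participants
rating every stimulus on 11 questions (nine 7-point scales, two
forced-choice categories).

Two generation tiers are provided, because no parametric skeleton can hit
eight arbitrary feature targets simultaneously:

* :func:`generate_feature_table` draws feature values directly from
  per-emotion Normal profiles, so category means are exact in expectation
  (and exactly the profile means at sd 0). Use it to test the RSA, ANOVA
  and classifier stages against known effect structure.
* :func:`generate_stimulus_set` animates a template standing skeleton with
  per-emotion sinusoidal limb swings, gait translation, vertical drift and
  Gaussian jitter. Its *computed* features are ordering-faithful (the
  between-category orderings of the reference profiles hold) but not
  mean-exact.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureTable, build_feature_table
from .pose import CANONICAL_KEYPOINTS, EMOTIONS, PoseSequence, StimulusSet
from .ratings import SCALE_QUESTIONS, RatingTable

__all__ = [
    "EmotionProfile",
    "GeneratorConfig",
    "RatingGeneratorConfig",
    "MotionParams",
    "default_profiles",
    "default_confusion",
    "generate_feature_table",
    "generate_stimulus_set",
    "generate_ratings",
    "generate_time_coded_tables",
]


@dataclass(frozen=True)
class MotionParams:
    """Skeleton animation parameters for one emotion category.

    limb_flexion_mean: target interior elbow/knee angle, degrees (0, 180];
    swing_amplitude: arm/leg swing excursion at the extremity, px;
    swing_frequency: cycles/second; speed_scale: horizontal gait
    translation, px/frame; lateral_asymmetry: extra left-arm abduction at
    the wrist, px; vertical_drift: net whole-body drift, px/frame,
    up-positive.
    """

    limb_flexion_mean: float
    swing_amplitude: float
    swing_frequency: float
    speed_scale: float
    lateral_asymmetry: float
    vertical_drift: float

    def __post_init__(self) -> None:
        if not (0.0 < self.limb_flexion_mean <= 180.0):
            raise ValueError("limb_flexion_mean must be in (0, 180]")
        if self.swing_frequency <= 0:
            raise ValueError("swing_frequency must be > 0")


@dataclass(frozen=True)
class EmotionProfile:
    """Per-emotion feature targets and skeleton motion parameters."""

    emotion: str
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    motion_params: MotionParams

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.feature_sds.values()):
            raise ValueError(f"{self.emotion}: negative feature sd")


@dataclass(frozen=True)
class GeneratorConfig:
    """Stimulus-set design: counts, frame rate and skeleton scale."""

    n_per_category: int = 14
    n_actors: int = 7
    n_frames: int = 25
    fps: int = 25
    skeleton_height: float = 300.0
    jitter_sd: float = 0.8  # per-keypoint Gaussian position noise, px
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_category, self.n_actors, self.n_frames, self.fps) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.n_actors > self.n_per_category:
            raise ValueError("n_actors cannot exceed n_per_category")


#: Reference per-emotion feature means. Velocity/acceleration in px/frame
#: and px/frame^2, vertical movement px/frame (up-positive), limb angles
#: degrees, symmetry px, shoulder ratio dimensionless, surface px^2, limb
#: contraction px. Cells without an established reference value (vertical
#: movement for happiness/neutral, symmetry for fear, surface for
#: anger/fear) are filled with values inside the envelope of the others.
_REFERENCE_MEANS: dict[str, dict[str, float]] = {
    "velocity": {"anger": 3.4, "happiness": 3.71, "neutral": 1.9, "fear": 3.14},
    "acceleration": {"anger": 4.13, "happiness": 4.11, "neutral": 2.58,
                     "fear": 4.01},
    "vertical_movement": {"anger": 0.39, "happiness": 0.1, "neutral": 0.0,
                          "fear": -0.28},
    "limb_angles": {"anger": 141.87, "happiness": 148.36, "neutral": 140.39,
                    "fear": 121.27},
    "symmetry": {"anger": 33.27, "happiness": 32.26, "neutral": 50.68,
                 "fear": 40.0},
    "shoulder_ratio": {"anger": 0.49, "happiness": 0.5, "neutral": 0.69,
                       "fear": 0.51},
    "surface": {"anger": 41000.0, "happiness": 47054.6, "neutral": 36090.46,
                "fear": 41000.0},
    "limb_contraction": {"anger": 756.99, "happiness": 751.89,
                         "neutral": 803.6, "fear": 684.63},
}

#: Default within-category sd = 25% of each feature's between-category
#: mean range: large enough that recovery is non-trivial, small enough
#: that the reference contrasts are recoverable at n = 14 per category.
_SD_RANGE_FRACTION = 0.25

#: Skeleton animation parameters per emotion. Chosen so the *computed*
#: features of generated stimuli preserve the reference orderings: neutral
#: moves least (lowest velocity/acceleration, arms by the body so highest
#: shoulder ratio), fear is the most flexed (lowest limb angles, extremities
#: drawn in so lowest limb contraction) and retreats downward, anger drifts
#: upward more than fear.
_MOTION_PARAMS: dict[str, MotionParams] = {
    "anger": MotionParams(140.0, 25.0, 2.5, 2.5, 25.0, 0.39),
    "happiness": MotionParams(155.0, 30.0, 2.0, 2.0, 20.0, 0.1),
    "neutral": MotionParams(150.0, 4.0, 1.0, 0.4, 4.0, 0.0),
    "fear": MotionParams(95.0, 18.0, 2.2, 1.5, 22.0, -0.28),
}


def default_profiles() -> dict[str, EmotionProfile]:
    """The four default emotion profiles (reference means, default sds)."""
    ranges = {
        f: max(m.values()) - min(m.values()) for f, m in _REFERENCE_MEANS.items()
    }
    profiles = {}
    for emo in EMOTIONS:
        profiles[emo] = EmotionProfile(
            emotion=emo,
            feature_means={f: _REFERENCE_MEANS[f][emo] for f in FEATURE_NAMES},
            feature_sds={
                f: _SD_RANGE_FRACTION * ranges[f] for f in FEATURE_NAMES
            },
            motion_params=_MOTION_PARAMS[emo],
        )
    return profiles


def _stimulus_ids(config: GeneratorConfig) -> list[tuple[str, str, str]]:
    out = []
    for emo in EMOTIONS:
        for i in range(config.n_per_category):
            out.append((f"{emo}_{i:03d}", emo, f"actor_{i % config.n_actors}"))
    return out


def generate_feature_table(
    profiles: dict[str, EmotionProfile], config: GeneratorConfig
) -> FeatureTable:
    """Draw per-stimulus feature values directly from the Normal profiles.

    One row per stimulus (4 x n_per_category), each feature independent
    Normal(mean_e, sd_e). With all sds zero every row equals its
    category's means exactly.
    """
    rng = np.random.default_rng(config.seed)
    ids = _stimulus_ids(config)
    rows = []
    for sid, emo, _actor in ids:
        prof = profiles[emo]
        rows.append(
            {
                f: rng.normal(prof.feature_means[f], prof.feature_sds[f])
                for f in FEATURE_NAMES
            }
        )
    index = pd.Index([sid for sid, _, _ in ids], name="stimulus_id")
    data = pd.DataFrame(rows, index=index)
    emotions = pd.Series([e for _, e, _ in ids], index=index, name="emotion")
    return FeatureTable(data, emotions, "averaged")


# ---------------------------------------------------------------------------
# Skeleton-level generation
# ---------------------------------------------------------------------------

#: Template proportions as fractions of skeleton height H: rounded
#: anthropometric ratios for a standing adult.
_NECK_HIP = 0.30
_SHOULDER_HALF = 0.11   # shoulder width 0.22 H
_HIP_HALF = 0.07
_UPPER_ARM = 0.17
_LOWER_ARM = 0.17
_UPPER_LEG = 0.24
_LOWER_LEG = 0.24
_NOSE_ABOVE_NECK = 0.15

#: Baseline arm abduction from vertical, degrees, per emotion: emotional
#: categories hold the arms further out, which lowers the shoulder ratio.
_ARM_ABDUCTION = {"anger": 30.0, "happiness": 35.0, "neutral": 5.0, "fear": 25.0}
_LEG_SPREAD = 4.0  # degrees from vertical


def _rot(v: np.ndarray, degrees: float) -> np.ndarray:
    th = math.radians(degrees)
    c, s = math.cos(th), math.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _skeleton_frame(
    H: float,
    center: np.ndarray,
    arm_angles: dict[str, float],   # abduction from vertical per side, deg
    elbow_flex: float,              # interior elbow angle, deg
    knee_flex: float,               # interior knee angle, deg
) -> np.ndarray:
    """Build one 14-keypoint frame (image coords, y down) around ``center`` (neck)."""
    kp = np.zeros((14, 2))
    idx = {n: i for i, n in enumerate(CANONICAL_KEYPOINTS)}
    neck = center
    kp[idx["neck"]] = neck
    kp[idx["nose"]] = neck + (0.0, -_NOSE_ABOVE_NECK * H)
    down = np.array([0.0, 1.0])
    for side, sign in (("r", -1.0), ("l", 1.0)):
        shoulder = neck + (sign * _SHOULDER_HALF * H, 0.0)
        kp[idx[f"{side}_shoulder"]] = shoulder
        # upper arm hangs at `abd` degrees outward from vertical
        abd = arm_angles[side]
        d_upper = _rot(down, -sign * abd)
        elbow = shoulder + _UPPER_ARM * H * d_upper
        kp[idx[f"{side}_elbow"]] = elbow
        # lower arm deviates from the upper-arm direction by 180 - flex,
        # bending toward the body midline
        d_lower = _rot(d_upper, sign * (180.0 - elbow_flex))
        kp[idx[f"{side}_wrist"]] = elbow + _LOWER_ARM * H * d_lower
        hip = neck + (sign * _HIP_HALF * H, _NECK_HIP * H)
        kp[idx[f"{side}_hip"]] = hip
        d_thigh = _rot(down, -sign * _LEG_SPREAD)
        knee = hip + _UPPER_LEG * H * d_thigh
        kp[idx[f"{side}_knee"]] = knee
        d_shin = _rot(d_thigh, sign * (180.0 - knee_flex))
        kp[idx[f"{side}_ankle"]] = knee + _LOWER_LEG * H * d_shin
    return kp


def generate_stimulus_set(
    profiles: dict[str, EmotionProfile], config: GeneratorConfig
) -> StimulusSet:
    """Animate template skeletons into 4 x n_per_category pose sequences.

    Each stimulus is a standing skeleton (proportions scaled to
    ``skeleton_height``) whose arms swing sinusoidally in antiphase, with
    the per-emotion flexion, gait speed, drift and asymmetry of its
    category's :class:`MotionParams`, plus Gaussian keypoint jitter. Actor
    identity modulates the global scale by +-10%. Within-category
    variation comes from random swing phase and mild (10%) scatter of the
    motion parameters.
    """
    if config.n_frames < 3:
        raise ValueError("kinematic features need at least 3 frames")
    rng = np.random.default_rng(config.seed)
    H0 = config.skeleton_height
    actor_scales = (
        np.linspace(0.9, 1.1, config.n_actors)
        if config.n_actors > 1 else np.array([1.0])
    )
    arm_len = (_UPPER_ARM + _LOWER_ARM) * H0
    sequences = []
    for sid, emo, actor in _stimulus_ids(config):
        mp = profiles[emo].motion_params
        scale = actor_scales[int(actor.split("_")[1])]
        H = H0 * scale
        # mild per-stimulus scatter so exemplars within a category differ
        amp = mp.swing_amplitude * (1 + 0.1 * rng.standard_normal())
        freq = mp.swing_frequency * (1 + 0.1 * rng.standard_normal())
        speed = mp.speed_scale * (1 + 0.1 * rng.standard_normal())
        flex = float(
            np.clip(mp.limb_flexion_mean + 4.0 * rng.standard_normal(), 1, 180)
        )
        asym = mp.lateral_asymmetry * (1 + 0.1 * rng.standard_normal())
        phase = rng.uniform(0, 2 * np.pi)
        abd0 = _ARM_ABDUCTION[emo]
        amp_deg = math.degrees(amp / max(arm_len, 1e-9))
        asym_deg = math.degrees(asym / max(arm_len, 1e-9))
        frames = np.empty((config.n_frames, 14, 2))
        for t in range(config.n_frames):
            swing = amp_deg * math.sin(2 * np.pi * freq * t / config.fps + phase)
            arm_angles = {
                "r": abd0 + swing,
                "l": abd0 - swing + asym_deg,
            }
            center = np.array(
                [speed * t, -mp.vertical_drift * t]  # drift is up-positive
            )
            frames[t] = _skeleton_frame(H, center, arm_angles, flex, flex)
        frames += rng.normal(0.0, config.jitter_sd, size=frames.shape)
        sequences.append(
            PoseSequence(sid, emo, actor, frames, fps=config.fps)
        )
    return StimulusSet(sequences)


# ---------------------------------------------------------------------------
# Rating generation
# ---------------------------------------------------------------------------


def default_confusion() -> dict[str, dict[str, float]]:
    """Forced-choice emotion confusion rows.

    Happiness has the weakest recognition (78%, spilling mostly to
    neutral); neutral and fear are near-ceiling (97/98%); fear and anger
    are almost never confused with each other.
    """
    return {
        "anger": {"anger": 0.88, "happiness": 0.05, "neutral": 0.06,
                  "fear": 0.01},
        "happiness": {"anger": 0.03, "happiness": 0.78, "neutral": 0.16,
                      "fear": 0.03},
        "neutral": {"anger": 0.01, "happiness": 0.01, "neutral": 0.97,
                    "fear": 0.01},
        "fear": {"anger": 0.01, "happiness": 0.005, "neutral": 0.005,
                 "fear": 0.98},
    }


@dataclass(frozen=True)
class RatingGeneratorConfig:
    """Design of the simulated rating experiment."""

    n_participants: int = 30
    scale_range: tuple[float, float] = (1.0, 7.0)
    participant_noise_sd: float = 0.5
    confusion: dict[str, dict[str, float]] = field(
        default_factory=default_confusion
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for emo, row in self.confusion.items():
            if set(row) != set(EMOTIONS):
                raise ValueError(f"confusion row {emo!r} must cover {EMOTIONS}")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"confusion row {emo!r} does not sum to 1")


#: Category-level 7-point anchors for the questions that have no direct
#: feature counterpart: perceived approach (anger forward, fear away),
#: intensity (neutral near floor), valence (happy positive, fear/anger
#: negative), familiarity (everyday neutral actions most familiar).
_CATEGORY_ANCHORS = {
    "forward_away": {"anger": 6.0, "happiness": 4.5, "neutral": 4.0,
                     "fear": 2.0},
    "intensity": {"anger": 5.5, "happiness": 5.2, "neutral": 1.8, "fear": 5.8},
    "valence": {"anger": 2.0, "happiness": 6.0, "neutral": 4.0, "fear": 1.8},
    "familiarity": {"anger": 3.0, "happiness": 4.5, "neutral": 6.0,
                    "fear": 2.8},
}

#: Action labels mirror the emotion categories one-to-one (the stimuli are
#: category-typical actions), so the forced-choice action response reuses
#: the emotion confusion structure over these labels.
ACTION_LABELS = {
    "anger": "aggressive_gesture",
    "happiness": "celebratory_jump",
    "neutral": "everyday_action",
    "fear": "retreat",
}

#: Feature driving each feature-linked scale question, with sign: the
#: contraction question asks how contracted the body looks, so it runs
#: opposite to limb contraction (distance of extremities from the head).
_QUESTION_FEATURES = {
    "amount": ("velocity", +1.0),
    "fast": ("velocity", +1.0),
    "vertical": ("vertical_movement", +1.0),
    "contraction": ("limb_contraction", -1.0),
    "symmetry": ("symmetry", +1.0),
}


def _to_scale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Affine map of values spanning [min, max] onto [1.5, 6.5] of the scale."""
    xmin, xmax = float(np.min(x)), float(np.max(x))
    if xmax == xmin:
        return np.full_like(np.asarray(x, float), (lo + hi) / 2.0)
    span_lo, span_hi = lo + 0.5, hi - 0.5
    return span_lo + (span_hi - span_lo) * (np.asarray(x, float) - xmin) / (
        xmax - xmin
    )


def generate_ratings(
    stimuli: StimulusSet | FeatureTable, config: RatingGeneratorConfig
) -> RatingTable:
    """Simulate the full rating experiment for a stimulus set.

    Scale questions are affine transforms of the stimuli's true (computed
    or drawn) feature values — or of category anchors for questions
    without a feature counterpart — plus a per-participant bias (sd = half
    the noise sd) and response noise, clipped to the scale range.
    Forced-choice emotion and action responses are drawn from the
    confusion rows. With ``participant_noise_sd = 0`` and an identity
    confusion every participant responds identically.
    """
    if isinstance(stimuli, StimulusSet):
        table = build_feature_table(stimuli, mode="averaged")
    else:
        table = stimuli
    if table.mode != "averaged":
        raise ValueError("rating generation needs an averaged feature table")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.scale_range
    sids = table.stimulus_ids
    emotions = table.emotions
    # deterministic per-stimulus scale targets
    targets: dict[str, np.ndarray] = {}
    for q in SCALE_QUESTIONS:
        if q in _QUESTION_FEATURES:
            feat, sign = _QUESTION_FEATURES[q]
            targets[q] = _to_scale(sign * table.data[feat].to_numpy(), lo, hi)
        else:
            anchors = _CATEGORY_ANCHORS[q]
            targets[q] = np.array([anchors[emotions[s]] for s in sids])
    confusion_rows = {
        emo: (list(row.keys()), np.array(list(row.values())))
        for emo, row in config.confusion.items()
    }
    bias_sd = 0.5 * config.participant_noise_sd
    records: list[tuple] = []
    for p in range(config.n_participants):
        pid = f"p{p:02d}"
        bias = {q: rng.normal(0.0, bias_sd) if bias_sd > 0 else 0.0
                for q in SCALE_QUESTIONS}
        for si, sid in enumerate(sids):
            emo = emotions[sid]
            for q in SCALE_QUESTIONS:
                noise = (
                    rng.normal(0.0, config.participant_noise_sd)
                    if config.participant_noise_sd > 0 else 0.0
                )
                val = float(np.clip(targets[q][si] + bias[q] + noise, lo, hi))
                records.append((pid, sid, q, val))
            labels, probs = confusion_rows[emo]
            emo_resp = labels[rng.choice(len(labels), p=probs)]
            act_resp = ACTION_LABELS[labels[rng.choice(len(labels), p=probs)]]
            records.append((pid, sid, "emotion", emo_resp))
            records.append((pid, sid, "action", act_resp))
    data = pd.DataFrame(
        records, columns=["participant", "stimulus_id", "question", "response"]
    )
    return RatingTable(data, emotions.copy())


# ---------------------------------------------------------------------------
# Temporal-contrast construction
# ---------------------------------------------------------------------------


def generate_time_coded_tables(
    n_per_category: int = 14,
    n_frames: int = 25,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Stimuli whose emotion signal lives only in the temporal profile.

    Every feature column oscillates around a common baseline with a
    category-specific phase over exactly one period of the (n_frames - 2)
    frame axis, so the discrete time-average carries no category
    information. Returns the (averaged, time_preserving) table pair: a
    classifier on the averaged table can only reach chance, while the
    time-preserving table is separable.
    """
    rng = np.random.default_rng(seed)
    t_len = n_frames - 2
    phases = {emo: i * np.pi / 2 for i, emo in enumerate(EMOTIONS)}
    t = np.arange(t_len)
    ids, emos, rows_tp, rows_avg = [], [], [], []
    for emo in EMOTIONS:
        for i in range(n_per_category):
            sid = f"{emo}_{i:03d}"
            row_tp: dict[str, float] = {}
            row_avg: dict[str, float] = {}
            for fi, feat in enumerate(FEATURE_NAMES):
                base = 10.0 + fi
                signal = np.sin(2 * np.pi * t / t_len + phases[emo])
                vals = base + signal + rng.normal(0, noise_sd, t_len)
                for ti, v in enumerate(vals):
                    row_tp[f"{feat}_t{ti}"] = v
                row_avg[feat] = float(vals.mean())
            ids.append(sid)
            emos.append(emo)
            rows_tp.append(row_tp)
            rows_avg.append(row_avg)
    index = pd.Index(ids, name="stimulus_id")
    emotions = pd.Series(emos, index=index, name="emotion")
    averaged = FeatureTable(pd.DataFrame(rows_avg, index=index), emotions,
                            "averaged")
    preserved = FeatureTable(pd.DataFrame(rows_tp, index=index),
                             emotions.copy(), "time_preserving")
    return averaged, preserved
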