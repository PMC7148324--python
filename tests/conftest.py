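from __future__ import annotations

import json

import numpy as np
import pytest

from emokin.pose import CANONICAL_KEYPOINTS, EMOTIONS, PoseSequence, StimulusSet
from emokin.synthetic import GeneratorConfig, default_profiles, generate_stimulus_set


def random_sequence(rng: np.random.Generator, n_frames: int = 25,
                    spread: float = 100.0) -> PoseSequence:
    """A random (anatomy-free) but valid pose sequence for oracle checks."""
    frames = rng.uniform(-spread, spread, size=(n_frames, 14, 2))
    return PoseSequence("rand", "neutral", "a0", frames)


def mirror_sequence(seq: PoseSequence) -> PoseSequence:
    """Left-right mirror: negate x about the nose axis mean and swap L/R."""
    frames = seq.frames.copy()
    frames[:, :, 0] = -frames[:, :, 0]
    perm = []
    for name in CANONICAL_KEYPOINTS:
        if name.startswith("l_"):
            perm.append(CANONICAL_KEYPOINTS.index("r_" + name[2:]))
        elif name.startswith("r_"):
            perm.append(CANONICAL_KEYPOINTS.index("l_" + name[2:]))
        else:
            perm.append(CANONICAL_KEYPOINTS.index(name))
    return PoseSequence(seq.stimulus_id, seq.emotion, seq.actor_id,
                        frames[:, perm, :], fps=seq.fps)


def openpose_frames_json(coords18: np.ndarray, confidences: np.ndarray) -> str:
    """Serialize (T, 18, 2) coords + (T, 18) confidences as OpenPose JSON."""
    frames = []
    for t in range(coords18.shape[0]):
        flat = []
        for k in range(18):
            flat += [float(coords18[t, k, 0]), float(coords18[t, k, 1]),
                     float(confidences[t, k])]
        frames.append({"people": [{"pose_keypoints_2d": flat}]})
    return json.dumps(frames)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_stimulus_set(profiles) -> StimulusSet:
    """4 categories x 4 exemplars, 25 frames: fast shared fixture."""
    return generate_stimulus_set(
        profiles, GeneratorConfig(n_per_category=4, n_actors=2, seed=42)
    )


@pytest.fixture(scope="session")
def default_stimulus_set(profiles) -> StimulusSet:
    """The full default design: 56 stimuli x 25 frames x 14 keypoints."""
    return generate_stimulus_set(profiles, GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def emotions():
    return EMOTIONS
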