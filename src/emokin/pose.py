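"""Reading, validation and canonicalization of 2D pose keypoint sequences.

The accepted input dialect is OpenPose COCO-18 JSON: per frame, a
``people[0].pose_keypoints_2d`` flat array of 54 numbers
(x0, y0, c0, ..., x17, y17, c17) in image coordinates (y increases
downward), with a unitless detection confidence in [0, 1] per keypoint.

Canonicalization drops the four eye/ear keypoints (the nose is kept as a
head-position reference, so 14 joints remain), repairs missing detections
by per-coordinate linear interpolation across frames, and preserves the
coordinates of every confidently detected keypoint bit-exactly.
Coordinates stay in image convention at I/O; sign conventions (e.g.
up-positive vertical movement) are applied in the features module only.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COCO18_KEYPOINTS",
    "CANONICAL_KEYPOINTS",
    "N_CANONICAL",
    "EMOTIONS",
    "BONES",
    "PoseFormatError",
    "MissingPersonError",
    "AmbiguousPersonError",
    "RawPoseFrame",
    "PoseSequence",
    "StimulusSet",
    "ValidationReport",
    "read_openpose_json",
    "canonicalize_frames",
    "validate_sequence",
    "write_sequence_csv",
    "read_sequence_csv",
]

#: COCO-18 keypoint names in OpenPose v1.0.1 order.
COCO18_KEYPOINTS = (
    "nose", "neck",
    "r_shoulder", "r_elbow", "r_wrist",
    "l_shoulder", "l_elbow", "l_wrist",
    "r_hip", "r_knee", "r_ankle",
    "l_hip", "l_knee", "l_ankle",
    "r_eye", "l_eye", "r_ear", "l_ear",
)

#: The 14 keypoints retained after canonicalization (eyes/ears dropped).
CANONICAL_KEYPOINTS = COCO18_KEYPOINTS[:14]
N_CANONICAL = len(CANONICAL_KEYPOINTS)

EMOTIONS = ("anger", "happiness", "neutral", "fear")

#: Skeleton bones checked by validate_sequence, as (name, keypoint, keypoint).
BONES = (
    ("neck-r_shoulder", "neck", "r_shoulder"),
    ("neck-l_shoulder", "neck", "l_shoulder"),
    ("r_shoulder-r_elbow", "r_shoulder", "r_elbow"),
    ("l_shoulder-l_elbow", "l_shoulder", "l_elbow"),
    ("r_elbow-r_wrist", "r_elbow", "r_wrist"),
    ("l_elbow-l_wrist", "l_elbow", "l_wrist"),
    ("neck-r_hip", "neck", "r_hip"),
    ("neck-l_hip", "neck", "l_hip"),
    ("r_hip-r_knee", "r_hip", "r_knee"),
    ("l_hip-l_knee", "l_hip", "l_knee"),
    ("r_knee-r_ankle", "r_knee", "r_ankle"),
    ("l_knee-l_ankle", "l_knee", "l_ankle"),
)

#: Detections below this confidence count as missing and are interpolated.
CONFIDENCE_THRESHOLD = 0.1


class PoseFormatError(ValueError):
    """Malformed pose JSON or CSV (names the offending frame/file)."""


class MissingPersonError(PoseFormatError):
    """A frame contains no detected person."""


class AmbiguousPersonError(PoseFormatError):
    """A frame contains more than one detected person."""


@dataclass(frozen=True)
class RawPoseFrame:
    """One frame of raw COCO-18 keypoints: (18, 3) array of x, y, confidence."""

    keypoints: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.shape != (18, 3):
            raise PoseFormatError(
                f"frame {self.frame_index}: expected 18 keypoints x 3 values, "
                f"got array of shape {kp.shape}"
            )
        object.__setattr__(self, "keypoints", kp)
        if self.frame_index < 0:
            raise PoseFormatError(f"negative frame index {self.frame_index}")


@dataclass
class PoseSequence:
    """A canonicalized stimulus: frames x 14 keypoints x (x, y), image coords."""

    stimulus_id: str
    emotion: str
    actor_id: str
    frames: np.ndarray  # (n_frames, 14, 2)
    fps: float = 25.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 3 or arr.shape[1:] != (N_CANONICAL, 2):
            raise ValueError(
                f"{self.stimulus_id}: frames must have shape "
                f"(n_frames, {N_CANONICAL}, 2), got {arr.shape}"
            )
        if arr.shape[0] == 0:
            raise ValueError(f"{self.stimulus_id}: sequence has no frames")
        if not np.isfinite(arr).all():
            raise ValueError(f"{self.stimulus_id}: non-finite coordinates")
        if self.emotion not in EMOTIONS:
            raise ValueError(
                f"{self.stimulus_id}: unknown emotion {self.emotion!r}; "
                f"expected one of {EMOTIONS}"
            )
        self.frames = arr

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def keypoint(self, name: str) -> np.ndarray:
        """(n_frames, 2) trajectory of one canonical keypoint."""
        return self.frames[:, CANONICAL_KEYPOINTS.index(name), :]


@dataclass
class StimulusSet:
    """A collection of stimuli with unique ids and a common frame count."""

    sequences: list[PoseSequence]

    def __post_init__(self) -> None:
        ids = [s.stimulus_id for s in self.sequences]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate stimulus ids: {dupes}")
        n_frames = {s.n_frames for s in self.sequences}
        if len(n_frames) > 1:
            raise ValueError(f"sequences differ in frame count: {sorted(n_frames)}")

    @property
    def category_counts(self) -> dict[str, int]:
        return dict(Counter(s.emotion for s in self.sequences))

    @property
    def stimulus_ids(self) -> list[str]:
        return [s.stimulus_id for s in self.sequences]

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


@dataclass
class ValidationReport:
    """Frames whose bone lengths deviate from the sequence median."""

    stimulus_id: str
    tolerance: float
    flags: list[dict] = field(default_factory=list)

    @property
    def n_flagged_frames(self) -> int:
        return len({f["frame"] for f in self.flags})

    @property
    def ok(self) -> bool:
        return not self.flags


def _parse_frame_obj(obj: dict, frame_index: int, where: str) -> RawPoseFrame:
    people = obj.get("people")
    if people is None:
        raise PoseFormatError(f"{where}: frame {frame_index} has no 'people' entry")
    if len(people) == 0:
        raise MissingPersonError(
            f"{where}: no person detected in frame {frame_index}"
        )
    if len(people) > 1:
        raise AmbiguousPersonError(
            f"{where}: {len(people)} people detected in frame {frame_index}; "
            "stimuli must contain a single actor"
        )
    flat = people[0].get("pose_keypoints_2d")
    if flat is None or len(flat) != 54:
        n = None if flat is None else len(flat)
        raise PoseFormatError(
            f"{where}: frame {frame_index} pose_keypoints_2d must hold 54 "
            f"numbers, got {n}"
        )
    return RawPoseFrame(np.asarray(flat, float).reshape(18, 3), frame_index)


def canonicalize_frames(raw_frames: Sequence[RawPoseFrame]) -> np.ndarray:
    """Drop eyes/ears and repair missing keypoints by linear interpolation.

    A keypoint with confidence below :data:`CONFIDENCE_THRESHOLD` counts as
    missing; its x and y are filled independently by linear interpolation
    over frame index, with nearest-value extrapolation at the sequence ends.
    Confident detections are passed through bit-exactly.

    Returns a (n_frames, 14, 2) coordinate array in raw-frame order.
    """
    if not raw_frames:
        raise PoseFormatError("empty frame list")
    order = np.argsort([f.frame_index for f in raw_frames])
    kps = np.stack([raw_frames[i].keypoints for i in order])  # (T, 18, 3)
    coords = kps[:, :N_CANONICAL, :2].copy()
    conf = kps[:, :N_CANONICAL, 2]
    t = np.arange(coords.shape[0], dtype=float)
    for k in range(N_CANONICAL):
        good = conf[:, k] >= CONFIDENCE_THRESHOLD
        if good.all():
            continue
        if not good.any():
            raise PoseFormatError(
                f"keypoint {CANONICAL_KEYPOINTS[k]!r} missing in every frame; "
                "cannot interpolate"
            )
        for d in range(2):
            coords[~good, k, d] = np.interp(t[~good], t[good], coords[good, k, d])
    return coords


def read_openpose_json(
    path: str | Path,
    stimulus_id: str,
    emotion: str,
    actor_id: str = "unknown",
    fps: float = 25.0,
) -> PoseSequence:
    """Read an OpenPose COCO-18 JSON stimulus and canonicalize it.

    ``path`` may be a directory of per-frame ``*.json`` files (OpenPose's
    native output layout; lexicographic file order gives frame order) or a
    single JSON file holding a list of frame objects. Each frame object
    must contain ``people[0].pose_keypoints_2d`` with 54 numbers.
    """
    path = Path(path)
    raw: list[RawPoseFrame] = []
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise PoseFormatError(f"{path}: no JSON frame files found")
        for i, f in enumerate(files):
            try:
                obj = json.loads(f.read_text())
            except json.JSONDecodeError as e:
                raise PoseFormatError(f"{f} (frame {i}): malformed JSON: {e}") from e
            if isinstance(obj, list) and len(obj) == 1:
                obj = obj[0]  # tolerate a one-frame list per file
            if not isinstance(obj, dict):
                raise PoseFormatError(
                    f"{f} (frame {i}): expected one frame object per file"
                )
            raw.append(_parse_frame_obj(obj, i, str(f)))
    else:
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise PoseFormatError(f"{path}: malformed JSON: {e}") from e
        if not isinstance(doc, list):
            raise PoseFormatError(
                f"{path}: expected a list of frame objects, got {type(doc).__name__}"
            )
        for i, obj in enumerate(doc):
            raw.append(_parse_frame_obj(obj, i, str(path)))
    coords = canonicalize_frames(raw)
    return PoseSequence(stimulus_id, emotion, actor_id, coords, fps=fps)


def write_openpose_json(seq_coords: np.ndarray, path: str | Path,
                        confidence: float = 1.0) -> None:
    """Write canonical (or raw 18-kp) coordinates as a single OpenPose JSON file.

    Canonical 14-keypoint input is padded back to 18 keypoints with
    zero-confidence eye/ear slots so the file is a valid COCO-18 dialect.
    """
    arr = np.asarray(seq_coords, float)
    frames = []
    for frame in arr:
        if frame.shape[0] == N_CANONICAL:
            full = np.zeros((18, 3))
            full[:N_CANONICAL, :2] = frame
            full[:N_CANONICAL, 2] = confidence
        else:
            full = frame
        frames.append({"people": [{"pose_keypoints_2d": full.ravel().tolist()}]})
    Path(path).write_text(json.dumps(frames))


def validate_sequence(seq: PoseSequence, bone_length_tolerance: float = 0.5
                      ) -> ValidationReport:
    """Flag frames whose bone lengths deviate from the sequence median.

    A bone is flagged in a frame when its length differs from that bone's
    median length (over frames) by more than ``bone_length_tolerance`` as a
    fraction of the median. Reporting only; the sequence is not mutated.
    """
    report = ValidationReport(seq.stimulus_id, bone_length_tolerance)
    idx = {name: i for i, name in enumerate(CANONICAL_KEYPOINTS)}
    for bone, a, b in BONES:
        lengths = np.linalg.norm(
            seq.frames[:, idx[a]] - seq.frames[:, idx[b]], axis=1
        )
        med = float(np.median(lengths))
        if med == 0.0:
            bad = lengths != 0.0
        else:
            bad = np.abs(lengths - med) > bone_length_tolerance * med
        for t in np.nonzero(bad)[0]:
            report.flags.append(
                {"frame": int(t), "bone": bone,
                 "length": float(lengths[t]), "median": med}
            )
    return report


_CSV_COLUMNS = ["stimulus_id", "emotion", "actor_id", "frame", "keypoint", "x", "y"]


def write_sequence_csv(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence as long-format CSV (lossless round-trip).

    Columns: stimulus_id, emotion, actor_id, frame, keypoint, x, y.
    Coordinates are written with repr precision so that
    ``read_sequence_csv(write_sequence_csv(s))`` reproduces ``s`` bit-exactly.
    """
    n_frames = seq.n_frames
    df = pd.DataFrame(
        {
            "stimulus_id": seq.stimulus_id,
            "emotion": seq.emotion,
            "actor_id": seq.actor_id,
            "frame": np.repeat(np.arange(n_frames), N_CANONICAL),
            "keypoint": np.tile(CANONICAL_KEYPOINTS, n_frames),
            "x": seq.frames[:, :, 0].ravel(),
            "y": seq.frames[:, :, 1].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_sequence_csv(path: str | Path, fps: float = 25.0) -> PoseSequence:
    """Read a long-format CSV written by :func:`write_sequence_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise PoseFormatError(f"{path}: missing CSV columns {sorted(missing)}")
    sid = df["stimulus_id"].iloc[0]
    frames_idx = np.sort(df["frame"].unique())
    coords = np.empty((len(frames_idx), N_CANONICAL, 2))
    kp_order = {name: i for i, name in enumerate(CANONICAL_KEYPOINTS)}
    for t, fi in enumerate(frames_idx):
        sub = df[df["frame"] == fi]
        if len(sub) != N_CANONICAL:
            raise PoseFormatError(
                f"{path}: frame {fi} has {len(sub)} keypoints, "
                f"expected {N_CANONICAL}"
            )
        for _, row in sub.iterrows():
            k = kp_order[row["keypoint"]]
            coords[t, k] = (row["x"], row["y"])
    return PoseSequence(
        str(sid), str(df["emotion"].iloc[0]), str(df["actor_id"].iloc[0]),
        coords, fps=fps,
    )
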