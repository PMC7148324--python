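"""Kinematic and postural features of whole-body movement.

Three kinematic features (velocity, acceleration, vertical movement) and
five postural features (limb angles, symmetry, shoulder ratio, surface,
limb contraction) are computed per frame from a canonical 14-keypoint
:class:`~emokin.pose.PoseSequence` and then aggregated over time and/or
keypoints under caller control.

Conventions
-----------
* Input coordinates are in image convention (y increases downward).
  Vertical movement is reported **up-positive**: the image y displacement
  is negated so that a positive mean means net upward motion.
* Velocity and acceleration are magnitudes of the 2D displacement /
  velocity-change vectors, in px/frame and px/frame^2.
* Symmetry is an *asymmetry distance*: for each left/right joint pair,
  ``| |x_L - x_nose| - |x_R - x_nose| |`` in px, so 0 means the pair is
  mirror-symmetric about the vertical axis through the nose.
* Limb angles are interior angles at elbows, knees, shoulders and hips in
  degrees (180 = fully extended limb).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .pose import CANONICAL_KEYPOINTS, PoseSequence, StimulusSet

__all__ = [
    "FEATURE_NAMES",
    "KINEMATIC_FEATURES",
    "POSTURAL_FEATURES",
    "FeatureSeries",
    "FeatureTable",
    "UndefinedAngleError",
    "compute_velocity",
    "compute_acceleration",
    "compute_vertical_movement",
    "compute_limb_angles",
    "compute_symmetry",
    "compute_shoulder_ratio",
    "compute_surface",
    "compute_limb_contraction",
    "compute_feature",
    "aggregate",
    "build_feature_table",
]

KINEMATIC_FEATURES = ("velocity", "acceleration", "vertical_movement")
POSTURAL_FEATURES = (
    "limb_angles", "symmetry", "shoulder_ratio", "surface", "limb_contraction"
)
FEATURE_NAMES = KINEMATIC_FEATURES + POSTURAL_FEATURES

_KP = {name: i for i, name in enumerate(CANONICAL_KEYPOINTS)}

#: Angle sites as (site name, vertex, endpoint A, endpoint B). The interior
#: angle at the vertex is measured between vertex->A and vertex->B. The torso
#: reference for shoulder and hip angles is the neck keypoint, so every angle
#: is between two adjacent body segments.
ANGLE_SITES = (
    ("r_elbow", "r_elbow", "r_shoulder", "r_wrist"),
    ("l_elbow", "l_elbow", "l_shoulder", "l_wrist"),
    ("r_knee", "r_knee", "r_hip", "r_ankle"),
    ("l_knee", "l_knee", "l_hip", "l_ankle"),
    ("r_shoulder", "r_shoulder", "neck", "r_elbow"),
    ("l_shoulder", "l_shoulder", "neck", "l_elbow"),
    ("r_hip", "r_hip", "neck", "r_knee"),
    ("l_hip", "l_hip", "neck", "l_knee"),
)

#: Left/right joint pairs entering the symmetry feature.
SYMMETRY_PAIRS = ("shoulder", "elbow", "wrist", "hip", "knee", "ankle")


class UndefinedAngleError(ValueError):
    """A limb angle is undefined because two adjacent joints coincide."""


@dataclass
class FeatureSeries:
    """Per-frame values of one feature: array of shape (frames, components)."""

    feature_name: str
    values: np.ndarray
    component_names: tuple[str, ...]
    units: str
    aggregated_over: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != len(self.component_names):
            raise ValueError(
                f"{self.feature_name}: {v.shape[1]} columns vs "
                f"{len(self.component_names)} component names"
            )
        self.values = v

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def compute_velocity(seq: PoseSequence) -> FeatureSeries:
    """Per-keypoint speed: Euclidean displacement between adjacent frames.

    Shape (n_frames - 1, 14), px/frame.
    """
    if seq.n_frames < 2:
        raise ValueError("velocity needs at least 2 frames")
    disp = np.diff(seq.frames, axis=0)
    return FeatureSeries(
        "velocity", np.linalg.norm(disp, axis=2), CANONICAL_KEYPOINTS, "px/frame"
    )


def compute_acceleration(seq: PoseSequence) -> FeatureSeries:
    """Per-keypoint magnitude of the change in the 2D velocity vector.

    Shape (n_frames - 2, 14), px/frame^2.
    """
    if seq.n_frames < 3:
        raise ValueError("acceleration needs at least 3 frames")
    vel = np.diff(seq.frames, axis=0)
    dv = np.diff(vel, axis=0)
    return FeatureSeries(
        "acceleration", np.linalg.norm(dv, axis=2), CANONICAL_KEYPOINTS,
        "px/frame^2",
    )


def compute_vertical_movement(seq: PoseSequence) -> FeatureSeries:
    """Signed up-positive per-keypoint vertical displacement between frames.

    Image y increases downward, so the raw y difference is negated; a
    positive value is upward motion. Shape (n_frames - 1, 14), px/frame.
    """
    if seq.n_frames < 2:
        raise ValueError("vertical movement needs at least 2 frames")
    dy = np.diff(seq.frames[:, :, 1], axis=0)
    return FeatureSeries(
        "vertical_movement", -dy, CANONICAL_KEYPOINTS, "px/frame"
    )


def _interior_angle(vertex: np.ndarray, a: np.ndarray, b: np.ndarray,
                    site: str) -> np.ndarray:
    u = a - vertex
    w = b - vertex
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    bad = (nu == 0) | (nw == 0)
    if bad.any():
        raise UndefinedAngleError(
            f"zero-length segment at site {site!r} in frame(s) "
            f"{np.nonzero(bad)[0].tolist()}"
        )
    cos = np.clip(np.einsum("ij,ij->i", u, w) / (nu * nw), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def compute_limb_angles(seq: PoseSequence) -> FeatureSeries:
    """Interior angles at elbows, knees, shoulders and hips, degrees in [0, 180].

    Shape (n_frames, 8). Elbow: between elbow->shoulder and elbow->wrist;
    knee: knee->hip and knee->ankle; shoulder: shoulder->neck and
    shoulder->elbow; hip: hip->neck and hip->knee.
    """
    cols = []
    names = []
    for site, vtx, a, b in ANGLE_SITES:
        cols.append(
            _interior_angle(
                seq.frames[:, _KP[vtx]], seq.frames[:, _KP[a]],
                seq.frames[:, _KP[b]], site,
            )
        )
        names.append(site)
    return FeatureSeries(
        "limb_angles", np.column_stack(cols), tuple(names), "degrees"
    )


def compute_symmetry(seq: PoseSequence) -> FeatureSeries:
    """Left/right asymmetry distance about the vertical nose axis, px.

    For each joint pair, with d = |x_joint - x_nose|, the value is
    |d_L - d_R|; 0 means the pair is mirror-symmetric. Shape (n_frames, 6).
    """
    x_nose = seq.frames[:, _KP["nose"], 0]
    cols = []
    for joint in SYMMETRY_PAIRS:
        d_l = np.abs(seq.frames[:, _KP[f"l_{joint}"], 0] - x_nose)
        d_r = np.abs(seq.frames[:, _KP[f"r_{joint}"], 0] - x_nose)
        cols.append(np.abs(d_l - d_r))
    return FeatureSeries(
        "symmetry", np.column_stack(cols), SYMMETRY_PAIRS, "px"
    )


def compute_shoulder_ratio(seq: PoseSequence) -> FeatureSeries:
    """Shoulder span over total horizontal body extent, dimensionless.

    ``||shoulder_L - shoulder_R|| / (max x - min x)`` per frame; a smaller
    ratio means the joints extend further beyond the shoulders. Shape
    (n_frames, 1).
    """
    span = np.linalg.norm(
        seq.frames[:, _KP["l_shoulder"]] - seq.frames[:, _KP["r_shoulder"]],
        axis=1,
    )
    extent = seq.frames[:, :, 0].max(axis=1) - seq.frames[:, :, 0].min(axis=1)
    if (extent == 0).any():
        raise ValueError(
            "degenerate pose: zero horizontal extent in frame(s) "
            f"{np.nonzero(extent == 0)[0].tolist()}"
        )
    return FeatureSeries(
        "shoulder_ratio", (span / extent)[:, None], ("shoulder_ratio",), "ratio"
    )


def compute_surface(seq: PoseSequence) -> FeatureSeries:
    """Bounding-box area of the 14 keypoints per frame, px^2. Shape (n_frames, 1)."""
    dx = seq.frames[:, :, 0].max(axis=1) - seq.frames[:, :, 0].min(axis=1)
    dy = seq.frames[:, :, 1].max(axis=1) - seq.frames[:, :, 1].min(axis=1)
    return FeatureSeries("surface", (dx * dy)[:, None], ("surface",), "px^2")


def compute_limb_contraction(seq: PoseSequence) -> FeatureSeries:
    """Mean distance of wrists and ankles to the nose per frame, px.

    Larger values mean a more extended body. Shape (n_frames, 1).
    """
    nose = seq.frames[:, _KP["nose"], :]
    dists = [
        np.linalg.norm(seq.frames[:, _KP[kp], :] - nose, axis=1)
        for kp in ("l_wrist", "r_wrist", "l_ankle", "r_ankle")
    ]
    return FeatureSeries(
        "limb_contraction", np.mean(dists, axis=0)[:, None],
        ("limb_contraction",), "px",
    )


_COMPUTE: dict[str, Callable[[PoseSequence], FeatureSeries]] = {
    "velocity": compute_velocity,
    "acceleration": compute_acceleration,
    "vertical_movement": compute_vertical_movement,
    "limb_angles": compute_limb_angles,
    "symmetry": compute_symmetry,
    "shoulder_ratio": compute_shoulder_ratio,
    "surface": compute_surface,
    "limb_contraction": compute_limb_contraction,
}


def compute_feature(seq: PoseSequence, name: str) -> FeatureSeries:
    """Compute one named feature; see the per-feature functions for details."""
    try:
        fn = _COMPUTE[name]
    except KeyError:
        raise KeyError(
            f"unknown feature {name!r}; expected one of {FEATURE_NAMES}"
        ) from None
    return fn(seq)


def aggregate(series: FeatureSeries, over_time: bool = False,
              over_components: bool = False) -> FeatureSeries | float:
    """Arithmetic mean over the requested axes.

    Averaging both axes returns a scalar. Aggregating an axis that was
    already aggregated is a no-op. Means over the two axes commute.
    """
    values = series.values
    done = list(series.aggregated_over)
    if over_components and "components" not in done:
        values = values.mean(axis=1, keepdims=True)
        done.append("components")
    if over_time and "time" not in done:
        values = values.mean(axis=0, keepdims=True)
        done.append("time")
    if "time" in done and "components" in done:
        return float(values[0, 0])
    names = (
        (series.feature_name,) if "components" in done else series.component_names
    )
    return replace(
        series, values=values, component_names=names,
        aggregated_over=tuple(done),
    )


@dataclass
class FeatureTable:
    """Stimuli x feature-descriptor table with aggregation metadata.

    ``data`` is indexed by stimulus id. In ``averaged`` mode there is one
    column per feature (8 columns, each a time- and keypoint-mean). In
    ``time_preserving`` mode keypoints are averaged but each frame keeps a
    column (``<feature>_t<frame>``); all features are truncated to the
    acceleration frame axis (n_frames - 2) so every column is defined for
    every stimulus.
    """

    data: pd.DataFrame
    emotions: pd.Series
    mode: Literal["averaged", "time_preserving"]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.emotions.index):
            raise ValueError("data and emotions must share the stimulus index")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def stimulus_ids(self) -> list[str]:
        return list(self.data.index)

    def feature_vector(self, feature: str) -> pd.DataFrame:
        """Columns belonging to one feature (one column in averaged mode)."""
        if self.mode == "averaged":
            return self.data[[feature]]
        cols = [c for c in self.data.columns if c.rsplit("_t", 1)[0] == feature]
        return self.data[cols]

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write the table as wide CSV plus a JSON sidecar with metadata."""
        import json as _json
        from pathlib import Path as _Path

        self.data.assign(emotion=self.emotions).to_csv(
            path, index_label="stimulus_id", float_format="%.17g"
        )
        if sidecar_path is None:
            sidecar_path = _Path(str(path)).with_suffix(".meta.json")
        _Path(sidecar_path).write_text(
            _json.dumps({"mode": self.mode, "units": self.units}, indent=2)
        )

    @classmethod
    def from_csv(cls, path, sidecar_path=None) -> "FeatureTable":
        import json as _json
        from pathlib import Path as _Path

        df = pd.read_csv(path, index_col="stimulus_id",
                         float_precision="round_trip")
        emotions = df.pop("emotion")
        if sidecar_path is None:
            sidecar_path = _Path(str(path)).with_suffix(".meta.json")
        meta = _json.loads(_Path(sidecar_path).read_text())
        return cls(df, emotions, meta["mode"], meta.get("units", {}))


def build_feature_table(
    stimuli: StimulusSet,
    mode: Literal["averaged", "time_preserving"] = "averaged",
) -> FeatureTable:
    """Compute all eight features for every stimulus and tabulate them.

    ``averaged``: one scalar per feature per stimulus (mean over frames and
    components) — an n x 8 table. ``time_preserving``: components are
    averaged but the frame axis is kept; frame axes are aligned by
    truncating every feature to the shortest axis, the acceleration axis of
    length n_frames - 2, giving 8 x (n_frames - 2) columns.
    """
    if mode not in ("averaged", "time_preserving"):
        raise ValueError(f"unknown mode {mode!r}")
    n_frames = {s.n_frames for s in stimuli}
    if len(n_frames) > 1:
        raise ValueError(
            f"stimuli differ in frame count {sorted(n_frames)}; cannot align"
        )
    rows = []
    units: dict[str, str] = {}
    for seq in stimuli:
        row: dict[str, float] = {}
        for name in FEATURE_NAMES:
            series = compute_feature(seq, name)
            units[name] = series.units
            if mode == "averaged":
                row[name] = aggregate(series, over_time=True, over_components=True)
            else:
                per_frame = aggregate(series, over_components=True)
                t_len = seq.n_frames - 2
                vals = per_frame.values[:t_len, 0]
                for t, v in enumerate(vals):
                    row[f"{name}_t{t}"] = v
        rows.append(row)
    data = pd.DataFrame(rows, index=pd.Index(stimuli.stimulus_ids, name="stimulus_id"))
    emotions = pd.Series(
        [s.emotion for s in stimuli], index=data.index, name="emotion"
    )
    return FeatureTable(data, emotions, mode, units)
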