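"""Bagged decision-tree classification of emotion with predictor importances.

Each tree in the ensemble is an entropy-split (information-gain) CART
grown to purity on a bootstrap resample of the stimuli; class prediction
is by majority vote, and accuracy / confusion are estimated out-of-bag
(each stimulus predicted only by the trees whose bootstrap missed it).
Predictor importances come from a single tree fit to the full data
(impurity decrease), summed within predictor groups where a descriptor
spans several columns (e.g. the x and y of a joint).

Six predictor sets are supported: the 8 features averaged over time and
keypoints; the keypoint-averaged features with the frame axis kept; nine
behavioural ratings (all scales); the six kinematic/postural ratings; and
two body-part sets built from time-averaged keypoint positions — three
descriptors (centre / left side / right side) or fourteen per-joint
descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable
from .pose import CANONICAL_KEYPOINTS, StimulusSet
from .ratings import (
    KINEMATIC_POSTURAL_QUESTIONS,
    SCALE_QUESTIONS,
    RatingTable,
)

__all__ = [
    "PREDICTOR_SET_NAMES",
    "PredictorSet",
    "TreeEnsembleReport",
    "build_predictor_set",
    "fit_bagged_trees",
    "importance_ranking",
    "compare_models",
]

PREDICTOR_SET_NAMES = (
    "features_averaged",
    "features_time_preserving",
    "ratings_nine",
    "ratings_six",
    "bodyside_three",
    "joints_fourteen",
)

_BODY_SIDES = {
    "centre": ("nose", "neck"),
    "left": tuple(k for k in CANONICAL_KEYPOINTS if k.startswith("l_")),
    "right": tuple(k for k in CANONICAL_KEYPOINTS if k.startswith("r_")),
}


@dataclass
class PredictorSet:
    """A named predictor matrix with optional grouping of columns.

    ``groups`` maps descriptor name -> column indices; ungrouped sets use
    one singleton group per column. Grouped importances are summed over a
    descriptor's columns.
    """

    name: str
    X: np.ndarray
    predictor_names: list[str]
    labels: np.ndarray
    stimulus_ids: list[str]
    groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.shape != (len(self.labels), len(self.predictor_names)):
            raise ValueError(
                f"{self.name}: X {self.X.shape} vs {len(self.labels)} labels "
                f"x {len(self.predictor_names)} predictors"
            )
        if not self.groups:
            self.groups = {
                n: [i] for i, n in enumerate(self.predictor_names)
            }

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.groups)


def _timeavg_keypoints(stimuli: StimulusSet) -> np.ndarray:
    """(n_stimuli, 14, 2) time-averaged keypoint positions."""
    return np.stack([seq.frames.mean(axis=0) for seq in stimuli])


def build_predictor_set(source, name: str) -> PredictorSet:
    """Build one of the six named predictor sets from its source object.

    ``features_averaged`` / ``features_time_preserving`` need a
    :class:`FeatureTable` in the matching mode; ``ratings_nine`` /
    ``ratings_six`` need a :class:`RatingTable` (predictors are the
    across-participant mean rating per stimulus); ``bodyside_three`` /
    ``joints_fourteen`` need a :class:`StimulusSet`.
    """
    if name not in PREDICTOR_SET_NAMES:
        raise ValueError(f"unknown predictor set {name!r}")
    if name.startswith("features_"):
        if not isinstance(source, FeatureTable):
            raise TypeError(f"{name} needs a FeatureTable")
        want = "averaged" if name == "features_averaged" else "time_preserving"
        if source.mode != want:
            raise ValueError(
                f"{name} needs a table in {want!r} mode, got {source.mode!r}"
            )
        return PredictorSet(
            name, source.data.to_numpy(), list(source.data.columns),
            source.emotions.to_numpy(), source.stimulus_ids,
        )
    if name in ("ratings_nine", "ratings_six"):
        if not isinstance(source, RatingTable):
            raise TypeError(f"{name} needs a RatingTable")
        questions = (
            SCALE_QUESTIONS if name == "ratings_nine"
            else KINEMATIC_POSTURAL_QUESTIONS
        )
        means = source.stimulus_means(questions)
        return PredictorSet(
            name, means.to_numpy(), list(means.columns),
            source.emotions.loc[means.index].to_numpy(), list(means.index),
        )
    if not isinstance(source, StimulusSet):
        raise TypeError(f"{name} needs a StimulusSet")
    pos = _timeavg_keypoints(source)
    labels = np.array([s.emotion for s in source])
    ids = source.stimulus_ids
    if name == "joints_fourteen":
        cols, names, groups = [], [], {}
        for k, kp in enumerate(CANONICAL_KEYPOINTS):
            groups[kp] = [2 * k, 2 * k + 1]
            names += [f"{kp}_x", f"{kp}_y"]
            cols += [pos[:, k, 0], pos[:, k, 1]]
        return PredictorSet(name, np.column_stack(cols), names, labels, ids,
                            groups)
    # bodyside_three: mean position of the centre, left and right joints
    cols, names, groups = [], [], {}
    for gi, (side, kps) in enumerate(_BODY_SIDES.items()):
        kidx = [CANONICAL_KEYPOINTS.index(k) for k in kps]
        mean_xy = pos[:, kidx, :].mean(axis=1)
        groups[side] = [2 * gi, 2 * gi + 1]
        names += [f"{side}_x", f"{side}_y"]
        cols += [mean_xy[:, 0], mean_xy[:, 1]]
    return PredictorSet(name, np.column_stack(cols), names, labels, ids, groups)


@dataclass
class TreeEnsembleReport:
    """Fitted bagged-tree ensemble with OOB performance and importances."""

    name: str
    n_trees: int
    seed: int
    classes: list[str]
    oob_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: pd.DataFrame         # rows true, columns predicted (counts)
    importances: dict[str, float]   # descriptor -> weight, sums to 1
    importance_source: str = "full_data_tree"
    weighted_vote: bool = False
    labels: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "classes": self.classes,
            "oob_accuracy": self.oob_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion": self.confusion.to_dict(),
            "importances": self.importances,
            "importance_source": self.importance_source,
            "weighted_vote": self.weighted_vote,
        }


def _grouped_importances(pset: PredictorSet, tree: DecisionTreeClassifier
                         ) -> dict[str, float]:
    imp = tree.feature_importances_
    grouped = {g: float(imp[cols].sum()) for g, cols in pset.groups.items()}
    total = sum(grouped.values())
    if total > 0:
        grouped = {g: v / total for g, v in grouped.items()}
    return grouped


def fit_bagged_trees(
    pset: PredictorSet,
    n_trees: int = 100,
    seed: int = 0,
    weighted_vote: bool = False,
) -> TreeEnsembleReport:
    """Fit a bagged ensemble of entropy-split trees and report out-of-bag.

    Each tree is grown to purity (no depth limit) on a bootstrap resample;
    a resample missing one of the classes is redrawn (at most 100
    attempts). Prediction is by majority vote over the trees for which a
    stimulus was out of bag; with ``weighted_vote`` each tree's vote is
    weighted by its in-bag training accuracy (1.0 for purity-grown trees,
    so the default unweighted vote is the principled choice).
    Importances come from one tree fit to the full data, grouped-summed
    per descriptor and normalized to sum to 1. Deterministic given seed.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    classes = np.unique(pset.labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    n = len(pset.labels)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_to_idx[c] for c in pset.labels])
    votes = np.zeros((n, len(classes)))
    for _ in range(n_trees):
        for _attempt in range(100):
            boot = rng.integers(0, n, size=n)
            if len(np.unique(y_idx[boot])) == len(classes):
                break
        else:
            raise RuntimeError(
                "could not draw a bootstrap containing every class in 100 "
                "attempts"
            )
        tree = DecisionTreeClassifier(
            criterion="entropy",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(pset.X[boot], y_idx[boot])
        oob = np.setdiff1d(np.arange(n), np.unique(boot), assume_unique=True)
        if len(oob) == 0:
            continue
        pred = tree.predict(pset.X[oob])
        weight = 1.0
        if weighted_vote:
            weight = float(
                (tree.predict(pset.X[boot]) == y_idx[boot]).mean()
            )
        votes[oob, pred] += weight
    covered = votes.sum(axis=1) > 0
    # ties broken toward the lower class index (stable, deterministic)
    oob_pred = votes.argmax(axis=1)
    correct = (oob_pred == y_idx) & covered
    oob_accuracy = float(correct[covered].mean()) if covered.any() else np.nan
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for i in np.nonzero(covered)[0]:
        conf[y_idx[i], oob_pred[i]] += 1
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    per_class = {}
    for c in classes:
        mask = (pset.labels == c) & covered
        per_class[str(c)] = (
            float(correct[mask].mean()) if mask.any() else np.nan
        )
    full_tree = DecisionTreeClassifier(
        criterion="entropy", random_state=int(seed) % (2**31 - 1)
    )
    full_tree.fit(pset.X, y_idx)
    return TreeEnsembleReport(
        name=pset.name,
        n_trees=n_trees,
        seed=seed,
        classes=[str(c) for c in classes],
        oob_accuracy=oob_accuracy,
        per_class_accuracy=per_class,
        confusion=confusion,
        importances=_grouped_importances(pset, full_tree),
        weighted_vote=weighted_vote,
        labels=pset.labels,
    )


def importance_ranking(report: TreeEnsembleReport
                       ) -> list[tuple[str, float, bool]]:
    """Descriptors sorted by descending importance.

    Returns (name, importance, tied) triples; ties (equal importance) are
    broken lexicographically by name and flagged.
    """
    items = sorted(
        report.importances.items(), key=lambda kv: (-kv[1], kv[0])
    )
    values = [v for _, v in items]
    out = []
    for i, (name, v) in enumerate(items):
        tied = (i > 0 and values[i - 1] == v) or (
            i + 1 < len(values) and values[i + 1] == v
        )
        out.append((name, v, tied))
    return out


def compare_models(reports: dict[str, TreeEnsembleReport]) -> pd.DataFrame:
    """Rank fitted models by OOB accuracy (rank 1 = best; ties share a rank)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    label_sets = [
        tuple(np.sort(r.labels)) for r in reports.values()
        if r.labels is not None
    ]
    if len(set(label_sets)) > 1:
        raise ValueError("reports were fitted on different label sets")
    rows = []
    for name, r in reports.items():
        row = {"model": name, "oob_accuracy": r.oob_accuracy}
        row.update(
            {f"acc_{c}": a for c, a in r.per_class_accuracy.items()}
        )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("model")
    df["rank"] = (
        df["oob_accuracy"].rank(ascending=False, method="min").astype(int)
    )
    df["tied"] = df.duplicated("oob_accuracy", keep=False)
    return df.sort_values("rank")
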