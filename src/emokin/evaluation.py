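"""Recovery-rate and chance-level evaluation of the analysis pipeline.

These routines quantify, over many simulated datasets, how reliably the
pipeline recovers the effect structure the synthetic generator encodes:
the directional between-category feature contrasts, the dominance of
postural predictors in tree importances, the chance level of label-
permuted classification, and the advantage of time-preserving over
time-averaged descriptors when the category signal is purely temporal.
"""

from __future__ import annotations

import numpy as np

from . import classify, stats
from .features import FEATURE_NAMES
from .synthetic import (
    GeneratorConfig,
    default_profiles,
    generate_feature_table,
    generate_time_coded_tables,
)

__all__ = [
    "REFERENCE_CONTRASTS",
    "anova_by_emotion",
    "contrast_recovery_rate",
    "importance_top3_rate",
    "permuted_label_oob",
    "temporal_model_ordering",
]

#: Directional between-category differences, as (larger, smaller) pairs per
#: feature, that a successful analysis should find significant: the three
#: emotional categories move faster than neutral, fear is the most flexed
#: and contracted, anger rises while fear sinks, emotional movements are
#: less symmetric and more extended than neutral, and happy movements span
#: the largest surface.
REFERENCE_CONTRASTS: dict[str, tuple[tuple[str, str], ...]] = {
    "velocity": (("anger", "neutral"), ("happiness", "neutral"),
                 ("fear", "neutral")),
    "acceleration": (("anger", "neutral"), ("happiness", "neutral"),
                     ("fear", "neutral")),
    "vertical_movement": (("anger", "fear"),),
    "limb_angles": (("anger", "fear"), ("happiness", "fear"),
                    ("neutral", "fear")),
    "symmetry": (("neutral", "anger"), ("neutral", "happiness")),
    "shoulder_ratio": (("neutral", "anger"), ("neutral", "happiness"),
                       ("neutral", "fear")),
    "surface": (("happiness", "neutral"),),
    "limb_contraction": (("anger", "fear"), ("happiness", "fear"),
                         ("neutral", "fear")),
}


def anova_by_emotion(table, feature: str):
    """Exemplar x emotion wide table for one feature of a FeatureTable."""
    import pandas as pd

    df = pd.DataFrame(
        {"value": table.data[feature], "emotion": table.emotions}
    )
    df["exemplar"] = df.groupby("emotion").cumcount()
    wide = df.pivot(index="exemplar", columns="emotion", values="value")
    if wide.isna().any().any():
        raise ValueError("unbalanced design across emotion categories")
    return wide


def _seed_recovers_all(table, alpha: float = 0.05) -> bool:
    for feature in FEATURE_NAMES:
        wide = anova_by_emotion(table, feature)
        if stats.rm_anova(wide).p >= alpha:
            return False
        posthoc = stats.posthoc_bonferroni(wide)
        for larger, smaller in REFERENCE_CONTRASTS[feature]:
            row = posthoc.contrast(larger, smaller)
            if row["mean_diff"] <= 0 or row["p_bonferroni"] >= alpha:
                return False
    return True


def contrast_recovery_rate(n_seeds: int = 200, base_seed: int = 0,
                           profiles=None) -> float:
    """Fraction of simulated datasets recovering every reference effect.

    Each dataset is a default feature-level simulation (n = 14 per
    category); a dataset counts as recovered when all eight features show
    a significant repeated-measures emotion effect AND every reference
    directional contrast is Bonferroni-significant with the right sign.
    """
    profiles = profiles or default_profiles()
    hits = 0
    for i in range(n_seeds):
        table = generate_feature_table(
            profiles, GeneratorConfig(seed=base_seed + i)
        )
        hits += _seed_recovers_all(table)
    return hits / n_seeds


def importance_top3_rate(
    n_seeds: int = 100,
    base_seed: int = 0,
    targets: tuple[str, ...] = ("limb_angles", "symmetry"),
    top_k: int = 3,
    profiles=None,
) -> float:
    """Fraction of datasets where a target feature ranks in the top-k
    full-data-tree importances of the averaged-feature classifier."""
    profiles = profiles or default_profiles()
    hits = 0
    for i in range(n_seeds):
        table = generate_feature_table(
            profiles, GeneratorConfig(seed=base_seed + i)
        )
        pset = classify.build_predictor_set(table, "features_averaged")
        report = classify.fit_bagged_trees(pset, n_trees=1, seed=base_seed + i)
        top = [n for n, _, _ in classify.importance_ranking(report)[:top_k]]
        hits += any(t in top for t in targets)
    return hits / n_seeds


def permuted_label_oob(
    n_permutations: int = 200,
    seed: int = 0,
    n_trees: int = 50,
) -> np.ndarray:
    """OOB accuracies of the bagged classifier under label permutation.

    One default synthetic feature table is generated, then its emotion
    labels are permuted ``n_permutations`` times; the returned accuracies
    should scatter around the 4-class chance level (the out-of-bag
    protocol itself is slightly pessimistic, so the mean sits a couple of
    points below nominal 25%).
    """
    table = generate_feature_table(default_profiles(), GeneratorConfig(seed=seed))
    pset = classify.build_predictor_set(table, "features_averaged")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(pset.labels))
        permuted = classify.PredictorSet(
            pset.name, pset.X, pset.predictor_names, pset.labels[perm],
            pset.stimulus_ids,
        )
        accs[i] = classify.fit_bagged_trees(
            permuted, n_trees=n_trees, seed=int(rng.integers(2**31 - 1))
        ).oob_accuracy
    return accs


def temporal_model_ordering(seed: int = 0, n_trees: int = 100
                            ) -> tuple[float, float]:
    """(time_preserving, averaged) OOB accuracy on purely temporal signal."""
    avg, tp = generate_time_coded_tables(seed=seed)
    r_avg = classify.fit_bagged_trees(
        classify.build_predictor_set(avg, "features_averaged"),
        n_trees=n_trees, seed=seed,
    )
    r_tp = classify.fit_bagged_trees(
        classify.build_predictor_set(tp, "features_time_preserving"),
        n_trees=n_trees, seed=seed,
    )
    return r_tp.oob_accuracy, r_avg.oob_accuracy
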