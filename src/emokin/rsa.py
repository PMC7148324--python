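"""Representational similarity analysis over stimulus sets.

First level: a representational dissimilarity matrix (RDM) per descriptor
— Euclidean distances between per-stimulus feature values, dummy-coded
category distances (0 within a category, sqrt(2) between), and
participant-averaged rating RDMs. Second level: Spearman rank correlation
between the strictly-lower-triangle entries of RDM pairs, with Bonferroni
control over a caller-specified number of comparisons per item.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .ratings import RatingTable

__all__ = [
    "RDM",
    "RDMComparison",
    "SecondLevelResult",
    "euclidean_rdm",
    "dummy_rdm",
    "rating_rdms",
    "compare_rdms",
    "second_level_matrix",
]

DUMMY_DISTANCE = math.sqrt(2.0)  # distance between distinct one-hot vectors


@dataclass
class RDM:
    """Symmetric stimulus x stimulus dissimilarity matrix, zero diagonal."""

    matrix: np.ndarray
    stimulus_order: list[str]
    source: str
    distance_kind: str  # euclidean | dummy | one_minus_spearman

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.stimulus_order)
        if m.shape != (n, n):
            raise ValueError(
                f"RDM {self.source!r}: matrix {m.shape} vs {n} stimuli"
            )
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError(f"RDM {self.source!r} is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError(f"RDM {self.source!r} has a nonzero diagonal")
        if (m < -1e-12).any():
            raise ValueError(f"RDM {self.source!r} has negative entries")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.stimulus_order)

    def lower_triangle(self) -> np.ndarray:
        """Strictly-lower-triangle entries (the diagonal carries no information)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.matrix[i, j]

    def to_csv(self, path, sidecar_path=None) -> None:
        pd.DataFrame(
            self.matrix, index=self.stimulus_order, columns=self.stimulus_order
        ).to_csv(path, float_format="%.17g")
        if sidecar_path is None:
            sidecar_path = Path(str(path)).with_suffix(".meta.json")
        Path(sidecar_path).write_text(
            json.dumps(
                {"source": self.source, "distance_kind": self.distance_kind}
            )
        )


@dataclass(frozen=True)
class RDMComparison:
    """Second-level Spearman comparison of two RDM lower triangles."""

    rho: float
    df: int
    p_raw: float
    p_bonferroni: float
    m_comparisons: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")


def euclidean_rdm(
    values: np.ndarray | pd.Series | pd.DataFrame,
    ids: list[str] | None = None,
    source: str = "feature",
) -> RDM:
    """Pairwise Euclidean distances between per-stimulus descriptors.

    ``values`` is (n,) scalars — where the distance reduces to the
    absolute difference — or an (n, d) array of descriptor vectors.
    """
    if isinstance(values, (pd.Series, pd.DataFrame)):
        if ids is None:
            ids = list(values.index)
        values = values.to_numpy()
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"expected 1-D or 2-D values, got shape {arr.shape}")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 stimuli")
    if ids is None:
        ids = [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError(f"{len(ids)} ids for {n} stimuli")
    return RDM(squareform(pdist(arr)), list(ids), source, "euclidean")


def dummy_rdm(
    labels, ids: list[str] | None = None, source: str = "emotion"
) -> RDM:
    """Dummy-coded category RDM: 0 within a category, sqrt(2) between.

    sqrt(2) is the Euclidean distance between distinct one-hot vectors.
    """
    if isinstance(labels, pd.Series):
        if ids is None:
            ids = list(labels.index)
        labels = list(labels)
    labels = list(labels)
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab))
           for lab in labels):
        raise ValueError("missing category label")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 stimuli")
    if ids is None:
        ids = [str(i) for i in range(n)]
    arr = np.array(labels, dtype=object)
    same = arr[:, None] == arr[None, :]
    matrix = np.where(same, 0.0, DUMMY_DISTANCE)
    return RDM(matrix, list(ids), source, "dummy")


def rating_rdms(ratings: RatingTable) -> dict[str, RDM]:
    """Group-average RDM per rating question.

    Scale questions: one Euclidean RDM per participant from their 7-point
    responses, averaged entrywise across participants. Forced-choice
    questions: per-participant dummy RDMs, averaged entrywise. Missing
    responses raise (no imputation), via :meth:`RatingTable.pivot`.
    """
    out: dict[str, RDM] = {}
    sids = ratings.stimulus_ids
    for q in ratings.questions:
        wide = ratings.pivot(q)  # participants x stimuli
        mats = []
        for _, row in wide.iterrows():
            if ratings.is_scale(q):
                mats.append(euclidean_rdm(row.to_numpy(), sids, q).matrix)
            else:
                mats.append(dummy_rdm(list(row), sids, q).matrix)
        out[q] = RDM(np.mean(mats, axis=0), sids, q, "euclidean"
                     if ratings.is_scale(q) else "dummy")
    return out


def compare_rdms(a: RDM, b: RDM, m_comparisons: int = 1) -> RDMComparison:
    """Spearman rank correlation of two RDMs' strictly-lower triangles.

    df = n(n-1)/2 - 2 over the n(n-1)/2 unordered pairs; the two-sided p
    comes from the t approximation (ties get average ranks);
    ``p_bonferroni = min(1, p_raw * m_comparisons)``.
    """
    if a.stimulus_order != b.stimulus_order:
        raise ValueError(
            f"stimulus orders differ between {a.source!r} and {b.source!r}"
        )
    x = a.lower_triangle()
    y = b.lower_triangle()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "undefined correlation: an RDM triangle has zero variance "
            f"({a.source!r} vs {b.source!r})"
        )
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    df = len(x) - 2
    p = float(res.pvalue)
    return RDMComparison(rho, df, p, min(1.0, p * m_comparisons), m_comparisons)


@dataclass
class SecondLevelResult:
    """Pairwise second-level comparisons of a set of named RDMs.

    ``distance`` holds 1 - rho (0 on the diagonal); masks mark Bonferroni
    (alpha = 0.05 / m_per_item) and uncorrected (alpha = 0.05) significance.
    """

    names: list[str]
    distance: pd.DataFrame          # 1 - rho
    comparisons: dict[tuple[str, str], RDMComparison]
    significant_bonferroni: pd.DataFrame
    significant_uncorrected: pd.DataFrame
    m_per_item: int

    def tidy(self) -> pd.DataFrame:
        rows = []
        for (a, b), c in self.comparisons.items():
            rows.append(
                {"item_a": a, "item_b": b, "rho": c.rho, "df": c.df,
                 "p_raw": c.p_raw, "p_bonferroni": c.p_bonferroni}
            )
        return pd.DataFrame(rows)


def second_level_matrix(
    rdms: dict[str, RDM], m_per_item: int, alpha: float = 0.05
) -> SecondLevelResult:
    """All pairwise Spearman comparisons among named RDMs.

    The stored matrix is 1 - rho (a dissimilarity: 0 means identical rank
    structure). ``m_per_item`` is the Bonferroni divisor applied to every
    comparison (e.g. 9 for the computed-feature analysis, 12 for the
    behavioural one).
    """
    names = list(rdms)
    if len(names) < 2:
        raise ValueError("need at least 2 RDMs")
    n = len(names)
    dist = np.zeros((n, n))
    sig_b = np.zeros((n, n), dtype=bool)
    sig_u = np.zeros((n, n), dtype=bool)
    comparisons: dict[tuple[str, str], RDMComparison] = {}
    for i in range(n):
        for j in range(i + 1, n):
            c = compare_rdms(rdms[names[i]], rdms[names[j]], m_per_item)
            comparisons[(names[i], names[j])] = c
            dist[i, j] = dist[j, i] = 1.0 - c.rho
            sig_b[i, j] = sig_b[j, i] = c.p_raw < alpha / m_per_item
            sig_u[i, j] = sig_u[j, i] = c.p_raw < alpha
    return SecondLevelResult(
        names,
        pd.DataFrame(dist, index=names, columns=names),
        comparisons,
        pd.DataFrame(sig_b, index=names, columns=names),
        pd.DataFrame(sig_u, index=names, columns=names),
        m_per_item,
    )
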