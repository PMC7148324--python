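"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops and textbook formulas, kept
deliberately separate from the package's vectorised code paths.
"""

from __future__ import annotations

import math

import numpy as np

from emokin.features import ANGLE_SITES, SYMMETRY_PAIRS
from emokin.pose import CANONICAL_KEYPOINTS

_KP = {name: i for i, name in enumerate(CANONICAL_KEYPOINTS)}


def velocity_oracle(frames: np.ndarray) -> np.ndarray:
    T, K, _ = frames.shape
    out = np.zeros((T - 1, K))
    for t in range(T - 1):
        for k in range(K):
            dx = frames[t + 1, k, 0] - frames[t, k, 0]
            dy = frames[t + 1, k, 1] - frames[t, k, 1]
            out[t, k] = math.hypot(dx, dy)
    return out


def acceleration_oracle(frames: np.ndarray) -> np.ndarray:
    T, K, _ = frames.shape
    out = np.zeros((T - 2, K))
    for t in range(T - 2):
        for k in range(K):
            v1 = frames[t + 1, k] - frames[t, k]
            v2 = frames[t + 2, k] - frames[t + 1, k]
            out[t, k] = math.hypot(v2[0] - v1[0], v2[1] - v1[1])
    return out


def vertical_movement_oracle(frames: np.ndarray) -> np.ndarray:
    T, K, _ = frames.shape
    out = np.zeros((T - 1, K))
    for t in range(T - 1):
        for k in range(K):
            out[t, k] = -(frames[t + 1, k, 1] - frames[t, k, 1])
    return out


def limb_angles_oracle(frames: np.ndarray) -> np.ndarray:
    """Interior angles via absolute segment headings (atan2), not arccos."""
    T = frames.shape[0]
    out = np.zeros((T, len(ANGLE_SITES)))
    for t in range(T):
        for j, (_site, vtx, a, b) in enumerate(ANGLE_SITES):
            v = frames[t, _KP[vtx]]
            ua = frames[t, _KP[a]] - v
            ub = frames[t, _KP[b]] - v
            th = math.atan2(ua[1], ua[0]) - math.atan2(ub[1], ub[0])
            th = abs(math.degrees(th)) % 360.0
            out[t, j] = min(th, 360.0 - th)
    return out


def symmetry_oracle(frames: np.ndarray) -> np.ndarray:
    T = frames.shape[0]
    out = np.zeros((T, len(SYMMETRY_PAIRS)))
    for t in range(T):
        xn = frames[t, _KP["nose"], 0]
        for j, joint in enumerate(SYMMETRY_PAIRS):
            dl = abs(frames[t, _KP[f"l_{joint}"], 0] - xn)
            dr = abs(frames[t, _KP[f"r_{joint}"], 0] - xn)
            out[t, j] = abs(dl - dr)
    return out


def shoulder_ratio_oracle(frames: np.ndarray) -> np.ndarray:
    T = frames.shape[0]
    out = np.zeros((T, 1))
    for t in range(T):
        ls = frames[t, _KP["l_shoulder"]]
        rs = frames[t, _KP["r_shoulder"]]
        span = math.hypot(ls[0] - rs[0], ls[1] - rs[1])
        xs = [frames[t, k, 0] for k in range(frames.shape[1])]
        out[t, 0] = span / (max(xs) - min(xs))
    return out


def surface_oracle(frames: np.ndarray) -> np.ndarray:
    T = frames.shape[0]
    out = np.zeros((T, 1))
    for t in range(T):
        xs = [frames[t, k, 0] for k in range(frames.shape[1])]
        ys = [frames[t, k, 1] for k in range(frames.shape[1])]
        out[t, 0] = (max(xs) - min(xs)) * (max(ys) - min(ys))
    return out


def limb_contraction_oracle(frames: np.ndarray) -> np.ndarray:
    T = frames.shape[0]
    out = np.zeros((T, 1))
    for t in range(T):
        nose = frames[t, _KP["nose"]]
        dists = []
        for kp in ("l_wrist", "r_wrist", "l_ankle", "r_ankle"):
            p = frames[t, _KP[kp]]
            dists.append(math.hypot(p[0] - nose[0], p[1] - nose[1]))
        out[t, 0] = sum(dists) / 4.0
    return out


FEATURE_ORACLES = {
    "velocity": velocity_oracle,
    "acceleration": acceleration_oracle,
    "vertical_movement": vertical_movement_oracle,
    "limb_angles": limb_angles_oracle,
    "symmetry": symmetry_oracle,
    "shoulder_ratio": shoulder_ratio_oracle,
    "surface": surface_oracle,
    "limb_contraction": limb_contraction_oracle,
}


def euclidean_rdm_oracle(vectors: np.ndarray) -> np.ndarray:
    vectors = np.atleast_2d(np.asarray(vectors, float))
    if vectors.shape[0] == 1:
        vectors = vectors.T
    n = vectors.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = math.sqrt(
                sum((vectors[i, d] - vectors[j, d]) ** 2
                    for d in range(vectors.shape[1]))
            )
    return out


def _avg_ranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for m in range(i, j + 1):
            ranks[order[m]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Average-rank transform followed by a hand-coded Pearson correlation."""
    rx, ry = _avg_ranks(np.asarray(x)), _avg_ranks(np.asarray(y))
    mx, my = rx.mean(), ry.mean()
    num = float(((rx - mx) * (ry - my)).sum())
    den = math.sqrt(float(((rx - mx) ** 2).sum() * ((ry - my) ** 2).sum()))
    return num / den


def rm_anova_oracle(wide: np.ndarray) -> dict:
    """Textbook within-subject sums-of-squares decomposition + GG epsilon."""
    x = np.asarray(wide, float)
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((x[i, :].mean() - grand) ** 2 for i in range(n))
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    np2 = ss_cond / (ss_cond + ss_err)
    # Greenhouse-Geisser epsilon from the condition covariance matrix
    S = np.cov(x, rowvar=False, ddof=1)
    mean_all = S.mean()
    mean_diag = np.diag(S).mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        (S ** 2).sum() - 2 * k * (row_means ** 2).sum() + k ** 2 * mean_all ** 2
    )
    eps = num / den
    return {"F": F, "df1": df1, "df2": df2, "np2": np2, "epsilon": eps,
            "ss_cond": ss_cond, "ss_err": ss_err}


def icc_oracle(arr: np.ndarray) -> dict:
    """ICC(2,1)/ICC(2,k) from the two-way random-effects mean squares."""
    x = np.asarray(arr, float)  # raters x targets
    k, n = x.shape
    grand = x.mean()
    target_means = x.mean(axis=0)
    rater_means = x.mean(axis=1)
    ss_targets = k * sum((m - grand) ** 2 for m in target_means)
    ss_raters = n * sum((m - grand) ** 2 for m in rater_means)
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_targets - ss_raters
    msr = ss_targets / (n - 1)        # between targets
    msc = ss_raters / (k - 1)         # between raters
    mse = ss_err / ((n - 1) * (k - 1))
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    average = (msr - mse) / (msr + (msc - mse) / n)
    return {"single": single, "average": average}
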