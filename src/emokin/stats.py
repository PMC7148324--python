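"""Repeated-measures ANOVA, Bonferroni post-hocs and inter-rater ICC.

The one-way repeated-measures ANOVA treats each exemplar (video index) as
the repeated-measure unit and the emotion category as a k = 4 level
within-unit factor, reporting F, (possibly Greenhouse-Geisser-corrected)
degrees of freedom, p and partial eta squared. Sphericity is assessed by
Mauchly's test; in ``auto`` mode the GG correction is applied when that
test rejects at alpha = 0.05.

Inter-rater reliability uses the two-way random-effects intraclass
correlation under the absolute-agreement definition, reporting both the
single-rater ICC(2,1) and the average-of-k-raters ICC(2,k).

Computation is delegated to pingouin; this module owns table layout,
mode handling and result containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosthocTable",
    "ICCResult",
    "rm_anova",
    "posthoc_bonferroni",
    "icc_absolute_agreement",
]

SPHERICITY_ALPHA = 0.05


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA result for a k-level factor."""

    F: float
    df1: float
    df2: float
    p: float
    partial_eta_squared: float
    epsilon: float           # Greenhouse-Geisser estimate
    corrected: bool          # whether df1/df2/p are GG-corrected
    mauchly_w: float
    mauchly_p: float

    def summary(self) -> str:
        return (
            f"F({self.df1:g}, {self.df2:g}) = {self.F:.3f}, p = {self.p:.4g}, "
            f"partial eta^2 = {self.partial_eta_squared:.3f}"
            + (" (Greenhouse-Geisser corrected)" if self.corrected else "")
        )


@dataclass
class PosthocTable:
    """All pairwise paired t-tests with Bonferroni-multiplied p-values."""

    rows: pd.DataFrame  # pair_a, pair_b, mean_diff, t, df, p_raw, p_bonferroni

    def contrast(self, a: str, b: str) -> pd.Series:
        """The row for conditions (a, b), with mean_diff oriented as a - b."""
        m = self.rows
        hit = m[(m.pair_a == a) & (m.pair_b == b)]
        if len(hit):
            return hit.iloc[0]
        hit = m[(m.pair_a == b) & (m.pair_b == a)]
        if not len(hit):
            raise KeyError(f"no contrast for pair ({a}, {b})")
        row = hit.iloc[0].copy()
        row["pair_a"], row["pair_b"] = a, b
        row["mean_diff"] = -row["mean_diff"]
        row["t"] = -row["t"]
        return row


@dataclass(frozen=True)
class ICCResult:
    """Two-way random, absolute-agreement intraclass correlations."""

    icc_single: float    # ICC(2,1)
    icc_average: float   # ICC(2,k)
    ci_single: tuple[float, float]
    ci_average: tuple[float, float]
    n_raters: int
    n_targets: int


def _as_wide(values) -> pd.DataFrame:
    """Coerce a unit x condition table to a wide DataFrame and validate it."""
    if isinstance(values, pd.DataFrame):
        wide = values.copy()
    else:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D unit x condition table")
        wide = pd.DataFrame(arr)
    if wide.isna().any().any():
        raise ValueError("missing cells in the repeated-measures table")
    n, k = wide.shape
    if k < 2 or n < 2:
        raise ValueError(
            f"need >= 2 conditions and >= 2 units, got {k} x {n}"
        )
    return wide


def _long(wide: pd.DataFrame) -> pd.DataFrame:
    return (
        wide.reset_index(names="unit")
        .melt(id_vars="unit", var_name="condition", value_name="y")
    )


def rm_anova(
    values, correct: Literal["auto", "never", "always"] = "auto"
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a unit x condition table.

    ``values``: complete n x k table (DataFrame with condition columns, or
    array). ``correct`` controls the Greenhouse-Geisser correction:
    ``auto`` applies it when Mauchly's test rejects sphericity at
    alpha = 0.05, ``always``/``never`` force it on/off. Uncorrected dfs are
    (k - 1, (k - 1)(n - 1)); corrected dfs are epsilon times those.
    """
    if correct not in ("auto", "never", "always"):
        raise ValueError(f"unknown correct mode {correct!r}")
    wide = _as_wide(values)
    n, k = wide.shape
    arr = wide.to_numpy(dtype=float)
    if np.allclose(arr.var(axis=1), 0.0):
        # every unit identical across conditions: no effect, no error SS
        return AnovaResult(
            F=0.0, df1=float(k - 1), df2=float((k - 1) * (n - 1)), p=1.0,
            partial_eta_squared=0.0, epsilon=1.0, corrected=False,
            mauchly_w=1.0, mauchly_p=1.0,
        )
    long = _long(wide)
    aov = pg.rm_anova(
        data=long, dv="y", within="condition", subject="unit",
        correction=True, effsize="np2", detailed=False,
    ).iloc[0]
    spher = pg.sphericity(data=long, dv="y", within="condition", subject="unit")
    eps = float(
        pg.epsilon(data=long, dv="y", within="condition", subject="unit",
                   correction="gg")
    )
    apply_gg = correct == "always" or (
        correct == "auto" and spher.pval < SPHERICITY_ALPHA
    )
    df1, df2 = float(aov["ddof1"]), float(aov["ddof2"])
    p = float(aov["p_unc"])
    if apply_gg:
        df1, df2 = eps * df1, eps * df2
        p = float(aov.get("p_GG_corr", sps.f.sf(aov["F"], df1, df2)))
    return AnovaResult(
        F=float(aov["F"]), df1=df1, df2=df2, p=p,
        partial_eta_squared=float(aov["np2"]),
        epsilon=float(np.clip(eps, 1.0 / (k - 1), 1.0)),
        corrected=apply_gg,
        mauchly_w=float(spher.W), mauchly_p=float(spher.pval),
    )


def posthoc_bonferroni(values) -> PosthocTable:
    """Paired t-tests for every condition pair, Bonferroni over C(k, 2).

    Each test has df = n - 1; the raw two-sided p is multiplied by the
    number of pairs and capped at 1.
    """
    wide = _as_wide(values)
    conds = list(wide.columns)
    m = len(conds) * (len(conds) - 1) // 2
    rows = []
    for a, b in combinations(conds, 2):
        diff = wide[a].to_numpy(dtype=float) - wide[b].to_numpy(dtype=float)
        if np.allclose(diff, diff[0]) and diff.std() == 0:
            t, p = (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(wide[a], wide[b])
        rows.append(
            {
                "pair_a": a, "pair_b": b,
                "mean_diff": float(np.mean(diff)),
                "t": float(t), "df": len(wide) - 1,
                "p_raw": float(p),
                "p_bonferroni": min(1.0, float(p) * m),
            }
        )
    return PosthocTable(pd.DataFrame(rows))


def icc_absolute_agreement(ratings) -> ICCResult:
    """ICC(2,1) and ICC(2,k) for a complete rater x target matrix.

    ``ratings``: raters in rows, targets (stimuli) in columns, or a
    DataFrame laid out that way. Both the single-rater and the
    average-of-k-raters coefficients of the two-way random-effects,
    absolute-agreement model are returned with their 95% CIs.
    """
    if isinstance(ratings, pd.DataFrame):
        arr = ratings.to_numpy(dtype=float)
    else:
        arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D rater x target matrix")
    if np.isnan(arr).any():
        raise ValueError("missing cells in the rating matrix")
    n_raters, n_targets = arr.shape
    if n_raters < 2 or n_targets < 2:
        raise ValueError("need >= 2 raters and >= 2 targets")
    if np.ptp(arr.mean(axis=0)) == 0:
        raise ValueError("undefined ICC: no between-target variance")
    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n_targets), n_raters),
            "rater": np.repeat(np.arange(n_raters), n_targets),
            "score": arr.ravel(),
        }
    )
    icc = pg.intraclass_corr(
        data=long, targets="target", raters="rater", ratings="score"
    ).set_index("Type")
    single = icc.loc["ICC2"] if "ICC2" in icc.index else icc.loc["ICC(A,1)"]
    average = icc.loc["ICC2k"] if "ICC2k" in icc.index else icc.loc["ICC(A,k)"]
    ci_col = "CI95%" if "CI95%" in icc.columns else "CI95"
    return ICCResult(
        icc_single=float(single["ICC"]),
        icc_average=float(average["ICC"]),
        ci_single=tuple(np.asarray(single[ci_col], dtype=float)),
        ci_average=tuple(np.asarray(average[ci_col], dtype=float)),
        n_raters=n_raters,
        n_targets=n_targets,
    )
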