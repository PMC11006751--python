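"""Group-comparison and regression statistics for per-vessel measurements.

Operates on tabular immunofluorescence quantifications (one row per blood
vessel: subject, genotype group, diameter, marker intensity).  Implements
the heteroscedastic one-way ANOVAs (Welch and Brown-Forsythe), the
Benjamini-Krieger-Yekutieli two-stage adaptive FDR step-up, Kruskal-Wallis
with Dunn's pairwise post-hoc (Bonferroni-adjusted), intensity-vs-diameter
least-squares fits (linear or second-order polynomial, unweighted), percent
change versus a reference group, and the two-sample Kolmogorov-Smirnov test.

Intensities are in arbitrary fluorescence units; only relative quantities
(percent change, R^2, p-values) are meaningful.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "BkyResult",
    "KruskalDunnResult",
    "RegressionFit",
    "welch_anova",
    "brown_forsythe_anova",
    "bky_two_stage",
    "kruskal_dunn",
    "fit_intensity_vs_diameter",
    "percent_change",
    "ks_two_sample",
    "MAX_VESSEL_DIAMETER",
]

#: vessels wider than this (micrometers) are excluded upstream
MAX_VESSEL_DIAMETER = 50.0


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    df_num: float
    df_denom: float
    p: float


@dataclass(frozen=True)
class BkyResult:
    """Two-stage adaptive FDR outcome at level q."""

    reject: np.ndarray
    adjusted: np.ndarray  # smallest q'-scale values comparable to q
    n_stage1_rejections: int
    q: float


@dataclass(frozen=True)
class KruskalDunnResult:
    h: float
    p: float
    #: (group_i, group_j, z, p_adjusted) for every pair, Bonferroni-adjusted
    pairwise: tuple


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    slope_p: float
    quadratic: float | None = None


def _check_groups(groups: Sequence[np.ndarray], min_n: int = 2) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < min_n:
            raise ValueError(f"every group needs n >= {min_n}")
    return gs


def welch_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Welch's heteroscedastic one-way ANOVA (Satterthwaite-type df).

    With two groups the statistic equals the squared Welch t statistic.
    """
    gs = _check_groups(groups)
    if all(np.var(g, ddof=1) == 0 for g in gs):
        raise ValueError("all groups have zero variance; Welch ANOVA undefined")
    from statsmodels.stats.oneway import anova_oneway

    res = anova_oneway(gs, use_var="unequal", welch_correction=True)
    return AnovaResult(
        statistic=float(res.statistic),
        df_num=float(res.df_num),
        df_denom=float(res.df_denom),
        p=float(res.pvalue),
    )


def brown_forsythe_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Brown-Forsythe modified F test for equal means.

    Classical between-group sum of squares over a variance-weighted
    denominator sum (1 - n_i/N) s_i^2, with adjusted denominator df; equals
    the classical one-way F when variances are equal and n is large.
    """
    gs = _check_groups(groups)
    if all(np.var(g, ddof=1) == 0 for g in gs):
        raise ValueError("all groups have zero variance; test undefined")
    from statsmodels.stats.oneway import anova_oneway

    res = anova_oneway(gs, use_var="bf")
    return AnovaResult(
        statistic=float(res.statistic),
        df_num=float(res.df_num),
        df_denom=float(res.df_denom),
        p=float(res.pvalue),
    )


def bky_two_stage(pvalues: Sequence[float], q: float = 0.05) -> BkyResult:
    """Benjamini-Krieger-Yekutieli two-stage adaptive linear step-up FDR.

    Stage 1: Benjamini-Hochberg at q' = q/(1+q), giving r1 rejections.  If
    r1 is 0 or m, that is the answer.  Otherwise the null proportion is
    estimated as (m - r1)/m and stage 2 re-runs BH at q' * m/(m - r1).

    ``adjusted`` values are comparable to q: hypothesis i is rejected iff
    ``adjusted[i] <= q`` (BH step-up values scaled by (m - r1)(1+q)/m,
    which reproduces both stages' stopping rules).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return BkyResult(np.zeros(0, bool), np.zeros(0), 0, q)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    r1 = _bh_rejections(p, q1)
    m0_hat = m - r1
    if r1 == 0:
        # stage 2 at m0 = m is BH at q' again: rejects nothing
        reject = np.zeros(m, dtype=bool)
    elif r1 == m:
        reject = np.ones(m, dtype=bool)
    else:
        reject = _bh_reject_mask(p, q1 * m / m0_hat)
    adjusted = _bh_adjusted(p) * max(m0_hat, 0) * (1.0 + q) / m
    adjusted = np.minimum(adjusted, 1.0)
    return BkyResult(reject=reject, adjusted=adjusted, n_stage1_rejections=r1, q=q)


def _bh_adjusted(p: np.ndarray) -> np.ndarray:
    """Standard BH step-up adjusted p-values (monotone)."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj
    return out


def _bh_rejections(p: np.ndarray, q: float) -> int:
    m = p.size
    ps = np.sort(p)
    below = ps <= q * np.arange(1, m + 1) / m
    return int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0


def _bh_reject_mask(p: np.ndarray, q: float) -> np.ndarray:
    r = _bh_rejections(p, q)
    if r == 0:
        return np.zeros(p.size, dtype=bool)
    thresh = np.sort(p)[r - 1]
    return p <= thresh


def kruskal_dunn(
    groups: Sequence[np.ndarray], labels: Sequence[str] | None = None
) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise post-hoc.

    Dunn z statistics compare mean ranks over the pooled sample; two-sided
    normal p-values are Bonferroni-adjusted over all tested pairs.  If all
    observations are identical, H = 0 and p = 1.
    """
    gs = _check_groups(groups, min_n=1)
    labels = list(labels) if labels is not None else [str(i) for i in range(len(gs))]
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        pairs = tuple(
            (labels[i], labels[j], 0.0, 1.0)
            for i, j in itertools.combinations(range(len(gs)), 2)
        )
        return KruskalDunnResult(h=0.0, p=1.0, pairwise=pairs)
    h, p = stats.kruskal(*gs)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    sizes = [g.size for g in gs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(gs))]
    # tie correction for the Dunn variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    n_pairs = len(gs) * (len(gs) - 1) // 2
    pairs = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        p_adj = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_pairs)
        pairs.append((labels[i], labels[j], float(z), float(p_adj)))
    return KruskalDunnResult(h=float(h), p=float(p), pairwise=tuple(pairs))


def fit_intensity_vs_diameter(
    diameter: np.ndarray, intensity: np.ndarray, model: str = "linear"
) -> RegressionFit:
    """Least-squares fit of marker intensity on vessel diameter.

    ``model`` is ``"linear"`` or ``"quadratic"`` (second-order polynomial,
    unweighted).  Reports the linear slope, R^2, adjusted
    R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1), and the t-test p-value for a
    non-zero slope.
    """
    import statsmodels.api as sm

    x = np.asarray(diameter, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if model not in ("linear", "quadratic"):
        raise ValueError("model must be 'linear' or 'quadratic'")
    min_n = 3 if model == "linear" else 4
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points for a {model} fit")
    if np.all(x == x[0]):
        raise ValueError("diameter is constant; fit undefined")
    cols = {"diameter": x}
    if model == "quadratic":
        cols["diameter2"] = x**2
    import pandas as pd

    X = sm.add_constant(pd.DataFrame(cols))
    res = sm.OLS(y, X).fit()
    return RegressionFit(
        slope=float(res.params["diameter"]),
        intercept=float(res.params["const"]),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        slope_p=float(res.pvalues["diameter"]),
        quadratic=float(res.params["diameter2"]) if model == "quadratic" else None,
    )


def percent_change(mean_test: float, mean_ref: float) -> float:
    """Percent change of a test-group mean versus the reference-group mean."""
    if mean_ref == 0:
        raise ValueError("reference mean is zero; percent change undefined")
    return 100.0 * (mean_test - mean_ref) / mean_ref


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
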