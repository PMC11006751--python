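"""Replication statistics for a candidate protective variant.

Carrier-based effect-allele frequencies, unadjusted 2x2 odds ratios with
Wald confidence intervals (Haldane-Anscombe 0.5 correction when a cell is
empty), standard-error recovery from printed confidence bounds,
fixed-effects inverse-variance-weighted (IVW) meta-analysis with Cochran's
Q heterogeneity test, covariate-adjustable logistic association, and
ordinary-least-squares age-at-onset regression.

All odds-scale quantities are handled on the log-odds scale internally;
95% intervals use the fixed normal quantile 1.959964 so printed bounds
round-trip bit-stably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z95",
    "CohortAssociation",
    "MetaResult",
    "LogisticFit",
    "AaoFit",
    "eaf_from_carrier_counts",
    "odds_ratio_2x2",
    "se_from_ci",
    "ivw_meta",
    "logistic_assoc",
    "aao_regression",
    "association_from_counts",
    "meta_from_cohort_table",
]

#: normal quantile for two-sided 95% intervals
Z95 = 1.959964


@dataclass(frozen=True)
class CohortAssociation:
    """Per-cohort carrier counts with the derived 2x2 association."""

    cohort: str
    cn_carriers: int
    cn_total: int
    ad_carriers: int
    ad_total: int
    eaf_total: float  # percent
    eaf_cn: float
    eaf_ad: float
    log_or: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effects IVW pooled estimate with Cochran's Q heterogeneity."""

    pooled_log_or: float
    pooled_se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    cochran_q: float
    q_df: int
    q_p: float


@dataclass(frozen=True)
class LogisticFit:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    log_or: float
    se: float
    separation: bool = False


@dataclass(frozen=True)
class AaoFit:
    """Age-at-onset regression: years of onset delay per protective allele."""

    beta_per_allele: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    covariate_estimates: dict


def eaf_from_carrier_counts(
    n_carriers: int, n_total: int, copies_per_carrier: int = 1
) -> float:
    """Effect-allele frequency (percent) from carrier counts.

    In the rare-variant regime carriers are assumed single-copy:
    ``100 * n_carriers * copies / (2 * n_total)``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_carriers <= n_total:
        raise ValueError("n_carriers must lie in [0, n_total]")
    return 100.0 * (n_carriers * copies_per_carrier) / (2.0 * n_total)


def odds_ratio_2x2(
    cn_carriers: float,
    cn_noncarriers: float,
    ad_carriers: float,
    ad_noncarriers: float,
) -> tuple[float, tuple[float, float], float]:
    """Unadjusted odds ratio of disease for carriers vs non-carriers.

    Cross-product ratio with Wald CI and two-sided Wald p on the log scale;
    0.5 is added to every cell iff any cell is zero (Haldane-Anscombe).
    Returns ``(or, (ci_low, ci_high), p)``.
    """
    cells = np.array(
        [cn_carriers, cn_noncarriers, ad_carriers, ad_noncarriers], dtype=float
    )
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    # an empty group margin cannot be rescued by a continuity correction
    if cells[0] + cells[1] == 0 or cells[2] + cells[3] == 0:
        raise ValueError("2x2 table has an empty margin")
    if np.any(cells == 0):
        cells = cells + 0.5
    a, b, c, d = cells  # CN carriers, CN non-carriers, AD carriers, AD non-carriers
    log_or = math.log((c * b) / (a * d))
    se = math.sqrt((1 / a + 1 / b + 1 / c + 1 / d))
    ci = (math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se))
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return math.exp(log_or), ci, p


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Recover the log-scale SE from a printed odds-ratio confidence interval."""
    if not 0 < ci_low < ci_high:
        raise ValueError("confidence bounds must satisfy 0 < low < high")
    z = Z95 if level == 0.95 else stats.norm.ppf((1 + level) / 2)
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)


def ivw_meta(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """Fixed-effects inverse-variance-weighted pooling of log odds ratios.

    ``estimates`` is a sequence of ``(log_or, se)``.  Weights are
    ``1/se^2``; Cochran's Q = sum w_i (theta_i - pooled)^2 is referred to a
    chi-square with k-1 degrees of freedom.
    """
    if len(estimates) == 0:
        raise ValueError("at least one estimate is required")
    theta = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = se**-2
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (theta - pooled) ** 2))
    q_df = len(estimates) - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    return MetaResult(
        pooled_log_or=pooled,
        pooled_se=pooled_se,
        odds_ratio=math.exp(pooled),
        ci_low=math.exp(pooled - Z95 * pooled_se),
        ci_high=math.exp(pooled + Z95 * pooled_se),
        z=z,
        p=p,
        cochran_q=q,
        q_df=q_df,
        q_p=q_p,
    )


def logistic_assoc(
    status: np.ndarray,
    allele_dosage: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of case status on allele dosage.

    With no covariates the slope equals the closed-form 2x2 allele-dosage
    log odds ratio.  Complete separation is flagged and the CI reported as
    unbounded.
    """
    import statsmodels.api as sm

    y = np.asarray(status, dtype=float)
    x = np.asarray(allele_dosage, dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    if x.min() == x.max():
        raise ValueError("allele dosage is constant; slope undefined")
    X = pd.DataFrame({"dosage": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    model = sm.Logit(y, X)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=PerfectSeparationWarning)
        try:
            res = model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # perfectly separated data: the MLE diverges
            return LogisticFit(
                odds_ratio=float("nan"),
                ci_low=0.0,
                ci_high=float("inf"),
                p=float("nan"),
                log_or=float("nan"),
                se=float("inf"),
                separation=True,
            )
    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    separation = bool(not np.isfinite(se) or se > 1e3 or not res.mle_retvals.get("converged", True))
    if separation:
        return LogisticFit(
            odds_ratio=math.exp(beta) if np.isfinite(beta) else float("nan"),
            ci_low=0.0,
            ci_high=float("inf"),
            p=float("nan"),
            log_or=beta,
            se=float("inf"),
            separation=True,
        )
    return LogisticFit(
        odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        p=float(2.0 * stats.norm.sf(abs(beta / se))),
        log_or=beta,
        se=se,
    )


def aao_regression(
    ages_at_onset: np.ndarray,
    allele_dosage: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> AaoFit:
    """OLS regression of age at onset on protective-allele dosage (cases only)."""
    import statsmodels.api as sm

    y = np.asarray(ages_at_onset, dtype=float)
    x = np.asarray(allele_dosage, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct dosage values")
    X = pd.DataFrame({"dosage": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    ci = res.conf_int().loc["dosage"]
    others = {
        k: float(v) for k, v in res.params.items() if k != "dosage"
    }
    return AaoFit(
        beta_per_allele=beta,
        se=se,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(res.pvalues["dosage"]),
        covariate_estimates=others,
    )


def association_from_counts(
    cohort: str, cn_carriers: int, cn_total: int, ad_carriers: int, ad_total: int
) -> CohortAssociation:
    """Build a :class:`CohortAssociation` from carrier-count data."""
    or_, (lo, hi), p = odds_ratio_2x2(
        cn_carriers, cn_total - cn_carriers, ad_carriers, ad_total - ad_carriers
    )
    log_or = math.log(or_)
    return CohortAssociation(
        cohort=cohort,
        cn_carriers=cn_carriers,
        cn_total=cn_total,
        ad_carriers=ad_carriers,
        ad_total=ad_total,
        eaf_total=eaf_from_carrier_counts(
            cn_carriers + ad_carriers, cn_total + ad_total
        ),
        eaf_cn=eaf_from_carrier_counts(cn_carriers, cn_total),
        eaf_ad=eaf_from_carrier_counts(ad_carriers, ad_total),
        log_or=log_or,
        se=(math.log(hi) - math.log(lo)) / (2 * Z95),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p=p,
    )


def meta_from_cohort_table(table: pd.DataFrame) -> tuple[list[CohortAssociation], MetaResult]:
    """Per-cohort associations + IVW meta from a carrier-count table.

    ``table`` columns: cohort, cn_carriers, cn_total, ad_carriers, ad_total.
    """
    assocs = [
        association_from_counts(
            str(r.cohort),
            int(r.cn_carriers),
            int(r.cn_total),
            int(r.ad_carriers),
            int(r.ad_total),
        )
        for r in table.itertuples(index=False)
    ]
    meta = ivw_meta([(a.log_or, a.se) for a in assocs])
    return assocs, meta
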