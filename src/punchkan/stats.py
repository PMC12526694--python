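"""Condition-comparison statistics on per-subject kinetic summaries.

The pipeline mirrors standard repeated-measures practice: box-plot (Tukey
fence) outlier screening, Shapiro-Wilk normality, one-way repeated-measures
ANOVA across the three NMES conditions with Mauchly's sphericity test gating
a Greenhouse-Geisser correction, and Bonferroni-adjusted paired t tests.

The RM-ANOVA decomposition is implemented directly from the sums of squares
(subject x condition two-way layout without replication):

    SS_cond = n * sum_j (mean_j - grand)^2
    SS_err  = sum_ij (x_ij - mean_i. - mean_.j + grand)^2
    F       = [SS_cond / (k-1)] / [SS_err / ((n-1)(k-1))]

Outliers are flagged, never removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import List, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RMDataset",
    "AnovaResult",
    "PairwiseComparison",
    "iqr_outliers",
    "shapiro_wilk",
    "rm_anova",
    "bonferroni_pairwise",
]


@dataclass
class RMDataset:
    """Complete n-subjects x k-conditions matrix of per-subject values."""

    values: np.ndarray
    condition_names: Sequence[str]
    indicator: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be n x k")
        if self.values.shape[1] != len(self.condition_names):
            raise ValueError("one name per condition column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RM matrix must be complete and finite")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float  # Greenhouse-Geisser epsilon (1.0 when sphericity holds)
    sphericity_p: float  # Mauchly test p (nan for k = 2)
    corrected: bool


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple
    t: float
    p_raw: float
    p_adj: float
    significant: bool


def iqr_outliers(values) -> np.ndarray:
    """Tukey fences: flag points outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 4:
        raise ValueError("need at least 4 values for a box-plot screen")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)


def shapiro_wilk(values):
    """Shapiro-Wilk W and p (3 <= n <= 5000; zero-variance input is an error)."""
    x = np.asarray(values, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance input")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the contrast-projected covariance."""
    n, k = values.shape
    S = np.cov(values, rowvar=False, ddof=1)
    C = _helmert_contrasts(k)
    D = C @ S @ C.T
    tr = np.trace(D)
    denom = (k - 1) * np.trace(D @ D)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(tr**2 / denom, 1.0 / (k - 1))))


def _helmert_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts."""
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1)
        C[i] /= np.linalg.norm(C[i])
    return C


def _mauchly(values: np.ndarray) -> float:
    """Mauchly's sphericity test p-value (chi-square approximation)."""
    n, k = values.shape
    if k < 3 or n <= k - 1:
        return math.nan
    S = np.cov(values, rowvar=False, ddof=1)
    C = _helmert_contrasts(k)
    D = C @ S @ C.T
    d = k - 1
    eig = np.linalg.eigvalsh(D)
    if np.any(eig <= 1e-14):
        return 0.0
    W = float(np.prod(eig) / (np.mean(eig) ** d))
    dd = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1.0))
    chi2 = -(n - 1.0) * dd * math.log(W)
    df = d * (d + 1) // 2 - 1
    return float(sps.chi2.sf(chi2, df))


def rm_anova(data: RMDataset, alpha_sphericity: float = 0.05) -> AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser gating.

    The correction is applied only when Mauchly's test rejects sphericity at
    ``alpha_sphericity``. Zero error variance yields F = inf, p = 0.
    """
    x = data.values
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = x.mean()
    subj_means = x.mean(axis=1, keepdims=True)
    cond_means = x.mean(axis=0, keepdims=True)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    resid = x - subj_means - cond_means + grand
    ss_err = float(np.sum(resid**2))
    df1, df2 = float(k - 1), float((n - 1) * (k - 1))
    if ss_err <= 1e-300:
        if ss_cond <= 1e-300:  # identical columns: no effect, no error
            return AnovaResult(0.0, df1, df2, 1.0, 1.0, math.nan, False)
        return AnovaResult(math.inf, df1, df2, 0.0, 1.0, math.nan, False)
    F = (ss_cond / df1) / (ss_err / df2)

    sph_p = _mauchly(x)
    eps, corrected = 1.0, False
    if not math.isnan(sph_p) and sph_p < alpha_sphericity:
        eps = _gg_epsilon(x)
        corrected = eps < 1.0
    p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return AnovaResult(float(F), df1 * eps, df2 * eps, p, eps, sph_p, corrected)


def bonferroni_pairwise(data: RMDataset, alpha: float = 0.05) -> List[PairwiseComparison]:
    """Paired t per condition pair; p_adj = min(1, m * p) with m = k(k-1)/2."""
    x = data.values
    k = x.shape[1]
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        diff = x[:, i] - x[:, j]
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            res = sps.ttest_rel(x[:, i], x[:, j])
            t, p = float(res.statistic), float(res.pvalue)
        p_adj = min(1.0, m * p)
        out.append(
            PairwiseComparison(
                pair=(data.condition_names[i], data.condition_names[j]),
                t=t, p_raw=p, p_adj=p_adj, significant=p_adj < alpha,
            )
        )
    return out
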