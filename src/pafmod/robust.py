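"""Distribution-level group comparisons.

Implements the robust-graphical-methods toolkit used to compare female and
male outcome distributions: Harrell-Davis quantile estimation, decile shift
functions with simultaneous percentile-bootstrap confidence intervals,
two-sample Kolmogorov-Smirnov tests, and the Fisher r-to-z comparison of two
independent correlations. Benjamini-Hochberg FDR adjustment is re-exported
behind the same surface.

Orientation convention: shift functions are female minus male, evaluated at
the deciles of each group's own distribution (the difference at decile d is
q_x(d) - q_y(d) with x = females), matching the reporting convention of the
figures this feeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DECILES = np.arange(1, 10) / 10.0


def _hd_weights(n: int, q: float) -> np.ndarray:
    """Harrell-Davis weights: successive differences of the Beta CDF at i/n.

    The estimator is sum_i w_i * x_(i) with w_i = I_{i/n}(a, b) -
    I_{(i-1)/n}(a, b), a = (n+1)q, b = (n+1)(1-q).
    """
    a = (n + 1) * q
    b = (n + 1) * (1 - q)
    grid = np.arange(n + 1) / n
    cdf = stats.beta.cdf(grid, a, b)
    return np.diff(cdf)


def hd_quantile(sample, q: float) -> float:
    """Harrell-Davis estimate of the q-th quantile (Beta-weighted order statistics)."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample must be 1-D")
    if x.size < 2:
        raise ValueError("Harrell-Davis estimation needs at least 2 observations")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly inside (0, 1)")
    return float(np.sort(x) @ _hd_weights(x.size, q))


def _hd_deciles_rows(sorted_rows: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(m, n) pre-sorted rows x (9, n) decile weights -> (m, 9) estimates."""
    return sorted_rows @ weights.T


@dataclass
class ShiftResult:
    """Decile shift function between two samples with simultaneous bootstrap CIs."""

    deciles: np.ndarray
    q_x: np.ndarray
    q_y: np.ndarray
    difference: np.ndarray           # q_x - q_y per decile
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray          # simultaneous CI excludes 0
    n_boot: int
    alpha: float
    seed: int | None
    orientation: str = "x - y (female - male)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "decile": self.deciles, "q_x": self.q_x, "q_y": self.q_y,
            "difference": self.difference, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "significant": self.significant,
        })


def shift_function(x, y, n_boot: int = 2000, alpha: float = 0.05,
                   seed: int | None = None) -> ShiftResult:
    """Harrell-Davis decile shift function of x (females) vs y (males).

    Per-decile differences q_x(d) - q_y(d) for d = 0.1..0.9 with percentile
    bootstrap confidence intervals (independent resampling of the two groups).
    Joint (1 - alpha) coverage over the 9 deciles is obtained by evaluating
    each decile's percentile interval at the Bonferroni-adjusted level
    alpha / 9, which is conservative (coverage >= 1 - alpha).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10 or y.size < 10:
        raise ValueError("shift function needs n >= 10 per group for stable deciles")
    if n_boot < 200:
        logger.warning("n_boot=%d is small; simultaneous bounds may be unstable", n_boot)

    wx = np.stack([_hd_weights(x.size, d) for d in DECILES])
    wy = np.stack([_hd_weights(y.size, d) for d in DECILES])
    q_x = np.sort(x) @ wx.T
    q_y = np.sort(y) @ wy.T
    diff = q_x - q_y

    rng = np.random.default_rng(seed)
    bx = np.sort(rng.choice(x, size=(n_boot, x.size), replace=True), axis=1)
    by = np.sort(rng.choice(y, size=(n_boot, y.size), replace=True), axis=1)
    boot_diff = _hd_deciles_rows(bx, wx) - _hd_deciles_rows(by, wy)

    a_adj = alpha / DECILES.size
    ci_low = np.quantile(boot_diff, a_adj / 2, axis=0)
    ci_high = np.quantile(boot_diff, 1 - a_adj / 2, axis=0)
    significant = (ci_low > 0) | (ci_high < 0)
    return ShiftResult(deciles=DECILES.copy(), q_x=q_x, q_y=q_y, difference=diff,
                       ci_low=ci_low, ci_high=ci_high, significant=significant,
                       n_boot=n_boot, alpha=alpha, seed=seed)


@dataclass
class KSResult:
    d_statistic: float
    p_value: float
    n_x: int
    n_y: int


def ks_2samp(x, y, mode: str = "asymp") -> KSResult:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    D is the supremum over the pooled support of |ECDF_x - ECDF_y|; the
    p-value uses the asymptotic two-sided KS distribution with effective
    n = n_x n_y / (n_x + n_y) by default (``mode='exact'`` switches to the
    exact small-sample computation, sensible for n <= 25).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method=mode)
    return KSResult(d_statistic=float(res.statistic), p_value=float(res.pvalue),
                    n_x=x.size, n_y=y.size)


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired samples of length >= 3 required")
    return float(stats.pearsonr(x, y).statistic)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z test of the difference between two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); returns (z, two-sided p).
    """
    if min(n1, n2) <= 3:
        raise ValueError("both sample sizes must exceed 3")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("correlations of magnitude 1 have an infinite transform")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
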