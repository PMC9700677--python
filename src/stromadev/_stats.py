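"""Shared statistical primitives: BH correction and the negative-binomial
Wald test used for both chromatin accessibility and bulk expression."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "nb_wald_test"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _dispersion_trend(mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu over regions with usable estimates and
    evaluate it at every region's mean. Falls back to the median method-of-
    moments dispersion when the fit is degenerate."""
    ok = (mean > 0) & np.isfinite(alpha_mom) & (alpha_mom > 0)
    if ok.sum() < 10:
        fill = float(np.median(alpha_mom[ok])) if ok.any() else 0.1
        return np.full_like(mean, max(fill, 1e-8))
    x = 1.0 / mean[ok]
    y = alpha_mom[ok]
    a1, a0 = np.polyfit(x, y, 1)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mean > 0, mean, np.nan)
    trend = np.where(np.isfinite(trend), trend, np.nanmedian(y))
    return np.clip(trend, 1e-8, 50.0)


def nb_wald_test(
    norm_counts: np.ndarray,
    groups: np.ndarray,
    cond_a: str,
    cond_b: str,
    shrink_weight: float = 0.5,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-region negative-binomial Wald test of ``cond_b`` vs ``cond_a``.

    Dispersion per region is estimated by method of moments from the pooled
    within-condition variance of the (already normalized) counts and shrunk
    toward a fitted mean-dispersion trend with weight ``shrink_weight``.
    The Wald statistic is the log2 fold change of normalized group means
    (pseudocount added) over its delta-method standard error.

    Returns a DataFrame with columns ``baseMean``, ``log2FC``, ``lfcSE``,
    ``stat``, ``p``, ``padj``; ``log2FC`` > 0 means higher in ``cond_b``.
    """
    norm_counts = np.asarray(norm_counts, dtype=float)
    groups = np.asarray(groups)
    ia = np.flatnonzero(groups == cond_a)
    ib = np.flatnonzero(groups == cond_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need >= 2 replicates per condition to estimate dispersion")

    xa, xb = norm_counts[:, ia], norm_counts[:, ib]
    na, nb = len(ia), len(ib)
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    base_mean = norm_counts[:, np.concatenate([ia, ib])].mean(axis=1)

    # pooled within-condition variance (df = na + nb - 2)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mom = np.where(base_mean > 0, (s2 - base_mean) / base_mean**2, np.nan)
    alpha_mom = np.clip(alpha_mom, 0.0, 50.0)

    trend = _dispersion_trend(base_mean, alpha_mom)
    alpha = np.where(
        np.isfinite(alpha_mom),
        (1.0 - shrink_weight) * alpha_mom + shrink_weight * trend,
        trend,
    )
    alpha = np.clip(alpha, 1e-8, 50.0)

    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    ln2sq = np.log(2.0) ** 2
    var_ma = (mean_a + alpha * mean_a**2) / na
    var_mb = (mean_b + alpha * mean_b**2) / nb
    var_l2 = var_ma / ((mean_a + pseudocount) ** 2 * ln2sq) + var_mb / ((mean_b + pseudocount) ** 2 * ln2sq)
    se = np.sqrt(var_l2)

    testable = (base_mean > 0) & (se > 0)
    stat = np.full(len(base_mean), np.nan)
    p = np.ones(len(base_mean))
    stat[testable] = log2fc[testable] / se[testable]
    p[testable] = 2.0 * stats.norm.sf(np.abs(stat[testable]))

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "lfcSE": se,
            "stat": stat,
            "p": p,
            "padj": bh_adjust(p),
            "dispersion": alpha,
        }
    )
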