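"""Whole-genome bisulfite pipeline: coverage filtering, kernel-smoothed
methylation levels, group t-statistics and DMR construction.

A differentially methylated region (DMR) here is a maximal run of CpGs that
(1) holds at least ``min_cpg`` CpGs, (2) with consecutive members at most
``max_gap`` bp apart, (3) a mean smoothed methylation difference of at least
``min_diff``, and (4) every member CpG carrying a t-statistic beyond the
empirical ``q_low``/``q_high`` quantile cutoffs of the genome-wide t
distribution. Coordinates are 0-based half-open; a CpG occupies
``[pos, pos + 2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MethylomeTable

__all__ = [
    "DMR",
    "coverage_filter",
    "smooth",
    "group_tstat",
    "find_dmrs",
    "pairwise_dmr_sets",
    "annotate_promoter",
    "dmrs_to_frame",
]


@dataclass
class DMR:
    chrom: str
    start: int
    end: int  # half-open; last CpG position + 2
    n_cpg: int
    mean_diff: float
    direction: str  # "hyper" (B above A) or "hypo"
    area_stat: float  # sum of member t-statistics
    contrast: str = ""
    annotated_gene: str | None = None


def coverage_filter(table: MethylomeTable, min_cov: int = 5, min_reps: int = 2) -> MethylomeTable:
    """Keep CpGs covered by >= ``min_cov`` reads in >= ``min_reps``
    replicates of at least one condition."""
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    cov = table.coverage()
    keep = np.zeros(table.n_cpg, dtype=bool)
    for cond in sorted(set(table.groups.values())):
        cols = [table.samples.index(s) for s in table.samples_of(cond)]
        keep |= (cov[:, cols] >= min_cov).sum(axis=1) >= min_reps
    return MethylomeTable(table.df.loc[keep].reset_index(drop=True), list(table.samples), dict(table.groups))


def _tricube(u: np.ndarray) -> np.ndarray:
    w = (1.0 - np.abs(u) ** 3) ** 3
    return np.where(np.abs(u) < 1.0, w, 0.0)


def _wls_linear_at(x: np.ndarray, y: np.ndarray, w: np.ndarray, x0: float) -> float:
    """Weighted local-linear prediction at x0; degrades to a weighted mean
    when the design is degenerate."""
    sw = w.sum()
    if sw <= 0:
        return np.nan
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-12:
        return ym
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return ym + slope * (x0 - xm)


def smooth(table: MethylomeTable, bandwidth: int = 500, min_cpg_window: int = 10) -> np.ndarray:
    """BSmooth-style coverage-weighted local-linear smoothing.

    For each CpG the window half-width is the larger of ``bandwidth / 2``
    and the distance to the ``min_cpg_window``-th nearest CpG; weights are
    tricube in distance times read coverage. Returns smoothed methylation
    levels (CpGs x samples) clipped to [0, 1]; CpGs with zero coverage in a
    sample still receive the local fit of their neighbours.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    levels = table.levels()
    cov = table.coverage().astype(float)
    y_all = np.nan_to_num(levels, nan=0.0)  # zero-coverage sites carry zero weight
    out = np.full_like(levels, np.nan, dtype=float)

    for chrom, sub in table.df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy().astype(float)
        n = len(pos)
        weighted_mean_only = n < min_cpg_window
        if weighted_mean_only and n > 1:
            warnings.warn(
                f"{chrom}: only {n} CpGs (< {min_cpg_window}); falling back to a coverage-weighted mean",
                stacklevel=2,
            )
        y = y_all[idx]  # (n, samples)
        wc = cov[idx]
        for j in range(n):
            if n == 1:
                out[idx[j]] = levels[idx[j]]
                continue
            # distance to the min_cpg_window-th nearest CpG, from a local scan
            lo_k = max(0, j - min_cpg_window)
            hi_k = min(n, j + min_cpg_window + 1)
            d_loc = np.sort(np.abs(pos[lo_k:hi_k] - pos[j]))
            kth = d_loc[min(min_cpg_window, len(d_loc) - 1)]
            h = max(bandwidth / 2.0, kth)
            a = np.searchsorted(pos, pos[j] - h, side="left")
            b = np.searchsorted(pos, pos[j] + h, side="right")
            d = pos[a:b] - pos[j]
            w = _tricube(d / (h * 1.0001))[:, None] * wc[a:b]  # (win, samples)
            sw = w.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ym = (w * y[a:b]).sum(axis=0) / sw
                if weighted_mean_only:
                    fit = ym
                else:
                    xm = (w * d[:, None]).sum(axis=0) / sw
                    xc = d[:, None] - xm
                    sxx = (w * xc**2).sum(axis=0)
                    sxy = (w * xc * (y[a:b] - ym)).sum(axis=0)
                    slope = np.where(sxx > 1e-12, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
                    fit = ym + slope * (0.0 - xm)
            # sites whose whole window is uncovered keep their raw ratio
            out[idx[j]] = np.where(sw > 0, fit, levels[idx[j]])
    return np.clip(out, 0.0, 1.0)


def group_tstat(
    smoothed: np.ndarray,
    table: MethylomeTable,
    cond_a: str,
    cond_b: str,
    sd_floor_quantile: float = 0.75,
) -> np.ndarray:
    """Per-CpG t-statistic of smoothed levels, ``cond_a`` minus ``cond_b``.

    The pooled standard deviation is floored at its genome-wide
    ``sd_floor_quantile`` quantile to stabilise low-variance sites (the
    shrinkage idea of BSmooth's t-statistic)."""
    ia = [table.samples.index(s) for s in table.samples_of(cond_a)]
    ib = [table.samples.index(s) for s in table.samples_of(cond_b)]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(
            "each group needs >= 2 samples for a t-statistic; "
            "with single samples use the variance-floor-only mode (not implemented)"
        )
    xa, xb = smoothed[:, ia], smoothed[:, ib]
    na, nb = len(ia), len(ib)
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((xb - xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sd = np.sqrt(ss / (na + nb - 2))
    floor = np.nanquantile(sd, sd_floor_quantile)
    sd = np.maximum(sd, max(floor, 1e-12))
    return diff / (sd * np.sqrt(1.0 / na + 1.0 / nb))


def find_dmrs(
    tstats: np.ndarray,
    table: MethylomeTable,
    smoothed: np.ndarray,
    cond_a: str,
    cond_b: str,
    q_low: float = 0.01,
    q_high: float = 0.99,
    max_gap: int = 300,
    min_cpg: int = 3,
    min_diff: float = 0.25,
    contrast: str = "",
) -> list[DMR]:
    """Construct DMRs from per-CpG t-statistics.

    Cutoffs are the empirical ``q_low``/``q_high`` quantiles of the
    genome-wide t distribution; candidate CpGs fall below the low cutoff or
    above the high cutoff, and maximal same-sign candidate runs with
    consecutive gaps <= ``max_gap`` that hold >= ``min_cpg`` CpGs and an
    absolute mean smoothed group difference >= ``min_diff`` are reported.
    """
    tstats = np.asarray(tstats, dtype=float)
    if np.isfinite(tstats).sum() < 100:
        raise ValueError("fewer than 100 CpGs genome-wide: refusing quantile cutoff estimation")
    lo = np.nanquantile(tstats, q_low)
    hi = np.nanquantile(tstats, q_high)

    ia = [table.samples.index(s) for s in table.samples_of(cond_a)]
    ib = [table.samples.index(s) for s in table.samples_of(cond_b)]
    diff = smoothed[:, ia].mean(axis=1) - smoothed[:, ib].mean(axis=1)

    out: list[DMR] = []
    for chrom, sub in table.df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        t = tstats[idx]
        cand = (t < lo) | (t > hi)
        sign = np.sign(t)

        run: list[int] = []  # indices into idx
        def flush(run: list[int]) -> None:
            if len(run) < min_cpg:
                return
            members = idx[run]
            mean_diff = float(diff[members].mean())
            if abs(mean_diff) < min_diff:
                return
            out.append(
                DMR(
                    chrom=chrom,
                    start=int(pos[run[0]]),
                    end=int(pos[run[-1]]) + 2,
                    n_cpg=len(run),
                    mean_diff=mean_diff,
                    direction="hypo" if mean_diff < 0 else "hyper",
                    area_stat=float(t[run].sum()),
                    contrast=contrast,
                )
            )

        for j in range(len(idx)):
            if not cand[j]:
                flush(run)
                run = []
                continue
            if run and (pos[j] - pos[run[-1]] > max_gap or sign[j] != sign[run[-1]]):
                flush(run)
                run = []
            run.append(j)
        flush(run)
    return out


def pairwise_dmr_sets(
    table: MethylomeTable,
    contrasts: list[tuple[str, str]],
    bandwidth: int = 500,
    min_cpg_window: int = 10,
    **dmr_kwargs,
) -> pd.DataFrame:
    """Run the DMR pipeline per contrast and merge overlapping regions
    across contrasts into a non-overlapping union, tagging each union
    interval with the contributing contrasts."""
    if len(contrasts) < 2:
        raise ValueError("need >= 2 contrasts")
    smoothed = smooth(table, bandwidth=bandwidth, min_cpg_window=min_cpg_window)
    all_dmrs: list[DMR] = []
    for a, b in contrasts:
        t = group_tstat(smoothed, table, a, b)
        all_dmrs.extend(find_dmrs(t, table, smoothed, a, b, contrast=f"{a}_vs_{b}", **dmr_kwargs))

    rows = []
    by_chrom: dict[str, list[DMR]] = {}
    for d in all_dmrs:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom in sorted(by_chrom):
        ds = sorted(by_chrom[chrom], key=lambda d: (d.start, d.end))
        cur_start, cur_end, tags = ds[0].start, ds[0].end, {ds[0].contrast}
        for d in ds[1:]:
            if d.start < cur_end:  # >= 1 bp overlap
                cur_end = max(cur_end, d.end)
                tags.add(d.contrast)
            else:
                rows.append((chrom, cur_start, cur_end, sorted(tags)))
                cur_start, cur_end, tags = d.start, d.end, {d.contrast}
        rows.append((chrom, cur_start, cur_end, sorted(tags)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "contrasts"])


def annotate_promoter(dmrs: list[DMR], genes: pd.DataFrame, window: int = 2000) -> list[DMR]:
    """Assign each DMR whose midpoint lies within +/- ``window`` bp of a
    transcription start site to the nearest TSS's gene.

    ``genes`` needs columns ``gene``, ``chrom``, ``tss``.
    """
    by_chrom = {c: sub for c, sub in genes.groupby("chrom")}
    for d in dmrs:
        sub = by_chrom.get(d.chrom)
        d.annotated_gene = None
        if sub is None:
            continue
        mid = (d.start + d.end) // 2
        dist = np.abs(sub["tss"].to_numpy() - mid)
        j = int(np.argmin(dist))
        if dist[j] <= window:
            d.annotated_gene = str(sub["gene"].iloc[j])
    return dmrs


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in dmrs])
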