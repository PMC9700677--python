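"""ATAC-seq downstream pipeline: peak consolidation, blacklist removal,
median-of-ratios normalization, NB differential accessibility, TSS
annotation and per-gene cumulative fold change.

The pipeline starts at called peak intervals and a region x sample count
table; read alignment, peak calling and read counting are upstream of this
package.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import nb_wald_test
from .containers import CountMatrix, IntervalSet

__all__ = [
    "merge_peaks",
    "count_normalize",
    "diff_accessibility",
    "annotate_regions",
    "cumulative_fc",
]


def merge_peaks(replicate_sets: list[IntervalSet], blacklist: IntervalSet | None = None) -> IntervalSet:
    """Union-merge peaks across replicates (>= 1 bp overlap merges, half-open
    coordinates) and drop merged intervals overlapping the blacklist by
    >= 1 bp."""
    if not replicate_sets:
        raise ValueError("need at least one replicate peak set")
    frames = [r.df[["chrom", "start", "end"]] for r in replicate_sets]
    allp = pd.concat(frames, ignore_index=True).sort_values(["chrom", "start", "end"])
    rows = []
    for chrom, sub in allp.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # half-open: touching intervals do not merge
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        rows.append((chrom, int(cur_s), int(cur_e)))
    merged = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    if blacklist is not None and len(blacklist):
        keep = ~merged.overlaps_any(blacklist)
        merged = IntervalSet(merged.df.loc[keep].reset_index(drop=True))
    df = merged.df.copy()
    df["name"] = [f"region{i:05d}" for i in range(len(df))]
    return IntervalSet(df)


def count_normalize(counts: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Median-of-ratios size factors and the normalized matrix.

    The reference is the per-region geometric mean over regions positive in
    every sample; each sample's factor is the median ratio of its counts to
    the reference. Falls back to library-size factors (scaled to geometric
    mean 1) when no region is positive everywhere.
    """
    c = counts.counts.astype(float)
    if c.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    allpos = np.all(c > 0, axis=1)
    if not allpos.any():
        warnings.warn("no region positive in all samples; using library-size factors", stacklevel=2)
        lib = c.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    else:
        ref = np.exp(np.log(c[allpos]).mean(axis=1))
        sf = np.median(c[allpos] / ref[:, None], axis=0)
    return sf, c / sf[None, :]


def diff_accessibility(
    counts: CountMatrix,
    cond_a: str,
    cond_b: str,
    max_padj: float = 0.05,
    min_fc: float = 2.0,
    condition_key: str = "condition",
) -> pd.DataFrame:
    """Differential accessibility of ``cond_b`` vs ``cond_a``.

    Median-of-ratios normalization followed by a per-region NB Wald test
    with trend-shrunk method-of-moments dispersions. A region is flagged as
    a DAR iff ``padj < max_padj`` (strict) and fold change >= ``min_fc``
    (inclusive, on the unshrunk log2FC).
    """
    groups = counts.cell_meta[condition_key].to_numpy()
    for cond in (cond_a, cond_b):
        if (groups == cond).sum() < 2:
            raise ValueError(f"condition {cond!r} has < 2 replicates: dispersion cannot be estimated")
    _, norm = count_normalize(counts)
    res = nb_wald_test(norm, groups, cond_a, cond_b)
    res.insert(0, "region", counts.feature_names.to_numpy())
    res["contrast"] = f"{cond_b}_vs_{cond_a}"
    res["is_dar"] = (res["padj"] < max_padj) & (np.abs(res["log2FC"]) >= np.log2(min_fc))
    return res


def annotate_regions(
    regions: IntervalSet,
    genes: pd.DataFrame,
    promoter_window: int = 2000,
) -> pd.DataFrame:
    """Classify each region as promoter / gene_body / intergenic and assign
    the nearest gene (by TSS distance from the region midpoint).

    ``genes`` needs columns ``gene``, ``chrom``, ``tss`` and optionally
    ``start``/``end`` for the gene span (gene-body overlap); promoter means
    the midpoint lies within +/- ``promoter_window`` of a TSS.
    """
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in genes.groupby("chrom")}
    rows = []
    for r in regions:
        sub = by_chrom.get(r.chrom)
        if sub is None:
            rows.append((r.name, "intergenic", None, np.nan))
            continue
        mid = (r.start + r.end) // 2
        dist = np.abs(sub["tss"].to_numpy() - mid)
        j = int(np.argmin(dist))
        gene = str(sub["gene"].iloc[j])
        if dist[j] <= promoter_window:
            cls = "promoter"
        elif {"start", "end"} <= set(sub.columns) and bool(
            np.any((sub["start"].to_numpy() < r.end) & (sub["end"].to_numpy() > r.start))
        ):
            cls = "gene_body"
        else:
            cls = "intergenic"
        rows.append((r.name, cls, gene, int(dist[j])))
    return pd.DataFrame(rows, columns=["region", "feature_class", "gene", "tss_distance"])


def cumulative_fc(dars: pd.DataFrame, gene_map: pd.DataFrame) -> pd.Series:
    """Per-gene cumulative accessibility change: the arithmetic mean of the
    signed log2 fold changes of that gene's DARs. Genes without any DAR are
    absent from the output."""
    dar_rows = dars.loc[dars["is_dar"], ["region", "log2FC"]]
    joined = dar_rows.merge(gene_map[["region", "gene"]], on="region", how="left").dropna(subset=["gene"])
    if not len(joined):
        return pd.Series(dtype=float, name="cumulative_log2FC")
    out = joined.groupby("gene")["log2FC"].mean()
    out.name = "cumulative_log2FC"
    return out
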