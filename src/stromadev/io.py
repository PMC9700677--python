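"""Readers and writers for the pipeline's plain-text interchange formats:
10x-style MTX triplets for single-cell counts, dense TSV count tables,
per-CpG methylome TSV, BED6 intervals and DMR BED6+ exports.

Every writer/reader pair round-trips bit-exactly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix, IntervalSet, MethylomeTable

__all__ = [
    "write_sc_mtx",
    "read_sc_mtx",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_methylome_tsv",
    "read_methylome_tsv",
    "write_bed",
    "read_bed",
    "write_dmrs_bed",
]


# ---------------------------------------------------------------- sc MTX
def write_sc_mtx(m: CountMatrix, out_dir: str) -> None:
    """10x-style triplet: matrix.mtx (features x cells), features.tsv,
    barcodes.tsv, plus cell_meta.tsv / feature_meta.tsv side tables."""
    os.makedirs(out_dir, exist_ok=True)
    spio.mmwrite(os.path.join(out_dir, "matrix.mtx"), sparse.csr_matrix(m.counts))
    m.feature_names.to_series().to_csv(os.path.join(out_dir, "features.tsv"), sep="\t", header=False, index=False)
    m.cell_names.to_series().to_csv(os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=False, index=False)
    m.feature_meta.to_csv(os.path.join(out_dir, "feature_meta.tsv"), sep="\t")
    m.cell_meta.to_csv(os.path.join(out_dir, "cell_meta.tsv"), sep="\t")


def read_sc_mtx(out_dir: str) -> CountMatrix:
    counts = np.asarray(spio.mmread(os.path.join(out_dir, "matrix.mtx")).todense()).astype(np.int64)
    features = pd.read_csv(os.path.join(out_dir, "features.tsv"), sep="\t", header=None)[0]
    barcodes = pd.read_csv(os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=None)[0]
    fmeta_path = os.path.join(out_dir, "feature_meta.tsv")
    cmeta_path = os.path.join(out_dir, "cell_meta.tsv")
    fmeta = (
        pd.read_csv(fmeta_path, sep="\t", index_col=0)
        if os.path.exists(fmeta_path)
        else pd.DataFrame(index=pd.Index(features, name="gene"))
    )
    cmeta = (
        pd.read_csv(cmeta_path, sep="\t", index_col=0)
        if os.path.exists(cmeta_path)
        else pd.DataFrame(index=pd.Index(barcodes, name="cell"))
    )
    return CountMatrix(counts, fmeta, cmeta)


# ------------------------------------------------------------- dense TSV
def write_counts_tsv(m: CountMatrix, path: str) -> None:
    pd.DataFrame(m.counts, index=m.feature_names, columns=m.cell_names).to_csv(path, sep="\t")


def read_counts_tsv(path: str, feature_meta: pd.DataFrame | None = None, cell_meta: pd.DataFrame | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if feature_meta is None:
        feature_meta = pd.DataFrame(index=df.index)
    if cell_meta is None:
        cell_meta = pd.DataFrame(index=df.columns)
    return CountMatrix(df.to_numpy(), feature_meta, cell_meta)


# -------------------------------------------------------------- methylome
def write_methylome_tsv(t: MethylomeTable, path: str) -> None:
    t.df.to_csv(path, sep="\t", index=False)


def read_methylome_tsv(path: str, groups: dict[str, str]) -> MethylomeTable:
    """``groups`` maps sample name -> condition; sample names are taken
    from the ``M_<sample>`` columns."""
    df = pd.read_csv(path, sep="\t")
    samples = [c[2:] for c in df.columns if c.startswith("M_")]
    return MethylomeTable(df, samples, {s: groups[s] for s in samples})


# -------------------------------------------------------------------- BED
def write_bed(iv: IntervalSet, path: str) -> None:
    iv.df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    return IntervalSet(df)


def write_dmrs_bed(dmrs, path: str) -> None:
    """DMRs as BED6+: name = contrast, score = area statistic x 10
    (rounded), strand '.', plus n_cpg / mean_diff / direction columns."""
    rows = [
        (d.chrom, d.start, d.end, d.contrast or ".", int(round(d.area_stat * 10)), ".", d.n_cpg, d.mean_diff, d.direction)
        for d in dmrs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
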