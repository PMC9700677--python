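"""Subset signatures and cumulative Z-score (cZscore) matching.

A subset signature is the Top-N upregulated marker genes of an
endogenously identified stromal subset. The cZscore of a bulk
overexpression profile against a signature is the sum, over signature
genes that are differentially expressed in the overexpression arm, of the
per-gene standardized expression change on log(TPM + 1) relative to the
control arm; its per-cell analogue standardizes log-normalized expression
across cells. Both references are interpretation choices and are exposed
here explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import nb_wald_test
from .chromatin import count_normalize
from .containers import CountMatrix
from .sc import normalize_log

__all__ = [
    "SignatureSet",
    "bulk_de",
    "build_signatures",
    "czscore_bulk",
    "czscore_per_cell",
    "isg_overlap",
]


@dataclass
class SignatureSet:
    name: str
    genes: list[str]  # ordered, best first
    source_contrast: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")


def _tpm(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Transcripts per million from raw counts and exon lengths (bp);
    columns sum to 1e6."""
    rpk = counts / (lengths[:, None] / 1000.0)
    denom = rpk.sum(axis=0)
    return rpk / np.where(denom > 0, denom, 1.0) * 1e6


def bulk_de(
    counts: CountMatrix,
    cond_a: str = "control",
    cond_b: str = "overexpression",
    min_reads: int = 5,
    min_reps: int = 2,
    min_fc: float = 2.0,
    max_padj: float = 0.05,
    condition_key: str = "condition",
) -> pd.DataFrame:
    """Bulk differential expression of ``cond_b`` vs ``cond_a``.

    Genes are flagged ``expressed`` when they have >= ``min_reads`` reads
    in >= ``min_reps`` replicates (any arm); the NB Wald test runs on
    median-of-ratios-normalized counts. A gene is DE iff expressed,
    fold change > ``min_fc`` (strict) and ``padj < max_padj``. TPM columns
    (``tpm_<sample>``) are included when ``length`` is present in the
    feature metadata, otherwise omitted with a warning.
    """
    groups = counts.cell_meta[condition_key].to_numpy()
    for cond in (cond_a, cond_b):
        if (groups == cond).sum() < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
    expressed = (counts.counts >= min_reads).sum(axis=1) >= min_reps
    _, norm = count_normalize(counts)
    res = nb_wald_test(norm, groups, cond_a, cond_b)
    res.insert(0, "gene", counts.feature_names.to_numpy())
    res["expressed"] = expressed
    res["is_de"] = expressed & (np.abs(res["log2FC"]) > np.log2(min_fc)) & (res["padj"] < max_padj)
    if "length" in counts.feature_meta.columns:
        tpm = _tpm(counts.counts.astype(float), counts.feature_meta["length"].to_numpy(float))
        for j, s in enumerate(counts.cell_names):
            res[f"tpm_{s}"] = tpm[:, j]
    else:
        warnings.warn("no gene lengths in feature metadata; TPM omitted", stacklevel=2)
    return res


def build_signatures(degs: pd.DataFrame, n: int = 100) -> list[SignatureSet]:
    """Per-subset Top-``n`` signatures from a cluster DEG table.

    Upregulated genes only, ranked by ``padj`` then ``|log2FC|``
    (descending), ties broken by gene name. Subsets with fewer than ``n``
    DEGs yield shorter signatures with a warning. Signatures of different
    subsets may share genes.
    """
    out = []
    for cl, sub in degs.groupby("cluster"):
        up = sub.loc[sub["log2FC"] > 0].copy()
        up["absfc"] = up["log2FC"].abs()
        up = up.sort_values(["padj", "absfc", "gene"], ascending=[True, False, True], kind="mergesort")
        genes = up["gene"].head(n).tolist()
        if len(genes) < n:
            warnings.warn(f"subset {cl}: only {len(genes)} upregulated DEGs (< {n})", stacklevel=2)
        out.append(SignatureSet(name=str(cl), genes=genes, source_contrast=f"cluster_{cl}_vs_rest"))
    return out


def czscore_bulk(
    de: pd.DataFrame,
    signature: SignatureSet,
    counts: CountMatrix,
    cond_a: str = "control",
    cond_b: str = "overexpression",
    condition_key: str = "condition",
) -> tuple[float, float]:
    """Cumulative Z-score of a bulk overexpression profile against a subset
    signature, plus the percent of signature genes that are DE.

    For each signature gene that is DE, z = (mean log(TPM+1) in the
    overexpression arm - control mean) / control sd; cZscore is the sum of
    those z (non-DE signature genes contribute 0). Genes with zero control
    sd are skipped with a warning.
    """
    groups = counts.cell_meta[condition_key].to_numpy()
    tpm_cols = [f"tpm_{s}" for s in counts.cell_names]
    if not all(c in de.columns for c in tpm_cols):
        raise ValueError("TPM columns required for the bulk cZscore (run bulk_de with gene lengths)")
    logtpm = np.log1p(de[tpm_cols].to_numpy())
    ia = np.flatnonzero(groups == cond_a)
    ib = np.flatnonzero(groups == cond_b)
    mu_a = logtpm[:, ia].mean(axis=1)
    sd_a = logtpm[:, ia].std(axis=1, ddof=1)
    mu_b = logtpm[:, ib].mean(axis=1)

    de_idx = de.set_index("gene")
    cz, n_de, skipped = 0.0, 0, 0
    for g in signature.genes:
        if g not in de_idx.index or not bool(de_idx.at[g, "is_de"]):
            continue
        i = de.index[de["gene"] == g][0]
        n_de += 1
        if sd_a[i] == 0:
            skipped += 1
            continue
        cz += (mu_b[i] - mu_a[i]) / sd_a[i]
    if skipped:
        warnings.warn(f"{skipped} DE signature genes skipped (zero control sd)", stacklevel=2)
    pct_overlap = 100.0 * n_de / len(signature.genes) if signature.genes else 0.0
    return float(cz), float(pct_overlap)


def czscore_per_cell(m: CountMatrix, gene_set: list[str], scale: float = 10_000.0) -> np.ndarray:
    """Per-cell cumulative Z-score of a gene set: each gene's log-normalized
    expression is z-scored across cells and summed over the set. Constant
    genes contribute 0; at least one set gene must be present."""
    present = [g for g in gene_set if g in m.feature_names]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    x = normalize_log(m, scale)[m.feature_names.get_indexer(present)]
    sd = x.std(axis=1)
    mu = x.mean(axis=1)
    ok = sd > 0
    z = np.zeros_like(x)
    z[ok] = (x[ok] - mu[ok, None]) / sd[ok, None]
    return z.sum(axis=0)


def isg_overlap(
    isg_table: pd.DataFrame,
    fc_min: float = 2.0,
    max_p: float = 0.05,
    tmax: float = 6.0,
) -> list[str]:
    """Filter an interferon-stimulated-gene table (columns ``gene``, ``fc``,
    ``p``, ``time`` in hours) to genes induced within ``tmax`` hours with
    fold change > ``fc_min`` and p < ``max_p``; the resulting set feeds
    :func:`czscore_per_cell` / :func:`czscore_bulk`."""
    sel = (isg_table["time"] <= tmax) & (isg_table["fc"] > fc_min) & (isg_table["p"] < max_p)
    genes = isg_table.loc[sel, "gene"].drop_duplicates().tolist()
    if not genes:
        raise ValueError("ISG filter produced an empty gene set")
    return genes
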