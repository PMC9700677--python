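"""Single-cell core: QC, normalization, HVG selection, cell-cycle scoring,
covariate regression, SNN-Louvain clustering, marker-gene gating,
per-cluster differential expression and subset-composition summaries.

Named QC/clustering presets encode the three study designs this pipeline
was built around (postnatal ontogeny, germ-free vs SPF, Irf3 knockout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._stats import bh_adjust
from .containers import CountMatrix

__all__ = [
    "PRESETS",
    "ClusterResult",
    "CellCycleScores",
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "score_cell_cycle",
    "regress_covariates",
    "cluster",
    "gate_non_endothelial",
    "cluster_degs",
    "composition_heatmap",
]

# QC thresholds (min genes, max genes, max % mitochondrial reads) and
# clustering settings of the three study designs
PRESETS = {
    "ontogeny": dict(min_genes=1000, max_genes=4600, max_pct_mito=4.5, dims=12, resolution=1.1),
    "gfspf": dict(min_genes=750, max_genes=4000, max_pct_mito=7.0, dims=17, resolution=0.4),
    "irf3": dict(min_genes=750, max_genes=4500, max_pct_mito=6.0, dims=30, resolution=0.4),
}


@dataclass
class ClusterResult:
    labels: np.ndarray  # contiguous ids from 0, one per cell
    embedding: np.ndarray  # cells x 2, for plots only
    pc_scores: np.ndarray  # cells x dims
    resolution: float
    dims_used: int


@dataclass
class CellCycleScores:
    s_score: np.ndarray
    g2m_score: np.ndarray


def qc_filter(
    m: CountMatrix,
    min_genes: int,
    max_genes: float,
    max_pct_mito: float,
    mito_prefix: str = "mt-",
) -> CountMatrix:
    """Keep cells with ``min_genes <= detected genes <= max_genes`` and
    percent mitochondrial reads ``<= max_pct_mito`` (all bounds inclusive).
    Detected means raw count > 0. Features are untouched; an empty result is
    returned as an empty matrix, not an error."""
    if min_genes >= max_genes:
        raise ValueError("min_genes must be < max_genes")
    ng = m.n_genes_detected()
    pct = m.pct_of_prefix(mito_prefix)
    keep = (ng >= min_genes) & (ng <= max_genes) & (pct <= max_pct_mito)
    return m.subset_cells(keep)


def normalize_log(m: CountMatrix, scale: float = 10_000.0) -> np.ndarray:
    """log1p of per-cell counts scaled to ``scale`` total (genes x cells).
    Cells with zero total come out as all-zero with a warning."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    total = m.counts.sum(axis=0).astype(float)
    if np.any(total == 0) and m.n_cells > 0:
        warnings.warn("cells with zero total counts normalized to all-zero", stacklevel=2)
    denom = np.where(total > 0, total, 1.0)
    return np.log1p(m.counts / denom[None, :] * scale)


def select_hvg(m: CountMatrix, n: int, scale: float = 10_000.0) -> list[str]:
    """Top-``n`` highly variable genes by variance of log-normalized
    expression detrended on mean expression (lowess fit of variance on
    mean); ties broken deterministically by gene name."""
    if n > m.n_features:
        raise ValueError("n exceeds the number of features")
    x = normalize_log(m, scale)
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    if np.ptp(mean) > 0:
        fit = lowess(var, mean, frac=0.3, return_sorted=False)
        resid = var - fit
    else:
        resid = var.copy()
    resid[var == 0] = -np.inf  # genes with no variability are never variable
    order = pd.DataFrame({"resid": resid, "gene": m.feature_names}).sort_values(
        ["resid", "gene"], ascending=[False, True], kind="mergesort"
    )
    return order["gene"].head(n).tolist()


def score_cell_cycle(
    m: CountMatrix,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 25,
    seed: int = 0,
    ctrl_per_gene: int = 50,
    scale: float = 10_000.0,
) -> CellCycleScores:
    """Per-cell S-phase and G2/M scores: mean log-normalized expression of
    the gene set minus the mean of control genes drawn from matching
    mean-expression bins (the standard module-score construction)."""
    x = normalize_log(m, scale)
    names = m.feature_names
    mean = x.mean(axis=1)
    ranks = pd.Series(mean, index=names).rank(method="first")
    bins = pd.cut(ranks, bins=n_bins, labels=False)
    rng = np.random.default_rng(seed)

    def one_score(genes: list[str], label: str) -> np.ndarray:
        present = [g for g in genes if g in names]
        missing = [g for g in genes if g not in names]
        if not present:
            raise ValueError(f"no {label} genes found in the matrix; missing: {missing}")
        gi = names.get_indexer(present)
        ctrl_idx: list[int] = []
        for g in gi:
            pool = np.flatnonzero((bins == bins.iloc[g]).to_numpy())
            pool = pool[~np.isin(pool, gi)]
            if len(pool) == 0:
                pool = np.flatnonzero(~np.isin(np.arange(len(names)), gi))
            ctrl_idx.extend(rng.choice(pool, size=min(ctrl_per_gene, len(pool)), replace=False))
        return x[gi].mean(axis=0) - x[sorted(set(ctrl_idx))].mean(axis=0)

    return CellCycleScores(s_score=one_score(s_genes, "S"), g2m_score=one_score(g2m_genes, "G2M"))


def regress_covariates(x: np.ndarray, covs: pd.DataFrame) -> np.ndarray:
    """Residuals of per-gene OLS of expression (genes x cells) on the given
    per-cell covariates (with intercept). Collinear covariate columns are
    dropped with a warning."""
    c = covs.to_numpy(dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("covariates must be finite")
    design = np.column_stack([np.ones(len(c)), c])
    colnames = ["intercept", *covs.columns]
    # greedily drop columns that do not increase rank
    keep = [0]
    for j in range(1, design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate {colnames[j]!r}", stacklevel=2)
    X = design[:, keep]
    beta, *_ = np.linalg.lstsq(X, x.T, rcond=None)
    return x - (X @ beta).T


def _snn_graph(pc: np.ndarray, k_nn: int) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = pc.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k_nn, n)).fit(pc)
    _, idx = nn.kneighbors(pc)
    neigh = [set(row) for row in idx]  # includes self, as in the standard SNN build
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[j])
            jac = inter / (2 * len(neigh[i]) - inter)
            if jac > 1.0 / 15.0:  # prune weak links, the conventional SNN cutoff
                edges.append((i, j))
                weights.append(jac)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster(
    x: np.ndarray,
    dims: int = 12,
    resolution: float = 1.1,
    k_nn: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """PCA to ``dims`` -> SNN graph (Jaccard weights) -> Louvain community
    detection at the given resolution. ``x`` is genes x cells; the 2-D
    embedding returned is the first two PCs (plots only). Cluster ids are
    contiguous from 0, ordered by decreasing size."""
    n_cells = x.shape[1]
    if dims > min(x.shape):
        raise ValueError("dims must be <= min(n_genes, n_cells)")
    if n_cells < k_nn:
        warnings.warn(f"n_cells < k_nn; reducing k_nn to {n_cells}", stacklevel=2)
        k_nn = n_cells
    pc = PCA(n_components=dims, svd_solver="full").fit_transform(x.T)
    g = _snn_graph(pc, k_nn)
    import random as _random

    ig.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    # relabel by decreasing size, contiguous from 0
    order = pd.Series(labels).value_counts().index.to_list()
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in labels])
    return ClusterResult(
        labels=labels,
        embedding=pc[:, :2].copy(),
        pc_scores=pc,
        resolution=resolution,
        dims_used=dims,
    )


def gate_non_endothelial(
    m: CountMatrix,
    labels: np.ndarray,
    gate_gene: str = "Pecam1",
    max_expr: float = 1.0,
    scale: float = 10_000.0,
) -> CountMatrix:
    """Drop clusters whose mean normalized expression of ``gate_gene`` is
    >= ``max_expr`` (clusters strictly below the gate are retained, matching
    the endothelial-exclusion rule Pecam1 < 1)."""
    if gate_gene not in m.feature_names:
        raise ValueError(f"gate gene {gate_gene!r} absent from the matrix")
    x = normalize_log(m, scale)
    expr = x[m.feature_names.get_loc(gate_gene)]
    keep_cells = np.zeros(m.n_cells, dtype=bool)
    for lab in np.unique(labels):
        in_c = labels == lab
        if expr[in_c].mean() < max_expr:
            keep_cells |= in_c
    return m.subset_cells(keep_cells)


def cluster_degs(
    m: CountMatrix,
    labels: np.ndarray,
    min_log2fc: float = 0.2,
    max_padj: float = 0.05,
    scale: float = 10_000.0,
) -> pd.DataFrame:
    """Per-cluster one-vs-rest differential expression.

    Two-sided Wilcoxon rank-sum per gene on normalized expression, BH
    correction per cluster; reported genes satisfy ``|log2FC| >=
    min_log2fc`` and ``padj <= max_padj``, with
    ``log2FC = log2((mean expm1 in + 1) / (mean expm1 out + 1))``.
    """
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    x = normalize_log(m, scale)
    ex = np.expm1(x)
    frames = []
    for lab in uniq:
        in_c = labels == lab
        if in_c.sum() < 2:
            warnings.warn(f"cluster {lab}: singleton, skipped", stacklevel=2)
            continue
        res = stats.mannwhitneyu(x[:, in_c], x[:, ~in_c], axis=1, alternative="two-sided", method="auto")
        lfc = np.log2(ex[:, in_c].mean(axis=1) + 1.0) - np.log2(ex[:, ~in_c].mean(axis=1) + 1.0)
        padj = bh_adjust(res.pvalue)
        sel = (np.abs(lfc) >= min_log2fc) & (padj <= max_padj)
        frames.append(
            pd.DataFrame(
                {
                    "gene": m.feature_names[sel],
                    "cluster": lab,
                    "log2FC": lfc[sel],
                    "p": res.pvalue[sel],
                    "padj": padj[sel],
                    "direction": np.where(lfc[sel] > 0, "up", "down"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["gene", "cluster", "log2FC", "p", "padj", "direction"])
    return pd.concat(frames, ignore_index=True)


def composition_heatmap(labels: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Subset x group percentage matrix, corrected for unequal group sizes.

    Step 1: within each group, the fraction of its cells in each subset.
    Step 2: within each subset, fractions are renormalized across groups to
    sum to 100. Empty groups yield a NaN column with a warning."""
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    subsets = np.unique(labels)
    group_ids = np.unique(groups)
    frac = pd.DataFrame(index=subsets, columns=group_ids, dtype=float)
    for g in group_ids:
        in_g = groups == g
        if in_g.sum() == 0:
            warnings.warn(f"group {g!r} is empty", stacklevel=2)
            frac[g] = np.nan
            continue
        for s in subsets:
            frac.loc[s, g] = np.mean(labels[in_g] == s)
    row_tot = frac.sum(axis=1)
    return frac.div(row_tot, axis=0) * 100.0
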