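"""Joint interpretation of differential expression and chromatin
accessibility: the three-class regulatory scheme, Fisher set enrichment,
motif enrichment per regulatory class, and TF nomination at trajectory
branch points.

The regulatory classes, per gene and relative to a two-condition contrast:

* ``correlated`` — differential expression and promoter accessibility move
  together (same sign);
* ``inducible`` — differentially accessible but not differentially
  expressed (poised loci that can respond to activation);
* ``active_tf_regulated`` — differentially expressed with no associated
  differential accessibility, implying regulation through already-open
  chromatin by active transcription factors;
* ``unregulated`` — neither signal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "classify_genes",
    "fisher_set_enrichment",
    "motif_enrichment_by_class",
    "nominate_tfs",
]

CLASSES = ("correlated", "inducible", "active_tf_regulated")


def classify_genes(
    degs: pd.DataFrame,
    dars: pd.DataFrame,
    gene_map: pd.DataFrame,
    universe: list[str],
    promoter_only: bool = True,
    side_labels: tuple[str, str] = ("up", "down"),
) -> pd.DataFrame:
    """Classify every gene of ``universe`` into one regulatory class.

    ``degs`` needs columns ``gene``/``log2FC`` (already thresholded
    upstream); ``dars`` the DAR table with ``region``/``log2FC``/``is_dar``;
    ``gene_map`` the region annotation with ``region``/``gene`` and
    ``feature_class``. With ``promoter_only`` only promoter-annotated DARs
    count. The ``side`` column says which condition is up (first label =
    expression or accessibility up).

    ``correlated`` requires sign agreement between the expression log2FC
    and the cumulative accessibility log2FC of the gene's DARs.
    """
    from .chromatin import cumulative_fc

    cmap = gene_map
    if promoter_only:
        cmap = gene_map.loc[gene_map["feature_class"] == "promoter"]
    cum = cumulative_fc(dars, cmap)

    expr = degs.drop_duplicates(subset="gene").set_index("gene")["log2FC"]
    rows = []
    for g in universe:
        e = expr.get(g)
        a = cum.get(g)
        if e is not None and a is not None:
            cls = "correlated" if np.sign(e) == np.sign(a) else "active_tf_regulated"
            side_fc = e
        elif a is not None:
            cls, side_fc = "inducible", a
        elif e is not None:
            cls, side_fc = "active_tf_regulated", e
        else:
            cls, side_fc = "unregulated", np.nan
        side = side_labels[0] if side_fc > 0 else side_labels[1] if side_fc < 0 else None
        rows.append((g, cls, e if e is not None else np.nan, a if a is not None else np.nan, side))
    return pd.DataFrame(rows, columns=["gene", "reg_class", "log2FC_expr", "cum_log2FC_access", "side"])


def fisher_set_enrichment(
    foreground: set,
    background: set,
    annotations: dict[str, set],
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each annotation set in the
    foreground versus the background universe, BH-corrected across sets.

    The 2x2 table per set: a = foreground & set, b = foreground without the
    set, c = background-only & set, d = the rest of the universe.
    Annotation sets disjoint from the universe are skipped with a warning.
    """
    foreground, background = set(foreground), set(background)
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background universe")
    rest = background - foreground
    rows = []
    for name, genes in annotations.items():
        genes = set(genes) & background
        if not genes:
            warnings.warn(f"annotation {name!r} disjoint from the universe; skipped", stacklevel=2)
            continue
        a = len(foreground & genes)
        b = len(foreground) - a
        c = len(rest & genes)
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, b, c, d, odds, p))
    out = pd.DataFrame(rows, columns=["set", "a", "b", "c", "d", "odds_ratio", "p"])
    out["padj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def motif_enrichment_by_class(
    classes: pd.DataFrame,
    motif_hits: pd.DataFrame,
    min_recurrent: int = 5,
    max_padj: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Motif enrichment within each regulatory class-by-side gene set.

    Splits the classified genes into the six loci sets (3 classes x 2
    sides) and runs Fisher enrichment of every motif's target genes against
    the full accessible universe (all classified genes). Returns the long
    enrichment table and a per-motif summary with ``n_enriched`` (sets with
    padj < ``max_padj``) and the ``recurrent`` flag (enriched in at least
    ``min_recurrent`` of the six sets).
    """
    universe = set(classes["gene"]) & set(motif_hits.columns)
    annotations = {m: set(motif_hits.columns[motif_hits.loc[m] > 0]) for m in motif_hits.index}
    frames = []
    sides = [s for s in classes["side"].dropna().unique()]
    for cls in CLASSES:
        for side in sides:
            fg = set(classes.loc[(classes["reg_class"] == cls) & (classes["side"] == side), "gene"]) & universe
            if not fg:
                continue
            res = fisher_set_enrichment(fg, universe, annotations)
            res.insert(0, "loci_set", f"{cls}:{side}")
            frames.append(res)
    enr = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(enr):
        summary = (
            enr.assign(hit=enr["padj"] < max_padj)
            .groupby("set")["hit"]
            .sum()
            .rename("n_enriched")
            .reset_index()
            .rename(columns={"set": "motif"})
        )
        summary["recurrent"] = summary["n_enriched"] >= min_recurrent
    else:
        summary = pd.DataFrame(columns=["motif", "n_enriched", "recurrent"])
    return enr, summary


def nominate_tfs(
    motif_to_tf: dict[str, list[str]],
    enriched_motifs: list[str],
    branch_degs_a: pd.DataFrame,
    branch_degs_b: pd.DataFrame,
    dmr_tfs: set | None = None,
) -> dict:
    """Nominate TFs by intersecting accessibility-derived candidates with
    trajectory branch-point differential expression.

    ``motif_to_tf`` maps enriched motifs to their putative TFs (many-to-
    many); ``branch_degs_a``/``branch_degs_b`` are the branch-point DEG
    tables of the two trajectories (e.g. CD34 and FRC). Returns the
    fraction of accessibility-derived TFs differentially expressed along
    each trajectory, the Venn partition (unique to each branch point,
    shared), and optionally the union with DMR-proximal TFs.
    """
    if not motif_to_tf:
        raise ValueError("empty motif -> TF map")
    access_tfs = sorted({tf for m in enriched_motifs for tf in motif_to_tf.get(m, [])})
    deg_a = set(branch_degs_a["gene"]) if len(branch_degs_a) else set()
    deg_b = set(branch_degs_b["gene"]) if len(branch_degs_b) else set()
    in_a = {tf for tf in access_tfs if tf in deg_a}
    in_b = {tf for tf in access_tfs if tf in deg_b}
    n = len(access_tfs)
    report = {
        "accessibility_tfs": access_tfs,
        "frac_dynamic_a": len(in_a) / n if n else 0.0,
        "frac_dynamic_b": len(in_b) / n if n else 0.0,
        "venn": {
            "unique_a": sorted(in_a - in_b),
            "unique_b": sorted(in_b - in_a),
            "shared": sorted(in_a & in_b),
        },
    }
    if dmr_tfs is not None:
        report["with_dmr_tfs"] = sorted(set(access_tfs) | set(dmr_tfs))
    return report
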