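# Methods

`stromadev` re-implements, as a tested library, an integrative analysis of
lymph-node non-endothelial stromal cells: single-cell subset and trajectory
analysis, DNA-methylation DMR calling, ATAC differential accessibility, a
joint DAR × DEG regulatory classification with motif-based TF nomination,
dynamical gene-regulatory-network inference, and cumulative-Z-score matching
of TF-overexpression profiles to stromal subsets. Every step runs end-to-end
on seeded synthetic data with planted ground truth.

## Single-cell core (`sc`)

Cells are filtered on detected genes ("detected" = raw count > 0, the
standard convention) and percent mitochondrial reads, with all bounds
inclusive. Three named presets encode the thresholds of the three study
designs: `ontogeny` (1000–4600 genes, ≤ 4.5 % mito, 12 PCs, resolution 1.1),
`gfspf` (750–4000, 7 %, 17 PCs, 0.4) and `irf3` (750–4500, 6 %, 30 PCs,
0.4). Normalization is counts-per-`scale` (default 10 000 — the toolchain's
default scale is assumed, as it is rarely reported) followed by `log1p`.
Highly variable genes are ranked by the residual of a lowess fit of
per-gene variance on mean (zero-variance genes are excluded outright); ties
break deterministically by gene name. Cell-cycle scores are module scores:
mean expression of the program genes minus the mean of control genes drawn
from matched mean-expression bins (25 bins, 50 controls per gene, seeded).
Covariates (UMIs, percent mito/ribo, S and G2M scores, as configured) are
removed by per-gene OLS; collinear columns are dropped with a warning.

Clustering is PCA → shared-nearest-neighbour graph (k = 20, Jaccard edge
weights, edges below 1/15 pruned — the conventional SNN cutoff) → Louvain at
the requested resolution, with the igraph RNG seeded, and labels relabelled
by decreasing cluster size. Per-cluster markers use a two-sided Wilcoxon
rank-sum per gene against all other cells, BH correction per cluster
(the global-vs-per-cluster choice is not standardised; per-cluster treats
each subset contrast as its own family), thresholds |log2FC| ≥ 0.2 and
padj ≤ 0.05, with `log2FC = log2((mean expm1 in + 1)/(mean expm1 out + 1))`.
Endothelial exclusion drops clusters whose mean normalized *Pecam1* is ≥ 1
(strictly-below survives). Composition heatmaps first take within-group
subset fractions (correcting unequal group sizes), then renormalize each
subset across groups to 100 %.

## Trajectory (`trajectory`)

The principal tree is deliberately simple: PCA, k-means centroids (default
12 nodes — enough to resolve a bifurcation without fragmenting it), a
minimum spanning tree over centroids, and projection of every cell onto its
nearest tree edge. Terminal edges extrapolate beyond the leaf so cells past
the last centroid keep distinct orderings. Pseudotime is geodesic distance
from the root, shifted and scaled to [0, 1]. The root is the node whose
projected cells carry the highest fraction of the earliest timepoint
(ties: highest mean proliferation score, then smallest id) — a codification
of the observation that the proliferating progenitor pool forms the
trajectory's starting point. Branch segments are maximal unbranched paths;
the *two-fate split* takes the branch node maximizing the size of the
smaller of its two largest downstream subtrees (robust to small spurs) and
forces every cell to the nearer fate polyline, which is how a binary fate
split is consumed downstream. Marker-based splitting assigns each fate to
whichever of the two markers (*Vcam1* vs *Cd34* by default) is higher on
average in its cells. Branch-point differential expression reuses the
Wilcoxon machinery.

This construction reproduces what the downstream claims need — bifurcation
topology, ordering, branch DEGs — but is not a latent-graph optimizer: it
will not recover trees whose geometry is invisible to PCA + k-means, and
pseudotime units are arbitrary.

## Methylome (`methylome`)

CpGs must reach ≥ 5 reads in ≥ 2 replicates of at least one condition.
Smoothing is BSmooth-style: per sample, a coverage-weighted local-linear
fit with tricube distance weights over a window whose half-width is the
larger of half the bandwidth (default 500 bp) and the distance to the 10th
nearest CpG; chromosomes with fewer CpGs than that fall back to a weighted
mean. These smoothing defaults suit the synthetic genome (CpG every
~200 bp) and are exposed in the API. The per-CpG t-statistic uses the
pooled standard deviation floored at its genome-wide 75th percentile — the
same variance-stabilisation idea as the original smoothing method. DMRs are
maximal same-sign runs of CpGs whose t lies beyond the empirical 1 %/99 %
quantile cutoffs, with inter-CpG gaps ≤ 300 bp, ≥ 3 CpGs, and
|mean smoothed difference| ≥ 0.25; the quantile reference is all filtered
CpGs of the contrast. Coordinates are 0-based half-open with a CpG spanning
`[pos, pos+2)`. Pairwise contrasts are merged into a non-overlapping union
tagged with contributing contrasts; promoter annotation assigns the nearest
TSS within ± 2 kb of the DMR midpoint.

## Chromatin (`chromatin`)

Replicate peak lists are union-merged (≥ 1 bp overlap merges; half-open
touching intervals do not) and any merged region overlapping the blacklist
by ≥ 1 bp is dropped. Normalization is median-of-ratios against the
geometric-mean pseudo-reference over regions positive in all samples, with
library-size factors as fallback. The differential test is an NB Wald test:
per-region method-of-moments dispersion from the pooled within-condition
variance, shrunk half-way toward a fitted `a0 + a1/mu` mean-dispersion
trend, and a delta-method standard error on the log2 fold change of
normalized group means (pseudocount 0.5). A region is a DAR iff padj < 0.05
(strict) and fold change ≥ 2 (inclusive, on the unshrunk estimate). This is
simpler than the Cox-Reid/MAP machinery of full NB frameworks; on planted
data its effect estimates match DESeq2's essentially exactly (r > 0.99,
checked in the test suite) while its calls are mildly more conservative.
Region annotation classifies promoter (± 2 kb of a TSS), gene body, or
intergenic, and the per-gene cumulative accessibility change is the
arithmetic mean of the signed log2FC over that gene's DARs.

## Integration (`integrate`)

Genes are partitioned into regulatory classes against a contrast:
*correlated* (differential expression and promoter accessibility with the
same sign — the quadrant structure implies but does not state the sign
requirement; we enforce it), *inducible* (accessible-but-not-expressed),
*active-TF-regulated* (expressed with no associated DAR), else
*unregulated*. "Differential" means the upstream thresholds already
applied. Set enrichment is a one-sided Fisher exact test with BH across
sets (verified against an exact hypergeometric tail-sum oracle to 1e-12).
Motif enrichment runs per class × side (six loci sets) against the full
accessible universe; a motif is *recurrent* when enriched (padj < 0.05) in
at least five of the six sets. TF nomination intersects
accessibility-derived TFs (via a user-supplied motif → TF map; families are
the caller's responsibility to collapse) with branch-point DEGs of the two
trajectories, reporting per-trajectory dynamic fractions and the Venn
partition. De novo motif discovery is out of scope; supplied hit tables
replace it.

## Signatures (`signatures`)

Bulk DE filters to genes with ≥ 5 reads in ≥ 2 replicates, computes TPM
from exon lengths, and reuses the NB Wald engine; DE requires fold change
> 2 (strict) and padj < 0.05. Subset signatures are the Top-100
upregulated cluster markers ranked by padj then |log2FC| (name tie-break).
The bulk cZscore sums, over signature genes that are DE in the
overexpression arm, `z = (mean log(TPM+1)_oe − mean_ctrl)/sd_ctrl`; non-DE
signature genes contribute 0. The per-cell cZscore z-scores each gene's
log-normalized expression across all cells and sums over the set. Both
z-references are interpretation choices (the construction is defined
without one) and are implemented exactly as stated here. ISG-overlap
scoring filters an interferon-stimulated-gene table (time ≤ 6 h,
fold change > 2, p < 0.05 by default) and feeds the result to either scorer.

## GRN (`grn`)

Cells of a branch are ordered by (pseudo)time and averaged into 20
equal-occupancy bins. For each target the decay-corrected response
`y_t = (x(t+1) − x(t))/Δt + α·x(t)` (single global α, default 0.02 per bin
— per-gene decay estimation is not attempted) is regressed on candidate-TF
expression at the preceding bin with a random forest (100 trees,
mtry = √|TF|, seeded); importances, scaled by the response spread so
weights compare across targets, become link weights, self-links are
dropped, and the global Top-500 links are kept. Degree and betweenness are
computed on the directed unweighted link graph. The candidate-TF list can
be the union of accessibility-derived and DMR-proximal TFs.

## Synthetic data (`simulate`)

All generators are pure functions of their arguments including the seed,
live on one 10-Mb synthetic chromosome `chrS`, and return a `SimTruth`
record of what was planted. Negative-binomial dispersion is 0.2 for
bulk/ATAC and 0.5 for scRNA (typical over-dispersion regimes); the
mitochondrial prefix is `mt-` (mouse nomenclature).

* **scRNA** — a proliferating Cdk1+ progenitor pool (the root) bifurcating
  into an FRC-like and a CD34-like branch. Genes partition into
  housekeeping, per-subset markers, branch markers (*Vcam1*/*Cd34*), a
  cell-cycle program elevated in progenitors, and trajectory-dynamic genes
  monotone in true time (shared and branch-specific); `branch_sep` is the
  log2 effect of markers and dynamics. Subsets within a branch occupy
  successive time windows, matching the observed segregation of subsets
  along development. Library sizes are log-normal.
* **Bifurcation geometry** — the trajectory engine's quantitative testbed:
  a Y in 10 dimensions (stem then two arms, path 8 units long) with
  isotropic Gaussian noise (sd 0.5 by default). Arm separation ramps to
  `branch_sep` within the first quarter of arm progression and stays there,
  reflecting rapid fate commitment after a branch point; `branch_sep` = 0
  makes arms indistinguishable by construction.
* **Methylome** — beta-distributed baseline methylation shared by both
  conditions, binomial reads at Poisson coverage; planted regions hold 4–8
  CpGs spaced 20–80 bp, flanked by ≥ 1 kb without CpGs so regions cannot
  merge, with condition B shifted ± delta (alternating sign, clamped with
  a warning).
* **ATAC** — log-normal per-peak baselines around `mean_count` (default
  100), per-sample size factors, planted peaks scaled by `fc` in condition
  B; per-replicate peak lists add dropout and ≤ 50 bp boundary jitter.
* **Motif hits** — Bernoulli hit tables (base rate 0.1) with the hit odds
  multiplied inside planted (motif, gene-set) pairs.
* **Overexpression bulk** — control vs overexpression arms with signature
  genes up-shifted by `strength` log2 units, plus gene lengths for TPM.

What the generators do **not** emulate: doublets, ambient RNA, batch
effects beyond library size, bisulfite conversion error, non-CpG contexts,
fragment-level ATAC structure, or read-level data of any kind. Passing
recovery tests therefore demonstrates the engines' correctness and
calibration under idealized noise, not robustness to those artefacts.

## Problem sizes and benchmark conditions

The recovery benchmarks (shared by `scripts/acceptance.py` and the
acceptance tests) use: 50 000 CpGs with 50 planted DMRs at delta 0.4 and
coverage 30 (3+3 replicates), with the null check over 25 seeded delta-0
runs at the same size; 5 000 ATAC regions with 250 planted 4-fold DARs at
mean 100 (3+3), nulls over 50 seeded runs; 2 000-cell bifurcations and
count datasets; 10-seed GRN replicates; 100 arm permutations for the
cZscore null. These sizes make every benchmark run in seconds to about a
minute on one core while leaving Monte-Carlo error well below the decision
margins.

## Known limitations

* The NB Wald test's power at dispersion 0.2 with three replicates per
  condition tops out near 75 % for 4-fold effects — an information limit of
  the design (the log2FC standard error is ~0.53 even with dispersion known
  exactly), shared by reference NB frameworks, not an implementation gap.
* The principal tree assumes the trajectory is visible in a few principal
  components; it does not learn a latent graph.
* Quantile-based DMR candidate cutoffs always nominate ~2 % of CpGs; the
  mean-difference and run-length criteria do the null filtering, so very
  small genomes (< 100 CpGs) are refused rather than mis-calibrated.
* Fisher enrichment treats genes as exchangeable; no GO-DAG propagation or
  gene-length bias correction is attempted.
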