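"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments (including ``seed``) and
returns, alongside the dataset, a :class:`SimTruth` record of what was
planted, so downstream recovery can be scored.

The simulated study mirrors the biology the pipeline targets: a lymph-node
stromal compartment whose proliferating Cdk1+ progenitors bifurcate into an
FRC branch and a CD34+ branch; two-condition methylomes and chromatin
accessibility with planted differential regions; promoter motif tables with
planted enrichments; and bulk TF-overexpression profiles contaminated with a
chosen subset signature.

All genomic coordinates live on a single synthetic chromosome ``chrS``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountMatrix, IntervalSet, MethylomeTable

__all__ = [
    "SimTruth",
    "make_sc_dataset",
    "make_methylome",
    "make_atac",
    "make_replicate_peak_sets",
    "make_blacklist",
    "make_motif_hits",
    "make_overexpression_bulk",
]

CHROM = "chrS"

# negative-binomial over-dispersion regimes: alpha such that
# var = mu + alpha * mu^2
NB_DISPERSION_SC = 0.5
NB_DISPERSION_BULK = 0.2


@dataclass
class SimTruth:
    """Ground truth planted by the generators."""

    dmr_intervals: list = field(default_factory=list)  # (chrom, start, end, signed delta)
    dar_ids: dict = field(default_factory=dict)  # peak id -> true fold change (> 0)
    branch_of_cell: dict = field(default_factory=dict)  # cell -> root | branchA | branchB
    true_time: dict = field(default_factory=dict)  # cell -> t in [0, 1]
    signature_genes: dict = field(default_factory=dict)  # subset -> gene list
    regulator_links: list = field(default_factory=list)  # (TF, target)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["dmr_intervals"] = [tuple(x) for x in d["dmr_intervals"]]
        d["regulator_links"] = [tuple(x) for x in d["regulator_links"]]
        return cls(**d)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=np.maximum(mean, 1e-12) * dispersion)
    return rng.poisson(lam)


# ----------------------------------------------------------------------
# single-cell dataset with a planted bifurcating trajectory
# ----------------------------------------------------------------------

def make_sc_dataset(
    n_cells: int = 2000,
    n_genes: int = 1000,
    subset_props: tuple = (0.2, 0.2, 0.2, 0.2, 0.2),
    branch_sep: float = 2.0,
    seed: int = 0,
    mito_prefix: str = "mt-",
) -> tuple[CountMatrix, SimTruth]:
    """Simulate clustered scRNA counts with a bifurcating trajectory.

    The first subset is the proliferating Cdk1+ progenitor pool (the root of
    the trajectory); remaining subsets alternate between the FRC-like branch
    (A) and the CD34-like branch (B). ``branch_sep`` is the log2 fold change
    of subset markers, branch markers (Vcam1 / Cd34) and trajectory-dynamic
    genes; 0 makes branch identity unrecoverable.
    """
    if n_cells < 100 or n_genes < 200:
        raise ValueError("need n_cells >= 100 and n_genes >= 200")
    props = np.asarray(subset_props, dtype=float)
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("subset proportions must sum to 1 within 1e-8")
    rng = np.random.default_rng(seed)

    # --- subsets and branches -----------------------------------------
    n_sub = len(props)
    subset_names = ["Cdk1+"]
    branch_of_subset = {"Cdk1+": "root"}
    for i in range(1, n_sub):
        if i % 2 == 1:
            name = f"FRC_{i}"
            branch_of_subset[name] = "branchA"
        else:
            name = f"CD34_{i}"
            branch_of_subset[name] = "branchB"
        subset_names.append(name)
    if n_sub == 1:
        subset_names = ["Cdk1+"]

    subset_of_cell = rng.choice(n_sub, size=n_cells, p=props)
    cells = [f"cell{i:05d}" for i in range(n_cells)]
    t_branch = 0.3
    # subsets appear in succession along their branch: the q-th subset of a
    # branch occupies the q-th pseudotime window after the branch point,
    # emulating the observed segregation of subsets along development
    ordinal: dict[str, tuple[int, int]] = {}
    for br in ("branchA", "branchB"):
        members = [s for s in subset_names if branch_of_subset[s] == br]
        for q, s in enumerate(members):
            ordinal[s] = (q, len(members))
    lo = np.empty(n_cells)
    hi = np.empty(n_cells)
    for i, k in enumerate(subset_of_cell):
        sub = subset_names[k]
        if branch_of_subset[sub] == "root":
            lo[i], hi[i] = 0.0, t_branch
        else:
            q, nb = ordinal[sub]
            lo[i] = t_branch + (1 - t_branch) * q / nb
            hi[i] = t_branch + (1 - t_branch) * (q + 1) / nb
    true_time = rng.uniform(lo, hi)

    # --- gene panel ----------------------------------------------------
    n_mito, n_ribo, n_cc = 10, 20, 40
    n_marker_per_subset = max(10, n_genes // (5 * max(n_sub, 1)))
    n_dyn_each = max(10, n_genes // 20)  # per dynamic class (shared up/down, A, B)
    names: list[str] = []
    names += [f"{mito_prefix}gene{i}" for i in range(n_mito)]
    names += [f"Rps{i}" if i % 2 == 0 else f"Rpl{i}" for i in range(n_ribo)]
    cc_s = [f"CcS_{i}" for i in range(n_cc // 2)]
    cc_g2m = [f"CcG2m_{i}" for i in range(n_cc - n_cc // 2)]
    names += cc_s + cc_g2m
    marker_genes: dict[str, list[str]] = {}
    for k, sub in enumerate(subset_names):
        mk = [f"Mk{k}_{j}" for j in range(n_marker_per_subset)]
        marker_genes[sub] = mk
        names += mk
    branch_markers = ["Vcam1", "Cd34"] if n_sub > 1 else []
    names += branch_markers
    dyn_up = [f"DynUp_{i}" for i in range(n_dyn_each)]
    dyn_down = [f"DynDown_{i}" for i in range(n_dyn_each)]
    dyn_a = [f"DynA_{i}" for i in range(n_dyn_each)] if n_sub > 1 else []
    dyn_b = [f"DynB_{i}" for i in range(n_dyn_each)] if n_sub > 1 else []
    names += dyn_up + dyn_down + dyn_a + dyn_b
    names.append("Pecam1")
    n_hk = n_genes - len(names)
    if n_hk < 0:
        raise ValueError("n_genes too small for the configured gene panel")
    names += [f"Hk_{i}" for i in range(n_hk)]
    name_idx = {g: i for i, g in enumerate(names)}

    # --- expression means ---------------------------------------------
    base = rng.lognormal(mean=np.log(0.8), sigma=0.8, size=n_genes)
    base[[name_idx[g] for g in names if g.startswith(mito_prefix)]] = 2.0
    for g in names:
        if g.startswith(("Rps", "Rpl")):
            base[name_idx[g]] = 3.0
    base[name_idx["Pecam1"]] = 0.05

    log2mult = np.zeros((n_genes, n_cells))
    for k, sub in enumerate(subset_names):
        in_sub = subset_of_cell == k
        for g in marker_genes[sub]:
            log2mult[name_idx[g], in_sub] += branch_sep
    branch_of_cell_arr = np.array([branch_of_subset[subset_names[k]] for k in subset_of_cell])
    if branch_markers:
        log2mult[name_idx["Vcam1"], branch_of_cell_arr == "branchA"] += branch_sep
        log2mult[name_idx["Cd34"], branch_of_cell_arr == "branchB"] += branch_sep
    # proliferation program in the progenitor pool (fixed 3-fold log2)
    cc_amp = rng.uniform(1.2, 1.8, size=n_cc)
    is_root = branch_of_cell_arr == "root"
    for j, g in enumerate(cc_s + cc_g2m):
        log2mult[name_idx[g], is_root] += cc_amp[j]
    # trajectory-dynamic genes: monotone in true_time
    for g in dyn_up:
        log2mult[name_idx[g]] += branch_sep * true_time
    for g in dyn_down:
        log2mult[name_idx[g]] += branch_sep * (1.0 - true_time)
    prog_a = np.where(branch_of_cell_arr == "branchA", (true_time - t_branch) / (1 - t_branch), 0.0)
    prog_b = np.where(branch_of_cell_arr == "branchB", (true_time - t_branch) / (1 - t_branch), 0.0)
    for g in dyn_a:
        log2mult[name_idx[g]] += branch_sep * prog_a
    for g in dyn_b:
        log2mult[name_idx[g]] += branch_sep * prog_b

    lib = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    mu = base[:, None] * (2.0 ** log2mult) * lib[None, :]
    counts = _nb_counts(rng, mu, NB_DISPERSION_SC)

    feature_meta = pd.DataFrame(index=pd.Index(names, name="gene"))
    feature_meta["biotype"] = "protein_coding"
    cell_meta = pd.DataFrame(
        {
            "subset": [subset_names[k] for k in subset_of_cell],
            "branch": branch_of_cell_arr,
            "timepoint": np.digitize(true_time, [0.25, 0.5, 0.75]),
            "true_time": true_time,
        },
        index=pd.Index(cells, name="cell"),
    )
    m = CountMatrix(counts, feature_meta, cell_meta)

    regulators = []
    if dyn_a:
        regulators += [(dyn_a[0], g) for g in dyn_a[1:]]
    if dyn_b:
        regulators += [(dyn_b[0], g) for g in dyn_b[1:]]
    truth = SimTruth(
        branch_of_cell=dict(zip(cells, branch_of_cell_arr.tolist())),
        true_time=dict(zip(cells, true_time.tolist())),
        signature_genes={s: list(g) for s, g in marker_genes.items()},
        regulator_links=regulators,
    )
    truth.cell_cycle_genes = {"s": cc_s, "g2m": cc_g2m}  # extra attribute for tests
    return m, truth


def make_bifurcation(
    n_cells: int = 2000,
    branch_sep: float = 2.0,
    noise_sd: float = 0.5,
    dims: int = 10,
    seed: int = 0,
    t_branch: float = 0.3,
    path_length: float = 8.0,
    commit_frac: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Geometric bifurcation testbed for trajectory inference.

    Cells lie on a Y embedded in ``dims`` dimensions: a stem up to
    ``t_branch``, then two arms whose transverse separation ramps to
    ``branch_sep`` within the first ``commit_frac`` of arm progression and
    stays there (fate commitment is rapid after a branch point), with
    isotropic Gaussian noise of ``noise_sd``. The developmental path spans
    ``path_length`` units, many noise widths, as real trajectories do.
    Returns ``(points, true_time, arm)`` with ``points`` shaped
    features x cells and ``arm`` in {"root", "branchA", "branchB"}.
    ``branch_sep`` = 0 collapses the arms: branch identity is then
    unrecoverable by construction.
    """
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, n_cells)
    arm_sign = np.where(rng.random(n_cells) < 0.5, 1.0, -1.0)
    arm = np.where(t < t_branch, "root", np.where(arm_sign > 0, "branchA", "branchB"))
    prog = np.maximum(0.0, t - t_branch) / (1.0 - t_branch)
    commit = np.minimum(1.0, prog / commit_frac)
    pos = np.zeros((n_cells, dims))
    pos[:, 0] = path_length * t
    pos[:, 1] = arm_sign * commit * branch_sep / 2.0
    pos += rng.normal(0.0, noise_sd, size=pos.shape)
    return pos.T, t, arm


# ----------------------------------------------------------------------
# methylome with planted DMRs
# ----------------------------------------------------------------------

def make_methylome(
    n_cpg: int = 50_000,
    n_dmr: int = 50,
    delta: float = 0.4,
    coverage_mean: float = 30.0,
    reps_per_group: int = 3,
    seed: int = 0,
) -> tuple[MethylomeTable, SimTruth]:
    """Two-condition CpG methylome with ``n_dmr`` planted regions.

    Each planted region holds 4-8 CpGs spaced 20-80 bp and is flanked by
    >= 1 kb without CpGs so regions never merge. Outside regions the two
    conditions share the same beta-distributed methylation level; inside,
    condition B is shifted by +/- ``delta`` (alternating direction, clamped
    into (0.01, 0.99) with a warning when clamping bites).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = np.random.default_rng(seed)
    plant = delta > 0
    n_dmr_eff = n_dmr if plant else 0

    block_sizes = rng.integers(4, 9, size=n_dmr_eff)
    n_bg = n_cpg - int(block_sizes.sum())
    if n_bg < n_dmr_eff:
        raise ValueError("n_cpg too small for the requested number of DMRs")

    # split background CpGs into n_dmr_eff + 1 stretches
    cuts = np.sort(rng.choice(n_bg, size=n_dmr_eff, replace=False)) if n_dmr_eff else np.array([], dtype=int)
    bg_runs = np.diff(np.concatenate([[0], cuts, [n_bg]]))

    positions: list[int] = []
    p_a: list[float] = []
    p_b: list[float] = []
    dmr_intervals: list[tuple] = []
    pos = 1000
    clamped = False

    def emit_background(k: int) -> None:
        nonlocal pos
        for _ in range(k):
            pos += int(rng.integers(50, 350))
            p = float(rng.beta(2.0, 2.0))
            positions.append(pos)
            p_a.append(p)
            p_b.append(p)

    for b in range(n_dmr_eff + 1):
        emit_background(int(bg_runs[b]))
        if b < n_dmr_eff:
            pos += 1000  # flank: no CpGs within 1 kb of a planted region
            direction = 1 if b % 2 == 0 else -1
            if direction > 0:
                p0 = float(rng.uniform(0.10, 0.95 - delta)) if delta < 0.85 else 0.05
            else:
                p0 = float(rng.uniform(0.05 + delta, 0.90)) if delta < 0.85 else 0.95
            start = None
            for j in range(int(block_sizes[b])):
                if j > 0:
                    pos += int(rng.integers(20, 81))
                pj = p0 + float(rng.uniform(-0.03, 0.03))
                pa = float(np.clip(pj, 0.01, 0.99))
                pb_raw = pj + direction * delta
                pb = float(np.clip(pb_raw, 0.01, 0.99))
                if pb != pb_raw:
                    clamped = True
                positions.append(pos)
                p_a.append(pa)
                p_b.append(pb)
                if start is None:
                    start = pos
            dmr_intervals.append((CHROM, start, pos + 2, direction * delta))
            pos += 1000

    if clamped:
        warnings.warn("delta pushed methylation outside (0,1); values were clamped", stacklevel=2)

    pos_arr = np.asarray(positions)
    pa_arr, pb_arr = np.asarray(p_a), np.asarray(p_b)
    samples = [f"A{r + 1}" for r in range(reps_per_group)] + [f"B{r + 1}" for r in range(reps_per_group)]
    groups = {s: ("A" if s.startswith("A") else "B") for s in samples}
    df = pd.DataFrame({"chrom": CHROM, "pos": pos_arr})
    for s in samples:
        p = pa_arr if groups[s] == "A" else pb_arr
        cov = rng.poisson(coverage_mean, size=len(pos_arr))
        meth = rng.binomial(cov, p)
        df[f"M_{s}"] = meth
        df[f"C_{s}"] = cov

    table = MethylomeTable(df, samples, groups)
    return table, SimTruth(dmr_intervals=dmr_intervals)


# ----------------------------------------------------------------------
# ATAC: master peaks, counts and replicate peak lists
# ----------------------------------------------------------------------

def make_atac(
    n_peaks: int = 5000,
    n_dar: int = 250,
    fc: float = 4.0,
    reps: int = 3,
    seed: int = 0,
    mean_count: float = 100.0,
) -> tuple[IntervalSet, CountMatrix, SimTruth]:
    """Accessibility peak set and count matrix with planted DARs.

    Counts are negative-binomial (dispersion 0.2) around a per-peak baseline
    (log-normal around ``mean_count``) times a per-sample size factor;
    planted peaks are scaled by ``fc`` in condition B. ``fc`` = 1 plants
    nothing.
    """
    if fc < 1:
        raise ValueError("fc must be >= 1")
    rng = np.random.default_rng(seed)

    widths = rng.integers(200, 801, size=n_peaks)
    gaps = rng.integers(300, 1500, size=n_peaks)
    starts = 1000 + np.cumsum(gaps) + np.concatenate([[0], np.cumsum(widths[:-1])])
    ends = starts + widths
    peak_ids = [f"peak{i:05d}" for i in range(n_peaks)]
    peaks = IntervalSet(pd.DataFrame({"chrom": CHROM, "start": starts, "end": ends, "name": peak_ids}))

    base = rng.lognormal(mean=np.log(mean_count), sigma=0.5, size=n_peaks)
    dar_idx = rng.choice(n_peaks, size=n_dar, replace=False) if (fc > 1 and n_dar > 0) else np.array([], dtype=int)
    size_factors = rng.lognormal(0.0, 0.2, size=2 * reps)
    samples = [f"A{r + 1}" for r in range(reps)] + [f"B{r + 1}" for r in range(reps)]
    mu = np.tile(base[:, None], (1, 2 * reps)) * size_factors[None, :]
    mu[np.ix_(dar_idx, np.arange(reps, 2 * reps))] *= fc
    counts = _nb_counts(rng, mu, NB_DISPERSION_BULK)

    feature_meta = pd.DataFrame({"chrom": CHROM, "start": starts, "end": ends}, index=pd.Index(peak_ids, name="peak"))
    cell_meta = pd.DataFrame(
        {"condition": ["A"] * reps + ["B"] * reps}, index=pd.Index(samples, name="sample")
    )
    cm = CountMatrix(counts, feature_meta, cell_meta)
    truth = SimTruth(dar_ids={peak_ids[i]: float(fc) for i in dar_idx})
    return peaks, cm, truth


def make_replicate_peak_sets(
    master: IntervalSet,
    n_reps: int,
    dropout: float = 0.1,
    max_jitter: int = 50,
    seed: int = 0,
) -> list[IntervalSet]:
    """Per-replicate peak lists: the master set with random dropout and
    +/- jitter of at most ``max_jitter`` bp on each boundary."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        keep = rng.random(len(master)) >= dropout
        sub = master.df.loc[keep].copy()
        j1 = rng.integers(-max_jitter, max_jitter + 1, size=len(sub))
        j2 = rng.integers(-max_jitter, max_jitter + 1, size=len(sub))
        sub["start"] = np.maximum(0, sub["start"].to_numpy() + j1)
        sub["end"] = np.maximum(sub["start"].to_numpy() + 1, sub["end"].to_numpy() + j2)
        out.append(IntervalSet(sub.reset_index(drop=True)))
    return out


def make_blacklist(n: int = 20, seed: int = 0, span: int = 10_000_000) -> IntervalSet:
    """Random blacklist intervals on the synthetic chromosome."""
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(0, span - 5000, size=n))
    widths = rng.integers(500, 5000, size=n)
    return IntervalSet(pd.DataFrame({"chrom": CHROM, "start": starts, "end": starts + widths, "name": "blacklist"}))


# ----------------------------------------------------------------------
# motif hits and overexpression bulk
# ----------------------------------------------------------------------

def make_motif_hits(
    n_motifs: int = 50,
    n_genes: int = 2000,
    enriched_pairs: list | None = None,
    odds: float = 1.0,
    seed: int = 0,
    base_prob: float = 0.1,
) -> pd.DataFrame:
    """Bernoulli motif x gene hit table (0/1).

    ``enriched_pairs`` is a list of ``(motif, gene_list)``; inside a pair the
    hit probability is raised so the odds of a hit are multiplied by
    ``odds`` relative to ``base_prob``.
    """
    if odds < 1:
        raise ValueError("odds must be >= 1")
    rng = np.random.default_rng(seed)
    motifs = [f"motif{i:03d}" for i in range(n_motifs)]
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    p = np.full((n_motifs, n_genes), base_prob)
    if enriched_pairs:
        gene_idx = {g: i for i, g in enumerate(genes)}
        motif_idx = {m: i for i, m in enumerate(motifs)}
        p_enr = odds * base_prob / (1.0 - base_prob + odds * base_prob)
        for motif, gene_list in enriched_pairs:
            cols = [gene_idx[g] for g in gene_list if g in gene_idx]
            p[motif_idx[motif], cols] = p_enr
    hits = (rng.random((n_motifs, n_genes)) < p).astype(int)
    return pd.DataFrame(hits, index=pd.Index(motifs, name="motif"), columns=pd.Index(genes, name="gene"))


def make_overexpression_bulk(
    signature_genes: list[str],
    strength: float = 3.0,
    reps: int = 3,
    seed: int = 0,
    n_genes: int = 2000,
) -> CountMatrix:
    """Bulk counts for a control arm vs a TF-overexpression arm in which the
    given signature genes are shifted up by ``strength`` log2 units."""
    if reps < 2:
        raise ValueError("need >= 2 replicates per arm")
    rng = np.random.default_rng(seed)
    filler = [f"bulk{i:05d}" for i in range(n_genes)]
    names = list(dict.fromkeys(list(signature_genes) + filler))[: max(n_genes, len(signature_genes))]
    idx = {g: i for i, g in enumerate(names)}
    base = rng.lognormal(np.log(50.0), 1.0, size=len(names))
    lengths = rng.integers(500, 5001, size=len(names))

    mu = np.tile(base[:, None], (1, 2 * reps))
    sig_rows = [idx[g] for g in signature_genes if g in idx]
    mu[np.ix_(sig_rows, np.arange(reps, 2 * reps))] *= 2.0**strength
    lib = rng.lognormal(0.0, 0.15, size=2 * reps)
    counts = _nb_counts(rng, mu * lib[None, :], NB_DISPERSION_BULK)

    samples = [f"ctrl{r + 1}" for r in range(reps)] + [f"oe{r + 1}" for r in range(reps)]
    feature_meta = pd.DataFrame({"length": lengths, "biotype": "protein_coding"}, index=pd.Index(names, name="gene"))
    cell_meta = pd.DataFrame(
        {"condition": ["control"] * reps + ["overexpression"] * reps},
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(counts, feature_meta, cell_meta)
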