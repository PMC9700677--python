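"""Pseudotime ordering on a principal tree, branch assignment and
branch-point differential expression.

The principal tree is a deliberate simplification of latent-graph
optimizers (DDRTree and kin): PCA, k-means centroids, a minimum spanning
tree over the centroids, and projection of every cell onto its nearest tree
edge. The downstream claims exercised here — bifurcation topology, ordering
along branches, branch-point differential expression — depend only on tree
topology and geodesic ordering, which this construction provides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._stats import bh_adjust
from .containers import CountMatrix
from .sc import normalize_log

__all__ = [
    "TrajectoryModel",
    "expression_gene_filter",
    "fit_principal_tree",
    "choose_root",
    "split_by_markers",
    "branch_degs",
    "branch_composition",
]


@dataclass
class TrajectoryModel:
    node_pos: np.ndarray  # nodes x dims
    edges: list  # (u, v) pairs, undirected
    edge_lengths: np.ndarray
    cell_edge: np.ndarray  # per cell: index into edges
    cell_offset: np.ndarray  # per cell: distance from edge endpoint u along the edge
    cell_names: pd.Index
    cell_pos: np.ndarray = field(default=None)  # cells x dims, reduced space
    root_node: int = 0
    pseudotime: np.ndarray = field(default=None)  # per cell, normalized to [0, 1]
    branch_label: np.ndarray = field(default=None)  # per cell, branch segment id
    node_dist: np.ndarray = field(default=None)  # geodesic node distance from root

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.node_pos)))
        for (u, v), w in zip(self.edges, self.edge_lengths):
            g.add_edge(u, v, weight=float(w))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.node_pos)

    def nearest_node_per_cell(self) -> np.ndarray:
        """The edge endpoint each cell projects closer to."""
        out = np.empty(len(self.cell_edge), dtype=int)
        for i, (e, off) in enumerate(zip(self.cell_edge, self.cell_offset)):
            u, v = self.edges[e]
            out[i] = u if off <= self.edge_lengths[e] / 2 else v
        return out

    # ------------------------------------------------------------------
    def set_root(self, root: int) -> "TrajectoryModel":
        """Root the tree: recompute geodesic pseudotime (normalized to
        [0, 1]) and branch labels (maximal unbranched segments)."""
        g = self.graph()
        dist = nx.single_source_dijkstra_path_length(g, root, weight="weight")
        self.root_node = root
        self.node_dist = np.array([dist[i] for i in range(self.n_nodes)])

        pt = np.empty(len(self.cell_edge))
        for i, (e, off) in enumerate(zip(self.cell_edge, self.cell_offset)):
            u, v = self.edges[e]
            # orient the edge away from the root
            if self.node_dist[u] <= self.node_dist[v]:
                pt[i] = self.node_dist[u] + off
            else:
                pt[i] = self.node_dist[v] + (self.edge_lengths[e] - off)
        pt = pt - pt.min()  # cells extrapolated past a root-side leaf shift the origin
        mx = pt.max()
        self.pseudotime = pt / mx if mx > 0 else pt

        # branch segments: split the tree at the root and at nodes of
        # degree >= 3; every edge belongs to exactly one segment
        seg_of_edge = np.full(len(self.edges), -1, dtype=int)
        breakpoints = {n for n in g.nodes if g.degree(n) >= 3} | {root}
        edge_index = {frozenset(e): i for i, e in enumerate(self.edges)}
        seg = 0
        for start in sorted(breakpoints):
            for nb in sorted(g.neighbors(start)):
                i = edge_index[frozenset((start, nb))]
                if seg_of_edge[i] >= 0:
                    continue
                prev, cur = start, nb
                while True:
                    seg_of_edge[edge_index[frozenset((prev, cur))]] = seg
                    if cur in breakpoints or g.degree(cur) != 2:
                        break
                    nxt = next(n for n in g.neighbors(cur) if n != prev)
                    prev, cur = cur, nxt
                seg += 1
        self._seg_of_edge = seg_of_edge
        self.branch_label = seg_of_edge[self.cell_edge]
        return self

    def terminal_branches(self) -> dict[int, int]:
        """Map branch segment id -> leaf node, for segments ending in a
        non-root leaf."""
        g = self.graph()
        edge_index = {frozenset(e): i for i, e in enumerate(self.edges)}
        out = {}
        for leaf in g.nodes:
            if g.degree(leaf) == 1 and leaf != self.root_node:
                e = edge_index[frozenset((leaf, next(iter(g.neighbors(leaf)))))]
                out[int(self._seg_of_edge[e])] = leaf
        return out

    def first_branch_node(self) -> int | None:
        """The degree >= 3 node closest to the root (geodesically), or
        ``None`` for an unbranched tree."""
        g = self.graph()
        bps = [n for n in g.nodes if g.degree(n) >= 3]
        if not bps:
            return None
        return int(min(bps, key=lambda n: (self.node_dist[n], n)))

    def fate_split(self) -> np.ndarray:
        """Forced two-fate assignment below the first branch point.

        The fates are the two largest-by-cell-count subtrees hanging off the
        main branch node — the degree >= 3 node that maximizes the size of
        the smaller of its two largest downstream subtrees (robust against
        small spurs); every cell is assigned 0 or 1 by its distance to the
        nearest edge of each fate's polyline (stem cells are forced to the
        nearer fate, which is how a binary fate split is used downstream).
        Returns -1 for all cells when the tree is unbranched.
        """
        n_cells = len(self.cell_edge)
        if self.cell_pos is None:
            return np.full(n_cells, -1, dtype=int)
        g = self.graph()
        edge_index = {frozenset(e): i for i, e in enumerate(self.edges)}

        def downstream_subtrees(bp: int) -> list[tuple[int, list[int]]]:
            subtrees = []
            for nb in g.neighbors(bp):
                if self.node_dist[nb] <= self.node_dist[bp]:
                    continue  # walk away from the root only
                seen = {bp, nb}
                stack = [nb]
                edges = [edge_index[frozenset((bp, nb))]]
                while stack:
                    cur = stack.pop()
                    for nxt in g.neighbors(cur):
                        if nxt in seen:
                            continue
                        seen.add(nxt)
                        stack.append(nxt)
                        edges.append(edge_index[frozenset((cur, nxt))])
                n_proj = int(np.isin(self.cell_edge, edges).sum())
                subtrees.append((n_proj, edges))
            subtrees.sort(key=lambda t: -t[0])
            return subtrees

        best_key, subtrees = None, []
        for bp in (n for n in g.nodes if g.degree(n) >= 3):
            subs = downstream_subtrees(bp)
            if len(subs) < 2:
                continue
            key = (subs[1][0], -self.node_dist[bp])
            if best_key is None or key > best_key:
                best_key, subtrees = key, subs
        if len(subtrees) < 2:
            return np.full(n_cells, -1, dtype=int)
        out = np.empty(n_cells, dtype=int)
        dists = []
        for _, edges in subtrees[:2]:
            best = np.full(n_cells, np.inf)
            for e in edges:
                u, v = self.edges[e]
                dd, _ = _project_to_segment(self.cell_pos, self.node_pos[u], self.node_pos[v])
                best = np.minimum(best, dd)
            dists.append(best)
        out = (dists[1] < dists[0]).astype(int)
        return out


def expression_gene_filter(m: CountMatrix, min_mean: float = 0.1, scale: float = 10_000.0) -> list[str]:
    """Genes with mean normalized expression strictly above ``min_mean``."""
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    x = normalize_log(m, scale)
    return list(m.feature_names[x.mean(axis=1) > min_mean])


def _project_to_segment(
    p: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    extend_a: bool = False,
    extend_b: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Distances and offsets of points ``p`` to segment a-b.

    ``extend_a``/``extend_b`` allow extrapolation past the respective
    endpoint (used on terminal edges so cells beyond a leaf keep distinct
    orderings instead of piling onto the leaf node)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        off = np.zeros(len(p))
    else:
        off = (p - a) @ ab / denom
        off = np.clip(off, None if extend_a else 0.0, None if extend_b else 1.0)
    foot = a + off[:, None] * ab
    return np.linalg.norm(p - foot, axis=1), off * np.sqrt(denom)


def fit_principal_tree(
    x: np.ndarray,
    dims: int = 5,
    n_nodes: int = 10,
    seed: int = 0,
    cell_names: pd.Index | None = None,
) -> TrajectoryModel:
    """PCA -> k-means centroids -> minimum spanning tree -> edge projection.

    ``x`` is genes x cells. The returned model is provisionally rooted at
    node 0; call :func:`choose_root` (or ``set_root``) for a meaningful
    root. Identical input points are rejected (the tree is degenerate)."""
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all cells identical")
    n_cells = x.shape[1]
    dims = min(dims, min(x.shape))
    pc = PCA(n_components=dims, svd_solver="full").fit_transform(x.T)
    km = KMeans(n_clusters=min(n_nodes, n_cells), n_init=10, random_state=seed).fit(pc)
    centroids = km.cluster_centers_

    d = cdist(centroids, centroids)
    mst = minimum_spanning_tree(d).toarray()
    edges = [(int(u), int(v)) for u, v in zip(*np.nonzero(mst))]
    lengths = np.array([d[u, v] for u, v in edges])

    deg = np.zeros(len(centroids), dtype=int)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    best_dist = np.full(n_cells, np.inf)
    cell_edge = np.zeros(n_cells, dtype=int)
    cell_offset = np.zeros(n_cells)
    for e, (u, v) in enumerate(edges):
        dd, off = _project_to_segment(pc, centroids[u], centroids[v], extend_a=deg[u] == 1, extend_b=deg[v] == 1)
        upd = dd < best_dist
        best_dist[upd] = dd[upd]
        cell_edge[upd] = e
        cell_offset[upd] = off[upd]

    if cell_names is None:
        cell_names = pd.RangeIndex(n_cells)
    model = TrajectoryModel(
        node_pos=centroids,
        edges=edges,
        edge_lengths=lengths,
        cell_edge=cell_edge,
        cell_offset=cell_offset,
        cell_names=pd.Index(cell_names),
        cell_pos=pc,
    )
    return model.set_root(0)


def choose_root(
    t: TrajectoryModel,
    cell_groups: np.ndarray | None = None,
    proliferation_score: np.ndarray | None = None,
) -> int:
    """Root node: the tree node whose projected cells hold the highest
    fraction of cells from the earliest timepoint; ties broken by highest
    mean proliferation score (if given), then smallest node id. Requires
    orderable timepoints unless an explicit root is set on the model."""
    if cell_groups is None:
        raise ValueError("no timepoint metadata: pass an explicit root to set_root instead")
    groups = np.asarray(cell_groups)
    earliest = np.min(groups)
    nearest = t.nearest_node_per_cell()
    best, best_key = 0, None
    for node in range(t.n_nodes):
        mask = nearest == node
        if mask.sum() == 0:
            continue
        frac = float(np.mean(groups[mask] == earliest))
        prolif = float(np.mean(proliferation_score[mask])) if proliferation_score is not None else 0.0
        key = (frac, prolif, -node)
        if best_key is None or key > best_key:
            best, best_key = node, key
    return best


def split_by_markers(
    t: TrajectoryModel,
    m: CountMatrix,
    marker_a: str = "Vcam1",
    marker_b: str = "Cd34",
    scale: float = 10_000.0,
) -> tuple[list, list, list]:
    """Split the trajectory into two marker-defined cell sets.

    When the tree bifurcates, the two fates below the first branch point
    (see :meth:`TrajectoryModel.fate_split`) are each assigned to the
    marker with the higher mean normalized expression among their cells;
    every cell inherits its fate's assignment. On an unbranched tree the
    rule falls back to terminal branch segments. Ties (both fates
    preferring the same marker, or equal means) leave cells unassigned.
    Returns (cells_a, cells_b, unassigned)."""
    for g in (marker_a, marker_b):
        if g not in m.feature_names:
            raise ValueError(f"marker {g!r} absent from the matrix")
    x = normalize_log(m, scale)
    ea = x[m.feature_names.get_loc(marker_a)]
    eb = x[m.feature_names.get_loc(marker_b)]

    def assign(groups: list[np.ndarray]) -> tuple[list, list, list]:
        set_a, set_b, unassigned = [], [], []
        prefs = []
        for cells in groups:
            ma, mb = ea[cells].mean(), eb[cells].mean()
            prefs.append("a" if ma > mb else "b" if mb > ma else None)
        if len(groups) == 2 and {None} != set(prefs) and prefs[0] == prefs[1]:
            # both groups prefer the same marker: the larger difference wins
            d = [abs(ea[c].mean() - eb[c].mean()) for c in groups]
            w = int(np.argmax(d))
            prefs[1 - w] = "b" if prefs[w] == "a" else "a"
        for cells, pref in zip(groups, prefs):
            names = list(t.cell_names[cells])
            (set_a if pref == "a" else set_b if pref == "b" else unassigned).extend(names)
        return set_a, set_b, unassigned

    fates = t.fate_split()
    if fates.max() >= 0:
        return assign([np.flatnonzero(fates == 0), np.flatnonzero(fates == 1)])
    terminal = set(t.terminal_branches())
    set_a, set_b, unassigned = [], [], []
    for seg in np.unique(t.branch_label):
        cells = np.flatnonzero(t.branch_label == seg)
        if seg not in terminal or len(cells) == 0:
            unassigned.extend(list(t.cell_names[cells]))
            continue
        a1, b1, u1 = assign([cells])
        set_a.extend(a1)
        set_b.extend(b1)
        unassigned.extend(u1)
    return set_a, set_b, unassigned


def branch_degs(
    t: TrajectoryModel,
    m: CountMatrix,
    branch_pair: tuple[int, int],
    min_log2fc: float = 0.2,
    max_padj: float = 0.05,
    min_cells: int = 10,
    scale: float = 10_000.0,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between the cells of two
    post-branch-point branches (BH per contrast, thresholds as for cluster
    markers). Branches below ``min_cells`` cells are skipped with a
    warning."""
    a, b = branch_pair
    ia = np.flatnonzero(t.branch_label == a)
    ib = np.flatnonzero(t.branch_label == b)
    if len(ia) < min_cells or len(ib) < min_cells:
        warnings.warn(f"branch pair {branch_pair}: fewer than {min_cells} cells, skipped", stacklevel=2)
        return pd.DataFrame(columns=["gene", "contrast", "log2FC", "p", "padj", "direction"])
    x = normalize_log(m, scale)
    ex = np.expm1(x)
    res = stats.mannwhitneyu(x[:, ia], x[:, ib], axis=1, alternative="two-sided", method="auto")
    lfc = np.log2(ex[:, ia].mean(axis=1) + 1.0) - np.log2(ex[:, ib].mean(axis=1) + 1.0)
    padj = bh_adjust(res.pvalue)
    sel = (np.abs(lfc) >= min_log2fc) & (padj <= max_padj)
    return pd.DataFrame(
        {
            "gene": m.feature_names[sel],
            "contrast": f"branch{a}_vs_branch{b}",
            "log2FC": lfc[sel],
            "p": res.pvalue[sel],
            "padj": padj[sel],
            "direction": np.where(lfc[sel] > 0, "up", "down"),
        }
    )


def branch_composition(t: TrajectoryModel, labels: np.ndarray) -> pd.DataFrame:
    """Subset x branch percentage matrix with the same two-step
    normalization as the timepoint composition heatmap."""
    from .sc import composition_heatmap

    return composition_heatmap(labels, t.branch_label)
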