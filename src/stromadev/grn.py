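"""Time-ordered gene regulatory network inference over trajectory branches.

The dynamical formulation: cells of a branch are ordered by (pseudo)time
and binned into a pseudo-timeseries; for every target gene g the response

    y_t = (x_g(t+1) - x_g(t)) / dt + alpha * x_g(t)

(the transcription rate under first-order decay ``alpha``) is regressed on
the candidate-TF expressions at time t with a random forest, and the total
impurity-reduction importance of each TF is that link's weight. Only the
global Top-K links by weight are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = ["GRNetwork", "order_expression", "infer_network", "node_stats", "shared_regulators"]


@dataclass
class GRNetwork:
    links: pd.DataFrame  # regulator, target, weight; sorted by weight desc
    decay: float
    top_k: int

    def regulators(self) -> set:
        return set(self.links["regulator"])

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for r in self.links.itertuples(index=False):
            g.add_edge(r.regulator, r.target, weight=float(r.weight))
        return g


def order_expression(
    x: np.ndarray,
    gene_names: pd.Index,
    time: np.ndarray,
    branch_mask: np.ndarray | None = None,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Bin a branch's cells into an equal-occupancy pseudo-timeseries.

    ``x`` is genes x cells; cells (optionally restricted to a branch) are
    sorted by ``time`` and split into ``n_bins`` equal-occupancy bins whose
    per-gene means form the series (genes x bins). Branches with fewer
    cells than bins use one bin per cell, with a warning."""
    if branch_mask is not None:
        x = x[:, branch_mask]
        time = time[branch_mask]
    n_cells = x.shape[1]
    if n_cells < n_bins:
        warnings.warn(f"only {n_cells} cells; reducing bins to {n_cells}", stacklevel=2)
        n_bins = n_cells
    order = np.argsort(time, kind="stable")
    xo = x[:, order]
    edges = np.linspace(0, n_cells, n_bins + 1).astype(int)
    series = np.column_stack([xo[:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])])
    return pd.DataFrame(series, index=gene_names, columns=[f"bin{b}" for b in range(n_bins)])


def infer_network(
    ts: pd.DataFrame,
    candidate_tfs: list[str],
    alpha: float = 0.02,
    n_trees: int = 100,
    seed: int = 0,
    top_k: int = 500,
    dt: float = 1.0,
) -> GRNetwork:
    """Random-forest dynamical network inference on a pseudo-timeseries.

    ``ts`` is genes x time bins. Per target, the decay-corrected response
    is regressed on candidate-TF expressions at the preceding bin
    (``mtry = sqrt(|TF|)``); importances become link weights, self-links are
    excluded, constant targets are skipped, and the global Top-``top_k``
    links by weight are kept."""
    missing = [g for g in candidate_tfs if g not in ts.index]
    if missing:
        raise ValueError(f"candidate TFs absent from the series: {missing[:5]}")
    xs = ts.to_numpy(dtype=float)
    genes = list(ts.index)
    tf_idx = [genes.index(g) for g in candidate_tfs]
    X_full = xs[tf_idx, :-1].T  # bins-1 x TFs
    rng = np.random.default_rng(seed)

    rows = []
    for gi, g in enumerate(genes):
        xg = xs[gi]
        y = (xg[1:] - xg[:-1]) / dt + alpha * xg[:-1]
        preds = [j for j, t in enumerate(candidate_tfs) if t != g]
        if not preds or np.ptp(y) == 0:
            continue
        Xp = X_full[:, preds]
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(Xp, y)
        for j, imp in zip(preds, rf.feature_importances_):
            # scale importances by the response spread so weights are
            # comparable across targets (dynGENIE3-style normalization)
            rows.append((candidate_tfs[j], g, float(imp * y.std(ddof=1))))
    links = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    links = links.sort_values(["weight", "regulator", "target"], ascending=[False, True, True], kind="mergesort")
    links = links.head(top_k).reset_index(drop=True)
    return GRNetwork(links=links, decay=alpha, top_k=top_k)


def node_stats(net: GRNetwork) -> pd.DataFrame:
    """Per-node degree (in + out link count) and betweenness (standard
    shortest-path counting on the directed, unweighted link graph)."""
    if not len(net.links):
        raise ValueError("empty network")
    g = net.graph()
    btw = nx.betweenness_centrality(g, normalized=False)
    rows = [(n, g.in_degree(n) + g.out_degree(n), btw[n]) for n in g.nodes]
    return pd.DataFrame(rows, columns=["node", "degree", "betweenness"]).sort_values(
        "degree", ascending=False
    ).reset_index(drop=True)


def shared_regulators(net_a: GRNetwork, net_b: GRNetwork) -> dict:
    """Regulator overlap between two branch networks: the intersection and
    its fraction of the union."""
    if not len(net_a.links) or not len(net_b.links):
        raise ValueError("both networks must be non-empty")
    ra, rb = net_a.regulators(), net_b.regulators()
    union = ra | rb
    inter = ra & rb
    return {
        "regulators_a": sorted(ra),
        "regulators_b": sorted(rb),
        "shared": sorted(inter),
        "shared_fraction": len(inter) / len(union) if union else 0.0,
    }
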