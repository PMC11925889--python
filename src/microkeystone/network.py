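"""Correlation-based co-occurrence networks, centralities and keystones.

Edges connect feature pairs whose Spearman correlation passes a fixed
magnitude threshold (default |rho| >= 0.6) at a BH-corrected significance
level.  Keystone candidates are the argmax nodes of four centralities on the
unweighted skeleton: degree, betweenness ("mediator number"), stress (count
of shortest paths through a node) and eigenvector centrality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .containers import RelAbundanceTable, ValidationError

__all__ = [
    "CooccurrenceNetwork",
    "spearman_matrix",
    "build_network",
    "node_centralities",
    "detect_modules",
    "keystone_nodes",
]

CENTRALITY_METRICS = ("degree", "betweenness", "stress", "eigenvector")


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    rho_min: float
    alpha: float
    correction: str
    node_table: pd.DataFrame | None = field(default=None)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def spearman_matrix(
    rel: RelAbundanceTable | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho (mid-rank ties) with t-approximation p-values.

    Constant features yield NaN rho/p against every partner.
    """
    data = rel.data if hasattr(rel, "data") else rel
    x = data.to_numpy(dtype=float)
    ids = list(data.index)
    n = x.shape[1]
    if n < 5:
        raise ValidationError("need >= 5 samples for correlation estimates")
    ranks = np.apply_along_axis(rankdata, 1, x)
    sd = ranks.std(axis=1)
    constant = sd == 0
    z = np.zeros_like(ranks)
    z[~constant] = (
        ranks[~constant] - ranks[~constant].mean(axis=1, keepdims=True)
    ) / sd[~constant, None]
    rho = z @ z.T / n
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    np.fill_diagonal(p, 0.0)
    p[np.isnan(rho)] = np.nan
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    correction: str = "bh",
) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into an undirected network.

    An edge (i, j) exists iff |rho_ij| >= rho_min and its (BH-corrected)
    p-value is < alpha.  Isolated nodes are retained.
    """
    if not 0.0 <= rho_min <= 1.0:
        raise ValidationError(f"rho_min must lie in [0, 1], got {rho_min}")
    if correction not in ("bh", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValidationError("rho and p matrices are not aligned")
    ids = list(rho.index)
    r = rho.to_numpy(dtype=float)
    pv = p.to_numpy(dtype=float)
    iu = np.triu_indices(len(ids), 1)
    pv_flat = pv[iu]
    valid = ~np.isnan(pv_flat)
    qv_flat = np.full_like(pv_flat, np.nan)
    if valid.any():
        if correction == "bh":
            qv_flat[valid] = multipletests(pv_flat[valid], method="fdr_bh")[1]
        else:
            qv_flat[valid] = pv_flat[valid]
    r_flat = r[iu]
    keep = valid & (np.abs(r_flat) >= rho_min) & (qv_flat < alpha)

    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, j, rr, pp, qq in zip(
        iu[0][keep], iu[1][keep], r_flat[keep], pv_flat[keep], qv_flat[keep]
    ):
        g.add_edge(ids[i], ids[j], rho=float(rr), p=float(pp), q=float(qq))
    return CooccurrenceNetwork(
        graph=g, rho_min=rho_min, alpha=alpha, correction=correction
    )


def _stress_centrality(g: nx.Graph) -> dict:
    """Stress centrality: number of shortest paths passing through each node.

    Computed from per-source BFS shortest-path counts; a node v mediates pair
    {s, t} with multiplicity sigma_sv * sigma_vt when d_sv + d_vt = d_st.
    """
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    big = np.iinfo(np.int64).max // 4
    dist = np.full((n, n), big, dtype=np.int64)
    sigma = np.zeros((n, n), dtype=float)
    for s in nodes:
        si = index[s]
        d = nx.single_source_shortest_path_length(g, s)
        # path counts by BFS layer
        counts = {s: 1.0}
        for v in sorted(d, key=d.get):
            if v == s:
                continue
            counts[v] = sum(
                counts[u] for u in g.neighbors(v) if d.get(u, -1) == d[v] - 1
            )
        for v, dv in d.items():
            dist[si, index[v]] = dv
            sigma[si, index[v]] = counts[v]
    stress = np.zeros(n)
    for vi in range(n):
        through = dist[:, vi][:, None] + dist[vi, :][None, :] == dist
        through[vi, :] = False
        through[:, vi] = False
        np.fill_diagonal(through, False)
        contrib = sigma[:, vi][:, None] * sigma[vi, :][None, :]
        stress[vi] = contrib[through].sum() / 2.0  # unordered pairs
    return {v: float(stress[index[v]]) for v in nodes}


def _eigenvector_centrality(g: nx.Graph) -> dict:
    """Principal adjacency eigenvector per connected component, each
    max-normalised to 1; edgeless components score 0."""
    out = {v: 0.0 for v in g.nodes}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        sub = g.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        a = nx.to_numpy_array(sub, nodelist=comp)
        eigvals, eigvecs = np.linalg.eigh(a)
        vec = np.abs(eigvecs[:, -1])
        vec = vec / vec.max()
        for v, c in zip(comp, vec):
            out[v] = float(c)
    return out


def node_centralities(net: CooccurrenceNetwork) -> CooccurrenceNetwork:
    """Attach degree, betweenness, stress and eigenvector centralities."""
    g = net.graph
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=False)
    stress = _stress_centrality(g)
    eigen = _eigenvector_centrality(g)
    for v in g.nodes:
        g.nodes[v]["degree"] = int(degree[v])
        g.nodes[v]["betweenness"] = float(betweenness[v])
        g.nodes[v]["stress"] = float(stress[v])
        g.nodes[v]["eigenvector"] = float(eigen[v])
    net.node_table = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "stress": pd.Series(stress),
            "eigenvector": pd.Series(eigen),
        }
    ).loc[list(g.nodes)]
    net.node_table.index.name = "feature_id"
    return net


def detect_modules(net: CooccurrenceNetwork, seed: int | None = None) -> CooccurrenceNetwork:
    """Greedy modularity module detection on the unweighted skeleton.

    The algorithm is deterministic; ``seed`` is accepted and recorded for
    interface stability.  Module ids are ordered by each module's smallest
    node id, so labels are stable across runs.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return net
    communities = [
        set(c)
        for c in nx.algorithms.community.greedy_modularity_communities(g)
    ]
    communities.sort(key=lambda c: min(str(v) for v in c))
    for mid, comm in enumerate(communities):
        for v in comm:
            g.nodes[v]["module"] = mid
    if net.node_table is not None:
        net.node_table["module"] = [g.nodes[v]["module"] for v in net.node_table.index]
    return net


def keystone_nodes(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Argmax node(s) of each centrality metric, ties included."""
    if net.node_table is None:
        raise ValidationError("run node_centralities first")
    rows = []
    for metric in CENTRALITY_METRICS:
        col = net.node_table[metric]
        if len(col) == 0:
            continue
        best = col.max()
        for node in col.index[col == best]:
            rows.append({"metric": metric, "node": node, "value": float(best)})
    return pd.DataFrame(rows, columns=["metric", "node", "value"])
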