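"""Thresholded functional graphs, modularity communities and hub metrics.

A group's graph keeps every region as a node and draws an edge for each
region pair whose correlation passes the compound criterion
r > threshold_r AND p < alpha (defaults 0.60 and 0.05; with the default
threshold all edges are positive correlations). Edges carry their r as a
weight, but degree and the node-role metrics are computed on the
unweighted graph; community detection may use the r weights.

Communities come from two-phase modularity optimization (iterative local
moves followed by graph aggregation, repeated to convergence), maximizing

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] delta(c_i, c_j)

Node roles follow the within-module degree z-score and participation
coefficient:

    z_i = (kappa_i - mean(kappa, community)) / sd(kappa, community)
    P_i = 1 - sum_s (kappa_is / k_i)^2

where kappa_is counts i's edges into community s and kappa_i = kappa_i,s_i.
High-z, high-P nodes are the candidate hubs coordinating activity across
the network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import GroupCorrelation
from .data import ValidationError

DEFAULT_THRESHOLD_R = 0.60
DEFAULT_ALPHA = 0.05


def build_graph(
    corr: GroupCorrelation,
    threshold_r: float = DEFAULT_THRESHOLD_R,
    alpha: float = DEFAULT_ALPHA,
    bh_correction: bool = False,
) -> nx.Graph:
    """Unweighted-topology graph with all regions as nodes and edges for
    pairs with r > threshold_r and p < alpha (strict inequalities; missing
    entries never form edges). Edge attributes keep r and p.

    bh_correction applies Benjamini-Hochberg across the region-pair
    p-values before the alpha filter, for users who want control of the
    edge false-discovery rate instead of the plain per-pair criterion.
    """
    graph = nx.Graph()
    graph.add_nodes_from(corr.regions)
    nreg = len(corr.regions)
    p_matrix = corr.p
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        iu = np.triu_indices(nreg, k=1)
        raw = corr.p[iu]
        adj = np.full_like(raw, np.nan)
        ok = ~np.isnan(raw)
        if ok.any():
            adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        p_matrix = np.full_like(corr.p, np.nan)
        p_matrix[iu] = adj
        p_matrix.T[iu] = adj
    for i, j in itertools.combinations(range(nreg), 2):
        r = corr.r[i, j]
        p = p_matrix[i, j]
        if np.isnan(r) or np.isnan(p):
            continue
        if r > threshold_r and p < alpha:
            graph.add_edge(corr.regions[i], corr.regions[j], r=float(r), p=float(p))
    graph.graph["threshold_r"] = threshold_r
    graph.graph["alpha"] = alpha
    graph.graph["group"] = "/".join(corr.group)
    return graph


def _edge_weight(data: dict, weighted: bool) -> float:
    return float(data.get("r", 1.0)) if weighted else 1.0


def modularity(
    graph: nx.Graph,
    assignment: dict,
    weighted: bool = False,
    resolution: float = 1.0,
) -> float:
    """Q of a partition; 0 for a graph with no edges."""
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValidationError(f"assignment does not cover nodes: {missing}")
    m2 = sum(_edge_weight(d, weighted) for _, _, d in graph.edges(data=True)) * 2.0
    if m2 == 0:
        return 0.0
    internal: dict = {}
    tot: dict = {}
    for node in graph.nodes:
        c = assignment[node]
        strength = sum(
            _edge_weight(d, weighted) for _, _, d in graph.edges(node, data=True)
        )
        tot[c] = tot.get(c, 0.0) + strength
    for u, v, d in graph.edges(data=True):
        if assignment[u] == assignment[v]:
            internal[assignment[u]] = internal.get(assignment[u], 0.0) + _edge_weight(
                d, weighted
            )
    q = 0.0
    for c in tot:
        q += 2.0 * internal.get(c, 0.0) / m2 - resolution * (tot[c] / m2) ** 2
    return q


@dataclass
class CommunityPartition:
    assignment: dict  # node -> community id (0-based, relabeled contiguous)
    Q: float
    seed: int

    def communities(self) -> list[list]:
        out: dict = {}
        for node, c in self.assignment.items():
            out.setdefault(c, []).append(node)
        return [out[c] for c in sorted(out)]


def _louvain_level(
    adjacency: dict, rng: np.random.Generator, resolution: float = 1.0
) -> tuple[dict, bool]:
    """One local-move phase. adjacency: node -> {neighbor: weight}.

    Moves nodes (in seeded random sweep order) to the neighboring
    community with the largest positive modularity gain; on a tie with
    zero gain, or no positive gain, the node keeps its community.
    """
    nodes = list(adjacency)
    community = {v: i for i, v in enumerate(nodes)}
    strength = {v: sum(adjacency[v].values()) for v in nodes}
    m2 = sum(strength.values())  # = 2m
    if m2 == 0:
        return community, False
    tot = {community[v]: strength[v] for v in nodes}

    improved_any = False
    improved = True
    while improved:
        improved = False
        order = list(nodes)
        rng.shuffle(order)
        for v in order:
            c_old = community[v]
            k_v = strength[v]
            # weight from v to each neighboring community
            links: dict = {}
            for u, w in adjacency[v].items():
                if u != v:
                    links[community[u]] = links.get(community[u], 0.0) + w
            tot[c_old] -= k_v
            best_c, best_gain = c_old, 0.0
            base = links.get(c_old, 0.0) - resolution * k_v * tot[c_old] / m2
            for c, w_in in links.items():
                if c == c_old:
                    continue
                gain = (w_in - resolution * k_v * tot[c] / m2) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            tot[best_c] += k_v
            if best_c != c_old:
                community[v] = best_c
                improved = True
                improved_any = True
    return community, improved_any


def _aggregate(adjacency: dict, community: dict) -> tuple[dict, dict]:
    """Collapse communities into super-nodes; self-loops keep internal weight."""
    agg: dict = {}
    for v, nbrs in adjacency.items():
        cv = community[v]
        agg.setdefault(cv, {})
        for u, w in nbrs.items():
            cu = community[u]
            agg[cv][cu] = agg[cv].get(cu, 0.0) + w
    return agg, {c: c for c in agg}


def detect_communities(
    graph: nx.Graph,
    seed: int = 0,
    weighted: bool = True,
    resolution: float = 1.0,
) -> CommunityPartition:
    """Two-phase modularity optimization (local moves + aggregation).

    Isolated nodes form singleton communities; a graph with no edges
    yields all singletons with Q defined as 0. The sweep order is
    randomized by the seed; the same seed always yields the same
    partition.
    """
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    adjacency: dict = {v: {} for v in nodes}
    for u, v, d in graph.edges(data=True):
        w = _edge_weight(d, weighted)
        adjacency[u][v] = adjacency[u].get(v, 0.0) + w
        adjacency[v][u] = adjacency[v].get(u, 0.0) + w

    # membership of original nodes in the current level's nodes
    member = {v: v for v in nodes}
    while True:
        community, moved = _louvain_level(adjacency, rng, resolution)
        member = {v: community[member[v]] for v in member}
        if not moved:
            break
        adjacency, _ = _aggregate(adjacency, community)

    labels = sorted(set(member.values()), key=lambda c: min(
        nodes.index(v) for v in member if member[v] == c
    ))
    relabel = {c: i for i, c in enumerate(labels)}
    assignment = {v: relabel[c] for v, c in member.items()}
    q = modularity(graph, assignment, weighted=weighted, resolution=resolution)
    return CommunityPartition(assignment=assignment, Q=q, seed=seed)


#: flags used in the node metrics table
ISOLATE = "isolate"
DEGENERATE_COMMUNITY = "degenerate_community"


def node_metrics(graph: nx.Graph, partition: CommunityPartition) -> pd.DataFrame:
    """Per-node degree, within-community z and participation coefficient.

    Columns: region, community, degree, within_degree, z, P, flags.
    z uses the population SD of within-community degrees over the node's
    community; communities of size 1 or zero SD give z = 0 with a
    degenerate flag, isolates give P = 0 with an isolate flag.
    """
    assignment = partition.assignment
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValidationError(f"partition does not cover nodes: {missing}")

    nodes = list(graph.nodes)
    communities = sorted(set(assignment.values()))
    kappa = {
        v: {c: 0 for c in communities} for v in nodes
    }  # edges from v into each community
    for u, v in graph.edges:
        kappa[u][assignment[v]] += 1
        kappa[v][assignment[u]] += 1

    within = {v: kappa[v][assignment[v]] for v in nodes}
    stats = {}
    for c in communities:
        vals = np.array([within[v] for v in nodes if assignment[v] == c], dtype=float)
        stats[c] = (len(vals), vals.mean(), vals.std(ddof=0))

    rows = []
    for v in nodes:
        k = int(graph.degree(v))
        c = assignment[v]
        size, mean_w, sd_w = stats[c]
        flags = []
        if k == 0:
            flags.append(ISOLATE)
        if size <= 1 or sd_w == 0:
            z = 0.0
            flags.append(DEGENERATE_COMMUNITY)
        else:
            z = (within[v] - mean_w) / sd_w
        if k == 0:
            P = 0.0
        else:
            P = 1.0 - sum((kappa[v][s] / k) ** 2 for s in communities)
        rows.append(
            {
                "region": v,
                "community": c,
                "degree": k,
                "within_degree": within[v],
                "z": float(z),
                "P": float(P),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def hub_table(
    metrics: pd.DataFrame,
    z_cutoff: float | None = None,
    p_cutoff: float | None = None,
) -> pd.DataFrame:
    """All nodes ranked by descending participation coefficient (ties:
    descending z, then region label). Optional user-supplied cutoffs add
    a boolean is_hub column; no default cutoffs are asserted.
    """
    ranked = metrics.sort_values(
        by=["P", "z", "region"], ascending=[False, False, True]
    ).reset_index(drop=True)
    if z_cutoff is not None or p_cutoff is not None:
        is_hub = pd.Series(True, index=ranked.index)
        if z_cutoff is not None:
            is_hub &= ranked["z"] >= z_cutoff
        if p_cutoff is not None:
            is_hub &= ranked["P"] >= p_cutoff
        ranked["is_hub"] = is_hub
    return ranked
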