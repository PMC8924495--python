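"""Co-activation graphs: extraction, centralities, communities.

A trained network's neurons become nodes of an undirected graph whose edge
weights are the Spearman rank correlations of the neurons' activation
values across a sample set.  Rank correlation is used because neuron
activations are not expected to relate linearly; edge weights live in
[-1, 1].  Community structure (Louvain) and centralities (weighted degree,
PageRank) then expose what the network has encoded: communities of
co-activating nodes play the role of relating relational networks, and
cross-community links carry properties such as a transfer of function from
one relational network to the next.

Centralities and Louvain run on absolute edge weights (the algorithms are
defined for non-negative weights); the signed weight is kept as an edge
attribute for reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .relnet import (
    TRANSFER_TYPES,
    FunctionProvenance,
    Provenance,
    RelationalNetwork,
    RelationType,
    derive_closure,
    transform_function,
)

# trained coordination/opposition transfer both ways once ME runs
_SYMMETRIC_TRANSFER = frozenset({RelationType.COORDINATION, RelationType.OPPOSITION})

logger = logging.getLogger(__name__)

__all__ = [
    "build_graph",
    "degree_centrality",
    "pagerank",
    "communities",
    "CrossCommunityReport",
    "relate_networks",
]


def build_graph(
    activations: np.ndarray,
    edge_threshold: float = 0.0,
    node_names=None,
) -> nx.Graph:
    """Spearman co-activation graph from a (neurons x samples) matrix.

    Edges with |weight| below ``edge_threshold`` are dropped; constant
    neurons (zero rank variance) have undefined correlations and their
    edges are dropped with a warning.  The result is symmetric with no
    self-edges; each edge carries ``weight`` (signed) and ``abs_weight``.
    """
    activations = np.asarray(activations, dtype=float)
    if activations.ndim != 2:
        raise ValueError("activations must be a 2-D (neurons x samples) matrix")
    n_neurons, n_samples = activations.shape
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    names = list(node_names) if node_names is not None else list(range(n_neurons))
    if len(names) != n_neurons:
        raise ValueError("one node name per neuron required")

    constant = np.array([np.allclose(row, row[0]) for row in activations])
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant neuron(s): their edges are undefined and dropped"
        )
    ranks = np.vstack([stats.rankdata(row) for row in activations])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)

    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i in range(n_neurons):
        for j in range(i + 1, n_neurons):
            if constant[i] or constant[j]:
                continue
            w = float(corr[i, j])
            if not np.isfinite(w) or abs(w) < edge_threshold:
                continue
            graph.add_edge(names[i], names[j], weight=w, abs_weight=abs(w))
    return graph


def degree_centrality(graph: nx.Graph) -> dict:
    """Weighted degree D(n_i) = sum_j |A_ij| over the thresholded graph."""
    return {node: float(deg) for node, deg in graph.degree(weight="abs_weight")}


def pagerank(
    graph: nx.Graph,
    d: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> dict:
    """Power-iteration PageRank on absolute edge weights.

    Scores start at 1/N and iterate
    PR(n_i) = (1-d)/N + d * sum_j A_ij PR(n_j) / D(n_j)
    until the L1 change falls below ``tol``; dangling nodes redistribute
    their mass uniformly, so converged scores sum to 1.
    """
    if not (0.0 < d < 1.0):
        raise ValueError("damping factor d must lie in (0, 1)")
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    index = {node: i for i, node in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = abs(data.get("weight", 1.0))
        A[index[u], index[v]] = w
        A[index[v], index[u]] = w
    deg = A.sum(axis=1)
    dangling = deg == 0
    pr = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        contrib = np.where(dangling, 0.0, pr / np.where(deg > 0, deg, 1.0))
        new = (1.0 - d) / n + d * (A @ contrib) + d * pr[dangling].sum() / n
        if np.abs(new - pr).sum() < tol:
            pr = new
            break
        pr = new
    return {node: float(pr[index[node]]) for node in nodes}


def communities(
    graph: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[dict, float]:
    """Louvain communities on |weights|; returns (labels, modularity Q).

    An edgeless graph yields singleton communities with Q = 0; the seed
    controls Louvain's tie-breaking.
    """
    if graph.number_of_edges() == 0:
        return {node: i for i, node in enumerate(graph.nodes)}, 0.0
    parts = nx.community.louvain_communities(
        graph, weight="abs_weight", resolution=resolution, seed=seed
    )
    labels = {}
    for cid, part in enumerate(sorted(parts, key=lambda p: sorted(map(str, p)))):
        for node in part:
            labels[node] = cid
    q = nx.community.modularity(
        graph, [ {n for n, c in labels.items() if c == cid} for cid in sorted(set(labels.values())) ],
        weight="abs_weight", resolution=resolution,
    )
    return labels, float(q)


# ---------------------------------------------------------------------------
# Relating relational networks
# ---------------------------------------------------------------------------

@dataclass
class CrossCommunityReport:
    """Summary of how community-labelled relational networks relate.

    ``edges`` rows: (community_a, community_b, relation type, aggregate
    trained strength), sorted by strength descending.  ``function_chains``
    maps each trained function name to the ordered list of communities it
    reaches via transformation of function (seed community first).
    """

    edges: list[tuple[str, str, str, float]] = field(default_factory=list)
    function_chains: dict[str, list[str]] = field(default_factory=dict)


def relate_networks(
    net: RelationalNetwork,
    active_context=None,
    max_path: int = 4,
) -> CrossCommunityReport:
    """Summarize inter-community structure of a labelled network.

    Trained relations whose endpoints sit in different communities are
    aggregated per (community pair, relation type); stimuli without a
    community label fall into an "unassigned" pseudo-community.  Function
    transfer direction is recovered by breadth-first distance from each
    trained function's seed stimulus over the derived closure.
    """
    work = net.copy()
    derive_closure(work, active_context, max_path=max_path)
    transform_function(work, active_context, run_derivation=False)

    def comm(sid: str) -> str:
        return work.communities.get(sid, "unassigned")

    agg: dict[tuple[str, str, str], float] = {}
    for rel in work.relations.values():
        if rel.provenance is not Provenance.TRAINED:
            continue
        ca, cb = comm(rel.source), comm(rel.target)
        if ca == cb:
            continue
        key = (ca, cb, rel.rtype.value)
        agg[key] = agg.get(key, 0.0) + rel.strength
    edges = sorted(
        [(a, b, t, s) for (a, b, t), s in agg.items()],
        key=lambda row: (-row[3], row[0], row[1], row[2]),
    )

    # breadth-first community order of each transferred function, following
    # the *trained* transfer-capable relations so hop distance is meaningful
    # (the closure collapses every chain to length one)
    ctx = frozenset(active_context or ())
    adjacency: dict[str, set[str]] = {}
    for rel in work.relations.values():
        if (
            rel.provenance is Provenance.TRAINED
            and rel.eligible(ctx)
            and rel.rtype in TRANSFER_TYPES
        ):
            adjacency.setdefault(rel.target, set()).add(rel.source)
            if rel.rtype in _SYMMETRIC_TRANSFER:
                adjacency.setdefault(rel.source, set()).add(rel.target)

    chains: dict[str, list[str]] = {}
    for func in work.functions.values():
        if func.provenance is not FunctionProvenance.TRAINED or not func.eligible(ctx):
            continue
        reached = {
            f.stimulus
            for f in work.functions.values()
            if f.name == func.name
        }
        order = [comm(func.stimulus)]
        frontier = {func.stimulus}
        seen = {func.stimulus}
        while frontier:
            nxt = set()
            for host in frontier:
                for receiver in adjacency.get(host, ()):  # direction of transfer
                    if receiver not in seen and receiver in reached:
                        nxt.add(receiver)
                        seen.add(receiver)
            for sid in sorted(nxt):
                c = comm(sid)
                if c not in order:
                    order.append(c)
            frontier = nxt
        chains[func.name] = order
    return CrossCommunityReport(edges=edges, function_chains=chains)
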