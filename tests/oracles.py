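"""Independent oracles used by the test-suite and the acceptance script.

Each oracle recomputes a quantity with a deliberately different algorithm
from the library implementation: explicit path enumeration with recursive
bracketing for the derivation closure, naive per-exemplar loops for the
GCM, manual rank-and-correlate Spearman, linear-system PageRank, and an
exact backprop gradient for the predictive-coding comparison.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from relcat.relnet import (
    Provenance,
    RelationType,
    RelationalNetwork,
    compose,
)


# ---------------------------------------------------------------------------
# Closure oracle: enumerate node paths, compose under every bracketing
# ---------------------------------------------------------------------------

def closure_oracle(
    net: RelationalNetwork,
    active_context=None,
    max_path: int = 4,
) -> set[tuple[str, str, str]]:
    """All (source, target, rtype) derivable from eligible trained edges.

    Brute force: the edge set is every eligible trained relation plus its
    inverse; every node sequence of up to ``max_path`` edges is enumerated
    explicitly, and a sequence yields a relation type if ANY bracketing of
    pairwise compositions is determinate (computed by a recursive split,
    CYK-style).  Mirrors the entailment semantics by a path-first algorithm
    completely unlike the engine's semi-naive worklist.
    """
    ctx = frozenset(active_context or ())
    edges: dict[tuple[str, str], set[RelationType]] = {}
    trained = set()
    for rel in net.relations.values():
        if rel.provenance is not Provenance.TRAINED:
            continue
        # any trained triple (eligible or not) is "not derived beyond training"
        trained.add((rel.source, rel.target, rel.rtype.value))
        if not rel.eligible(ctx):
            continue
        edges.setdefault((rel.source, rel.target), set()).add(rel.rtype)
        edges.setdefault((rel.target, rel.source), set()).add(rel.rtype.inverse)

    adjacency: dict[str, set[str]] = {}
    for (a, b) in edges:
        adjacency.setdefault(a, set()).add(b)

    @lru_cache(maxsize=None)
    def bracketings(types: tuple[RelationType, ...]) -> frozenset[RelationType]:
        if len(types) == 1:
            return frozenset(types)
        out = set()
        for split in range(1, len(types)):
            for left in bracketings(types[:split]):
                for right in bracketings(types[split:]):
                    combined = compose(left, right)
                    if combined is not None:
                        out.add(combined)
        return frozenset(out)

    derived: set[tuple[str, str, str]] = set()

    def extend(path_nodes: list[str], type_seq: list[tuple[RelationType, ...]]) -> None:
        if len(path_nodes) >= 2:
            for combo in itertools.product(*type_seq):
                for rtype in bracketings(tuple(combo)):
                    a, c = path_nodes[0], path_nodes[-1]
                    if a == c and rtype is not RelationType.COORDINATION:
                        continue
                    key = (a, c, rtype.value)
                    if key not in trained:
                        derived.add(key)
        if len(path_nodes) - 1 >= max_path:
            return
        for nxt in adjacency.get(path_nodes[-1], ()):  # repeat nodes allowed
            extend(path_nodes + [nxt], type_seq + [tuple(sorted(edges[(path_nodes[-1], nxt)], key=lambda t: t.value))])

    for start in net.stimuli:
        extend([start], [])
    return derived


def engine_derived_set(net: RelationalNetwork) -> set[tuple[str, str, str]]:
    """(source, target, rtype) of everything the engine marked derived.

    Triples that coincide with a trained relation (ignoring context tags)
    are excluded, matching the oracle's notion of "derived beyond training".
    """
    trained = {
        (r.source, r.target, r.rtype.value)
        for r in net.relations.values()
        if r.provenance is Provenance.TRAINED
    }
    return {
        (r.source, r.target, r.rtype.value)
        for r in net.relations.values()
        if r.provenance is not Provenance.TRAINED
    } - trained


# ---------------------------------------------------------------------------
# GCM oracle: naive double loop
# ---------------------------------------------------------------------------

def gcm_summed_similarity_oracle(space, probe, category) -> float:
    total = 0.0
    for coords, cat in zip(space.coords, space.categories):
        if cat != category:
            continue
        inner = 0.0
        for w, yx, yj in zip(space.weights, probe, coords):
            inner += w * abs(yx - yj) ** space.r
        dist = inner ** (1.0 / space.r)
        total += float(np.exp(-space.c * dist ** space.q))
    return total


def gcm_choice_oracle(space, probe) -> dict[str, float]:
    names = sorted(set(space.categories))
    ev = {cat: space.biases[cat] * gcm_summed_similarity_oracle(space, probe, cat) for cat in names}
    z = sum(ev.values())
    return {cat: v / z for cat, v in ev.items()}


# ---------------------------------------------------------------------------
# Spearman oracle: rank with average ties, then Pearson by hand
# ---------------------------------------------------------------------------

def average_ranks(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


# ---------------------------------------------------------------------------
# PageRank oracle: solve the stationary linear system directly
# ---------------------------------------------------------------------------

def pagerank_linear_oracle(adjacency: np.ndarray, d: float) -> np.ndarray:
    """Solve pr = (1-d)/N + d M pr exactly (no dangling nodes)."""
    A = np.abs(np.asarray(adjacency, dtype=float))
    n = A.shape[0]
    M = A / A.sum(axis=1, keepdims=True)
    return np.linalg.solve(np.eye(n) - d * M.T, np.full(n, (1.0 - d) / n))
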