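"""Synthetic fixtures and data generators.

Everything the other modules consume can be generated here, seeded and
deterministic:

* the worked relational networks (snake/woods/self in a negative- and a
  positive-self variant, the bachelor frame, the jogger frame),
* random *consistent* relational networks built from a latent class
  structure so that the derivation closure can never contradict itself,
* training corpora of (concept, relation-context, attribute) triples for
  the semantic network,
* block-correlated "planted community" activation matrices for the
  co-activation graph pipeline,
* confidence-scale tables with planted subgroup offsets for the two-stage
  cluster analysis.

Generated tabular artifacts are written as RFC-4180 CSV with a sidecar
metadata JSON recording the seed and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .relnet import (
    DerivationConfig,
    Modality,
    Provenance,
    Relation,
    RelationalNetwork,
    RelationType,
    Stimulus,
    StimulusFunction,
    Valence,
    derive_closure,
)

__all__ = [
    "ScenarioSpec",
    "SNAKE_WOODS_CONTEXT",
    "SCENARIO_NAMES",
    "build_fixture",
    "sample_triples",
    "planted_activation_matrix",
    "confidence_table",
    "write_table",
]

#: Contextual cues under which the snake/woods fixtures fully derive:
#: the comparison relations are gated by "dangerous", the fear function by
#: "snakes-in-woods", and the self-related coordination by "walking".
SNAKE_WOODS_CONTEXT = frozenset({"dangerous", "snakes-in-woods", "walking"})

SCENARIO_NAMES = (
    "snake-woods-negative-self",
    "snake-woods-positive-self",
    "bachelor",
    "jogger",
    "random",
)


@dataclass
class ScenarioSpec:
    """Parameters of a generated scenario.

    ``seed`` fixes all randomness; the size parameters only matter for the
    ``random`` scenario.  ``effect_size`` / ``noise_sd`` are defaults for
    generated participant tables.
    """

    name: str = "snake-woods-negative-self"
    seed: int = 0
    n_stimuli: int = 8
    n_relations: int = 12
    n_contexts: int = 2
    effect_size: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
            )


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------

def _snake_woods(negative_self: bool) -> RelationalNetwork:
    """Three-community snake/woods/self network.

    The snake community carries the trained fear function and the stripe
    comparisons; the woods community is linked to the snakes by a weak
    containment edge (strength 0.4) and to the verbal self by a strong
    coordination edge (strength 0.9), preserving the ordinal weak-vs-strong
    claim of the figure it emulates.  The self community couples the self to
    failure (negative variant) or success (positive variant) and to the two
    category outcomes "unsafe-and-avoid" / "unsafe-but-walk".
    """
    net = RelationalNetwork()
    snake_nodes = ["snake", "snake5", "snake3", "snake2", "fangs", "venom"]
    woods_nodes = ["woods", "walk-path", "trees", "undergrowth"]
    self_nodes = [
        "self", "failure", "success", "confidence",
        "unsafe-and-avoid", "unsafe-but-walk",
    ]
    for sid in snake_nodes:
        net.add_stimulus(Stimulus(sid, label=sid, modality=Modality.CONCEPT))
    for sid in woods_nodes:
        net.add_stimulus(Stimulus(sid, label=sid, modality=Modality.OBJECT))
    for sid in self_nodes:
        net.add_stimulus(Stimulus(sid, label=sid, modality=Modality.SELF))
    for sid in snake_nodes:
        net.communities[sid] = "snake"
    for sid in woods_nodes:
        net.communities[sid] = "woods"
    for sid in self_nodes:
        net.communities[sid] = "self"

    # snake community: the stripe-count danger ordering plus the class
    # hierarchy (a five-stripe snake is a *type of* snake; hierarchy rather
    # than coordination, so class membership never contradicts the ranking)
    net.relate("snake5", RelationType.COMPARISON_MORE, "snake3", 1.0, {"dangerous"})
    net.relate("snake3", RelationType.COMPARISON_MORE, "snake2", 1.0, {"dangerous"})
    net.relate("snake", RelationType.CONTAINMENT_INCLUDES, "snake5", 1.0)
    net.relate("snake", RelationType.CONTAINMENT_INCLUDES, "snake3", 1.0)
    net.relate("snake", RelationType.CONTAINMENT_INCLUDES, "snake2", 1.0)
    net.relate("snake", RelationType.COORDINATION, "fangs", 0.9)
    net.relate("snake", RelationType.COORDINATION, "venom", 0.9)
    net.relate("fangs", RelationType.COORDINATION, "venom", 0.9)

    # weak snake->woods containment (edge "a"), strong woods<->self link (edge "b")
    net.relate("woods", RelationType.CONTAINMENT_INCLUDES, "snake", 0.4, {"snakes-in-woods"})
    net.relate("woods", RelationType.CONTAINMENT_INCLUDES, "walk-path", 1.0)
    net.relate("woods", RelationType.CONTAINMENT_INCLUDES, "trees", 1.0)
    net.relate("woods", RelationType.CONTAINMENT_INCLUDES, "undergrowth", 1.0)
    net.relate("trees", RelationType.COORDINATION, "undergrowth", 0.9)
    net.relate("walk-path", RelationType.COORDINATION, "undergrowth", 0.9)
    net.relate("self", RelationType.COORDINATION, "woods", 0.9, {"walking"})

    # verbal-self community
    strong, weak = (0.9, 0.2)
    failure_strength = strong if negative_self else weak
    success_strength = weak if negative_self else strong
    net.relate("self", RelationType.COORDINATION, "failure", failure_strength)
    net.relate("self", RelationType.COORDINATION, "success", success_strength)
    net.relate("success", RelationType.OPPOSITION, "failure", 1.0)
    net.relate("success", RelationType.COORDINATION, "confidence", 0.9)
    net.relate("failure", RelationType.COORDINATION, "unsafe-and-avoid", 0.9)
    net.relate("confidence", RelationType.COORDINATION, "unsafe-but-walk", 0.9)

    net.attach("snake", "fear", Valence.AVERSIVE, 1.0, {"snakes-in-woods"})
    net.attach("failure", "avoid-tendency", Valence.AVERSIVE, 1.0)
    net.attach("confidence", "approach-tendency", Valence.APPETITIVE, 1.0)
    return net


def _bachelor() -> RelationalNetwork:
    net = RelationalNetwork()
    for sid in ["bachelor", "male", "female", "married", "unmarried"]:
        net.add_stimulus(Stimulus(sid, label=sid))
    net.relate("bachelor", RelationType.COORDINATION, "male")
    net.relate("bachelor", RelationType.COORDINATION, "unmarried")
    net.relate("male", RelationType.DISTINCTION, "female")
    net.relate("married", RelationType.DISTINCTION, "unmarried")
    return net


def _jogger() -> RelationalNetwork:
    # Stand-in feature set: the scenario is illustrative, not a reproduction.
    net = RelationalNetwork()
    for sid in [
        "jogger", "expensive-trainers", "healthy-living", "fitness",
        "runs-weekly", "couch-potato",
    ]:
        net.add_stimulus(Stimulus(sid, label=sid))
    net.relate("jogger", RelationType.CONTAINMENT_INCLUDES, "healthy-living", 0.9)
    net.relate("jogger", RelationType.CONTAINMENT_INCLUDES, "fitness", 0.9)
    net.relate("jogger", RelationType.COORDINATION, "runs-weekly", 0.9)
    net.relate("jogger", RelationType.COORDINATION, "expensive-trainers", 0.7)
    net.relate("jogger", RelationType.OPPOSITION, "couch-potato", 0.8)
    net.attach("healthy-living", "approach-tendency", Valence.APPETITIVE, 1.0)
    return net


# ---------------------------------------------------------------------------
# Random consistent networks
# ---------------------------------------------------------------------------

def _random_network(spec: ScenarioSpec) -> RelationalNetwork:
    """Random relational network that is consistent by construction.

    Stimuli are partitioned into latent classes; coordination holds within a
    class, comparison follows a strict class-level rank, opposition pairs up
    polarity-opposed classes of equal rank, containment follows a strict
    class order in a disjoint class group, and distinction links otherwise
    unrelated classes.  Because every trained relation respects the latent
    structure, the derivation closure cannot produce a contradictory pair.
    """
    rng = np.random.default_rng(spec.seed)
    n = max(2, spec.n_stimuli)
    net = RelationalNetwork()
    ids = [f"s{i}" for i in range(n)]
    for sid in ids:
        net.add_stimulus(Stimulus(sid, label=sid))

    n_classes = int(rng.integers(2, max(3, n // 2 + 1)))
    classes = [int(rng.integers(0, n_classes)) for _ in range(n)]
    members: dict[int, list[str]] = {}
    for sid, cls in zip(ids, classes):
        members.setdefault(cls, []).append(sid)
    class_list = sorted(members)

    # split class groups: comparison-ranked vs containment-ordered
    group = {cls: ("cmp" if rng.random() < 0.6 else "cont") for cls in class_list}
    perm = rng.permutation(len(class_list))
    rank = {cls: float(perm[i]) for i, cls in enumerate(class_list)}
    # opposition axes: pair up some comparison classes and force equal rank
    opp_partner: dict[int, int] = {}
    cmp_classes = [c for c in class_list if group[c] == "cmp"]
    rng.shuffle(cmp_classes)
    for a, b in zip(cmp_classes[0::2], cmp_classes[1::2]):
        if rng.random() < 0.5:
            opp_partner[a], opp_partner[b] = b, a
            rank[b] = rank[a]

    contexts = [f"ctx{i}" for i in range(max(1, spec.n_contexts))]

    def tags() -> frozenset[str]:
        if rng.random() < 0.3:
            return frozenset({contexts[int(rng.integers(0, len(contexts)))]})
        return frozenset()

    attempts, added = 0, 0
    target = spec.n_relations
    while added < target and attempts < 50 * target:
        attempts += 1
        xi, yi = rng.choice(n, size=2, replace=False)
        x, y = ids[int(xi)], ids[int(yi)]
        cx, cy = classes[int(xi)], classes[int(yi)]
        if cx == cy:
            rtype = RelationType.COORDINATION
        elif opp_partner.get(cx) == cy:
            rtype = RelationType.OPPOSITION
        elif group[cx] == group[cy] == "cmp" and rank[cx] != rank[cy]:
            if rank[cx] > rank[cy]:
                rtype = RelationType.COMPARISON_MORE
            else:
                rtype = RelationType.COMPARISON_LESS
        elif group[cx] == group[cy] == "cont" and rank[cx] != rank[cy]:
            if rank[cx] > rank[cy]:
                rtype = RelationType.CONTAINMENT_INCLUDES
            else:
                rtype = RelationType.CONTAINMENT_BELONGS_TO
        else:
            rtype = RelationType.DISTINCTION
        strength = float(np.round(rng.uniform(0.3, 1.0), 3))
        try:
            net.relate(x, rtype, y, strength, tags())
            added += 1
        except Exception:
            continue

    # a couple of trained functions on random stimuli
    for _ in range(max(1, n // 4)):
        sid = str(rng.choice(ids))
        valence = Valence.AVERSIVE if rng.random() < 0.5 else Valence.APPETITIVE
        name = f"func-{sid}"
        if (sid, name) not in net.functions:
            net.attach(sid, name, valence, float(np.round(rng.uniform(0.5, 1.5), 3)))
    return net


def build_fixture(spec: ScenarioSpec | str, seed: int | None = None) -> RelationalNetwork:
    """Build a named scenario network; deterministic per (name, seed)."""
    if isinstance(spec, str):
        spec = ScenarioSpec(name=spec, seed=seed or 0)
    net = {
        "snake-woods-negative-self": lambda: _snake_woods(negative_self=True),
        "snake-woods-positive-self": lambda: _snake_woods(negative_self=False),
        "bachelor": _bachelor,
        "jogger": _jogger,
        "random": lambda: _random_network(spec),
    }[spec.name]()
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Training triples
# ---------------------------------------------------------------------------

def network_triples(
    net: RelationalNetwork,
    active_context: frozenset[str] | None = None,
    include_derived: bool = True,
    max_path: int = 4,
) -> list[tuple[str, str, str]]:
    """The ground-truth (concept, relation-context, attribute) triples.

    Relations contribute (source, rtype, target); functions contribute
    (stimulus, "function", name).  When ``include_derived`` the closure is
    taken first, so the triples express everything the network entails.
    """
    work = net.copy()
    if include_derived:
        derive_closure(work, active_context, max_path=max_path)
    rows = [
        (r.source, r.rtype.value, r.target)
        for r in work.relations.values()
        if r.eligible(frozenset(active_context or ()))
    ]
    rows += [(f.stimulus, "function", f.name) for f in work.functions.values()]
    return sorted(set(rows))


def sample_triples(
    net: RelationalNetwork,
    n: int,
    seed: int = 0,
    noise: float = 0.0,
    active_context: frozenset[str] | None = None,
    class_balanced: bool = False,
) -> pd.DataFrame:
    """Sample a training corpus of triples from the network's closure.

    ``noise`` is the probability that a row's attribute is replaced by a
    uniformly random *wrong* attribute.  ``class_balanced`` balances rows
    across relation-context classes.  Byte-identical per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    truth = network_triples(net, active_context)
    if not truth:
        raise ValueError("cannot sample triples from an empty network")
    rng = np.random.default_rng(seed)
    attributes = sorted({t[2] for t in truth})

    if class_balanced:
        by_rel: dict[str, list[tuple[str, str, str]]] = {}
        for t in truth:
            by_rel.setdefault(t[1], []).append(t)
        rel_names = sorted(by_rel)
        picks = []
        for i in range(n):
            rel = rel_names[i % len(rel_names)]
            rows = by_rel[rel]
            picks.append(rows[int(rng.integers(0, len(rows)))])
    else:
        picks = [truth[int(rng.integers(0, len(truth)))] for _ in range(n)]

    records = []
    for concept, rel, attr in picks:
        noisy = 0
        if noise > 0 and rng.random() < noise:
            wrong = [a for a in attributes if a != attr]
            if wrong:
                attr = wrong[int(rng.integers(0, len(wrong)))]
                noisy = 1
        records.append({"concept": concept, "relation": rel, "attribute": attr, "noisy": noisy})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Planted activation matrices
# ---------------------------------------------------------------------------

def planted_activation_matrix(
    n_neurons: int,
    n_samples: int,
    k_communities: int,
    within_rho: float,
    between_rho: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-correlated activations with per-neuron monotone distortions.

    Samples are drawn from a Gaussian with an equicorrelation block
    structure (``within_rho`` inside a community, ``between_rho`` across),
    then each neuron is passed through a randomly chosen strictly monotone
    transform so only the rank structure survives — which is precisely what
    a rank (Spearman) co-activation graph should recover.

    Returns ``(activations, labels)`` with activations shaped
    (n_neurons, n_samples) and integer community labels per neuron.
    """
    if not (0.0 <= between_rho < within_rho <= 1.0):
        raise ValueError("need 0 <= between_rho < within_rho <= 1")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k_communities), int(np.ceil(n_neurons / k_communities)))[:n_neurons]
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, within_rho, between_rho)
    np.fill_diagonal(corr, 1.0)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("infeasible correlation matrix (not positive semidefinite)")
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_neurons))
    z = chol @ rng.standard_normal((n_neurons, n_samples))

    transforms = [
        lambda v: v,
        lambda v: np.exp(v),
        lambda v: v ** 3,
        lambda v: 1.0 / (1.0 + np.exp(-2.0 * v)),
        lambda v: np.sign(v) * np.sqrt(np.abs(v)),
    ]
    for i in range(n_neurons):
        z[i] = transforms[int(rng.integers(0, len(transforms)))](z[i])
    return z, labels


# ---------------------------------------------------------------------------
# Confidence tables
# ---------------------------------------------------------------------------

def confidence_table(
    n_per_group: int,
    group_profiles: Sequence[Sequence[float]] | Mapping[str, Sequence[float]],
    seed: int = 0,
    noise_sd: float = 1.0,
    feature_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian confidence-scale table with planted standardized offsets.

    ``group_profiles`` gives one offset vector per group, in units of the
    per-feature noise standard deviation (so an offset of 1.0 is a planted
    effect size of ~1 pooled SD).  Returns the participant x feature table
    and the true group labels.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if isinstance(group_profiles, Mapping):
        profiles = [np.asarray(v, dtype=float) for v in group_profiles.values()]
    else:
        profiles = [np.asarray(v, dtype=float) for v in group_profiles]
    if len(profiles) < 2:
        raise ValueError("need at least 2 groups")
    n_features = len(profiles[0])
    if n_features < 2 or any(len(p) != n_features for p in profiles):
        raise ValueError("need >= 2 features, identical length across groups")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for g, profile in enumerate(profiles):
        block = profile[None, :] * noise_sd + rng.normal(
            0.0, noise_sd, size=(n_per_group, n_features)
        )
        blocks.append(block)
        labels.extend([g] * n_per_group)
    names = list(feature_names) if feature_names else [f"item{j+1}" for j in range(n_features)]
    table = pd.DataFrame(np.vstack(blocks), columns=names)
    return table, np.asarray(labels)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, seed: int | None = None, **params) -> None:
    """Write CSV plus a sidecar ``<path>.meta.json`` (seed + parameters)."""
    path = str(path)
    df.to_csv(path, index=False, lineterminator="\n")
    meta = {"seed": seed, "parameters": params, "n_rows": int(df.shape[0]), "n_cols": int(df.shape[1])}
    with open(path + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
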