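"""Relational-frame knowledge store and inference engine.

Relational Frame Theory (RFT) treats language and higher cognition as
contextually controlled relational responding between stimuli.  A trained
relation such as "a five-stripe snake is *more dangerous* than a three-stripe
snake" supports three kinds of derived responding:

* **Mutual entailment (ME)** — the inverse relation is derived for free
  (the three-stripe snake is *less dangerous* than the five-stripe one).
* **Combinatorial entailment (CE)** — relations compose along chains
  (A more B, B more C therefore A more C, and C less A by ME).
* **Transformation of stimulus function (ToF)** — behavioural functions
  (fear, approach, avoidance...) attached to one stimulus propagate to
  related stimuli, modulated by the relation type: copied across
  coordination, valence-flipped across opposition, amplified or attenuated
  across comparison, and passed from contained member to container.

All derivation is gated by contextual cues: a relation or function with
context tags only participates when at least one tag is in the active
context (empty tags mean context-free).

The module also computes the hyperdimensional multi-level (HDML) metrics —
coherence, complexity, derivation level, and flexibility — that describe a
relational network as a measured object rather than a constraint system.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "RelationType",
    "Modality",
    "Valence",
    "Provenance",
    "FunctionProvenance",
    "Stimulus",
    "Relation",
    "StimulusFunction",
    "RelationalNetwork",
    "HdmlReport",
    "DerivationConfig",
    "ValidationError",
    "compose",
    "derive_mutual_entailment",
    "derive_combinatorial_entailment",
    "derive_closure",
    "transform_function",
    "categorize_by_knowledge",
    "hdml_metrics",
]


class ValidationError(ValueError):
    """Raised when a network document violates a structural invariant."""


class Modality(str, Enum):
    CONCEPT = "concept"
    OBJECT = "object"
    WORD = "word"
    SELF = "self"


class RelationType(str, Enum):
    """The relational frames the engine understands.

    ``inverse`` gives the mutually entailed frame; ``compose`` combines two
    frames along a chain (returning ``None`` when the combination is
    indeterminate — e.g. distinction composes with nothing, and deictic
    frames are stored but never composed).
    """

    COORDINATION = "coordination"
    DISTINCTION = "distinction"
    OPPOSITION = "opposition"
    COMPARISON_MORE = "comparison-more"
    COMPARISON_LESS = "comparison-less"
    CONTAINMENT_INCLUDES = "containment-includes"
    CONTAINMENT_BELONGS_TO = "containment-belongs-to"
    DEICTIC = "deictic"

    @property
    def inverse(self) -> "RelationType":
        return _INVERSE[self]


_INVERSE = {
    RelationType.COORDINATION: RelationType.COORDINATION,
    RelationType.DISTINCTION: RelationType.DISTINCTION,
    RelationType.OPPOSITION: RelationType.OPPOSITION,
    RelationType.COMPARISON_MORE: RelationType.COMPARISON_LESS,
    RelationType.COMPARISON_LESS: RelationType.COMPARISON_MORE,
    RelationType.CONTAINMENT_INCLUDES: RelationType.CONTAINMENT_BELONGS_TO,
    RelationType.CONTAINMENT_BELONGS_TO: RelationType.CONTAINMENT_INCLUDES,
    RelationType.DEICTIC: RelationType.DEICTIC,
}

# Minimal composition algebra consistent with the in-scope worked examples:
# coordination is the identity, opposition is an involution, comparison and
# containment compose transitively with themselves, everything else is
# indeterminate (distinction and deictic never compose).
_COMPOSE: dict[tuple[RelationType, RelationType], RelationType] = {}
for _t in RelationType:
    if _t in (RelationType.DISTINCTION, RelationType.DEICTIC):
        continue
    _COMPOSE[(RelationType.COORDINATION, _t)] = _t
    _COMPOSE[(_t, RelationType.COORDINATION)] = _t
_COMPOSE[(RelationType.OPPOSITION, RelationType.OPPOSITION)] = RelationType.COORDINATION
_COMPOSE[(RelationType.COMPARISON_MORE, RelationType.COMPARISON_MORE)] = RelationType.COMPARISON_MORE
_COMPOSE[(RelationType.COMPARISON_LESS, RelationType.COMPARISON_LESS)] = RelationType.COMPARISON_LESS
_COMPOSE[(RelationType.CONTAINMENT_INCLUDES, RelationType.CONTAINMENT_INCLUDES)] = RelationType.CONTAINMENT_INCLUDES
_COMPOSE[(RelationType.CONTAINMENT_BELONGS_TO, RelationType.CONTAINMENT_BELONGS_TO)] = RelationType.CONTAINMENT_BELONGS_TO


def compose(a: RelationType, b: RelationType) -> RelationType | None:
    """Compose two relation types along a chain; ``None`` = indeterminate."""
    return _COMPOSE.get((a, b))


class Provenance(str, Enum):
    TRAINED = "trained"
    DERIVED_ME = "derived-ME"
    DERIVED_CE = "derived-CE"


class Valence(str, Enum):
    APPETITIVE = "appetitive"
    AVERSIVE = "aversive"
    NEUTRAL = "neutral"

    @property
    def flipped(self) -> "Valence":
        if self is Valence.APPETITIVE:
            return Valence.AVERSIVE
        if self is Valence.AVERSIVE:
            return Valence.APPETITIVE
        return Valence.NEUTRAL


class FunctionProvenance(str, Enum):
    TRAINED = "trained"
    TRANSFERRED = "transferred"


@dataclass(frozen=True)
class Stimulus:
    id: str
    label: str = ""
    modality: Modality = Modality.CONCEPT

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("stimulus id must be non-empty")


@dataclass(frozen=True)
class Relation:
    """A typed, context-gated relation between two stimuli.

    ``context_tags`` are the C_rel cues: the relation participates in
    derivation only when tag-free or when a tag is in the active context.
    ``emission_count`` counts how often a derived relation has been
    re-emitted; it feeds the HDML derivation-level metric.
    """

    source: str
    target: str
    rtype: RelationType
    strength: float = 1.0
    provenance: Provenance = Provenance.TRAINED
    context_tags: frozenset[str] = frozenset()
    emission_count: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ValidationError(
                f"relation strength {self.strength!r} outside [0, 1]"
            )
        if self.source == self.target and self.rtype is not RelationType.COORDINATION:
            raise ValidationError(
                f"self-relation {self.source!r} must be coordination, not {self.rtype.value}"
            )
        if self.emission_count < 0:
            raise ValidationError("emission_count must be non-negative")
        object.__setattr__(self, "context_tags", frozenset(self.context_tags))

    @property
    def key(self) -> tuple[str, str, RelationType, frozenset[str]]:
        return (self.source, self.target, self.rtype, self.context_tags)

    def eligible(self, active_context: frozenset[str]) -> bool:
        return not self.context_tags or bool(self.context_tags & active_context)


@dataclass(frozen=True)
class StimulusFunction:
    """A behavioural function (e.g. "fear") attached to a stimulus.

    ``context_tags`` are the C_func cues gating whether the function is
    active / transferable in the current context.
    """

    stimulus: str
    name: str
    valence: Valence = Valence.NEUTRAL
    magnitude: float = 1.0
    context_tags: frozenset[str] = frozenset()
    provenance: FunctionProvenance = FunctionProvenance.TRAINED

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValidationError("function magnitude must be >= 0")
        object.__setattr__(self, "context_tags", frozenset(self.context_tags))

    @property
    def key(self) -> tuple[str, str]:
        return (self.stimulus, self.name)

    def eligible(self, active_context: frozenset[str]) -> bool:
        return not self.context_tags or bool(self.context_tags & active_context)


@dataclass
class DerivationConfig:
    """Tunable decay/gain constants for derivation and function transfer.

    me_decay   strength multiplier per mutual-entailment inversion.
    ce_decay   per-extra-edge strength decay of combinatorial chains
               (strength = product of chain strengths * ce_decay**(len-1)).
    tof_decay  magnitude multiplier per coordination/opposition/containment
               hop of a transferred function.
    comp_gain  magnitude multiplier across a "more" comparison hop (>= 1);
               "less" hops divide by it.  Comparison hops use comp_gain
               instead of tof_decay so a function transferred up a
               comparison relation really is stronger at its destination.
    """

    me_decay: float = 1.0
    ce_decay: float = 0.9
    tof_decay: float = 0.8
    comp_gain: float = 1.25
    max_hops: int = 6


@dataclass
class RelationalNetwork:
    """The RFT knowledge store: stimuli, relations, functions, communities."""

    stimuli: dict[str, Stimulus] = field(default_factory=dict)
    relations: dict[tuple, Relation] = field(default_factory=dict)
    functions: dict[tuple, StimulusFunction] = field(default_factory=dict)
    communities: dict[str, str] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def add_stimulus(self, stim: Stimulus | str, **kwargs) -> Stimulus:
        if isinstance(stim, str):
            stim = Stimulus(id=stim, **kwargs)
        if stim.id in self.stimuli:
            raise ValidationError(f"duplicate stimulus id {stim.id!r}")
        self.stimuli[stim.id] = stim
        return stim

    def add_relation(self, rel: Relation) -> Relation:
        self._check_endpoint(rel.source)
        self._check_endpoint(rel.target)
        if rel.key in self.relations:
            raise ValidationError(f"duplicate relation {rel.key!r}")
        self.relations[rel.key] = rel
        return rel

    def relate(
        self,
        source: str,
        rtype: RelationType | str,
        target: str,
        strength: float = 1.0,
        context_tags: Iterable[str] = (),
        provenance: Provenance = Provenance.TRAINED,
    ) -> Relation:
        return self.add_relation(
            Relation(
                source=source,
                target=target,
                rtype=RelationType(rtype),
                strength=strength,
                provenance=provenance,
                context_tags=frozenset(context_tags),
            )
        )

    def add_function(self, func: StimulusFunction) -> StimulusFunction:
        self._check_endpoint(func.stimulus)
        self.functions[func.key] = func
        return func

    def attach(
        self,
        stimulus: str,
        name: str,
        valence: Valence | str = Valence.NEUTRAL,
        magnitude: float = 1.0,
        context_tags: Iterable[str] = (),
    ) -> StimulusFunction:
        return self.add_function(
            StimulusFunction(
                stimulus=stimulus,
                name=name,
                valence=Valence(valence),
                magnitude=magnitude,
                context_tags=frozenset(context_tags),
            )
        )

    def _check_endpoint(self, sid: str) -> None:
        if sid not in self.stimuli:
            raise ValidationError(f"unknown stimulus id {sid!r}")

    # -- views ------------------------------------------------------------
    @property
    def trained_relations(self) -> list[Relation]:
        return [r for r in self.relations.values() if r.provenance is Provenance.TRAINED]

    @property
    def derived_relations(self) -> list[Relation]:
        return [r for r in self.relations.values() if r.provenance is not Provenance.TRAINED]

    def validate(self) -> None:
        for rel in self.relations.values():
            self._check_endpoint(rel.source)
            self._check_endpoint(rel.target)
        for func in self.functions.values():
            self._check_endpoint(func.stimulus)
        for sid in self.communities:
            self._check_endpoint(sid)

    # -- JSON document dialect --------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stimuli": [
                {"id": s.id, "label": s.label, "modality": s.modality.value}
                for s in sorted(self.stimuli.values(), key=lambda s: s.id)
            ],
            "relations": [
                {
                    "source": r.source,
                    "target": r.target,
                    "rtype": r.rtype.value,
                    "strength": r.strength,
                    "provenance": r.provenance.value,
                    "context_tags": sorted(r.context_tags),
                    "emission_count": r.emission_count,
                }
                for r in sorted(
                    self.relations.values(),
                    key=lambda r: (r.source, r.target, r.rtype.value, sorted(r.context_tags)),
                )
            ],
            "functions": [
                {
                    "stimulus": f.stimulus,
                    "name": f.name,
                    "valence": f.valence.value,
                    "magnitude": f.magnitude,
                    "context_tags": sorted(f.context_tags),
                    "provenance": f.provenance.value,
                }
                for f in sorted(self.functions.values(), key=lambda f: (f.stimulus, f.name))
            ],
            "communities": dict(sorted(self.communities.items())),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RelationalNetwork":
        net = cls()
        for s in doc.get("stimuli", []):
            net.add_stimulus(
                Stimulus(id=s["id"], label=s.get("label", ""), modality=Modality(s.get("modality", "concept")))
            )
        for r in doc.get("relations", []):
            try:
                rtype = RelationType(r["rtype"])
            except ValueError as exc:
                raise ValidationError(f"unknown relation type {r['rtype']!r}") from exc
            net.add_relation(
                Relation(
                    source=r["source"],
                    target=r["target"],
                    rtype=rtype,
                    strength=float(r.get("strength", 1.0)),
                    provenance=Provenance(r.get("provenance", "trained")),
                    context_tags=frozenset(r.get("context_tags", [])),
                    emission_count=int(r.get("emission_count", 0)),
                )
            )
        for f in doc.get("functions", []):
            net.add_function(
                StimulusFunction(
                    stimulus=f["stimulus"],
                    name=f["name"],
                    valence=Valence(f.get("valence", "neutral")),
                    magnitude=float(f.get("magnitude", 1.0)),
                    context_tags=frozenset(f.get("context_tags", [])),
                    provenance=FunctionProvenance(f.get("provenance", "trained")),
                )
            )
        for sid, cid in doc.get("communities", {}).items():
            net._check_endpoint(sid)
            net.communities[sid] = cid
        return net

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RelationalNetwork":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        return cls.from_dict(doc)

    def write_edge_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "rtype", "strength", "provenance"])
            for r in sorted(
                self.relations.values(),
                key=lambda r: (r.source, r.target, r.rtype.value, sorted(r.context_tags)),
            ):
                writer.writerow([r.source, r.target, r.rtype.value, f"{r.strength:.10g}", r.provenance.value])

    def copy(self) -> "RelationalNetwork":
        clone = RelationalNetwork()
        clone.stimuli = dict(self.stimuli)
        clone.relations = dict(self.relations)
        clone.functions = dict(self.functions)
        clone.communities = dict(self.communities)
        return clone


# ---------------------------------------------------------------------------
# Derivation engine
# ---------------------------------------------------------------------------

def _as_context(active_context: Iterable[str] | None) -> frozenset[str]:
    return frozenset(active_context or ())


def derive_mutual_entailment(
    net: RelationalNetwork,
    active_context: Iterable[str] | None = None,
    config: DerivationConfig | None = None,
    _emitted: set | None = None,
) -> list[Relation]:
    """Derive the ME inverse (B, inv(R), A) of every eligible relation.

    Idempotent: re-deriving adds nothing new (but bumps the emission count
    of re-emitted relations — once per derivation pass — which lowers
    their HDML derivation level).
    """
    net.validate()
    config = config or DerivationConfig()
    ctx = _as_context(active_context)
    emitted = set() if _emitted is None else _emitted
    new: list[Relation] = []
    for rel in list(net.relations.values()):
        if not rel.eligible(ctx):
            continue
        inv = Relation(
            source=rel.target,
            target=rel.source,
            rtype=rel.rtype.inverse,
            strength=min(1.0, rel.strength * config.me_decay),
            provenance=Provenance.DERIVED_ME,
            context_tags=rel.context_tags,
        )
        added = _emit(net, inv, emitted)
        if added is not None:
            new.append(added)
    return new


def _emit(net: RelationalNetwork, rel: Relation, emitted: set) -> Relation | None:
    """Insert a derived relation, or re-emit an existing one.

    A trained relation is never overwritten.  A derived relation enters
    with emission count 1; re-deriving it in a *later* pass bumps the
    count (at most once per pass, tracked through ``emitted``) and keeps
    the maximum strength over derivation routes.
    """
    existing = net.relations.get(rel.key)
    if existing is None:
        net.relations[rel.key] = replace(rel, emission_count=1)
        emitted.add(rel.key)
        return net.relations[rel.key]
    if existing.provenance is Provenance.TRAINED:
        return None
    bump = 0 if rel.key in emitted else 1
    emitted.add(rel.key)
    net.relations[rel.key] = replace(
        existing,
        strength=max(existing.strength, rel.strength),
        emission_count=existing.emission_count + bump,
    )
    return None


def derive_combinatorial_entailment(
    net: RelationalNetwork,
    active_context: Iterable[str] | None = None,
    max_path: int = 4,
    config: DerivationConfig | None = None,
) -> list[Relation]:
    """Fixed-point CE closure over eligible relations.

    Chains A-R1-B-R2-C with a determinate composed type emit
    (A, R1∘R2, C) and its ME inverse.  Derived strength is the product of
    the underlying trained strengths times ``ce_decay**(path_len - 1)``.
    Indeterminate compositions are skipped (debug-logged), never emitted.
    Terminates: stimuli are finite and the derived set only grows.
    """
    if max_path < 2:
        raise ValueError("max_path must be >= 2")
    net.validate()
    config = config or DerivationConfig()
    ctx = _as_context(active_context)

    # Working items: (source, target, rtype, tags) -> (raw chain product, path length)
    # seeded with eligible trained relations and their ME inverses.
    emitted: set = set()
    derive_mutual_entailment(net, active_context, config, _emitted=emitted)
    items: dict[tuple, tuple[float, int]] = {}
    for rel in net.relations.values():
        # Seed with trained/ME edges at path length 1; CE relations from an
        # earlier run are re-derived from scratch (idempotence).
        if rel.provenance is Provenance.DERIVED_CE or not rel.eligible(ctx):
            continue
        old = items.get(rel.key)
        if old is None or rel.strength > old[0]:
            items[rel.key] = (rel.strength, 1)

    by_source: dict[str, set[tuple]] = {}
    by_target: dict[str, set[tuple]] = {}

    def index(key: tuple) -> None:
        by_source.setdefault(key[0], set()).add(key)
        by_target.setdefault(key[1], set()).add(key)

    for key in items:
        index(key)

    new_relations: list[Relation] = []
    frontier = list(items.keys())
    while frontier:
        next_frontier: list[tuple] = []
        for key in frontier:
            if key not in items:
                continue
            raw, length = items[key]
            src, tgt, rtype, tags = key
            # compose with items starting at tgt and items ending at src
            partners = [
                (key, other, True) for other in by_source.get(tgt, set())
            ] + [
                (other, key, False) for other in by_target.get(src, set())
            ]
            for left_key, right_key, _ in partners:
                if left_key not in items or right_key not in items:
                    continue
                lraw, llen = items[left_key]
                rraw, rlen = items[right_key]
                total_len = llen + rlen
                if total_len > max_path:
                    continue
                composed = compose(left_key[2], right_key[2])
                if composed is None:
                    logger.debug(
                        "indeterminate composition %s ∘ %s (%s → %s)",
                        left_key[2].value, right_key[2].value, left_key[0], right_key[1],
                    )
                    continue
                a, c = left_key[0], right_key[1]
                if a == c and composed is not RelationType.COORDINATION:
                    continue
                new_tags = left_key[3] | right_key[3]
                new_key = (a, c, composed, new_tags)
                new_raw = lraw * rraw
                old = items.get(new_key)
                if old is not None and old[1] <= total_len and old[0] >= new_raw:
                    continue
                if old is None:
                    items[new_key] = (new_raw, total_len)
                else:
                    items[new_key] = (max(old[0], new_raw), min(old[1], total_len))
                index(new_key)
                next_frontier.append(new_key)
        frontier = next_frontier

    # Materialize CE relations (anything with path length > 1) plus ME inverses.
    for (src, tgt, rtype, tags), (raw, length) in sorted(
        items.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value, sorted(kv[0][3]))
    ):
        if length <= 1:
            continue
        strength = min(1.0, raw * config.ce_decay ** (length - 1))
        rel = Relation(
            source=src, target=tgt, rtype=rtype, strength=strength,
            provenance=Provenance.DERIVED_CE, context_tags=tags,
        )
        added = _emit(net, rel, emitted)
        if added is not None:
            new_relations.append(added)
        inv = Relation(
            source=tgt, target=src, rtype=rtype.inverse,
            strength=min(1.0, strength * config.me_decay),
            provenance=Provenance.DERIVED_CE, context_tags=tags,
        )
        added = _emit(net, inv, emitted)
        if added is not None:
            new_relations.append(added)
    return new_relations


def derive_closure(
    net: RelationalNetwork,
    active_context: Iterable[str] | None = None,
    max_path: int = 4,
    config: DerivationConfig | None = None,
) -> RelationalNetwork:
    """Run ME + CE derivation in place and return the network."""
    derive_combinatorial_entailment(net, active_context, max_path=max_path, config=config)
    return net


# ---------------------------------------------------------------------------
# Transformation of stimulus function
# ---------------------------------------------------------------------------

#: Relation types able to carry a stimulus function from target to source.
TRANSFER_TYPES = frozenset({
    RelationType.COORDINATION,
    RelationType.OPPOSITION,
    RelationType.COMPARISON_MORE,
    RelationType.COMPARISON_LESS,
    RelationType.CONTAINMENT_INCLUDES,
})


# magnitude multiplier and valence action per relation type crossed from the
# function's current host X over a relation (Y, R, X): Y receives the function.
def _transfer_step(rtype: RelationType, config: DerivationConfig) -> tuple[float, bool] | None:
    if rtype is RelationType.COORDINATION:
        return config.tof_decay, False
    if rtype is RelationType.OPPOSITION:
        return config.tof_decay, True
    if rtype is RelationType.COMPARISON_MORE:
        return config.comp_gain, False
    if rtype is RelationType.COMPARISON_LESS:
        return 1.0 / config.comp_gain, False
    if rtype is RelationType.CONTAINMENT_INCLUDES:
        # (container, includes, member): function climbs member -> container
        return config.tof_decay, False
    return None  # belongs-to (container->member), distinction, deictic: no transfer


def transform_function(
    net: RelationalNetwork,
    active_context: Iterable[str] | None = None,
    config: DerivationConfig | None = None,
    run_derivation: bool = True,
    max_path: int = 4,
) -> list[StimulusFunction]:
    """Propagate stimulus functions across the (derived) relational network.

    Each eligible trained function seeds a breadth-first propagation over
    eligible relations incident to its host.  Per hop the magnitude is
    scaled by the relation-type factor (see :class:`DerivationConfig`) and
    opposition flips valence.  Propagation is bounded by ``config.max_hops``
    (a warning is logged on truncation); C_func cues gate the transfer step
    only.  Transferred functions carry ``provenance = transferred`` and the
    maximum-magnitude route wins when several routes reach one stimulus.
    """
    config = config or DerivationConfig()
    ctx = _as_context(active_context)
    if run_derivation:
        derive_closure(net, active_context, max_path=max_path, config=config)

    incoming: dict[str, list[Relation]] = {}
    for rel in net.relations.values():
        if rel.eligible(ctx):
            incoming.setdefault(rel.target, []).append(rel)

    # best (magnitude, valence) found per (stimulus, function name)
    best: dict[tuple[str, str], tuple[float, Valence]] = {}
    seeds = [
        f for f in net.functions.values()
        if f.provenance is FunctionProvenance.TRAINED and f.eligible(ctx)
    ]
    for seed in seeds:
        frontier = [(seed.stimulus, seed.magnitude, seed.valence, 0)]
        while frontier:
            next_frontier = []
            for host, mag, val, hops in frontier:
                if hops >= config.max_hops:
                    logger.warning(
                        "function %r truncated at %d hops (cycle bound)", seed.name, hops
                    )
                    continue
                for rel in incoming.get(host, []):
                    step = _transfer_step(rel.rtype, config)
                    if step is None:
                        continue
                    factor, flip = step
                    receiver = rel.source
                    if receiver == seed.stimulus:
                        continue
                    new_mag = mag * factor
                    new_val = val.flipped if flip else val
                    key = (receiver, seed.name)
                    old = best.get(key)
                    if old is not None and old[0] >= new_mag:
                        continue
                    best[key] = (new_mag, new_val)
                    next_frontier.append((receiver, new_mag, new_val, hops + 1))
            frontier = next_frontier

    transferred: list[StimulusFunction] = []
    for (stim, name), (mag, val) in sorted(best.items()):
        if (stim, name) in net.functions and net.functions[(stim, name)].provenance is FunctionProvenance.TRAINED:
            continue
        func = StimulusFunction(
            stimulus=stim, name=name, valence=val, magnitude=mag,
            context_tags=frozenset(), provenance=FunctionProvenance.TRANSFERRED,
        )
        net.functions[func.key] = func
        transferred.append(func)
    return transferred


# ---------------------------------------------------------------------------
# Knowledge-driven categorization
# ---------------------------------------------------------------------------

_POSITIVE_LINK = {
    RelationType.COORDINATION,
    RelationType.CONTAINMENT_INCLUDES,
    RelationType.CONTAINMENT_BELONGS_TO,
}
_NEGATIVE_LINK = {RelationType.DISTINCTION, RelationType.OPPOSITION}


def categorize_by_knowledge(
    net: RelationalNetwork,
    query_stimulus: str,
    candidate_categories: Sequence[str],
    active_context: Iterable[str] | None = None,
    config: DerivationConfig | None = None,
    max_path: int = 4,
) -> list[tuple[str, float]]:
    """Rank candidate category stimuli for a query under the active context.

    The score aggregates (a) derived coordination / containment strength
    from the query to the category (distinction and opposition count
    against), and (b) alignment of the signed function profiles transferred
    to the query and carried by the category (shared function names with
    matching valence raise the score; clashing valence lowers it).
    Deterministic given network + context; ties broken by category id.
    """
    if query_stimulus not in net.stimuli:
        raise ValidationError(f"query stimulus {query_stimulus!r} not in network")
    for cat in candidate_categories:
        if cat not in net.stimuli:
            raise ValidationError(f"candidate category {cat!r} not in network")
    config = config or DerivationConfig()
    ctx = _as_context(active_context)
    work = net.copy()
    transform_function(work, active_context, config=config, max_path=max_path)

    scores: dict[str, float] = {cat: 0.0 for cat in candidate_categories}
    for rel in work.relations.values():
        if rel.source != query_stimulus or rel.target not in scores:
            continue
        if not rel.eligible(ctx):
            continue
        if rel.rtype in _POSITIVE_LINK:
            scores[rel.target] += rel.strength
        elif rel.rtype in _NEGATIVE_LINK:
            scores[rel.target] -= rel.strength

    def signed(func: StimulusFunction) -> float:
        if func.valence is Valence.AVERSIVE:
            return -func.magnitude
        if func.valence is Valence.APPETITIVE:
            return func.magnitude
        return 0.0

    query_funcs = {
        f.name: signed(f) for f in work.functions.values() if f.stimulus == query_stimulus
    }
    for cat in candidate_categories:
        for f in work.functions.values():
            if f.stimulus != cat or f.name not in query_funcs:
                continue
            scores[cat] += query_funcs[f.name] * signed(f)

    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# HDML metrics
# ---------------------------------------------------------------------------

_CONFLICTS = [
    {RelationType.COMPARISON_MORE, RelationType.COMPARISON_LESS},
    {RelationType.COORDINATION, RelationType.DISTINCTION},
    {RelationType.COORDINATION, RelationType.OPPOSITION},
    {RelationType.CONTAINMENT_INCLUDES, RelationType.CONTAINMENT_BELONGS_TO},
]


@dataclass(frozen=True)
class HdmlReport:
    """Hyperdimensional multi-level metrics of a relational network.

    coherence        1 - contradictory / total derived ordered pairs.
    complexity       weighted count of the multi-level strata present
                     (mutual entailing < framing < networking-with-rules <
                     relating relations < relating relational networks).
    derivation_level 1 / (1 + emission count) per derived relation — a
                     freshly derived response is maximally "derived" and the
                     value decays as it is re-emitted.
    flexibility      fraction of relations whose context tags admit a
                     context override (i.e. are context-gated at all).
    """

    coherence: float
    complexity: float
    derivation_level: dict[tuple[str, str, str], float]
    flexibility: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.coherence <= 1.0):
            raise ValidationError("coherence outside [0, 1]")
        if self.complexity < 0:
            raise ValidationError("complexity must be >= 0")
        if not (0.0 <= self.flexibility <= 1.0):
            raise ValidationError("flexibility outside [0, 1]")
        for level in self.derivation_level.values():
            if not (0.0 < level <= 1.0):
                raise ValidationError("derivation levels must lie in (0, 1]")


def hdml_metrics(
    net: RelationalNetwork,
    active_context: Iterable[str] | None = None,
) -> HdmlReport:
    """Measure coherence, complexity, derivation and flexibility.

    Contradictions (the same ordered stimulus pair carrying clashing frame
    types under overlapping context) are *reported*, never auto-resolved.
    An empty network is maximally coherent (1.0) with zero complexity.
    """
    ctx = _as_context(active_context)
    derived = [r for r in net.derived_relations if r.eligible(ctx)]

    pair_types: dict[tuple[str, str], set[RelationType]] = {}
    for rel in derived:
        pair_types.setdefault((rel.source, rel.target), set()).add(rel.rtype)
    total_pairs = len(pair_types)
    contradictory = sum(
        1
        for types in pair_types.values()
        if any(conflict <= types for conflict in _CONFLICTS)
    )
    coherence = 1.0 if total_pairs == 0 else 1.0 - contradictory / total_pairs

    # Multi-level complexity: each stratum present contributes its level weight.
    levels_present = 0.0
    relations = [r for r in net.relations.values() if r.eligible(ctx)]
    if relations:
        levels_present += 1.0  # level 1: mutual entailing possible at all
    if len({r.rtype for r in relations}) >= 2:
        levels_present += 2.0  # level 2: framing across multiple frame types
    if any(r.provenance is Provenance.DERIVED_CE for r in relations):
        levels_present += 3.0  # level 3: networking (rule-like chains)
    if any(r.context_tags for r in relations):
        levels_present += 4.0  # level 4: relating relations under cue control
    if net.communities:
        comm = net.communities
        if any(
            comm.get(r.source) is not None
            and comm.get(r.target) is not None
            and comm[r.source] != comm[r.target]
            for r in relations
        ):
            levels_present += 5.0  # level 5: relating relational networks

    derivation_level = {
        (r.source, r.target, r.rtype.value): 1.0 / (1.0 + r.emission_count)
        for r in derived
    }

    all_relations = list(net.relations.values())
    flexibility = (
        0.0
        if not all_relations
        else sum(1 for r in all_relations if r.context_tags) / len(all_relations)
    )

    return HdmlReport(
        coherence=coherence,
        complexity=levels_present,
        derivation_level=derivation_level,
        flexibility=flexibility,
    )
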