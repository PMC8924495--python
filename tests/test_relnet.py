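"""Relational-frame engine: entailment, function transfer, HDML metrics."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import closure_oracle, engine_derived_set
from relcat.relnet import (
    DerivationConfig,
    Provenance,
    Relation,
    RelationType,
    RelationalNetwork,
    Stimulus,
    StimulusFunction,
    Valence,
    ValidationError,
    categorize_by_knowledge,
    compose,
    derive_closure,
    derive_combinatorial_entailment,
    derive_mutual_entailment,
    hdml_metrics,
    transform_function,
)
from relcat.scenarios import ScenarioSpec, build_fixture


def simple_net(*relations, functions=()):
    net = RelationalNetwork()
    ids = {r[0] for r in relations} | {r[2] for r in relations} | {f[0] for f in functions}
    for sid in sorted(ids):
        net.add_stimulus(Stimulus(sid))
    for src, rtype, tgt, *rest in relations:
        tags = rest[0] if rest else ()
        net.relate(src, rtype, tgt, context_tags=tags)
    for stim, name, valence, *rest in functions:
        tags = rest[0] if rest else ()
        net.attach(stim, name, valence, context_tags=tags)
    return net


class TestRelationTypeAlgebra:
    def test_inverse_is_involutive(self):
        for rtype in RelationType:
            assert rtype.inverse.inverse is rtype

    def test_coordination_self_inverse_comparisons_mutual(self):
        assert RelationType.COORDINATION.inverse is RelationType.COORDINATION
        assert RelationType.COMPARISON_MORE.inverse is RelationType.COMPARISON_LESS
        assert RelationType.COMPARISON_LESS.inverse is RelationType.COMPARISON_MORE

    def test_composition_table_defined_over_whole_enum(self):
        # total: every pair answers either a type or indeterminate (None)
        for a in RelationType:
            for b in RelationType:
                result = compose(a, b)
                assert result is None or isinstance(result, RelationType)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (RelationType.COORDINATION, RelationType.COMPARISON_MORE, RelationType.COMPARISON_MORE),
            (RelationType.OPPOSITION, RelationType.OPPOSITION, RelationType.COORDINATION),
            (RelationType.COORDINATION, RelationType.OPPOSITION, RelationType.OPPOSITION),
            (RelationType.COMPARISON_MORE, RelationType.COMPARISON_MORE, RelationType.COMPARISON_MORE),
            (RelationType.COMPARISON_MORE, RelationType.COMPARISON_LESS, None),
            (RelationType.CONTAINMENT_INCLUDES, RelationType.CONTAINMENT_INCLUDES, RelationType.CONTAINMENT_INCLUDES),
            (RelationType.DISTINCTION, RelationType.COORDINATION, None),
            (RelationType.DEICTIC, RelationType.DEICTIC, None),
        ],
    )
    def test_composition_cases(self, a, b, expected):
        assert compose(a, b) is expected


class TestValidation:
    def test_unknown_endpoint_rejected(self):
        net = RelationalNetwork()
        net.add_stimulus(Stimulus("a"))
        with pytest.raises(ValidationError):
            net.relate("a", RelationType.COORDINATION, "ghost")

    def test_strength_bounds(self):
        with pytest.raises(ValidationError):
            Relation(source="a", target="b", rtype=RelationType.COORDINATION, strength=1.2)

    def test_self_relation_only_coordination(self):
        with pytest.raises(ValidationError):
            Relation(source="a", target="a", rtype=RelationType.OPPOSITION)
        Relation(source="a", target="a", rtype=RelationType.COORDINATION)

    def test_unknown_relation_type_in_document(self):
        doc = {
            "stimuli": [{"id": "a"}, {"id": "b"}],
            "relations": [{"source": "a", "target": "b", "rtype": "sameness"}],
        }
        with pytest.raises(ValidationError):
            RelationalNetwork.from_dict(doc)


class TestMutualEntailment:
    def test_snake_comparison_inverts(self):
        net = simple_net(("snake5", RelationType.COMPARISON_MORE, "snake3", {"dangerous"}))
        derived = derive_mutual_entailment(net, {"dangerous"})
        assert [(r.source, r.target, r.rtype) for r in derived] == [
            ("snake3", "snake5", RelationType.COMPARISON_LESS)
        ]
        assert derived[0].provenance is Provenance.DERIVED_ME

    def test_coordination_is_symmetric(self):
        net = simple_net(("A", RelationType.COORDINATION, "B"))
        derived = derive_mutual_entailment(net)
        assert {(r.source, r.target, r.rtype) for r in derived} == {
            ("B", "A", RelationType.COORDINATION)
        }

    def test_empty_network_entails_nothing(self):
        assert derive_mutual_entailment(RelationalNetwork()) == []

    def test_me_strength_decay(self):
        net = simple_net(("A", RelationType.COORDINATION, "B"))
        net.relations[("A", "B", RelationType.COORDINATION, frozenset())] = Relation(
            "A", "B", RelationType.COORDINATION, strength=0.8
        )
        derived = derive_mutual_entailment(net, config=DerivationConfig(me_decay=0.5))
        assert derived[0].strength == pytest.approx(0.4)

    def test_context_gate_blocks_ineligible_relations(self):
        net = simple_net(("A", RelationType.COORDINATION, "B", {"school"}))
        assert derive_mutual_entailment(net, {"work"}) == []
        assert len(derive_mutual_entailment(net, {"school"})) == 1


class TestCombinatorialEntailment:
    def test_three_term_comparison_chain(self, three_snake_net):
        derive_combinatorial_entailment(three_snake_net, {"dangerous"})
        derived = engine_derived_set(three_snake_net)
        assert ("snake5", "snake2", "comparison-more") in derived
        assert ("snake2", "snake5", "comparison-less") in derived

    def test_equivalence_transitivity(self):
        net = simple_net(
            ("A", RelationType.COORDINATION, "B"),
            ("B", RelationType.COORDINATION, "C"),
        )
        derive_combinatorial_entailment(net)
        assert ("A", "C", "coordination") in engine_derived_set(net)

    def test_indeterminate_compositions_never_emitted(self):
        net = simple_net(
            ("A", RelationType.COMPARISON_MORE, "B"),
            ("B", RelationType.DISTINCTION, "C"),
        )
        derive_combinatorial_entailment(net)
        derived = engine_derived_set(net)
        assert all(pair != ("A", "C") for pair, *_ in [(d[:2], d) for d in derived])

    def test_max_path_must_allow_chains(self, three_snake_net):
        with pytest.raises(ValueError):
            derive_combinatorial_entailment(three_snake_net, max_path=1)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle_on_random_networks(self, seed):
        """Engine closure equals all-paths/all-bracketings enumeration."""
        net = build_fixture(ScenarioSpec(name="random", seed=seed, n_stimuli=8, n_relations=16))
        expected = closure_oracle(net, max_path=4)
        derive_closure(net, max_path=4)
        assert engine_derived_set(net) == expected

    def test_idempotent(self, three_snake_net):
        derive_closure(three_snake_net, {"dangerous"})
        once = {r.key for r in three_snake_net.relations.values()}
        derive_closure(three_snake_net, {"dangerous"})
        assert {r.key for r in three_snake_net.relations.values()} == once

    def test_derived_strength_below_min_constituent(self):
        net = simple_net(
            ("A", RelationType.COMPARISON_MORE, "B"),
            ("B", RelationType.COMPARISON_MORE, "C"),
        )
        net.relations.clear()
        net.relate("A", RelationType.COMPARISON_MORE, "B", 0.7)
        net.relate("B", RelationType.COMPARISON_MORE, "C", 0.9)
        derive_closure(net)
        ce = [r for r in net.derived_relations if (r.source, r.target) == ("A", "C")]
        assert ce and all(r.strength <= 0.7 + 1e-12 for r in ce)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), extra=st.sets(st.sampled_from(["ctx0", "ctx1"])))
    def test_context_monotonicity(self, seed, extra):
        """Enlarging the active context never removes a derived relation."""
        net = build_fixture(ScenarioSpec(name="random", seed=seed, n_stimuli=6, n_relations=10))
        small = net.copy()
        derive_closure(small, {"ctx0"})
        big = net.copy()
        derive_closure(big, {"ctx0"} | extra)
        assert engine_derived_set(small) <= engine_derived_set(big)


class TestTransformFunction:
    def test_fear_climbs_containment_to_woods(self, snake_woods, full_context):
        transferred = transform_function(snake_woods, full_context)
        fear = {f.stimulus: f for f in transferred if f.name == "fear"}
        assert "woods" in fear
        assert fear["woods"].provenance.value == "transferred"
        assert fear["woods"].valence is Valence.AVERSIVE

    def test_avoidance_reaches_the_self(self, snake_woods, full_context):
        transferred = transform_function(snake_woods, full_context)
        avoid = {f.stimulus for f in transferred if f.name == "avoid-tendency"}
        assert "self" in avoid

    def test_comparison_amplifies_fear(self):
        """Fear established to A grows when transferred across (B more A)."""
        net = simple_net(
            ("B", RelationType.COMPARISON_MORE, "A"),
            functions=[("A", "shock-fear", Valence.AVERSIVE)],
        )
        transferred = transform_function(net)
        fear_b = next(f for f in transferred if f.stimulus == "B")
        assert fear_b.magnitude > net.functions[("A", "shock-fear")].magnitude

    def test_closed_context_gate_blocks_transfer(self):
        net = simple_net(
            ("woods", RelationType.CONTAINMENT_INCLUDES, "snake"),
            functions=[("snake", "fear", Valence.AVERSIVE, {"snakes-in-woods"})],
        )
        assert transform_function(net, active_context=set()) == []

    def test_opposition_flips_valence_twice_restores(self):
        net = simple_net(
            ("B", RelationType.OPPOSITION, "A"),
            ("C", RelationType.OPPOSITION, "B"),
            functions=[("A", "dread", Valence.AVERSIVE)],
        )
        transferred = {f.stimulus: f for f in transform_function(net)}
        assert transferred["B"].valence is Valence.APPETITIVE
        assert transferred["C"].valence is Valence.AVERSIVE


class TestCategorization:
    def test_bachelor_ranks_male_first(self):
        net = build_fixture("bachelor")
        ranking = categorize_by_knowledge(net, "bachelor", ["male", "female"])
        assert ranking[0][0] == "male"
        assert ranking[0][1] > ranking[1][1]

    def test_negative_self_prefers_avoidance(self, snake_woods, full_context):
        ranking = categorize_by_knowledge(
            snake_woods, "woods", ["unsafe-and-avoid", "unsafe-but-walk"], full_context
        )
        assert ranking[0][0] == "unsafe-and-avoid"

    def test_positive_self_prefers_walking(self, snake_woods_positive, full_context):
        ranking = categorize_by_knowledge(
            snake_woods_positive, "woods", ["unsafe-and-avoid", "unsafe-but-walk"], full_context
        )
        assert ranking[0][0] == "unsafe-but-walk"

    def test_empty_relations_all_tie_at_zero(self):
        net = RelationalNetwork()
        for sid in ["q", "a", "b"]:
            net.add_stimulus(Stimulus(sid))
        ranking = categorize_by_knowledge(net, "q", ["a", "b"])
        assert [score for _, score in ranking] == [0.0, 0.0]

    def test_unknown_query_rejected(self, snake_woods):
        with pytest.raises(ValidationError):
            categorize_by_knowledge(snake_woods, "dragon", ["woods"])


class TestHdmlMetrics:
    def test_consistent_closure_fully_coherent(self):
        net = build_fixture(ScenarioSpec(name="random", seed=5, n_stimuli=8, n_relations=14))
        derive_closure(net)
        assert hdml_metrics(net).coherence == 1.0

    def test_planted_contradiction_lowers_coherence(self):
        net = simple_net(
            ("A", RelationType.COMPARISON_MORE, "B"),
            ("A", RelationType.COMPARISON_LESS, "B"),
        )
        derive_closure(net)
        assert hdml_metrics(net).coherence < 1.0

    def test_derivation_level_decays_with_emission(self, three_snake_net):
        for _ in range(3):  # emitted in three derivation passes
            derive_closure(three_snake_net, {"dangerous"})
        report = hdml_metrics(three_snake_net, {"dangerous"})
        assert report.derivation_level[("snake5", "snake2", "comparison-more")] == pytest.approx(0.25)

    def test_empty_network_limits(self):
        report = hdml_metrics(RelationalNetwork())
        assert report.coherence == 1.0
        assert report.complexity == 0.0

    def test_flexibility_counts_context_gated_fraction(self):
        net = simple_net(
            ("A", RelationType.COORDINATION, "B", {"school"}),
            ("C", RelationType.COORDINATION, "D"),
        )
        assert hdml_metrics(net).flexibility == pytest.approx(0.5)


class TestDocumentRoundTrip:
    def test_json_round_trip_lossless(self, snake_woods, full_context, tmp_path):
        transform_function(snake_woods, full_context)
        path = tmp_path / "net.json"
        snake_woods.to_json(path)
        reread = RelationalNetwork.from_json(path)
        assert reread.to_dict() == snake_woods.to_dict()

    def test_edge_csv_export(self, three_snake_net, tmp_path):
        derive_closure(three_snake_net, {"dangerous"})
        path = tmp_path / "edges.csv"
        three_snake_net.write_edge_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "source,target,rtype,strength,provenance"
        assert len(lines) == len(three_snake_net.relations) + 1
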