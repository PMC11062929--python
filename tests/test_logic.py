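import random

import pytest
from hypothesis import given, strategies as st

import isagap as ig
from isagap.core import DefiningRelation, InferredDefinition, RelationGroup


def make_relation_ontology(n_values=12, edge_prob=0.25, seed=0):
    """Small ontology with a value DAG and three attribute concepts (a2 ⊑ a1)."""
    ont = ig.random_dag(n_values, edge_prob, seed)
    concepts = dict(ont.concepts)
    for aid, name in (("a1", "Agent (attribute)"), ("a2", "Specific agent (attribute)"),
                      ("a3", "Site (attribute)")):
        concepts[aid] = ig.Concept(aid, name)
    edges = set(ont.isa_edges) | {("a2", "a1")}
    return ig.Ontology(concepts, edges)


def random_definition(ont, rng, concept="c1", max_groups=3):
    values = sorted(c for c in ont.concepts if c.startswith("c"))
    groups = []
    for gi in range(rng.randint(1, max_groups)):
        rels = frozenset(
            DefiningRelation(rng.choice(["a1", "a2", "a3"]), rng.choice(values))
            for _ in range(rng.randint(1, 3))
        )
        groups.append(RelationGroup(gi, rels))
    return InferredDefinition(concept, tuple(groups))


def specialize(ont, definition, rng, start_index=0):
    """A definition pointwise more specific: each value replaced by a
    random descendant-or-self, each a1 attribute possibly narrowed to a2."""
    groups = []
    for gi, g in enumerate(definition.groups):
        rels = set()
        for r in g.relations:
            below = sorted(ig.descendants(ont, r.value) | {r.value})
            attr = "a2" if (r.attribute == "a1" and rng.random() < 0.3) else r.attribute
            rels.add(DefiningRelation(attr, rng.choice(below)))
        groups.append(RelationGroup(start_index + gi, frozenset(rels)))
    return InferredDefinition(definition.concept, tuple(groups))


class TestRelationMoreSpecific:
    def test_worked_example_morphology_is_inclusion(self, worked_ontology):
        rx = DefiningRelation("attr-assoc-morph", "morph-malignant")
        ry = DefiningRelation("attr-assoc-morph", "morph-neoplasm")
        assert ig.relation_more_specific(worked_ontology, rx, ry) == "inclusion"

    def test_edetate_pair_matches_via_chain_only(self, chain_ontology):
        rx = DefiningRelation("attr-causative", "sce")
        ry = DefiningRelation("attr-causative", "edetate")
        assert ig.relation_more_specific(chain_ontology, rx, ry) == "chain"
        # without the chain axiom the pair is incomparable
        stripped = chain_ontology.with_chains([])
        assert ig.relation_more_specific(stripped, rx, ry) is None

    def test_any_relation_more_specific_than_itself(self, chain_ontology):
        r = DefiningRelation("attr-causative", "sce")
        assert ig.relation_more_specific(chain_ontology, r, r) == "inclusion"

    def test_isa_only_matches_isa(self, worked_ontology):
        isa = worked_ontology.isa_attribute_id
        rx = DefiningRelation(isa, "morph-malignant")
        ry = DefiningRelation("attr-assoc-morph", "morph-neoplasm")
        assert ig.relation_more_specific(worked_ontology, rx, ry) is None
        assert ig.relation_more_specific(worked_ontology, ry, rx) is None

    def test_isa_matches_isa_by_value_subsumption(self, worked_ontology):
        isa = worked_ontology.isa_attribute_id
        rx = DefiningRelation(isa, "126992002")
        ry = DefiningRelation(isa, "nl-trunk-nerves")
        assert ig.relation_more_specific(worked_ontology, rx, ry) == "inclusion"

    def test_unknown_id_raises(self, worked_ontology):
        with pytest.raises(ig.UnknownConceptError):
            ig.relation_more_specific(
                worked_ontology,
                DefiningRelation("attr-assoc-morph", "ghost"),
                DefiningRelation("attr-assoc-morph", "morph-neoplasm"),
            )

    def test_chain_value_subtype_flag(self, chain_ontology):
        # add a child of edetate as chain target: (sce --mod--> edetate);
        # comparing against that child's ancestor requires the flag.
        ont = chain_ontology
        concepts = dict(ont.concepts)
        concepts["edetate-parent"] = ig.Concept("edetate-parent", "Chelator (substance)")
        ont2 = ig.Ontology(
            concepts,
            set(ont.isa_edges) | {("edetate", "edetate-parent")},
            ont.attribute_relations,
            ont.chains,
        )
        rx = DefiningRelation("attr-causative", "sce")
        ry = DefiningRelation("attr-causative", "edetate-parent")
        assert ig.relation_more_specific(ont2, rx, ry) is None
        assert (
            ig.relation_more_specific(ont2, rx, ry, allow_chain_value_subtype=True)
            == "chain"
        )


class TestGroupMoreSpecific:
    def test_worked_example_bottom_groups(self, worked_ontology):
        gx = RelationGroup(1, frozenset({
            DefiningRelation("attr-assoc-morph", "morph-malignant"),
            DefiningRelation("attr-finding-site", "site-pn-abdomen"),
        }))
        gy = RelationGroup(1, frozenset({
            DefiningRelation("attr-assoc-morph", "morph-neoplasm"),
            DefiningRelation("attr-finding-site", "site-pn-abdomen"),
        }))
        matches = ig.group_more_specific(worked_ontology, gx, gy)
        assert matches is not None
        assert all(rule == "inclusion" for _, rule in matches.values())
        assert ig.group_more_specific(worked_ontology, gy, gx) is None

    def test_identical_groups_match(self, worked_ontology):
        g = RelationGroup(1, frozenset({DefiningRelation("attr-finding-site", "site-pn-abdomen")}))
        assert ig.group_more_specific(worked_ontology, g, g) is not None

    def test_unmatched_general_relation_fails(self, worked_ontology):
        gx = RelationGroup(1, frozenset({DefiningRelation("attr-assoc-morph", "morph-malignant")}))
        gy = RelationGroup(1, frozenset({
            DefiningRelation("attr-assoc-morph", "morph-neoplasm"),
            DefiningRelation("attr-finding-site", "site-pn-abdomen"),
        }))
        assert ig.group_more_specific(worked_ontology, gx, gy) is None


class TestDefinitionMoreSpecific:
    def test_worked_example_holds(self, worked_ontology):
        ev = ig.definition_more_specific(
            worked_ontology,
            worked_ontology.inferred_definition("188326001"),
            worked_ontology.inferred_definition("126992002"),
        )
        assert ev.holds
        # every supertype group is matched
        supertype_groups = {
            g.group_index
            for g in worked_ontology.inferred_definition("126992002").groups
        }
        assert set(ev.group_matching) == supertype_groups

    def test_reflexive_on_every_fixture_concept(self, worked_ontology, chain_ontology):
        for ont in (worked_ontology, chain_ontology):
            for cid in ont.concepts:
                definition = ont.inferred_definition(cid)
                assert ig.definition_more_specific(ont, definition, definition).holds

    def test_empty_supertype_definition_holds_vacuously(self, worked_ontology):
        empty = InferredDefinition("64572001", ())
        ix = worked_ontology.inferred_definition("188326001")
        assert ig.definition_more_specific(worked_ontology, ix, empty).holds

    @given(st.integers(0, 500))
    def test_monotone_in_both_arguments(self, seed):
        rng = random.Random(seed)
        ont = make_relation_ontology(seed=seed % 7)
        iy = random_definition(ont, rng)
        ix = specialize(ont, iy, rng)
        assert ig.definition_more_specific(ont, ix, iy).holds
        # adding a group to the subtype side preserves the result
        extra = random_definition(ont, rng, max_groups=1).groups[0]
        bigger_ix = InferredDefinition(
            ix.concept,
            ix.groups + (RelationGroup(len(ix.groups), extra.relations),),
        )
        assert ig.definition_more_specific(ont, bigger_ix, iy).holds
        # adding a group to the supertype side can only remove the result
        bigger_iy = InferredDefinition(
            iy.concept,
            iy.groups + (RelationGroup(len(iy.groups), extra.relations),),
        )
        if ig.definition_more_specific(ont, ix, bigger_iy).holds:
            assert ig.definition_more_specific(ont, ix, iy).holds

    @given(st.integers(0, 500))
    def test_transitive_without_chains(self, seed):
        rng = random.Random(seed)
        ont = make_relation_ontology(seed=seed % 5)
        assert not ont.chains
        iz = random_definition(ont, rng)
        iy = specialize(ont, iz, rng)
        ix = specialize(ont, iy, rng)
        assert ig.definition_more_specific(ont, iy, iz).holds
        assert ig.definition_more_specific(ont, ix, iy).holds
        assert ig.definition_more_specific(ont, ix, iz).holds

    def test_injective_matching_requires_distinct_witnesses(self, worked_ontology):
        # one subtype group cannot witness two supertype groups injectively
        g = RelationGroup(0, frozenset({DefiningRelation("attr-finding-site", "site-pn-abdomen")}))
        ix = InferredDefinition("188326001", (g,))
        iy = InferredDefinition(
            "126992002",
            (
                RelationGroup(0, g.relations),
                RelationGroup(1, g.relations),
            ),
        )
        assert ig.definition_more_specific(worked_ontology, ix, iy).holds
        assert not ig.definition_more_specific(
            worked_ontology, ix, iy, injective=True
        ).holds


class TestHasAttributeRelation:
    def test_isa_only_definition_has_none(self, worked_ontology):
        isa = worked_ontology.isa_attribute_id
        definition = InferredDefinition(
            "x", (RelationGroup(0, frozenset({DefiningRelation(isa, "64572001")})),)
        )
        assert not ig.has_attribute_relation(definition, isa)

    def test_worked_example_supertype_has_one(self, worked_ontology):
        definition = worked_ontology.inferred_definition("126992002")
        assert ig.has_attribute_relation(definition, worked_ontology.isa_attribute_id)

    def test_empty_definition_has_none(self):
        assert not ig.has_attribute_relation(InferredDefinition("x", ()), "isa")
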