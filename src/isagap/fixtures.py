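"""Bundled worked-example ontologies and a planted-relation generator.

Two hand-built fixtures ship as native TSV bundles: a neoplasm
non-lattice subgraph whose primitive supertype hides two valid
subsumptions, and an adverse-reaction pair whose subsumption is only
witnessed through the property chain
``Causative agent o Is modification of`` ⊑ ``Causative agent``.

The generator plants missing IS-A relations inside random background
ontologies with every precondition of the detection method guaranteed
by construction (primitive parent with an attribute group, pointwise
more-specific child definition, compositional names giving the lexical
superset, a second maximal common descendant forcing a non-lattice
pair), then self-checks each guarantee and certifies the instance
collision-free when no other concept can pass the supertype filters.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx

from .core import (
    Concept,
    DefiningRelation,
    DefinitionStatus,
    ISA_TYPE_ID,
    Ontology,
    PropertyChain,
    RelationGroup,
    load_native_tables,
)
from .lexical import RuleBasedProvider, enriched_feature_set, lexical_subsumes
from .logic import definition_more_specific, has_attribute_relation
from .nonlattice import build_nonlattice_subgraph, candidate_pairs, find_nonlattice_pairs

# ids of the pivotal worked-example concepts, for tests and examples
WORKED = {
    "pair_root_trunk_nerves": "nl-trunk-nerves",
    "pair_root_abdomen": "nl-abdomen",
    "primitive_supertype": "126992002",  # Neoplasm of peripheral nerves of abdomen
    "malignant_child": "188326001",  # Malignant neoplasm of peripheral nerve of abdomen
    "benign_child": "426134002",  # Benign ganglioneuroma of abdomen
    "morph_neoplasm": "morph-neoplasm",
    "morph_malignant": "morph-malignant",
    "assoc_morph": "attr-assoc-morph",
    "finding_site": "attr-finding-site",
    "site": "site-pn-abdomen",
}

CHAIN = {
    "specific_reaction": "sce-reaction",
    "general_reaction": "edetate-reaction",
    "specific_substance": "sce",
    "general_substance": "edetate",
    "causative_agent": "attr-causative",
    "is_modification_of": "attr-modification",
}


def _data_dir(name: str) -> Path:
    return Path(resources.files("isagap").joinpath("data", name))


def paper_fixture_snomed() -> Ontology:
    """The neoplasm worked example: a non-lattice pair of disorder concepts
    with three maximal common descendants, one of which is a primitive
    supertype with a two-relation attribute group."""
    return load_native_tables(_data_dir("snomed_worked_example"))


def paper_fixture_chain() -> Ontology:
    """The edetate adverse-reaction example: substance specificity carried
    by an "Is modification of" link under a property chain, not by IS-A."""
    return load_native_tables(_data_dir("edetate_chain"))


# ---------------------------------------------------------------------------
# random ontologies
# ---------------------------------------------------------------------------

_ADJECTIVES = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "sigma", "omega", "chronic", "acute", "focal",
)
_NOUNS = (
    "lesion", "swelling", "infection", "cyst", "nodule", "ulcer", "stenosis",
    "fibrosis", "rupture", "atrophy", "erosion", "granuloma", "polyp", "scar",
)
_SITES = (
    "spleen", "liver", "kidney", "femur", "cortex", "retina", "larynx",
    "pleura", "ileum", "dermis", "tendon", "thymus", "palate", "sternum",
)


def _synthetic_name(rng: random.Random, index: int, tag: str = "synthetic") -> str:
    adj = rng.choice(_ADJECTIVES)
    noun = rng.choice(_NOUNS)
    site = rng.choice(_SITES)
    return f"{adj.capitalize()} {noun}{index} of {site} ({tag})"


def random_dag(n: int, edge_prob: float, seed: int) -> Ontology:
    """Random acyclic ontology: edges only from higher to lower index, names
    synthetic multi-word strings so lexical operations are exercisable."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = random.Random(seed)
    concepts = [Concept(ISA_TYPE_ID, "Is a (attribute)")]
    ids = [f"c{i}" for i in range(1, n + 1)]
    for i, cid in enumerate(ids):
        concepts.append(Concept(cid, _synthetic_name(rng, i + 1)))
    edges = set()
    for j in range(1, n):
        for i in range(j):
            if rng.random() < edge_prob:
                edges.add((ids[j], ids[i]))
    return Ontology(concepts, edges)


# ---------------------------------------------------------------------------
# planted missing IS-A instances
# ---------------------------------------------------------------------------

@dataclass
class PlantedInstance:
    """A background ontology with planted, certified missing IS-A relations."""

    ontology: Ontology
    planted: frozenset[tuple[str, str]]
    certificate: dict[tuple[str, str], bool] = field(default_factory=dict)

    @property
    def certified(self) -> bool:
        return bool(self.certificate) and all(self.certificate.values())


def plant_missing_isas(
    n_background: int, n_planted: int, seed: int, with_chains: bool = True
) -> PlantedInstance:
    """Build a background ontology with ``n_planted`` planted missing IS-A
    relations (alternating inclusion-rule and, when ``with_chains``,
    chain-rule attribute groups) and certify the construction.
    """
    if n_planted < 1:
        raise ValueError("n_planted must be >= 1")
    if n_planted > len(_NOUNS) * len(_SITES):
        raise ValueError("n_planted too large for the controlled vocabulary")
    rng = random.Random(seed)
    concepts: list[Concept] = [
        Concept(ISA_TYPE_ID, "Is a (attribute)"),
        Concept("attr-agent", "Causative agent (attribute)"),
        Concept("attr-mod", "Is modification of (attribute)"),
    ]
    edges: set[tuple[str, str]] = set()
    attribute_relations: dict[str, list[RelationGroup]] = {}
    chains: list[PropertyChain] = []
    planted: set[tuple[str, str]] = set()

    combos = [(noun, site) for noun in _NOUNS for site in _SITES]
    rng.shuffle(combos)
    for k in range(n_planted):
        noun, site = combos[k]
        chain_case = with_chains and k % 2 == 1
        root_a = f"pl{k}-root-a"
        root_b = f"pl{k}-root-b"
        parent = f"pl{k}-parent"
        child = f"pl{k}-child"
        decoy = f"pl{k}-decoy"
        val_general = f"pl{k}-val-general"
        concepts += [
            Concept(root_a, f"Primary finding of {site} (finding)", DefinitionStatus.FULLY_DEFINED),
            Concept(root_b, f"Secondary finding of {site} (finding)", DefinitionStatus.FULLY_DEFINED),
            Concept(parent, f"{noun.capitalize()} of {site} (disorder)", DefinitionStatus.PRIMITIVE),
            Concept(child, f"Alpha {noun} of {site} (disorder)", DefinitionStatus.FULLY_DEFINED),
            Concept(decoy, f"Other finding of {site} (finding)", DefinitionStatus.FULLY_DEFINED),
            Concept(val_general, f"Generic agent {k} (substance)"),
        ]
        for c in (parent, child, decoy):
            edges.add((c, root_a))
            edges.add((c, root_b))
        attribute_relations[parent] = [
            RelationGroup(1, frozenset({DefiningRelation("attr-agent", val_general)}))
        ]
        if chain_case:
            modified = f"pl{k}-val-modified"
            # fully defined so the value concept can never itself pass the
            # primitive-supertype filter
            concepts.append(
                Concept(modified, f"Modified agent {k} (substance)", DefinitionStatus.FULLY_DEFINED)
            )
            attribute_relations[modified] = [
                RelationGroup(1, frozenset({DefiningRelation("attr-mod", val_general)}))
            ]
            child_value = modified
        else:
            specific = f"pl{k}-val-specific"
            concepts.append(Concept(specific, f"Specific agent {k} (substance)"))
            edges.add((specific, val_general))
            child_value = specific
        attribute_relations[child] = [
            RelationGroup(1, frozenset({DefiningRelation("attr-agent", child_value)}))
        ]
        planted.add((child, parent))
    if with_chains and n_planted > 1:
        chains.append(PropertyChain("attr-agent", "attr-mod", "attr-agent"))

    # background: fully defined, attribute-free concepts in a random DAG —
    # they can never pass the supertype filters.
    bg_ids = [f"bg{i}" for i in range(n_background)]
    for i, cid in enumerate(bg_ids):
        concepts.append(
            Concept(cid, _synthetic_name(rng, i, "finding"), DefinitionStatus.FULLY_DEFINED)
        )
    for j in range(1, n_background):
        for i in range(j):
            if rng.random() < 2.0 / max(n_background, 1):
                edges.add((bg_ids[j], bg_ids[i]))

    ontology = Ontology(concepts, edges, attribute_relations, chains)
    certificate = _certify(ontology, planted)
    return PlantedInstance(ontology, frozenset(planted), certificate)


def _certify(ontology: Ontology, planted: set[tuple[str, str]]) -> dict[tuple[str, str], bool]:
    """Verify every construction guarantee for each planted relation and the
    absence of colliding valid pairs elsewhere."""
    provider = RuleBasedProvider()
    cache: dict = {}
    subgraphs = [
        build_nonlattice_subgraph(ontology, p) for p in find_nonlattice_pairs(ontology)
    ]
    candidates = {(c.x, c.y) for c in candidate_pairs(ontology, subgraphs)}
    isa = ontology.isa_attribute_id

    # only the planted parents may pass the supertype filters
    passable = {
        cid
        for cid, concept in ontology.concepts.items()
        if concept.definition_status is DefinitionStatus.PRIMITIVE
        and has_attribute_relation(ontology.inferred_definition(cid), isa)
    }
    collision_free = passable == {p for (_, p) in planted}

    certificate: dict[tuple[str, str], bool] = {}
    augmented = ontology.isa_edges | planted
    for child, parent in sorted(planted):
        checks = [
            collision_free,
            ontology.concepts[parent].definition_status is DefinitionStatus.PRIMITIVE,
            has_attribute_relation(ontology.inferred_definition(parent), isa),
            definition_more_specific(
                ontology,
                ontology.inferred_definition(child),
                ontology.inferred_definition(parent),
            ).holds,
            lexical_subsumes(
                enriched_feature_set(ontology, child, provider, cache),
                enriched_feature_set(ontology, parent, provider, cache),
            ),
            not ontology.is_subsumed_by(child, parent),
            not ontology.is_subsumed_by(parent, child),
            tuple(sorted((child, parent))) in candidates,
            _non_redundant(ontology, (child, parent), augmented),
        ]
        certificate[(child, parent)] = all(checks)
    return certificate


def _non_redundant(
    ontology: Ontology, relation: tuple[str, str], augmented: frozenset | set
) -> bool:
    graph = nx.DiGraph(e for e in augmented if e != relation)
    graph.add_nodes_from(ontology.concepts)
    if not nx.is_directed_acyclic_graph(nx.DiGraph(augmented)):
        return False
    return not nx.has_path(graph, relation[0], relation[1])
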