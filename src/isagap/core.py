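"""Terminology data model, readers/writers and reachability queries.

The central object is :class:`Ontology`: a set of concepts, a directed
acyclic IS-A graph (child -> parent edges), grouped attribute relations
(each concept's non-hierarchical defining relations, partitioned into
relation groups), and property-chain axioms of the form
``leading o intermediate`` is a sub-property of ``super_attribute``.

Two input dialects are supported: SNOMED CT RF2 snapshot releases
(tab-separated ``sct2_*`` files, active rows only, inferred
characteristic type only) and a simple native table format (TSV or a
single JSON document) suitable for toy and synthetic ontologies.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

#: SNOMED CT identifier of the IS-A relationship type; used as the
#: reserved hierarchical attribute id in every ontology unless overridden.
ISA_TYPE_ID = "116680003"

#: RF2 concrete ids.
FSN_TYPE_ID = "900000000000003001"
INFERRED_CHARACTERISTIC_ID = "900000000000011006"
FULLY_DEFINED_STATUS_ID = "900000000000073002"
PRIMITIVE_STATUS_ID = "900000000000074008"


class OntologyError(Exception):
    """Base class for ontology loading/validation failures."""


class OntologyLoadError(OntologyError):
    """A release file is missing or malformed."""


class OntologyValidationError(OntologyError):
    """The loaded content violates a structural invariant."""


class UnknownConceptError(OntologyError, KeyError):
    """An operation referenced a concept id absent from the ontology."""

    def __init__(self, concept_id: str):
        super().__init__(f"unknown concept id: {concept_id!r}")
        self.concept_id = concept_id


class DefinitionStatus(str, Enum):
    PRIMITIVE = "primitive"
    FULLY_DEFINED = "fully_defined"


@dataclass(frozen=True)
class Concept:
    id: str
    name: str
    definition_status: DefinitionStatus = DefinitionStatus.PRIMITIVE
    active: bool = True

    def __post_init__(self):
        if not self.id:
            raise OntologyValidationError("concept id must be non-empty")
        if not self.name:
            raise OntologyValidationError(f"concept {self.id!r} has an empty name")


@dataclass(frozen=True, order=True)
class DefiningRelation:
    """An attribute-value pair (k : v); the IS-A id is a permitted attribute."""

    attribute: str
    value: str


@dataclass(frozen=True)
class RelationGroup:
    group_index: int
    relations: frozenset[DefiningRelation]

    def __post_init__(self):
        if not self.relations:
            raise OntologyValidationError("relation group must be non-empty")
        if self.group_index < 0:
            raise OntologyValidationError("group_index must be non-negative")

    def sorted_relations(self) -> list[DefiningRelation]:
        return sorted(self.relations)


@dataclass(frozen=True)
class InferredDefinition:
    """A concept's inferred logical definition: a set of relation groups.

    Every direct IS-A parent appears as its own singleton group; the
    concept's attribute relations keep their grouping.
    """

    concept: str
    groups: tuple[RelationGroup, ...]

    def __post_init__(self):
        indices = [g.group_index for g in self.groups]
        if len(indices) != len(set(indices)):
            raise OntologyValidationError(
                f"duplicate group_index in definition of {self.concept!r}"
            )


@dataclass(frozen=True)
class PropertyChain:
    """Axiom ``leading o intermediate`` is a sub-property of ``super_attribute``."""

    leading: str
    intermediate: str
    super_attribute: str


class Ontology:
    """Concepts, IS-A edges, grouped attribute relations and property chains.

    Treated as immutable after construction; reachability queries are
    memoized.  Use :meth:`with_edges` / :meth:`with_chains` to derive
    modified copies.
    """

    def __init__(
        self,
        concepts: Mapping[str, Concept] | Iterable[Concept],
        isa_edges: Iterable[tuple[str, str]] = (),
        attribute_relations: Mapping[str, Sequence[RelationGroup]] | None = None,
        chains: Iterable[PropertyChain] = (),
        isa_attribute_id: str = ISA_TYPE_ID,
        validate: bool = True,
    ):
        if not isinstance(concepts, Mapping):
            concepts = {c.id: c for c in concepts}
        self.concepts: dict[str, Concept] = dict(concepts)
        self.isa_edges: frozenset[tuple[str, str]] = frozenset(isa_edges)
        self.attribute_relations: dict[str, tuple[RelationGroup, ...]] = {
            cid: tuple(groups) for cid, groups in (attribute_relations or {}).items() if groups
        }
        self.chains: tuple[PropertyChain, ...] = tuple(chains)
        self.isa_attribute_id = isa_attribute_id
        self._graph: nx.DiGraph | None = None
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}
        if validate:
            self.validate()

    # -- construction helpers ------------------------------------------------

    def with_edges(self, extra_edges: Iterable[tuple[str, str]]) -> "Ontology":
        return Ontology(
            self.concepts,
            set(self.isa_edges) | set(extra_edges),
            self.attribute_relations,
            self.chains,
            self.isa_attribute_id,
        )

    def with_chains(self, chains: Iterable[PropertyChain]) -> "Ontology":
        return Ontology(
            self.concepts,
            self.isa_edges,
            self.attribute_relations,
            chains,
            self.isa_attribute_id,
        )

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        for child, parent in self.isa_edges:
            for cid in (child, parent):
                if cid not in self.concepts:
                    raise OntologyValidationError(
                        f"IS-A edge ({child!r}, {parent!r}) references unknown id {cid!r}"
                    )
        for source, groups in self.attribute_relations.items():
            if source not in self.concepts:
                raise OntologyValidationError(
                    f"attribute relations reference unknown source {source!r}"
                )
            for group in groups:
                for rel in group.relations:
                    for cid in (rel.attribute, rel.value):
                        if cid not in self.concepts:
                            raise OntologyValidationError(
                                f"relation ({rel.attribute!r}: {rel.value!r}) of "
                                f"{source!r} references unknown id {cid!r}"
                            )
        for chain in self.chains:
            for cid in (chain.leading, chain.intermediate, chain.super_attribute):
                if cid not in self.concepts:
                    raise OntologyValidationError(
                        f"property chain {chain} references unknown id {cid!r}"
                    )
        graph = self.graph
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            pretty = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyValidationError(f"IS-A hierarchy contains a cycle: {pretty}")

    # -- graph queries -------------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """Directed child -> parent IS-A graph over all concepts."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.concepts)
            g.add_edges_from(self.isa_edges)
            self._graph = g
        return self._graph

    def _require(self, concept_id: str) -> None:
        if concept_id not in self.concepts:
            raise UnknownConceptError(concept_id)

    def parents(self, concept_id: str) -> frozenset[str]:
        self._require(concept_id)
        return frozenset(self.graph.successors(concept_id))

    def children(self, concept_id: str) -> frozenset[str]:
        self._require(concept_id)
        return frozenset(self.graph.predecessors(concept_id))

    def ancestors(self, concept_id: str) -> frozenset[str]:
        """All concepts reachable via child -> parent edges, excluding self."""
        self._require(concept_id)
        if concept_id not in self._anc_cache:
            self._anc_cache[concept_id] = frozenset(nx.descendants(self.graph, concept_id))
        return self._anc_cache[concept_id]

    def descendants(self, concept_id: str) -> frozenset[str]:
        """All concepts from which concept_id is reachable, excluding self."""
        self._require(concept_id)
        if concept_id not in self._desc_cache:
            self._desc_cache[concept_id] = frozenset(nx.ancestors(self.graph, concept_id))
        return self._desc_cache[concept_id]

    def is_subsumed_by(self, a: str, b: str) -> bool:
        """True iff a is b, or b is an ancestor of a (a ⊑ b)."""
        self._require(a)
        self._require(b)
        return a == b or b in self.ancestors(a)

    def inferred_definition(self, concept_id: str) -> InferredDefinition:
        """The concept's relation groups: IS-A parents as singleton groups,
        then its attribute relation groups, re-indexed deterministically."""
        self._require(concept_id)
        groups: list[RelationGroup] = []
        idx = 0
        for parent in sorted(self.parents(concept_id)):
            groups.append(
                RelationGroup(
                    idx, frozenset({DefiningRelation(self.isa_attribute_id, parent)})
                )
            )
            idx += 1
        for group in self.attribute_relations.get(concept_id, ()):
            groups.append(RelationGroup(idx, group.relations))
            idx += 1
        return InferredDefinition(concept_id, tuple(groups))


# ---------------------------------------------------------------------------
# module-level functional facade (mirrors the method surface)
# ---------------------------------------------------------------------------

def ancestors(ontology: Ontology, concept_id: str) -> frozenset[str]:
    return ontology.ancestors(concept_id)


def descendants(ontology: Ontology, concept_id: str) -> frozenset[str]:
    return ontology.descendants(concept_id)


def is_subsumed_by(ontology: Ontology, a: str, b: str) -> bool:
    return ontology.is_subsumed_by(a, b)


def inferred_definition(ontology: Ontology, concept_id: str) -> InferredDefinition:
    return ontology.inferred_definition(concept_id)


# ---------------------------------------------------------------------------
# RF2 snapshot reader
# ---------------------------------------------------------------------------

def _find_rf2_file(directory: Path, stem: str) -> Path:
    matches = sorted(directory.rglob(f"sct2_{stem}_*.txt")) or sorted(
        directory.rglob(f"sct2_{stem}*.txt")
    )
    if not matches:
        raise OntologyLoadError(f"no RF2 {stem} file (sct2_{stem}_*.txt) under {directory}")
    return matches[0]


def _read_rf2(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_rf2_snapshot(directory_path, isa_attribute_id: str = ISA_TYPE_ID) -> Ontology:
    """Load an RF2 snapshot directory (concept, description, relationship files).

    Only ``active=1`` rows are kept; only inferred-characteristic
    relationships are kept.  IS-A rows become hierarchy edges; other rows
    become defining relations grouped by ``relationshipGroup`` (group 0
    rows each form their own singleton group, the SNOMED convention for
    ungrouped relations).  FSN descriptions supply concept names.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise OntologyLoadError(f"RF2 snapshot directory not found: {directory}")
    concept_df = _read_rf2(_find_rf2_file(directory, "Concept"))
    desc_df = _read_rf2(_find_rf2_file(directory, "Description"))
    rel_df = _read_rf2(_find_rf2_file(directory, "Relationship"))

    concept_df = concept_df[concept_df["active"] == "1"]
    desc_df = desc_df[(desc_df["active"] == "1") & (desc_df["typeId"] == FSN_TYPE_ID)]
    fsn = dict(zip(desc_df["conceptId"], desc_df["term"]))

    concepts: dict[str, Concept] = {}
    for row in concept_df.itertuples(index=False):
        cid = row.id
        if cid not in fsn:
            raise OntologyLoadError(f"active concept {cid!r} has no active FSN description")
        status = (
            DefinitionStatus.FULLY_DEFINED
            if row.definitionStatusId == FULLY_DEFINED_STATUS_ID
            else DefinitionStatus.PRIMITIVE
        )
        concepts[cid] = Concept(cid, fsn[cid], status)

    rel_df = rel_df[
        (rel_df["active"] == "1")
        & (rel_df["characteristicTypeId"] == INFERRED_CHARACTERISTIC_ID)
    ]
    isa_edges: set[tuple[str, str]] = set()
    grouped: dict[tuple[str, str], set[DefiningRelation]] = {}
    ungrouped: dict[str, list[DefiningRelation]] = {}
    for row in rel_df.itertuples(index=False):
        if row.typeId == isa_attribute_id:
            isa_edges.add((row.sourceId, row.destinationId))
        elif row.relationshipGroup == "0":
            ungrouped.setdefault(row.sourceId, []).append(
                DefiningRelation(row.typeId, row.destinationId)
            )
        else:
            grouped.setdefault((row.sourceId, row.relationshipGroup), set()).add(
                DefiningRelation(row.typeId, row.destinationId)
            )

    attribute_relations: dict[str, list[RelationGroup]] = {}
    per_source: dict[str, list[frozenset[DefiningRelation]]] = {}
    for (source, _), rels in sorted(grouped.items()):
        per_source.setdefault(source, []).append(frozenset(rels))
    for source, rels in ungrouped.items():
        per_source.setdefault(source, []).extend(frozenset({r}) for r in sorted(rels))
    for source, groups in per_source.items():
        attribute_relations[source] = [
            RelationGroup(i + 1, rels)
            for i, rels in enumerate(sorted(groups, key=lambda g: sorted(g)))
        ]
    return Ontology(concepts, isa_edges, attribute_relations, isa_attribute_id=isa_attribute_id)


# ---------------------------------------------------------------------------
# native table reader/writer
# ---------------------------------------------------------------------------

_NATIVE_FILES = ("concepts.tsv", "isa.tsv", "attributes.tsv", "chains.tsv")


def load_native_tables(path, isa_attribute_id: str = ISA_TYPE_ID) -> Ontology:
    """Load the native table format.

    ``path`` is either a directory holding ``concepts.tsv`` (required),
    ``isa.tsv``, ``attributes.tsv``, ``chains.tsv``, or a ``.json`` file
    holding the equivalent single document.  When the attributes table
    has no ``group_index`` column each relation forms its own group.
    """
    path = Path(path)
    if path.suffix == ".json":
        return _ontology_from_document(json.loads(path.read_text()), isa_attribute_id)
    if not path.is_dir():
        raise OntologyLoadError(f"native table directory not found: {path}")
    doc: dict = {}
    concepts_path = path / "concepts.tsv"
    if not concepts_path.exists():
        raise OntologyLoadError(f"missing required table: {concepts_path}")

    def read(name: str) -> pd.DataFrame | None:
        p = path / name
        if not p.exists():
            return None
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)

    doc["concepts"] = read("concepts.tsv").to_dict("records")
    for key, name in (("isa", "isa.tsv"), ("attributes", "attributes.tsv"), ("chains", "chains.tsv")):
        df = read(name)
        doc[key] = [] if df is None else df.to_dict("records")
    return _ontology_from_document(doc, isa_attribute_id)


def _ontology_from_document(doc: Mapping, isa_attribute_id: str) -> Ontology:
    concepts: dict[str, Concept] = {}
    for row in doc.get("concepts", []):
        cid = str(row["id"])
        if cid in concepts:
            raise OntologyLoadError(f"duplicate concept id {cid!r}")
        status = DefinitionStatus(row.get("definition_status", "primitive"))
        active = str(row.get("active", "1")) in ("1", "true", "True")
        concepts[cid] = Concept(cid, str(row["name"]), status, active)

    isa_edges = {
        (str(row["child_id"]), str(row["parent_id"])) for row in doc.get("isa", [])
    }

    has_group_col = any("group_index" in row and str(row["group_index"]) != "" for row in doc.get("attributes", []))
    grouped: dict[tuple[str, str], set[DefiningRelation]] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(doc.get("attributes", [])):
        source = str(row["source_id"])
        key = (source, str(row["group_index"]) if has_group_col else f"__auto{i}")
        if key not in grouped:
            grouped[key] = set()
            order.append(key)
        grouped[key].add(DefiningRelation(str(row["attribute_id"]), str(row["value_id"])))

    attribute_relations: dict[str, list[RelationGroup]] = {}
    counters: dict[str, int] = {}
    for key in order:
        source = key[0]
        counters[source] = counters.get(source, 0) + 1
        attribute_relations.setdefault(source, []).append(
            RelationGroup(counters[source], frozenset(grouped[key]))
        )

    chains = [
        PropertyChain(str(row["leading_id"]), str(row["intermediate_id"]), str(row["super_id"]))
        for row in doc.get("chains", [])
    ]
    return Ontology(concepts, isa_edges, attribute_relations, chains, isa_attribute_id)


def write_native_tables(ontology: Ontology, directory) -> None:
    """Serialize an ontology to the native TSV table bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    concepts = pd.DataFrame(
        [
            {
                "id": c.id,
                "name": c.name,
                "definition_status": c.definition_status.value,
                "active": "1" if c.active else "0",
            }
            for c in sorted(ontology.concepts.values(), key=lambda c: c.id)
        ],
        columns=["id", "name", "definition_status", "active"],
    )
    concepts.to_csv(directory / "concepts.tsv", sep="\t", index=False)
    isa = pd.DataFrame(
        sorted(ontology.isa_edges), columns=["child_id", "parent_id"]
    )
    isa.to_csv(directory / "isa.tsv", sep="\t", index=False)
    attr_rows = []
    for source in sorted(ontology.attribute_relations):
        for group in ontology.attribute_relations[source]:
            for rel in group.sorted_relations():
                attr_rows.append(
                    {
                        "source_id": source,
                        "group_index": group.group_index,
                        "attribute_id": rel.attribute,
                        "value_id": rel.value,
                    }
                )
    pd.DataFrame(
        attr_rows, columns=["source_id", "group_index", "attribute_id", "value_id"]
    ).to_csv(directory / "attributes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "leading_id": ch.leading,
                "intermediate_id": ch.intermediate,
                "super_id": ch.super_attribute,
            }
            for ch in ontology.chains
        ],
        columns=["leading_id", "intermediate_id", "super_id"],
    ).to_csv(directory / "chains.tsv", sep="\t", index=False)
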