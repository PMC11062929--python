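"""End-to-end missing IS-A suggestion pipeline.

Stages: non-lattice extraction -> candidate pairs -> per-pair logical
and lexical checks (both orientations) -> cycle removal -> redundancy
removal.  Suggestions carry their logical evidence, their lexical
margin (child-only enriched features) and subgraph provenance, and are
never silently dropped: filtered suggestions keep a status of
``removed_cycle`` or ``removed_redundant``.

Cycle removal runs before redundancy removal: an edge on a cycle would
make every other edge of that cycle trivially derivable, corrupting the
redundancy fixed point.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import yaml

from .core import DefinitionStatus, Ontology, UnknownConceptError
from .lexical import FeatureSet, enriched_feature_set, get_provider, lexical_subsumes
from .logic import LogicalEvidence, definition_more_specific, has_attribute_relation
from .nonlattice import (
    CandidatePair,
    build_nonlattice_subgraph,
    candidate_pairs,
    find_nonlattice_pairs,
)

logger = logging.getLogger(__name__)

STATUS_KEPT = "kept"
STATUS_REMOVED_REDUNDANT = "removed_redundant"
STATUS_REMOVED_CYCLE = "removed_cycle"


@dataclass
class PipelineConfig:
    """Tunable filters of the suggestion pipeline (defaults match the method)."""

    require_primitive_supertype: bool = True
    require_attribute_relation: bool = True
    chain_value_subtype_allowed: bool = False
    provider: str = "rulebased"
    injective_group_matching: bool = False

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {f.name: getattr(self, f.name) for f in fields(self)},
            sort_keys=True,
            default_flow_style=False,
        )

    @classmethod
    def from_yaml(cls, text_or_path) -> "PipelineConfig":
        path = Path(str(text_or_path))
        text = path.read_text() if path.exists() else str(text_or_path)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class Suggestion:
    """A directed potentially missing IS-A edge with its evidence."""

    child: str
    parent: str
    logical: LogicalEvidence
    lexical_margin: int
    source_subgraphs: frozenset[str] = frozenset()
    status: str = STATUS_KEPT

    @property
    def edge(self) -> tuple[str, str]:
        return (self.child, self.parent)


def evaluate_pair(
    ontology: Ontology,
    pair: CandidatePair,
    config: Optional[PipelineConfig] = None,
    provider=None,
    cache: Optional[dict[str, FeatureSet]] = None,
) -> list[Suggestion]:
    """Evaluate both orientations of an unrelated candidate pair.

    A suggestion child IS-A parent is emitted iff the parent passes the
    supertype filters (primitive status, at least one attribute
    relation), the child's definition is more specific at group level,
    and the child's enriched lexical features form a superset of the
    parent's.
    """
    config = config or PipelineConfig()
    provider = provider or get_provider(config.provider)
    cache = cache if cache is not None else {}
    for cid in (pair.x, pair.y):
        if cid not in ontology.concepts:
            raise UnknownConceptError(cid)
    out: list[Suggestion] = []
    for child, parent in ((pair.x, pair.y), (pair.y, pair.x)):
        parent_concept = ontology.concepts[parent]
        if (
            config.require_primitive_supertype
            and parent_concept.definition_status is not DefinitionStatus.PRIMITIVE
        ):
            continue
        parent_def = ontology.inferred_definition(parent)
        if config.require_attribute_relation and not has_attribute_relation(
            parent_def, ontology.isa_attribute_id
        ):
            continue
        evidence = definition_more_specific(
            ontology,
            ontology.inferred_definition(child),
            parent_def,
            allow_chain_value_subtype=config.chain_value_subtype_allowed,
            injective=config.injective_group_matching,
        )
        if not evidence.holds:
            continue
        child_set = enriched_feature_set(ontology, child, provider, cache)
        parent_set = enriched_feature_set(ontology, parent, provider, cache)
        if not lexical_subsumes(child_set, parent_set):
            continue
        out.append(
            Suggestion(
                child=child,
                parent=parent,
                logical=evidence,
                lexical_margin=len(child_set.features - parent_set.features),
                source_subgraphs=pair.source_subgraphs,
            )
        )
    return out


def remove_cycle_causing(
    ontology: Ontology, suggestions: Sequence[Suggestion]
) -> list[Suggestion]:
    """Mark ``removed_cycle`` every suggestion lying on a directed cycle of
    existing edges plus the full suggestion set (mutually-suggested pairs
    and suggestions contradicting an existing path included)."""
    graph = nx.DiGraph(ontology.isa_edges)
    graph.add_nodes_from(ontology.concepts)
    active = [s for s in suggestions if s.status == STATUS_KEPT]
    graph.add_edges_from(s.edge for s in active)
    scc_of: dict[str, int] = {}
    for i, comp in enumerate(nx.strongly_connected_components(graph)):
        for node in comp:
            scc_of[node] = i
    for s in active:
        if scc_of[s.child] == scc_of[s.parent]:
            s.status = STATUS_REMOVED_CYCLE
    return list(suggestions)


def remove_redundant(
    ontology: Ontology, suggestions: Sequence[Suggestion]
) -> list[Suggestion]:
    """Mark ``removed_redundant`` every suggestion derivable from the
    existing edges plus the other still-kept suggestions.

    Deterministic sequential fixed point: suggestions are re-examined in
    (child, parent) order until no status changes; cycle-causing
    suggestions must have been removed beforehand.
    """
    base = nx.DiGraph(ontology.isa_edges)
    base.add_nodes_from(ontology.concepts)
    changed = True
    while changed:
        changed = False
        active = sorted(
            (s for s in suggestions if s.status == STATUS_KEPT),
            key=lambda s: s.edge,
        )
        for s in active:
            graph = base.copy()
            graph.add_edges_from(t.edge for t in active if t is not s and t.status == STATUS_KEPT)
            if nx.has_path(graph, s.child, s.parent):
                s.status = STATUS_REMOVED_REDUNDANT
                changed = True
    return list(suggestions)


@dataclass
class PipelineReport:
    """Per-stage counts and the evidence-bearing suggestion list."""

    n_subgraphs: int
    n_candidates: int
    n_raw_suggestions: int
    n_removed_cycle: int
    n_removed_redundant: int
    n_kept: int
    suggestions: list[Suggestion] = field(default_factory=list)

    @property
    def kept(self) -> list[Suggestion]:
        return [s for s in self.suggestions if s.status == STATUS_KEPT]

    def to_tsv(self, ontology: Ontology, path=None) -> str:
        """Serialize suggestions as a deterministic TSV (sorted rows)."""
        columns = [
            "child_id", "child_name", "parent_id", "parent_name", "status",
            "rule_summary", "lexical_margin", "source_subgraphs", "logical_evidence",
        ]
        lines = ["\t".join(columns)]
        for s in sorted(self.suggestions, key=lambda s: s.edge):
            rules = "+".join(sorted(s.logical.rules_used())) or "none"
            lines.append(
                "\t".join(
                    [
                        s.child,
                        ontology.concepts[s.child].name,
                        s.parent,
                        ontology.concepts[s.parent].name,
                        s.status,
                        rules,
                        str(s.lexical_margin),
                        ";".join(sorted(s.source_subgraphs)),
                        s.logical.to_json(),
                    ]
                )
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def run(ontology: Ontology, config: Optional[PipelineConfig] = None) -> PipelineReport:
    """Execute the full pipeline and return its report."""
    config = config or PipelineConfig()
    provider = get_provider(config.provider)
    pairs = sorted(find_nonlattice_pairs(ontology), key=lambda p: p.id)
    subgraphs = [build_nonlattice_subgraph(ontology, p) for p in pairs]
    logger.info("non-lattice subgraphs: %d", len(subgraphs))
    candidates = sorted(candidate_pairs(ontology, subgraphs), key=lambda c: (c.x, c.y))
    logger.info("candidate pairs: %d", len(candidates))
    cache: dict[str, FeatureSet] = {}
    merged: dict[tuple[str, str], Suggestion] = {}
    for cand in candidates:
        for sugg in evaluate_pair(ontology, cand, config, provider, cache):
            logger.debug(
                "suggestion %s IS-A %s via %s",
                sugg.child, sugg.parent, sorted(sugg.logical.rules_used()),
            )
            existing = merged.get(sugg.edge)
            if existing is None:
                merged[sugg.edge] = sugg
            else:
                existing.source_subgraphs = frozenset(
                    existing.source_subgraphs | sugg.source_subgraphs
                )
    suggestions = [merged[k] for k in sorted(merged)]
    n_raw = len(suggestions)
    logger.info("raw suggestions: %d", n_raw)
    remove_cycle_causing(ontology, suggestions)
    remove_redundant(ontology, suggestions)
    n_cycle = sum(s.status == STATUS_REMOVED_CYCLE for s in suggestions)
    n_redundant = sum(s.status == STATUS_REMOVED_REDUNDANT for s in suggestions)
    report = PipelineReport(
        n_subgraphs=len(subgraphs),
        n_candidates=len(candidates),
        n_raw_suggestions=n_raw,
        n_removed_cycle=n_cycle,
        n_removed_redundant=n_redundant,
        n_kept=n_raw - n_cycle - n_redundant,
        suggestions=suggestions,
    )
    logger.info(
        "kept %d (removed %d cycle, %d redundant)", report.n_kept, n_cycle, n_redundant
    )
    return report
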