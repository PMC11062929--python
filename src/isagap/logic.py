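"""Relation-group-level logical definition subsumption.

A concept X's inferred definition I_X is a set of relation groups, each
a set of attribute-value defining relations (direct IS-A parents count
as singleton groups).  I_X is *more specific* than I_Y when every group
of I_Y has a witnessing group in I_X, where a group witnesses another
when every relation of the more general group has a more specific
counterpart in the witnessing group.

Two rules decide relation-level specificity:

* inclusion — the attribute and the value of the specific relation are
  each the same as or a descendant of their general counterparts;
* property chain — given an axiom ``k_a o k_b`` sub-property of ``k_Y``,
  a relation (k_X : v_X) is more specific than (k_Y : v_Y) when
  k_X ⊑ k_a and v_X carries a k_b relation to v_Y.  This covers e.g.
  (Causative agent : Sodium calcium edetate) vs (Causative agent :
  Edetate) through "Is modification of".

The IS-A attribute is structural: it only ever compares against itself
and never participates in chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .core import (
    DefiningRelation,
    InferredDefinition,
    Ontology,
    RelationGroup,
    UnknownConceptError,
)

RULE_INCLUSION = "inclusion"
RULE_CHAIN = "chain"

#: (general relation) -> (matched specific relation, rule)
RelationMatches = dict[DefiningRelation, tuple[DefiningRelation, str]]


@dataclass
class LogicalEvidence:
    """Outcome of a definition-level subsumption check with its matching."""

    holds: bool
    group_matching: dict[int, int] = field(default_factory=dict)
    relation_matches: dict[int, RelationMatches] = field(default_factory=dict)

    def rules_used(self) -> frozenset[str]:
        return frozenset(
            rule
            for matches in self.relation_matches.values()
            for (_, rule) in matches.values()
        )

    def to_document(self) -> dict:
        return {
            "holds": self.holds,
            "group_matching": {str(k): v for k, v in sorted(self.group_matching.items())},
            "relation_matches": {
                str(gi): {
                    f"{ry.attribute}:{ry.value}": {
                        "matched_by": f"{rx.attribute}:{rx.value}",
                        "rule": rule,
                    }
                    for ry, (rx, rule) in sorted(matches.items())
                }
                for gi, matches in sorted(self.relation_matches.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_document(), sort_keys=True, separators=(",", ":"))


def relation_more_specific(
    ontology: Ontology,
    rx: DefiningRelation,
    ry: DefiningRelation,
    *,
    allow_chain_value_subtype: bool = False,
) -> Optional[str]:
    """Return the first rule under which rx is more specific than ry, else None.

    The inclusion rule is tried before the property-chain rule.  With
    ``allow_chain_value_subtype`` the chain rule accepts a k_b relation
    to any descendant-or-self of v_Y instead of v_Y exactly.
    """
    isa = ontology.isa_attribute_id
    for cid in (rx.attribute, rx.value, ry.attribute, ry.value):
        if cid not in ontology.concepts:
            raise UnknownConceptError(cid)
    if (rx.attribute == isa) != (ry.attribute == isa):
        return None
    if rx.attribute == isa:
        # IS-A only matches IS-A, by value subsumption.
        if ontology.is_subsumed_by(rx.value, ry.value):
            return RULE_INCLUSION
        return None
    if ontology.is_subsumed_by(rx.attribute, ry.attribute) and ontology.is_subsumed_by(
        rx.value, ry.value
    ):
        return RULE_INCLUSION
    for chain in ontology.chains:
        if not ontology.is_subsumed_by(chain.super_attribute, ry.attribute):
            continue
        if not ontology.is_subsumed_by(rx.attribute, chain.leading):
            continue
        # v_X must carry a k_b relation to v_Y, in any of its groups.
        for group in ontology.attribute_relations.get(rx.value, ()):
            for rel in group.relations:
                if rel.attribute != chain.intermediate:
                    continue
                if rel.value == ry.value or (
                    allow_chain_value_subtype
                    and ontology.is_subsumed_by(rel.value, ry.value)
                ):
                    return RULE_CHAIN
    return None


def group_more_specific(
    ontology: Ontology,
    gx: RelationGroup,
    gy: RelationGroup,
    *,
    allow_chain_value_subtype: bool = False,
) -> Optional[RelationMatches]:
    """Matching if every relation of gy has a more specific relation in gx.

    Matching is existential and non-injective: one relation of gx may
    witness several relations of gy.
    """
    matches: RelationMatches = {}
    for ry in gy.sorted_relations():
        found = None
        for rx in gx.sorted_relations():
            rule = relation_more_specific(
                ontology, rx, ry, allow_chain_value_subtype=allow_chain_value_subtype
            )
            if rule is not None:
                found = (rx, rule)
                break
        if found is None:
            return None
        matches[ry] = found
    return matches


def definition_more_specific(
    ontology: Ontology,
    ix: InferredDefinition,
    iy: InferredDefinition,
    *,
    allow_chain_value_subtype: bool = False,
    injective: bool = False,
) -> LogicalEvidence:
    """Check that every group of iy is witnessed by some group of ix.

    By default one group of ix may witness several groups of iy; with
    ``injective`` each ix group is consumed by at most one iy group
    (decided by backtracking over the group bipartite matching).
    """
    witness_sets: dict[int, list[tuple[int, RelationMatches]]] = {}
    for gy in iy.groups:
        options = []
        for gx in ix.groups:
            matches = group_more_specific(
                ontology, gx, gy, allow_chain_value_subtype=allow_chain_value_subtype
            )
            if matches is not None:
                options.append((gx.group_index, matches))
        if not options:
            return LogicalEvidence(False)
        witness_sets[gy.group_index] = options

    evidence = LogicalEvidence(True)
    if not injective:
        for gy_index, options in witness_sets.items():
            gx_index, matches = options[0]
            evidence.group_matching[gy_index] = gx_index
            evidence.relation_matches[gy_index] = matches
        return evidence

    order = sorted(witness_sets, key=lambda gi: len(witness_sets[gi]))
    assignment: dict[int, tuple[int, RelationMatches]] = {}

    def assign(pos: int, used: set[int]) -> bool:
        if pos == len(order):
            return True
        gy_index = order[pos]
        for gx_index, matches in witness_sets[gy_index]:
            if gx_index in used:
                continue
            assignment[gy_index] = (gx_index, matches)
            if assign(pos + 1, used | {gx_index}):
                return True
        assignment.pop(gy_index, None)
        return False

    if not assign(0, set()):
        return LogicalEvidence(False)
    for gy_index, (gx_index, matches) in assignment.items():
        evidence.group_matching[gy_index] = gx_index
        evidence.relation_matches[gy_index] = matches
    return evidence


def has_attribute_relation(
    definition: InferredDefinition, isa_attribute_id: str
) -> bool:
    """True iff the definition carries at least one non-IS-A relation."""
    return any(
        rel.attribute != isa_attribute_id
        for group in definition.groups
        for rel in group.relations
    )
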