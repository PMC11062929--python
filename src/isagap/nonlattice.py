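"""Non-lattice pair and subgraph extraction, and candidate pair generation.

A pair of concepts is *non-lattice* when it has two or more maximal
common descendants (MCDs) — a violation of lattice structure that
frequently marks modelling defects in large terminologies.  A
non-lattice subgraph is aggregated from such a pair by computing the
minimal common ancestors (MCAs) of its MCDs and collecting every concept
lying on a hierarchical path from an MCD up to an MCA.  Candidate pairs
for missing IS-A detection are the hierarchically unrelated concept
pairs inside these subgraphs.

Reachability is evaluated over packed integer bitsets computed once per
ontology in topological order, which keeps whole-ontology pair
enumeration cheap at the scales this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .core import Ontology, UnknownConceptError


@dataclass(frozen=True)
class NonLatticePair:
    """Unordered concept pair with >= 2 maximal common descendants."""

    a: str
    b: str

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("non-lattice pair endpoints must differ")
        if self.a > self.b:  # canonical order for hashing/dedup
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def id(self) -> str:
        return f"{self.a}|{self.b}"


@dataclass(frozen=True)
class NonLatticeSubgraph:
    pair: NonLatticePair
    mcds: frozenset[str]
    mcas: frozenset[str]
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @property
    def id(self) -> str:
        return self.pair.id

    def to_document(self) -> dict:
        return {
            "pair": [self.pair.a, self.pair.b],
            "mcds": sorted(self.mcds),
            "mcas": sorted(self.mcas),
            "nodes": sorted(self.nodes),
            "edges": sorted(list(e) for e in self.edges),
        }


@dataclass(frozen=True)
class CandidatePair:
    """Unordered, hierarchically unrelated pair drawn from subgraphs."""

    x: str
    y: str
    source_subgraphs: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.x > self.y:
            x, y = self.x, self.y
            object.__setattr__(self, "x", y)
            object.__setattr__(self, "y", x)
        if self.x == self.y:
            raise ValueError("candidate pair endpoints must differ")


class _Bitsets:
    """Descendant-or-self / ancestor-or-self sets as packed ints."""

    def __init__(self, ontology: Ontology):
        self.ids: list[str] = sorted(ontology.concepts)
        self.index = {cid: i for i, cid in enumerate(self.ids)}
        graph = ontology.graph
        desc = {}
        anc = {}
        for cid in nx.topological_sort(graph):  # children before parents
            mask = 1 << self.index[cid]
            for child in graph.predecessors(cid):
                mask |= desc[child]
            desc[cid] = mask
        for cid in reversed(list(nx.topological_sort(graph))):
            mask = 1 << self.index[cid]
            for parent in graph.successors(cid):
                mask |= anc[parent]
            anc[cid] = mask
        self.desc_or_self = desc
        self.anc_or_self = anc

    def members(self, mask: int) -> frozenset[str]:
        out = []
        while mask:
            low = mask & -mask
            out.append(self.ids[low.bit_length() - 1])
            mask ^= low
        return frozenset(out)

    def maximal(self, mask: int) -> frozenset[str]:
        """Members of mask that are not proper descendants of another member."""
        members = self.members(mask)
        out = []
        for c in members:
            bit = 1 << self.index[c]
            if not any(
                d != c and (self.desc_or_self[d] & bit) for d in members
            ):
                out.append(c)
        return frozenset(out)

    def minimal(self, mask: int) -> frozenset[str]:
        members = self.members(mask)
        out = []
        for c in members:
            bit = 1 << self.index[c]
            if not any(
                d != c and (self.anc_or_self[d] & bit) for d in members
            ):
                out.append(c)
        return frozenset(out)


def _bitsets(ontology: Ontology) -> _Bitsets:
    # memoized on the (immutable) ontology instance
    cached = getattr(ontology, "_nl_bitsets", None)
    if cached is None:
        cached = _Bitsets(ontology)
        ontology._nl_bitsets = cached  # type: ignore[attr-defined]
    return cached


def maximal_common_descendants(ontology: Ontology, a: str, b: str) -> frozenset[str]:
    """The ⊑-maximal elements of the common descendant-or-self set of a and b."""
    for cid in (a, b):
        if cid not in ontology.concepts:
            raise UnknownConceptError(cid)
    bs = _bitsets(ontology)
    return bs.maximal(bs.desc_or_self[a] & bs.desc_or_self[b])


def minimal_common_ancestors(ontology: Ontology, concept_set: Iterable[str]) -> frozenset[str]:
    """The ⊑-minimal concepts that are ancestor-or-self of every input concept."""
    concept_set = list(concept_set)
    if not concept_set:
        raise ValueError("concept_set must be non-empty")
    bs = _bitsets(ontology)
    for cid in concept_set:
        if cid not in ontology.concepts:
            raise UnknownConceptError(cid)
    common = bs.anc_or_self[concept_set[0]]
    for cid in concept_set[1:]:
        common &= bs.anc_or_self[cid]
    return bs.minimal(common)


def find_nonlattice_pairs(ontology: Ontology) -> frozenset[NonLatticePair]:
    """All unordered pairs with >= 2 maximal common descendants."""
    bs = _bitsets(ontology)
    # >= 2 maximal common descendants needs >= 2 common descendants, so
    # each endpoint's descendant-or-self set must have >= 2 members.
    candidates = [cid for cid in bs.ids if bs.desc_or_self[cid].bit_count() >= 2]
    pairs = []
    for a, b in combinations(candidates, 2):
        common = bs.desc_or_self[a] & bs.desc_or_self[b]
        if common.bit_count() < 2:
            continue
        if len(bs.maximal(common)) >= 2:
            pairs.append(NonLatticePair(a, b))
    return frozenset(pairs)


def build_nonlattice_subgraph(ontology: Ontology, pair: NonLatticePair) -> NonLatticeSubgraph:
    """Aggregate the subgraph spanned between a pair's MCDs and their MCAs."""
    mcds = maximal_common_descendants(ontology, pair.a, pair.b)
    if len(mcds) < 2:
        raise ValueError(f"pair {pair.id} is not a non-lattice pair")
    mcas = minimal_common_ancestors(ontology, mcds)
    bs = _bitsets(ontology)
    below_mcas = 0
    for cid in mcas:
        below_mcas |= bs.desc_or_self[cid]
    above_mcds = 0
    for cid in mcds:
        above_mcds |= bs.anc_or_self[cid]
    nodes = bs.members(below_mcas & above_mcds)
    edges = frozenset(
        (c, p) for c, p in ontology.isa_edges if c in nodes and p in nodes
    )
    return NonLatticeSubgraph(pair, mcds, mcas, nodes, edges)


def candidate_pairs(
    ontology: Ontology, subgraphs: Sequence[NonLatticeSubgraph]
) -> frozenset[CandidatePair]:
    """Hierarchically unrelated node pairs within each subgraph, de-duplicated
    across subgraphs with provenance."""
    bs = _bitsets(ontology)
    merged: dict[tuple[str, str], set[str]] = {}
    for sg in subgraphs:
        nodes = sorted(sg.nodes)
        for x, y in combinations(nodes, 2):
            if bs.anc_or_self[x] & (1 << bs.index[y]):
                continue
            if bs.anc_or_self[y] & (1 << bs.index[x]):
                continue
            merged.setdefault((x, y), set()).add(sg.id)
    return frozenset(
        CandidatePair(x, y, frozenset(sources)) for (x, y), sources in merged.items()
    )
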