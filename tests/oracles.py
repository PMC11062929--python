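"""Brute-force graph oracles, independent of the package's implementation
(no networkx, no bitsets): plain dict-and-set fixed-point reachability."""

from __future__ import annotations


def reachable(edges: set[tuple[str, str]], start: str) -> set[str]:
    """Nodes reachable from start via repeated edge expansion (excl. start
    unless on a cycle)."""
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
    out: set[str] = set()
    frontier = {start}
    while frontier:
        nxt = set()
        for node in frontier:
            for succ in adj.get(node, ()):
                if succ not in out:
                    out.add(succ)
                    nxt.add(succ)
        frontier = nxt
    return out


def ancestors_oracle(edges, node):
    return reachable(set(edges), node)


def descendants_oracle(edges, node):
    return reachable({(b, a) for a, b in edges}, node)


def desc_or_self(edges, node):
    return descendants_oracle(edges, node) | {node}


def anc_or_self(edges, node):
    return ancestors_oracle(edges, node) | {node}


def mcd_oracle(edges, nodes, a, b):
    """Maximal common descendants: intersect descendant-or-self sets, then
    keep members that are proper descendants of no other member."""
    common = desc_or_self(edges, a) & desc_or_self(edges, b)
    return {
        c
        for c in common
        if not any(d != c and c in descendants_oracle(edges, d) for d in common)
    }


def mca_oracle(edges, nodes, concept_set):
    common = None
    for c in concept_set:
        s = anc_or_self(edges, c)
        common = s if common is None else common & s
    return {
        c
        for c in common
        if not any(d != c and c in ancestors_oracle(edges, d) for d in common)
    }


def nonlattice_pairs_oracle(edges, nodes):
    out = set()
    nodes = sorted(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if len(mcd_oracle(edges, nodes, a, b)) >= 2:
                out.add((a, b))
    return out


def transitively_derivable(edges: set[tuple[str, str]], edge: tuple[str, str]) -> bool:
    return edge[1] in reachable(edges, edge[0])
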