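# Methods

## Data model

An `Ontology` holds concepts (opaque string ids, names with SNOMED-style
trailing semantic tags, a primitive / fully-defined status flag), a
directed acyclic IS-A graph stored as child → parent edges, per-concept
attribute relations partitioned into relation groups, and property-chain
axioms `leading ∘ intermediate ⊑ super`. The IS-A attribute id
(default `116680003`) is reserved and structural: IS-A relations are
represented uniformly as attribute–value pairs inside definitions, but
they only ever compare against other IS-A relations and never
participate in chains or in the attribute hierarchy.

A concept's inferred definition is the set of its direct IS-A parents,
one singleton group each, plus its attribute groups. Direct parents —
not inherited ancestors — populate the IS-A groups; the value-level
same-or-descendant test inside the inclusion rule supplies the
transitive slack that inherited parents would otherwise provide.
Attribute subsumption uses the same IS-A graph (attributes are
concepts); an attribute with no hierarchy entries matches only itself.

Two readers are provided. The RF2 snapshot reader keeps only `active=1`
rows and inferred-characteristic relationships, maps FSN descriptions to
names, treats `relationshipGroup=0` rows as singleton groups (the SNOMED
convention for ungrouped relations) and rejects missing files, dangling
references and hierarchy cycles. The native table reader ingests small
TSV bundles (`concepts/isa/attributes/chains.tsv`) or an equivalent JSON
document; when the attributes table has no `group_index` column every
relation is its own group, which is also how NCIt-style content (which
does not group relations) is represented. Full/Delta RF2 releases and
OWL parsing are out of scope; property chains arrive via the chains
table, since the handful of relevant axioms does not justify an OWL
axiom-refset parser.

## Non-lattice extraction

Descendant-or-self and ancestor-or-self sets are computed once per
ontology, in topological order, as packed integer bitsets; all pair
enumeration, maximality filtering and subgraph aggregation is bit
arithmetic on those. Common-descendant semantics are
*descendant-or-self*, so a pair endpoint can itself be a common
descendant and singleton cases are well defined. A subgraph's node set
is (descendants-or-self of the MCAs) ∩ (ancestors-or-self of the MCDs),
i.e. exactly the concepts on some directed path from an MCD up to an
MCA; its edges are the induced IS-A edges. Candidate pairs are all
hierarchically unrelated node pairs of each subgraph (not only pairs
involving MCDs), de-duplicated across subgraphs with the canonical
subgraph id `"a|b"` as provenance; pairs spanning two different
subgraphs' node sets are not generated. Exhaustive pair enumeration is
quadratic in concept count, which is adequate at the package's target
scales (fixtures, synthetic instances, subhierarchy extracts); the
brute-force oracles in the test suite are independent fixed-point
reachability implementations without bitsets or networkx.

## Logical subsumption

Matching is existential and non-injective at both levels: one subtype
group may witness several supertype groups, one relation several
relations. An `injective` flag (off by default) switches the group
level to a backtracking bipartite assignment for users who want
one-to-one witnesses. Rule precedence is fixed: inclusion first, the
property-chain rule only on inclusion failure, and the first success is
recorded in the evidence. The chain rule is literal about its value
condition — `v_X` must carry an `intermediate`-attribute relation to
exactly `v_Y` — with a config flag (`chain_value_subtype_allowed`, off
by default) that relaxes it to descendant-or-self. A chain applies when
its super-attribute equals or descends from the general relation's
attribute, and the intermediate relation of `v_X` is searched across
all of `v_X`'s groups. Transitive attributes are expressed as chains
`k ∘ k ⊑ k`; chains are applied once, never nested.

A definition with no groups is vacuously subsumed by everything; the
pipeline's supertype filters (below) keep such concepts from producing
suggestions.

## Lexical features

Names are tokenised on whitespace after stripping one trailing
parenthesized semantic tag. Three feature classes are unioned, all
lowercase: dependency pairs `"head object"` for pobj/dobj tokens;
base noun phrases of ≥ 2 tokens; and residual words whose token index
was not consumed (as head or dependent) by a dependency pair.
Single-token noun phrases deliberately fall through to the residual
rule, and a residual word consumed by a pair is dropped — together these
reproduce the canonical seven-feature example
(`{of nerve, of abdomen, malignant, neoplasm, peripheral, malignant
neoplasm, peripheral nerve}`). No lemmatisation, stop-word removal or
plural folding is applied; enrichment is the union of the concept's own
features with those of *all* its IS-A ancestors (whole ontology, not
per-subhierarchy), memoised per concept.

The default syntactic provider is a bundled deterministic rule-based
parser for the prepositional patterns
`<modifier>* <noun> (of <modifier>* <noun>)*` that dominate terminology
labels: contiguous non-preposition runs become noun-phrase spans, and
the last token of a run following a preposition is its pobj. Its
analyses are pure functions of the input string, so every lexical
result in the package is bit-stable. A spaCy adapter
(`model:<name>`) is available for free-form names; its output varies
with the model version, so it is never used in tests.

## Pipeline

Both orientations of every candidate pair are tested. A suggestion
`X IS-A Y` requires, in order: Y primitive (flag-gated, on by default —
in an inferred release a fully defined supertype would already have its
subtypes inferred, and the generator and fixtures model hand-built
content the same way); Y carrying at least one attribute relation
(flag-gated, on by default — an IS-A-only definition is too weak to
certify subtypes); the logical check; the lexical superset check.
Suggestions found via several subgraphs are emitted once with merged
provenance.

Cycle removal runs **before** redundancy removal: an edge on a cycle
makes every other edge of the cycle trivially derivable, which would
corrupt the redundancy fixed point. Cycle removal marks every
suggestion whose endpoints share a strongly connected component of
(existing edges ∪ all suggestions) — covering mutually-suggested pairs
and suggestions contradicting an existing path. Redundancy removal is
a deterministic sequential fixed point: suggestions are scanned in
(child, parent) order, one is marked redundant when its endpoint is
reachable through existing edges plus the other still-kept suggestions,
and scanning repeats until stable. The simultaneous "all others"
reading is ill-defined when two suggestions mutually imply each other;
the sequential variant coincides with it on every acyclic case.

Output is a TSV sorted by (child, parent) with the evidence serialized
as canonical JSON, so identical inputs yield byte-identical files.

## Synthetic data

`random_dag(n, edge_prob, seed)` draws edges only from higher to lower
index (acyclic by construction) and names concepts from a controlled
multi-word vocabulary so the lexical operations are exercisable.

`plant_missing_isas(n_background, n_planted, seed)` plants each missing
relation as a five-concept gadget: two fully defined roots, a primitive
parent with one attribute group, a fully defined child whose group is
pointwise more specific (inclusion-rule cases alternate with
property-chain cases), and a decoy sibling, all three placed under both
roots so the root pair is non-lattice with the parent, child and decoy
as its maximal common descendants. The child's name is the parent's
name with a leading modifier token, which with ancestor enrichment
guarantees the lexical superset. Background concepts form a sparse
random DAG (expected in-range degree ≈ 2) and are fully defined and
attribute-free, so they can never pass the supertype filters. The
generator defaults used throughout testing are 200 background concepts
and 5 planted relations per instance. A certificate re-verifies every
guarantee through the package's own operations (primitive status,
attribute presence, logical and lexical subsumption, candidate-pair
membership, acyclicity and non-redundancy of the planted set) and
additionally confirms that the planted parents are the *only* concepts
able to pass the supertype filters, so a certified instance is
collision-free by construction and recall = precision = 1.0 is the
expected pipeline outcome.

What the generator does not emulate: multi-group definitions with
partially overlapping groups, homonymous names, deep diamond-rich
hierarchies, near-miss lexical overlaps, or the noisy modelling
practices of real releases. Passing on planted instances therefore
demonstrates the machinery end to end, not the precision that expert
review would measure on a licensed terminology.

## Numerical and degenerate-input choices

- Ontologies are immutable after construction; derived variants come
  from `with_edges` / `with_chains`, which re-validate.
- Acyclicity is checked at load; the error names one offending cycle.
- Unknown ids raise `UnknownConceptError` uniformly.
- Ties (which group witnesses, which suggestion is scanned first) are
  broken by sorted order on indices and ids, never by hash order.
- `NonLatticePair` / `CandidatePair` canonicalise endpoint order, so
  deduplication is structural.

## Known limitations

- No DL reasoning: the tool consumes inferred releases and never
  re-classifies; stated axioms are out of scope.
- The rule-based provider mis-parses names that are not noun-phrase /
  prepositional-chain shaped (verbal constructions, coordination);
  dobj features effectively require the spaCy provider.
- Whole-ontology pair enumeration is quadratic; very large releases
  should be processed per subhierarchy.
- Suggested relations are candidates for expert review, not repairs:
  the underlying defect may be a wrong logical definition rather than
  a missing edge.
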