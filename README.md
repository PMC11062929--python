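# isagap

Detect potentially missing IS-A (subtype) relations in biomedical
terminologies such as SNOMED CT and the NCI thesaurus.

## The problem

Large clinical terminologies are maintained as description-logic
ontologies: each concept carries a logical definition (hierarchical
IS-A relations plus grouped attribute–value relations such as
*Finding site* or *Causative agent*), and a DL classifier infers the
concept hierarchy from the *fully defined* concepts. When a concept is
marked **primitive**, the classifier never infers subtypes beneath it —
so a concept whose definition is genuinely more specific than a
primitive concept's can silently lack the IS-A edge. `isagap` finds
such candidates automatically.

## The method

1. **Non-lattice extraction.** A concept pair is *non-lattice* when it
   has two or more maximal common descendants (MCDs); such graph
   fragments concentrate modelling defects. For each non-lattice pair
   the subgraph between its MCDs and their minimal common ancestors is
   aggregated, and every hierarchically unrelated concept pair inside
   it becomes a candidate.
2. **Logical subsumption at relation-group level.** Writing a concept's
   inferred definition as a set of relation groups
   `I_X = {X_n}`, `X_n = {(k : v)}`, `I_X` is more specific than `I_Y`
   iff every group `Y_m` has a witnessing group `X_n` in which every
   relation `(k_Y : v_Y)` has a more specific counterpart `(k_X : v_X)`:
   - *inclusion rule*: `k_X ⊑ k_Y` and `v_X ⊑ v_Y` (same-or-descendant);
   - *property-chain rule*: given `k_a ∘ k_b ⊑ k_Y`, it suffices that
     `k_X ⊑ k_a` and `v_X` carries a `k_b` relation to `v_Y`
     (e.g. *Causative agent ∘ Is modification of ⊑ Causative agent*).
   Supertype candidates must be primitive and carry at least one
   attribute relation.
3. **Lexical corroboration.** Each concept name (semantic tag stripped)
   yields a feature set of dependency pairs (`"of nerve"`), multi-word
   base noun phrases (`"malignant neoplasm"`) and residual words;
   enriching with all ancestors' features, `X IS-A Y` additionally
   requires enriched(X) ⊇ enriched(Y).
4. **Pruning.** Suggestions that would create cycles are removed, then
   suggestions transitively derivable from the existing hierarchy plus
   the other kept suggestions are marked redundant.

## Worked example

The bundled neoplasm fixture encodes a non-lattice subgraph whose pair
roots (*Neoplasm of peripheral nerves of trunk*, *Neoplasm of abdomen*)
share three maximal common descendants, one of which — *Neoplasm of
peripheral nerves of abdomen (disorder)* — is primitive with a
two-relation attribute group:

```python
import isagap as ig

ont = ig.paper_fixture_snomed()
report = ig.run(ont)
print(f"subgraphs={report.n_subgraphs} candidates={report.n_candidates} "
      f"kept={report.n_kept}")
for s in report.kept:
    print(ont.concepts[s.child].name, " IS-A ", ont.concepts[s.parent].name)
```

prints

```
subgraphs=1 candidates=4 raw=2 removed_cycle=0 removed_redundant=0 kept=2
Malignant neoplasm of peripheral nerve of abdomen (disorder)  IS-A  Neoplasm of peripheral nerves of abdomen (disorder)  [rules=inclusion, margin=4]
Benign ganglioneuroma of abdomen (disorder)  IS-A  Neoplasm of peripheral nerves of abdomen (disorder)  [rules=inclusion, margin=3]
```

One non-lattice subgraph produced four unrelated candidate pairs, of
which exactly two satisfy both the logical and the lexical subsumption
check in one direction; neither is cycle-causing nor redundant, so both
are kept. `rules=inclusion` says every relation matched by the
inclusion rule; `margin` counts the child-only enriched features.

The same works from the shell on any RF2 snapshot or native table
bundle:

```bash
isagap suggest --ontology path/to/ontology --out suggestions.tsv
isagap features "Malignant neoplasm of peripheral nerve of abdomen (disorder)"
isagap synth --preset planted --n 200 --seed 7 --out synth/
```

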