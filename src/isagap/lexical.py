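"""Lexical feature sets of concept names and the superset subsumption check.

Three feature classes are aggregated from a concept name (after the
SNOMED semantic tag, e.g. "(disorder)", is stripped):

1. dependency pairs "head word + object word" for prepositional-object
   (pobj) and direct-object (dobj) dependencies, e.g. "of nerve";
2. base noun phrases spanning at least two tokens, e.g. "malignant
   neoplasm" (single-token phrases fall through to class 3);
3. residual single words whose token was not consumed by a dependency
   pair, e.g. "malignant", "neoplasm", "peripheral".

Features are lowercase.  A concept's *enriched* set is the union of its
own initial set with the initial sets of all its IS-A ancestors; concept
X is lexically more specific than Y when enriched(X) ⊇ enriched(Y).

Syntactic analyses come from a provider.  The bundled rule-based
provider is deterministic and handles the prepositional concept-name
patterns ("<modifier>* <noun> (of <modifier>* <noun>)*") that dominate
terminology labels; a spaCy adapter can be selected for free-form names
when that library is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol

from .core import Ontology, UnknownConceptError

DEPENDENCY_LABELS = ("pobj", "dobj")

#: prepositions recognised by the rule-based provider
_PREPOSITIONS = {
    "of", "in", "on", "by", "with", "without", "to", "from", "for", "at",
    "into", "via", "during", "due",
}


@dataclass(frozen=True)
class Token:
    surface: str
    lower: str
    dep: str
    head: int


@dataclass(frozen=True)
class TokenAnalysis:
    tokens: tuple[Token, ...]
    noun_phrase_spans: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class FeatureSet:
    """Set of lowercase lexical features."""

    features: frozenset[str]

    def __contains__(self, item: str) -> bool:
        return item in self.features

    def __len__(self) -> int:
        return len(self.features)

    def union(self, *others: "FeatureSet") -> "FeatureSet":
        out = set(self.features)
        for other in others:
            out |= other.features
        return FeatureSet(frozenset(out))


class SyntacticProvider(Protocol):
    name: str
    deterministic: bool

    def analyze(self, text: str) -> TokenAnalysis: ...


class ProviderError(RuntimeError):
    """A syntactic provider failed to analyse a name."""


class RuleBasedProvider:
    """Deterministic parser for prepositional concept-name patterns.

    Tokens split on whitespace ("/" stays inside tokens).  Contiguous
    runs of non-preposition tokens become base noun-phrase spans; the
    last token of the run following a preposition is marked ``pobj``
    with the preposition as its head.
    """

    name = "rulebased"
    deterministic = True

    def analyze(self, text: str) -> TokenAnalysis:
        surfaces = text.split()
        lowers = [s.lower() for s in surfaces]
        deps = [""] * len(surfaces)
        heads = list(range(len(surfaces)))
        spans: list[tuple[int, int]] = []
        i = 0
        while i < len(surfaces):
            if lowers[i] in _PREPOSITIONS:
                i += 1
                continue
            j = i
            while j < len(surfaces) and lowers[j] not in _PREPOSITIONS:
                j += 1
            spans.append((i, j))
            if i > 0 and lowers[i - 1] in _PREPOSITIONS:
                deps[j - 1] = "pobj"
                heads[j - 1] = i - 1
            i = j
        tokens = tuple(
            Token(surfaces[k], lowers[k], deps[k], heads[k])
            for k in range(len(surfaces))
        )
        return TokenAnalysis(tokens, tuple(spans))


class SpacyProvider:
    """Adapter around a spaCy pipeline (statistical parse, noun chunks).

    Requires spaCy and the named model to be installed; analyses are
    deterministic only insofar as the loaded model is.
    """

    deterministic = False

    def __init__(self, model: str = "en_core_web_sm"):
        try:
            import spacy  # noqa: PLC0415
        except ImportError as exc:  # pragma: no cover - spaCy optional
            raise ProviderError(
                f"provider model:{model} requires spaCy, which is not installed"
            ) from exc
        self.name = f"model:{model}"
        self._nlp = spacy.load(model)

    def analyze(self, text: str) -> TokenAnalysis:  # pragma: no cover - optional
        doc = self._nlp(text)
        tokens = tuple(
            Token(t.text, t.text.lower(), t.dep_ if t.dep_ in DEPENDENCY_LABELS else "", t.head.i)
            for t in doc
        )
        spans = tuple((chunk.start, chunk.end) for chunk in doc.noun_chunks)
        return TokenAnalysis(tokens, spans)


def get_provider(spec: str = "rulebased") -> SyntacticProvider:
    """Resolve a provider identifier: ``rulebased`` or ``model:<name>``."""
    if spec == "rulebased":
        return RuleBasedProvider()
    if spec.startswith("model:"):
        return SpacyProvider(spec.split(":", 1)[1])
    raise ValueError(f"unknown lexical provider: {spec!r}")


_TAG_RE = re.compile(r"\s*\([^()]*\)\s*$")


def strip_semantic_tag(name: str) -> str:
    """Remove one trailing parenthesized semantic tag, if present."""
    return _TAG_RE.sub("", name)


def _dependency_pairs(analysis: TokenAnalysis) -> tuple[set[str], set[int]]:
    features: set[str] = set()
    consumed: set[int] = set()
    for idx, token in enumerate(analysis.tokens):
        if token.dep in DEPENDENCY_LABELS:
            head = analysis.tokens[token.head]
            features.add(f"{head.lower} {token.lower}")
            consumed.add(idx)
            consumed.add(token.head)
    return features, consumed


def extract_dependency_pairs(analysis: TokenAnalysis) -> frozenset[str]:
    """Lowercase "head word + object word" features for pobj/dobj tokens."""
    features, _ = _dependency_pairs(analysis)
    return frozenset(features)


def extract_noun_phrase_features(analysis: TokenAnalysis) -> frozenset[str]:
    """Lowercase multi-word base noun phrases (single-token spans are left
    to the residual-word rule)."""
    out = set()
    for start, end in analysis.noun_phrase_spans:
        if end - start >= 2:
            out.add(" ".join(t.lower for t in analysis.tokens[start:end]))
    return frozenset(out)


def initial_feature_set(
    name: str, provider: Optional[SyntacticProvider] = None
) -> FeatureSet:
    """Aggregate dependency pairs, multi-word noun phrases and residual words."""
    if not name:
        raise ValueError("concept name must be non-empty")
    provider = provider or RuleBasedProvider()
    try:
        analysis = provider.analyze(strip_semantic_tag(name))
    except ProviderError:
        raise
    except Exception as exc:
        raise ProviderError(f"provider {provider.name!r} failed on {name!r}") from exc
    pairs, consumed = _dependency_pairs(analysis)
    phrases = extract_noun_phrase_features(analysis)
    residual = {
        token.lower
        for idx, token in enumerate(analysis.tokens)
        if idx not in consumed
    }
    return FeatureSet(frozenset(pairs | phrases | residual))


def enriched_feature_set(
    ontology: Ontology,
    concept_id: str,
    provider: Optional[SyntacticProvider] = None,
    cache: Optional[dict[str, FeatureSet]] = None,
) -> FeatureSet:
    """The concept's initial set unioned with all its ancestors' initial sets."""
    if concept_id not in ontology.concepts:
        raise UnknownConceptError(concept_id)
    provider = provider or RuleBasedProvider()
    cache = cache if cache is not None else {}

    def initial(cid: str) -> FeatureSet:
        if cid not in cache:
            cache[cid] = initial_feature_set(ontology.concepts[cid].name, provider)
        return cache[cid]

    out = initial(concept_id)
    return out.union(*(initial(a) for a in sorted(ontology.ancestors(concept_id))))


def lexical_subsumes(child_set: FeatureSet, parent_set: FeatureSet) -> bool:
    """True iff the parent's features are a (non-strict) subset of the child's."""
    return parent_set.features <= child_set.features
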