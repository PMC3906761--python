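"""Sentence- and abstract-level drug–SE co-occurrence in a literature corpus.

An in-process inverted index maps each lexicon term (drug generics, trade
names — resolved to generics — and side-effect terms) to the (document,
sentence) positions where it occurs as a contiguous token sequence,
case-insensitively. A pair has sentence-level evidence when both terms occur
in the same sentence, and abstract-level evidence when both occur anywhere
in the same document; sentence-level evidence always implies abstract-level.

Plain co-occurrence admits false positives where the side-effect term's
tokens appear in a non-entity role ("baclofen decreased activity during a
30-min period" is not reporting the side effect "decreased activity"). A
syntactic filter is out of scope here, but ``evidence_for`` accepts a
``sentence_filter`` hook so one can be plugged in.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .corpus_io import DrugLexicon, LiteratureDocument, SideEffectLexicon
from .normalize import _TOKEN_RE, normalize
from .pair_extraction import DrugSEPair

# hook signature: (doc_id, sentence_index, sentence_text, drug, se) -> keep?
SentenceFilter = Callable[[str, int, str, str, str], bool]


@dataclass
class LiteratureEvidence:
    """Per-pair co-occurrence counts at sentence and abstract level."""

    sentence_count: dict[DrugSEPair, int] = field(default_factory=dict)
    abstract_count: dict[DrugSEPair, int] = field(default_factory=dict)

    def evidence_set(self, level: str) -> set[DrugSEPair]:
        """Pairs with a positive count at the requested level."""
        if level == "sentence":
            return {p for p, c in self.sentence_count.items() if c > 0}
        if level == "abstract":
            return {p for p, c in self.abstract_count.items() if c > 0}
        raise ValueError(f"level must be sentence|abstract, got {level!r}")


def evidence_set(ev: LiteratureEvidence, level: str) -> set[DrugSEPair]:
    return ev.evidence_set(level)


class LiteratureIndex:
    """Inverted index of lexicon-term occurrences in a sentence corpus.

    Postings record every sentence whose token sequence contains the term's
    token sequence contiguously (so nested terms are all indexed, and a term
    never matches inside a longer token). Deterministic for fixed inputs.
    """

    def __init__(
        self,
        corpus: Sequence[LiteratureDocument],
        drug_lex: DrugLexicon,
        se_lex: SideEffectLexicon,
    ):
        # canonical term -> set of surface token tuples
        surfaces: dict[tuple[str, ...], str] = {}
        for g in drug_lex.generics:
            surfaces[tuple(_TOKEN_RE.findall(g))] = g
        for t, g in drug_lex.trade_to_generic.items():
            surfaces[tuple(_TOKEN_RE.findall(t))] = g
        for term in se_lex.terms:
            surfaces[tuple(_TOKEN_RE.findall(term))] = term
        surfaces.pop((), None)
        max_len = max((len(k) for k in surfaces), default=0)

        self.sentence_postings: dict[str, set[tuple[str, int]]] = defaultdict(set)
        self.doc_postings: dict[str, set[str]] = defaultdict(set)
        self._sentences: dict[tuple[str, int], str] = {}
        for doc in corpus:
            for si, sent in enumerate(doc.sentences):
                self._sentences[(doc.doc_id, si)] = sent
                toks = _TOKEN_RE.findall(normalize(sent))
                seen: set[str] = set()
                for i in range(len(toks)):
                    for L in range(1, min(max_len, len(toks) - i) + 1):
                        canonical = surfaces.get(tuple(toks[i : i + L]))
                        if canonical is not None:
                            seen.add(canonical)
                for canonical in seen:
                    self.sentence_postings[canonical].add((doc.doc_id, si))
                    self.doc_postings[canonical].add(doc.doc_id)

    def postings(self, term: str, level: str = "sentence") -> set:
        term = normalize(term)
        if level == "sentence":
            return set(self.sentence_postings.get(term, ()))
        if level == "abstract":
            return set(self.doc_postings.get(term, ()))
        raise ValueError(f"level must be sentence|abstract, got {level!r}")

    def sentence_text(self, doc_id: str, sentence_index: int) -> str:
        return self._sentences[(doc_id, sentence_index)]


def build_index(
    corpus: Sequence[LiteratureDocument],
    drug_lex: DrugLexicon,
    se_lex: SideEffectLexicon,
) -> LiteratureIndex:
    """Index every lexicon term's sentence and document occurrences."""
    return LiteratureIndex(corpus, drug_lex, se_lex)


def evidence_for(
    pairs: Iterable[DrugSEPair | tuple[str, str]],
    index: LiteratureIndex,
    sentence_filter: SentenceFilter | None = None,
) -> LiteratureEvidence:
    """Co-occurrence counts for each queried pair.

    sentence_count is the number of sentences containing both terms (after
    the optional filter); abstract_count is the number of documents
    containing both terms anywhere. Trade names were already resolved to
    generics when the index was built, so queries use generic names.
    """
    ev = LiteratureEvidence()
    for p in pairs:
        pair = DrugSEPair(*p)
        d_sent = index.sentence_postings.get(pair.drug, ())
        s_sent = index.sentence_postings.get(pair.se, ())
        hits = set(d_sent) & set(s_sent)
        if sentence_filter is not None:
            hits = {
                (doc, si)
                for doc, si in hits
                if sentence_filter(doc, si, index.sentence_text(doc, si), pair.drug, pair.se)
            }
        d_doc = index.doc_postings.get(pair.drug, ())
        s_doc = index.doc_postings.get(pair.se, ())
        ev.sentence_count[pair] = len(hits)
        ev.abstract_count[pair] = len(set(d_doc) & set(s_doc))
    return ev
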