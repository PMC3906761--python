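"""Dictionary-based named-entity recognition for drugs and side effects.

Drug strings in spontaneous reports are free text ("erbitux 100 mg imclone
/bms"); drug entities are found by longest-leftmost dictionary matching on
token boundaries against the drug lexicon, and trade names are mapped to
their generic names. Misspellings are deliberately not recovered: a string
with no dictionary hit yields an empty result, which run statistics count.

Event strings are MedDRA-coded, so side-effect recognition is whole-string
matching against the cleaned side-effect lexicon after normalization.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus_io import DrugLexicon, SideEffectLexicon
from .errors import ValidationError
from .normalize import _TOKEN_RE, normalize


@dataclass
class NERResult:
    """Entities recognized in one input string.

    Spans index into the NFC-lowercased input; they are token-aligned and
    non-overlapping. ``unmatched`` is true iff no entity was found.
    """

    input_string: str
    entities: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def unmatched(self) -> bool:
        return not self.entities

    @property
    def canonical_names(self) -> list[str]:
        """Deduplicated canonical names, first occurrence preserved."""
        seen: dict[str, None] = {}
        for name, _, _ in self.entities:
            seen.setdefault(name)
        return list(seen)


class DictionaryMatcher:
    """Longest-leftmost, token-boundary phrase matcher over a fixed dictionary.

    Phrases are stored as normalized token tuples, so matching is insensitive
    to case, surrounding punctuation and runs of whitespace, and a phrase
    never matches inside a longer token ("ici" does not hit "toxicity").
    Lexicon insertion order does not affect results.
    """

    def __init__(self, phrases: Mapping[str, str] | Iterable[str]):
        if not isinstance(phrases, Mapping):
            phrases = {p: p for p in phrases}
        self._phrases: dict[tuple[str, ...], str] = {}
        for surface, canonical in phrases.items():
            toks = tuple(_TOKEN_RE.findall(normalize(surface)))
            if toks:
                self._phrases[toks] = canonical
        self.max_len = max((len(t) for t in self._phrases), default=0)

    def find(self, s: str) -> list[tuple[str, int, int]]:
        """All longest-leftmost non-overlapping matches as (canonical, start, end)."""
        base = unicodedata.normalize("NFC", s).lower()
        toks = [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(base)]
        out: list[tuple[str, int, int]] = []
        i = 0
        while i < len(toks):
            hit = None
            for L in range(min(self.max_len, len(toks) - i), 0, -1):
                key = tuple(t[0] for t in toks[i : i + L])
                canonical = self._phrases.get(key)
                if canonical is not None:
                    hit = (canonical, toks[i][1], toks[i + L - 1][2], L)
                    break
            if hit is None:
                i += 1
            else:
                out.append(hit[:3])
                i += hit[3]
        return out

    def phrase_set(self) -> set[tuple[str, ...]]:
        return set(self._phrases)


def drug_matcher(lex: DrugLexicon) -> DictionaryMatcher:
    """Matcher over all drug surface forms, mapping trade names to generics."""
    surfaces = {g: g for g in lex.generics}
    surfaces.update(lex.trade_to_generic)
    return DictionaryMatcher(surfaces)


def recognize_drugs(
    s: str, lex: DrugLexicon, matcher: DictionaryMatcher | None = None
) -> list[str]:
    """Generic drug names recognized in a free-text drug string.

    Trade names are replaced by their generics; duplicates are removed
    preserving first occurrence; an unrecognized (e.g. misspelled) string
    yields an empty list.
    """
    if matcher is None:
        matcher = drug_matcher(lex)
    return NERResult(s, matcher.find(s)).canonical_names


def recognize_drug_entities(
    s: str, lex: DrugLexicon, matcher: DictionaryMatcher | None = None
) -> NERResult:
    """Span-level variant of :func:`recognize_drugs`."""
    if matcher is None:
        matcher = drug_matcher(lex)
    return NERResult(s, matcher.find(s))


def recognize_ses(s: str, lex: SideEffectLexicon) -> list[str]:
    """Side-effect terms recognized in a coded event string.

    Event strings are already MedDRA-coded, so this is exact whole-string
    matching after normalization: any term present in the clean lexicon is
    always recalled; terms curated out of the lexicon never match.
    """
    t = normalize(s)
    return [t] if t in lex.terms else []


@dataclass
class NERAccuracyReport:
    accuracy: float
    total: int
    correct: int
    mismatches: list[tuple[str, list[str], list[str]]]  # (input, predicted, expected)


def ner_accuracy(
    results: Sequence[NERResult], truth: Mapping[str, Iterable[str]]
) -> NERAccuracyReport:
    """Exact-set agreement of NER output against a manually curated truth set.

    Every evaluated string must have a truth entry; accuracy is the fraction
    of strings whose recognized entity set equals the truth set exactly.
    """
    mismatches = []
    correct = 0
    for res in results:
        if res.input_string not in truth:
            raise ValidationError(f"no truth entry for input {res.input_string!r}")
        expected = sorted({normalize(x) for x in truth[res.input_string]})
        predicted = sorted(set(res.canonical_names))
        if predicted == expected:
            correct += 1
        else:
            mismatches.append((res.input_string, predicted, expected))
    total = len(results)
    return NERAccuracyReport(
        accuracy=correct / total if total else 0.0,
        total=total,
        correct=correct,
        mismatches=mismatches,
    )
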