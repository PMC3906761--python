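"""Drug–side-effect pair counting and 2×2 contingency tables.

Each spontaneous report yields the full cross product of its recognized
drugs and recognized side effects: a report with m distinct drugs and n
distinct events contributes m×n pairs, each counted at most once per report.
Marginals are report-level as is conventional for disproportionality
analysis, and the table universe N counts only reports that contributed at
least one recognized drug AND one recognized side effect, so a+b+c+d is the
same for every pair of a dataset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from .corpus_io import DrugLexicon, ReportRecord, SideEffectLexicon
from .errors import ConsistencyError
from .ner import DictionaryMatcher, drug_matcher, recognize_ses


class DrugSEPair(NamedTuple):
    """A (generic drug, side-effect term) association; both components normalized."""

    drug: str
    se: str


@dataclass
class PairCounts:
    """Report-level pair and marginal counts over one dataset.

    ``N`` is the number of reports with at least one recognized drug and one
    recognized side effect; invariant
    ``n_pair(d,s) <= min(n_drug(d), n_se(s)) <= N``.
    """

    n_pair: Counter = field(default_factory=Counter)
    n_drug: Counter = field(default_factory=Counter)
    n_se: Counter = field(default_factory=Counter)
    N: int = 0

    @property
    def pairs(self) -> list[DrugSEPair]:
        return list(self.n_pair)


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 report counts for one pair: a with both, b drug-only, c SE-only, d neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConsistencyError(f"negative 2x2 cell: {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_se(self) -> int:
        return self.a + self.c


@dataclass
class ExtractionStats:
    """Run statistics for one extraction pass."""

    n_reports: int = 0
    n_reports_counted: int = 0  # both a drug and an SE recognized
    n_drug_strings: int = 0
    n_drug_strings_unmatched: int = 0
    n_event_strings: int = 0
    n_event_strings_unmatched: int = 0


def extract_pairs(
    reports: Sequence[ReportRecord],
    drug_lex: DrugLexicon,
    se_lex: SideEffectLexicon,
    stats: ExtractionStats | None = None,
) -> PairCounts:
    """NER every report and accumulate pair and marginal report counts.

    Per report, the distinct recognized generics D and distinct recognized
    side effects S contribute one count to every pair in D×S; marginals count
    reports, not mentions. Reports where either D or S is empty are excluded
    from the 2×2 universe entirely.
    """
    matcher = drug_matcher(drug_lex)
    # NER is memoized per distinct string: report files repeat strings heavily.
    drug_cache: dict[str, tuple[str, ...]] = {}
    se_cache: dict[str, tuple[str, ...]] = {}
    pc = PairCounts()
    for rec in reports:
        if stats is not None:
            stats.n_reports += 1
        drugs: dict[str, None] = {}
        for s in rec.drug_strings:
            hit = drug_cache.get(s)
            if hit is None:
                hit = tuple(_find_drugs(s, matcher))
                drug_cache[s] = hit
            if stats is not None:
                stats.n_drug_strings += 1
                if not hit:
                    stats.n_drug_strings_unmatched += 1
            for g in hit:
                drugs.setdefault(g)
        ses: dict[str, None] = {}
        for s in rec.event_terms:
            hit = se_cache.get(s)
            if hit is None:
                hit = tuple(recognize_ses(s, se_lex))
                se_cache[s] = hit
            if stats is not None:
                stats.n_event_strings += 1
                if not hit:
                    stats.n_event_strings_unmatched += 1
            for t in hit:
                ses.setdefault(t)
        if not drugs or not ses:
            continue
        if stats is not None:
            stats.n_reports_counted += 1
        pc.N += 1
        for d in drugs:
            pc.n_drug[d] += 1
        for s in ses:
            pc.n_se[s] += 1
        for d in drugs:
            for s in ses:
                pc.n_pair[DrugSEPair(d, s)] += 1
    return pc


def _find_drugs(s: str, matcher: DictionaryMatcher) -> list[str]:
    seen: dict[str, None] = {}
    for name, _, _ in matcher.find(s):
        seen.setdefault(name)
    return list(seen)


def contingency(pc: PairCounts, pair: DrugSEPair | tuple[str, str]) -> ContingencyTable:
    """2×2 table for one pair; a pair never observed gets a=0."""
    pair = DrugSEPair(*pair)
    a = pc.n_pair.get(pair, 0)
    b = pc.n_drug.get(pair.drug, 0) - a
    c = pc.n_se.get(pair.se, 0) - a
    d = pc.N - a - b - c
    if min(a, b, c, d) < 0:
        raise ConsistencyError(
            f"inconsistent counts for {pair}: a={a} b={b} c={c} d={d} N={pc.N}"
        )
    return ContingencyTable(a, b, c, d)
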