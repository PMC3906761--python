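"""Readers and writers for every external format the pipeline touches.

Spontaneous-report files come in two dialects of the same two-file layout:

* ``faers_dollar`` — ``$``-delimited with a header row, the layout of the
  public FAERS quarterly ASCII distributions (``DRUGyyQq.TXT`` /
  ``REACyyQq.TXT``). The first column is the report ID; the second is the
  free-text drug string (DRUG file) or the MedDRA-coded event term (REAC
  file). Additional columns are ignored.
* ``tsv`` — the same layout, tab-delimited; used by the synthetic generator.

All other artifacts are plain TSV: lexicons, the literature corpus
(doc_id, sentence_index, text), pair lists (drug, se[, score/count]).

Every name is normalized on the way in (see :mod:`pharmaboost.normalize`);
writers emit rows in sorted order so outputs are byte-stable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, ValidationError
from .normalize import normalize

logger = logging.getLogger(__name__)

DIALECTS = {"faers_dollar": "$", "tsv": "\t"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugLexicon:
    """Dictionary of drug names: canonical generics plus trade-name mapping.

    Invariants: every name normalized; every trade name maps to exactly one
    generic, and every mapping target is itself in :attr:`generics`.
    """

    generics: frozenset[str]
    trade_to_generic: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [g for t, g in self.trade_to_generic.items() if g not in self.generics]
        if bad:
            raise ValidationError(
                f"trade names map to unknown generics: {sorted(set(bad))[:5]}"
            )

    @property
    def all_names(self) -> set[str]:
        return set(self.generics) | set(self.trade_to_generic)

    def canonical(self, name: str) -> str | None:
        """Generic name for a recognized drug name, else ``None``."""
        if name in self.generics:
            return name
        return self.trade_to_generic.get(name)


@dataclass(frozen=True)
class SideEffectLexicon:
    """Cleaned side-effect term list with category ancestry.

    ``ancestors`` maps a term to its category labels (e.g. "cardiac
    disorders"); category subsets such as cardiovascular terms are derived
    only through this map.
    """

    terms: frozenset[str]
    ancestors: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.ancestors) - set(self.terms)
        if extra:
            raise ValidationError(f"ancestor keys not in terms: {sorted(extra)[:5]}")

    def subset_with_ancestor(self, labels: Iterable[str]) -> set[str]:
        wanted = {normalize(x) for x in labels}
        return {t for t, anc in self.ancestors.items() if anc & wanted}


@dataclass
class ReportRecord:
    """One spontaneous report: its ID, drug strings and coded event terms.

    Either list may be empty — a report may appear in only one of the
    DRUG/REAC files.
    """

    report_id: str
    drug_strings: list[str] = field(default_factory=list)
    event_terms: list[str] = field(default_factory=list)


@dataclass
class LiteratureDocument:
    """A literature abstract as an ordered list of sentences."""

    doc_id: str
    sentences: list[str]

    @property
    def abstract_text(self) -> str:
        return " ".join(self.sentences)


@dataclass(frozen=True)
class GoldStandard:
    """Reference set of (generic drug, side-effect term) pairs."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs


@dataclass(frozen=True)
class ExternalScoreTable:
    """Externally supplied (drug, se) -> score table (OffSides-style)."""

    scores: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        import math

        bad = [p for p, v in self.scores.items() if not math.isfinite(v)]
        if bad:
            raise ValidationError(f"non-finite external scores for {bad[:5]}")


# ---------------------------------------------------------------------------
# Report files
# ---------------------------------------------------------------------------


def _open_rows(path: str | Path, delim: str):
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        yield from csv.reader(fh, delimiter=delim)


def _read_two_col(path: str | Path, dialect: str, what: str) -> list[tuple[str, str]]:
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    delim = DIALECTS[dialect]
    rows = _open_rows(path, delim)
    try:
        header = next(rows)
    except StopIteration:
        raise FormatError(f"{path}: line 1: empty file, expected header") from None
    if len(header) < 2:
        raise FormatError(
            f"{path}: line 1: malformed header {header!r}, expected >=2 "
            f"{delim!r}-delimited columns"
        )
    out: list[tuple[str, str]] = []
    skipped = 0
    for lineno, row in enumerate(rows, start=2):
        if not row:
            continue
        if len(row) < 2:
            raise FormatError(f"{path}: line {lineno}: expected >=2 columns, got {len(row)}")
        rid = row[0].strip()
        if not rid:
            skipped += 1
            continue
        out.append((rid, row[1]))
    if skipped:
        logger.warning("%s: skipped %d %s rows with empty report ID", path, skipped, what)
    return out


def read_reports(
    drug_file: str | Path, reac_file: str | Path, dialect: str = "faers_dollar"
) -> list[ReportRecord]:
    """Join a DRUG file and a REAC file on report ID into ReportRecords.

    Outer-merge semantics: a report ID present in only one file yields a
    record with the other list empty. Per-report lists keep file order;
    records are returned sorted by report ID so output is order-independent
    with respect to input row order.
    """
    records: dict[str, ReportRecord] = {}
    for rid, drug in _read_two_col(drug_file, dialect, "drug"):
        records.setdefault(rid, ReportRecord(rid)).drug_strings.append(drug)
    for rid, event in _read_two_col(reac_file, dialect, "event"):
        records.setdefault(rid, ReportRecord(rid)).event_terms.append(event)
    return [records[rid] for rid in sorted(records)]


def merge_reports(*batches: Sequence[ReportRecord]) -> list[ReportRecord]:
    """Merge quarterly batches by union on report ID (duplicates deduplicated)."""
    merged: dict[str, ReportRecord] = {}
    for batch in batches:
        for rec in batch:
            tgt = merged.setdefault(rec.report_id, ReportRecord(rec.report_id))
            for s in rec.drug_strings:
                if s not in tgt.drug_strings:
                    tgt.drug_strings.append(s)
            for e in rec.event_terms:
                if e not in tgt.event_terms:
                    tgt.event_terms.append(e)
    return [merged[rid] for rid in sorted(merged)]


def write_reports(
    drug_file: str | Path,
    reac_file: str | Path,
    reports: Sequence[ReportRecord],
    dialect: str = "tsv",
) -> None:
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}")
    delim = DIALECTS[dialect]
    with open(drug_file, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["report_id", "drug"])
        for rec in reports:
            for s in rec.drug_strings:
                w.writerow([rec.report_id, s])
    with open(reac_file, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["report_id", "event"])
        for rec in reports:
            for e in rec.event_terms:
                w.writerow([rec.report_id, e])


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------


def read_lexicons(
    drug_lexicon: str | Path, se_lexicon: str | Path
) -> tuple[DrugLexicon, SideEffectLexicon]:
    """Load the drug lexicon (name, generic, kind) and SE lexicon (term, ancestors).

    Duplicate trade names with conflicting generics resolve deterministically
    to the lexicographically smallest generic, with a logged warning. A trade
    row whose generic is absent from the generic set is a validation error.
    """
    generics: set[str] = set()
    trade_rows: list[tuple[str, str]] = []
    for lineno, row in enumerate(_open_rows(drug_lexicon, "\t"), start=1):
        if lineno == 1:
            if len(row) < 3:
                raise FormatError(
                    f"{drug_lexicon}: line 1: expected header (name, generic, kind)"
                )
            continue
        if not row:
            continue
        if len(row) < 3:
            raise FormatError(f"{drug_lexicon}: line {lineno}: expected 3 columns")
        name, generic, kind = normalize(row[0]), normalize(row[1]), row[2].strip().lower()
        if kind == "generic":
            generics.add(name)
        elif kind == "trade":
            trade_rows.append((name, generic))
        else:
            raise FormatError(
                f"{drug_lexicon}: line {lineno}: kind must be generic|trade, got {kind!r}"
            )
    trade_to_generic: dict[str, str] = {}
    for trade, generic in trade_rows:
        if generic not in generics:
            raise ValidationError(
                f"trade name {trade!r} maps to {generic!r}, which is not a known generic"
            )
        if trade in trade_to_generic and trade_to_generic[trade] != generic:
            keep = min(trade_to_generic[trade], generic)
            logger.warning(
                "conflicting generics for trade name %r (%r vs %r); keeping %r",
                trade, trade_to_generic[trade], generic, keep,
            )
            trade_to_generic[trade] = keep
        else:
            trade_to_generic.setdefault(trade, generic)

    terms: set[str] = set()
    ancestors: dict[str, frozenset[str]] = {}
    for lineno, row in enumerate(_open_rows(se_lexicon, "\t"), start=1):
        if lineno == 1:
            if len(row) < 1:
                raise FormatError(f"{se_lexicon}: line 1: expected header (term, ancestors)")
            continue
        if not row:
            continue
        term = normalize(row[0])
        terms.add(term)
        anc_field = row[1] if len(row) > 1 else ""
        anc = frozenset(normalize(a) for a in anc_field.split(";") if a.strip())
        if anc:
            ancestors[term] = anc
    return (
        DrugLexicon(frozenset(generics), trade_to_generic),
        SideEffectLexicon(frozenset(terms), ancestors),
    )


def write_lexicons(
    drug_lexicon: str | Path, se_lexicon: str | Path,
    dlex: DrugLexicon, slex: SideEffectLexicon,
) -> None:
    with open(drug_lexicon, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["name", "generic", "kind"])
        for g in sorted(dlex.generics):
            w.writerow([g, g, "generic"])
        for t in sorted(dlex.trade_to_generic):
            w.writerow([t, dlex.trade_to_generic[t], "trade"])
    with open(se_lexicon, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["term", "ancestors"])
        for t in sorted(slex.terms):
            w.writerow([t, ";".join(sorted(slex.ancestors.get(t, ())))])


# ---------------------------------------------------------------------------
# Literature corpus
# ---------------------------------------------------------------------------


def read_corpus(path: str | Path) -> list[LiteratureDocument]:
    """Read a (doc_id, sentence_index, text) TSV into documents.

    sentence_index must be contiguous from 0 within each document; a gap is
    a format error. Document order follows first appearance in the file.
    """
    sentences: dict[str, dict[int, str]] = {}
    order: list[str] = []
    for lineno, row in enumerate(_open_rows(path, "\t"), start=1):
        if lineno == 1:
            if row and len(row) < 3:
                raise FormatError(f"{path}: line 1: expected header (doc_id, sentence_index, text)")
            continue
        if not row:
            continue
        if len(row) < 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 columns")
        doc_id = row[0].strip()
        try:
            idx = int(row[1])
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: sentence_index {row[1]!r} not an integer") from None
        if doc_id not in sentences:
            order.append(doc_id)
            sentences[doc_id] = {}
        if idx in sentences[doc_id]:
            raise FormatError(f"{path}: line {lineno}: duplicate sentence_index {idx} for {doc_id}")
        sentences[doc_id][idx] = row[2]
    docs: list[LiteratureDocument] = []
    for doc_id in order:
        idxs = sentences[doc_id]
        if sorted(idxs) != list(range(len(idxs))):
            raise FormatError(
                f"{path}: document {doc_id}: sentence_index not contiguous from 0 "
                f"(got {sorted(idxs)[:10]})"
            )
        docs.append(LiteratureDocument(doc_id, [idxs[i] for i in range(len(idxs))]))
    return docs


def write_corpus(path: str | Path, docs: Sequence[LiteratureDocument]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["doc_id", "sentence_index", "text"])
        for doc in docs:
            for i, s in enumerate(doc.sentences):
                w.writerow([doc.doc_id, i, s])


# ---------------------------------------------------------------------------
# Pair lists, gold standard, external scores
# ---------------------------------------------------------------------------


def read_pairs(path: str | Path) -> list[tuple]:
    """Read a pair-list TSV: (drug, se) rows with optional numeric extras."""
    out: list[tuple] = []
    for lineno, row in enumerate(_open_rows(path, "\t"), start=1):
        if lineno == 1:
            if row and len(row) < 2:
                raise FormatError(f"{path}: line 1: expected header (drug, se, ...)")
            continue
        if not row:
            continue
        if len(row) < 2:
            raise FormatError(f"{path}: line {lineno}: expected >=2 columns")
        drug, se = normalize(row[0]), normalize(row[1])
        extras = []
        for v in row[2:]:
            try:
                extras.append(float(v))
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric score {v!r}") from None
        out.append((drug, se, *extras))
    return out


def write_pairs(path: str | Path, rows: Iterable[Sequence], header: Sequence[str] = ("drug", "se")) -> None:
    """Write pair rows sorted by (drug, se) so diffs are stable."""
    rows = sorted(rows, key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(list(header))
        for r in rows:
            w.writerow(list(r))


def read_gold(path: str | Path) -> GoldStandard:
    return GoldStandard(frozenset((d, s) for d, s, *_ in read_pairs(path)))


def write_gold(path: str | Path, gold: GoldStandard) -> None:
    write_pairs(path, sorted(gold.pairs))


def read_external_scores(path: str | Path) -> ExternalScoreTable:
    scores: dict[tuple[str, str], float] = {}
    for row in read_pairs(path):
        if len(row) < 3:
            raise FormatError(f"{path}: external score table needs a score column")
        scores[(row[0], row[1])] = row[2]
    return ExternalScoreTable(scores)


def write_external_scores(path: str | Path, table: ExternalScoreTable) -> None:
    write_pairs(
        path,
        [(d, s, v) for (d, s), v in table.scores.items()],
        header=("drug", "se", "score"),
    )
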