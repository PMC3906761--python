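"""Literature-evidence signal boosting and total ranking of drug–SE pairs.

The boosting rule: a pair that co-occurs in the literature (at the chosen
evidence level) has its ranking score replaced by the square of its original
signal; a pair seen only in the report data keeps its original signal. No
pair is ever filtered — the ranked list is a permutation of the input pairs.

Squaring a base signal below 1 (possible for ratio-type signals) decreases
it; the rule is applied literally, a warning is logged when that happens,
and ``boost_floor=True`` offers a sensitivity variant squaring
``max(value, 1)`` instead (not the default behavior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError
from .literature_evidence import LiteratureEvidence
from .dpa_signals import SignalScore
from .pair_extraction import DrugSEPair

logger = logging.getLogger(__name__)


def boost(value: float | None, has_evidence: bool, boost_floor: bool = False) -> float | None:
    """Squared signal for evidence pairs, identity otherwise.

    Undefined signals (None) pass through unchanged. Note value 1 is a fixed
    point: a count-1 pair gains nothing from evidence.
    """
    if value is None or not has_evidence:
        return value
    if boost_floor:
        value = max(value, 1.0)
    return value * value


@dataclass
class RankedEntry:
    pair: DrugSEPair
    base_value: float | None
    boosted_value: float | None
    evidence: bool


@dataclass
class RankedPairList:
    """Total ranking of all pairs under one base method and evidence level."""

    entries: list[RankedEntry]
    method: str
    level: str

    @property
    def pairs(self) -> list[DrugSEPair]:
        return [e.pair for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def rank(
    scores: Sequence[SignalScore],
    ev: LiteratureEvidence | None,
    level: str = "sentence",
    freq: Mapping[DrugSEPair, int] | None = None,
    boost_floor: bool = False,
) -> RankedPairList:
    """Boost and totally order a set of signal scores.

    Sort order: defined before undefined; boosted value descending; then the
    deterministic tie-break base FREQ descending, drug ascending, SE
    ascending. ``freq`` supplies the tie-break counts (pair report counts);
    without it the tie-break falls back to the lexicographic keys alone.
    """
    seen: set[DrugSEPair] = set()
    for s in scores:
        if s.pair in seen:
            raise ValidationError(f"duplicate pair in scores: {s.pair}")
        seen.add(s.pair)
    evidence_pairs = ev.evidence_set(level) if ev is not None else set()
    method = scores[0].method if scores else "FREQ"

    entries: list[RankedEntry] = []
    n_sub_unit = 0
    for s in scores:
        has_ev = s.pair in evidence_pairs
        if has_ev and s.value is not None and s.value < 1.0 and not boost_floor:
            n_sub_unit += 1
        entries.append(RankedEntry(s.pair, s.value, boost(s.value, has_ev, boost_floor), has_ev))
    if n_sub_unit:
        logger.warning(
            "%d evidence pair(s) have base %s signal < 1; squaring decreases them",
            n_sub_unit, method,
        )

    def key(e: RankedEntry):
        undefined = e.boosted_value is None
        f = freq.get(e.pair, 0) if freq is not None else 0
        return (
            undefined,
            -(e.boosted_value if not undefined else 0.0),
            -f,
            e.pair.drug,
            e.pair.se,
        )

    entries.sort(key=key)
    return RankedPairList(entries, method=method, level=level)
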