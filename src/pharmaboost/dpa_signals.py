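"""Disproportionality and ranking signals on 2×2 report tables.

Seven signals are supported, all oriented so that larger means stronger:

==========  ===========================================================
FREQ        raw co-report count a
PRR         proportional reporting ratio  [a/(a+b)] / [c/(c+d)]
RRR         relative reporting ratio      a·N / ((a+b)(a+c))
ROR         reporting odds ratio          (a·d)/(b·c)
PHI         phi coefficient               (ad−bc)/√((a+b)(c+d)(a+c)(b+d))
IC          information component         log2(RRR) (raw) or a 0.5-shrunk
            variant log2((a+0.5)/(E+0.5)), E=(a+b)(a+c)/N
EXTERNAL    score looked up in an externally supplied table
==========  ===========================================================

All equal their independence null (1 for the ratios, 0 for PHI and IC) when
a·d = b·c. Zero cells in b, c or d trigger the Haldane–Anscombe correction
(+0.5 to every cell) for PRR and ROR, flagged in the output. A signal that
is undefined for a table (e.g. PHI with a zero marginal, raw IC with a=0)
carries value ``None`` and sorts below every defined signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .corpus_io import ExternalScoreTable
from .errors import ValidationError
from .pair_extraction import ContingencyTable, DrugSEPair, PairCounts, contingency

METHODS = ("FREQ", "PRR", "RRR", "ROR", "PHI", "IC", "EXTERNAL")


@dataclass(frozen=True)
class SignalScore:
    """One pair's score under one method; ``value is None`` marks undefined."""

    pair: DrugSEPair
    method: str
    value: float | None
    corrected: bool = False

    @property
    def defined(self) -> bool:
        return self.value is not None


def freq(t: ContingencyTable) -> float:
    return float(t.a)


def _corrected_cells(t: ContingencyTable) -> tuple[float, float, float, float, bool]:
    if min(t.b, t.c, t.d) == 0:
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, True
    return float(t.a), float(t.b), float(t.c), float(t.d), False


def prr(t: ContingencyTable) -> tuple[float | None, bool]:
    """Proportional reporting ratio; None when the drug row is empty."""
    if t.a + t.b == 0:
        return None, False
    a, b, c, d, corrected = _corrected_cells(t)
    return (a / (a + b)) / (c / (c + d)), corrected


def ror(t: ContingencyTable) -> tuple[float | None, bool]:
    """Reporting odds ratio; None when the drug row or SE column is empty."""
    if t.a + t.b == 0 or t.a + t.c == 0:
        return None, False
    a, b, c, d, corrected = _corrected_cells(t)
    return (a * d) / (b * c), corrected


def rrr(t: ContingencyTable) -> tuple[float | None, bool]:
    """Relative reporting ratio (observed over expected); None on an empty margin."""
    if t.a + t.b == 0 or t.a + t.c == 0 or t.n == 0:
        return None, False
    return t.a * t.n / ((t.a + t.b) * (t.a + t.c)), False


def phi_corr(t: ContingencyTable) -> tuple[float | None, bool]:
    """Phi coefficient in [-1, 1]; None when any marginal is zero."""
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if denom == 0:
        return None, False
    return (t.a * t.d - t.b * t.c) / math.sqrt(denom), False


def ic(t: ContingencyTable, mode: str = "raw") -> tuple[float | None, bool]:
    """Information component.

    raw: log2 of the relative reporting ratio (undefined at a=0);
    shrunk: log2((a+0.5)/(E+0.5)) with E the expected count under
    independence, finite for every table.
    """
    if mode not in ("raw", "shrunk"):
        raise ValidationError(f"ic mode must be raw|shrunk, got {mode!r}")
    if t.a + t.b == 0 or t.a + t.c == 0 or t.n == 0:
        return None, False
    if mode == "raw":
        if t.a == 0:
            return None, False
        return math.log2(t.a * t.n / ((t.a + t.b) * (t.a + t.c))), False
    expected = (t.a + t.b) * (t.a + t.c) / t.n
    return math.log2((t.a + 0.5) / (expected + 0.5)), False


def external_signal(
    pair: DrugSEPair | tuple[str, str], ext: ExternalScoreTable
) -> float | None:
    """Externally supplied score for a pair, or None when the table lacks it.

    Absent pairs rank below every present pair; a pair can be FREQ-strong in
    the report data yet absent from the external table.
    """
    return ext.scores.get(tuple(pair))


def score_table(t: ContingencyTable, method: str, ic_mode: str = "raw") -> tuple[float | None, bool]:
    if method == "FREQ":
        return freq(t), False
    if method == "PRR":
        return prr(t)
    if method == "RRR":
        return rrr(t)
    if method == "ROR":
        return ror(t)
    if method == "PHI":
        return phi_corr(t)
    if method == "IC":
        return ic(t, mode=ic_mode)
    raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")


def score_all(
    pc: PairCounts,
    method: str,
    external: ExternalScoreTable | None = None,
    ic_mode: str = "raw",
    pairs: Sequence[DrugSEPair] | None = None,
) -> list[SignalScore]:
    """Score every pair in the counts (or an explicit pair list) under one method."""
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    if pairs is None:
        pairs = pc.pairs
    out: list[SignalScore] = []
    if method == "EXTERNAL":
        if external is None:
            raise ValidationError("method EXTERNAL requires an external score table")
        for p in pairs:
            out.append(SignalScore(p, method, external_signal(p, external)))
        return out
    for p in pairs:
        value, corrected = score_table(contingency(pc, p), method, ic_mode=ic_mode)
        out.append(SignalScore(p, method, value, corrected))
    return out
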