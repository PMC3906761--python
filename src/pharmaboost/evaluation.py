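"""Evaluation of pair sets and ranked lists against a drug-label gold standard.

Set metrics are the usual precision/recall/F1 on pair sets. Ranked lists are
scored with 11-point interpolated average precision: walking down the list,
precision and recall are computed at every rank; the interpolated precision
at recall level r is the maximum precision achieved at any recall >= r; the
average over the 11 levels 0.0, 0.1, ..., 1.0 is the average precision (AP).

The gold standard here calibrates ranking comparisons rather than measuring
true accuracy — drug labels underestimate post-marketing signals — so the
default recall denominator is the reachable gold (gold pairs present in the
candidate universe); ``denominator="full"`` uses the whole gold set instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from .corpus_io import GoldStandard
from .errors import ValidationError
from .pair_extraction import DrugSEPair

RECALL_LEVELS = tuple(i / 10 for i in range(11))


@dataclass(frozen=True)
class SetMetrics:
    """Precision/recall/F1 of an extracted pair set against gold.

    Precision is NaN (undefined) for an empty extracted set.
    """

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


def set_metrics(extracted: set, gold: GoldStandard) -> SetMetrics:
    extracted = {tuple(p) for p in extracted}
    tp = len(extracted & gold.pairs)
    fp = len(extracted) - tp
    fn = len(gold.pairs) - tp
    precision = tp / len(extracted) if extracted else math.nan
    recall = tp / len(gold.pairs) if gold.pairs else math.nan
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = 0.0 if not (math.isnan(precision) or math.isnan(recall)) else math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return SetMetrics(precision, recall, f1, tp, fp, fn)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class PRCurve:
    """11-point interpolated precision curve and its mean (average precision)."""

    recall_levels: tuple = RECALL_LEVELS
    interp_precision: tuple = ()
    average_precision: float = math.nan

    @property
    def defined(self) -> bool:
        return not math.isnan(self.average_precision)


def interpolated_pr(
    ranked, gold: GoldStandard, denominator: str = "reachable"
) -> PRCurve:
    """11-point interpolated precision-recall of a ranked pair list.

    ``ranked`` is a RankedPairList or any ordered sequence of pairs. At rank
    k, recall is tp_k over the recall denominator and precision is tp_k/k;
    interpolated precision at level r is max{p_k : r_k >= r}. Levels no
    ranking reaches get interpolated precision 0. A gold set disjoint from
    the ranking yields an undefined (NaN) curve.
    """
    pairs = ranked.pairs if hasattr(ranked, "pairs") else [DrugSEPair(*p) for p in ranked]
    if denominator not in ("reachable", "full"):
        raise ValidationError(f"denominator must be reachable|full, got {denominator!r}")
    reachable = len({tuple(p) for p in pairs} & gold.pairs)
    denom = reachable if denominator == "reachable" else len(gold.pairs)
    if reachable == 0 or denom == 0:
        return PRCurve(interp_precision=tuple(math.nan for _ in RECALL_LEVELS))

    # best precision at or beyond each rank's recall, one backward sweep
    tp = 0
    pr_points: list[tuple[float, float]] = []  # (recall_k, precision_k)
    gold_pairs = gold.pairs
    for k, p in enumerate(pairs, start=1):
        if tuple(p) in gold_pairs:
            tp += 1
            pr_points.append((tp / denom, tp / k))
    # only ranks where a gold pair is hit matter: precision at other ranks is
    # dominated by an earlier hit at equal recall.
    interp = []
    for level in RECALL_LEVELS:
        best = 0.0
        for r_k, p_k in pr_points:
            if r_k >= level and p_k > best:
                best = p_k
        interp.append(best)
    return PRCurve(
        interp_precision=tuple(interp),
        average_precision=sum(interp) / len(RECALL_LEVELS),
    )


def precision_at_recall(curve: PRCurve, level: float) -> float:
    """Interpolated precision at one of the 11 recall levels."""
    for i, r in enumerate(curve.recall_levels):
        if math.isclose(r, level):
            return curve.interp_precision[i]
    raise ValidationError(f"recall level {level} not on the 11-point grid")


@dataclass(frozen=True)
class RelativeChange:
    """Change of a metric vs a baseline, as a fold and a percent increase."""

    fraction: float

    @property
    def fold(self) -> float:
        return round(self.fraction, 1)

    @property
    def percent(self) -> int:
        return round(self.fraction * 100)


def relative_change(new: float, base: float) -> RelativeChange:
    """(new - base)/base; e.g. 0.278 vs 0.025 is a 10.1-fold (1012%) increase."""
    if base <= 0:
        raise ValidationError("relative_change requires a positive baseline")
    return RelativeChange((new - base) / base)


CURATION_CLASSES = ("CAUSE", "TREAT", "NONE")


@dataclass(frozen=True)
class CurationLabels:
    """Manual CAUSE/TREAT/NONE classification of a curated pair subset."""

    labels: dict

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values() if v not in CURATION_CLASSES}
        if bad:
            raise ValidationError(f"unknown curation classes: {sorted(bad)}")

    def pairs_with(self, cls: str) -> set:
        return {p for p, v in self.labels.items() if v == cls}


@dataclass(frozen=True)
class CurationReport:
    n_pairs: int
    precision: float  # fraction labeled CAUSE
    class_fractions: dict
    novelty: float  # fraction of CAUSE pairs absent from gold


def curation_metrics(labels: CurationLabels, gold: GoldStandard) -> CurationReport:
    """Precision and label-novelty of a manually curated pair subset.

    Precision is the CAUSE fraction of all curated pairs; novelty is the
    fraction of CAUSE pairs not already in the gold standard (i.e. candidate
    signals absent from drug labels).
    """
    if not labels.labels:
        raise ValidationError("curation label set is empty")
    n = len(labels.labels)
    cause = labels.pairs_with("CAUSE")
    fractions = {c: len(labels.pairs_with(c)) / n for c in CURATION_CLASSES}
    novel = {p for p in cause if tuple(p) not in gold.pairs}
    novelty = len(novel) / len(cause) if cause else 0.0
    return CurationReport(
        n_pairs=n,
        precision=len(cause) / n,
        class_fractions=fractions,
        novelty=novelty,
    )
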