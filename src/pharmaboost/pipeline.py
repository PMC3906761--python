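"""End-to-end pipeline: extract → score → match literature → boost → evaluate.

`run_pipeline` wires the stages together from a validated
:class:`PipelineConfig`, writes the ranked list and an evaluation report,
and logs stage counts (reports read, pairs extracted, evidence pairs per
level). Every output embeds a hash of the configuration so ranked lists are
attributable to the exact run that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import corpus_io
from .boosted_ranking import RankedPairList, rank
from .dpa_signals import METHODS, score_all
from .errors import PharmaboostError, ValidationError
from .evaluation import (
    interpolated_pr,
    precision_at_recall,
    relative_change,
    set_metrics,
)
from .literature_evidence import build_index, evidence_for
from .pair_extraction import ExtractionStats, extract_pairs
from .synthetic_faers import SimulatedData

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and knobs for one end-to-end run."""

    drug_files: list[str]
    reac_files: list[str]
    drug_lexicon: str
    se_lexicon: str
    corpus: str
    gold: str
    external_scores: str | None = None
    outdir: str = "pharmaboost_out"
    dialect: str = "tsv"
    method: str = "FREQ"
    level: str = "sentence"
    ic_mode: str = "raw"
    boost_floor: bool = False
    recall_denominator: str = "reachable"

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.level not in ("sentence", "abstract"):
            raise ValidationError(f"level must be sentence|abstract, got {self.level!r}")
        if len(self.drug_files) != len(self.reac_files):
            raise ValidationError("drug_files and reac_files must pair up one-to-one")
        if not self.drug_files:
            raise ValidationError("at least one DRUG/REAC file pair is required")
        if self.method == "EXTERNAL" and not self.external_scores:
            raise ValidationError("method EXTERNAL requires external_scores")
        missing = [
            p
            for p in (
                *self.drug_files, *self.reac_files,
                self.drug_lexicon, self.se_lexicon, self.corpus, self.gold,
                *( [self.external_scores] if self.external_scores else [] ),
            )
            if not Path(p).exists()
        ]
        if missing:
            raise ValidationError(f"missing input files: {missing}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Everything a run produced, in memory plus on disk under ``outdir``."""

    config: PipelineConfig
    ranked: RankedPairList
    unboosted: RankedPairList
    report: dict
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full extraction → ranking → evaluation flow."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        batches = [
            corpus_io.read_reports(d, r, cfg.dialect)
            for d, r in zip(cfg.drug_files, cfg.reac_files)
        ]
        reports = corpus_io.merge_reports(*batches) if len(batches) > 1 else batches[0]
        drug_lex, se_lex = corpus_io.read_lexicons(cfg.drug_lexicon, cfg.se_lexicon)
        corpus = corpus_io.read_corpus(cfg.corpus)
        gold = corpus_io.read_gold(cfg.gold)
        external = (
            corpus_io.read_external_scores(cfg.external_scores)
            if cfg.external_scores
            else None
        )

        stage = "extract"
        stats = ExtractionStats()
        pc = extract_pairs(reports, drug_lex, se_lex, stats=stats)

        stage = "score"
        scores = score_all(pc, cfg.method, external=external, ic_mode=cfg.ic_mode)

        stage = "match-literature"
        index = build_index(corpus, drug_lex, se_lex)
        ev = evidence_for(pc.pairs, index)

        stage = "boost"
        ranked = rank(scores, ev, cfg.level, freq=pc.n_pair, boost_floor=cfg.boost_floor)
        unboosted = rank(scores, None, cfg.level, freq=pc.n_pair)

        stage = "evaluate"
        all_pairs = set(pc.n_pair)
        ev_pairs = ev.evidence_set(cfg.level) & all_pairs
        m_all = set_metrics(all_pairs, gold)
        m_ev = set_metrics(ev_pairs, gold)
        curve_boosted = interpolated_pr(ranked, gold, cfg.recall_denominator)
        curve_base = interpolated_pr(unboosted, gold, cfg.recall_denominator)
        report = _build_report(cfg, m_all, m_ev, curve_base, curve_boosted, ev, pc, stats)
    except PharmaboostError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    _write_outputs(cfg, outdir, ranked, report)
    counts = report["stage_counts"]
    logger.info("pipeline done: %s", json.dumps(counts))
    return PipelineResult(cfg, ranked, unboosted, report, counts)


def _build_report(cfg, m_all, m_ev, curve_base, curve_boosted, ev, pc, stats) -> dict:
    n_sent = len(ev.evidence_set("sentence") & set(pc.n_pair))
    n_abs = len(ev.evidence_set("abstract") & set(pc.n_pair))
    report = {
        "config_hash": cfg.config_hash(),
        "method": cfg.method,
        "level": cfg.level,
        "stage_counts": {
            "reports": stats.n_reports,
            "reports_counted": stats.n_reports_counted,
            "drug_strings_unmatched": stats.n_drug_strings_unmatched,
            "event_strings_unmatched": stats.n_event_strings_unmatched,
            "pairs_extracted": len(pc.n_pair),
            "pairs_with_sentence_evidence": n_sent,
            "pairs_with_abstract_evidence": n_abs,
        },
        "set_metrics": {
            "all_pairs": _metrics_dict(m_all),
            "evidence_pairs": _metrics_dict(m_ev),
        },
        "pr_curves": {
            "base": _curve_dict(curve_base),
            "boosted": _curve_dict(curve_boosted),
        },
    }
    if curve_base.defined and curve_boosted.defined:
        p_base = precision_at_recall(curve_base, 0.1)
        p_boost = precision_at_recall(curve_boosted, 0.1)
        report["precision_at_recall_0.1"] = {"base": p_base, "boosted": p_boost}
        if p_base > 0:
            rc = relative_change(p_boost, p_base)
            report["boost_change_at_recall_0.1"] = {
                "fold": rc.fold,
                "percent": rc.percent,
            }
    return report


def _metrics_dict(m) -> dict:
    return {
        "precision": None if math.isnan(m.precision) else m.precision,
        "recall": None if math.isnan(m.recall) else m.recall,
        "f1": None if math.isnan(m.f1) else m.f1,
        "tp": m.tp, "fp": m.fp, "fn": m.fn,
    }


def _curve_dict(c) -> dict:
    if not c.defined:
        return {"average_precision": None, "interp_precision": None}
    return {
        "average_precision": c.average_precision,
        "interp_precision": list(c.interp_precision),
    }


def _write_outputs(cfg, outdir: Path, ranked: RankedPairList, report: dict) -> None:
    header = ["drug", "se", "base_value", "boosted_value", "evidence"]
    ranked_path = outdir / "ranked.tsv"
    with open(ranked_path, "w", encoding="utf-8") as fh:
        fh.write(f"# pharmaboost ranked list; config_hash={report['config_hash']}\n")
        fh.write("\t".join(header) + "\n")
        for e in ranked.entries:
            fh.write(
                "\t".join(
                    [
                        e.pair.drug,
                        e.pair.se,
                        "NA" if e.base_value is None else repr(e.base_value),
                        "NA" if e.boosted_value is None else repr(e.boosted_value),
                        "1" if e.evidence else "0",
                    ]
                )
                + "\n"
            )
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def run_on_simulated(data: SimulatedData, workdir: str | Path, **overrides) -> PipelineResult:
    """Write a simulated dataset to disk and run the pipeline on the files.

    Convenience wrapper used by tests and the acceptance script; `overrides`
    update PipelineConfig fields (method, level, ...).
    """
    from .synthetic_faers import write_all

    workdir = Path(workdir)
    paths = write_all(data, workdir / "data")
    cfg = PipelineConfig(
        drug_files=[str(paths["drug_file"])],
        reac_files=[str(paths["reac_file"])],
        drug_lexicon=str(paths["drug_lexicon"]),
        se_lexicon=str(paths["se_lexicon"]),
        corpus=str(paths["corpus"]),
        gold=str(paths["gold"]),
        external_scores=str(paths["external"]),
        outdir=str(workdir / "out"),
        dialect="tsv",
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValidationError(f"unknown pipeline option {k!r}")
        setattr(cfg, k, v)
    return run_pipeline(cfg)
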