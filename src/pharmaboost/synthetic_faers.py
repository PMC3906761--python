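"""Seedable synthetic spontaneous-report and literature data.

The generator emulates the statistical structure the signal-detection method
assumes, so every pipeline stage is testable without the real report
database, literature corpus or drug-label resource:

* each drug carries a few *causal* side effects and a few *indications*
  (diseases it treats, disjoint from its causal effects);
* drug usage is heavy-tailed (Zipf-weighted draws by default, as in real
  prescription data), and each planted pair has its own reporting-rate
  multiplier, so co-report counts of causal, treatment and noise pairs
  overlap and frequency ranking is informative but imperfect — the regime
  disproportionality methods actually face;
* a report draws one or more drugs; its events are each taken drug's causal
  effects (each reported with that pair's causal rate), its indications
  misreported as events (``p_indication_event`` scaled the same way —
  confounding by indication), plus Poisson background noise drawn uniformly
  from the SE vocabulary;
* drug strings are decorated free text: dose/form tokens appended, and a
  fraction written as trade names, so dictionary NER is genuinely exercised;
* the literature corpus contains one templated sentence per sampled
  co-occurrence — causal pairs most often, treatment pairs often (the
  literature is dominated by treatment relations), any other pair rarely —
  plus distractor sentences; some co-occurrences are split across two
  sentences of one abstract, giving abstract-level-only evidence;
* the gold standard is the planted causal-pair set; the external score table
  scores causal pairs higher on average, with noise and partial coverage.

Identical seed + config produce byte-identical output files. Each stage
draws from its own substream of one root seed, so e.g. adding reports does
not perturb corpus generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import corpus_io
from .corpus_io import (
    DrugLexicon,
    ExternalScoreTable,
    GoldStandard,
    LiteratureDocument,
    ReportRecord,
    SideEffectLexicon,
)
from .errors import ValidationError
from .pair_extraction import DrugSEPair

_DOSES = ("10", "20", "50", "100", "250", "500")
_FORMS = ("", "tablets", "capsules", "injection", "oral solution")
_SUPPLIERS = ("", "imclone /bms", "pfizer", "generics ltd")
_SE_CATEGORIES = (
    "cardiac disorders",
    "vascular disorders",
    "gastrointestinal disorders",
    "nervous system disorders",
    "skin disorders",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic reporting regime.

    Defaults are the package's reference study conditions; probabilities are
    per-opportunity Bernoulli rates, ``lambda_noise`` a Poisson mean per
    report, ``drugs_per_report`` the mean of a shifted-Poisson count (>= 1).
    """

    n_drugs: int = 200
    n_ses: int = 400
    n_reports: int = 50_000
    k_causal: int = 5
    k_indic: int = 2
    p_causal_event: float = 0.3
    p_indication_event: float = 0.15
    lambda_noise: float = 1.0
    drugs_per_report: float = 2.0
    p_lit_causal: float = 0.4
    p_lit_treat: float = 0.3
    p_lit_background: float = 0.002
    p_lit_split: float = 0.25  # co-occurrence split across two sentences
    trade_name_fraction: float = 0.3
    drug_popularity: str = "zipf"  # "zipf" (heavy-tailed usage) or "uniform"
    zipf_exponent: float = 1.0
    rate_heterogeneity: float = 0.8  # pair rate multiplier ~ U(1-h, 1)
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_causal_event": self.p_causal_event,
            "p_indication_event": self.p_indication_event,
            "p_lit_causal": self.p_lit_causal,
            "p_lit_treat": self.p_lit_treat,
            "p_lit_background": self.p_lit_background,
            "p_lit_split": self.p_lit_split,
            "trade_name_fraction": self.trade_name_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        for name in ("n_drugs", "n_ses", "n_reports", "k_causal", "k_indic"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.k_causal + self.k_indic > self.n_ses:
            raise ValidationError(
                f"k_causal+k_indic={self.k_causal + self.k_indic} exceeds n_ses={self.n_ses}"
            )
        if self.drugs_per_report < 1:
            raise ValidationError("drugs_per_report must be >= 1")
        if self.lambda_noise < 0:
            raise ValidationError("lambda_noise must be >= 0")
        if self.drug_popularity not in ("zipf", "uniform"):
            raise ValidationError(
                f"drug_popularity must be zipf|uniform, got {self.drug_popularity!r}"
            )
        if not 0.0 <= self.rate_heterogeneity < 1.0:
            raise ValidationError("rate_heterogeneity must be in [0, 1)")
        if self.zipf_exponent < 0:
            raise ValidationError("zipf_exponent must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted pair sets: causal pairs (the simulation gold standard) and
    treatment (indication) pairs; disjoint by construction."""

    causal_pairs: frozenset[DrugSEPair]
    treat_pairs: frozenset[DrugSEPair]


@dataclass
class SimulatedData:
    """In-memory result of one simulation run."""

    config: SimConfig
    drug_lex: DrugLexicon
    se_lex: SideEffectLexicon
    reports: list[ReportRecord]
    corpus: list[LiteratureDocument]
    truth: GroundTruth
    external: ExternalScoreTable

    @property
    def gold(self) -> GoldStandard:
        return GoldStandard(frozenset(tuple(p) for p in self.truth.causal_pairs))


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # independent substream per stage keyed on (seed, stage)
    return np.random.default_rng([cfg.seed, stage])


def _drug_names(cfg: SimConfig) -> tuple[list[str], dict[str, str]]:
    generics = [f"genadrin{i:04d}" for i in range(cfg.n_drugs)]
    trades = {f"tradex{i:04d}": generics[i] for i in range(cfg.n_drugs)}
    return generics, trades


def _se_names(cfg: SimConfig) -> list[str]:
    # alternate single- and two-token terms so contiguous-phrase matching is exercised
    return [
        f"sympt{i:04d}" if i % 2 == 0 else f"sympt{i:04d} syndrome"
        for i in range(cfg.n_ses)
    ]


def _drug_weights(cfg: SimConfig) -> np.ndarray:
    """Per-drug draw weights: heavy-tailed (Zipf) by default."""
    if cfg.drug_popularity == "uniform":
        w = np.ones(cfg.n_drugs)
    else:
        w = 1.0 / np.arange(1, cfg.n_drugs + 1, dtype=float) ** cfg.zipf_exponent
    return w / w.sum()


def simulate(cfg: SimConfig = SimConfig()) -> SimulatedData:
    """Generate one synthetic dataset under the configured regime."""
    cfg.validate()
    generics, trades = _drug_names(cfg)
    ses = _se_names(cfg)

    rng = _rng(cfg, 0)
    causal: dict[str, list[str]] = {}
    indic: dict[str, list[str]] = {}
    for g in generics:
        picked = rng.choice(cfg.n_ses, size=cfg.k_causal + cfg.k_indic, replace=False)
        causal[g] = [ses[j] for j in picked[: cfg.k_causal]]
        indic[g] = [ses[j] for j in picked[cfg.k_causal :]]
    causal_pairs = frozenset(DrugSEPair(d, s) for d, lst in causal.items() for s in lst)
    treat_pairs = frozenset(DrugSEPair(d, s) for d, lst in indic.items() for s in lst)
    # per-pair reporting-rate multipliers: real pairs differ widely in how
    # often they are reported, which keeps frequency ranking imperfect
    h = cfg.rate_heterogeneity
    causal_rate = {
        g: cfg.p_causal_event * rng.uniform(1.0 - h, 1.0, size=cfg.k_causal)
        for g in generics
    }
    indic_rate = {
        g: cfg.p_indication_event * rng.uniform(1.0 - h, 1.0, size=cfg.k_indic)
        for g in generics
    }

    se_lex = SideEffectLexicon(
        frozenset(ses),
        {t: frozenset({_SE_CATEGORIES[i % len(_SE_CATEGORIES)]}) for i, t in enumerate(ses)},
    )
    drug_lex = DrugLexicon(frozenset(generics), dict(trades))
    trade_of = {g: t for t, g in trades.items()}

    reports = _simulate_reports(
        cfg, generics, ses, causal, indic, causal_rate, indic_rate, trade_of
    )
    corpus = _simulate_corpus(cfg, generics, ses, causal_pairs, treat_pairs)
    external = _simulate_external(cfg, generics, ses, causal_pairs)
    return SimulatedData(
        config=cfg,
        drug_lex=drug_lex,
        se_lex=se_lex,
        reports=reports,
        corpus=corpus,
        truth=GroundTruth(causal_pairs, treat_pairs),
        external=external,
    )


def _simulate_reports(
    cfg, generics, ses, causal, indic, causal_rate, indic_rate, trade_of
) -> list[ReportRecord]:
    rng = _rng(cfg, 1)
    n_drugs = cfg.n_drugs
    weights = _drug_weights(cfg)
    logw = np.log(weights)
    reports: list[ReportRecord] = []
    n_per = 1 + rng.poisson(cfg.drugs_per_report - 1.0, size=cfg.n_reports)
    for r in range(cfg.n_reports):
        k = min(int(n_per[r]), n_drugs)
        if cfg.drug_popularity == "uniform":
            idx = rng.choice(n_drugs, size=k, replace=False)
        else:
            # Gumbel-top-k: weighted sampling without replacement
            keys = logw + rng.gumbel(size=n_drugs)
            idx = np.argpartition(-keys, k - 1)[:k]
        drawn = [generics[int(j)] for j in idx]
        events: dict[str, None] = {}
        for g in drawn:
            for s, p in zip(causal[g], causal_rate[g]):
                if rng.random() < p:
                    events.setdefault(s)
            for s, p in zip(indic[g], indic_rate[g]):
                if rng.random() < p:
                    events.setdefault(s)
        for _ in range(int(rng.poisson(cfg.lambda_noise))):
            events.setdefault(ses[int(rng.integers(cfg.n_ses))])
        drug_strings = [_decorate(g, trade_of, cfg, rng) for g in drawn]
        reports.append(ReportRecord(f"r{r:07d}", drug_strings, list(events)))
    return reports


def _decorate(generic: str, trade_of, cfg: SimConfig, rng) -> str:
    name = trade_of[generic] if rng.random() < cfg.trade_name_fraction else generic
    dose = _DOSES[int(rng.integers(len(_DOSES)))]
    form = _FORMS[int(rng.integers(len(_FORMS)))]
    supplier = _SUPPLIERS[int(rng.integers(len(_SUPPLIERS)))]
    return " ".join(x for x in (name, dose, "mg", form, supplier) if x)


_SENT_BOTH = "in this cohort {drug} was associated with {se} in several patients."
_SENT_TREAT = "patients received {drug} for the management of {se} symptoms."
_SENT_DRUG_ONLY = "pharmacokinetics of {drug} were studied in healthy volunteers."
_SENT_SE_ONLY = "the incidence of {se} increased with age in the registry."
_SENT_DISTRACTOR = "no significant toxicity was observed in the placebo arm."


def _simulate_corpus(cfg, generics, ses, causal_pairs, treat_pairs) -> list[LiteratureDocument]:
    rng = _rng(cfg, 2)
    docs: list[LiteratureDocument] = []

    def add_doc(sentences: list[str]) -> None:
        docs.append(LiteratureDocument(f"pm{len(docs):07d}", sentences))

    def sample_pairs(pairs, p):
        pairs = sorted(pairs)
        mask = rng.random(len(pairs)) < p
        return [pr for pr, m in zip(pairs, mask) if m]

    for pair in sample_pairs(causal_pairs, cfg.p_lit_causal):
        _emit(pair, _SENT_BOTH, cfg, rng, add_doc)
    for pair in sample_pairs(treat_pairs, cfg.p_lit_treat):
        _emit(pair, _SENT_TREAT, cfg, rng, add_doc)
    other = [
        DrugSEPair(d, s)
        for d in generics
        for s in ses
        if DrugSEPair(d, s) not in causal_pairs and DrugSEPair(d, s) not in treat_pairs
    ]
    for pair in sample_pairs(other, cfg.p_lit_background):
        _emit(pair, _SENT_BOTH, cfg, rng, add_doc)
    # distractors: single-entity and no-entity sentences
    n_distract = max(10, cfg.n_drugs // 4)
    for _ in range(n_distract):
        d = generics[int(rng.integers(len(generics)))]
        s = ses[int(rng.integers(len(ses)))]
        add_doc([_SENT_DRUG_ONLY.format(drug=d)])
        add_doc([_SENT_SE_ONLY.format(se=s)])
        add_doc([_SENT_DISTRACTOR])
    return docs


def _emit(pair: DrugSEPair, template: str, cfg, rng, add_doc) -> None:
    if rng.random() < cfg.p_lit_split:
        # abstract-level only: drug and SE in different sentences of one doc
        add_doc(
            [
                _SENT_DRUG_ONLY.format(drug=pair.drug),
                _SENT_SE_ONLY.format(se=pair.se),
            ]
        )
    else:
        add_doc([template.format(drug=pair.drug, se=pair.se), _SENT_DISTRACTOR])


def _simulate_external(cfg, generics, ses, causal_pairs) -> ExternalScoreTable:
    rng = _rng(cfg, 3)
    scores: dict[tuple[str, str], float] = {}
    for pair in sorted(causal_pairs):
        if rng.random() < 0.6:  # partial coverage, like any external resource
            scores[tuple(pair)] = float(2.0 + rng.normal(0.0, 1.0))
    n_random = len(causal_pairs)
    for _ in range(n_random):
        d = generics[int(rng.integers(len(generics)))]
        s = ses[int(rng.integers(len(ses)))]
        scores.setdefault((d, s), float(abs(rng.normal(0.0, 1.0))))
    return ExternalScoreTable(scores)


def expected_counts(cfg: SimConfig) -> dict[str, float]:
    """Closed-form expectations for recovery tests.

    ``p_drug_drawn`` is the mean probability a given drug appears in a
    report — exact for uniform popularity (E[#drugs]/n_drugs), a first-order
    approximation ``min(E[#drugs]·w_i, 1)`` averaged over drugs for Zipf
    weights. ``e_causal_a`` is the mean expected co-report count of a causal
    pair, n_reports · p_drug_drawn · p_causal_event · E[rate multiplier]
    (contributions of the noise/indication channels to a causal pair are
    ignored). Exact recovery tests should use uniform popularity and
    ``rate_heterogeneity=0``.
    """
    cfg.validate()
    if cfg.drug_popularity == "uniform":
        p_drawn = min(cfg.drugs_per_report / cfg.n_drugs, 1.0)
    else:
        w = _drug_weights(cfg)
        p_drawn = float(np.minimum(cfg.drugs_per_report * w, 1.0).mean())
    mean_mult = 1.0 - cfg.rate_heterogeneity / 2.0
    return {
        "p_drug_drawn": p_drawn,
        "e_causal_a": cfg.n_reports * p_drawn * cfg.p_causal_event * mean_mult,
        "e_treat_a": cfg.n_reports * p_drawn * cfg.p_indication_event * mean_mult,
        "e_noise_a": cfg.n_reports * p_drawn * cfg.lambda_noise / cfg.n_ses,
    }


def write_all(data: SimulatedData, outdir: str | Path, dialect: str = "tsv") -> dict[str, Path]:
    """Write every artifact of a run in the formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "drug_file": outdir / "DRUG.tsv",
        "reac_file": outdir / "REAC.tsv",
        "drug_lexicon": outdir / "drug_lexicon.tsv",
        "se_lexicon": outdir / "se_lexicon.tsv",
        "corpus": outdir / "corpus.tsv",
        "gold": outdir / "gold.tsv",
        "external": outdir / "external_scores.tsv",
        "treat_pairs": outdir / "treat_pairs.tsv",
    }
    corpus_io.write_reports(paths["drug_file"], paths["reac_file"], data.reports, dialect)
    corpus_io.write_lexicons(paths["drug_lexicon"], paths["se_lexicon"], data.drug_lex, data.se_lex)
    corpus_io.write_corpus(paths["corpus"], data.corpus)
    corpus_io.write_gold(paths["gold"], data.gold)
    corpus_io.write_external_scores(paths["external"], data.external)
    corpus_io.write_pairs(paths["treat_pairs"], sorted(data.truth.treat_pairs))
    return paths
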