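# Methods

## The problem

Spontaneous reporting systems (FAERS being the prominent example) collect
post-marketing reports of suspected adverse drug events. Linking a report's
drug list with its coded event list yields drug–side-effect (drug–SE)
candidate pairs, but the overwhelming majority of them are spurious: a
patient on m drugs reporting n events contributes all m×n pairs, most of
which reflect polypharmacy, background morbidity, or the disease the drug
was prescribed for (confounding by indication) rather than causation. The
signal-detection task is to rank the millions of candidate pairs so that
true causal associations concentrate at the top.

`pharmaboost` implements a literature-augmented ranking strategy: score
every pair with a within-database signal, then *square* the score of any
pair that also co-occurs in the biomedical literature. The rationale is
that a pair mentioned in the literature usually has some real semantic
relationship (cause, treatment, …), and among literature-supported pairs a
high report count makes the causal reading more likely. No pair is ever
filtered out: pairs without literature support keep their original score,
preserving recall.

## Pipeline stages

1. **Extraction.** DRUG/REAC report files are joined on report ID. Drug
   strings are free text, so drug entities are recognized by dictionary
   matching (longest-leftmost, token-boundary) against a drug lexicon, with
   trade names mapped to generic names; misspelled strings deliberately
   yield no match — no fuzzy correction is attempted, and unmatched strings
   are only counted in run statistics. Event strings are terminology-coded
   (MedDRA-style), so SE recognition is whole-string matching against a
   cleaned SE lexicon. Per report, distinct drugs × distinct SEs each count
   once; marginals count reports, not mentions (the usual convention for
   disproportionality analysis). The 2×2 universe N includes only reports
   with at least one recognized drug *and* one recognized SE, so every
   pair's table cells sum to the same N.

2. **Signals.** Seven ranking signals over the per-pair 2×2 table
   (a = reports with drug and SE, b = drug only, c = SE only, d = neither):

   | signal | definition | null |
   |---|---|---|
   | FREQ | a | — |
   | PRR  | [a/(a+b)] / [c/(c+d)] | 1 |
   | RRR  | aN / ((a+b)(a+c)) | 1 |
   | ROR  | ad / bc | 1 |
   | PhiCorr | (ad−bc)/√((a+b)(c+d)(a+c)(b+d)) | 0 |
   | IC   | log₂ RRR (raw) or log₂((a+0.5)/(E+0.5)), E=(a+b)(a+c)/N | 0 |
   | EXTERNAL | score from a supplied table (OffSides-style) | — |

   Raw IC is the default because it keeps the identity IC ≡ log₂(RRR)
   exact and testable; the 0.5-shrinkage variant is offered for a=0 tables
   and is, by design, the one measure that is not invariant under scaling
   all four cells. Zero cells in b, c or d trigger the Haldane–Anscombe
   correction (+0.5 to every cell) for PRR and ROR only, flagged in the
   output. Signals that are genuinely undefined (empty drug row for PRR, a
   zero marginal for phi, a=0 for raw IC, a pair absent from the external
   table) carry an undefined marker and always sort below defined ones,
   ordered among themselves by FREQ then lexicographically.

3. **Literature evidence.** An in-process inverted index maps every lexicon
   term (generics, trade names resolved to generics, SE terms) to the
   (document, sentence) positions where its token sequence occurs
   contiguously, case-insensitively. A pair has *sentence-level* evidence
   when both terms share a sentence and *abstract-level* evidence when both
   occur anywhere in one document; sentence evidence implies abstract
   evidence. Matching is exact at the token level: no inflection or gap
   tolerance. Plain co-occurrence admits false positives where the SE
   term's tokens appear in a non-entity role ("baclofen **decreased
   activity** during a 30-min period" is a verb phrase, not the side effect
   term); a syntactic filter is out of scope here, but `evidence_for`
   accepts a `sentence_filter` hook where one can be attached.

4. **Boosting and ranking.** A pair with evidence at the chosen level gets
   score² ; others keep their score. Squaring a score below 1 — possible
   for the ratio-type signals — *decreases* it; the rule is applied
   literally, a warning is logged when it fires, and a `boost_floor` option
   squares max(score, 1) instead for sensitivity analysis. Ties break by
   boosted value, then base FREQ, then (drug, se) lexicographically, so
   rankings are fully deterministic. The ranked list is always a
   permutation of the input pairs.

5. **Evaluation.** A drug-label-derived gold standard (SIDER-style)
   calibrates *comparisons between rankings*; it does not measure true
   accuracy, because labels lag post-marketing evidence. Pair sets get
   precision/recall/F1; rankings get 11-point interpolated average
   precision: at recall levels 0.0, 0.1, …, 1.0 the interpolated precision
   is max{precision at any rank with recall ≥ level}, and AP is the mean of
   the 11 values. The default recall denominator is the *reachable* gold
   (gold ∩ candidate universe); a `full` option uses the whole gold set,
   in which case levels beyond the reachable recall score 0. Relative
   changes are reported as (new−base)/base, both as a fold (1 decimal) and
   a percent (integer); set rates round to 3 decimals. `curation_metrics`
   summarizes a manual CAUSE/TREAT/NONE classification of a pair subset:
   precision is the CAUSE fraction, novelty the fraction of CAUSE pairs
   absent from the gold standard.

## The synthetic regime

Real report databases, literature corpora and label gold standards are
large external downloads; the package instead ships a generator whose
output has the statistical structure the method assumes, so the whole
pipeline and the boosting benefit are testable end to end.

Each drug gets `k_causal` causal SEs and `k_indic` indications (disjoint).
A report draws ≥1 drugs, then events arise through three channels: causal
(per-pair rate), misreported indications (per-pair rate — this plants
confounding by indication), and Poisson background noise uniform over the
SE vocabulary. Drug strings are decorated free text (dose/form/supplier
tokens; a fraction written as trade names), so dictionary NER is genuinely
exercised. The literature corpus holds one templated sentence per sampled
co-occurrence — causal pairs with probability `p_lit_causal`, treatment
pairs `p_lit_treat` (the literature is dominated by treatment relations),
any other pair `p_lit_background` — plus distractor sentences; a fraction
`p_lit_split` of co-occurrences is split across two sentences of one
document, producing abstract-level-only evidence. The gold standard is the
planted causal-pair set; the external score table covers causal pairs
partially and noisily.

Two structural features keep the regime honest. Drug usage is Zipf-weighted
(`drug_popularity="zipf"`, exponent 1.0), mirroring the heavy-tailed
prescription frequencies of real data, and every planted pair has its own
reporting-rate multiplier drawn from U(1−h, 1) with h=0.8. Without them,
causal, treatment and noise pair counts separate into disjoint bands and
frequency ranking is a perfect classifier — a regime in which literature
boosting has nothing to improve and which no spontaneous-reporting dataset
resembles. With them, counts overlap across classes: frequency ranking is
informative but imperfect, confounded treatment pairs rank high, and the
evidence channel carries independent information — exactly the situation
the method was designed for.

Reference conditions (the defaults): 200 drugs, 400 SEs, 50,000 reports,
mean 2.0 drugs/report, p_causal_event = 0.3, p_indication_event = 0.15,
λ_noise = 1.0, p_lit_causal = 0.4, p_lit_treat = 0.3,
p_lit_background = 0.002, p_lit_split = 0.25, trade_name_fraction = 0.3.
A full run at these sizes takes a few seconds. Determinism is strict:
identical seed and config give byte-identical files, and each generation
stage draws from its own substream keyed on (seed, stage), so enlarging the
report set does not perturb the corpus.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: duplicate and follow-up reports, real MedDRA
hierarchy and term granularity, misspelled drug strings (NER precision on
real free text must be measured with `ner_accuracy` on curated samples),
temporal reporting dynamics, and literature sentences whose syntax defeats
co-occurrence matching (the verb-phrase false positive above). Measured
precisions on synthetic data are calibration checks of the machinery, not
forecasts of field performance.

## Numerical and design notes

- All strings pass one normalizer (Unicode NFC, lowercase, whitespace
  collapse, edge-punctuation strip); it is idempotent, and every module
  matches on its output, so extraction, literature lookup and evaluation
  agree on pair identity. Tokens are maximal alphanumeric runs with
  internal hyphens kept (catalogue-style drug codes stay single tokens).
- Duplicate trade names mapping to different generics resolve to the
  lexicographically smallest generic, with a warning — deterministic
  rather than silently order-dependent.
- Reports appearing in several quarterly files merge by union of their
  string lists, de-duplicated.
- Writers emit sorted rows (ranked lists excepted, where order is the
  payload) so outputs diff cleanly; every pipeline output embeds a hash of
  the run configuration.
- Undefined metrics are NaN/None markers, never silently zero; the CLI
  maps error classes to exit codes (2 validation, 3 format, 4 internal
  consistency).

## Known limitations

Dictionary NER cannot recognize misspellings or novel names absent from
the lexicon, by design. Sentence-level evidence over-counts verb-phrase
collisions without a syntactic filter. The boosting rule is presence-based
only; evidence counts are computed and stored but deliberately unused in
ranking. Squared sub-unit scores demote rather than promote (warned, with
the `boost_floor` escape hatch). The evaluation's gold standard remains a
ranking calibrator, not ground truth.
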