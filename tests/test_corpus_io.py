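import pytest

from pharmaboost import corpus_io
from pharmaboost.corpus_io import (
    DrugLexicon,
    GoldStandard,
    LiteratureDocument,
    ReportRecord,
)
from pharmaboost.errors import FormatError, ValidationError
from pharmaboost.normalize import normalize


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return str(path)


class TestReadReports:
    def test_joins_drug_and_reac_rows_by_report_id(self, tmp_path):
        drug = _write(tmp_path / "DRUG.txt", "id$drug\nr1$aspirin\nr1$warfarin\n")
        reac = _write(tmp_path / "REAC.txt", "id$event\nr1$nausea\n")
        recs = corpus_io.read_reports(drug, reac, "faers_dollar")
        assert len(recs) == 1
        assert recs[0].drug_strings == ["aspirin", "warfarin"]
        assert recs[0].event_terms == ["nausea"]

    def test_outer_merge_keeps_reports_seen_in_one_file_only(self, tmp_path):
        drug = _write(tmp_path / "d", "id\tdrug\nr1\taspirin\n")
        reac = _write(tmp_path / "r", "id\tevent\nr1\tnausea\nr2\trash\n")
        recs = {r.report_id: r for r in corpus_io.read_reports(drug, reac, "tsv")}
        assert recs["r2"].drug_strings == []
        assert recs["r2"].event_terms == ["rash"]

    def test_result_is_independent_of_row_order(self, tmp_path):
        a = corpus_io.read_reports(
            _write(tmp_path / "d1", "id\tdrug\nr1\ta\nr2\tb\n"),
            _write(tmp_path / "r1", "id\tevent\nr2\ty\nr1\tx\n"),
            "tsv",
        )
        b = corpus_io.read_reports(
            _write(tmp_path / "d2", "id\tdrug\nr2\tb\nr1\ta\n"),
            _write(tmp_path / "r2", "id\tevent\nr1\tx\nr2\ty\n"),
            "tsv",
        )
        assert [(r.report_id, r.drug_strings, r.event_terms) for r in a] == [
            (r.report_id, r.drug_strings, r.event_terms) for r in b
        ]

    def test_empty_report_ids_are_skipped(self, tmp_path):
        drug = _write(tmp_path / "d", "id\tdrug\n\taspirin\nr1\tibuprofen\n")
        reac = _write(tmp_path / "r", "id\tevent\nr1\tnausea\n")
        recs = corpus_io.read_reports(drug, reac, "tsv")
        assert [r.report_id for r in recs] == ["r1"]

    def test_malformed_header_names_file(self, tmp_path):
        drug = _write(tmp_path / "DRUG.txt", "onlyonecolumn\nr1$aspirin\n")
        reac = _write(tmp_path / "REAC.txt", "id$event\n")
        with pytest.raises(FormatError, match="DRUG.txt.*line 1"):
            corpus_io.read_reports(drug, reac, "faers_dollar")

    def test_unknown_dialect_is_a_configuration_error(self, tmp_path):
        drug = _write(tmp_path / "d", "id\tdrug\n")
        with pytest.raises(ValidationError, match="dialect"):
            corpus_io.read_reports(drug, drug, "csv")

    def test_quarterly_merge_unions_by_report_id(self):
        q1 = [ReportRecord("r1", ["aspirin"], ["nausea"])]
        q2 = [ReportRecord("r1", ["aspirin", "warfarin"], []), ReportRecord("r2", ["x"], [])]
        merged = {r.report_id: r for r in corpus_io.merge_reports(q1, q2)}
        assert merged["r1"].drug_strings == ["aspirin", "warfarin"]
        assert merged["r1"].event_terms == ["nausea"]
        assert set(merged) == {"r1", "r2"}

    def test_reports_round_trip_both_dialects(self, tmp_path):
        recs = [ReportRecord("r1", ["aspirin 100 mg"], ["nausea"]),
                ReportRecord("r2", ["warfarin"], ["rash", "headache"])]
        for dialect in ("tsv", "faers_dollar"):
            d, r = tmp_path / f"D.{dialect}", tmp_path / f"R.{dialect}"
            corpus_io.write_reports(d, r, recs, dialect)
            back = corpus_io.read_reports(d, r, dialect)
            assert [(x.report_id, x.drug_strings, x.event_terms) for x in back] == [
                (x.report_id, x.drug_strings, x.event_terms) for x in recs
            ]


class TestLexicons:
    def test_trade_names_map_to_generics(self, tmp_path):
        dl = _write(
            tmp_path / "drugs.tsv",
            "name\tgeneric\tkind\ncetuximab\tcetuximab\tgeneric\nerbitux\tcetuximab\ttrade\n",
        )
        sl = _write(tmp_path / "ses.tsv", "term\tancestors\nnausea\t\n")
        dlex, slex = corpus_io.read_lexicons(dl, sl)
        assert dlex.trade_to_generic["erbitux"] == "cetuximab"
        assert slex.ancestors.get("nausea", frozenset()) == frozenset()

    def test_conflicting_trade_duplicates_pick_smallest_generic(self, tmp_path, caplog):
        dl = _write(
            tmp_path / "drugs.tsv",
            "name\tgeneric\tkind\n"
            "agen\tagen\tgeneric\nbgen\tbgen\tgeneric\n"
            "drugx\tbgen\ttrade\ndrugx\tagen\ttrade\n",
        )
        sl = _write(tmp_path / "ses.tsv", "term\tancestors\n")
        with caplog.at_level("WARNING"):
            dlex, _ = corpus_io.read_lexicons(dl, sl)
        assert dlex.trade_to_generic["drugx"] == "agen"
        assert any("conflicting" in r.message for r in caplog.records)

    def test_trade_row_with_unknown_generic_fails_validation(self, tmp_path):
        dl = _write(tmp_path / "d.tsv", "name\tgeneric\tkind\nerbitux\tcetuximab\ttrade\n")
        sl = _write(tmp_path / "s.tsv", "term\tancestors\n")
        with pytest.raises(ValidationError, match="cetuximab"):
            corpus_io.read_lexicons(dl, sl)

    def test_normalization_is_idempotent(self):
        for s in ("  NAUSEA ", "Érbitux  100  mg.", "warfarin", "(coumadin)"):
            once = normalize(s)
            assert normalize(once) == once

    def test_lexicon_round_trip(self, tmp_path, tiny_drug_lexicon, tiny_se_lexicon):
        dp, sp = tmp_path / "d.tsv", tmp_path / "s.tsv"
        corpus_io.write_lexicons(dp, sp, tiny_drug_lexicon, tiny_se_lexicon)
        dlex, slex = corpus_io.read_lexicons(dp, sp)
        assert dlex == tiny_drug_lexicon
        assert slex == tiny_se_lexicon


class TestCorpus:
    def test_sentences_grouped_in_index_order(self, tmp_path):
        p = _write(
            tmp_path / "c.tsv",
            "doc_id\tsentence_index\ttext\nd1\t0\tfirst.\nd2\t0\tother.\nd1\t1\tsecond.\n",
        )
        docs = corpus_io.read_corpus(p)
        assert [d.doc_id for d in docs] == ["d1", "d2"]
        assert docs[0].sentences == ["first.", "second."]
        assert docs[0].abstract_text == "first. second."

    def test_empty_corpus_file(self, tmp_path):
        p = _write(tmp_path / "c.tsv", "doc_id\tsentence_index\ttext\n")
        assert corpus_io.read_corpus(p) == []

    def test_sentence_index_gap_is_a_format_error(self, tmp_path):
        p = _write(tmp_path / "c.tsv", "doc_id\tsentence_index\ttext\nd1\t0\ta\nd1\t2\tb\n")
        with pytest.raises(FormatError, match="contiguous"):
            corpus_io.read_corpus(p)

    def test_corpus_round_trip(self, tmp_path):
        docs = [LiteratureDocument("d1", ["one.", "two."]), LiteratureDocument("d2", ["x."])]
        p = tmp_path / "c.tsv"
        corpus_io.write_corpus(p, docs)
        assert corpus_io.read_corpus(p) == docs


class TestPairLists:
    def test_gold_standard_deduplicates(self, tmp_path):
        p = _write(
            tmp_path / "g.tsv",
            "drug\tse\naspirin\tnausea\nwarfarin\trash\naspirin\tnausea\nibuprofen\tnausea\n",
        )
        gold = corpus_io.read_gold(p)
        assert len(gold) == 3

    def test_write_then_read_is_identity_and_sorted(self, tmp_path):
        pairs = [("b", "y"), ("a", "z"), ("a", "x")]
        p = tmp_path / "pairs.tsv"
        corpus_io.write_pairs(p, pairs)
        assert corpus_io.read_pairs(p) == [("a", "x"), ("a", "z"), ("b", "y")]
        # byte-stable: a second write is identical
        q = tmp_path / "pairs2.tsv"
        corpus_io.write_pairs(q, corpus_io.read_pairs(p))
        assert p.read_bytes() == q.read_bytes()

    def test_scientific_notation_scores_parse(self, tmp_path):
        p = _write(tmp_path / "x.tsv", "drug\tse\tscore\naspirin\tnausea\t1e3\n")
        table = corpus_io.read_external_scores(p)
        assert table.scores[("aspirin", "nausea")] == 1000.0

    def test_non_numeric_score_is_a_format_error(self, tmp_path):
        p = _write(tmp_path / "x.tsv", "drug\tse\tscore\naspirin\tnausea\thigh\n")
        with pytest.raises(FormatError, match="non-numeric"):
            corpus_io.read_pairs(p)

    def test_gold_membership_uses_tuple_semantics(self):
        gold = GoldStandard(frozenset({("a", "x")}))
        assert ("a", "x") in gold
        assert ("a", "y") not in gold


def test_se_category_subset_derived_from_ancestors(tiny_se_lexicon):
    cv = tiny_se_lexicon.subset_with_ancestor(["cardiac disorders", "vascular disorders"])
    assert cv == {"myocardial infarction"}


def test_drug_lexicon_rejects_dangling_trade_mapping():
    with pytest.raises(ValidationError):
        DrugLexicon(frozenset({"warfarin"}), {"erbitux": "cetuximab"})
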