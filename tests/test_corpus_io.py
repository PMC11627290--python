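import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import phenomine as pm
from phenomine.corpus import CorpusError, DictionaryError

MEDLINE_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>100001</PMID>
      <Article>
        <ArticleTitle>Gray hair in elderly cohorts.</ArticleTitle>
        <Abstract>
          <AbstractText Label="BACKGROUND">Dementia was common.</AbstractText>
          <AbstractText Label="RESULTS">Prevalence increased with age.</AbstractText>
        </Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>100002</PMID>
      <Article>
        <ArticleTitle>A title-only citation.</ArticleTitle>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


class TestMedlineXML:
    def test_two_records_map_to_two_abstracts(self, tmp_path):
        p = tmp_path / "baseline.xml"
        p.write_text(MEDLINE_XML)
        corpus = pm.read_medline_xml(p)
        assert corpus.ids == ["100001", "100002"]
        assert corpus["100001"].text == (
            "Gray hair in elderly cohorts. Dementia was common. "
            "Prevalence increased with age."
        )

    def test_title_only_record_falls_back_to_title(self, tmp_path):
        p = tmp_path / "baseline.xml"
        p.write_text(MEDLINE_XML)
        assert pm.read_medline_xml(p)["100002"].text == "A title-only citation."

    def test_include_title_off_drops_titles(self, tmp_path):
        p = tmp_path / "baseline.xml"
        p.write_text(MEDLINE_XML)
        corpus = pm.read_medline_xml(p, include_title=False)
        assert corpus["100001"].text.startswith("Dementia")
        assert corpus["100002"].text == ""

    def test_gzip_transparent(self, tmp_path):
        import gzip

        p = tmp_path / "baseline.xml.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(MEDLINE_XML)
        assert len(pm.read_medline_xml(p)) == 2

    def test_duplicate_pmid_rejected(self, tmp_path):
        p = tmp_path / "dup.xml"
        p.write_text(MEDLINE_XML.replace("100002", "100001"))
        with pytest.raises(CorpusError, match="duplicate"):
            pm.read_medline_xml(p)

    def test_malformed_xml_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text(MEDLINE_XML[:200])
        with pytest.raises(CorpusError, match="malformed"):
            pm.read_medline_xml(p)


class TestJsonlCorpus:
    @settings(max_examples=25, deadline=None)
    @given(
        records=st.lists(
            st.tuples(st.uuids().map(str), st.text(max_size=80)),
            max_size=10,
            unique_by=lambda t: t[0],
        )
    )
    def test_round_trip_identity(self, records, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("jsonl")
        corpus = pm.Corpus([pm.Abstract(i, t) for i, t in records])
        path = tmp / "c.jsonl"
        pm.write_jsonl_corpus(corpus, path)
        back = pm.read_jsonl_corpus(path)
        assert back.ids == corpus.ids
        assert [a.text for a in back] == [a.text for a in corpus]

    def test_empty_file_empty_corpus(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("")
        assert len(pm.read_jsonl_corpus(p)) == 0

    def test_missing_id_names_line(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text('{"id": "1", "text": "a"}\n{"text": "b"}\n')
        with pytest.raises(CorpusError, match="line 2"):
            pm.read_jsonl_corpus(p)

    def test_duplicate_id_rejected_at_load(self, tmp_path):
        p = tmp_path / "dup.jsonl"
        p.write_text('{"id": "1", "text": "a"}\n{"id": "1", "text": "b"}\n')
        with pytest.raises(CorpusError, match="duplicate"):
            pm.read_jsonl_corpus(p)


class TestDictionaryTSV:
    def test_synonym_rows_group_under_canonical(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "canonical\tsynonym\n"
            "Graying of hair\t\n"
            "Graying of hair\tGray Hair\n"
        )
        d = pm.read_dictionary_tsv(p)
        assert len(d) == 1
        assert d["Graying of hair"].surface_forms == ["Graying of hair", "Gray Hair"]
        assert d.n_surface_forms == 2

    def test_canonical_only_dictionary(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("canonical\tsynonym\nDementia\t\nCataract\t\n")
        d = pm.read_dictionary_tsv(p)
        assert d.canonical_terms == ["Dementia", "Cataract"]
        assert all(not e.synonyms for e in d)

    def test_semantic_tag_and_concept_id_kept(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "canonical\tsynonym\tconcept_id\tsemantic_tag\n"
            "Appendectomy\t\t80146002\tprocedure\n"
        )
        e = pm.read_dictionary_tsv(p)["Appendectomy"]
        assert (e.concept_id, e.semantic_tag) == ("80146002", "procedure")

    def test_ambiguous_synonym_collision_error(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "canonical\tsynonym\n"
            "Graying of hair\tgray hair\n"
            "Hair depigmentation\tGray Hair\n"
        )
        with pytest.raises(DictionaryError, match="ambiguous"):
            pm.read_dictionary_tsv(p)

    def test_unambiguous_random_tables_accepted(self, tmp_path):
        rng = np.random.default_rng(3)
        lines = ["canonical\tsynonym"]
        for i in range(30):
            lines.append(f"term {i}\t")
            for j in range(int(rng.integers(0, 3))):
                lines.append(f"term {i}\tsyn {i} {j}")
        p = tmp_path / "d.tsv"
        p.write_text("\n".join(lines) + "\n")
        assert len(pm.read_dictionary_tsv(p)) == 30


class TestMatrixIO:
    @pytest.mark.parametrize("mode", ["presence", "count"])
    def test_random_round_trip(self, tmp_path, mode):
        rng = np.random.default_rng(11)
        dense = rng.integers(0, 2 if mode == "presence" else 5, size=(4, 7))
        m = pm.TermDocMatrix(
            [f"t{i}" for i in range(4)],
            [f"a{j}" for j in range(7)],
            sp.csr_matrix(dense),
            mode,
        )
        pm.write_matrix(m, tmp_path / "m")
        back = pm.read_matrix(tmp_path / "m")
        assert back.mode == mode
        assert back.row_labels == m.row_labels
        assert back.col_labels == m.col_labels
        assert (back.values != m.values).nnz == 0

    def test_all_zero_matrix_round_trip(self, tmp_path):
        m = pm.TermDocMatrix(["t0", "t1"], ["a0"], sp.csr_matrix((2, 1), dtype=int))
        pm.write_matrix(m, tmp_path / "z")
        back = pm.read_matrix(tmp_path / "z")
        assert back.values.nnz == 0 and back.shape == (2, 1)

    def test_sidecar_mismatch_raises(self, tmp_path):
        m = pm.TermDocMatrix(["t0", "t1"], ["a0"], sp.csr_matrix((2, 1), dtype=int))
        pm.write_matrix(m, tmp_path / "m")
        (tmp_path / "m.rows.txt").write_text("only_one_row\n")
        with pytest.raises(ValueError, match="sidecar"):
            pm.read_matrix(tmp_path / "m")

    def test_presence_mode_rejects_counts(self):
        with pytest.raises(ValueError, match="binary"):
            pm.TermDocMatrix(["t"], ["a"], sp.csr_matrix(np.array([[3]])), "presence")
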