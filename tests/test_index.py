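"""Inverted index: analysis, commit semantics, search, scoring, fuzzy."""

import math

import pytest

from seqindex.analysis import damerau_levenshtein, fuzzy_expand, tokenize
from seqindex.errors import (
    FieldNotSearchableError,
    PartialUpdateError,
    UnknownDocumentError,
)
from seqindex.index import Index
from seqindex.model import Document, FieldSchema, Schema
from seqindex.oracle import linear_scan


def _doc(doc_id, **fields):
    return Document(doc_id=doc_id, content_type="biosequence/gff",
                    fields={k: v if isinstance(v, list) else [v]
                            for k, v in fields.items()})


def _index(*docs, schema=None):
    ix = Index(schema=schema or Schema())
    for d in docs:
        ix.add_document(d)
    ix.commit()
    return ix


class TestTokenize:
    @pytest.mark.parametrize("text,expected", [
        ("ABC kinase, gene", ["abc", "kinase", "gene"]),
        ("GO:0005634", ["go", "0005634"]),
        ("", []),
        ("NM_000546.6", ["nm_000546.6"]),  # ._- kept inside runs
        ("-leading trailing-", ["leading", "trailing"]),
    ])
    def test_analyzer_rules(self, text, expected):
        assert tokenize(text) == expected


class TestDamerauLevenshtein:
    def _brute(self, a, b):
        # naive recursive definition, memoized: the independent oracle
        from functools import lru_cache

        @lru_cache(maxsize=None)
        def d(i, j):
            if i == 0 or j == 0:
                return i + j
            best = min(d(i - 1, j) + 1, d(i, j - 1) + 1,
                       d(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                best = min(best, d(i - 2, j - 2) + 1)
            return best

        return d(len(a), len(b))

    def test_matches_brute_force_on_word_pairs(self):
        words = ["gene", "gone", "gane", "kinase", "kinsae", "knase", "geen", ""]
        for a in words:
            for b in words:
                assert damerau_levenshtein(a, b) == self._brute(a, b), (a, b)

    def test_transposition_is_one_edit(self):
        assert damerau_levenshtein("kinsae", "kinase") == 1

    def test_fuzzy_expand_examples(self):
        vocab = ["gene", "gone", "kinase"]
        assert fuzzy_expand("gane", vocab, 1) == ["gene", "gone"]
        assert "gene" in fuzzy_expand("gene", vocab, 1)  # distance 0 included
        assert fuzzy_expand("kinsae", vocab, 1) == ["kinase"]
        with pytest.raises(ValueError):
            fuzzy_expand("x", vocab, 3)


class TestCommitSemantics:
    def test_add_commit_get(self):
        ix = _index(_doc("d1", type="gene"))
        assert ix.get("d1").fields["type"] == ["gene"]

    def test_add_not_visible_before_commit(self):
        ix = Index()
        ix.add_document(_doc("d1", type="gene"))
        assert ix.search("type:gene").total == 0
        ix.commit()
        assert ix.search("type:gene").total == 1

    def test_replace_semantics_last_write_wins(self):
        ix = Index()
        ix.add_document(_doc("d1", type="gene"))
        ix.add_document(_doc("d1", type="exon"))
        ix.commit()
        assert ix.search("type:exon").total == 1
        assert ix.search("type:gene").total == 0
        assert ix.doc_count == 1

    def test_delete_removes_findability_readd_restores(self):
        ix = _index(_doc("d1", type="gene"))
        ix.delete_document("d1")
        ix.commit()
        assert ix.search("type:gene").total == 0
        ix.add_document(_doc("d1", type="gene"))
        ix.commit()
        assert ix.search("type:gene").total == 1

    def test_delete_unknown_is_noop_warning(self):
        ix = _index(_doc("d1", type="gene"))
        ix.delete_document("ghost")
        ix.commit()
        assert ix.doc_count == 1

    def test_crash_between_add_and_commit_preserves_state(self, tmp_path):
        path = str(tmp_path / "seg")
        ix = Index(path=path)
        ix.add_document(_doc("d1", type="gene"))
        ix.commit()
        ix.add_document(_doc("d2", type="exon"))
        # crash: the writer disappears without committing
        del ix
        again = Index.open(path)
        assert again.doc_count == 1 and "d2" not in again

    def test_persistence_round_trip(self, tmp_path):
        path = str(tmp_path / "seg")
        schema = Schema([FieldSchema(name="start", kind="numeric")])
        ix = Index(path=path, schema=schema)
        ix.add_document(_doc("d1", type="gene", start=100))
        ix.commit()
        again = Index.open(path, schema=schema)
        assert again.search("type:gene").total == 1
        assert again.search("start:[50 TO 150]").total == 1


class TestPartialUpdate:
    def test_only_named_fields_change(self):
        ix = _index(_doc("d1", organism="Mus musculus", type="gene"))
        ix.update_document("d1", {"organism": "Homo sapiens"})
        ix.commit()
        doc = ix.get("d1")
        assert doc.fields["organism"] == ["Homo sapiens"]
        assert doc.fields["type"] == ["gene"]
        assert ix.search("organism:sapiens").total == 1
        assert ix.search("organism:musculus").total == 0

    def test_update_unknown_id_errors(self):
        ix = _index(_doc("d1", type="gene"))
        with pytest.raises(UnknownDocumentError):
            ix.update_document("ghost", {"a": "b"})

    def test_unstored_field_blocks_partial_update(self):
        schema = Schema([FieldSchema(name="secret", kind="text",
                                     indexed=True, stored=False)])
        ix = _index(_doc("d1", secret="hidden", type="gene"), schema=schema)
        with pytest.raises(PartialUpdateError) as exc:
            ix.update_document("d1", {"type": "exon"})
        assert "secret" in str(exc.value)


class TestSearch:
    def test_term_match(self):
        ix = _index(_doc("d1", body="gene kinase"), _doc("d2", body="gene"))
        res = ix.search("kinase")
        assert res.total == 1 and res.hits[0].doc_id == "d1"

    def test_paging(self):
        ix = _index(_doc("d1", body="gene kinase"), _doc("d2", body="gene"))
        res = ix.search("gene", offset=1, limit=1)
        assert res.total == 2 and len(res.hits) == 1
        full = ix.search("gene", 0, 10)
        assert res.hits[0].doc_id == full.hits[1].doc_id

    def test_range_bounds_inclusive(self):
        schema = Schema([FieldSchema(name="start", kind="numeric")])
        ix = _index(_doc("a", start=100), _doc("b", start=200),
                    _doc("c", start=300), schema=schema)
        res = ix.search("start:[150 TO 350]", 0, None)
        assert {h.doc_id for h in res.hits} == {"b", "c"}
        res = ix.search("start:[100 TO 300]", 0, None)
        assert res.total == 3

    def test_non_indexed_field_errors(self):
        schema = Schema([FieldSchema(name="raw", kind="text",
                                     indexed=False, stored=True)])
        ix = _index(_doc("d1", raw="x", type="gene"), schema=schema)
        with pytest.raises(FieldNotSearchableError):
            ix.search("raw:x")

    def test_paging_consistency(self, gff_index, oracle_queries):
        """Concatenated pages reproduce the full ranked list exactly once."""
        for q in oracle_queries[:20]:
            full = [h.doc_id for h in gff_index.search(q, 0, None).hits]
            paged = []
            k = 7
            for off in range(0, len(full) + k, k):
                paged.extend(h.doc_id for h in gff_index.search(q, off, k).hits)
            assert paged == full, q


class TestScoring:
    def test_single_doc_single_term_scores_one(self):
        ix = _index(_doc("d1", type="gene"))
        assert ix.score_document("d1", "type:gene") == pytest.approx(1.0, abs=1e-12)

    def test_two_doc_idf(self):
        ix = _index(_doc("d1", type="gene"), _doc("d2", type="exon"))
        expected = 1 + math.log(3 / 2)
        assert ix.score_document("d1", "type:gene") == \
            pytest.approx(expected, abs=1e-12)

    def test_range_only_scores_one(self):
        schema = Schema([FieldSchema(name="start", kind="numeric")])
        ix = _index(_doc("d1", start=5), schema=schema)
        assert ix.score_document("d1", "start:[1 TO 10]") == 1.0

    def test_score_monotone_in_tf(self):
        """More occurrences of a query term never lower the score."""
        base = _index(_doc("d1", body="gene"), _doc("d2", body="exon"))
        more = _index(_doc("d1", body="gene gene"), _doc("d2", body="exon"))
        assert more.score_document("d1", "gene") >= \
            base.score_document("d1", "gene")

    def test_new_df_holder_never_raises_others(self):
        base = _index(_doc("d1", body="gene"), _doc("d2", body="exon"))
        wider = _index(_doc("d1", body="gene"), _doc("d2", body="exon gene"))
        assert wider.score_document("d1", "gene") <= \
            base.score_document("d1", "gene")


class TestOracleEquivalence:
    def test_200_random_queries_match_linear_scan(self, gff_index, gff_docs,
                                                  oracle_queries, schema):
        for q in oracle_queries:
            ast = gff_index.prepare(q)
            got = {h.doc_id for h in
                   gff_index.search(ast, 0, None, prenormalized=True).hits}
            expected = linear_scan(gff_docs, ast, schema)
            assert got == expected, q
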