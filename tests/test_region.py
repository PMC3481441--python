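"""Region driver: interval overlap, sequence retrieval, GFF3 export."""

import io
import random

import pytest

from seqindex.chunks import ChunkStore
from seqindex.errors import SubrangeError, UnknownKeyError
from seqindex.index import Index
from seqindex.model import Document
from seqindex.readers import parse_gff3
from seqindex.region import (
    Region, export_region_gff, features_in_region, sequence_of_region,
)


def _feature(doc_id, seqid, start, end, ftype="gene"):
    return Document(doc_id=doc_id, content_type="biosequence/gff",
                    fields={"seqid": [seqid], "type": [ftype],
                            "start": [start], "end": [end], "strand": ["+"],
                            "ID": [doc_id]})


@pytest.fixture()
def small_index(schema):
    ix = Index(schema=schema)
    for d in (_feature("a", "chr1", 100, 200), _feature("b", "chr1", 150, 250),
              _feature("c", "chr1", 300, 400)):
        ix.add_document(d)
    ix.commit()
    return ix


class TestOverlap:
    def test_all_three_overlap(self, small_index):
        hits = features_in_region(small_index, Region("chr1", 160, 310))
        assert [h.doc_id for h in hits] == ["a", "b", "c"]

    def test_gap_region_matches_only_spanning_feature(self, small_index):
        hits = features_in_region(small_index, Region("chr1", 201, 299))
        assert [h.doc_id for h in hits] == ["b"]

    def test_type_filter(self, small_index):
        hits = features_in_region(small_index, Region("chr1", 1, 500),
                                  type_filter="gene")
        assert len(hits) == 3
        assert features_in_region(small_index, Region("chr1", 1, 500),
                                  type_filter="cds") == []

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            Region("chr1", 10, 5)
        with pytest.raises(ValueError):
            Region("chr1", 0, 5)

    def test_oracle_100_random_regions(self, gff_index, gff_docs):
        feats = [d for d in gff_docs if d.content_type == "biosequence/gff"]
        rng = random.Random(9)
        for _ in range(100):
            sid = f"chr{rng.randint(1, 5)}"
            a = rng.randint(1, 9500)
            b = rng.randint(a, min(10000, a + rng.randint(1, 4000)))
            got = [h.doc_id for h in
                   features_in_region(gff_index, Region(sid, a, b))]
            expected = sorted(
                (d for d in feats
                 if d.fields["seqid"] == [sid]
                 and d.fields["start"][0] <= b and d.fields["end"][0] >= a),
                key=lambda d: (d.fields["start"][0], d.fields["end"][0], d.doc_id))
            assert got == [d.doc_id for d in expected], (sid, a, b)


class TestSequence:
    @pytest.fixture()
    def store(self):
        s = ChunkStore()
        s.put("chr1", b"ACGTACGTAC")
        return s

    def test_coordinate_conversion(self, store):
        assert sequence_of_region(store, Region("chr1", 3, 6)) == "GTAC"

    def test_whole_sequence(self, store):
        assert sequence_of_region(store, Region("chr1", 1, 10)) == "ACGTACGTAC"

    def test_end_past_length_is_range_error(self, store):
        with pytest.raises(SubrangeError):
            sequence_of_region(store, Region("chr1", 1, 11))

    def test_unknown_seqid(self, store):
        with pytest.raises(UnknownKeyError):
            sequence_of_region(store, Region("chrX", 1, 5))

    def test_substring_of_payload_with_exact_length(self, gff_bank, gff_index):
        store = ChunkStore()
        refs = {t.doc_id: t.payload for t in gff_bank.records
                if t.content_type == "biosequence/fasta"}
        for sid, seq in refs.items():
            store.put(sid, seq.encode())
        rng = random.Random(4)
        for _ in range(50):
            sid = rng.choice(sorted(refs))
            a = rng.randint(1, 9000)
            b = rng.randint(a, 10000)
            seq = sequence_of_region(store, Region(sid, a, b))
            assert seq == refs[sid][a - 1:b]
            assert len(seq) == b - a + 1


class TestExport:
    def test_single_feature_two_lines(self, small_index):
        hits = features_in_region(small_index, Region("chr1", 100, 120))
        text = export_region_gff(hits)
        lines = text.strip().split("\n")
        assert lines[0] == "##gff-version 3" and len(lines) == 2
        assert lines[1].split("\t")[2] == "gene"

    def test_empty_feature_list_pragma_only(self):
        assert export_region_gff([]) == "##gff-version 3\n"

    def test_round_trip_through_parser(self, gff_index):
        hits = features_in_region(gff_index, Region("chr2", 1, 10000))
        assert len(hits) > 50
        text = export_region_gff(hits)
        reparsed = list(parse_gff3(io.BytesIO(text.encode()), "export.gff"))
        assert len(reparsed) == len(hits)
        for rec, hit in zip(reparsed, hits):
            assert rec.document.fields == hit.fields

    def test_missing_mandatory_field_names_doc(self):
        bad = Document(doc_id="broken", content_type="biosequence/gff",
                       fields={"seqid": ["c"], "type": ["gene"]})
        with pytest.raises(Exception) as exc:
            export_region_gff([bad])
        assert "broken" in str(exc.value)
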