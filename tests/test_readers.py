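"""Bank readers: mapping rules, byte-accurate provenance, plugins, recoding.

Biopython serves as an independent cross-check on FASTA/GenBank content
(ids, sequences, feature counts); the ground-truth comparisons live in
test_synth.py and the acceptance suite.
"""

import io

import pytest
from Bio import SeqIO

from seqindex.errors import MalformedInputError, PluginError, TruncatedRecordError
from seqindex.ingest import fetch_original
from seqindex.model import SourceLocation, make_document
from seqindex.readers import (
    FormatPlugin,
    ParsedRecord,
    RecoderRule,
    apply_recoders,
    default_reader_registry,
    parse_embl,
    parse_fasta,
    parse_genbank,
    parse_gff3,
    parse_pdb,
)


def _parse(fn, text, path="x", **kw):
    return list(fn(io.BytesIO(text.encode()), path, **kw))


class TestFasta:
    def test_field_mapping(self):
        recs = _parse(parse_fasta, ">s1 my desc\nACGT\nAC\n")
        doc = recs[0].document
        assert doc.fields == {"id": ["s1"], "description": ["my desc"],
                              "length": [6]}
        assert recs[0].payload == b"ACGTAC"
        assert doc.content_type == "biosequence/fasta"

    def test_second_record_offset_matches_byte_scan(self):
        text = ">s1 a\nACGT\n>s2 b\nGG\n"
        recs = _parse(parse_fasta, text)
        assert recs[1].document.source.offset == text.encode().index(b">s2")

    def test_empty_sequence_record(self):
        recs = _parse(parse_fasta, ">s1\n\n>s2\nA\n")
        assert recs[0].document.fields["length"] == [0]
        assert recs[1].document.fields["length"] == [1]

    def test_sequence_before_header_is_malformed(self):
        with pytest.raises(MalformedInputError):
            _parse(parse_fasta, "ACGT\n>s1\nAC\n")

    def test_empty_stream_empty_iterator(self):
        assert _parse(parse_fasta, "") == []

    def test_agrees_with_biopython(self, fasta_bank):
        ours = {}
        with open(fasta_bank.path, "rb") as fh:
            for rec in parse_fasta(fh, fasta_bank.path):
                ours[rec.document.doc_id] = rec.payload.decode()
        theirs = {r.id: str(r.seq) for r in SeqIO.parse(fasta_bank.path, "fasta")}
        assert ours == theirs


class TestGff3:
    def test_feature_line_mapping(self):
        recs = _parse(parse_gff3,
                      "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;Name=abc\n")
        f = recs[0].document.fields
        assert f["seqid"] == ["chr1"] and f["type"] == ["gene"]
        assert f["start"] == [100] and f["end"] == [200]
        assert f["strand"] == ["+"] and f["ID"] == ["g1"] and f["Name"] == ["abc"]
        assert "score" not in f and "phase" not in f

    def test_pragmas_and_comments_skipped(self):
        recs = _parse(parse_gff3, "##gff-version 3\n# comment\n")
        assert recs == []

    def test_comma_values_become_multi_valued(self):
        recs = _parse(parse_gff3,
                      "c\ts\tgene\t1\t2\t.\t+\t.\tDbxref=GO:1,GO:2\n")
        assert recs[0].document.fields["Dbxref"] == ["GO:1", "GO:2"]

    def test_bad_column_count_skipped_and_reported(self):
        errs = []
        recs = _parse(parse_gff3, "c\ts\tgene\t1\t2\n"
                                  "c\ts\tgene\t1\t2\t.\t+\t.\tID=ok\n",
                      on_error=lambda off, msg: errs.append(off))
        assert len(recs) == 1 and errs == [0]

    def test_embedded_fasta_payloads_keyed_by_seqid(self):
        recs = _parse(parse_gff3,
                      "c1\ts\tgene\t1\t2\t.\t+\t.\tID=g\n##FASTA\n>c1\nACGT\n")
        assert recs[1].payload == b"ACGT" and recs[1].payload_id == "c1"


class TestGenBank:
    MINIMAL = (
        "LOCUS       X                4 bp    DNA     linear   SYN 01-JAN-2000\n"
        "ACCESSION   X1\n"
        "ORIGIN\n"
        "        1 acgt\n"
        "//\n"
    )

    def test_minimal_record(self):
        recs = _parse(parse_genbank, self.MINIMAL)
        doc = recs[0].document
        assert doc.fields["locus"] == ["X"] and doc.fields["accession"] == ["X1"]
        assert doc.fields["length"] == [4]
        assert recs[0].payload == b"ACGT"  # uppercased, digits stripped

    FEATURED = (
        "LOCUS       X                100 bp    DNA     linear   SYN 01-JAN-2000\n"
        "ACCESSION   X1\n"
        "FEATURES             Location/Qualifiers\n"
        "     gene            10..50\n"
        "                     /gene=\"abc\"\n"
        "     gene            complement(60..90)\n"
        "ORIGIN\n"
        "//\n"
    )

    def test_feature_explosion_and_strand(self):
        recs = _parse(parse_genbank, self.FEATURED)
        feats = [r.document for r in recs[1:]]
        assert feats[0].fields["start"] == [10] and feats[0].fields["end"] == [50]
        assert feats[0].fields["strand"] == ["+"]
        assert feats[0].fields["gene"] == ["abc"]
        assert feats[1].fields["strand"] == ["-"]
        assert all(d.content_type == "biosequence/gff" for d in feats)
        assert all(d.fields["seqid"] == ["X1"] for d in feats)

    def test_explosion_can_be_disabled(self):
        recs = _parse(parse_genbank, self.FEATURED, explode_features=False)
        assert len(recs) == 1

    def test_missing_terminator_is_truncated_record(self):
        with pytest.raises(TruncatedRecordError):
            _parse(parse_genbank, self.MINIMAL.replace("//\n", ""))

    def test_agrees_with_biopython(self, genbank_bank):
        ours = {}
        with open(genbank_bank.path, "rb") as fh:
            for rec in parse_genbank(fh, genbank_bank.path, explode_features=False):
                ours[rec.document.doc_id] = rec.payload.decode()
        theirs = {}
        feature_counts = {}
        for r in SeqIO.parse(genbank_bank.path, "genbank"):
            theirs[r.id.split(".")[0]] = str(r.seq)
            feature_counts[r.id.split(".")[0]] = len(r.features)
        assert ours == theirs
        mine = {t.doc_id.split(":")[0]: 0 for t in genbank_bank.records}
        for t in genbank_bank.records:
            if t.content_type == "biosequence/gff":
                mine[t.doc_id.split(":")[0]] += 1
        for acc, n in feature_counts.items():
            assert mine[acc] == n


class TestEmbl:
    RECORD = (
        "ID   X1; SV 1; linear; DNA; STD; SYN; 4 BP.\n"
        "AC   X1;\n"
        "DE   line one\n"
        "DE   line two\n"
        "OS   Synthetica exempli\n"
        "FT   gene            2..3\n"
        "SQ   Sequence 4 BP;\n"
        "     acgt                                                              4\n"
        "//\n"
    )

    def test_header_mapping(self):
        recs = _parse(parse_embl, self.RECORD)
        f = recs[0].document.fields
        assert f["locus"] == ["X1"] and f["length"] == [4]
        assert f["definition"] == ["line one line two"]
        assert f["organism"] == ["Synthetica exempli"]
        assert recs[0].payload == b"ACGT"

    def test_feature_document(self):
        recs = _parse(parse_embl, self.RECORD)
        f = recs[1].document.fields
        assert f["type"] == ["gene"] and f["start"] == [2] and f["end"] == [3]


class TestPdb:
    RECORD = (
        "HEADER    TRANSFERASE                             01-JAN-00   1ABC\n"
        "TITLE     SYNTHETIC STRUCTURE OF A\n"
        "TITLE    2 PROTEIN KINASE\n"
        "COMPND    MOL_ID: 1;\n"
        "COMPND   2 MOLECULE: PROTEIN KINASE;\n"
        "END\n"
    )

    def test_header_columns_and_title_join(self):
        recs = _parse(parse_pdb, self.RECORD)
        f = recs[0].document.fields
        assert f["pdb_id"] == ["1ABC"]
        assert f["classification"] == ["TRANSFERASE"]
        assert f["title"] == ["SYNTHETIC STRUCTURE OF A PROTEIN KINASE"]
        assert f["molecule"] == ["PROTEIN KINASE"]
        assert "organism" not in f  # SOURCE absent, not an error
        assert recs[0].payload == self.RECORD.encode()

    def test_missing_header_is_malformed(self):
        with pytest.raises(MalformedInputError):
            _parse(parse_pdb, "TITLE     X\nEND\n")


class TestSourceFidelity:
    """Bytes [offset, offset+length) re-parse to an equal document."""

    @pytest.mark.parametrize("bank_fixture,parser", [
        ("fasta_bank", parse_fasta),
        ("gff_bank", parse_gff3),
        ("genbank_bank", parse_genbank),
    ])
    def test_slice_reparses_equal(self, bank_fixture, parser, request):
        truth = request.getfixturevalue(bank_fixture)
        with open(truth.path, "rb") as fh:
            records = list(parser(fh, truth.path))
        for rec in records[:: max(1, len(records) // 100)]:
            doc = rec.document
            data = fetch_original(doc.source)
            again = list(parser(io.BytesIO(data), doc.source.path))
            assert any(doc.content_equal(r.document) for r in again), doc.doc_id

    def test_parser_totality_concatenation(self):
        a, b = ">s1 x\nACGT\n", ">s2 y\nGG\n"
        combined = _parse(parse_fasta, a + b)
        separate = _parse(parse_fasta, a) + _parse(parse_fasta, b)
        assert [r.document.fields for r in combined] == \
               [r.document.fields for r in separate]


class TestRecoders:
    DOC = make_document({"id": "d", "db_xref": "taxon:9606",
                         "definition": "some protein"}, "biosequence/genbank")

    def test_split(self):
        out = apply_recoders(self.DOC, [RecoderRule(
            field="db_xref", operation="split", args=(":",),
            outputs=("db_xref_db", "db_xref_id"))])
        assert out.fields["db_xref_db"] == ["taxon"]
        assert out.fields["db_xref_id"] == ["9606"]
        assert out.fields["db_xref"] == ["taxon:9606"]  # original kept

    def test_rename_preserves_values(self):
        out = apply_recoders(self.DOC, [RecoderRule(
            field="definition", operation="rename", outputs=("description",))])
        assert out.fields["description"] == ["some protein"]
        assert "definition" not in out.fields

    def test_rule_on_absent_field_is_noop(self):
        out = apply_recoders(self.DOC, [RecoderRule(
            field="nope", operation="drop")])
        assert out.fields == self.DOC.fields

    def test_split_separator_absent_passes_through(self):
        out = apply_recoders(self.DOC, [RecoderRule(
            field="definition", operation="split", args=(":",),
            outputs=("a", "b"))])
        assert "a" not in out.fields and out.fields["definition"] == ["some protein"]


class TestPlugins:
    @staticmethod
    def _twoline_reader(stream, path, registry=None):
        offset = 0
        lines = stream.read().split(b"\n")
        for i in range(0, len(lines) - 1, 2):
            rid, seq = lines[i].decode(), lines[i + 1].decode()
            length = len(lines[i]) + 1 + len(lines[i + 1])
            loc = SourceLocation(path=path, offset=offset, length=length)
            doc = make_document({"id": rid, "length": len(seq)},
                                "biosequence/fasta", loc, registry=registry)
            yield ParsedRecord(document=doc, payload=seq.encode())
            offset += length + 1

    def test_plugin_round_trip(self):
        reg = default_reader_registry()
        reg.register_plugin(FormatPlugin("twoline", self._twoline_reader,
                                         "biosequence/fasta"))
        recs = list(reg.get("twoline")(
            io.BytesIO(b"r1\nACGT\nr2\nGG\nr3\nTTT\n"), "x",
            registry=reg.content_types))
        assert [r.document.doc_id for r in recs] == ["r1", "r2", "r3"]
        assert [r.payload for r in recs] == [b"ACGT", b"GG", b"TTT"]

    def test_builtin_name_collision_rejected(self):
        reg = default_reader_registry()
        with pytest.raises(PluginError):
            reg.register_plugin(FormatPlugin("fasta", self._twoline_reader,
                                             "biosequence/fasta"))

    def test_unregistered_content_type_rejected(self):
        reg = default_reader_registry()
        with pytest.raises(PluginError):
            reg.register_plugin(FormatPlugin("x", self._twoline_reader,
                                             "biosequence/mystery"))
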