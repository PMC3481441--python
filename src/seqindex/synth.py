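"""Deterministic synthetic databank generator.

Every property suite in the package runs against banks produced here: the
writer emits the flat file and, in the same pass, a machine-readable
ground truth (expected document fields, payloads, and byte offsets once
written), so parser tests need no downloads and no hand-maintained
fixtures.  Content is format-valid but biologically meaningless: sequences
are uniform over ACGT (amino acids for proteins), intervals are random
non-degenerate spans inside declared sequence lengths.  All randomness
comes from the caller's seed; the same (format, n, seed, params) always
produces byte-identical files.

Dirty mode injects a known number of malformed lines (wrong column count)
into GFF3 output so indexer skip-reporting can be tested by construction.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field as dc_field
from typing import Optional

from .model import Value, fallback_doc_id

DNA = "ACGT"
AMINO = "ACDEFGHIKLMNPQRSTVWY"

_WORDS = ("kinase", "transporter", "ribosomal", "hypothetical", "membrane",
          "binding", "protein", "synthase", "regulator", "polymerase",
          "transferase", "receptor", "domain", "putative", "chromosome")

_ORGANISMS = ("Synthetica exempli", "Exemplum minor", "Testus modelus")


@dataclass
class TruthRecord:
    """Expected parse of one record of a generated bank."""

    doc_id: str
    content_type: str
    fields: dict[str, list[Value]]
    payload: Optional[str] = None
    payload_id: Optional[str] = None
    offset: int = 0
    length: int = 0

    def to_json(self) -> dict:
        return {
            "doc_id": self.doc_id, "content_type": self.content_type,
            "fields": self.fields, "payload": self.payload,
            "payload_id": self.payload_id,
            "offset": self.offset, "length": self.length,
        }


@dataclass
class GroundTruth:
    """Everything the generator knows about a bank it just wrote."""

    path: str
    format: str
    records: list[TruthRecord] = dc_field(default_factory=list)
    expected_skips: int = 0

    @property
    def record_count(self) -> int:
        return len(self.records)

    @property
    def residue_total(self) -> int:
        return sum(len(r.payload) for r in self.records if r.payload)

    def write_sidecar(self, path: str | None = None) -> str:
        path = path or self.path + ".truth.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "path": self.path, "format": self.format,
                "expected_skips": self.expected_skips,
                "record_count": self.record_count,
                "residue_total": self.residue_total,
                "records": [r.to_json() for r in self.records],
            }, fh, indent=1)
        return path


def _seq(rng: random.Random, length: int, alphabet: str = DNA) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def _words(rng: random.Random, k: int) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(k))


def _wrap(seq: str, width: int = 60) -> list[str]:
    return [seq[i:i + width] for i in range(0, len(seq), width)]


def generate_bank(format: str, n_records: int, seed: int, out: str,
                  params: dict | None = None) -> GroundTruth:
    """Write a synthetic bank to *out* and return its ground truth.

    ``out`` is a file path (a directory for the one-record-per-file PDB
    format).  The truth sidecar is not written automatically; call
    :meth:`GroundTruth.write_sidecar` if needed.
    """
    params = dict(params or {})
    rng = random.Random(seed)
    if format == "fasta":
        return _gen_fasta(rng, n_records, out, params)
    if format == "gff3":
        return _gen_gff3(rng, n_records, out, params)
    if format == "genbank":
        return _gen_genbank(rng, n_records, out, params)
    if format == "embl":
        return _gen_embl(rng, n_records, out, params)
    if format == "pdb":
        return _gen_pdb(rng, n_records, out, params)
    raise ValueError(f"unknown format {format!r}")


# ------------------------------------------------------------------ FASTA

def _gen_fasta(rng: random.Random, n: int, out: str, params: dict) -> GroundTruth:
    lo, hi = params.get("len_range", (50, 200))
    truth = GroundTruth(path=out, format="fasta")
    offset = 0
    with open(out, "wb") as fh:
        for i in range(n):
            rid = f"seq{i:05d}"
            desc = _words(rng, rng.randint(1, 4))
            seq = _seq(rng, rng.randint(lo, hi))
            text = f">{rid} {desc}\n" + "".join(l + "\n" for l in _wrap(seq))
            data = text.encode("ascii")
            length = len(data.rstrip(b"\n"))
            truth.records.append(TruthRecord(
                doc_id=rid, content_type="biosequence/fasta",
                fields={"id": [rid], "description": [desc],
                        "length": [len(seq)]},
                payload=seq, payload_id=rid, offset=offset, length=length,
            ))
            fh.write(data)
            offset += len(data)
    return truth


# ------------------------------------------------------------------ GFF3

_FEATURE_TYPES = ("gene", "mRNA", "exon", "CDS", "repeat_region")


def _gen_gff3(rng: random.Random, n: int, out: str, params: dict) -> GroundTruth:
    n_seqs = params.get("n_seqs", 5)
    seq_len = params.get("seq_len", 10000)
    dirty = params.get("dirty_lines", 0)
    include_fasta = params.get("include_fasta", True)
    seqids = [f"chr{i + 1}" for i in range(n_seqs)]
    truth = GroundTruth(path=out, format="gff3")

    # decide up front where the malformed lines go
    dirty_after = sorted(rng.sample(range(n), min(dirty, n))) if n else []

    lines: list[tuple[str, Optional[TruthRecord]]] = [("##gff-version 3", None)]
    for sid in seqids:
        lines.append((f"##sequence-region {sid} 1 {seq_len}", None))
    for i in range(n):
        sid = rng.choice(seqids)
        ftype = rng.choice(_FEATURE_TYPES)
        start = rng.randint(1, seq_len - 10)
        end = rng.randint(start, min(seq_len, start + rng.randint(10, 2000)))
        strand = rng.choice("+-.")
        score = round(rng.uniform(0, 1000), 1) if rng.random() < 0.5 else None
        phase = rng.randint(0, 2) if ftype == "CDS" else None
        fields: dict[str, list[Value]] = {
            "seqid": [sid], "source_tag": ["synth"], "type": [ftype],
            "start": [start], "end": [end],
        }
        attrs = [f"ID=feat{i:05d}"]
        fields["ID"] = [f"feat{i:05d}"]
        if rng.random() < 0.7:
            name = rng.choice(_WORDS) + str(rng.randint(1, 99))
            attrs.append(f"Name={name}")
            fields["Name"] = [name]
        if rng.random() < 0.3:
            xrefs = [f"GO:{rng.randint(1, 9999999):07d}"
                     for _ in range(rng.randint(1, 3))]
            attrs.append("Dbxref=" + ",".join(xrefs))
            fields["Dbxref"] = list(xrefs)
        if score is not None:
            fields["score"] = [score]
        if strand != ".":
            fields["strand"] = [strand]
        if phase is not None:
            fields["phase"] = [phase]
        cols = [sid, "synth", ftype, str(start), str(end),
                "." if score is None else str(score), strand,
                "." if phase is None else str(phase), ";".join(attrs)]
        rec = TruthRecord(doc_id="", content_type="biosequence/gff",
                          fields=fields)
        lines.append(("\t".join(cols), rec))
        if i in dirty_after:
            # malformed: only 5 columns
            lines.append(("\t".join([sid, "synth", "broken",
                                     str(start), str(end)]), None))
            truth.expected_skips += 1

    ref_seqs = {sid: _seq(rng, seq_len) for sid in seqids} if include_fasta else {}

    offset = 0
    with open(out, "wb") as fh:
        for text, rec in lines:
            data = (text + "\n").encode("ascii")
            if rec is not None:
                rec.offset = offset
                rec.length = len(text.encode("ascii"))
                rec.doc_id = fallback_doc_id(out, offset)
                truth.records.append(rec)
            fh.write(data)
            offset += len(data)
        if include_fasta:
            fh.write(b"##FASTA\n")
            offset += len(b"##FASTA\n")
            for sid in seqids:
                text = f">{sid}\n" + "".join(l + "\n" for l in _wrap(ref_seqs[sid]))
                data = text.encode("ascii")
                truth.records.append(TruthRecord(
                    doc_id=sid, content_type="biosequence/fasta",
                    fields={"id": [sid], "length": [seq_len]},
                    payload=ref_seqs[sid], payload_id=sid,
                    offset=offset, length=len(data.rstrip(b"\n")),
                ))
                fh.write(data)
                offset += len(data)
    return truth


# ---------------------------------------------------------------- GenBank

def _gen_genbank(rng: random.Random, n: int, out: str, params: dict) -> GroundTruth:
    lo, hi = params.get("len_range", (240, 1200))
    min_features = params.get("min_features", 3)
    truth = GroundTruth(path=out, format="genbank")
    offset = 0
    with open(out, "wb") as fh:
        for i in range(n):
            acc = f"SYN{i:04d}"
            locus = f"SYNL{i:04d}"
            organism = rng.choice(_ORGANISMS)
            definition = _words(rng, rng.randint(2, 5)) + "."
            seqlen = rng.randint(lo, hi)
            seq = _seq(rng, seqlen)
            n_feat = rng.randint(min_features, min_features + 3)

            lines = [
                f"LOCUS       {locus:<16} {seqlen} bp    DNA     linear   SYN 01-JAN-2000",
                f"DEFINITION  {definition}",
                f"ACCESSION   {acc}",
                f"VERSION     {acc}.1",
                "SOURCE      synthetic construct",
                f"  ORGANISM  {organism}",
                "FEATURES             Location/Qualifiers",
            ]
            feat_truth: list[TruthRecord] = []
            # feature 0 is always the full-span source feature
            specs = [("source", 1, seqlen, "+", {"organism": organism})]
            for j in range(1, n_feat):
                fs = rng.randint(1, seqlen - 10)
                fe = rng.randint(fs + 1, min(seqlen, fs + 500))
                strand = rng.choice("+-")
                quals = {"gene": f"g{i}_{j}"}
                if rng.random() < 0.4:
                    quals["note"] = _words(rng, 2)
                specs.append((rng.choice(("gene", "CDS", "misc_feature")),
                              fs, fe, strand, quals))
            for j, (key, fs, fe, strand, quals) in enumerate(specs):
                loc = f"{fs}..{fe}" if strand == "+" else f"complement({fs}..{fe})"
                lines.append("     " + key.ljust(16) + loc)
                fields: dict[str, list[Value]] = {
                    "seqid": [acc], "type": [key], "start": [fs],
                    "end": [fe], "strand": [strand],
                }
                translation = None
                for qk, qv in quals.items():
                    lines.append(" " * 21 + f'/{qk}="{qv}"')
                    fields[qk] = [qv]
                if key == "CDS":
                    translation = _seq(rng, (fe - fs + 1) // 3 or 1, AMINO)
                    qlines = _wrap(translation, 45)
                    lines.append(" " * 21 + f'/translation="{qlines[0]}' +
                                 ('"' if len(qlines) == 1 else ""))
                    for ql in qlines[1:-1]:
                        lines.append(" " * 21 + ql)
                    if len(qlines) > 1:
                        lines.append(" " * 21 + qlines[-1] + '"')
                feat_truth.append(TruthRecord(
                    doc_id=f"{acc}:f{j}", content_type="biosequence/gff",
                    fields=fields,
                    payload=translation,
                    payload_id=f"{acc}:f{j}:translation" if translation else None,
                ))
            lines.append("ORIGIN")
            for pos in range(0, seqlen, 60):
                row = seq[pos:pos + 60].lower()
                groups = " ".join(row[k:k + 10] for k in range(0, len(row), 10))
                lines.append(f"{pos + 1:>9} {groups}")
            lines.append("//")

            data = ("\n".join(lines) + "\n").encode("ascii")
            length = len(data.rstrip(b"\n"))
            truth.records.append(TruthRecord(
                doc_id=acc, content_type="biosequence/genbank",
                fields={"locus": [locus], "length": [seqlen],
                        "definition": [definition], "accession": [acc],
                        "version": [f"{acc}.1"], "organism": [organism]},
                payload=seq, payload_id=acc, offset=offset, length=length,
            ))
            for rec in feat_truth:
                rec.offset, rec.length = offset, length
                truth.records.append(rec)
            fh.write(data)
            offset += len(data)
    return truth


# ------------------------------------------------------------------ EMBL

def _gen_embl(rng: random.Random, n: int, out: str, params: dict) -> GroundTruth:
    lo, hi = params.get("len_range", (240, 1200))
    min_features = params.get("min_features", 2)
    truth = GroundTruth(path=out, format="embl")
    offset = 0
    with open(out, "wb") as fh:
        for i in range(n):
            acc = f"SYNE{i:04d}"
            organism = rng.choice(_ORGANISMS)
            de_parts = [_words(rng, 2), _words(rng, 2)]
            seqlen = rng.randint(lo, hi)
            seq = _seq(rng, seqlen)

            lines = [
                f"ID   {acc}; SV 1; linear; DNA; STD; SYN; {seqlen} BP.",
                f"AC   {acc};",
                f"DE   {de_parts[0]}",
                f"DE   {de_parts[1]}",
                f"OS   {organism}",
                "FH   Key             Location/Qualifiers",
            ]
            feat_truth: list[TruthRecord] = []
            n_feat = rng.randint(min_features, min_features + 2)
            for j in range(n_feat):
                fs = rng.randint(1, seqlen - 10)
                fe = rng.randint(fs + 1, min(seqlen, fs + 500))
                strand = rng.choice("+-")
                key = rng.choice(("gene", "CDS", "misc_feature"))
                loc = f"{fs}..{fe}" if strand == "+" else f"complement({fs}..{fe})"
                gene = f"g{i}_{j}"
                lines.append("FT   " + key.ljust(16) + loc)
                lines.append("FT" + " " * 19 + f'/gene="{gene}"')
                feat_truth.append(TruthRecord(
                    doc_id=f"{acc}:f{j}", content_type="biosequence/gff",
                    fields={"seqid": [acc], "type": [key], "start": [fs],
                            "end": [fe], "strand": [strand], "gene": [gene]},
                ))
            lines.append(f"SQ   Sequence {seqlen} BP;")
            for pos in range(0, seqlen, 60):
                row = seq[pos:pos + 60].lower()
                groups = " ".join(row[k:k + 10] for k in range(0, len(row), 10))
                lines.append("     " + groups.ljust(66) + str(min(pos + 60, seqlen)))
            lines.append("//")

            data = ("\n".join(lines) + "\n").encode("ascii")
            length = len(data.rstrip(b"\n"))
            truth.records.append(TruthRecord(
                doc_id=acc, content_type="biosequence/embl",
                fields={"locus": [acc], "length": [seqlen],
                        "definition": [" ".join(de_parts)],
                        "accession": [acc], "organism": [organism]},
                payload=seq, payload_id=acc, offset=offset, length=length,
            ))
            for rec in feat_truth:
                rec.offset, rec.length = offset, length
                truth.records.append(rec)
            fh.write(data)
            offset += len(data)
    return truth


# ------------------------------------------------------------------- PDB

def _gen_pdb(rng: random.Random, n: int, out: str, params: dict) -> GroundTruth:
    os.makedirs(out, exist_ok=True)
    truth = GroundTruth(path=out, format="pdb")
    for i in range(n):
        pdb_id = f"S{i:03d}"
        classification = rng.choice(("TRANSFERASE", "HYDROLASE", "OXIDOREDUCTASE"))
        molecule = (rng.choice(_WORDS) + " " + rng.choice(_WORDS)).upper()
        organism = rng.choice(_ORGANISMS).upper()
        title = ("SYNTHETIC STRUCTURE OF " + molecule)
        path = os.path.join(out, f"{pdb_id}.pdb")
        lines = [
            f"HEADER    {classification:<40}01-JAN-00   {pdb_id:<4}",
            f"TITLE     {title}",
            "COMPND    MOL_ID: 1;",
            f"COMPND   2 MOLECULE: {molecule};",
            "SOURCE    MOL_ID: 1;",
            f"SOURCE   2 ORGANISM_SCIENTIFIC: {organism};",
            "ATOM      1  N   MET A   1      11.104  13.207   2.100  1.00 20.00           N",
            "END",
        ]
        data = ("\n".join(lines) + "\n").encode("ascii")
        with open(path, "wb") as fh:
            fh.write(data)
        truth.records.append(TruthRecord(
            doc_id=pdb_id, content_type="biosequence/pdb",
            fields={"pdb_id": [pdb_id], "classification": [classification],
                    "deposition_date": ["01-JAN-00"], "title": [title],
                    "molecule": [molecule], "organism": [organism]},
            payload=data.decode("ascii"), payload_id=pdb_id,
            offset=0, length=len(data),
        ))
    return truth
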