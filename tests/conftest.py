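"""Session fixtures: synthetic corpora generated once, shared by all suites."""

from __future__ import annotations

import os

import pytest

from seqindex import Index, default_bank_schema
from seqindex.oracle import random_queries
from seqindex.readers import parse_fasta, parse_genbank, parse_gff3
from seqindex.synth import generate_bank


@pytest.fixture(scope="session")
def schema():
    return default_bank_schema()


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("banks")


@pytest.fixture(scope="session")
def fasta_bank(corpus_dir):
    """1,000 FASTA records, seed 42."""
    path = str(corpus_dir / "bank.fa")
    return generate_bank("fasta", 1000, 42, path)


@pytest.fixture(scope="session")
def gff_bank(corpus_dir):
    """1,000 GFF3 features (plus reference FASTA section), seed 42."""
    path = str(corpus_dir / "bank.gff")
    return generate_bank("gff3", 1000, 42, path)


@pytest.fixture(scope="session")
def genbank_bank(corpus_dir):
    """100 GenBank records with at least 3 features each, seed 42."""
    path = str(corpus_dir / "bank.gb")
    return generate_bank("genbank", 100, 42, path, {"min_features": 3})


@pytest.fixture(scope="session")
def gff_records(gff_bank):
    with open(gff_bank.path, "rb") as fh:
        return list(parse_gff3(fh, gff_bank.path))


@pytest.fixture(scope="session")
def gff_docs(gff_records):
    return [r.document for r in gff_records]


@pytest.fixture(scope="session")
def gff_index(gff_docs, schema):
    ix = Index(schema=schema)
    for doc in gff_docs:
        ix.add_document(doc)
    ix.commit()
    return ix


@pytest.fixture(scope="session")
def oracle_queries():
    """200 random queries mixing terms, ranges, fuzzy, prefix, booleans."""
    vocab = {
        "type": ["gene", "exon", "cds", "mrna", "repeat_region"],
        "Name": ["kinase1", "membrane2", "binding3", "receptor7"],
        "seqid": ["chr1", "chr2", "chr3", "chr4", "chr5"],
        "source_tag": ["synth"],
    }
    return random_queries(200, 7, vocab, {"start": (1, 10000), "end": (1, 10000)})
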