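# seqindex

Indexing and search for biological flat-file databanks.

Public sequence databanks (GenBank and EMBL divisions, UniProt, PDB,
genome-annotation releases) ship as large flat files. Answering even a
simple question — *which records mention a kinase? which features sit
between positions A and B on this chromosome? what is the sequence there?*
— normally means re-parsing gigabytes or standing up a heavyweight search
stack. `seqindex` is a self-contained platform for that job, aimed at
bioinformaticians who maintain local bank mirrors and at tool authors who
need a searchable metadata layer behind a genome browser:

- **Readers** stream FASTA, GFF3 (with embedded `##FASTA`), GenBank, EMBL
  and PDB banks into key/value documents, each carrying a byte-accurate
  source location `(path, offset, length)` so every search result links
  back to — and byte-for-byte reproduces — its original record. New
  formats plug in via a registry; fields can be recoded declaratively
  (split/rename/map/drop, e.g. `db_xref` → `db_xref_db`, `db_xref_id`).
- **An embedded inverted index** with a Lucene-style query language:
  full-text and fielded terms, phrases, inclusive ranges
  (`start:[100 TO 200]`, `*` for open bounds), fuzzy matching
  (`gene~1`, Damerau–Levenshtein), prefix (`kin*`), and
  `AND`/`OR`/`NOT` with parentheses. A schema declares fields as
  text/keyword/numeric and indexed and/or stored; undeclared fields
  default to indexed+stored text.
- **Sharding** with a single query entry point: documents route to shards
  by a stable hash of their id, and a two-phase search (global statistics
  exchange, then merge by score) makes any shard layout return exactly the
  hits, order and scores of a single merged index.
- **A chunk store** holding raw payloads (chromosome sequences, GenBank
  translations, PDB bodies) split into fixed-size chunks, with subrange
  reads that touch only the chunks overlapping the requested window.
- **A region driver** answering genome-browser queries — features
  overlapping `seqid:start-end` as GFF3, and the sequence of a region —
  plus a REST facade (`/search`, `/document/<id>`, `/storage/<key>`,
  `/region`) and a CLI.
- **A synthetic bank generator** that writes format-valid banks together
  with machine-readable ground truth, so every property suite runs
  deterministically with no downloads.

## Scoring

Matching is boolean set algebra over posting lists and numeric trees;
ranking is a deliberately simple TF-IDF without length normalization. For
a document *d* and query *q*,

```
score(d, q) = Σ_t  (1 + ln tf(t,f,d)) · (1 + ln((N + 1)/(df(t,f) + 1)))
```

summed over the positive term/phrase/prefix/fuzzy leaves *t* of *q*
matching in field *f*; `tf` is the term's frequency in that field of *d*,
`df` its document frequency, `N` the corpus size. Range and negated
clauses are filters (contribution 0); a pure-filter query scores every
match 1.0. Ties break by ascending document id, so paging is
deterministic. Under sharding, `N` and `df` are summed across shards
before scoring — this is what makes distributed results identical to a
single index.

## Worked example

Generate a 500-feature annotation bank, index it, and query it:

```
$ seqindex gen --format gff3 --n 500 --seed 42 --out bank.gff
$ seqindex index -t gff3 bank.gff --index-dir ix
{
 "files": 1,
 "emitted": 505,
 "indexed": 505,
 "skipped": 0,
 ...
 "payloads": 5
}
```

505 documents were indexed: 500 feature lines plus 5 reference sequences
from the `##FASTA` section, whose residues went to the chunk store
(`payloads: 5`). Exit code is 0 because nothing was skipped.

```
$ seqindex search "type:gene AND start:[1000 TO 2000]" --index-dir ix --rows 2
{
 "total": 5,
 "offset": 0,
 "rows": 2,
 "hits": [
  {"id": "34f7fb09d84420c8", "score": 2.7721893730339575,
   "content_type": "biosequence/gff",
   "fields": {"seqid": ["chr3"], "type": ["gene"],
              "start": [1890], "end": [2424], ...}},
  ...
 ]
}
```

Five genes start inside the range; the page shows the top two. Both hits
score `2.772` = (1 + ln 1) · (1 + ln(506/86)) — one occurrence of the
term `gene` in `type`, which 85 of the 505 documents share; the range
clause filters without scoring, so the tie is broken by document id.

```
$ seqindex region chr1:1500-1600 --index-dir ix | head -4
##gff-version 3
##sequence-region chr1 1500 1600
chr1  synth  repeat_region  804   2045  904.2  .  .  ID=feat00097;Name=domain30
chr1  synth  gene           994   1739  .      -  .  ID=feat00020;Name=hypothetical25
```

Features are returned whole whenever they overlap the 1-based inclusive
region (804–2045 overlaps 1500–1600), serialized as round-trippable GFF3.

`seqindex serve --index-dir ix` exposes the same operations over HTTP,
e.g. `GET /storage/chr1?start=1499&stop=1600` for the raw sequence bytes.

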