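# Methods

This note records the models, conventions and numerical choices behind
`seqindex`, and what its test evidence does and does not establish.

## Document model and provenance

The indexed unit is a *document*: a mapping of field names to ordered
lists of values (strings or numbers), a `biosequence/<format>` content
type, and — for anything parsed from a bank file — a *source location*
`(path, byte offset, byte length)`. Offsets are always bytes, never
characters; text is decoded as UTF-8 with a Latin-1 fallback, so offsets
stay valid for legacy banks. The fidelity contract is strict: reading the
located byte slice back and re-parsing it must yield a document with
identical fields. For GenBank/EMBL the smallest slice that re-parses
standalone is the whole record, so a record's header document and all of
its exploded feature documents share the record's span; feature documents
get ids `<accession>:f<i>` because a pure (path, offset) hash would
collide across features of one record. Records with an explicit id field
(FASTA ids, accessions, PDB ids) use it as document id; everything else
hashes (path, offset), which is stable across re-indexing runs.

Fields are multi-valued ordered lists and a query matches if any value
matches; GenBank qualifiers and GFF3 `Dbxref` attributes repeat, so
single-valued fields would silently drop data. The schema is open by
default (undeclared fields behave as indexed+stored text) because bank
formats carry unpredictable qualifier keys; the CLI's default schema
additionally declares `start`, `end`, `length`, `score`, `phase` as
numeric so ranged queries compare numbers.

## Parsing conventions

- Coordinates stay exactly as the source format states them: 1-based,
  end-inclusive. Nothing is converted at parse time.
- GenBank/EMBL feature explosion is on by default (one searchable
  document per feature-table entry, typed `biosequence/gff` so the region
  driver treats native GFF features and exploded features identically); a
  flag restores header-only indexing.
- Compound and fuzzy locations (`join(...)`, `order(...)`, `<`, `>`) are
  reduced to their outermost `min..max` span, flagged
  `location_exact: false`; region queries need a single interval, and
  clipping or segment semantics belong to a renderer.
  `complement(a..b)` sets the minus strand.
- Sequences are uppercased and stripped of digits/whitespace before
  payload storage: ORIGIN/SQ block formatting is presentation, not data.
  `/translation` qualifiers become separate payloads keyed
  `<doc id>:translation` instead of fields — they are sequence data, not
  metadata.
- Error policy is two-level because real banks are large and dirty: a
  malformed line (wrong GFF3 column count) is skipped and reported,
  counting toward the ingest report's `skipped`; a structural error (a
  record missing its `//` terminator) aborts that record with an error.

## Analyzer

Text fields are tokenized by lowercasing and splitting on any character
that is not a letter or digit, keeping `.`, `_`, `-` only inside
alphanumeric runs: accession-like tokens (`NM_000546.6`) survive whole
while prefixed identifiers (`GO:0005634`) split at the colon, which is
what makes full-text hits on cross-references work. Keyword fields skip
tokenization (whole value, lowercased). Multi-valued fields insert a
position gap of 100 between values so phrases never match across value
boundaries.

## Scoring

`score(d,q) = Σ (1 + ln tf) · (1 + ln((N+1)/(df+1)))` over the positive
term/phrase/prefix/fuzzy leaves matching in a field; ranges and negated
clauses contribute 0, and a query with no scoring leaves (pure filter)
scores every match 1.0. This is a deliberately minimal TF-IDF: no length
normalization, no boosts, no proximity — reproducing any specific search
library's internal scoring is a non-goal, whereas a formula simple enough
to verify in closed form is what makes the sharding guarantee testable.
The `+1` terms keep the idf positive and defined for `df = N`. Ties break
by ascending document id. Fuzzy leaves expand against the field
vocabulary under restricted Damerau–Levenshtein distance (adjacent
transposition counts as one edit), max 1 or 2 edits.

## Sharding

Distributed search is two-phase. Phase 1 asks every shard for its
document count and the document frequencies of the query's scoring leaves
(fuzzy/prefix expanded against that shard's vocabulary, phrases reported
as phrase-level df); the handler sums them. Phase 2 has every shard score
its own matches with the summed global statistics and return its top
`offset + limit`; the handler merges by (score desc, id asc) and slices.
Per-shard statistics would break the headline transparency property — a
term common on one shard and rare on another would score differently
depending on placement — so the exchange is mandatory, not an
optimization. An unreachable shard fails the whole query naming the
shard: partial results presented as complete would be silent data loss,
and availability belongs to replicated infrastructure, not this layer.
Routing hashes the document id (SHA-1, process-independent) modulo the
shard count, so any shard count works for any input mix; explicit
bank→shard pinning is available for deployments that group banks.

## Chunk store

Payloads are split into fixed-size chunks (default 65,536 bytes; any
per-put override ≥ 1). Subranges are 0-based, stop-exclusive, in bytes —
pure storage semantics; the single 1-based inclusive → 0-based exclusive
conversion in the code base lives in the region driver
(`get(seqid, start−1, end)`). A subrange read touches only the chunks
overlapping the window, observable through a read counter and bounded by
`ceil((stop−start)/chunk_size) + 1`. Overwrites write the new chunks
first, switch the metadata blob last, then delete stale tail chunks, so a
reader never sees a torn value. Backends implement a four-method blob
interface; file-based (reference, durable) and in-memory backends ship,
and the store logic is backend-agnostic.

## Index persistence and commit

A segment persists as a single versioned JSON file written via
temp-file-plus-rename; mutations stage in memory and apply at commit, so
a crash between add and commit leaves the previous committed state
intact. Partial update requires every field of the target document to be
stored (an indexed-but-unstored field cannot be reconstructed for
reindexing) and fails naming the offending field. The optional
query-result memo is invalidated at every commit and correctness never
depends on it. Single writer, many readers; concurrent multi-writer
support is out of scope.

## Query language

Supported: fielded and bare terms (bare = all indexed text fields),
quoted phrases, inclusive ranges with `*` open bounds (a range always
names a field), `~1`/`~2` fuzzy (bare `~` = 2), trailing-`*` prefix,
`AND`/`OR`/`NOT`, parentheses; adjacent clauses combine with AND, giving
bare queries filter-like semantics. Precedence is NOT > AND > OR.
Excluded: boosts, regexes, proximity phrases, faceting, sort-by-field.
Normalization lowercases terms, rewrites a multi-token term against a
text field to an AND of its tokens, casts range bounds on numeric fields
(error if impossible), and rewrites a pure-negative query to
`match-all AND NOT ...` so evaluation always has a positive component. A
term query against a numeric field becomes an equality range. The
canonical printer round-trips: re-parsing a printed AST reproduces it,
which is also how remote shards receive queries.

## Synthetic banks and what tests show

The generator writes format-valid FASTA/GFF3/GenBank/EMBL/PDB banks and,
in the same pass, their expected parse (fields, payloads, byte spans), so
the parsers' primary test is exact equality against ground truth. The
standard test corpus is 1,000 FASTA records (50–200 bp), 1,000 GFF3
features over five 10 kb reference sequences with an embedded `##FASTA`
section, and 100 GenBank records (240–1,200 bp, ≥ 3 features each,
60-column ORIGIN blocks with position numbers to exercise whitespace and
digit stripping) — sizes chosen so every suite runs in seconds on one
core while still exercising multi-chunk payloads, multi-valued
attributes, both strands and dirty lines. All randomness is seeded; there
are no time-based seeds.

What passing these suites shows: the mapping rules, offsets, query
semantics, scoring and sharding behave exactly as specified on clean and
mildly dirty format-valid input. What it does not show: robustness to the
full diversity of real-world bank irregularities (vendor-specific
qualifier syntax, mixed line endings inside records, CONTIG/join
reconstruction), biological realism (sequences are uniform random, no
codon or gene-model structure), or performance at deployment scale —
the design streams records and shards indexes, but desk-scale tests make
no latency claims.

## Known limitations

- No replication, leader election or load balancing; sharding is about
  correctness of merged results, not availability.
- GenBank `CONTIG`/`join` reconstruction, mmCIF, and delegation to
  external format converters are out of scope; new formats enter through
  the plugin registry.
- Phrase matching uses positions but scoring ignores proximity.
- The REST facade is unauthenticated by design (local/trusted use).
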