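# Methods

## The document model

A VDJML 1.0 document records V(D)J alignment *results*, not sequences:
reads are referenced by their FASTA/FASTQ identifier and all intervals
are coordinates on the read. The model (`vdjml.model`) mirrors the XML
element structure one-to-one. Two conventions hold everywhere:

* every `*_pos0` attribute is **0-based**, and intervals are
  `[pos0, pos0 + len)` half-open — the attribute names carry the "0"
  suffix as a reminder;
* all identifiers (`aligner_id`, `gl_db_id`, `segment_match_id`,
  `gl_seg_match_id`) are opaque string tokens. Fixtures use small
  positive integers, but nothing is assumed about their form.

`validate_document` checks every invariant the model promises —
identifier uniqueness, referential integrity (combination →
segment match, gl_seg_match → aligner/germline database), coordinate
signs, BTOP span consistency against `read_len`/`gl_len`, identity in
[0, 100], V-then-D-then-J combination order with at most one match per
type — and returns violations as data (path, rule, message) so a
consumer can report all problems at once. Validation never raises.

The element name `gl_seg_match` fixes the spelling of its identifier
attribute as `gl_seg_match_id`; the variant spelling `gl_seq_match_id`
seen in some descriptions of the format is treated as a typo and not
emitted.

`vdj:aa_substitution` is part of the format but its attributes are not
fixed by any published description; this implementation uses
`read_codon_pos0`, `germline_aa`, `read_aa` (single-letter codes, `X`
for unknown).

## BTOP engine

BLAST trace-back-operations strings are parsed with the NCBI
convention: digit runs are match counts; in a two-character column the
**first character is the read (query) base and the second the germline
(subject) base**, so `C-` is an insertion in the read and `-T` a
deletion from it. `--` is rejected, as is any dangling single letter;
errors carry the text offset. Lowercase bases are accepted and
uppercased. Parser output never contains two adjacent match runs, and
serialization merges them, so `serialize(parse(s)) == s` for canonical
text.

Percent identity uses gap-inclusive columns in the denominator:
`100 · matches / (matches + substitutions + insertions + deletions)`,
matching common BLAST reporting. For the gap-free worked example the
choice is immaterial (275/295 = 93.2 %). Identity is serialized to one
decimal place; tests compare identities with tolerance 0.05.

`stats_to_flags` sets `out_frame_indel` iff
`(insertions − deletions) mod 3 ≠ 0`, i.e. the net indel length shifts
the reading frame; balanced or codon-length indels do not.

## Streaming I/O and the schema

Reading uses `lxml.etree.iterparse`: the metadata block is parsed
eagerly on open, then each `vdj:read` subtree is converted and freed
before the next is built, so memory is bounded by one record. A file
truncated after its first `</vdj:read>` still yields that read (the
error surfaces on the *next* pull). Writing is symmetric: metadata is
serialized on writer creation, reads are appended one at a time, and
each read is validated against the model rules before serialization, so
writer output is schema-valid by construction.

Compression is transparent: on read the codec comes from magic bytes
(`1f 8b` gzip, `BZh` bzip2) with the file extension as fallback; on
write the sink extension (`.gz`/`.bz2`) decides.

The shipped `vdjml-1.0.xsd` was authored for this package from the
format's structural description; where cardinalities are not fixed by
that description they are permissive (`0..*` children, attributes
optional unless required by the format — `aligner`'s `version` is
modeled optional since only `aligner_id` and `name` are stated as
required). XSD validation uses `lxml.etree.XMLSchema` (XSD 1.0);
referential rules that XSD 1.0 cannot express with non-NCName tokens
(identifier uniqueness, cross-references) are enforced at the model
level by `validate_document`, and `validate_file` reports both layers.

Foreign-namespace elements under `vdj:meta` and `vdj:read_results` are
preserved as opaque serialized payload and re-emitted on write
(round-trip fidelity), normalized only by dropping inherited namespace
declarations and surrounding whitespace. Unknown elements *in* the vdj
namespace (from hypothetical future minor versions) trigger a warning
and are preserved the same way rather than failing. Attribute order on
output is fixed (required attributes first) so files diff cleanly.
Multiple `vdj:combination` elements per alignment are structurally
permitted; the converter emits exactly one.

## IgBLAST conversion

The supported input dialect is IgBLAST's comment-delimited tabular
output whose hit table includes a BTOP column (`-outfmt '7 std btop'`);
the pretty-printed pairwise-alignment view carries the same information
but is not machine-parsed. Column and summary-field names are taken
from the `# Fields:` and parenthesized header lists, so minor dialect
variations (e.g. a light chain's missing "Top D gene match") parse
correctly. `Total` and `N/A` alignment-summary rows are skipped.

Conversion rules, in order:

1. **Grouping.** Hits with identical `(segment type, q_start, q_end,
   BTOP, bit score)` collapse into one segment match; the bit score is
   part of the key so coincidentally co-located alignments with
   different scores stay separate. Germline start positions may differ
   per `gl_seg_match`. Matches are ordered all V (descending score,
   stable), then D, then J, and numbered from 1. Grouped hits must
   agree on alignment length.
2. **Selection.** The combination takes the first (= highest-scoring,
   first-listed on ties) match of each type present; types without a
   match are omitted (light chains and TCRA have no D). Lower-scoring
   alternative combinations are not emitted.
3. **Statistics.** `identity`, `substitutions`, `insertions`,
   `deletions` and `out_frame_indel` on each segment match are
   recomputed from the BTOP by the engine above; `score` holds the bit
   score. E-values are not stored — VDJML 1.0 has no attribute for
   them.
4. **Regions.** Each alignment-summary row becomes a region
   (1-based inclusive `from`/`to` → 0-based `read_pos0`/`read_len`),
   names passed through verbatim apart from whitespace trimming; CDR3
   is emitted only if the aligner reports it. Junction regions are
   computed from the combination's segment matches: VD and DJ when a D
   match exists, VJ otherwise. Zero length marks abutting segments;
   if adjacent matches overlap on the read the junction is omitted
   rather than given a negative length.
5. **Read-level flags.** The rearrangement summary's stop-codon, V-J
   frame and strand fields map to `stop_codon`, `out_frame_vdj` and
   `inverted`. VDJML 1.0 attaches annotation flags only to segment
   matches and regions, so these ride on the combination's first (V)
   segment match — a documented convention of this converter. Absent
   summary fields leave flags unset, and `mutated_invariant` is never
   set (it is not derivable from IgBLAST tabular output alone).

Minus-strand hits set `inverted` and are otherwise stored as reported
by IgBLAST (coordinates on the oriented read, BTOP as printed).

## Fixtures

`make_canonical_fixture` renders the worked-example read: 9 hit rows
that group into 7 segment matches with combination `[1, 3, 5]`. The V
alignment spans read interval [123, 418) against germline position 0
over 295 gap-free columns, with a substitution at every alignment
offset `o` satisfying `(o + 1) mod 14 == 0` and `o ≤ 279`. The rule
makes the headline numbers *derived* quantities: enumerating it gives
20 substitutions and 275/295 = 93.2 % identity, and the per-region
mismatch counts in the alignment summary are counted from the same
offsets. Scores and e-values are synthetic and only order hits
(best first); germline nucleotide sequences are never materialized
because the format stores coordinates and BTOPs, not bases.

`make_random_fixture(seed, n_reads)` simulates each alignment column by
column (`random.Random(seed)`; defaults: 5 % substitutions, 1 %
insertions, 1 % deletions per column, V matches of 150–300 nt, D of
8–20 nt, J of 30–50 nt, junction gaps of 0–8 nt, 10 % of reads with no
hits, 20 % without a D, 15 % on the minus strand) and emits both the
tabular text and the ground-truth document from the same bookkeeping,
so converter recovery can be asserted element for element. Emitted
rows are self-consistent by construction: BTOP spans equal the printed
read and germline intervals and printed identity equals the
BTOP-derived identity.

The generator emulates IgBLAST's *output dialect*, not repertoire
biology: there is no somatic-hypermutation model, no junction
chemistry, no germline-database realism, and reads are independent.
Passing tests therefore demonstrate correct parsing, grouping,
selection, annotation arithmetic and serialization under realistic
file shapes — not biological accuracy of any aligner.

## Numerical and degenerate-input choices

* Identity: one decimal place in attributes; equality in tests at
  0.05.
* Scores: serialized with `%g`; parsed as floats.
* Ties in combination selection: first listed wins, deterministically.
* Empty IgBLAST input → a valid document with zero reads; a query
  block with zero hits → a read with no alignments.
* Zero-length regions are legal (abutting segments); negative-length
  junctions are never emitted.
* Random-fixture BTOPs never begin with a read deletion (a leading
  germline-only column), which local aligners do not produce.

## Problem sizes in the test suite

The default suite exercises 1,000 random alignments for the BTOP
oracle, 50 random documents across the three codecs for round-trip and
schema checks, and a 25-read fixture (seed 17) for ground-truth
recovery; the whole suite runs in a few seconds.

## Known limitations

* Only IgBLAST tabular output is converted; IMGT/High V-QUEST output
  is not supported.
* Only schema version 1.0; no random access or indexing into
  documents.
* No CIGAR/MD interconversion and no protein BTOPs.
* Clonal assignment, genotype correction and probabilistic annotations
  are outside the format's 1.0 scope and therefore this package's.
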