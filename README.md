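# vdjml

Tools for **VDJML 1.0**, an XML interchange format for the results of
aligning immune-receptor sequencing reads (BCR/TCR repertoires) to
germline V, D and J gene segments.

Adaptive immune receptors are assembled by V(D)J recombination and then
diversified by somatic hypermutation, so the first step of every
repertoire-sequencing analysis is aligning each read to germline
gene-segment databases (with tools such as IgBLAST) and annotating the
result: which segments matched, where, with how many mutations, and
which framework (FR) and complementarity-determining (CDR) regions cover
which read positions. Every aligner prints this differently. VDJML is a
common, validatable representation of exactly that information, so
downstream tools can consume one format and alignments can be shared
without redistributing raw reads — reads are referenced by their
FASTA/FASTQ identifier only.

This package is for developers and analysts in immune-repertoire
sequencing who need to produce, validate, stream, or convert such
alignment files.

## The representation

A document is `vdj:meta` (generator, aligners, germline databases —
enough provenance to recreate the file from the original reads) followed
by a stream of `vdj:read` elements. Within a read:

* **`vdj:segment_match`** — a read interval `[read_pos0, read_pos0 +
  read_len)` (0-based, half-open) aligned to `gl_len` germline
  positions. When several germline segments align *identically* they
  share one segment match, one `vdj:gl_seg_match` child each. The
  `vdj:btop` child stores the BLAST trace-back-operations string, a
  run-length alignment encoding (digits = match runs, letter pairs =
  read/germline columns, `-` marking the gapped side), from which the
  full gapped alignment and the mutation statistics are reconstructed:

  `identity = 100 · matches / (matches + substitutions + insertions + deletions)`

* **`vdj:combination`** — the inferred rearrangement: the
  highest-scoring segment match of each type present, first listed on
  ties, in V, D, J order, plus `vdj:region` annotations (FR1–FR3,
  CDR1–CDR2, and the VD/DJ — or VJ — junction intervals).

The package provides the validated in-memory model (`vdjml.model`), the
BTOP engine (`vdjml.btop`), streaming gzip/bzip2-transparent XML I/O
with a shipped XSD (`vdjml.io`), an IgBLAST tabular-output converter
(`vdjml.igblast`), deterministic fixture generators with ground truth
(`vdjml.fixtures`), and a `vdjml` command-line tool.

## Worked example

The canonical fixture emulates an IGH read whose V region aligns
identically to IGHV3-23\*01 and IGHV3-23D\*01, has two placements of
IGHD2-21\*01 (one shared identically by IGHD2-21\*02), a best J hit to
IGHJ4\*02, and lower-scoring alternatives — nine hit rows in all:

```sh
vdjml fixture --preset fig3 -o fig3.tsv
vdjml convert fig3.tsv \
    --aligner-name IgBLAST --aligner-version 1.4.0 \
    --db-name synthetic_gl --db-version 1 --db-species "Homo sapiens" \
    -o out.vdjml.gz
vdjml validate out.vdjml.gz
vdjml stats out.vdjml.gz
```

prints

```
valid
reads	1
segment_matches	7
gene_usage	IGHD2-21*01	1
gene_usage	IGHJ4*02	1
gene_usage	IGHV3-23*01	1
regions	CDR1,CDR2,DJ_junction,FR1,FR2,FR3,VD_junction
```

The nine hits collapse into **7 segment matches** (identical alignments
share a match); the combination selects matches 1, 3 and 5 — the top V,
D and J. The first segment match covers 295 read positions starting at
position 123; its BTOP encodes 20 substitutions, giving 93.2 % identity
(275/295), and those numbers are recomputed from the BTOP during
conversion, not copied from the aligner's printed columns.

In code:

```python
from vdjml import read_document

doc = read_document("out.vdjml.gz")
first = doc.reads[0].alignments[0].segment_matches[0]
print(first.read_pos0, first.read_len, first.identity,
      first.annotations.substitutions)
# 123 295 93.2 20
```

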