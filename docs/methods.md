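# Methods

## The mapping model

A protein-coding transcript is modelled as an ordered list of coding
segments in *transcription order*: ascending genomic coordinates on the
`+` strand, descending on `-`.  Concatenating the segment sequences
(reverse-complementing each on `-`) yields the spliced coding sequence
(CDS); translating it with a 64-codon table yields the protein.  All
coordinates are 1-based inclusive, the GTF/Ensembl convention; BED input
(0-based half-open) is converted on ingest.

Mapping reduces to arithmetic in *CDS space*.  Index the spliced CDS
`0 … L-1` in transcription order and let `off` be the leading phase (bases
skipped at the 5' end, nonzero only for 5'-incomplete annotations).  Amino
acid `p` (1-based) occupies CDS indices `off + 3(p-1) … off + 3p - 1`.
Because coding segments are disjoint and ordered along the chromosome, a
contiguous genomic interval always covers a contiguous CDS interval; the
mapper therefore only intersects interval boundaries, never materialises
per-base tables.  The reverse direction walks the cumulative segment
lengths and splits a CDS interval into genomic pieces at exon junctions.

The test suite and the acceptance script validate this arithmetic against a
deliberately naive oracle that *does* materialise every CDS base position
per transcript and answers queries by set membership; the two must agree
exactly on randomized gene models with 1–5 exons on both strands.

### Boundary codons

A genomic query rarely starts and ends on codon boundaries.  Two policies
are exposed:

* **trim** (default): only codons wholly inside the query are reported.
  Nothing outside the query is ever fabricated.
* **extend**: the query is widened outward to the nearest codon boundaries
  of the transcript under consideration, so boundary codons are complete.
  This mirrors the common situation where a motif match is extended by the
  one or two nucleotides that belong to the same translation frame.

In both modes `frame_note` records which boundaries were not codon-aligned
(`exact`, `trimmed_upstream`, `trimmed_downstream`, `trimmed_both`): in
trim mode partial codons were dropped there, in extend mode the boundary
was widened there.  A query that intersects coding sequence but contains no
complete codon yields a hit row with empty sequences and
`frame_note=trimmed_both` rather than no row, so the overlap is not
silently lost.

### Conventions and degenerate inputs

* Stop codons are expected *outside* the CDS features (Ensembl dialect).
  If a terminal stop is nevertheless annotated in-CDS it is trimmed from
  the protein (the coding DNA keeps it), so `3·len(protein)` is
  `len(CDS) - off` or `len(CDS) - off - 3`.
* An in-frame stop *before* the last codon is kept in place as `*` and the
  transcript is flagged `internal_stop`.
* A spliced length (minus `off`) that is not a multiple of 3 drops the
  trailing partial codon and flags `incomplete_cds`.
* The first segment's annotated frame is trusted (Ensembl encodes
  5'-incompleteness there); later frames are recomputed from cumulative
  lengths as `phase_k = (3 - Σ_{j<k} len_j mod 3) mod 3`, and any
  disagreement with the file flags the transcript.
* Codons containing N or any other ambiguity code translate to `X`;
  ambiguity codes are otherwise preserved verbatim.
* Chromosome names are compared after stripping an optional leading `chr`
  and case-folding, so `chr1`/`1`/`CHR1` interoperate.
* Gzip is detected from magic bytes, never the file extension (output
  paths ending `.gz` are written compressed).
* Per-row batch errors (unknown ID, out-of-range span, unknown chromosome)
  surface in the output's `error` column; only malformed files are fatal.
* A genomic query overlapping several transcripts yields one row per
  transcript (lossless; per-gene summaries can be derived downstream).
  Output preserves input order, then transcript ID lexicographically.
  `strand_hint` on genomic queries orients plain-DNA retrieval only; it
  never filters transcripts.
* Protein-region IDs resolve against protein IDs first, then transcript
  IDs; the two namespaces cannot collide within one index by construction.

### Index file

One tab-delimited row per transcript (gene/transcript/protein IDs, gene
name, chromosome, strand, comma-joined segment starts/ends/phases, spliced
CDS, protein, flags) under a provenance header naming the genome and
annotation files and the package version.  The header deliberately carries
no timestamp so identical builds are byte-identical.  The format is this
package's own; no byte compatibility with any other tool's cache is
claimed.  On re-reading, segment-list lengths and the CDS length are
re-validated per row.

## Positional codon usage

Given mapped hits for a family of same-length coding regions, the analysis
asks at each aligned position: of the codons synonymous for the amino acid
observed there, which are actually used?  "Re-scaling" restricts a codon
frequency vector to the synonymous set of the focal amino acid and
renormalises it to 100%.  Applied to the observed counts this gives the
observed row; applied to a genome-wide codon-usage reference (an input
file, `CODON<TAB>frequency`, any relative scale) it gives the expected row.
The focal amino acid at a position is the modal one across hits; hits
showing a different amino acid there are excluded from the re-scaling and
reported as a separate count.  Ties on the mode break towards the
alphabetically first amino acid.

Percentages are kept at full precision in memory — each row then sums to
exactly 100 — and rounded to one decimal place only in the written report.
The package ships the published human genome-wide codon-usage reference
(frequencies per 1000 codons) as a convenience input; the species-specific
reference is always an input, never a constant baked into the computation.

## Synthetic fixtures

The generator works backwards from known answers: it draws a random coding
sequence (ATG first, no internal stops), splits it into 1–5 exon pieces,
places the pieces on a chromosome with random intron gaps — on the `-`
strand the pieces are laid down in reverse genomic order and each is
reverse-complemented — appends a stop codon outside the CDS, computes GTF
frames from cumulative lengths, and embeds everything in uniform-random
intergenic sequence.  A truth table records each transcript's coding DNA
and protein, so every pipeline stage is checked against construction rather
than against another parser.  Intergenic sequence is plain uniform ACGT:
the index builder is annotation-driven and never scans for open reading
frames, so accidental ORFs cannot perturb the ground truth.

Defaults (3 genes, 1–5 exons of 9–60 bp, introns of 20–120 bp, half the
genes on `-`) keep each genome in the low kilobases; all randomness flows
from one seed, and identical seeds give byte-identical files.

What the fixtures do *not* emulate: realistic codon usage or GC content,
overlapping or multi-isoform genes, UTRs, trans-splicing, and
chromosome-scale sequence.  Passing tests therefore demonstrate coordinate
and splicing correctness, not robustness to every annotation pathology in
the wild; the flags and per-row error paths are exercised by dedicated
hand-built degenerate cases instead.

## Problem sizes

The oracle-equivalence check runs ~1080 random queries across 20 seeded
genomes (60 transcripts); round trips use 225 spans over 9 transcripts;
codon-usage checks tally 44 synthetic three-codon hits, the family size of
a typical motif-match region set.  The whole suite and the acceptance
script each complete in a few seconds on one CPU.

## Known limitations

* The genome is held in memory as plain strings; a mammalian genome needs
  roughly its FASTA size in RAM.  Fine for the intended batch use, not for
  memory-constrained servers.
* Only GTF (Ensembl dialect) is parsed; GFF3 is out of scope.
* Mapping is annotation-exact: no similarity search, and no variant-aware
  translation (a VCF cannot be applied before translating).
* Circular chromosomes and fusion/trans-spliced transcripts are not
  modelled.
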