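# cdsmap

Exact batch mapping between genomic regions and protein regions.

Many genome-wide experiments — ChIP-seq peak calling, variant discovery —
end with a list of genomic coordinates, and the next question is often:
*which amino acids do these regions encode?*  The converse arises just as
often: given a span of a protein (a domain, a modified residue, a motif
match), *which genomic bases code for it?*  Answering either question one
region at a time through a genome browser is laborious and error-prone once
more than a handful of regions are involved.

`cdsmap` answers both questions in batch, exactly (no similarity search),
for any genome for which a FASTA sequence file and an Ensembl-dialect GTF
annotation are available.  It first builds a **coding-sequence index**: for
every protein-coding transcript, the CDS segments are collected in
transcription order (ascending coordinates on the `+` strand, descending on
`-`), spliced out of the genome (reverse-complementing on `-`), and
translated with a user-supplied genetic-code table.  The index is plain
tab-delimited text, built once and reused by all mapping tasks.

Four batch tasks then run against the index or the genome:

| task | input | output |
|---|---|---|
| `g2p` | genomic intervals | amino acids + coding DNA inside each interval |
| `g2dna` | genomic intervals | plain DNA sequence of each interval |
| `p2g` | protein spans | genomic base intervals coding them (split at exon junctions) |
| `p2p` | protein spans | the amino-acid sequences themselves |

The coordinate arithmetic works in *CDS space*: with leading phase offset
`off`, amino acid `p` of a transcript occupies spliced-CDS indices
`off + 3(p-1) … off + 3p - 1`, and a contiguous genomic interval always
covers a contiguous CDS interval, so segment-boundary interval arithmetic
suffices.  Partial codons at query boundaries are either dropped
(`--frame-mode trim`, the default) or completed by widening the query
outward to the transcript's codon boundaries (`--frame-mode extend`).

A companion analysis tallies **positional codon usage** across a set of
equal-length coding regions: at each aligned amino-acid position, the
observed share of each synonymous codon (re-scaled so the row sums to 100%)
is compared with the re-scaled genome-wide expectation — useful for asking
whether DNA-level conservation at a position exceeds what the conserved
amino acid alone would predict.

## Worked example

A 44 bp toy chromosome `chrT` carries a two-exon gene: CDS segments 11–19
(`ATGGCCCGT`) and 31–36 (`GAAAAG`), so the spliced CDS is
`ATGGCCCGTGAAAAG` and the protein is `MAREK`.

```sh
python -c "from cdsmap import tiny_example; tiny_example('.')"
cdsmap build-index --genome tiny_example.fa --gtf tiny_example.gtf --output index.tsv
printf 'chrT\t11\t19\tq1\nchrT\t14\t22\tq2\n' > regions.txt
cdsmap g2p --index index.tsv --input regions.txt --output hits.tsv
```

`hits.tsv` (columns abridged):

```
query          segments      coding_dna  protein_seq  aa_start  aa_end  frame_note
chrT:11-19 q1  11-19         ATGGCCCGT   MAR          1         3       exact
chrT:14-22 q2  14-19         GCCCGT      AR           2         3       exact
```

Query `q1` covers the first exon exactly: nine bases, three codons, amino
acids 1–3 (`MAR`).  Query `q2` starts mid-exon and runs 3 bp into the
intron; the intronic bases are excluded and only the two codons wholly
inside the region remain (`AR`, amino acids 2–3).  Mapping the other way:

```sh
printf 'P1\t2\t4\tmotif\n' > prot.txt
cdsmap p2g --index index.tsv --input prot.txt --output p2g.tsv
```

```
query         segment_starts  segment_ends  coding_dna  protein_seq  aa_start  aa_end
P1:2-4 motif  14,31           19,33         GCCCGTGAA   ARE          2         4
```

Amino acids 2–4 (`ARE`) map to two genomic pieces, 14–19 and 31–33 — nine
bases in total, with codon 4 (E) split across the exon junction.

Batch rows that cannot be resolved (unknown ID, span past the protein end,
region off the chromosome) appear in the output with the `error` column set;
the batch always completes.

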