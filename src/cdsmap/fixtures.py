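"""Synthetic genomes and matching annotations with known ground truth.

The generator writes a small FASTA genome and an Ensembl-dialect GTF whose
protein-coding transcripts were constructed backwards from a known protein:
the coding DNA is laid down first, split into exons, placed on either strand
(reverse-complemented segment by segment on '-'), and surrounded with random
intergenic and intronic sequence.  A truth table records every transcript's
spliced coding DNA and protein, so any reader/indexer/mapper result can be
checked against construction rather than against another parser.

Stop codons follow the Ensembl convention: annotated as ``stop_codon``
features immediately 3' of the CDS, never inside the CDS rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import CdsmapError
from .mapping import reverse_complement, translate
from .reference_io import standard_genetic_code

__all__ = ["FixtureSpec", "FixtureFiles", "make_fixture", "tiny_example"]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic genome; ``seed`` fixes all randomness."""

    n_chroms: int = 1
    n_genes: int = 3
    exons_per_gene: tuple[int, int] = (1, 5)
    exon_length: tuple[int, int] = (9, 60)
    intron_length: tuple[int, int] = (20, 120)
    strand_minus_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name, rng in [
            ("exons_per_gene", self.exons_per_gene),
            ("exon_length", self.exon_length),
            ("intron_length", self.intron_length),
        ]:
            if rng[0] < 1 or rng[0] > rng[1]:
                raise CdsmapError(f"invalid {name} range {rng}")
        if self.exon_length[0] < 3:
            raise CdsmapError(
                "exon_length minimum below 3 cannot host a start codon in the "
                "first exon"
            )
        if self.exons_per_gene[0] * self.exon_length[1] < 6:
            raise CdsmapError("exon structure too small to host start and stop codons")
        if not 0.0 <= self.strand_minus_fraction <= 1.0:
            raise CdsmapError("strand_minus_fraction must lie in [0, 1]")


class FixtureFiles(NamedTuple):
    fasta: str
    gtf: str
    truth: str


def _random_coding_dna(rng: np.random.Generator, n_codons: int) -> str:
    """ATG followed by random non-stop codons."""
    code = standard_genetic_code()
    sense = [c for c, aa in code.items() if aa != code.stop_symbol and c != "ATG"]
    picks = rng.integers(0, len(sense), size=n_codons - 1)
    return "ATG" + "".join(sense[i] for i in picks)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _gtf_attrs(gene: str, tx: str, prot: str, name: str) -> str:
    return (
        f'gene_id "{gene}"; transcript_id "{tx}"; protein_id "{prot}"; '
        f'gene_name "{name}";'
    )


def make_fixture(spec: FixtureSpec, directory: str | os.PathLike) -> FixtureFiles:
    """Write genome FASTA, GTF and truth table for ``spec`` into ``directory``.

    The truth table is tab-delimited with columns transcript_id, gene_id,
    protein_id, chrom, strand, segment_starts, segment_ends, coding_dna,
    protein.  Identical specs (same seed) produce identical files.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)

    chrom_parts: dict[str, list[str]] = {f"chrF{i+1}": [] for i in range(spec.n_chroms)}
    chrom_cursor: dict[str, int] = {c: 0 for c in chrom_parts}
    gtf_lines: list[str] = []
    truth_rows: list[dict] = []

    def emit(chrom: str, seq: str) -> tuple[int, int]:
        """Append ``seq`` to the chromosome, returning its 1-based span."""
        start = chrom_cursor[chrom] + 1
        chrom_parts[chrom].append(seq)
        chrom_cursor[chrom] += len(seq)
        return start, chrom_cursor[chrom]

    for g in range(spec.n_genes):
        chrom = f"chrF{rng.integers(0, spec.n_chroms) + 1}"
        strand = "-" if rng.random() < spec.strand_minus_fraction else "+"
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        lengths = [
            int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
            for _ in range(n_exons)
        ]
        total = sum(lengths)
        lengths[-1] += (3 - total % 3) % 3  # make the CDS a whole number of codons
        total = sum(lengths)
        if total < 6:
            lengths[-1] += 3
            total += 3
        coding = _random_coding_dna(rng, total // 3)
        stop = _STOPS[int(rng.integers(0, len(_STOPS)))]

        # split the coding DNA into transcription-order pieces
        pieces, at = [], 0
        for ln in lengths:
            pieces.append(coding[at : at + ln])
            at += ln
        # genomic order: left-to-right along the chromosome
        genomic_pieces = pieces if strand == "+" else pieces[::-1]

        emit(chrom, _random_dna(rng, int(rng.integers(*spec.intron_length)) + 30))
        if strand == "-":
            # the 3' end of a '-' transcript is its genomically leftmost base
            stop_span = emit(chrom, reverse_complement(stop))
        spans: list[tuple[int, int]] = []
        for k, piece in enumerate(genomic_pieces):
            if k > 0:
                emit(chrom, _random_dna(rng, int(rng.integers(*spec.intron_length))))
            seq = piece if strand == "+" else reverse_complement(piece)
            spans.append(emit(chrom, seq))
        if strand == "+":
            stop_span = emit(chrom, stop)

        gene, tx, prot = f"GENE{g+1}", f"TX{g+1}", f"PROT{g+1}"
        attrs = _gtf_attrs(gene, tx, prot, f"gname{g+1}")
        tx_start = min(spans[0][0], stop_span[0])
        tx_end = max(spans[-1][1], stop_span[1])
        for feat, s, e, frame in [("gene", tx_start, tx_end, "."),
                                  ("transcript", tx_start, tx_end, ".")]:
            gtf_lines.append(
                f"{chrom}\tfixture\t{feat}\t{s}\t{e}\t.\t{strand}\t{frame}\t{attrs}"
            )
        # CDS rows carry frames; transcription order maps spans back to pieces
        tx_order_spans = spans if strand == "+" else spans[::-1]
        consumed = 0
        cds_rows = []
        for (s, e), ln in zip(tx_order_spans, lengths):
            frame = (3 - consumed % 3) % 3
            cds_rows.append((s, e, frame))
            consumed += ln
        exon_rows = [(s, e) for s, e, _ in cds_rows] + [stop_span]
        for s, e in sorted(exon_rows):
            gtf_lines.append(
                f"{chrom}\tfixture\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}"
            )
        for s, e, frame in sorted(cds_rows):
            gtf_lines.append(
                f"{chrom}\tfixture\tCDS\t{s}\t{e}\t.\t{strand}\t{frame}\t{attrs}"
            )
        gtf_lines.append(
            f"{chrom}\tfixture\tstop_codon\t{stop_span[0]}\t{stop_span[1]}\t.\t"
            f"{strand}\t0\t{attrs}"
        )

        truth_rows.append(
            {
                "transcript_id": tx,
                "gene_id": gene,
                "protein_id": prot,
                "chrom": chrom,
                "strand": strand,
                "segment_starts": ",".join(str(s) for s, _ in tx_order_spans),
                "segment_ends": ",".join(str(e) for _, e in tx_order_spans),
                "coding_dna": coding,
                "protein": translate(coding),
            }
        )

    for chrom in chrom_parts:
        emit(chrom, _random_dna(rng, int(rng.integers(*spec.intron_length)) + 30))

    fasta_path = os.path.join(directory, f"fixture_seed{spec.seed}.fa")
    with open(fasta_path, "w") as fh:
        for chrom, parts in chrom_parts.items():
            seq = "".join(parts)
            fh.write(f">{chrom} synthetic\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    gtf_path = os.path.join(directory, f"fixture_seed{spec.seed}.gtf")
    with open(gtf_path, "w") as fh:
        fh.write("#!genome-build cdsmap-fixture\n")
        fh.write("\n".join(gtf_lines) + "\n")

    truth_path = os.path.join(directory, f"fixture_seed{spec.seed}_truth.tsv")
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return FixtureFiles(fasta_path, gtf_path, truth_path)


def tiny_example(directory: str | os.PathLike) -> FixtureFiles:
    """The worked example: a 44 bp chromosome with a two-exon 'MAREK' gene.

    chrT carries CDS segments 11-19 (``ATGGCCCGT``) and 31-36 (``GAAAAG``)
    on the '+' strand followed by a TAA stop, so the spliced CDS is
    ``ATGGCCCGTGAAAAG`` and the protein is ``MAREK``.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    genome = "N" * 10 + "ATGGCCCGT" + "N" * 11 + "GAAAAG" + "TAA" + "N" * 5
    fasta_path = os.path.join(directory, "tiny_example.fa")
    with open(fasta_path, "w") as fh:
        fh.write(">chrT tiny example\n" + genome + "\n")
    attrs = _gtf_attrs("G1", "T1", "P1", "marek")
    lines = [
        f"chrT\tfixture\tgene\t11\t39\t.\t+\t.\t{attrs}",
        f"chrT\tfixture\ttranscript\t11\t39\t.\t+\t.\t{attrs}",
        f"chrT\tfixture\texon\t11\t19\t.\t+\t.\t{attrs}",
        f"chrT\tfixture\texon\t31\t39\t.\t+\t.\t{attrs}",
        f"chrT\tfixture\tCDS\t11\t19\t.\t+\t0\t{attrs}",
        f"chrT\tfixture\tCDS\t31\t36\t.\t+\t0\t{attrs}",
        f"chrT\tfixture\tstop_codon\t37\t39\t.\t+\t0\t{attrs}",
    ]
    gtf_path = os.path.join(directory, "tiny_example.gtf")
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    truth_path = os.path.join(directory, "tiny_example_truth.tsv")
    pd.DataFrame(
        [
            {
                "transcript_id": "T1",
                "gene_id": "G1",
                "protein_id": "P1",
                "chrom": "chrT",
                "strand": "+",
                "segment_starts": "11,31",
                "segment_ends": "19,36",
                "coding_dna": "ATGGCCCGTGAAAAG",
                "protein": "MAREK",
            }
        ]
    ).to_csv(truth_path, sep="\t", index=False)
    return FixtureFiles(fasta_path, gtf_path, truth_path)
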