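"""Shared fixtures and the per-base brute-force mapping oracle.

The oracle deliberately avoids all interval arithmetic: it materialises, for
every transcript, the explicit list of genomic positions of the spliced CDS
in transcription order (from the generator's truth table, not from the
package's index), and answers genomic and protein queries by per-base set
membership.  Agreement between this oracle and the package's segment-boundary
arithmetic is the core correctness property of the mapping layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from cdsmap import (
    CdsIndex,
    build_cds_index,
    make_fixture,
    read_genome_fasta,
    read_gtf,
    standard_genetic_code,
    tiny_example,
    FixtureSpec,
)


@dataclass
class TruthTranscript:
    """One row of a generator truth table, parsed."""

    transcript_id: str
    protein_id: str
    chrom: str
    strand: str
    spans: list[tuple[int, int]]  # transcription order
    coding_dna: str
    protein: str

    @property
    def positions(self) -> list[int]:
        """Genomic position of each CDS base, in transcription order."""
        pos = []
        for s, e in self.spans:
            pos.extend(range(s, e + 1) if self.strand == "+" else range(e, s - 1, -1))
        return pos


def load_truth(path: str) -> list[TruthTranscript]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        starts = [int(x) for x in str(row.segment_starts).split(",")]
        ends = [int(x) for x in str(row.segment_ends).split(",")]
        out.append(
            TruthTranscript(
                transcript_id=row.transcript_id,
                protein_id=row.protein_id,
                chrom=row.chrom,
                strand=row.strand,
                spans=list(zip(starts, ends)),
                coding_dna=row.coding_dna,
                protein=row.protein,
            )
        )
    return out


def _runs(positions: list[int], chrom: str, strand: str) -> list[tuple[str, int, int, str]]:
    """Group transcription-ordered positions into maximal contiguous pieces."""
    pieces = []
    step = 1 if strand == "+" else -1
    run = [positions[0]]
    for p in positions[1:]:
        if p == run[-1] + step:
            run.append(p)
        else:
            pieces.append(run)
            run = [p]
    pieces.append(run)
    return [(chrom, min(r), max(r), strand) for r in pieces]


class BruteForceMapper:
    """Answers mapping queries for one transcript by per-base enumeration."""

    def __init__(self, truth: TruthTranscript) -> None:
        self.t = truth
        self.positions = truth.positions

    def genomic_query(self, chrom: str, start: int, end: int):
        """Trim-mode expectation: (aa_start, aa_end, protein, dna, segments) or None."""
        t = self.t
        if chrom != t.chrom:
            return None
        covered = {
            i for i, p in enumerate(self.positions) if start <= p <= end
        }
        if not covered:
            return None
        n_aa = len(t.protein)
        whole = [
            p
            for p in range(1, n_aa + 1)
            if {3 * p - 3, 3 * p - 2, 3 * p - 1} <= covered
        ]
        if not whole:
            return (0, 0, "", "", [])
        a, b = min(whole), max(whole)
        assert whole == list(range(a, b + 1)), "codon coverage must be contiguous"
        dna = t.coding_dna[3 * a - 3 : 3 * b]
        segs = _runs(self.positions[3 * a - 3 : 3 * b], t.chrom, t.strand)
        return (a, b, t.protein[a - 1 : b], dna, segs)

    def protein_query(self, start_aa: int, end_aa: int):
        """(segments, dna, protein) for an amino-acid span."""
        t = self.t
        idx = list(range(3 * start_aa - 3, 3 * end_aa))
        segs = _runs([self.positions[i] for i in idx], t.chrom, t.strand)
        return (segs, t.coding_dna[idx[0] : idx[-1] + 1], t.protein[start_aa - 1 : end_aa])


@dataclass
class FixtureBundle:
    genome: object
    index: CdsIndex
    truths: list[TruthTranscript]
    fasta: str
    gtf: str


def build_bundle(spec: FixtureSpec, directory) -> FixtureBundle:
    files = make_fixture(spec, directory)
    genome = read_genome_fasta(files.fasta)
    index = build_cds_index(
        genome, read_gtf(files.gtf, {"CDS"}), standard_genetic_code()
    )
    return FixtureBundle(genome, index, load_truth(files.truth), files.fasta, files.gtf)


@pytest.fixture(scope="session")
def code():
    return standard_genetic_code()


@pytest.fixture(scope="session")
def tiny(tmp_path_factory):
    """The two-exon 'MAREK' worked example: (genome, index, files)."""
    d = tmp_path_factory.mktemp("tiny")
    files = tiny_example(d)
    genome = read_genome_fasta(files.fasta)
    index = build_cds_index(
        genome, read_gtf(files.gtf, {"CDS"}), standard_genetic_code()
    )
    return genome, index, files


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A mixed-strand multi-gene fixture genome used across mapping tests."""
    d = tmp_path_factory.mktemp("bundle")
    return build_bundle(
        FixtureSpec(n_chroms=2, n_genes=6, exons_per_gene=(1, 5), seed=7), d
    )
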