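"""The four batch mapping tasks and the sequence primitives they share.

Given a coding-sequence index (see :mod:`cdsmap.cds_index`), the mapping
layer answers four questions in batch:

1. which amino acids (and coding DNA) lie inside a list of genomic regions,
2. what is the plain DNA sequence of a list of genomic regions,
3. which genomic base intervals code for a list of protein regions,
4. what are the amino-acid sequences of a list of protein regions.

All coordinates are 1-based inclusive (the GTF/Ensembl convention); region
files in 0-based half-open BED convention can be converted on ingest.  The
position arithmetic works in "CDS space": each transcript's spliced coding
sequence is indexed 0..len-1 in transcription order, amino acid ``p``
occupies CDS indices ``off + 3(p-1) .. off + 3p - 1`` where ``off`` is the
leading phase offset, and a contiguous genomic interval always intersects a
transcript's coding segments in a single contiguous CDS interval.  Interval
arithmetic on segment boundaries therefore suffices; no per-base tables are
built.

Batch error policy: a bad row (unknown chromosome or protein ID, coordinates
off the end of a protein) produces an output row with its ``error`` field
set, and the batch continues.  Only malformed input files are fatal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from intervaltree import IntervalTree

from .errors import RegionFileError
from .reference_io import (
    GeneticCodeTable,
    GenomeSequence,
    normalize_chrom,
    standard_genetic_code,
)

if TYPE_CHECKING:  # pragma: no cover
    from .cds_index import CdsIndex, TranscriptModel

__all__ = [
    "reverse_complement",
    "translate",
    "GenomicRegion",
    "ProteinRegion",
    "CodingHit",
    "DnaHit",
    "SequenceHit",
    "genomic_to_protein_sequence",
    "genomic_to_dna",
    "protein_to_genomic",
    "protein_to_protein_sequence",
    "read_genomic_regions",
    "read_protein_regions",
    "write_coding_hits",
    "read_coding_hits",
    "write_dna_hits",
    "write_sequence_hits",
]

# IUPAC nucleotide complements (uppercase and lowercase preserved).
_IUPAC = "ACGTNRYSWKMBDHV"
_IUPAC_COMP = "TGCANYRSWMKVHDB"
_COMPLEMENT = str.maketrans(
    _IUPAC + _IUPAC.lower(), _IUPAC_COMP + _IUPAC_COMP.lower()
)
_IUPAC_SET = frozenset(_IUPAC + _IUPAC.lower())


def reverse_complement(dna: str) -> str:
    """Reverse complement of a DNA string over the IUPAC alphabet."""
    bad = next((b for b in dna if b not in _IUPAC_SET), None)
    if bad is not None:
        raise ValueError(f"character {bad!r} is not an IUPAC DNA symbol")
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, code: GeneticCodeTable | None = None) -> str:
    """Translate DNA codon-by-codon; trailing partial codon ignored.

    Any codon containing a base outside {A,C,G,T} (N or another ambiguity
    code) yields ``X``.  Stop codons yield the table's stop symbol.
    """
    if code is None:
        code = standard_genetic_code()
    dna = dna.upper()
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        out.append(code[codon] if codon in code else "X")
    return "".join(out)


# ---------------------------------------------------------------------------
# Query and result rows
# ---------------------------------------------------------------------------


@dataclass
class GenomicRegion:
    """One genomic query interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand_hint: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise RegionFileError(
                f"invalid genomic region {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand_hint not in {"+", "-", "."}:
            raise RegionFileError(f"invalid strand {self.strand_hint!r}")


@dataclass
class ProteinRegion:
    """One protein query: an ID (protein or transcript) and an amino-acid span."""

    id: str
    start_aa: int
    end_aa: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start_aa < 1 or self.start_aa > self.end_aa:
            raise RegionFileError(
                f"invalid protein region {self.id}:{self.start_aa}-{self.end_aa}"
            )


@dataclass
class CodingHit:
    """One mapped result: a query resolved against one transcript.

    ``segments`` are the genomic pieces of the answer in transcription order,
    each ``(chrom, start, end, strand)`` with ``start <= end``.  ``aa_start``
    and ``aa_end`` locate ``protein_seq`` within the full protein (both 0 when
    no complete codon was covered).  ``frame_note`` records which query
    boundaries were not codon-aligned: in trim mode partial codons were
    dropped there, in extend mode the boundary was widened there.
    """

    query: GenomicRegion | ProteinRegion
    gene_id: str = ""
    transcript_id: str = ""
    protein_id: str = ""
    segments: list[tuple[str, int, int, str]] = field(default_factory=list)
    coding_dna: str = ""
    protein_seq: str = ""
    aa_start: int = 0
    aa_end: int = 0
    frame_note: str = "exact"
    error: str = ""


@dataclass
class DnaHit:
    """Plain DNA retrieval result for one genomic region."""

    query: GenomicRegion
    dna: str = ""
    strand: str = "+"
    error: str = ""


@dataclass
class SequenceHit:
    """Amino-acid retrieval result for one protein region."""

    query: ProteinRegion
    protein_seq: str = ""
    error: str = ""


# ---------------------------------------------------------------------------
# CDS-space arithmetic
# ---------------------------------------------------------------------------


def _cumulative_offsets(tm: "TranscriptModel") -> list[int]:
    offs = [0]
    for seg in tm.segments:
        offs.append(offs[-1] + seg.length)
    return offs


def cds_interval_to_genomic(
    tm: "TranscriptModel", c0: int, c1: int
) -> list[tuple[str, int, int, str]]:
    """Genomic pieces (transcription order) covering CDS indices ``c0..c1``."""
    pieces: list[tuple[str, int, int, str]] = []
    cum = 0
    for seg in tm.segments:
        lo, hi = max(c0, cum), min(c1, cum + seg.length - 1)
        if lo <= hi:
            o0, o1 = lo - cum, hi - cum
            if seg.strand == "+":
                pieces.append((seg.chrom, seg.start + o0, seg.start + o1, "+"))
            else:
                pieces.append((seg.chrom, seg.end - o1, seg.end - o0, "-"))
        cum += seg.length
    return pieces


def genomic_overlap_cds(tm: "TranscriptModel", start: int, end: int) -> tuple[int, int] | None:
    """CDS-index interval covered by genomic ``[start, end]``, or None.

    A contiguous genomic interval covers a contiguous CDS interval because
    coding segments are disjoint and ordered along the chromosome.
    """
    lo = hi = None
    cum = 0
    for seg in tm.segments:
        s, e = max(start, seg.start), min(end, seg.end)
        if s <= e:
            if seg.strand == "+":
                a, b = cum + (s - seg.start), cum + (e - seg.start)
            else:
                a, b = cum + (seg.end - e), cum + (seg.end - s)
            lo = a if lo is None else min(lo, a)
            hi = b if hi is None else max(hi, b)
        cum += seg.length
    if lo is None:
        return None
    return lo, hi


class TranscriptLocator:
    """Interval tree over coding segments for chromosome-wise transcript lookup."""

    def __init__(self, index: "CdsIndex") -> None:
        self._trees: dict[str, IntervalTree] = {}
        for tm in index.transcripts():
            for seg in tm.segments:
                tree = self._trees.setdefault(normalize_chrom(seg.chrom), IntervalTree())
                # interval tree is half-open; +1 converts inclusive end
                tree.addi(seg.start, seg.end + 1, tm.transcript_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})

    def has_chrom(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._trees


# ---------------------------------------------------------------------------
# Task 1: genomic regions -> protein (and coding DNA) sequences
# ---------------------------------------------------------------------------


def _hit_for_transcript(
    region: GenomicRegion, tm: "TranscriptModel", frame_mode: str
) -> CodingHit:
    hit = CodingHit(
        query=region,
        gene_id=tm.gene_id,
        transcript_id=tm.transcript_id,
        protein_id=tm.protein_id,
    )
    cover = genomic_overlap_cds(tm, region.start, region.end)
    off = tm.leading_phase
    n_aa = len(tm.protein)
    if cover is None or n_aa == 0:
        hit.frame_note = "trimmed_both"
        return hit
    # restrict to the translated part of the CDS (drops phase-skipped bases
    # and any trailing partial or terminal-stop codon)
    lo = max(cover[0], off)
    hi = min(cover[1], off + 3 * n_aa - 1)
    up_aligned = lo <= hi and (lo - off) % 3 == 0
    down_aligned = lo <= hi and (hi - off + 1) % 3 == 0
    if lo > hi:
        hit.frame_note = "trimmed_both"
        return hit
    if frame_mode == "extend":
        lo = off + 3 * ((lo - off) // 3)
        hi = off + 3 * ((hi - off) // 3 + 1) - 1
        p_start = (lo - off) // 3 + 1
        p_end = (hi - off + 1) // 3
    elif frame_mode == "trim":
        p_start = (lo - off + 2) // 3 + 1 if (lo - off) % 3 else (lo - off) // 3 + 1
        p_end = (hi - off + 1) // 3
    else:
        raise ValueError(f"frame_mode must be 'trim' or 'extend', got {frame_mode!r}")
    if not up_aligned and not down_aligned:
        hit.frame_note = "trimmed_both"
    elif not up_aligned:
        hit.frame_note = "trimmed_upstream"
    elif not down_aligned:
        hit.frame_note = "trimmed_downstream"
    if p_start > p_end:
        return hit
    c0, c1 = off + 3 * (p_start - 1), off + 3 * p_end - 1
    hit.segments = cds_interval_to_genomic(tm, c0, c1)
    hit.coding_dna = tm.coding_dna[c0 : c1 + 1]
    hit.protein_seq = tm.protein[p_start - 1 : p_end]
    hit.aa_start, hit.aa_end = p_start, p_end
    return hit


def genomic_to_protein_sequence(
    regions: Sequence[GenomicRegion],
    index: "CdsIndex",
    code: GeneticCodeTable | None = None,  # noqa: ARG001 - sequences precomputed in index
    frame_mode: str = "trim",
    locator: TranscriptLocator | None = None,
) -> list[CodingHit]:
    """Find the amino-acid and coding-DNA sequences inside each genomic region.

    One hit per (region, overlapping transcript), in input order then by
    transcript ID.  ``frame_mode='trim'`` keeps only codons wholly inside the
    region; ``'extend'`` widens the region outward to the transcript's nearest
    codon boundaries so boundary codons are complete.
    """
    if locator is None:
        locator = TranscriptLocator(index)
    hits: list[CodingHit] = []
    for region in regions:
        if not locator.has_chrom(region.chrom):
            continue  # zero hits; batch semantics
        for tid in locator.overlapping(region.chrom, region.start, region.end):
            hits.append(_hit_for_transcript(region, index.by_transcript[tid], frame_mode))
    return hits


# ---------------------------------------------------------------------------
# Task 2: genomic regions -> whole DNA sequences
# ---------------------------------------------------------------------------


def genomic_to_dna(
    regions: Sequence[GenomicRegion], genome: GenomeSequence
) -> list[DnaHit]:
    """Fetch the plain DNA of each region; reverse-complemented when hinted '-'."""
    rows: list[DnaHit] = []
    for region in regions:
        row = DnaHit(query=region)
        if region.chrom not in genome:
            row.error = f"unknown chromosome {region.chrom!r}"
        elif region.end > genome.length(region.chrom):
            row.error = (
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {genome.length(region.chrom)}"
            )
        else:
            seq = genome.fetch(region.chrom, region.start, region.end)
            if region.strand_hint == "-":
                seq = reverse_complement(seq)
                row.strand = "-"
            row.dna = seq
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Task 3: protein regions -> genomic intervals
# ---------------------------------------------------------------------------


def _resolve_protein_id(index: "CdsIndex", pid: str) -> "TranscriptModel | None":
    return index.by_protein.get(pid) or index.by_transcript.get(pid)


def protein_to_genomic(
    regions: Sequence[ProteinRegion], index: "CdsIndex"
) -> list[CodingHit]:
    """Find the genomic base intervals coding each protein region.

    Intervals are contiguous within one coding segment and split at exon
    junctions; total genomic length is ``3 * (end_aa - start_aa + 1)``.
    """
    hits: list[CodingHit] = []
    for region in regions:
        hit = CodingHit(query=region)
        tm = _resolve_protein_id(index, region.id)
        if tm is None:
            hit.error = f"unknown protein or transcript ID {region.id!r}"
            hits.append(hit)
            continue
        hit.gene_id, hit.transcript_id, hit.protein_id = (
            tm.gene_id,
            tm.transcript_id,
            tm.protein_id,
        )
        if region.end_aa > len(tm.protein):
            hit.error = (
                f"region ends at amino acid {region.end_aa} but protein "
                f"{region.id} has length {len(tm.protein)}"
            )
            hits.append(hit)
            continue
        off = tm.leading_phase
        c0 = off + 3 * (region.start_aa - 1)
        c1 = off + 3 * region.end_aa - 1
        hit.segments = cds_interval_to_genomic(tm, c0, c1)
        hit.coding_dna = tm.coding_dna[c0 : c1 + 1]
        hit.protein_seq = tm.protein[region.start_aa - 1 : region.end_aa]
        hit.aa_start, hit.aa_end = region.start_aa, region.end_aa
        hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Task 4: protein regions -> protein sequences
# ---------------------------------------------------------------------------


def protein_to_protein_sequence(
    regions: Sequence[ProteinRegion], index: "CdsIndex"
) -> list[SequenceHit]:
    """Return the amino-acid substring of each protein region."""
    rows: list[SequenceHit] = []
    for region in regions:
        row = SequenceHit(query=region)
        tm = _resolve_protein_id(index, region.id)
        if tm is None:
            row.error = f"unknown protein or transcript ID {region.id!r}"
        elif region.end_aa > len(tm.protein):
            row.error = (
                f"region ends at amino acid {region.end_aa} but protein "
                f"{region.id} has length {len(tm.protein)}"
            )
        else:
            row.protein_seq = tm.protein[region.start_aa - 1 : region.end_aa]
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Region-list and result-table I/O (tab-delimited text)
# ---------------------------------------------------------------------------


def read_genomic_regions(
    path: str | os.PathLike, coords: str = "one"
) -> list[GenomicRegion]:
    """Read a tab-delimited genomic region list: chrom, start, end, [name], [strand].

    ``coords='one'`` for 1-based inclusive coordinates, ``'bed'`` for 0-based
    half-open (converted on ingest).  '#' comment lines are skipped.
    """
    if coords not in {"one", "bed"}:
        raise RegionFileError(f"coords must be 'one' or 'bed', got {coords!r}")
    regions: list[GenomicRegion] = []
    from .reference_io import open_text

    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionFileError(
                    f"{path}: line {lineno}: expected at least chrom/start/end"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise RegionFileError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if coords == "bed":
                start += 1
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[4] if len(fields) > 4 and fields[4] else "."
            try:
                regions.append(GenomicRegion(fields[0], start, end, name, strand))
            except RegionFileError as exc:
                raise RegionFileError(f"{path}: line {lineno}: {exc}") from None
    return regions


def read_protein_regions(path: str | os.PathLike) -> list[ProteinRegion]:
    """Read a tab-delimited protein region list: id, start_aa, end_aa, [name]."""
    regions: list[ProteinRegion] = []
    from .reference_io import open_text

    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionFileError(
                    f"{path}: line {lineno}: expected at least id/start_aa/end_aa"
                )
            try:
                a, b = int(fields[1]), int(fields[2])
            except ValueError:
                raise RegionFileError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            try:
                regions.append(
                    ProteinRegion(fields[0], a, b, fields[3] if len(fields) > 3 else "")
                )
            except RegionFileError as exc:
                raise RegionFileError(f"{path}: line {lineno}: {exc}") from None
    return regions


_HIT_COLUMNS = [
    "query_type",
    "query_chrom_or_id",
    "query_start",
    "query_end",
    "query_name",
    "gene_id",
    "transcript_id",
    "protein_id",
    "segment_starts",
    "segment_ends",
    "chrom",
    "strand",
    "coding_dna",
    "protein_seq",
    "aa_start",
    "aa_end",
    "frame_note",
    "error",
]


def _hit_row(hit: CodingHit) -> list[str]:
    q = hit.query
    if isinstance(q, GenomicRegion):
        qfields = ["genomic", q.chrom, str(q.start), str(q.end), q.name]
    else:
        qfields = ["protein", q.id, str(q.start_aa), str(q.end_aa), q.name]
    chrom = hit.segments[0][0] if hit.segments else ""
    strand = hit.segments[0][3] if hit.segments else ""
    return qfields + [
        hit.gene_id,
        hit.transcript_id,
        hit.protein_id,
        ",".join(str(s[1]) for s in hit.segments),
        ",".join(str(s[2]) for s in hit.segments),
        chrom,
        strand,
        hit.coding_dna,
        hit.protein_seq,
        str(hit.aa_start),
        str(hit.aa_end),
        hit.frame_note,
        hit.error,
    ]


def write_coding_hits(hits: Iterable[CodingHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_HIT_COLUMNS) + "\n")
        for hit in hits:
            fh.write("\t".join(_hit_row(hit)) + "\n")


def read_coding_hits(path: str | os.PathLike) -> list[CodingHit]:
    """Read back a table written by :func:`write_coding_hits`.

    Queries are reconstructed as :class:`GenomicRegion` when the first column
    parses as chrom/start/end, otherwise as :class:`ProteinRegion`.
    """
    from .reference_io import open_text

    hits: list[CodingHit] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_HIT_COLUMNS):
                raise RegionFileError(
                    f"{path}: line {lineno}: expected {len(_HIT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            (qtype, qid, qs, qe, qname, gene_id, tid, pid, starts, ends, chrom,
             strand, cdna, pseq, aa_s, aa_e, note, error) = fields
            query: GenomicRegion | ProteinRegion
            if qtype == "genomic":
                query = GenomicRegion(qid, int(qs), int(qe), qname)
            elif qtype == "protein":
                query = ProteinRegion(qid, int(qs), int(qe), qname)
            else:
                raise RegionFileError(
                    f"{path}: line {lineno}: unknown query_type {qtype!r}"
                )
            segs = []
            if starts:
                for s, e in zip(starts.split(","), ends.split(",")):
                    segs.append((chrom, int(s), int(e), strand))
            hits.append(
                CodingHit(
                    query=query,
                    gene_id=gene_id,
                    transcript_id=tid,
                    protein_id=pid,
                    segments=segs,
                    coding_dna=cdna,
                    protein_seq=pseq,
                    aa_start=int(aa_s),
                    aa_end=int(aa_e),
                    frame_note=note,
                    error=error,
                )
            )
    return hits


def write_dna_hits(rows: Iterable[DnaHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tstrand\tdna\terror\n")
        for row in rows:
            q = row.query
            fh.write(
                "\t".join([q.chrom, str(q.start), str(q.end), q.name, row.strand,
                           row.dna, row.error]) + "\n"
            )


def write_sequence_hits(rows: Iterable[SequenceHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#id\tstart_aa\tend_aa\tname\tprotein_seq\terror\n")
        for row in rows:
            q = row.query
            fh.write(
                "\t".join([q.id, str(q.start_aa), str(q.end_aa), q.name,
                           row.protein_seq, row.error]) + "\n"
            )
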