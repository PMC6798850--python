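"""Build and persist the coding-sequence index.

The index is built once per (genome, annotation) pair: every protein-coding
transcript's CDS rows are grouped, ordered in transcription order, spliced
out of the genome (reverse-complementing on the '-' strand) and translated.
It is stored as self-describing tab-delimited text (optionally gzipped), one
row per transcript, so it can be inspected with ordinary shell tools and is
the only hand-off between index building and region mapping.

Conventions follow the Ensembl GTF dialect: the stop codon is not part of
the CDS features, and a first-segment frame greater than zero marks a
5'-incomplete CDS whose leading bases are skipped before translation.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field

from . import __version__
from .errors import IndexFileError
from .mapping import reverse_complement, translate
from .reference_io import GeneticCodeTable, GenomeSequence, GtfRecord

logger = logging.getLogger(__name__)

FLAG_INCOMPLETE = "incomplete_cds"
FLAG_INTERNAL_STOP = "internal_stop"
FLAG_NO_PROTEIN_ID = "no_protein_id"


@dataclass
class CodingSegment:
    """One CDS piece of a transcript.

    ``phase`` is the number of bases to skip at the segment's start in
    transcription order before the first complete codon; ``segment_ordinal``
    counts segments 5' to 3' along the mRNA starting at 1.
    """

    chrom: str
    start: int
    end: int
    strand: str
    phase: int
    segment_ordinal: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """One protein-coding transcript: segments, spliced CDS and its protein."""

    gene_id: str
    transcript_id: str
    protein_id: str
    gene_name: str
    strand: str
    segments: list[CodingSegment]
    coding_dna: str
    protein: str
    flags: set[str] = field(default_factory=set)

    @property
    def leading_phase(self) -> int:
        """Bases skipped at the 5' end of the spliced CDS before translation."""
        return self.segments[0].phase if self.segments else 0

    @property
    def cds_length(self) -> int:
        return sum(seg.length for seg in self.segments)


class CdsIndex:
    """Lookup maps over transcript models, keyed by transcript and protein IDs."""

    def __init__(self, provenance: dict[str, str] | None = None) -> None:
        self.by_transcript: dict[str, TranscriptModel] = {}
        self.by_protein: dict[str, TranscriptModel] = {}
        self.provenance: dict[str, str] = provenance or {}
        self.skipped_records: int = 0

    def add(self, tm: TranscriptModel) -> None:
        self.by_transcript[tm.transcript_id] = tm
        if tm.protein_id:
            self.by_protein[tm.protein_id] = tm

    def transcripts(self) -> list[TranscriptModel]:
        return list(self.by_transcript.values())

    def __len__(self) -> int:
        return len(self.by_transcript)


def _expected_phases(lengths: list[int], first_phase: int) -> list[int]:
    """Phases implied by the first segment's phase and the segment lengths."""
    phases = [first_phase]
    consumed = -first_phase  # bases of complete codons consumed so far
    for length in lengths[:-1]:
        consumed += length
        phases.append((3 - consumed % 3) % 3)
    return phases


def build_cds_index(
    genome: GenomeSequence,
    cds_records: list[GtfRecord],
    code: GeneticCodeTable,
    provenance: dict[str, str] | None = None,
) -> CdsIndex:
    """Assemble one :class:`TranscriptModel` per transcript from CDS rows.

    Records on chromosomes absent from the genome are skipped with a warning
    (counted in ``index.skipped_records``).  Transcripts whose translated
    span is not a whole number of codons, or whose GTF frames disagree with
    the phases implied by the segment lengths, carry the ``incomplete_cds``
    flag; an in-frame stop before the last codon sets ``internal_stop`` (the
    stop symbol is kept in place in the protein).  A terminal stop codon
    annotated inside the CDS is trimmed from the protein output.
    """
    provenance = dict(provenance or {})
    provenance.setdefault("genome", genome.source)
    provenance.setdefault("builder", f"cdsmap-{__version__}")
    index = CdsIndex(provenance)

    grouped: dict[str, list[GtfRecord]] = {}
    for rec in cds_records:
        if rec.feature != "CDS":
            continue
        if genome.resolve(rec.chrom) is None:
            index.skipped_records += 1
            continue
        grouped.setdefault(rec.transcript_id, []).append(rec)
    if index.skipped_records:
        logger.warning(
            "skipped %d CDS records on chromosomes absent from the genome",
            index.skipped_records,
        )

    for tid, recs in grouped.items():
        # de-duplicate identical (start, end) rows
        seen: set[tuple[int, int]] = set()
        uniq: list[GtfRecord] = []
        for rec in recs:
            key = (rec.start, rec.end)
            if key in seen:
                logger.warning("transcript %s: duplicate CDS row %s dropped", tid, key)
                continue
            seen.add(key)
            uniq.append(rec)
        strand = uniq[0].strand
        uniq.sort(key=lambda r: r.start, reverse=(strand == "-"))

        flags: set[str] = set()
        lengths = [r.end - r.start + 1 for r in uniq]
        gtf_frames = [r.frame for r in uniq]
        if gtf_frames[0] is None:
            flags.add(FLAG_INCOMPLETE)
            first_phase = 0
        else:
            first_phase = gtf_frames[0]
            if first_phase != 0:
                flags.add(FLAG_INCOMPLETE)
        phases = _expected_phases(lengths, first_phase)
        # the first segment's annotated frame is trusted; later disagreement
        # (or missing frames) marks the transcript, recomputed phases are kept
        for got, want in zip(gtf_frames[1:], phases[1:]):
            if got is not None and got != want:
                flags.add(FLAG_INCOMPLETE)

        segments = [
            CodingSegment(
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                strand=strand,
                phase=phases[k],
                segment_ordinal=k + 1,
            )
            for k, r in enumerate(uniq)
        ]

        pieces = []
        for seg in segments:
            raw = genome.fetch(seg.chrom, seg.start, seg.end)
            pieces.append(reverse_complement(raw) if strand == "-" else raw)
        coding_dna = "".join(pieces)

        translatable = coding_dna[first_phase:]
        if len(translatable) % 3 != 0:
            flags.add(FLAG_INCOMPLETE)
        protein = translate(translatable, code)
        if protein.endswith(code.stop_symbol):
            protein = protein[:-1]  # terminal stop annotated within CDS
        if code.stop_symbol in protein:
            flags.add(FLAG_INTERNAL_STOP)

        protein_id = uniq[0].protein_id
        if not protein_id:
            flags.add(FLAG_NO_PROTEIN_ID)

        index.add(
            TranscriptModel(
                gene_id=uniq[0].gene_id,
                transcript_id=tid,
                protein_id=protein_id,
                gene_name=uniq[0].attributes.get("gene_name", ""),
                strand=strand,
                segments=segments,
                coding_dna=coding_dna,
                protein=protein,
                flags=flags,
            )
        )
    return index


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_INDEX_MAGIC = "#cdsmap-index"
_COLUMNS = [
    "gene_id",
    "transcript_id",
    "protein_id",
    "gene_name",
    "chrom",
    "strand",
    "segment_starts",
    "segment_ends",
    "segment_phases",
    "coding_dna",
    "protein",
    "flags",
]


def write_index(index: CdsIndex, path: str | os.PathLike) -> None:
    """Write the index as tab-delimited text; gzip when the path ends ``.gz``."""
    prov = "\t".join(f"{k}={v}" for k, v in sorted(index.provenance.items()))
    opener = gzip.open if os.fspath(path).endswith(".gz") else open
    try:
        fh = opener(path, "wt")
    except OSError as exc:
        raise IndexFileError(f"cannot write index to {path}: {exc}") from None
    with fh:
        fh.write(f"{_INDEX_MAGIC}\t{prov}\n")
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for tm in index.transcripts():
            fh.write(
                "\t".join(
                    [
                        tm.gene_id,
                        tm.transcript_id,
                        tm.protein_id,
                        tm.gene_name,
                        tm.segments[0].chrom if tm.segments else "",
                        tm.strand,
                        ",".join(str(s.start) for s in tm.segments),
                        ",".join(str(s.end) for s in tm.segments),
                        ",".join(str(s.phase) for s in tm.segments),
                        tm.coding_dna,
                        tm.protein,
                        ";".join(sorted(tm.flags)),
                    ]
                )
                + "\n"
            )


def read_index(path: str | os.PathLike) -> CdsIndex:
    """Read an index written by :func:`write_index`, validating each row."""
    from .reference_io import open_text

    with open_text(path) as fh:
        first = fh.readline()
        if not first.startswith(_INDEX_MAGIC):
            raise IndexFileError(f"{path}: missing index header line")
        provenance = {}
        for token in first.rstrip("\n").split("\t")[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                provenance[k] = v
        index = CdsIndex(provenance)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_COLUMNS):
                raise IndexFileError(
                    f"{path}: row {lineno}: expected {len(_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            (gene_id, tid, pid, gname, chrom, strand, starts_s, ends_s,
             phases_s, coding_dna, protein, flags_s) = fields
            starts = [int(x) for x in starts_s.split(",")] if starts_s else []
            ends = [int(x) for x in ends_s.split(",")] if ends_s else []
            phases = [int(x) for x in phases_s.split(",")] if phases_s else []
            if not (len(starts) == len(ends) == len(phases)):
                raise IndexFileError(
                    f"{path}: row {lineno}: segment list lengths disagree "
                    f"({len(starts)} starts, {len(ends)} ends, {len(phases)} phases)"
                )
            segments = [
                CodingSegment(chrom, s, e, strand, p, k + 1)
                for k, (s, e, p) in enumerate(zip(starts, ends, phases))
            ]
            if sum(seg.length for seg in segments) != len(coding_dna):
                raise IndexFileError(
                    f"{path}: row {lineno}: segment lengths sum to "
                    f"{sum(s.length for s in segments)} but coding_dna has "
                    f"{len(coding_dna)} bases"
                )
            index.add(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=tid,
                    protein_id=pid,
                    gene_name=gname,
                    strand=strand,
                    segments=segments,
                    coding_dna=coding_dna,
                    protein=protein,
                    flags=set(flags_s.split(";")) if flags_s else set(),
                )
            )
    return index
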