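"""Readers for the three external reference inputs.

A genome arrives as (optionally gzip-compressed) FASTA, gene annotation as
9-column Ensembl-dialect GTF, and the genetic code as a plain-text table of
``CODON<TAB>AA`` pairs with ``*`` as the stop symbol.  Everything downstream
(coding-sequence indexing, region mapping, codon-usage tallies) consumes the
containers defined here and nothing else, so dialect quirks — ``chr1`` versus
``1`` chromosome names, quoted versus bare GTF attribute values, RNA versus
DNA codon alphabets — are normalised at this boundary.

Compression is detected from the gzip magic bytes, never the file extension.
"""

from __future__ import annotations

import gzip
import io
import os
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

from .errors import ReferenceFileError

DNA_BASES = frozenset("ACGT")
STOP_SYMBOL = "*"

_GZIP_MAGIC = b"\x1f\x8b"


def open_text(path: str | os.PathLike) -> io.TextIOBase:
    """Open a text file, transparently decompressing gzip (detected by magic bytes)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ReferenceFileError(f"input file does not exist: {path}")
    raw = open(path, "rb")
    if raw.read(2) == _GZIP_MAGIC:
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    raw.seek(0)
    return io.TextIOWrapper(raw)


def normalize_chrom(name: str) -> str:
    """Canonical chromosome key: strip an optional leading ``chr`` and case-fold.

    Ensembl FASTA names chromosomes ``1``, ``X`` while many region lists say
    ``chr1``; comparisons are always made on this normalised form.
    """
    low = name.casefold()
    return low[3:] if low.startswith("chr") and len(low) > 3 else low


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------


class GenomeSequence:
    """Named chromosome sequences with 1-based inclusive substring extraction.

    Sequences are held uppercase in memory; ambiguity codes other than N are
    preserved verbatim (codons containing them translate to ``X`` downstream).
    """

    def __init__(self, sequences: Mapping[str, str], source: str = "") -> None:
        self._seqs: dict[str, str] = {name: seq.upper() for name, seq in sequences.items()}
        self._by_norm: dict[str, str] = {}
        for name in self._seqs:
            self._by_norm.setdefault(normalize_chrom(name), name)
        self.source = source

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return self.resolve(chrom) is not None

    def resolve(self, chrom: str) -> str | None:
        """Map a possibly dialect-differing chromosome name to the stored one."""
        if chrom in self._seqs:
            return chrom
        return self._by_norm.get(normalize_chrom(chrom))

    def length(self, chrom: str) -> int:
        key = self.resolve(chrom)
        if key is None:
            raise ReferenceFileError(f"unknown chromosome: {chrom!r}")
        return len(self._seqs[key])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the uppercase sequence of ``chrom[start..end]``, 1-based inclusive."""
        key = self.resolve(chrom)
        if key is None:
            raise ReferenceFileError(f"unknown chromosome: {chrom!r}")
        seq = self._seqs[key]
        if start < 1 or end < start:
            raise ReferenceFileError(
                f"invalid coordinates {chrom}:{start}-{end} (need 1 <= start <= end)"
            )
        if end > len(seq):
            raise ReferenceFileError(
                f"coordinates {chrom}:{start}-{end} exceed chromosome length {len(seq)}"
            )
        return seq[start - 1 : end]

    def to_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        """Write all chromosomes back out as FASTA (gzip when path ends ``.gz``)."""
        opener = gzip.open if os.fspath(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_genome_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Parse a (possibly gzipped) FASTA file into a :class:`GenomeSequence`.

    The chromosome name is the header token before the first whitespace; the
    rest of the header line is ignored.
    """
    sequences: dict[str, list[str]] = {}
    current: list[str] | None = None
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ReferenceFileError(f"{path}: empty FASTA header at line {lineno}")
                if name in sequences:
                    raise ReferenceFileError(
                        f"{path}: duplicate FASTA record {name!r} at line {lineno}"
                    )
                current = sequences.setdefault(name, [])
            else:
                if current is None:
                    raise ReferenceFileError(
                        f"{path}: sequence line before any FASTA header at line {lineno}"
                    )
                current.append(line)
    if not sequences:
        raise ReferenceFileError(f"{path}: empty FASTA file")
    return GenomeSequence(
        {name: "".join(parts) for name, parts in sequences.items()},
        source=os.path.basename(os.fspath(path)),
    )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

# Ensembl dialect: key "value"; -- bare (unquoted) values are tolerated too.
_ATTR_RE = re.compile(r'\s*(\S+)\s+(?:"([^"]*)"|([^;]*?))\s*;')

_VALID_STRANDS = {"+", "-", "."}


@dataclass
class GtfRecord:
    """One row of a 9-column GTF file, attributes parsed into a mapping."""

    chrom: str
    source: str
    feature: str
    start: int
    end: int
    score: str
    strand: str
    frame: int | None  # None when the frame column is '.'
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def gene_id(self) -> str:
        return self.attributes.get("gene_id", "")

    @property
    def transcript_id(self) -> str:
        return self.attributes.get("transcript_id", "")

    @property
    def protein_id(self) -> str:
        return self.attributes.get("protein_id", "")


def parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for m in _ATTR_RE.finditer(text):
        key, quoted, bare = m.groups()
        attrs[key] = quoted if quoted is not None else (bare or "").strip()
    return attrs


def read_gtf(
    path: str | os.PathLike, feature_filter: Iterable[str] | None = None
) -> list[GtfRecord]:
    """Read GTF rows whose feature is in ``feature_filter`` (all rows when None).

    File order is preserved; '#' comment lines are skipped.  Structural
    problems (short rows, non-integer coordinates, unknown strand on a
    retained record) are fatal and reported with their line number.
    """
    wanted = set(feature_filter) if feature_filter is not None else None
    records: list[GtfRecord] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ReferenceFileError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF fields, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, score, strand, frame_s = fields[:8]
            if wanted is not None and feature not in wanted:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ReferenceFileError(
                    f"{path}: line {lineno}: non-integer start/end ({start_s!r}, {end_s!r})"
                ) from None
            if start > end:
                raise ReferenceFileError(f"{path}: line {lineno}: start {start} > end {end}")
            if strand not in _VALID_STRANDS:
                raise ReferenceFileError(
                    f"{path}: line {lineno}: unknown strand symbol {strand!r}"
                )
            if frame_s == ".":
                frame = None
            elif frame_s in {"0", "1", "2"}:
                frame = int(frame_s)
            else:
                raise ReferenceFileError(
                    f"{path}: line {lineno}: invalid frame {frame_s!r} (expected 0/1/2/.)"
                )
            records.append(
                GtfRecord(
                    chrom=chrom,
                    source=source,
                    feature=feature,
                    start=start,
                    end=end,
                    score=score,
                    strand=strand,
                    frame=frame,
                    attributes=parse_gtf_attributes(fields[8]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Genetic-code table
# ---------------------------------------------------------------------------


class GeneticCodeTable:
    """A 64-codon DNA → single-letter amino-acid mapping with a stop symbol."""

    def __init__(self, mapping: Mapping[str, str], stop_symbol: str = STOP_SYMBOL) -> None:
        mapping = {c.upper(): aa for c, aa in mapping.items()}
        bad = sorted(
            c for c in mapping if len(c) != 3 or any(b not in DNA_BASES for b in c)
        )
        if bad:
            raise ReferenceFileError(f"invalid codons in genetic-code table: {bad}")
        if len(mapping) != 64:
            missing = sorted(_all_codons() - set(mapping))
            raise ReferenceFileError(
                f"genetic-code table has {len(mapping)} codons, expected 64"
                + (f"; missing: {missing}" if missing else "")
            )
        self.mapping: dict[str, str] = dict(mapping)
        self.stop_symbol = stop_symbol
        if stop_symbol not in self.mapping.values():
            raise ReferenceFileError(
                f"genetic-code table maps no codon to the stop symbol {stop_symbol!r}"
            )

    def __getitem__(self, codon: str) -> str:
        return self.mapping[codon.upper()]

    def __contains__(self, codon: str) -> bool:
        return codon.upper() in self.mapping

    @property
    def stop_codons(self) -> list[str]:
        return [c for c, aa in self.mapping.items() if aa == self.stop_symbol]

    def synonymous_codons(self, aa: str) -> list[str]:
        """All codons encoding ``aa``, in lexicographic order."""
        return sorted(c for c, a in self.mapping.items() if a == aa)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self.mapping.items())


def _all_codons() -> set[str]:
    return {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}


def read_genetic_code(path: str | os.PathLike) -> GeneticCodeTable:
    """Read a ``CODON AA`` pair-per-line table; RNA codons (U) are accepted."""
    mapping: dict[str, str] = {}
    duplicates: list[str] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ReferenceFileError(
                    f"{path}: line {lineno}: expected 'CODON AA', got {line!r}"
                )
            codon, aa = parts[0].upper(), parts[1]
            if any(b not in "ACGTU" for b in codon) or len(codon) != 3:
                raise ReferenceFileError(
                    f"{path}: line {lineno}: invalid codon {parts[0]!r}"
                )
            codon = codon.replace("U", "T")
            if codon in mapping:
                duplicates.append(codon)
            mapping[codon] = aa
    if duplicates:
        raise ReferenceFileError(f"{path}: duplicate codons: {sorted(set(duplicates))}")
    if len(mapping) != 64:
        missing = sorted(_all_codons() - set(mapping))
        raise ReferenceFileError(
            f"{path}: genetic-code table has {len(mapping)} codons, expected 64; "
            f"missing: {missing}"
        )
    return GeneticCodeTable(mapping)


def standard_genetic_code() -> GeneticCodeTable:
    """The standard genetic code shipped with the package."""
    with resources.files("cdsmap.data").joinpath("standard_genetic_code.txt").open() as fh:
        mapping: dict[str, str] = {}
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, aa = line.split()
            mapping[codon.replace("U", "T")] = aa
    return GeneticCodeTable(mapping)
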