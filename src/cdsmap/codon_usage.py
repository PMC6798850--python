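"""Positional codon-usage tables over a set of equal-length coding regions.

Given the mapped hits for a family of same-length coding regions (for
example, repeated motif instances across zinc-finger genes), this module
tallies which codon is used at each aligned amino-acid position and compares
the observed share of each synonymous codon against an expected genome-wide
codon-usage reference.

"Re-scaling" means: restrict a codon-frequency vector to the codons
synonymous for the focal amino acid and renormalise them to sum to 100%.
Applied to the observed counts this gives the observed percentage column;
applied to the genome-wide reference it gives the expected percentage
column.  A row of either kind sums to 100 up to rounding.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CdsmapError
from .mapping import CodingHit
from .reference_io import GeneticCodeTable, open_text, standard_genetic_code

__all__ = [
    "CodonFrequencyTable",
    "positional_codon_frequencies",
    "rescale",
    "read_codon_usage",
    "human_codon_usage",
    "frequency_frame",
    "write_frequency_tables",
]


@dataclass
class CodonFrequencyTable:
    """Codon tally at one aligned position across a region set.

    ``aa`` is the modal (most frequent) amino acid at the position; hits
    showing a different amino acid there are excluded from the synonymous
    re-scaling and reported in ``n_other``.  Percentages are exact here and
    rounded to one decimal place in the written report.
    """

    position: int
    aa: str
    counts: dict[str, int] = field(default_factory=dict)
    observed_pct: dict[str, float] = field(default_factory=dict)
    expected_pct: dict[str, float] = field(default_factory=dict)
    n_other: int = 0
    other_aa_counts: dict[str, int] = field(default_factory=dict)


def rescale(usage: Mapping[str, float], codons: Sequence[str]) -> dict[str, float]:
    """Restrict ``usage`` to ``codons`` and renormalise to percentages.

    Full precision is kept here so a row always sums to 100 exactly;
    rounding to the report's one decimal happens only on output.
    """
    total = sum(usage.get(c, 0.0) for c in codons)
    if total <= 0:
        return {c: 0.0 for c in codons}
    return {c: 100.0 * usage.get(c, 0.0) / total for c in codons}


def positional_codon_frequencies(
    hits: Sequence[CodingHit],
    positions: Iterable[int],
    expected_usage: Mapping[str, float],
    code: GeneticCodeTable | None = None,
) -> list[CodonFrequencyTable]:
    """Tally codons at the requested aligned positions across ``hits``.

    All hits must carry protein sequences of one common length; each
    requested position must lie within it.  ``expected_usage`` is any
    relative codon-frequency reference over the 64 codons (fractions,
    percentages or counts per 1000 all work — only ratios matter).
    """
    if code is None:
        code = standard_genetic_code()
    hits = [h for h in hits if not h.error]
    if not hits:
        raise CdsmapError("no usable hits: the hit list is empty or all rows errored")
    lengths = {len(h.protein_seq) for h in hits}
    if len(lengths) != 1:
        raise CdsmapError(
            f"hits have unequal protein lengths {sorted(lengths)}; "
            "positional tallies need one aligned length"
        )
    (length,) = lengths
    if length == 0:
        raise CdsmapError("hits carry empty protein sequences")
    missing = sorted(set(c for c, _ in code.items()) - set(expected_usage))
    if missing:
        raise CdsmapError(f"expected-usage reference lacks codons: {missing}")

    tables: list[CodonFrequencyTable] = []
    for pos in positions:
        if not 1 <= pos <= length:
            raise CdsmapError(f"position {pos} outside aligned length {length}")
        by_aa: dict[str, dict[str, int]] = {}
        for h in hits:
            codon = h.coding_dna[3 * pos - 3 : 3 * pos].upper()
            aa = h.protein_seq[pos - 1]
            by_aa.setdefault(aa, {}).setdefault(codon, 0)
            by_aa[aa][codon] += 1
        # modal amino acid; ties broken towards the alphabetically first
        modal = max(sorted(by_aa), key=lambda a: sum(by_aa[a].values()))
        counts = dict(sorted(by_aa[modal].items()))
        synonymous = code.synonymous_codons(modal)
        full_counts = {c: counts.get(c, 0) for c in synonymous}
        # codons of the modal aa not in the table's synonymous set (e.g. X)
        for c, n in counts.items():
            full_counts.setdefault(c, n)
        other = {
            a: sum(d.values()) for a, d in by_aa.items() if a != modal
        }
        tables.append(
            CodonFrequencyTable(
                position=pos,
                aa=modal,
                counts=full_counts,
                observed_pct=rescale(full_counts, sorted(full_counts)),
                expected_pct=rescale(expected_usage, synonymous),
                n_other=sum(other.values()),
                other_aa_counts=other,
            )
        )
    return tables


def read_codon_usage(path: str | os.PathLike) -> dict[str, float]:
    """Read a ``CODON<TAB>frequency`` reference table (RNA codons accepted)."""
    usage: dict[str, float] = {}
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise CdsmapError(f"{path}: line {lineno}: expected 'CODON frequency'")
            codon = parts[0].upper().replace("U", "T")
            try:
                usage[codon] = float(parts[1])
            except ValueError:
                raise CdsmapError(
                    f"{path}: line {lineno}: non-numeric frequency {parts[1]!r}"
                ) from None
    return usage


def human_codon_usage() -> dict[str, float]:
    """The packaged human genome-wide codon-usage reference (per 1000 codons)."""
    from importlib import resources

    with resources.files("cdsmap.data").joinpath("human_codon_usage.txt").open() as fh:
        usage = {}
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, freq = line.split()
            usage[codon] = float(freq)
    return usage


def frequency_frame(tables: Sequence[CodonFrequencyTable]) -> pd.DataFrame:
    """Long-format table: position, aa, codon, count, observed_pct, expected_pct."""
    rows = []
    for t in tables:
        codons = sorted(set(t.counts) | set(t.expected_pct))
        for codon in codons:
            rows.append(
                {
                    "position": t.position,
                    "aa": t.aa,
                    "codon": codon,
                    "count": t.counts.get(codon, 0),
                    "observed_pct": round(t.observed_pct.get(codon, 0.0), 1),
                    "expected_pct": round(t.expected_pct.get(codon, 0.0), 1),
                    "n_other_aa": t.n_other,
                }
            )
    return pd.DataFrame(rows)


def write_frequency_tables(
    tables: Sequence[CodonFrequencyTable], path: str | os.PathLike
) -> None:
    frequency_frame(tables).to_csv(path, sep="\t", index=False)
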