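"""Mapping layer: sequence primitives, the four tasks, oracle equivalence."""

import random

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from cdsmap import (
    GenomicRegion,
    ProteinRegion,
    genomic_to_dna,
    genomic_to_protein_sequence,
    protein_to_genomic,
    protein_to_protein_sequence,
    reverse_complement,
    translate,
    FixtureSpec,
)
from cdsmap.errors import RegionFileError
from cdsmap.mapping import (
    TranscriptLocator,
    read_coding_hits,
    read_genomic_regions,
    read_protein_regions,
    write_coding_hits,
)

from conftest import BruteForceMapper, build_bundle

dna_text = st.text(alphabet="ACGTNacgtnRYSWKM", max_size=60)


class TestPrimitives:
    def test_reverse_complement_examples(self):
        assert reverse_complement("ATGC") == "GCAT"
        assert reverse_complement("") == ""
        assert reverse_complement("NNR") == "YNN"

    @settings(derandomize=True)
    @given(dna_text)
    def test_reverse_complement_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s
        assert len(reverse_complement(s)) == len(s)

    def test_reverse_complement_rejects_non_iupac(self):
        with pytest.raises(ValueError, match="Q"):
            reverse_complement("ACQ")

    @settings(derandomize=True)
    @given(s=st.text(alphabet="ACGT", max_size=90))
    def test_reverse_complement_and_translate_match_biopython(self, code, s):
        assert reverse_complement(s) == str(Seq(s).reverse_complement())
        assert translate(s, code) == str(Seq(s[: len(s) - len(s) % 3]).translate())

    def test_translate_examples(self, code):
        assert translate("AGA", code) == "R"
        assert translate("CCC", code) == "P"
        assert translate("ATGNAA", code) == "MX"
        assert translate("ATGGCCCGTGAAAAG", code) == "MAREK"
        assert translate("AT", code) == ""


class TestGenomicToProtein:
    def test_exact_exon_query(self, tiny):
        _, index, _ = tiny
        (hit,) = genomic_to_protein_sequence([GenomicRegion("chrT", 11, 19)], index)
        assert (hit.coding_dna, hit.protein_seq) == ("ATGGCCCGT", "MAR")
        assert (hit.aa_start, hit.aa_end, hit.frame_note) == (1, 3, "exact")

    def test_intron_overhang_is_excluded(self, tiny):
        _, index, _ = tiny
        (hit,) = genomic_to_protein_sequence([GenomicRegion("chrT", 14, 22)], index)
        assert (hit.coding_dna, hit.protein_seq) == ("GCCCGT", "AR")
        assert (hit.aa_start, hit.aa_end) == (2, 3)

    def test_partial_codons_trim_vs_extend(self, tiny):
        _, index, _ = tiny
        region = [GenomicRegion("chrT", 15, 18)]
        (trim,) = genomic_to_protein_sequence(region, index, frame_mode="trim")
        assert trim.protein_seq == "" and trim.coding_dna == ""
        assert trim.frame_note == "trimmed_both"
        (ext,) = genomic_to_protein_sequence(region, index, frame_mode="extend")
        assert ext.protein_seq == "AR"
        assert ext.segments == [("chrT", 14, 19, "+")]

    def test_junction_spanning_codon_needs_both_exons(self, tiny):
        # codon 4 (E) spans the exon junction: bases 31-33 complete it only
        # when the upstream exon contributed nothing, so a query over exon 2
        # alone yields E and K
        _, index, _ = tiny
        (hit,) = genomic_to_protein_sequence([GenomicRegion("chrT", 31, 36)], index)
        assert hit.protein_seq == "EK" and hit.aa_start == 4

    def test_whole_transcript_span_recovers_protein(self, tiny):
        _, index, _ = tiny
        (hit,) = genomic_to_protein_sequence([GenomicRegion("chrT", 1, 44)], index)
        assert hit.protein_seq == "MAREK"
        assert hit.segments == [("chrT", 11, 19, "+"), ("chrT", 31, 36, "+")]

    def test_noncoding_region_yields_no_hit(self, tiny):
        _, index, _ = tiny
        assert genomic_to_protein_sequence([GenomicRegion("chrT", 20, 30)], index) == []
        assert genomic_to_protein_sequence([GenomicRegion("chrZ", 1, 5)], index) == []

    def test_output_order_input_then_transcript_id(self, bundle):
        regions = []
        for t in sorted(bundle.truths, key=lambda t: t.transcript_id, reverse=True):
            lo = min(min(s) for s in t.spans)
            hi = max(max(s) for s in t.spans)
            regions.append(GenomicRegion(t.chrom, lo, hi, name=t.transcript_id))
        hits = genomic_to_protein_sequence(regions, bundle.index)
        assert [h.query.name for h in hits] == [r.name for r in regions]


class TestGenomicToDna:
    def test_plain_fetch(self, tiny):
        genome, _, _ = tiny
        (row,) = genomic_to_dna([GenomicRegion("chrT", 11, 19)], genome)
        assert row.dna == "ATGGCCCGT" and row.error == ""

    def test_minus_hint_reverse_complements(self, tiny):
        genome, _, _ = tiny
        (row,) = genomic_to_dna([GenomicRegion("chrT", 11, 19, strand_hint="-")], genome)
        assert row.dna == "ACGGGCCAT" and row.strand == "-"

    def test_length_one(self, tiny):
        genome, _, _ = tiny
        (row,) = genomic_to_dna([GenomicRegion("chrT", 11, 11)], genome)
        assert row.dna == "A"

    def test_out_of_range_is_error_row_not_fatal(self, tiny):
        genome, _, _ = tiny
        rows = genomic_to_dna(
            [GenomicRegion("chrT", 40, 99), GenomicRegion("chrT", 1, 4)], genome
        )
        assert "exceeds" in rows[0].error and rows[0].dna == ""
        assert rows[1].dna == "NNNN"  # batch continues


class TestProteinToGenomic:
    def test_junction_spanning_span(self, tiny):
        _, index, _ = tiny
        (hit,) = protein_to_genomic([ProteinRegion("P1", 2, 4)], index)
        assert hit.segments == [("chrT", 14, 19, "+"), ("chrT", 31, 33, "+")]
        assert sum(e - s + 1 for _, s, e, _ in hit.segments) == 9
        assert hit.protein_seq == "ARE"

    def test_first_codon(self, tiny):
        _, index, _ = tiny
        (hit,) = protein_to_genomic([ProteinRegion("P1", 1, 1)], index)
        assert hit.segments == [("chrT", 11, 13, "+")]

    def test_transcript_id_also_resolves(self, tiny):
        _, index, _ = tiny
        (hit,) = protein_to_genomic([ProteinRegion("T1", 1, 5)], index)
        assert hit.protein_seq == "MAREK"

    def test_minus_strand_first_codon_is_highest_coordinates(self, tmp_path):
        bundle = build_bundle(
            FixtureSpec(n_genes=2, strand_minus_fraction=1.0, seed=3), tmp_path
        )
        for t in bundle.truths:
            (hit,) = protein_to_genomic([ProteinRegion(t.protein_id, 1, 1)], bundle.index)
            top_start, top_end = max(t.spans, key=lambda s: s[1])
            assert hit.segments == [(t.chrom, top_end - 2, top_end, "-")]

    def test_unknown_id_and_overrun_are_error_rows(self, tiny):
        _, index, _ = tiny
        hits = protein_to_genomic(
            [ProteinRegion("NOPE", 1, 2), ProteinRegion("P1", 2, 9)], index
        )
        assert "unknown" in hits[0].error
        assert "length 5" in hits[1].error
        assert hits[0].segments == hits[1].segments == []


class TestProteinToProtein:
    def test_substring_and_identity(self, tiny):
        _, index, _ = tiny
        rows = protein_to_protein_sequence(
            [ProteinRegion("P1", 2, 4), ProteinRegion("P1", 1, 5)], index
        )
        assert [r.protein_seq for r in rows] == ["ARE", "MAREK"]

    def test_single_positions_partition_protein(self, bundle):
        for t in bundle.truths:
            rows = protein_to_protein_sequence(
                [ProteinRegion(t.protein_id, k, k) for k in range(1, len(t.protein) + 1)],
                bundle.index,
            )
            assert "".join(r.protein_seq for r in rows) == t.protein


class TestRoundTrips:
    def test_protein_to_genomic_and_back(self, bundle):
        """p2g segments, re-queried in trim mode, recover the protein substring."""
        rng = random.Random(42)
        for t in bundle.truths:
            n = len(t.protein)
            for _ in range(20):
                a = rng.randint(1, n)
                b = rng.randint(a, n)
                (p2g,) = protein_to_genomic([ProteinRegion(t.protein_id, a, b)], bundle.index)
                parts = []
                for chrom, s, e, _ in p2g.segments:
                    hits = [
                        h
                        for h in genomic_to_protein_sequence(
                            [GenomicRegion(chrom, s, e)], bundle.index
                        )
                        if h.transcript_id == t.transcript_id
                    ]
                    parts.append(hits[0] if hits else None)
                # segments of one query may split codons at junctions; map the
                # whole span instead for the protein comparison
                lo = min(s[1] for s in p2g.segments)
                hi = max(s[2] for s in p2g.segments)
                back = [
                    h
                    for h in genomic_to_protein_sequence(
                        [GenomicRegion(t.chrom, lo, hi)], bundle.index
                    )
                    if h.transcript_id == t.transcript_id
                ]
                (p2p,) = protein_to_protein_sequence(
                    [ProteinRegion(t.protein_id, a, b)], bundle.index
                )
                assert back[0].protein_seq[: b - a + 1] == p2p.protein_seq == p2g.protein_seq

    def test_codon_aligned_genomic_query_recovers_segments(self, bundle):
        """g2p on a codon-aligned sub-span, then p2g of the reported amino
        acids, reproduces the g2p hit's segments exactly."""
        rng = random.Random(99)
        for t in bundle.truths:
            n = len(t.protein)
            for _ in range(20):
                a = rng.randint(1, n)
                b = rng.randint(a, n)
                (fwd,) = protein_to_genomic([ProteinRegion(t.protein_id, a, b)], bundle.index)
                lo = min(s[1] for s in fwd.segments)
                hi = max(s[2] for s in fwd.segments)
                g2p = [
                    h
                    for h in genomic_to_protein_sequence(
                        [GenomicRegion(t.chrom, lo, hi)], bundle.index
                    )
                    if h.transcript_id == t.transcript_id
                ][0]
                if (g2p.aa_start, g2p.aa_end) == (a, b):
                    (back,) = protein_to_genomic(
                        [ProteinRegion(t.protein_id, g2p.aa_start, g2p.aa_end)],
                        bundle.index,
                    )
                    assert back.segments == fwd.segments


class TestOracleEquivalence:
    def test_random_queries_match_brute_force(self, tmp_path):
        """Interval arithmetic equals per-base enumeration over random gene
        models on both strands with 1-5 exons."""
        rng = random.Random(2024)
        n_checked = 0
        for seed in range(1, 6):
            bundle = build_bundle(
                FixtureSpec(n_genes=4, exons_per_gene=(1, 5), seed=seed),
                tmp_path / f"s{seed}",
            )
            locator = TranscriptLocator(bundle.index)
            for t in bundle.truths:
                oracle = BruteForceMapper(t)
                lo = min(min(s) for s in t.spans) - 5
                hi = max(max(s) for s in t.spans) + 5
                for _ in range(30):
                    s = rng.randint(max(1, lo), hi)
                    e = rng.randint(s, hi)
                    expect = oracle.genomic_query(t.chrom, s, e)
                    hits = [
                        h
                        for h in genomic_to_protein_sequence(
                            [GenomicRegion(t.chrom, s, e)], bundle.index, locator=locator
                        )
                        if h.transcript_id == t.transcript_id
                    ]
                    n_checked += 1
                    if expect is None:
                        assert hits == []
                        continue
                    (hit,) = hits
                    aa_s, aa_e, prot, dna, segs = expect
                    assert (hit.aa_start, hit.aa_end) == (aa_s, aa_e)
                    assert hit.protein_seq == prot
                    assert hit.coding_dna == dna
                    assert hit.segments == segs
                    assert len(hit.coding_dna) == 3 * len(hit.protein_seq)
                for _ in range(15):
                    a = rng.randint(1, len(t.protein))
                    b = rng.randint(a, len(t.protein))
                    segs, dna, prot = oracle.protein_query(a, b)
                    (hit,) = protein_to_genomic(
                        [ProteinRegion(t.protein_id, a, b)], bundle.index
                    )
                    n_checked += 1
                    assert hit.segments == segs
                    assert hit.coding_dna == dna
                    assert hit.protein_seq == prot
                    assert sum(e - s + 1 for _, s, e, _ in hit.segments) == 3 * (b - a + 1)
        assert n_checked >= 500


class TestRegionFiles:
    def test_genomic_regions_one_based_and_bed(self, tmp_path):
        path = tmp_path / "r.txt"
        path.write_text("# comment\nchr1\t10\t20\tpeak1\t+\nchr2\t5\t6\n")
        one = read_genomic_regions(path, coords="one")
        assert (one[0].start, one[0].end, one[0].name, one[0].strand_hint) == (10, 20, "peak1", "+")
        bed = read_genomic_regions(path, coords="bed")
        assert (bed[0].start, bed[0].end) == (11, 20)

    def test_protein_regions(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("P1\t2\t4\tmotif\n")
        (r,) = read_protein_regions(path)
        assert (r.id, r.start_aa, r.end_aa, r.name) == ("P1", 2, 4, "motif")

    @pytest.mark.parametrize("text", ["chr1\t10\n", "chr1\tx\t20\n", "chr1\t20\t10\n"])
    def test_malformed_region_rows_fatal(self, tmp_path, text):
        path = tmp_path / "bad.txt"
        path.write_text(text)
        with pytest.raises(RegionFileError):
            read_genomic_regions(path)

    def test_hit_table_round_trip(self, tmp_path, tiny):
        _, index, _ = tiny
        hits = genomic_to_protein_sequence(
            [GenomicRegion("chrT", 11, 19, name="q1")], index
        ) + protein_to_genomic([ProteinRegion("P1", 2, 4)], index)
        path = tmp_path / "hits.tsv"
        write_coding_hits(hits, path)
        loaded = read_coding_hits(path)
        assert len(loaded) == 2
        assert loaded[0].protein_seq == "MAR" and loaded[0].query.name == "q1"
        assert loaded[1].segments == hits[1].segments
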