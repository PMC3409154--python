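"""Motif scanning, conservation scoring, amplicon and control design."""

import numpy as np
import pytest

from crmchip.alignment import AlignmentBlock, reverse_complement
from crmchip.errors import (
    CoordinateError,
    InfeasibleWindowError,
    ParameterError,
    PatternError,
)
from crmchip.motifs import (
    MotifSite,
    annotate_conservation,
    design_amplicon_window,
    iupac_regex,
    scan_reference_motifs,
    select_candidate_sites,
    select_control_regions,
)
from tests.conftest import single_row_block

FORWARD_HEXAMERS = {"TAATCC", "TAATCT"}          # TAATCY spelled out
REVERSE_HEXAMERS = {"GGATTA", "AGATTA"}          # reverse complement RGATTA


def brute_force_sites(seq: str):
    """Independent oracle: check every hexamer window against the spelled-out sets."""
    found = []
    for i in range(len(seq) - 5):
        hexamer = seq[i : i + 6]
        if hexamer in FORWARD_HEXAMERS:
            found.append((i, i + 6, "+"))
        if hexamer in REVERSE_HEXAMERS:
            found.append((i, i + 6, "-"))
    return sorted(found)


class TestScanReferenceMotifs:
    def test_forward_occurrence(self):
        sites = scan_reference_motifs(single_row_block("GGTAATCCAA"))
        assert [(s.start, s.end, s.strand, s.matched_hexamer) for s in sites] == [
            (2, 8, "+", "TAATCC")
        ]

    def test_reverse_occurrence(self):
        sites = scan_reference_motifs(single_row_block("CAGGATTACT"))
        assert [(s.start, s.end, s.strand) for s in sites] == [(2, 8, "-")]

    def test_no_match(self):
        assert scan_reference_motifs(single_row_block("AAAAAAAAAA")) == []

    def test_forward_only_flag(self):
        block = single_row_block("CAGGATTACT")
        assert scan_reference_motifs(block, forward_only=True) == []

    def test_overlapping_occurrences_all_reported(self):
        # TAATCT at 0 and GGATTA-containing overlap: TAATCTAATCC has TAATCT@0, TAATCC@5
        sites = scan_reference_motifs(single_row_block("TAATCTAATCC"))
        assert [(s.start, s.strand) for s in sites] == [(0, "+"), (5, "+")]

    def test_invalid_iupac_raises(self):
        with pytest.raises(PatternError):
            scan_reference_motifs(single_row_block("ACGTACGT"), motif="TAATXZ")

    def test_gapped_reference_uses_gapfree_coordinates(self):
        block = AlignmentBlock("mouse", "chr1", 10, (("mouse", "GG--TAATCC--AA"),))
        sites = scan_reference_motifs(block)
        assert [(s.start, s.end) for s in sites] == [(12, 18)]

    def test_oracle_equivalence_on_random_sequences(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 2000))))
            sites = scan_reference_motifs(single_row_block(seq))
            assert sorted((s.start, s.end, s.strand) for s in sites) == brute_force_sites(seq)

    def test_strand_symmetry_under_block_reverse_complement(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        block = single_row_block(seq)
        flipped = block.reverse_complemented()
        fwd = {(s.start, s.end, s.strand) for s in scan_reference_motifs(block)}
        rev = {(s.start, s.end, s.strand) for s in scan_reference_motifs(flipped)}
        n = len(seq)
        mapped = {(n - e, n - s, "-" if st == "+" else "+") for s, e, st in fwd}
        assert rev == mapped


def three_species_block(human_row="GGTAATCCAA"):
    return AlignmentBlock(
        "mouse", "chr1", 0,
        (
            ("mouse", "GGTAATCCAA"),
            ("rat", "GGTAATCCAA"),
            ("human", human_row),
        ),
    )


class TestAnnotateConservation:
    def test_all_species_conserve(self):
        block = three_species_block()
        sites = annotate_conservation(block, scan_reference_motifs(block))
        assert sites[0].n_species == 3
        assert sites[0].conserved_species == {"mouse", "rat", "human"}

    def test_gap_inside_hexamer_excludes_species(self):
        block = three_species_block(human_row="GGTAA-CCAA")
        sites = annotate_conservation(block, scan_reference_motifs(block))
        assert sites[0].conserved_species == {"mouse", "rat"}

    def test_n_inside_hexamer_excludes_species(self):
        block = three_species_block(human_row="GGTANTCCAA"[:10])
        sites = annotate_conservation(block, scan_reference_motifs(block))
        assert "human" not in sites[0].conserved_species

    def test_single_species_block(self):
        block = single_row_block("GGTAATCCAA")
        sites = annotate_conservation(block, scan_reference_motifs(block))
        assert sites[0].n_species == 1

    def test_minus_strand_conservation_reads_reverse_complement(self):
        block = AlignmentBlock(
            "mouse", "chr1", 0,
            (("mouse", "CAGGATTACT"), ("rat", "CAGGATTACT")),
        )
        sites = annotate_conservation(block, scan_reference_motifs(block))
        assert sites[0].strand == "-"
        assert sites[0].n_species == 2

    def test_degenerate_position_matches_either_pyrimidine(self):
        # rat carries TAATCT where mouse has TAATCC: both satisfy TAATCY
        block = AlignmentBlock(
            "mouse", "chr1", 0,
            (("mouse", "GGTAATCCAA"), ("rat", "GGTAATCTAA")),
        )
        sites = annotate_conservation(block, scan_reference_motifs(block))
        assert sites[0].n_species == 2

    def test_site_outside_block_raises(self):
        block = single_row_block("GGTAATCCAA")
        rogue = MotifSite("chr1", 100, 106, "+", "TAATCC")
        with pytest.raises(CoordinateError):
            annotate_conservation(block, [rogue])

    def test_removing_a_species_never_increases_counts(self, demo_alignment):
        block, _ = demo_alignment
        sites = annotate_conservation(block, scan_reference_motifs(block))
        for victim in block.species[1:4]:
            reduced = block.drop_species(victim)
            reduced_sites = annotate_conservation(reduced, scan_reference_motifs(reduced))
            for before, after in zip(sites, reduced_sites):
                assert after.n_species <= before.n_species

    def test_conservation_preserved_under_reverse_complement(self, demo_alignment):
        block, _ = demo_alignment
        sites = annotate_conservation(block, scan_reference_motifs(block))
        flipped = block.reverse_complemented()
        flipped_sites = annotate_conservation(flipped, scan_reference_motifs(flipped))
        assert sorted(s.n_species for s in sites) == sorted(s.n_species for s in flipped_sites)


class TestSelectCandidateSites:
    def make_sites(self, counts):
        return [
            MotifSite("chr1", 10 * i, 10 * i + 6, "+", "TAATCC",
                      frozenset(f"sp{j}" for j in range(n)))
            for i, n in enumerate(counts)
        ]

    def test_threshold_six_retains_two_of_three(self):
        assert len(select_candidate_sites(self.make_sites([3, 6, 9]), 6)) == 2

    def test_threshold_one_retains_all(self):
        assert len(select_candidate_sites(self.make_sites([3, 6, 9]), 1)) == 3

    def test_empty_input(self):
        assert select_candidate_sites([], 6) == []

    def test_invalid_threshold(self):
        with pytest.raises(ParameterError):
            select_candidate_sites([], 0)


class TestDesignAmpliconWindow:
    def test_centered_window(self):
        site = MotifSite("chr1", 500, 506, "+", "TAATCC")
        w = design_amplicon_window(site, 10_000, target_len=110)
        assert (w.start, w.end, w.length) == (448, 558, 110)
        assert w.start <= site.start and site.end <= w.end

    def test_shifted_inward_near_left_edge(self):
        site = MotifSite("chr1", 2, 8, "+", "TAATCC")
        w = design_amplicon_window(site, 10_000, target_len=110)
        assert (w.start, w.end) == (0, 110)

    def test_shifted_inward_near_right_edge(self):
        site = MotifSite("chr1", 9_995, 10_001, "+", "TAATCC")
        w = design_amplicon_window(site, 10_001, target_len=110)
        assert (w.start, w.end) == (10_001 - 110, 10_001)
        assert w.start <= site.start and site.end <= w.end

    def test_infeasible_sequence(self):
        site = MotifSite("chr1", 10, 16, "+", "TAATCC")
        with pytest.raises(InfeasibleWindowError):
            design_amplicon_window(site, 50)

    def test_target_length_outside_admissible_range(self):
        site = MotifSite("chr1", 500, 506, "+", "TAATCC")
        with pytest.raises(ParameterError):
            design_amplicon_window(site, 10_000, target_len=200)

    @pytest.mark.parametrize("pos", [0, 3, 40, 100, 4994])
    @pytest.mark.parametrize("target_len", [70, 110, 150])
    def test_length_and_containment_invariants(self, pos, target_len):
        site = MotifSite("chr1", pos, pos + 6, "+", "TAATCC")
        w = design_amplicon_window(site, 5_000, target_len=target_len)
        assert 70 <= w.length <= 150
        assert w.start <= site.start and site.end <= w.end


class TestSelectControlRegions:
    def test_single_far_site_allows_leftmost_region(self):
        sites = [MotifSite("chr1", 5_000, 5_006, "+", "TAATCC")]
        regions = select_control_regions(10_000, sites, n=1)
        assert (regions[0].start, regions[0].end) == (0, 110)

    def test_dense_sites_leave_no_room(self):
        sites = [MotifSite("chr1", p, p + 6, "+", "TAATCC") for p in range(0, 10_000, 500)]
        assert select_control_regions(10_000, sites, n=3) == []

    def test_no_sites_tiles_from_zero(self):
        regions = select_control_regions(10_000, [], n=3)
        assert [(r.start, r.end) for r in regions] == [(0, 110), (110, 220), (220, 330)]

    def test_exclusion_margin_respected(self):
        sites = [MotifSite("chr1", 3_000, 3_006, "+", "TAATCC")]
        for region in select_control_regions(20_000, sites, n=50):
            assert region.end + 1_000 <= 3_000 or region.start >= 3_006 + 1_000
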