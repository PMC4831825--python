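"""G4 scanner vs brute-force oracle, window assignment, CpG masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import g4_scan_oracle
from pol2poise.annotations import GeneModel
from pol2poise.quadruplex import (
    QuadruplexHit,
    assign_windows,
    compare_g4_groups,
    count_g4_per_gene,
    mask_cpg,
    merge_intervals,
    reverse_complement,
    scan_g4,
    scan_g4_both_strands,
)

EDGE_CASES = [
    # canonical 4-run motif
    ("GGGTGGGTGGGTGGG", [(0, 15)]),
    # only 3 runs: no hit
    ("GGGTGGGTGGG", []),
    # 5 runs: both 4-run windows merge into one region
    ("GGGAGGGAGGGAGGGAGGG", [(0, 19)]),
    # loop length exactly 7 (upper bound) is allowed
    ("GGGAAAAAAAGGGTGGGTGGG", [(0, 21)]),
    # loop length 8 breaks the chain
    ("GGGAAAAAAAAGGGTGGGTGGG", []),
    # loop length 1 (lower bound)
    ("GGGAGGGAGGGAGGG", [(0, 15)]),
    # runs of only 2 G never qualify
    ("GGTGGTGGTGG", []),
    # a longer maximal run is one run, not two
    ("GGGGGGTGGGTGGGTGGG", [(0, 18)]),
    # N inside a run splits it below threshold
    ("GGNGTGGGTGGGTGGGTGG", []),
    # N in a loop is fine
    ("GGGNGGGNGGGNGGG", [(0, 15)]),
    # a sub-threshold G-run (GG) inside a loop does not break the chain
    ("GGGAGGAGGGTGGGTGGG", [(0, 18)]),
    # flanking sequence does not join the motif
    ("ATGGGTGGGTGGGTGGGCAT", [(2, 17)]),
    # two well-separated motifs stay separate
    ("GGGTGGGTGGGTGGG" + "A" * 20 + "GGGTGGGTGGGTGGG", [(0, 15), (35, 50)]),
    # C-runs are invisible on the forward strand
    ("CCCACCCACCCACCC", []),
    # empty and tiny sequences
    ("", []),
    ("GGG", []),
]


class TestScanG4:
    @pytest.mark.parametrize("seq,expected", EDGE_CASES)
    def test_edge_cases(self, seq, expected):
        assert scan_g4(seq) == expected

    @pytest.mark.parametrize("seq,expected", EDGE_CASES)
    def test_edge_cases_match_oracle(self, seq, expected):
        assert g4_scan_oracle(seq) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            scan_g4("GGGTXGGG")

    @given(st.text(alphabet="ACGT", max_size=120))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, seq):
        assert scan_g4(seq) == g4_scan_oracle(seq)

    def test_g_rich_random_sequences_match_oracle(self, rng):
        # biased toward G so motifs actually occur
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), p=[0.15, 0.15, 0.55, 0.15], size=80))
            assert scan_g4(seq) == g4_scan_oracle(seq)

    def test_merge_idempotent_and_order_free(self, rng):
        ivs = [(int(s), int(s) + int(l)) for s, l in rng.integers(1, 60, size=(30, 2))]
        merged = merge_intervals(ivs)
        assert merge_intervals(merged) == merged
        rng.shuffle(ivs)
        assert merge_intervals(ivs) == merged


class TestBothStrands:
    def test_c_motif_is_reverse_strand_hit(self):
        hits = scan_g4_both_strands("CCCACCCACCCACCC")
        assert hits == [QuadruplexHit("chr1", 0, 15, "-")]

    def test_g_motif_is_forward_only(self):
        hits = scan_g4_both_strands("GGGTGGGTGGGTGGG")
        assert hits == [QuadruplexHit("chr1", 0, 15, "+")]

    def test_both_strands_compose(self):
        seq = "GGGTGGGTGGGTGGG" + "ATAT" * 5 + "CCCACCCACCCACCC"
        hits = scan_g4_both_strands(seq)
        strands = {(h.start, h.end): h.strand for h in hits}
        assert strands == {(0, 15): "+", (35, 50): "-"}

    def test_offset_shifts_coordinates(self):
        hits = scan_g4_both_strands("GGGTGGGTGGGTGGG", offset=1000)
        assert (hits[0].start, hits[0].end) == (1000, 1015)

    @given(st.text(alphabet="ACGT", max_size=100))
    @settings(max_examples=200, deadline=None)
    def test_strand_symmetry(self, seq):
        """Scanning the reverse complement swaps strands and reflects coords."""
        L = len(seq)
        fwd = scan_g4_both_strands(seq)
        rev = scan_g4_both_strands(reverse_complement(seq))
        flipped = sorted(
            (L - h.end, L - h.start, "+" if h.strand == "-" else "-") for h in rev
        )
        assert sorted((h.start, h.end, h.strand) for h in fwd) == flipped


class TestAssignWindows:
    def test_forward_gene_window_and_strand_rules(self, config):
        gene = GeneModel("NM_1", "chr1", "+", 10000, 16000, "NM")
        hits = [
            QuadruplexHit("chr1", 7500, 7520, "+"),   # upstream, non-template
            QuadruplexHit("chr1", 10100, 10130, "-"),  # downstream, template
        ]
        counts = assign_windows(hits, gene, config)
        assert counts["upstream_nontemplate"] == 1
        assert counts["downstream_template"] == 1
        assert counts["upstream_total"] == 1 and counts["downstream_total"] == 1

    def test_reverse_gene_upstream_is_larger_coordinates(self, config):
        gene = GeneModel("NM_2", "chr1", "-", 9000, 15000, "NM")  # TSS = 15000
        hit = QuadruplexHit("chr1", 15100, 15130, "+")  # opposite of gene strand
        counts = assign_windows([hit], gene, config)
        assert counts["upstream_template"] == 1
        assert counts["downstream_template"] == 0

    def test_boundary_overlap_one_bp(self, config):
        gene = GeneModel("NM_3", "chr1", "+", 50000, 56000, "NM")
        # ends exactly at window start: half-open, no overlap
        touching = QuadruplexHit("chr1", 46980, 47000, "+")
        inside = QuadruplexHit("chr1", 46981, 47001, "+")  # 1 bp inside
        assert assign_windows([touching], gene, config)["upstream_total"] == 0
        assert assign_windows([inside], gene, config)["upstream_total"] == 1

    def test_hit_spanning_tss_counts_in_both_windows(self, config):
        gene = GeneModel("NM_4", "chr1", "+", 30000, 36000, "NM")
        hit = QuadruplexHit("chr1", 29990, 30010, "+")
        counts = assign_windows([hit], gene, config)
        assert counts["upstream_total"] == 1 and counts["downstream_total"] == 1

    def test_totals_use_cross_strand_union(self, config):
        gene = GeneModel("NM_5", "chr1", "+", 30000, 36000, "NM")
        # overlapping hits on opposite strands: two strand-resolved counts,
        # one merged region in the total
        hits = [
            QuadruplexHit("chr1", 29000, 29030, "+"),
            QuadruplexHit("chr1", 29010, 29040, "-"),
        ]
        counts = assign_windows(hits, gene, config)
        assert counts["upstream_nontemplate"] == 1
        assert counts["upstream_template"] == 1
        assert counts["upstream_total"] == 1

    def test_count_g4_per_gene_table(self, config):
        genes = [
            GeneModel("NM_a", "chr1", "+", 10000, 16000, "NM"),
            GeneModel("NM_b", "chr2", "-", 10000, 16000, "NM"),
        ]
        hits = [
            QuadruplexHit("chr1", 9000, 9020, "+"),
            QuadruplexHit("chr2", 16100, 16120, "-"),  # upstream of reverse gene
        ]
        df = count_g4_per_gene(hits, genes, config)
        assert df.set_index("gene_id").loc["NM_a", "upstream_total"] == 1
        assert df.set_index("gene_id").loc["NM_b", "upstream_nontemplate"] == 1


class TestMaskCpg:
    def test_one_bp_overlap_removes(self):
        hit = QuadruplexHit("chr1", 100, 120, "+")
        assert mask_cpg([hit], [("chr1", 119, 200)]) == []

    def test_half_open_boundary_keeps(self):
        hit = QuadruplexHit("chr1", 100, 120, "+")
        assert mask_cpg([hit], [("chr1", 120, 200)]) == [hit]

    def test_empty_cpg_is_identity_and_self_mask_empties(self):
        hits = [
            QuadruplexHit("chr1", 100, 120, "+"),
            QuadruplexHit("chr1", 500, 530, "-"),
        ]
        assert mask_cpg(hits, []) == hits
        assert mask_cpg(hits, [(h.chrom, h.start, h.end) for h in hits]) == []

    def test_output_subset_of_input(self, rng):
        hits = [
            QuadruplexHit("chr1", int(s), int(s) + 20, "+")
            for s in rng.choice(10000, 50, replace=False)
        ]
        cpg = [("chr1", int(s), int(s) + 100) for s in rng.choice(10000, 20, replace=False)]
        masked = mask_cpg(hits, cpg)
        assert set(masked) <= set(hits)


class TestCompareGroups:
    def test_enriched_direction_small_sample(self):
        res = compare_g4_groups([2, 2, 3], [0, 0, 1])
        assert res.direction == "x-enriched"
        assert res.p_value < 0.2  # exact small-sample p, limited power

    def test_identical_groups_null(self):
        res = compare_g4_groups([1, 2, 3], [1, 2, 3])
        assert res.p_value > 0.9

    def test_all_zero_degenerate(self):
        res = compare_g4_groups([0, 0], [0, 0])
        assert res.p_value == 1.0 and res.direction == "undefined"

    def test_median_and_mad(self):
        res = compare_g4_groups([0, 1, 2, 10], [0, 0, 0, 0])
        assert res.median_x == pytest.approx(1.5)
        assert res.mad_x == pytest.approx(1.0)  # median of {1.5, 0.5, 0.5, 8.5}

    def test_planted_rates_recovered(self, rng):
        # higher downstream rate in group x, as planted for poised genes
        x = rng.binomial(1, 0.8, 300)
        y = rng.binomial(1, 0.2, 300)
        res = compare_g4_groups(x, y)
        assert res.direction == "x-enriched" and res.p_value < 0.01
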