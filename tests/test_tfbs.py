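"""PSSM calibration/scanning, enrichment, cluster typing and profiles."""

import numpy as np
import pytest

from enfragility import (GenomicInterval, PSSM, UndefinedStatisticError,
                         calibrate_pssm_threshold, demp_motif_profile,
                         find_clusters, fraction_sites_with_demp,
                         htc_fraction, revcomp, scan_pssm, tfbs_enrichment)
from enfragility.tfbs import HETEROTYPIC, HOMOTYPIC, TFBSHit, cluster_flags


def consensus_pssm(tf, consensus, strong=2.0, weak=-2.0, threshold=None):
    # per-position/base jitter keeps the score distribution fine-grained,
    # like a real position weight matrix
    m = np.full((len(consensus), 4), weak)
    for i, b in enumerate(consensus):
        for j in range(4):
            m[i, j] += 0.11 * ((i + j) % 5) / 5
        m[i, "ACGT".index(b)] = strong + 0.13 * (i % 3)
    return PSSM(tf, m, threshold)


def hit(tf, start, width=8, strand="+"):
    return TFBSHit(tf, GenomicInterval("chr1", start, start + width),
                   strand, 1.0)


def random_seq(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), p=p, size=n))


class TestPSSMValidation:
    def test_too_narrow_rejected(self):
        with pytest.raises(ValueError):
            PSSM("x", np.zeros((3, 4)))

    def test_nonfinite_rejected(self):
        m = np.zeros((5, 4))
        m[0, 0] = np.inf
        with pytest.raises(ValueError):
            PSSM("x", m)


class TestCalibration:
    def test_monotone_in_target_rate(self, rng):
        bg = random_seq(rng, 120_000)
        pssm = consensus_pssm("x", "ACGTTGCATG")
        t_loose = calibrate_pssm_threshold(pssm, bg, target_rate=50)
        t_tight = calibrate_pssm_threshold(pssm, bg, target_rate=5)
        assert t_tight >= t_loose

    def test_held_out_rate_within_poisson_error(self, rng):
        pssm = consensus_pssm("x", "ACGTTGCATG")
        train = random_seq(rng, 200_000)
        pssm.threshold = calibrate_pssm_threshold(pssm, train, target_rate=5)
        held = random_seq(rng, 200_000)
        n_hits = len(scan_pssm(held, pssm))
        expected = 5 * len(held) / 10_000
        assert abs(n_hits - expected) <= 3 * np.sqrt(expected)

    def test_degenerate_matrix_rejected(self, rng):
        bg = random_seq(rng, 120_000)
        pssm = PSSM("flat", np.zeros((6, 4)))
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_pssm_threshold(pssm, bg, target_rate=5)

    def test_uncalibrated_scan_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            scan_pssm("ACGTACGTAC", consensus_pssm("x", "ACGTT"))


class TestScan:
    def test_planted_consensus_found(self, rng):
        cons = "ACGTTGCATG"
        seq = random_seq(rng, 50) + cons + random_seq(rng, 50)
        pssm = consensus_pssm("x", cons, threshold=15.0)
        hits = scan_pssm(seq, pssm)
        assert any(h.interval.start == 50 and h.strand == "+" for h in hits)

    def test_reverse_complement_planted_gives_minus_hit(self, rng):
        cons = "ACGTTGCATG"
        seq = random_seq(rng, 50) + revcomp(cons) + random_seq(rng, 50)
        pssm = consensus_pssm("x", cons, threshold=15.0)
        hits = scan_pssm(seq, pssm)
        assert any(h.interval.start == 50 and h.strand == "-" for h in hits)

    def test_masked_site_not_hit(self, rng):
        cons = "ACGTTGCATG"
        seq = random_seq(rng, 50) + cons.lower() + random_seq(rng, 50)
        pssm = consensus_pssm("x", cons, threshold=15.0)
        assert not any(h.interval.start == 50 for h in scan_pssm(seq, pssm))

    def test_strand_symmetry(self, rng):
        """Scanning the reverse complement mirrors coordinates and swaps
        strands but preserves the hit multiset."""
        seq = random_seq(rng, 400)
        pssm = consensus_pssm("x", "ACGTTG", strong=1.5, weak=-1.0,
                              threshold=5.0)
        fw = scan_pssm(seq, pssm)
        rc = scan_pssm(revcomp(seq), pssm)
        L, w = len(seq), pssm.width
        mirrored = {(L - h.interval.end, "+-"[h.strand == "+"],
                     round(h.score, 9)) for h in rc}
        original = {(h.interval.start, h.strand, round(h.score, 9))
                    for h in fw}
        assert mirrored == original


class TestEnrichment:
    def test_direct_substitution(self):
        assert tfbs_enrichment(10, 2, 1000, 1000) == pytest.approx(5.0)

    def test_equal_densities_give_one(self):
        assert tfbs_enrichment(4, 8, 500, 1000) == pytest.approx(1.0)

    def test_zero_control_guard(self):
        val = tfbs_enrichment(10, 0, 1000, 1000)
        assert val == pytest.approx((10 / 1000) / (0.5 / 1000))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            tfbs_enrichment(1, 1, 0, 100)


class TestSiteFragility:
    def test_multiplicity_counts_once(self):
        hits = [hit("x", 10)]
        assert fraction_sites_with_demp(hits, [11, 12, 13]) == 1.0

    def test_disjoint_sets(self):
        assert fraction_sites_with_demp([hit("x", 10)], [100]) == 0.0

    def test_matches_pairwise_overlap_oracle(self, rng):
        hits = [hit("x", int(s)) for s in rng.integers(0, 500, size=40)]
        demps = sorted(int(p) for p in rng.integers(0, 520, size=30))
        got = fraction_sites_with_demp(hits, demps)
        oracle = sum(
            any(h.interval.start <= p < h.interval.end for p in demps)
            for h in hits) / len(hits)
        assert got == pytest.approx(oracle)


class TestClusters:
    def test_three_same_tf_within_span_is_homotypic(self):
        hits = [hit("A", 0), hit("A", 300), hit("A", 592)]
        clusters = find_clusters(hits)
        assert len(clusters) == 1
        assert clusters[0].type == HOMOTYPIC
        assert clusters[0].span <= 1000

    def test_three_distinct_tfs_within_span_is_heterotypic(self):
        hits = [hit("A", 0), hit("B", 400), hit("C", 892)]
        (c,) = find_clusters(hits)
        assert c.type == HETEROTYPIC

    def test_span_over_limit_is_no_cluster(self):
        hits = [hit("A", 0), hit("A", 600), hit("A", 1192)]
        assert find_clusters(hits) == []

    def test_homotypic_window_not_double_typed(self):
        hits = [hit("A", 0), hit("A", 100), hit("A", 200)]
        clusters = find_clusters(hits)
        assert [c.type for c in clusters] == [HOMOTYPIC]

    def test_two_distinct_tfs_is_untyped_under_strict_reading(self):
        hits = [hit("A", 0), hit("A", 100), hit("B", 200)]
        assert find_clusters(hits) == []

    def test_mixed_layout_flags(self):
        hits = [hit("A", 0), hit("A", 50), hit("A", 100),
                hit("B", 300), hit("C", 360), hit("D", 420)]
        has_homo, has_het = cluster_flags(find_clusters(hits))
        assert has_homo and has_het


class TestHtcFraction:
    def test_all_hits_clustered(self):
        hits = [hit("A", 0), hit("A", 50), hit("A", 100)]
        assert htc_fraction("A", hits, find_clusters(hits)) == 1.0

    def test_no_homotypic_clusters(self):
        hits = [hit("A", 0), hit("A", 2000)]
        assert htc_fraction("A", hits, find_clusters(hits)) == 0.0

    def test_mixed_membership_matches_enumeration(self):
        hits = [hit("A", 0), hit("A", 50), hit("A", 100), hit("A", 5000)]
        clusters = find_clusters(hits)
        assert htc_fraction("A", hits, clusters) == pytest.approx(3 / 4)

    def test_zero_hits_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            htc_fraction("Z", [hit("A", 0)], [])


class TestMotifProfile:
    def test_plus_strand_offset(self):
        profile = demp_motif_profile([hit("x", 10, strand="+")], [13], 8)
        assert profile[3] == 1 and profile.sum() == 1

    def test_minus_strand_mirrored(self):
        profile = demp_motif_profile([hit("x", 10, strand="-")], [13], 8)
        assert profile[8 - 1 - 3] == 1

    def test_sum_equals_containments(self, rng):
        hits = [hit("x", int(s), strand=str(st)) for s, st in
                zip(rng.integers(0, 200, size=20),
                    rng.choice(["+", "-"], size=20))]
        demps = [int(p) for p in rng.integers(0, 210, size=15)]
        profile = demp_motif_profile(hits, demps, 8)
        containments = sum(
            1 for h in hits for p in set(demps)
            if h.interval.start <= p < h.interval.end)
        assert profile.sum() == containments
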