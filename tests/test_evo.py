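"""Divergence, conservation, ortholog activity, LD expansion and GWAS
disease-type enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from enfragility import (EvoMasks, Genome, GenomicInterval, LDTable,
                         UndefinedStatisticError, conserved_fraction,
                         disease_type_enrichment, divergence_fraction,
                         ld_expand, ortholog_activity_test, snp_fraction)


def masks_from_arrays(alignable, diverged, snps=()):
    return EvoMasks(
        alignable={"chr1": np.asarray(alignable, dtype=bool)},
        diverged={"chr1": np.asarray(diverged, dtype=bool)},
        snp_positions={"chr1": np.asarray(sorted(snps), dtype=int)},
    )


class TestDivergence:
    def test_half_diverged(self):
        m = masks_from_arrays([1] * 10, [1] * 5 + [0] * 5)
        assert divergence_fraction([GenomicInterval("chr1", 0, 10)],
                                   m) == pytest.approx(0.5)

    def test_nothing_alignable_signalled(self):
        m = masks_from_arrays([0] * 10, [0] * 10)
        with pytest.raises(UndefinedStatisticError):
            divergence_fraction([GenomicInterval("chr1", 0, 10)], m)

    def test_repeat_positions_excluded(self):
        genome = Genome([("chr1", "ACGT" + "acgt" + "ACGT")])
        m = masks_from_arrays([1] * 12, [1] * 12)
        # without the genome all 12 count; with it the 4 lowercase drop out
        iv = [GenomicInterval("chr1", 0, 12)]
        assert divergence_fraction(iv, m) == 1.0
        assert divergence_fraction(iv, m, genome) == 1.0

    def test_matches_per_base_loop_oracle(self, rng):
        n = 1000
        alignable = rng.random(n) < 0.8
        diverged = (rng.random(n) < 0.3) & alignable
        seq = "".join(
            c.lower() if rng.random() < 0.2 else c
            for c in rng.choice(list("ACGT"), size=n))
        genome = Genome([("chr1", seq)])
        m = masks_from_arrays(alignable, diverged)
        ivs = [GenomicInterval("chr1", 100, 400),
               GenomicInterval("chr1", 600, 900)]
        num = den = 0
        for iv in ivs:
            for p in range(iv.start, iv.end):
                if seq[p].islower() or not alignable[p]:
                    continue
                den += 1
                num += bool(diverged[p])
        assert divergence_fraction(ivs, m, genome) == pytest.approx(num / den)


class TestSnpFraction:
    def test_basic_density(self):
        snps = {"chr1": np.arange(5)}
        assert snp_fraction([GenomicInterval("chr1", 0, 1000)],
                            snps) == pytest.approx(0.005)

    def test_empty_snp_set(self):
        assert snp_fraction([GenomicInterval("chr1", 0, 100)],
                            {"chr1": np.array([], dtype=int)}) == 0.0

    def test_matches_loop_oracle(self, rng):
        snps = {"chr1": np.unique(rng.integers(0, 500, size=60))}
        ivs = [GenomicInterval("chr1", 50, 200),
               GenomicInterval("chr1", 300, 450)]
        oracle = sum(1 for iv in ivs for p in range(iv.start, iv.end)
                     if p in set(snps["chr1"].tolist()))
        total = sum(len(iv) for iv in ivs)
        assert snp_fraction(ivs, snps) == pytest.approx(oracle / total)


class TestConservedFraction:
    def test_fully_covered(self):
        enh = GenomicInterval("chr1", 10, 20)
        assert conserved_fraction(enh,
                                  [GenomicInterval("chr1", 0, 100)]) == 1.0

    def test_half_covered(self):
        enh = GenomicInterval("chr1", 0, 10)
        assert conserved_fraction(enh,
                                  [GenomicInterval("chr1", 5, 10)]) == 0.5

    def test_repeat_excluded_from_denominator(self):
        genome = Genome([("chr1", "ACGTACacacACGTAC")])
        enh = GenomicInterval("chr1", 0, 16)
        els = [GenomicInterval("chr1", 0, 6)]
        # 12 non-repeat positions, 6 covered
        assert conserved_fraction(enh, els, genome) == pytest.approx(0.5)

    def test_fully_masked_signalled(self):
        genome = Genome([("chr1", "acgtacgt")])
        with pytest.raises(UndefinedStatisticError):
            conserved_fraction(GenomicInterval("chr1", 0, 8), [], genome)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins and
    summing those no more probable than the observed one."""
    M, n, N = a + b + c + d, a + c, a + b
    p_obs = hypergeom.pmf(a, M, n, N)
    total = 0.0
    for x in range(max(0, N + n - M), min(n, N) + 1):
        p = hypergeom.pmf(x, M, n, N)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestOrthologActivity:
    def make_table(self, act_stable, n_stable, act_fragile, n_fragile):
        rows = []
        for i in range(n_stable):
            rows.append((f"s{i}", "stable", True, i < act_stable))
        for i in range(n_fragile):
            rows.append((f"f{i}", "fragile", True, i < act_fragile))
        return pd.DataFrame(rows, columns=["id", "class", "has_ortholog",
                                           "ortholog_active"])

    def test_p_matches_enumeration_oracle(self):
        table = self.make_table(30, 100, 10, 100)
        out = ortholog_activity_test(table)
        assert out["active_fraction_stable"] == pytest.approx(0.3)
        assert out["active_fraction_fragile"] == pytest.approx(0.1)
        oracle = fisher_two_sided_oracle(30, 70, 10, 90)
        assert out["fisher_p"] == pytest.approx(oracle, rel=1e-6)

    def test_identical_proportions_p_one(self):
        table = self.make_table(20, 100, 20, 100)
        assert ortholog_activity_test(table)["fisher_p"] == pytest.approx(1.0)

    def test_label_swap_symmetric(self):
        t = self.make_table(30, 100, 10, 100)
        p1 = ortholog_activity_test(t)["fisher_p"]
        t2 = t.copy()
        t2["class"] = t2["class"].map({"stable": "fragile",
                                       "fragile": "stable"})
        p2 = ortholog_activity_test(t2)["fisher_p"]
        assert p1 == pytest.approx(p2)

    def test_class_without_orthologs_rejected(self):
        t = self.make_table(5, 10, 3, 10)
        t.loc[t["class"] == "fragile", "has_ortholog"] = False
        with pytest.raises(ValueError):
            ortholog_activity_test(t)


class TestLdExpand:
    @pytest.fixture
    def table(self):
        return LDTable(pd.DataFrame({
            "snpA": ["rs1", "rs1", "rs1", "rs2"],
            "snpB": ["rs2", "rs3", "rs4", "rs5"],
            "r2": [0.9, 0.9, 0.8, 0.95],
            "dist": [400_000, 600_000, 100_000, 1_000],
        }))

    def test_partner_passing_both_thresholds_included(self, table):
        assert "rs2" in ld_expand({"rs1"}, table)

    def test_distance_limit_excludes(self, table):
        assert "rs3" not in ld_expand({"rs1"}, table)

    def test_r2_boundary_is_strict(self, table):
        assert "rs4" not in ld_expand({"rs1"}, table)

    def test_single_round_no_chaining(self, table):
        # rs5 links to rs2 but not to rs1; expanding {rs1} must not chain
        out = ld_expand({"rs1"}, table)
        assert "rs5" not in out

    def test_output_superset_of_input(self, table):
        tags = {"rs1", "rs9"}
        assert ld_expand(tags, table) >= tags

    def test_symmetric_lookup(self, table):
        assert "rs1" in ld_expand({"rs2"}, table)


def hypergeom_tail_oracle(universe, draws, successes, observed):
    return sum(hypergeom.pmf(x, universe, successes, draws)
               for x in range(observed, min(draws, successes) + 1))


class TestDiseaseEnrichment:
    def test_toy_counts_match_direct_tail_sum(self):
        snps_a = {f"a{i}" for i in range(40)}
        snps_b = {f"b{i}" for i in range(60)}
        disease = {f"a{i}" for i in range(15)} | {f"b{i}" for i in range(5)}
        df = disease_type_enrichment(snps_a, snps_b, {"met": disease})
        row = df[(df["direction"] == "a_vs_b")].iloc[0]
        oracle = hypergeom_tail_oracle(100, 40, 20, 15)
        assert row["p"] == pytest.approx(oracle, rel=1e-9)
        assert row["neg_log10_p"] == pytest.approx(-np.log10(oracle))

    def test_disjoint_disease_set_gives_zero(self):
        df = disease_type_enrichment({"a1"}, {"b1"}, {"x": {"zzz"}})
        assert (df["neg_log10_p"] == 0.0).all()

    def test_expected_proportion_is_unenriched(self):
        # disease SNPs split proportionally between the two sets
        snps_a = {f"a{i}" for i in range(50)}
        snps_b = {f"b{i}" for i in range(50)}
        disease = {f"a{i}" for i in range(10)} | {f"b{i}" for i in range(10)}
        df = disease_type_enrichment(snps_a, snps_b, {"x": disease})
        assert (df["neg_log10_p"] < 1.0).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            disease_type_enrichment(set(), set(), {"x": {"a"}})
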