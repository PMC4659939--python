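"""Loner-SNP diversity, haplotype-diversity F_ST, extremes, and BSA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vicariscan import popdiv as pdv
from vicariscan import radgeno as rg


def matrix_from_genotypes(geno, pops, locus_ids=None, pos=None):
    """SnpMatrix from an (S, n) array of diploid genotype codes:
    0 = ref hom, 1 = het, 2 = alt hom, 3 = third-allele het, -1 missing."""
    geno = np.asarray(geno)
    S, n = geno.shape
    G = np.full((S, n, 2), -1, dtype=np.int8)
    G[geno == 0] = (0, 0)
    G[geno == 1] = (0, 1)
    G[geno == 2] = (1, 1)
    G[geno == 3] = (0, 2)
    lid = np.asarray(locus_ids if locus_ids is not None
                     else [f"L{s}" for s in range(S)], dtype=object)
    pos = np.asarray(pos if pos is not None
                     else np.arange(S) * 10_000 + 1000, dtype=np.int64)
    return rg.SnpMatrix(np.array(["chr1"] * S, dtype=object), pos, lid,
                        ["ACG"] * S, G, [f"i{k}" for k in range(n)],
                        np.asarray(pops, dtype=object))


class TestSnpFst:
    def test_fixed_difference_is_one(self):
        assert pdv.snp_fst([10, 0], [0, 10]) == 1.0

    def test_equal_frequencies_zero(self):
        assert abs(pdv.snp_fst([8, 2], [16, 4])) < 1e-15

    def test_hand_evaluated_example(self):
        # p = 0.8 vs 0.2: h = 0.32 each, H_T = 0.5 -> F_ST = 0.36
        assert abs(pdv.snp_fst([8, 2], [2, 8]) - 0.36) < 1e-12

    def test_matches_formula_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pa, pb = rng.uniform(0.01, 0.99, size=2)
            ha = 2 * pa * (1 - pa)
            hb = 2 * pb * (1 - pb)
            pbar = (pa + pb) / 2
            ht = 2 * pbar * (1 - pbar)
            expect = (ht - (ha + hb) / 2) / ht
            got = pdv.snp_fst([pa, 1 - pa], [pb, 1 - pb])
            assert abs(got - expect) < 1e-12

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_relabel_invariant(self, a0, a1, b0, b1):
        if a0 + a1 == 0 or b0 + b1 == 0:
            return
        f = pdv.snp_fst([a0, a1], [b0, b1])
        assert f == pytest.approx(pdv.snp_fst([b0, b1], [a0, a1]), abs=1e-12)
        assert f == pytest.approx(pdv.snp_fst([a1, a0], [b1, b0]), abs=1e-12)
        # haplotype diversity of a biallelic site never exceeds 0.5
        pa = np.array([a0, a1]) / (a0 + a1)
        assert 1 - (pa ** 2).sum() <= 0.5 + 1e-12

    def test_monomorphic_pair_is_zero(self):
        assert pdv.snp_fst([10, 0], [7, 0]) == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            pdv.snp_fst([0, 0], [5, 5])


class TestLoners:
    def test_multi_snp_loci_excluded_and_minor_count_rule(self):
        pops = ["a"] * 6
        geno = [[1, 1, 0, 0, 0, 0],      # L0 with 2 SNPs: not loners
                [0, 1, 1, 0, 0, 0],
                [1, 0, 0, 0, 0, 0],      # alone but minor count 1: excluded
                [1, 1, 0, 0, 0, 0]]      # alone, minor count 2: loner
        sm = matrix_from_genotypes(geno, pops,
                                   locus_ids=["LA", "LA", "LB", "LC"])
        loners = pdv.find_loner_snps(sm)
        assert list(loners.locus_id) == ["LC"]

    def test_tri_allelic_flag_requires_two_copies(self):
        pops = ["a"] * 8
        geno = [[3, 3, 1, 1, 0, 0, 0, 0],   # third allele twice: tri-allelic
                [3, 1, 1, 1, 0, 0, 0, 0]]   # third allele once: biallelic loner
        sm = matrix_from_genotypes(geno, pops, locus_ids=["LA", "LB"])
        loners = pdv.find_loner_snps(sm)
        assert list(loners.tri_allelic) == [True, False]

    def test_diversity_summary_bounds(self):
        pops = ["a"] * 4 + ["b"] * 4
        geno = [[1, 1, 0, 0, 0, 0, 0, 0],   # polymorphic only in pop a
                [0, 0, 0, 0, 1, 1, 0, 0]]   # polymorphic only in pop b
        sm = matrix_from_genotypes(geno, pops, locus_ids=["LA", "LB"])
        loners = pdv.find_loner_snps(sm)
        prop_a, _ = pdv.diversity_summary(sm, loners, "a")
        prop_all, _ = pdv.diversity_summary(sm, loners, ["a", "b"])
        assert prop_a == 0.5
        assert prop_all == 1.0


class TestFstScan:
    def test_maf_and_coverage_filters(self):
        pops = ["a"] * 20 + ["b"] * 20
        # SNP0: pooled MAF 0.25 -> kept; SNP1: pooled MAF 0.15 -> dropped
        g0 = [1] * 10 + [0] * 10 + [1] * 10 + [0] * 10
        g1 = [1] * 6 + [0] * 14 + [1] * 6 + [0] * 14
        g2 = [1] * 10 + [0] * 10 + [-1] * 10 + [1, 0] * 5   # pop b cov 20 < 21
        sm = matrix_from_genotypes([g0, g1, g2], pops,
                                   locus_ids=["LA", "LB", "LC"])
        tr = pdv.fst_scan(sm, "a", "b")
        assert list(tr.locus_id) == ["LA"]

    def test_one_snp_per_locus_keeps_highest_fst(self):
        pops = ["a"] * 20 + ["b"] * 20
        weak = [1] * 10 + [0] * 10 + [1] * 6 + [0] * 14
        strong = [2] * 20 + [0] * 20
        sm = matrix_from_genotypes([weak, strong], pops,
                                   locus_ids=["LA", "LA"], pos=[100, 150])
        tr = pdv.fst_scan(sm, "a", "b")
        assert len(tr) == 1
        assert tr.pos.iloc[0] == 150

    def test_identical_population_split_has_null_baseline(self, tiny_sim):
        """Splitting one population's individuals at random yields a
        baseline near the permutation null (|median| small)."""
        params, haps, ledger = tiny_sim
        sm = rg.snp_matrix_from_haplotypes(haps, ledger.loci)
        rng = np.random.default_rng(1)
        half = rng.permutation(sm.n_ind)[:sm.n_ind // 2]
        fake = np.array(["half_a"] * sm.n_ind, dtype=object)
        fake[half] = "half_b"
        sm.pops = fake
        tr = pdv.fst_scan(sm, "half_a", "half_b", min_coverage=4,
                          corrected=True)
        assert abs(tr.attrs["baseline"]) < 0.06


class TestExtremes:
    def track(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["chrom", "pos", "locus_id", "fst",
                                           "maf", "n_a", "n_b", "pair"])

    def test_spacing_excludes_nearby_candidates(self):
        t = self.track([("chr1", 1_000_000, "L0", 0.9, 0.3, 40, 40, "x"),
                        ("chr1", 1_100_000, "L1", 0.8, 0.3, 40, 40, "x"),
                        ("chr1", 1_300_000, "L2", 0.7, 0.3, 40, 40, "x")])
        ext = pdv.select_extremes(t, k=25, spacing=200_000)
        assert list(ext.pos) == [1_000_000, 1_300_000]

    def test_duplicates_across_pairings_counted_once(self):
        a = self.track([("chr1", 1_000_000, "L0", 0.9, 0.3, 40, 40, "a")])
        b = self.track([("chr1", 1_000_000, "L0", 0.95, 0.3, 40, 40, "b")])
        ext = pdv.select_extremes([a, b], k=25)
        assert len(ext) == 1
        assert ext.fst.iloc[0] == 0.95
        assert ext.pair.iloc[0] == "b"

    def test_k_limit_and_chromosome_independence(self):
        rows = [("chr%d" % (i % 2 + 1), 10_000 + 500_000 * i, f"L{i}",
                 0.9 - i * 0.01, 0.3, 40, 40, "x") for i in range(30)]
        ext = pdv.select_extremes(self.track(rows), k=25, spacing=200_000)
        assert len(ext) == 25

    def test_sweep_extremes_fall_near_true_sweeps(self, tiny_sim):
        from vicariscan import simcore as sc
        from conftest import small_params

        p = small_params(seed=10, n_loci=200, t_split=40)
        pos = sc.locus_position(p.loci_table(), "chr1", 2_000_000)
        p.sweeps = [sc.SweepSpec("lake", "chr1", pos, 0.5, init_freq=0.2)]
        haps, ledger = sc.simulate_populations(p)
        sm = rg.snp_matrix_from_haplotypes(haps, ledger.loci)
        tr = pdv.fst_scan(sm, "lake", "stream_c", min_coverage=10)
        ext = pdv.select_extremes(tr, k=5, spacing=200_000)
        assert (np.abs(ext.pos - pos) < 500_000).any()


class TestBsa:
    def test_empty_group_rejected(self, tiny_sim):
        import pandas as pd

        params, haps, ledger = tiny_sim
        sm = rg.snp_matrix_from_haplotypes(haps, ledger.loci)
        ph = pd.Series(["low"] * haps.n_ind, index=haps.individuals)
        with pytest.raises(ValueError, match="complete"):
            pdv.bsa_fst_scan(sm, ph, "complete", "low", n_per_group=4)

    def test_random_phenotype_matches_permutation_null(self, tiny_sim):
        import pandas as pd

        params, haps, ledger = tiny_sim
        sm = rg.snp_matrix_from_haplotypes(haps, ledger.loci)
        rng = np.random.default_rng(3)
        ph = pd.Series(rng.choice(["complete", "low"], size=haps.n_ind),
                       index=haps.individuals)
        tr = pdv.bsa_fst_scan(sm, ph, "complete", "low", n_per_group=10,
                              min_coverage=8, seed=0)
        # phenotype independent of genotype: median differentiation ~ null
        assert tr.attrs["baseline"] < 0.08
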