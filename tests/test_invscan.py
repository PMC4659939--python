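"""Inversion detection and characterization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vicariscan import invscan as iv
from vicariscan import simcore as sc
from vicariscan import radgeno as rg


def ratio_track(log2_values, chrom="chr1", window=20_000, missing=()):
    rows = []
    for k, v in enumerate(log2_values):
        if k in missing:
            continue
        rows.append((chrom, k * window + 1, (k + 1) * window, 2.0 ** v, v, 10))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio",
                                     "log2_ratio", "n_loci"])
    df.attrs["window"] = window
    return df


class TestCoverageRatio:
    def test_equal_normalized_coverage_gives_unit_ratio(self, tiny_sim,
                                                        tiny_reads):
        params, haps, ledger = tiny_sim
        pop_map = dict(zip(haps.individuals, haps.pops))
        tr = iv.coverage_ratio_track(tiny_reads, pop_map, "stream_a", "lake",
                                     min_total=50)
        assert abs(np.median(tr.ratio) - 1.0) < 0.15
        assert np.allclose(tr.log2_ratio, np.log2(tr.ratio))

    def test_low_coverage_loci_excluded(self, tiny_sim, tiny_reads):
        params, haps, ledger = tiny_sim
        pop_map = dict(zip(haps.individuals, haps.pops))
        strict = iv.coverage_ratio_track(tiny_reads, pop_map, "stream_a",
                                         "lake", min_total=10**9)
        assert len(strict) == 0

    def test_empty_group_rejected(self, tiny_reads):
        with pytest.raises(ValueError, match="empty"):
            iv.coverage_ratio_track(tiny_reads,
                                    {i: "x" for i in tiny_reads.individuals},
                                    "a", "b")


class TestDetect:
    def test_constructed_run_detected_exactly(self):
        vals = [0.0] * 30 + [-1.3] * 6 + [0.0] * 30
        # jitter so the MAD is positive
        rng = np.random.default_rng(0)
        vals = list(np.asarray(vals) + rng.normal(0, 0.02, len(vals)))
        regions = iv.detect_distortions(ratio_track(vals))
        assert len(regions) == 1
        assert regions[0]["start"] == 30 * 20_000 + 1
        assert regions[0]["end"] == 36 * 20_000
        assert regions[0]["direction"] == "deficit"

    def test_short_runs_ignored(self):
        rng = np.random.default_rng(0)
        vals = list(rng.normal(0, 0.02, 30)) + [-1.3] * 4 + list(rng.normal(0, 0.02, 30))
        assert iv.detect_distortions(ratio_track(vals)) == []

    def test_runs_separated_by_present_windows_stay_separate(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.02, 80)
        base[10:16] = -1.3
        base[19:25] = -1.3           # 3 quiet windows between
        regions = iv.detect_distortions(ratio_track(list(base)))
        assert len(regions) == 2

    def test_single_missing_window_bridged(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.02, 40)
        base[10:17] = -1.3
        regions = iv.detect_distortions(ratio_track(list(base), missing=(13,)))
        assert len(regions) == 1
        assert regions[0]["n_windows"] == 6

    def test_pure_noise_rarely_fires(self):
        hits = 0
        for seed in range(10):
            vals = list(np.random.default_rng(seed).normal(0, 0.05, 250))
            hits += len(iv.detect_distortions(ratio_track(vals))) > 0
        assert hits == 0


class TestMafClassAndBlocks:
    def diagnostic_matrix(self, freq=0.3, n=60, seed=4):
        """40 diagnostic SNPs tracking one 'arrangement' at `freq`, plus
        background SNPs of random frequencies, one per locus."""
        rng = np.random.default_rng(seed)
        carrier = rng.random(n) < freq          # haplotype-level arrangement
        hap2 = rng.random(n) < freq
        S_diag, S_bg = 40, 160
        G = np.zeros((S_diag + S_bg, n, 2), dtype=np.int8)
        pos = np.empty(S_diag + S_bg, dtype=np.int64)
        # diagnostics inside 1.0-1.5 Mb
        dpos = np.sort(rng.choice(np.arange(1_000_000, 1_500_000), S_diag, False))
        for s in range(S_diag):
            G[s, :, 0] = carrier
            G[s, :, 1] = hap2
            pos[s] = dpos[s]
        bpos = np.sort(rng.choice(
            np.concatenate([np.arange(1, 1_000_000), np.arange(1_500_001, 3_000_000)]),
            S_bg, False))
        for s in range(S_bg):
            q = rng.uniform(0.02, 0.5)
            G[S_diag + s, :, 0] = rng.random(n) < q
            G[S_diag + s, :, 1] = rng.random(n) < q
            pos[S_diag + s] = bpos[s]
        order = np.argsort(pos)
        lid = np.array([f"L{k}" for k in range(len(pos))], dtype=object)
        return rg.SnpMatrix(np.array(["chr1"] * len(pos), object), pos[order],
                            lid, ["AT"] * len(pos), G[order],
                            [f"i{k}" for k in range(n)])

    def test_peak_tracks_arrangement_frequency(self):
        sm = self.diagnostic_matrix(freq=0.3)
        lo, hi, peak = iv.maf_peak_class(sm, ("chr1", 1_000_000, 1_500_000), None)
        assert hi - lo == pytest.approx(0.15, abs=0.01)
        assert abs(peak - 0.3) <= 0.075

    def test_no_enriched_peak_flagged(self):
        sm = self.diagnostic_matrix(freq=0.0)   # arrangement absent
        with pytest.raises(ValueError):
            iv.maf_peak_class(sm, ("chr1", 1_000_000, 1_500_000), None)

    def test_breakpoints_snap_to_diagnostic_extent(self):
        sm = self.diagnostic_matrix(freq=0.3)
        lo, hi, peak = iv.maf_peak_class(sm, ("chr1", 1_000_000, 1_500_000), None)
        ref = iv.ld_block_breakpoints(sm, ("chr1", 1_000_000, 1_500_000),
                                      None, (lo, hi))
        in_reg = (sm.pos >= 1_000_000) & (sm.pos <= 1_500_000)
        assert ref["start"] >= 1_000_000 - 20_000
        assert ref["end"] <= 1_500_000 + 20_000
        assert ref["mean_r2"] > 0.9

    def test_impossible_threshold_returns_none(self):
        sm = self.diagnostic_matrix(freq=0.3)
        out = iv.ld_block_breakpoints(sm, ("chr1", 1_000_000, 1_500_000), None,
                                      (0.2, 0.4), block_threshold=1.01)
        assert out is None

    def test_no_class_snps_rejected(self):
        sm = self.diagnostic_matrix(freq=0.3)
        with pytest.raises(ValueError, match="MAF-class"):
            iv.ld_block_breakpoints(sm, ("chr1", 2_500_000, 2_600_000), None,
                                    (0.4999, 0.49995), padding=0)


class TestKaryotyping:
    def test_hom_and_het_patterns(self):
        tm = TestMafClassAndBlocks()
        sm = tm.diagnostic_matrix(freq=0.3, seed=8)
        region = {"chrom": "chr1", "start": 950_000, "end": 1_550_000}
        lo, hi, peak = iv.maf_peak_class(sm, ("chr1", 1_000_000, 1_500_000), None)
        kt = iv.assign_inversion_genotypes(sm, region, (lo, hi), None,
                                           exclusion=0)
        # reconstruct the truth from the generator pattern
        rng = np.random.default_rng(8)
        carrier = rng.random(60) < 0.3
        hap2 = rng.random(60) < 0.3
        dos = carrier.astype(int) + hap2.astype(int)
        truth = np.array(["LL", "SL", "SS"])[dos]
        assert (kt.to_numpy() == truth).all()

    def test_unknown_when_too_few_snps(self):
        tm = TestMafClassAndBlocks()
        sm = tm.diagnostic_matrix(freq=0.3, seed=8)
        region = {"chrom": "chr1", "start": 950_000, "end": 1_550_000}
        kt = iv.assign_inversion_genotypes(sm, region, (0.2, 0.4), None,
                                           exclusion=0, min_snps=10**6)
        assert (kt == "unknown").all()


class TestHomozygoteScan:
    def test_fixed_difference_and_shared_classes(self):
        n = 20
        kt = pd.Series(["SS"] * 8 + ["LL"] * 12,
                       index=[f"i{k}" for k in range(n)])
        G = np.zeros((3, n, 2), dtype=np.int8)
        G[0, :8] = 1                      # fixed difference
        G[1, 0, 0] = 1
        G[1, 10, 0] = 1                   # polymorphic in both: shared
        G[2, 3, 0] = 1
        G[2, 4, 0] = 1                    # polymorphic in SS only: unique-S
        sm = rg.SnpMatrix(np.array(["chr1"] * 3, object),
                          np.array([100, 200, 300], dtype=np.int64),
                          np.array(["LA", "LB", "LC"], object),
                          ["AT"] * 3, G, list(kt.index))
        track, loners = iv.homozygote_group_scan(sm, kt, ("chr1", 1, 1000))
        assert track.fst.iloc[0] == pytest.approx(1.0)
        assert dict(zip(loners.locus_id, loners["class"])) == {
            "LA": "fixed-difference", "LB": "shared", "LC": "unique-S"}

    def test_small_groups_rejected(self):
        kt = pd.Series(["SS"] * 2 + ["LL"] * 2, index=list("abcd"))
        sm = rg.SnpMatrix(np.array(["chr1"], object), np.array([100]),
                          np.array(["L0"], object), ["AT"],
                          np.zeros((1, 4, 2), np.int8), list("abcd"))
        with pytest.raises(ValueError, match="homozygotes"):
            iv.homozygote_group_scan(sm, kt, ("chr1", 1, 1000))


class TestHwe:
    def test_perfect_proportions(self):
        chi2, p = iv.hwe_check((25, 50, 25))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_strong_heterozygote_deficit_rejected(self):
        chi2, p = iv.hwe_check((50, 0, 50))
        # oracle: chi-square with 1 df equals n for complete het deficit at 0.5
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-10
        assert p == pytest.approx(stats.chi2.sf(100.0, 1))

    def test_monomorphic_returns_one(self):
        assert iv.hwe_check((30, 0, 0)) == (0.0, 1.0)

    def test_exact_test_matches_enumeration(self):
        # small counts: compare with direct enumeration of the conditional
        # distribution of heterozygote counts
        n_ss, n_sl, n_ll = 1, 2, 7
        _, p = iv.hwe_check((n_ss, n_sl, n_ll))
        n, na = 10, 4

        def exact(h):
            a = (na - h) // 2
            b = n - a - h
            from math import factorial as f
            return (2 ** h * f(n) / (f(a) * f(h) * f(b))
                    * f(na) * f(2 * n - na) / f(2 * n))
        total = {h: exact(h) for h in range(na % 2, min(na, 2 * n - na) + 1, 2)}
        p_obs = total[n_sl]
        expect = sum(q for q in total.values() if q <= p_obs + 1e-12)
        assert p == pytest.approx(expect, rel=1e-9)


class TestCrossovers:
    def test_single_switch_counted_in_one_interval(self):
        m = 5
        idx = pd.MultiIndex.from_arrays(
            [np.array(["chr1"] * m), np.arange(1, m + 1) * 1000],
            names=["chrom", "pos"])
        tbl = pd.DataFrame(np.zeros((m, 1), dtype=np.int8), index=idx,
                           columns=["F2_000"])
        gam = np.zeros((2, m), dtype=np.int8)
        gam[0, 3:] = 1                   # one switch between markers 2 and 3
        tbl.attrs["gametes"] = gam
        tbl.attrs["founder_genotypes"] = (np.zeros((2, m), np.int8),
                                          np.ones((2, m), np.int8))
        prof = iv.count_crossovers(tbl)
        assert list(prof.crossovers) == [0, 0, 1, 0]
        assert prof.rec_fraction.iloc[2] == pytest.approx(1 / 2)

    def test_no_switches_zero_profile(self):
        m = 4
        idx = pd.MultiIndex.from_arrays(
            [np.array(["chr1"] * m), np.arange(1, m + 1) * 1000],
            names=["chrom", "pos"])
        tbl = pd.DataFrame(index=idx)
        tbl.attrs["gametes"] = np.zeros((6, m), dtype=np.int8)
        tbl.attrs["founder_genotypes"] = (np.zeros((2, m), np.int8),
                                          np.ones((2, m), np.int8))
        assert iv.count_crossovers(tbl).crossovers.sum() == 0
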