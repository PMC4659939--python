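"""Generator: determinism, drift/migration behavior, sweeps, coverage model,
F2 cross and phenotypes."""

import numpy as np
import pytest
from scipy import stats

from vicariscan import simcore as sc
from vicariscan import radgeno as rg
from vicariscan import ldstats as ld
from vicariscan import popdiv as pdv

from conftest import small_params


class TestValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError, match="sizes"):
            small_params(N_lake=1).validate()
        with pytest.raises(ValueError, match="migration"):
            small_params(mig=np.full((4, 4), 0.6)).validate()
        bad = np.zeros((4, 4))
        bad[1, 2] = 0.01
        with pytest.raises(ValueError, match="stream-stream"):
            small_params(mig=bad).validate()

    def test_rejects_sweep_off_locus(self):
        p = small_params()
        locus_free = int(p.loci_table().end.iloc[0]) + 500
        p.sweeps = [sc.SweepSpec("lake", "chr1", locus_free, 0.5)]
        with pytest.raises(ValueError, match="coincides with no RAD locus"):
            p.validate()

    def test_rejects_inversion_frequency_outside_unit(self):
        p = small_params(inversion_specs=[
            sc.InversionSpec("chr1", 100_000, 400_000, stream_freq=1.2)])
        with pytest.raises(ValueError, match="frequency"):
            p.validate()


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        p1, p2 = small_params(), small_params()
        h1, _ = sc.simulate_populations(p1)
        h2, _ = sc.simulate_populations(p2)
        assert np.array_equal(h1.haps, h2.haps)
        assert np.array_equal(h1.site_pos, h2.site_pos)
        r1 = sc.apply_coverage_model(h1, p1)
        r2 = sc.apply_coverage_model(h2, p2)
        assert np.array_equal(r1.count, r2.count)
        assert np.array_equal(r1.hap_code, r2.hap_code)

    def test_different_seed_differs(self):
        h1, _ = sc.simulate_populations(small_params())
        h2, _ = sc.simulate_populations(small_params(seed=4))
        assert h1.n_sites != h2.n_sites or not np.array_equal(h1.haps, h2.haps)


class TestDrift:
    def _median_fst(self, haps, pop_b="stream_a"):
        fa = haps.allele_freq("lake")
        fb = haps.allele_freq(pop_b)
        maf = np.minimum((fa + fb) / 2, 1 - (fa + fb) / 2)
        keep = maf >= 0.05
        vals = [pdv.snp_fst([a, 1 - a], [b, 1 - b])
                for a, b in zip(fa[keep], fb[keep])]
        return float(np.median(vals))

    def test_zero_migration_differentiation_grows(self):
        base = dict(mig=np.zeros((4, 4)), n_loci=200, seed=5, mu=1e-6)
        early, _ = sc.simulate_populations(small_params(t_split=2, **base))
        late, _ = sc.simulate_populations(small_params(t_split=60, **base))
        assert self._median_fst(late) > self._median_fst(early)

    def test_forward_engine_matches_coalescent_oracle(self):
        """Median per-SNP F_ST of the forward engine agrees with an
        independent coalescent simulation of the same demography
        (star-shaped migration, Nm of 1 and 9), within Monte-Carlo spread."""
        import msprime

        N, t = 40, 240
        layout = sc.default_layout(n_loci=200, n_chrom=1, chrom_len=2_000_000)

        def forward(m, seed):
            p = sc.SimParams(seed=seed, n_loci=200, chrom_layout=layout,
                             N_anc=4 * N, N_lake=N, N_stream=(N, N, N),
                             t_split=t, mig=sc.migration_matrix((m, m, m)),
                             n_sample=20, mu=3e-6)
            haps, _ = sc.simulate_populations(p)
            return self._median_fst(haps)

        def oracle(m, seed):
            dem = msprime.Demography()
            dem.add_population(name="lake", initial_size=N)
            for s in ("sa", "sb", "sc"):
                dem.add_population(name=s, initial_size=N)
            dem.add_population(name="anc", initial_size=4 * N)
            for s in ("sa", "sb", "sc"):
                dem.set_migration_rate("lake", s, m)
                dem.set_migration_rate(s, "lake", m)
            dem.add_population_split(time=t, derived=["lake", "sa", "sb", "sc"],
                                     ancestral="anc")
            ts = msprime.sim_ancestry(
                {"lake": 20, "sa": 20, "sb": 20, "sc": 20}, demography=dem,
                sequence_length=2_000_000, recombination_rate=1e-7,
                random_seed=seed)
            ts = msprime.sim_mutations(ts, rate=8e-8,
                                       model=msprime.BinaryMutationModel(),
                                       random_seed=seed + 1)
            G = ts.genotype_matrix()
            fa = G[:, :40].mean(axis=1)
            fb = G[:, 40:80].mean(axis=1)
            maf = np.minimum((fa + fb) / 2, 1 - (fa + fb) / 2)
            keep = maf >= 0.05
            vals = [pdv.snp_fst([a, 1 - a], [b, 1 - b])
                    for a, b in zip(fa[keep], fb[keep])]
            return float(np.median(vals))

        for Nm in (1, 9):
            m = Nm / N
            fw = np.mean([forward(m, s) for s in (1, 2, 3)])
            co = np.mean([oracle(m, s) for s in (11, 13, 15, 17)])
            assert 0.4 < fw / co < 2.5, (Nm, fw, co)

    def test_baseline_fst_decreases_with_migration(self):
        meds = []
        for m in (0.002, 0.02):
            p = small_params(seed=8, t_split=60, n_loci=200, mu=1e-6,
                             mig=sc.migration_matrix((m, m, m)))
            haps, _ = sc.simulate_populations(p)
            meds.append(self._median_fst(haps))
        assert meds[1] < meds[0]


class TestSweeps:
    def test_sweep_fixes_and_erases_lake_diversity(self):
        p = small_params(n_loci=200, t_split=60, mig=np.zeros((4, 4)), seed=6)
        pos = sc.locus_position(p.loci_table(), "chr1", 500_000)
        p.sweeps = [sc.SweepSpec("lake", "chr1", pos, s=0.5, init_freq=0.3)]
        haps, ledger = sc.simulate_populations(p)
        assert ledger.sweeps[0]["fixed"]
        locus = p.loci_table().query("start <= @pos <= end").iloc[0]
        cols = haps.sites_in("chr1", locus.start, locus.end)
        fl = haps.allele_freq("lake")[cols]
        assert np.all((fl == 0) | (fl == 1))
        # streams never received the allele and stay diverse genome-wide
        fs = haps.allele_freq("stream_a")
        assert (2 * fs * (1 - fs)).mean() > 0

    def test_lake_sweeps_produce_vicariance_signature(self):
        """With sweeps only in the lake: lake diversity < stream diversity
        and lake windowed LD > stream windowed LD."""
        layout = sc.default_layout(n_loci=800, n_chrom=1, chrom_len=4_000_000)
        loci = sc.SimParams(n_loci=800, chrom_layout=layout).loci_table()
        sweeps = [sc.SweepSpec("lake", "chr1",
                               sc.locus_position(loci, "chr1", x), 0.5)
                  for x in (700_000, 2_000_000, 3_300_000)]
        p = sc.SimParams(seed=9, n_loci=800, chrom_layout=layout, t_split=50,
                         mig=sc.migration_matrix((0.01, 0.01, 0.01)),
                         sweeps=sweeps)
        haps, ledger = sc.simulate_populations(p)
        fl = haps.allele_freq("lake")
        fs = haps.allele_freq("stream_c")
        assert (2 * fl * (1 - fl)).mean() < (2 * fs * (1 - fs)).mean()
        sm = rg.snp_matrix_from_haplotypes(haps, ledger.loci)
        lake = ld.windowed_r2(sm, "lake")
        stream = ld.windowed_r2(sm, "stream_c")
        assert lake.value.mean() > stream.value.mean()


class TestCoverageModel:
    def test_median_depth_matches_model(self, tiny_sim, tiny_reads):
        # repeat loci pool extra paralog reads; judge depth where clean
        clean = np.setdiff1d(np.arange(len(tiny_reads.loci)),
                             tiny_reads.repeat_loci)
        depth = tiny_reads.depth_matrix()[:, clean].ravel()
        cov = tiny_sim[0].coverage
        model = stats.nbinom(cov.nb_dispersion,
                             cov.nb_dispersion / (cov.nb_dispersion + cov.mean_depth))
        assert abs(np.median(depth) - model.median()) <= 2
        assert abs(np.median(depth) - 38.5) <= 3
        assert abs(depth.mean() - 38.5) < 2

    def test_homozygous_error_free_reads_are_identical(self):
        p = small_params(n_loci=40, N_anc=50, N_lake=4, N_stream=(4, 4, 4),
                         t_split=2, n_sample=2, mu=0.0, seed=1)
        p.coverage = sc.CoverageParams(rho=0.0, error=0.0, repeat_fraction=0.0)
        haps, ledger = sc.simulate_populations(p)
        rt = sc.apply_coverage_model(haps, p, ledger)
        # no variation, no error: every cell has exactly one read haplotype
        cell = rt.ind_idx * len(rt.loci) + rt.locus_idx
        assert len(np.unique(cell)) == len(cell)
        assert not rt.error_haps.any()

    def test_repeat_fraction_creates_multihaplotype_loci(self, tiny_sim, tiny_reads):
        params, haps, ledger = tiny_sim
        rt = tiny_reads
        # loci where some individual shows >2 abundant (count >= 5) haplotypes
        big = rt.count >= 5
        cell_key = rt.ind_idx[big] * len(rt.loci) + rt.locus_idx[big]
        n_abund = np.bincount(cell_key, minlength=len(rt.individuals) * len(rt.loci))
        locus_hit = np.unique(np.flatnonzero(n_abund > 2) % len(rt.loci))
        truth = set(rt.repeat_loci.tolist())
        assert truth and truth.issubset(set(locus_hit.tolist()))
        assert len(truth) == round(params.coverage.repeat_fraction * len(rt.loci))

    def test_reads_trace_to_source_or_error(self, tiny_reads):
        """Mass conservation: every read haplotype is a sample haplotype, a
        repeat paralog (at a flagged repeat locus), or a flagged error."""
        rt = tiny_reads
        err_rows = rt.error_haps[rt.hap_code]
        at_repeat = np.isin(rt.locus_idx, rt.repeat_loci)
        assert rt.count.sum() == rt.count[err_rows].sum() \
            + rt.count[~err_rows].sum()
        # non-error haplotypes at non-repeat loci must match a sample haplotype
        clean = ~err_rows & ~at_repeat
        codes = np.unique(rt.hap_code[clean])
        assert len(codes) > 0


class TestF2Cross:
    @pytest.fixture(scope="class")
    def inversion_sim(self):
        layout = sc.default_layout(n_loci=400, n_chrom=1, chrom_len=5_000_000)
        p = sc.SimParams(seed=12, n_loci=400, chrom_layout=layout,
                         N_anc=400, N_lake=40, N_stream=(40, 40, 40),
                         t_split=30, n_sample=16,
                         inversion_specs=[sc.InversionSpec(
                             "chr1", 3_000_000, 3_500_000, stream_freq=0.4)])
        haps, ledger = sc.simulate_populations(p)
        return p, haps, ledger

    def _parents(self, haps, ledger):
        kt = ledger.inversion_genotypes(haps)
        return kt[kt == "SS"].index[0], kt[kt == "LL"].index[0]

    def test_total_suppression_and_flank_rate(self, inversion_sim):
        from vicariscan import invscan as iv

        p, haps, ledger = inversion_sim
        ss, ll = self._parents(haps, ledger)
        tbl, _ = sc.make_f2_cross(haps, ledger, ss, ll, p, n_offspring=282)
        prof = iv.count_crossovers(tbl)
        inside = prof[(prof.pos_left >= 3_000_000) & (prof.pos_right <= 3_500_000)]
        assert inside.crossovers.sum() == 0
        flank = prof[(prof.pos_right <= 3_000_000) | (prof.pos_left >= 3_500_000)]
        lam = 2 * 282 * p.recomb_rate * (flank.pos_right - flank.pos_left).sum()
        lo, hi = stats.poisson.interval(0.9999, lam)
        assert lo <= flank.crossovers.sum() <= hi

    def test_zero_offspring_gives_empty_table(self, inversion_sim):
        p, haps, ledger = inversion_sim
        ss, ll = self._parents(haps, ledger)
        tbl, _ = sc.make_f2_cross(haps, ledger, ss, ll, p, n_offspring=0)
        assert tbl.shape[1] == 0

    def test_rejects_non_homokaryotypic_parents(self, inversion_sim):
        p, haps, ledger = inversion_sim
        kt = ledger.inversion_genotypes(haps)
        het = kt[kt == "SL"].index[0]
        ll = kt[kt == "LL"].index[0]
        with pytest.raises(ValueError, match="homokaryotypic"):
            sc.make_f2_cross(haps, ledger, het, ll, p)


class TestPhenotypes:
    def test_genotype_map_and_hardy_weinberg(self):
        p = small_params(seed=7, n_loci=200, t_split=10)
        pos = sc.locus_position(p.loci_table(), "chr1", 600_000)
        p.pheno_locus = sc.PhenoLocusSpec(
            "chr1", pos, geno_map={0: "low", 1: "partial", 2: "complete"},
            freqs={"lake": 0.5, "stream": 0.5})
        p.n_sample = 30
        haps, ledger = sc.simulate_populations(p)
        ph = ledger.phenotypes
        col = haps.sites_in("chr1", pos, pos)[0]
        dos = haps.haps[0::2, col] + haps.haps[1::2, col]
        expect = np.array(["low", "partial", "complete"])[dos]
        assert (ph.to_numpy() == expect).all()
        # complete-phenotype (dominant map) frequency ~ Hardy-Weinberg
        q = haps.allele_freq()[col]
        dom = (dos > 0).mean()
        hw = 1 - (1 - q) ** 2
        se = np.sqrt(hw * (1 - hw) / len(dos))
        assert abs(dom - hw) < 5 * se + 0.05

    def test_missing_locus_rejected(self, tiny_sim):
        params, haps, _ = tiny_sim
        bad = sc.SimParams(**{**params.__dict__,
                              "pheno_locus": sc.PhenoLocusSpec("chr1", 17)})
        with pytest.raises(ValueError, match="absent"):
            sc.assign_phenotypes(haps, bad)
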