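import io

import numpy as np
import pandas as pd
import pytest

from vicariscan import simcore as sc
from vicariscan import radgeno as rg


def small_params(**kw):
    """Fast desk-top scenario used by most unit tests."""
    defaults = dict(n_loci=100, N_anc=400, N_lake=30, N_stream=(30, 30, 30),
                    t_split=20, n_sample=8, seed=3, mu=1.5e-6,
                    mig=sc.migration_matrix((0.01, 0.01, 0.01)))
    defaults.update(kw)
    return sc.SimParams(**defaults)


@pytest.fixture(scope="session")
def tiny_sim():
    params = small_params()
    haps, ledger = sc.simulate_populations(params)
    return params, haps, ledger


@pytest.fixture(scope="session")
def tiny_reads(tiny_sim):
    params, haps, ledger = tiny_sim
    return sc.apply_coverage_model(haps, params, ledger)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_sim, tiny_reads):
    params, haps, ledger = tiny_sim
    calls = rg.genotype_read_table(tiny_reads)
    # pooled-coverage threshold scaled to the 32-individual fixture
    return rg.build_snp_matrix(calls, pops=dict(zip(haps.individuals, haps.pops)),
                               min_pooled_coverage=20)


@pytest.fixture
def read_table_factory():
    """Build a ReadTable from {(individual, locus_id): {sequence: count}}.

    Sequences are padded to a common length with 'A'; locus coordinates are
    assigned along one chromosome unless given via `positions`.
    """

    def build(cells, positions=None, chrom="chr1"):
        seq_len = max(len(s) for counts in cells.values() for s in counts)
        rows = []
        loci = sorted({lid for _, lid in cells})
        pos_of = positions or {lid: 1000 + i * 10_000 for i, lid in enumerate(loci)}
        for (ind, lid), counts in sorted(cells.items()):
            for seq, cnt in sorted(counts.items()):
                rows.append((ind, lid, chrom, pos_of[lid],
                             seq.ljust(seq_len, "A"), cnt))
        df = pd.DataFrame(rows, columns=["individual", "locus_id", "chrom",
                                         "pos", "read_seq", "count"])
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        return sc.ReadTable.from_tsv(buf)

    return build


def truth_alleles(haps, reads, snp_matrix):
    """Base letters of the (ancestral, derived) alleles at each SNP of a
    genotyped matrix, plus the matching truth site index (-1 = no site)."""
    name_to_ci = {n: c for c, n in enumerate(haps.chrom_names)}
    key = haps.site_key
    snp_key = np.array([name_to_ci[c] for c in snp_matrix.chrom],
                       np.int64) * 10**9 + snp_matrix.pos
    idx = np.searchsorted(key, snp_key)
    ok = (idx < haps.n_sites) & (key[np.clip(idx, 0, haps.n_sites - 1)] == snp_key)
    site = np.where(ok, idx, -1)
    lid_to_row = {l: i for i, l in enumerate(reads.loci.locus_id)}
    letters = []
    for s in range(snp_matrix.n_snps):
        if site[s] < 0:
            letters.append(None)
            continue
        li = lid_to_row[snp_matrix.locus_id[s]]
        off = snp_matrix.pos[s] - int(reads.loci.start.iloc[li])
        ref = int(reads.ref_seqs[li, off])
        der = int(sc._derived_base(np.array([ref]), np.array([snp_matrix.pos[s]]))[0])
        letters.append(("ACGT"[ref], "ACGT"[der]))
    return site, letters


def diploid_concordance(haps, reads, snp_matrix):
    """Fraction of diploid SNP calls whose unordered allele pair matches the
    truth genotype."""
    site, letters = truth_alleles(haps, reads, snp_matrix)
    agree = total = 0
    for s in range(snp_matrix.n_snps):
        if site[s] < 0 or letters[s] is None:
            continue
        ref, der = letters[s]
        t1 = haps.haps[0::2, site[s]]
        t2 = haps.haps[1::2, site[s]]
        al = snp_matrix.alleles[s]
        G = snp_matrix.G[s]
        dip = (G >= 0).all(axis=1)
        for i in np.flatnonzero(dip):
            called = frozenset((al[G[i, 0]], al[G[i, 1]]))
            truth = frozenset((der if t1[i] else ref, der if t2[i] else ref))
            agree += called == truth
            total += 1
    return agree / total, total
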