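"""Haplotype-based RAD consensus genotyping and SNP-matrix construction.

The whole 89-bp read is the genotyping unit: per (individual, locus) the
distinct read sequences are ranked by count and the consensus genotype is
called from the two dominant read haplotypes, without using base qualities
or a theoretical read-count distribution (allelic counts at heterozygous
loci are overdispersed relative to the binomial, so the het/hom decision is
a plain ratio rule).

Calling rules (exact, integer arithmetic at the boundaries):

* repeat filters, per individual: a locus is excluded if its depth exceeds
  3x the mean locus depth of that individual, or, when polymorphic, if the
  two dominant read haplotypes fail to account for >70% of its reads;
* effective coverage = summed count of the two dominant haplotypes (total
  count when monomorphic);
* effective coverage >= 15: diploid call, heterozygous iff c2/(c1+c2) > 0.25;
* effective coverage in [2, 15): haploid call from the dominant haplotype;
* single-read loci are missing.

Ties in the haplotype ranking are broken lexicographically by sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simcore import ReadTable, _BASE2ASCII

PLOIDY_MISSING = 0
PLOIDY_HAPLOID = 1
PLOIDY_DIPLOID = 2


@dataclass
class ConsensusCall:
    """Consensus genotype of one individual at one RAD locus."""

    locus_id: str
    ploidy: int                   # PLOIDY_* constant
    haplotypes: tuple             # one or two read sequences (empty if missing)
    effective_coverage: int


def call_consensus(counts: dict, locus_id: str = "", min_diploid: int = 15,
                   het_ratio: float = 0.25) -> ConsensusCall:
    """Call the consensus genotype from a {read sequence: count} mapping.

    Pure function of the counts; ranking ties are broken lexicographically.
    """
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    items = [(h, c) for h, c in items if c > 0]
    if not items:
        return ConsensusCall(locus_id, PLOIDY_MISSING, (), 0)
    h1, c1 = items[0]
    h2, c2 = items[1] if len(items) > 1 else (None, 0)
    eff = c1 + c2
    if eff >= min_diploid:
        # c2/(c1+c2) > 0.25  <=>  3*c2 > c1 (exact at the printed boundary)
        if h2 is not None and c2 * (1.0 - het_ratio) > het_ratio * c1:
            return ConsensusCall(locus_id, PLOIDY_DIPLOID, (h1, h2), eff)
        return ConsensusCall(locus_id, PLOIDY_DIPLOID, (h1, h1), eff)
    if eff >= 2:
        return ConsensusCall(locus_id, PLOIDY_HAPLOID, (h1,), eff)
    return ConsensusCall(locus_id, PLOIDY_MISSING, (), eff)


def repeat_filter_mask(rt: ReadTable, depth_factor: float = 3.0,
                       top2_fraction: float = 0.70) -> np.ndarray:
    """Boolean (n_individuals, n_loci) mask of cells retained by the repeat
    filters. Cells without reads are False."""
    n, L = len(rt.individuals), len(rt.loci)
    depth = rt.depth_matrix()
    c1, c2, _ = _top2_counts(rt)
    has = depth > 0
    # mean locus depth per individual over loci with data
    with np.errstate(invalid="ignore"):
        mean_depth = depth.sum(axis=1) / has.sum(axis=1)
    mean_depth = np.nan_to_num(mean_depth)
    keep = has & (depth <= depth_factor * mean_depth[:, None])
    polymorphic = c2 > 0
    # two dominant haplotypes must account for >70% of all reads
    frac_ok = (c1 + c2) * 100 > int(round(top2_fraction * 100)) * depth
    keep &= ~polymorphic | frac_ok
    return keep


def filter_repeat_loci(rt: ReadTable, individual: str, **kw) -> set:
    """Locus ids retained for one individual by the repeat filters."""
    mask = repeat_filter_mask(rt, **kw)
    ii = rt.individuals.index(individual)
    return set(rt.loci.locus_id.to_numpy()[mask[ii]])


def _top2_counts(rt: ReadTable):
    """Per cell: counts and hap codes of the two dominant read haplotypes.

    Ranking is by count descending, then hap code ascending; hap codes are
    lexicographic sequence ranks within a locus by ReadTable construction.
    """
    n, L = len(rt.individuals), len(rt.loci)
    cell = rt.ind_idx * L + rt.locus_idx
    order = np.lexsort((rt.hap_code, -rt.count, cell))
    cell_s = cell[order]
    cnt_s = rt.count[order]
    code_s = rt.hap_code[order]
    first = np.concatenate([[True], np.diff(cell_s) > 0])
    second = np.concatenate([[False], first[:-1]]) & ~first

    c1 = np.zeros((n, L), dtype=np.int64)
    c2 = np.zeros((n, L), dtype=np.int64)
    a1 = np.full((n, L), -1, dtype=np.int64)
    a2 = np.full((n, L), -1, dtype=np.int64)
    i1 = cell_s[first]
    c1.ravel()[i1] = cnt_s[first]
    a1.ravel()[i1] = code_s[first]
    i2 = cell_s[second]
    c2.ravel()[i2] = cnt_s[second]
    a2.ravel()[i2] = code_s[second]
    return c1, c2, (a1, a2)


@dataclass
class ConsensusCalls:
    """Vectorized consensus calls for every (individual, locus) cell."""

    individuals: list
    loci: pd.DataFrame
    ploidy: np.ndarray            # (n, L) int8
    hap1: np.ndarray              # (n, L) hap codes, -1 where absent
    hap2: np.ndarray
    effective_coverage: np.ndarray
    filtered: np.ndarray          # (n, L) cells removed by the repeat filters
    read_table: ReadTable

    def call(self, individual: str, locus_id: str) -> ConsensusCall:
        ii = self.individuals.index(individual)
        ll = int(np.flatnonzero(self.loci.locus_id.to_numpy() == locus_id)[0])
        p = int(self.ploidy[ii, ll])
        haps = ()
        if p == PLOIDY_DIPLOID:
            haps = (self.read_table.hap_seq(self.hap1[ii, ll]),
                    self.read_table.hap_seq(self.hap2[ii, ll]))
        elif p == PLOIDY_HAPLOID:
            haps = (self.read_table.hap_seq(self.hap1[ii, ll]),)
        return ConsensusCall(locus_id, p, haps, int(self.effective_coverage[ii, ll]))

    def coverage_sidecar(self) -> pd.DataFrame:
        n, L = self.ploidy.shape
        ii, ll = np.nonzero(self.ploidy > 0)
        return pd.DataFrame({
            "individual": np.asarray(self.individuals, object)[ii],
            "locus_id": self.loci.locus_id.to_numpy()[ll],
            "ploidy": self.ploidy[ii, ll],
            "effective_coverage": self.effective_coverage[ii, ll],
        })


def genotype_read_table(rt: ReadTable, min_diploid: int = 15,
                        het_ratio: float = 0.25, apply_repeat_filter: bool = True,
                        depth_factor: float = 3.0, top2_fraction: float = 0.70
                        ) -> ConsensusCalls:
    """Consensus-genotype every cell of a read table (vectorized)."""
    n, L = len(rt.individuals), len(rt.loci)
    c1, c2, (a1, a2) = _top2_counts(rt)
    eff = c1 + c2
    het = 100 * c2 * int(round((1 - het_ratio) * 100)) > 100 * c1 * int(round(het_ratio * 100))

    ploidy = np.full((n, L), PLOIDY_MISSING, dtype=np.int8)
    ploidy[eff >= min_diploid] = PLOIDY_DIPLOID
    ploidy[(eff >= 2) & (eff < min_diploid)] = PLOIDY_HAPLOID

    hap1 = np.where(ploidy >= PLOIDY_HAPLOID, a1, -1)
    hap2 = np.full((n, L), -1, dtype=np.int64)
    dip = ploidy == PLOIDY_DIPLOID
    hap2[dip] = np.where(het[dip], a2[dip], a1[dip])

    if apply_repeat_filter:
        keep = repeat_filter_mask(rt, depth_factor, top2_fraction)
        filtered = ~keep & (eff > 0)
        ploidy[~keep] = PLOIDY_MISSING
        hap1[~keep] = -1
        hap2[~keep] = -1
    else:
        filtered = np.zeros((n, L), dtype=bool)
    eff = np.where(ploidy > 0, eff, 0)
    return ConsensusCalls(list(rt.individuals), rt.loci, ploidy, hap1, hap2,
                          eff, filtered, rt)


# ---------------------------------------------------------------------------
# SNP matrix
# ---------------------------------------------------------------------------


@dataclass
class SnpMatrix:
    """Biallelic-or-more SNPs x individuals with per-call ploidy.

    G[s, i] holds the two allele indices of individual i at SNP s (-1 =
    no call; haploid calls use slot 0 only). Within a RAD locus the slot
    order is the consensus read-haplotype phase, so locus-internal
    haplotypes can be reconstructed from consecutive rows.
    """

    chrom: np.ndarray             # (S,) object
    pos: np.ndarray               # (S,) int64, 1-based
    locus_id: np.ndarray          # (S,) object
    alleles: list                 # per SNP: string of base letters, index = code
    G: np.ndarray                 # (S, n, 2) int8
    individuals: list
    pops: np.ndarray = None       # population label per individual

    def __post_init__(self):
        if self.pops is None:
            self.pops = np.array(["pop"] * len(self.individuals), dtype=object)

    @property
    def n_snps(self):
        return len(self.pos)

    @property
    def n_ind(self):
        return len(self.individuals)

    def pop_mask(self, pop) -> np.ndarray:
        """`pop` may be a label, a list of labels, or None (everyone)."""
        if pop is None:
            return np.ones(self.n_ind, dtype=bool)
        pops = [pop] if isinstance(pop, str) else list(pop)
        return np.isin(self.pops, pops)

    def n_alleles(self) -> np.ndarray:
        return np.array([len(a) for a in self.alleles])

    def haploid_coverage(self, ind_mask=None) -> np.ndarray:
        """Called haploid genome copies per SNP (diploid = 2, haploid = 1)."""
        g = self.G if ind_mask is None else self.G[:, ind_mask]
        return (g >= 0).sum(axis=(1, 2))

    def allele_counts(self, ind_mask=None, max_alleles: int = 4) -> np.ndarray:
        """(S, max_alleles) counts of called alleles."""
        g = self.G if ind_mask is None else self.G[:, ind_mask]
        out = np.zeros((self.n_snps, max_alleles), dtype=np.int64)
        s_idx = np.repeat(np.arange(self.n_snps), g.shape[1] * 2)
        vals = g.reshape(self.n_snps, -1).ravel()
        ok = vals >= 0
        np.add.at(out, (s_idx[ok], vals[ok]), 1)
        return out

    def maf(self, ind_mask=None) -> np.ndarray:
        """Minor-allele frequency over called haploid copies (NaN if <2 alleles
        observed or no calls)."""
        ac = self.allele_counts(ind_mask)
        tot = ac.sum(axis=1)
        srt = np.sort(ac, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(tot > 0, (tot - srt[:, -1]) / tot, np.nan)
        return maf

    def dosage(self, ind_mask=None) -> np.ndarray:
        """(S, n) dosage of allele 1, NaN where uncalled; haploid in {0, 1}."""
        g = self.G if ind_mask is None else self.G[:, ind_mask]
        d = np.where(g >= 0, (g == 1).astype(float), np.nan)
        out = np.nansum(d, axis=2)
        out[np.isnan(d[:, :, 0])] = np.nan
        return out

    def diploid_missing_fraction(self, ind_mask=None) -> np.ndarray:
        """Per SNP: fraction of individuals without a diploid call."""
        g = self.G if ind_mask is None else self.G[:, ind_mask]
        dip = (g >= 0).all(axis=2)
        return 1.0 - dip.mean(axis=1)

    def select_snps(self, idx) -> "SnpMatrix":
        idx = np.asarray(idx)
        return SnpMatrix(self.chrom[idx], self.pos[idx], self.locus_id[idx],
                         [self.alleles[i] for i in idx], self.G[idx],
                         self.individuals, self.pops)

    # -- I/O ---------------------------------------------------------------

    def write_vcf(self, path):
        """VCF with within-locus phased GT; haploid calls carry one allele."""
        chroms = pd.unique(self.chrom)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=vicariscan-radgeno\n")
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##INFO=<ID=LID,Number=1,Type=String,Description="RAD locus id">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.individuals) + "\n")
            for s in range(self.n_snps):
                al = self.alleles[s]
                alt = ",".join(al[1:]) if len(al) > 1 else "."
                gts = []
                for i in range(self.n_ind):
                    a, b = self.G[s, i]
                    if a < 0:
                        gts.append(".")
                    elif b < 0:
                        gts.append(str(a))
                    else:
                        gts.append(f"{a}|{b}")
                fh.write(f"{self.chrom[s]}\t{self.pos[s]}\t.\t{al[0]}\t{alt}\t.\tPASS\t"
                         f"LID={self.locus_id[s]}\tGT\t" + "\t".join(gts) + "\n")

    @staticmethod
    def read_vcf(path, pops: dict | None = None) -> "SnpMatrix":
        import pysam

        vf = pysam.VariantFile(path)
        individuals = list(vf.header.samples)
        chrom, pos, lid, alleles, rows = [], [], [], [], []
        for rec in vf:
            chrom.append(rec.chrom)
            pos.append(rec.pos)
            lid.append(rec.info.get("LID", "."))
            al = rec.ref + "".join(a for a in (rec.alts or ()) if a != ".")
            alleles.append(al)
            row = np.full((len(individuals), 2), -1, dtype=np.int8)
            for i, s in enumerate(individuals):
                gt = rec.samples[s]["GT"]
                if gt is None:
                    continue
                vals = [v for v in gt if v is not None]
                for j, v in enumerate(vals[:2]):
                    row[i, j] = v
            rows.append(row)
        G = np.stack(rows) if rows else np.zeros((0, len(individuals), 2), np.int8)
        poparr = None
        if pops is not None:
            poparr = np.array([pops.get(i, "pop") for i in individuals], dtype=object)
        return SnpMatrix(np.array(chrom, object), np.array(pos, np.int64),
                         np.array(lid, object), alleles, G, individuals, poparr)


def snp_matrix_from_haplotypes(haps, loci: pd.DataFrame | None = None) -> SnpMatrix:
    """SnpMatrix directly from phased truth haplotypes (every call diploid,
    fully observed; slot order = haplotype phase). Karyotype pseudo-sites
    are excluded. Useful when a scan should see error-free genotypes."""
    from .simcore import KIND_SNP

    keep = np.flatnonzero(haps.site_kind == KIND_SNP)
    S = len(keep)
    G = np.empty((S, haps.n_ind, 2), dtype=np.int8)
    G[:, :, 0] = haps.haps[0::2][:, keep].T
    G[:, :, 1] = haps.haps[1::2][:, keep].T
    lid = np.array(["."] * S, dtype=object)
    if loci is not None:
        key = haps.site_key[keep]
        name_to_ci = {n: c for c, n in enumerate(haps.chrom_names)}
        lkey = loci.chrom.map(name_to_ci).to_numpy(np.int64) * 10**9
        starts = lkey + loci.start.to_numpy(np.int64)
        ends = lkey + loci.end.to_numpy(np.int64)
        order = np.argsort(starts)
        j = np.searchsorted(starts[order], key, side="right") - 1
        ok = (j >= 0) & (key <= ends[order][np.clip(j, 0, None)])
        lid[ok] = loci.locus_id.to_numpy()[order][j[ok]]
    return SnpMatrix(haps.site_chrom_names()[keep], haps.site_pos[keep].copy(),
                     lid, ["AT"] * S, G, list(haps.individuals),
                     np.asarray(haps.pops, dtype=object))


def build_snp_matrix(calls: ConsensusCalls, pops=None, max_snps_per_locus: int = 6,
                     min_pooled_coverage: int = 80) -> SnpMatrix:
    """Extract SNP columns from the consensus haplotypes, pooled across all
    populations.

    At most `max_snps_per_locus` variant columns are emitted per RAD locus
    (the first by position); SNPs whose pooled haploid consensus coverage is
    below `min_pooled_coverage` are dropped.
    """
    rt = calls.read_table
    n, L = calls.ploidy.shape
    llen = rt.locus_len
    loci = calls.loci
    chrom_arr, pos_arr, lid_arr, alleles_list, G_rows = [], [], [], [], []

    hap1, hap2, ploidy = calls.hap1, calls.hap2, calls.ploidy
    for l in range(L):
        called = ploidy[:, l] > 0
        if not called.any():
            continue
        codes = np.unique(np.concatenate([hap1[called, l],
                                          hap2[called & (ploidy[:, l] == 2), l]]))
        codes = codes[codes >= 0]
        seqs = rt.hap_matrix(codes)
        if seqs.shape[1] != llen:
            raise ValueError(f"inconsistent haplotype lengths at locus {l}")
        # haploid consensus coverage pooled over individuals
        pooled_cov = int((2 * (ploidy[:, l] == 2) + (ploidy[:, l] == 1)).sum())
        if len(codes) < 2 or pooled_cov < min_pooled_coverage:
            continue
        var_cols = np.flatnonzero((seqs != seqs[0]).any(axis=0))
        var_cols = var_cols[:max_snps_per_locus]
        if len(var_cols) == 0:
            continue
        code_pos = {c: k for k, c in enumerate(codes)}
        h1 = np.array([code_pos.get(c, -1) for c in hap1[:, l]])
        h2 = np.array([code_pos.get(c, -1) for c in hap2[:, l]])
        for vc in var_cols:
            col = seqs[:, vc].astype(np.int64)
            b1 = np.where(h1 >= 0, col[np.clip(h1, 0, None)], -1)
            b2 = np.where(h2 >= 0, col[np.clip(h2, 0, None)], -1)
            # allele coding: by descending pooled count, ties by base code
            obs = np.concatenate([b1[b1 >= 0], b2[b2 >= 0]]).astype(np.int64)
            cnt = np.bincount(obs, minlength=4)
            order = [int(b) for b in np.lexsort((np.arange(4), -cnt)) if cnt[b] > 0]
            base_to_code = np.full(4, -1, dtype=np.int8)
            base_to_code[order] = np.arange(len(order))
            al = bytes(order).translate(_BASE2ASCII).decode()
            g = np.full((n, 2), -1, dtype=np.int8)
            m1, m2 = b1 >= 0, b2 >= 0
            g[m1, 0] = base_to_code[b1[m1].astype(int)]
            g[m2, 1] = base_to_code[b2[m2].astype(int)]
            chrom_arr.append(loci.chrom.iloc[l])
            pos_arr.append(int(loci.start.iloc[l]) + int(vc))
            lid_arr.append(loci.locus_id.iloc[l])
            alleles_list.append(al)
            G_rows.append(g)

    if not G_rows:
        G = np.zeros((0, n, 2), dtype=np.int8)
        sm = SnpMatrix(np.array([], object), np.array([], np.int64),
                       np.array([], object), [], G, list(calls.individuals))
    else:
        sm = SnpMatrix(np.array(chrom_arr, object), np.array(pos_arr, np.int64),
                       np.array(lid_arr, object), alleles_list, np.stack(G_rows),
                       list(calls.individuals))
    order = np.lexsort((sm.pos, sm.chrom))
    sm = sm.select_snps(order)
    if pops is not None:
        if isinstance(pops, dict):
            sm.pops = np.array([pops.get(i, "pop") for i in sm.individuals], object)
        else:
            sm.pops = np.asarray(pops, dtype=object)
    return sm
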