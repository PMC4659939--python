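"""Forward-time synthetic-data generator for lake-stream divergence under gene flow.

The generator emulates an ecological-vicariance scenario: four populations
(one lake, three streams) split from a much larger stream-adapted ancestor
and keep exchanging migrants across the lake-stream boundary only. Standing
variation in the ancestor is drawn from the neutral coalescent (msprime);
the post-split phase is an explicit diploid Wright-Fisher process so that
positive selection (sweeps), chromosomal inversions with recombination
suppression in heterokaryotypes, and migration compose mechanistically.

On top of the phased haplotypes, an overdispersed RAD short-read coverage
model produces per-individual, per-locus read-haplotype count tables:
negative-binomial total depth, beta-binomial allelic split, per-base
sequencing error, repeat-element contamination (multi-copy paralog read
pooling), and restriction-site dropout on diverged inversion arrangements.

Coordinates are 1-based; intervals are closed; positions are bp on named
chromosomes throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# site kinds
KIND_SNP = 0
KIND_KARYOTYPE = 1

_CHROM_KEY = 10**9  # encodes (chromosome, position) as one sortable int64
_BASE2ASCII = bytes.maketrans(bytes(range(4)), b"ACGT")
_ASCII2BASE = bytes.maketrans(b"ACGT", bytes(range(4)))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def default_layout(n_loci: int = 2000, n_chrom: int = 2,
                   chrom_len: int = 5_000_000, locus_len: int = 89):
    """Evenly spaced restriction sites, each flanked by a sister pair of RAD loci.

    Returns a list of ``(chrom_name, length, locus_start_positions)``.
    Loci come in sister pairs [s-len, s-1] and [s+1, s+len] around each
    restriction site s, mirroring the paired-flank read stacks of real
    RAD libraries.
    """
    if n_loci % 2:
        raise ValueError("n_loci must be even (sister-pair layout)")
    n_sites = n_loci // 2
    per_chrom = [n_sites // n_chrom + (1 if c < n_sites % n_chrom else 0)
                 for c in range(n_chrom)]
    layout = []
    for c, ns in enumerate(per_chrom):
        spacing = chrom_len / (ns + 1)
        starts = []
        for k in range(ns):
            s = int(round((k + 1) * spacing))
            s = min(max(s, locus_len + 2), chrom_len - locus_len - 1)
            starts.extend([s - locus_len, s + 1])
        layout.append((f"chr{c + 1}", chrom_len, starts))
    return layout


def locus_position(loci: pd.DataFrame, chrom: str, pos: int) -> int:
    """The bp at the center of the RAD locus nearest to (chrom, pos);
    useful for placing sweep or phenotype loci on a locus."""
    sub = loci[loci.chrom == chrom]
    if not len(sub):
        raise ValueError(f"no loci on chromosome {chrom!r}")
    centers = ((sub.start + sub.end) // 2).to_numpy()
    return int(centers[np.argmin(np.abs(centers - pos))])


def migration_matrix(lake_stream_rates=(0.02, 0.01, 0.0025)):
    """Symmetric lake<->stream migration; no direct stream-stream exchange."""
    m = np.zeros((4, 4))
    for i, r in enumerate(lake_stream_rates, start=1):
        m[0, i] = m[i, 0] = r
    return m


@dataclass
class SweepSpec:
    population: str
    chrom: str
    pos: int
    s: float
    start_gen: int = 0
    init_freq: float = 0.05


@dataclass
class InversionSpec:
    chrom: str
    start: int
    end: int
    stream_freq: float = 0.3
    lake_freq: float = 0.0
    divergence: float = 0.02      # per-bp divergence between arrangements
    flux_rate: float = 0.0        # double-crossover rate per heterokaryotype meiosis


@dataclass
class PhenoLocusSpec:
    chrom: str
    pos: int
    # phenotype by dosage of the dominant C allele; default complete dominance
    geno_map: dict = field(default_factory=lambda: {0: "low", 1: "complete", 2: "complete"})
    freqs: dict = field(default_factory=lambda: {"lake": 0.8, "stream": 0.3})


@dataclass
class CoverageParams:
    mean_depth: float = 38.5
    nb_dispersion: float = 10.0   # NB size parameter; var = mu + mu^2/k
    rho: float = 0.1              # beta-binomial intraclass correlation
    error: float = 0.002          # per-base per-read error probability
    repeat_fraction: float = 0.05
    repeat_copies: tuple = (3, 5)  # inclusive range of paralog copy number
    paralog_divergence: float = 0.03
    site_span: int = 20           # effective restriction-site footprint (bp)
    max_mismatches: int = 2       # unique-alignment mismatch tolerance per read


@dataclass
class SimParams:
    """Scenario description.

    The defaults are the desk-scale study conditions used throughout:
    2 chromosomes x 5 Mb, 2,000 sister-paired 89-bp RAD loci, four
    populations of 200 diploids sampled 24 each, a 20x larger ancestor,
    and 100 generations of divergence with lake<->stream gene flow.
    Mutation and recombination rates are rescaled so that the
    population-scaled densities (4*N*mu and 4*N*r per bp) stay in a
    realistic range at these small population sizes.
    """

    n_loci: int = 2000
    locus_len: int = 89
    chrom_layout: list = None
    N_anc: int = 4000
    N_lake: int = 200
    N_stream: tuple = (200, 200, 200)
    t_split: int = 100
    mig: np.ndarray = None
    mu: float = 2.5e-7
    recomb_rate: float = 1e-7
    sweeps: list = field(default_factory=list)
    inversion_specs: list = field(default_factory=list)
    pheno_locus: PhenoLocusSpec | None = None
    coverage: CoverageParams = field(default_factory=CoverageParams)
    pop_names: tuple = ("lake", "stream_a", "stream_b", "stream_c")
    n_sample: int = 24
    stabilize_gain: float = 4.0   # restoring selection on inversion / plate loci
    sweep_tract: int = 400_000    # founder tract copied around introduced alleles
    burnin: int = 0               # optional extra forward WF generations pre-split
    prune_every: int = 20
    seed: int = 1

    def __post_init__(self):
        if self.chrom_layout is None:
            self.chrom_layout = default_layout(self.n_loci, locus_len=self.locus_len)
        if self.mig is None:
            self.mig = migration_matrix()
        self.mig = np.asarray(self.mig, dtype=float)

    @property
    def pop_sizes(self):
        return (self.N_lake,) + tuple(self.N_stream)

    @property
    def chrom_names(self):
        return [c for c, _, _ in self.chrom_layout]

    def loci_table(self) -> pd.DataFrame:
        rows = []
        i = 0
        for chrom, _length, starts in self.chrom_layout:
            for s in starts:
                rows.append((f"L{i:06d}", chrom, int(s), int(s) + self.locus_len - 1))
                i += 1
        return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"])

    def validate(self):
        if any(n < 2 for n in self.pop_sizes) or self.N_anc < 2:
            raise ValueError("all population sizes must be >= 2")
        if self.mig.shape != (4, 4):
            raise ValueError("migration matrix must be 4x4")
        if np.any(self.mig < 0) or np.any(self.mig > 0.5):
            raise ValueError("migration entries must lie in [0, 0.5]")
        off_diag = self.mig[1:, 1:] - np.diag(np.diag(self.mig[1:, 1:]))
        if np.any(off_diag != 0):
            raise ValueError("stream-stream migration must be zero")
        chrom_len = {c: L for c, L, _ in self.chrom_layout}
        for inv in self.inversion_specs:
            if inv.chrom not in chrom_len or not (1 <= inv.start < inv.end <= chrom_len[inv.chrom]):
                raise ValueError(f"inversion interval outside chromosome: {inv}")
            for f in (inv.stream_freq, inv.lake_freq):
                if not 0.0 <= f <= 1.0:
                    raise ValueError("inversion frequency outside [0, 1]")
        loci = self.loci_table()
        for sw in self.sweeps:
            if sw.population not in self.pop_names:
                raise ValueError(f"unknown sweep population {sw.population!r}")
            on_locus = ((loci.chrom == sw.chrom) & (loci.start <= sw.pos)
                        & (sw.pos <= loci.end)).any()
            if not on_locus:
                raise ValueError(f"sweep position {sw.chrom}:{sw.pos} coincides with no RAD locus")
        if self.n_sample > min(self.pop_sizes):
            raise ValueError("n_sample exceeds a population size")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeSet:
    """Phased 0/1 haplotypes at segregating sites, two rows per individual."""

    haps: np.ndarray            # int8 (2n, S)
    site_chrom: np.ndarray      # chromosome index per site
    site_pos: np.ndarray        # 1-based bp per site
    site_kind: np.ndarray       # KIND_SNP / KIND_KARYOTYPE
    chrom_names: list
    individuals: list
    pops: np.ndarray            # population label per individual

    def __post_init__(self):
        assert self.haps.shape[0] == 2 * len(self.individuals)
        if self.n_sites and np.any(np.diff(self.site_key) <= 0):
            raise ValueError("site positions must be strictly increasing within chromosome")

    @property
    def n_ind(self):
        return len(self.individuals)

    @property
    def n_sites(self):
        return self.haps.shape[1]

    @property
    def site_key(self):
        return self.site_chrom.astype(np.int64) * _CHROM_KEY + self.site_pos

    def site_chrom_names(self):
        return np.asarray(self.chrom_names, dtype=object)[self.site_chrom]

    def pop_mask(self, pop) -> np.ndarray:
        """Boolean mask over individuals; `pop` may be a label, a list of
        labels, or None (= every individual)."""
        if pop is None:
            return np.ones(self.n_ind, dtype=bool)
        pops = [pop] if isinstance(pop, str) else list(pop)
        return np.isin(self.pops, pops)

    def hap_rows(self, ind_mask) -> np.ndarray:
        rows = np.repeat(np.flatnonzero(ind_mask) * 2, 2)
        rows[1::2] += 1
        return rows

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        c = self.chrom_names.index(chrom)
        return np.flatnonzero((self.site_chrom == c) & (self.site_pos >= start)
                              & (self.site_pos <= end))

    def select_individuals(self, ind_mask) -> "HaplotypeSet":
        idx = np.flatnonzero(ind_mask)
        return HaplotypeSet(self.haps[self.hap_rows(ind_mask)].copy(),
                            self.site_chrom, self.site_pos, self.site_kind,
                            self.chrom_names,
                            [self.individuals[i] for i in idx], self.pops[idx])

    def genotype_dosage(self) -> np.ndarray:
        """Diploid derived-allele dosage matrix (S, n)."""
        return (self.haps[0::2] + self.haps[1::2]).T

    def allele_freq(self, pop=None) -> np.ndarray:
        rows = self.haps if pop is None else self.haps[self.hap_rows(self.pop_mask(pop))]
        return rows.mean(axis=0)

    def write_vcf(self, path):
        """Phased truth genotypes as a minimal VCF (karyotype sites excluded)."""
        keep = self.site_kind == KIND_SNP
        names = self.site_chrom_names()
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name in self.chrom_names:
                fh.write(f"##contig=<ID={name}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.individuals) + "\n")
            for j in np.flatnonzero(keep):
                gts = "\t".join(f"{self.haps[2*i, j]}|{self.haps[2*i+1, j]}"
                                for i in range(self.n_ind))
                fh.write(f"{names[j]}\t{self.site_pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


@dataclass
class TruthLedger:
    """Ground truth the analysis modules are benchmarked against."""

    loci: pd.DataFrame
    sweeps: list = field(default_factory=list)          # dicts with final_freq/fixed
    inversions: list = field(default_factory=list)      # dicts incl. interval + divergence
    phenotypes: pd.Series | None = None
    repeat_loci: list = field(default_factory=list)     # locus ids with paralog pooling
    dropout_loci: dict = field(default_factory=dict)    # inversion index -> locus ids
    f2_crossovers: list = field(default_factory=list)   # per-gamete (chrom_idx, bp)

    def inversion_genotypes(self, haps: HaplotypeSet, inv_index: int = 0) -> pd.Series:
        """Per-individual karyotype: LL = standard (lake-type) homozygote,
        SS = inverted (stream-type) homozygote, SL = heterokaryotype."""
        inv = self.inversions[inv_index]
        col = _karyotype_column(haps, inv)
        dos = haps.haps[0::2, col] + haps.haps[1::2, col]
        labels = np.array(["LL", "SL", "SS"])[dos]
        return pd.Series(labels, index=haps.individuals, name="karyotype")


def _karyotype_column(haps: HaplotypeSet, inv: dict) -> int:
    c = haps.chrom_names.index(inv["chrom"])
    hit = np.flatnonzero((haps.site_kind == KIND_KARYOTYPE) & (haps.site_chrom == c)
                         & (haps.site_pos == inv["midpoint"]))
    if hit.size != 1:
        raise ValueError("karyotype site not found in haplotype set")
    return int(hit[0])


# ---------------------------------------------------------------------------
# site bookkeeping during the forward phase
# ---------------------------------------------------------------------------


class _Genome:
    """Mutable site table + haplotype matrix used during forward simulation."""

    def __init__(self, haps, chrom_idx, pos, kind, protected):
        self.H = haps
        self.chrom_idx = np.asarray(chrom_idx, dtype=np.int32)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.kind = np.asarray(kind, dtype=np.int8)
        self.protected = np.asarray(protected, dtype=bool)

    @property
    def key(self):
        return self.chrom_idx.astype(np.int64) * _CHROM_KEY + self.pos

    def add_sites(self, chrom_idx, pos, kind, protected, columns):
        self.H = np.concatenate([self.H, columns], axis=1)
        self.chrom_idx = np.concatenate([self.chrom_idx, np.asarray(chrom_idx, np.int32)])
        self.pos = np.concatenate([self.pos, np.asarray(pos, np.int64)])
        self.kind = np.concatenate([self.kind, np.asarray(kind, np.int8)])
        self.protected = np.concatenate([self.protected, np.asarray(protected, bool)])
        self._reorder(np.argsort(self.key, kind="stable"))

    def _reorder(self, order):
        self.H = np.ascontiguousarray(self.H[:, order])
        self.chrom_idx = self.chrom_idx[order]
        self.pos = self.pos[order]
        self.kind = self.kind[order]
        self.protected = self.protected[order]

    def prune(self):
        s = self.H.sum(axis=0, dtype=np.int64)
        keep = self.protected | ((s > 0) & (s < self.H.shape[0]))
        if not keep.all():
            self._reorder(np.flatnonzero(keep))

    def find(self, chrom_idx, pos):
        """Column index of site (chrom, pos), or -1."""
        k = int(chrom_idx) * _CHROM_KEY + int(pos)
        key = self.key
        i = int(np.searchsorted(key, k))
        if i < len(self.pos) and key[i] == k:
            return i
        return -1


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _meiosis(genome: _Genome, parents: np.ndarray, rng,
             chrom_lens: np.ndarray, recomb_rate: float,
             inversions=None, record_crossovers=False):
    """Draw one gamete per entry of `parents` (individual indices into genome.H).

    Crossover counts per chromosome are Poisson with the map length; in
    heterokaryotypes, crossovers falling inside an inversion are discarded
    (single crossovers there yield unbalanced meiotic products), while an
    optional double-crossover gene flux exchanges a short, center-biased
    interior segment. Returns (gametes, crossover_log | None).
    """
    H = genome.H
    n = len(parents)
    n_chrom = len(chrom_lens)
    S = H.shape[1]
    bounds = np.searchsorted(genome.chrom_idx, np.arange(n_chrom + 1))
    starts = rng.integers(0, 2, size=(n, n_chrom), dtype=np.int8)
    ncx = rng.poisson(chrom_lens * recomb_rate, size=(n, n_chrom))

    choice = np.empty((n, S), dtype=np.int8)
    for c in range(n_chrom):
        choice[:, bounds[c]:bounds[c + 1]] = starts[:, c][:, None]

    inv_info = []
    for inv in (inversions or []):
        col = genome.find(inv["chrom_idx"], inv["midpoint"])
        het = H[2 * parents, col] != H[2 * parents + 1, col]
        inv_info.append((inv, het))

    cx_log = [[] for _ in range(n)] if record_crossovers else None

    gi, ci = np.nonzero(ncx)
    for g, c in zip(gi, ci):
        xs = rng.integers(1, chrom_lens[c] + 1, size=ncx[g, c])
        for inv, het in inv_info:
            if inv["chrom_idx"] == c and het[g]:
                xs = xs[(xs < inv["start"]) | (xs >= inv["end"])]
        if xs.size == 0:
            continue
        lo, hi = bounds[c], bounds[c + 1]
        seg_pos = genome.pos[lo:hi]
        for x in xs:
            j = lo + np.searchsorted(seg_pos, x, side="right")
            choice[g, j:hi] ^= 1
        if record_crossovers:
            cx_log[g].extend((c, int(x)) for x in xs)

    # double-crossover gene flux inside inversions of heterokaryotypes
    for inv, het in inv_info:
        rate = inv.get("flux_rate", 0.0)
        if rate <= 0:
            continue
        hit = np.flatnonzero(het & (rng.random(n) < rate))
        c = inv["chrom_idx"]
        lo, hi = bounds[c], bounds[c + 1]
        seg_pos = genome.pos[lo:hi]
        span = inv["end"] - inv["start"]
        for g in hit:
            center = inv["start"] + rng.beta(3.0, 3.0) * span  # biased away from breakpoints
            half = 0.5 * rng.uniform(0.0, 0.1) * span
            a = max(inv["start"] + 1, int(center - half))
            b = min(inv["end"] - 1, int(center + half))
            ja = lo + np.searchsorted(seg_pos, a, side="left")
            jb = lo + np.searchsorted(seg_pos, b, side="right")
            choice[g, ja:jb] ^= 1
            if record_crossovers:
                cx_log[g].extend([(c, a), (c, b)])

    A = H[2 * parents]
    B = H[2 * parents + 1]
    gametes = np.where(choice == 0, A, B)
    return gametes, cx_log


# ---------------------------------------------------------------------------
# forward Wright-Fisher phase
# ---------------------------------------------------------------------------


def _forward_phase(genome, params: SimParams, rng, inversions, sel_targets):
    """Evolve the 4 populations for t_split generations with migration and
    selection (sweeps; frequency-restoring selection on balanced loci)."""
    sizes = params.pop_sizes
    N_tot = sum(sizes)
    pop_of_ind = np.repeat(np.arange(4), sizes)
    pop_inds = [np.flatnonzero(pop_of_ind == i) for i in range(4)]
    chrom_lens = np.array([L for _, L, _ in params.chrom_layout], dtype=np.int64)
    loci = params.loci_table()
    name_to_ci = {name: c for c, name in enumerate(params.chrom_names)}
    loci_chrom_idx = loci.chrom.map(name_to_ci).to_numpy()
    loci_start = loci.start.to_numpy()
    total_bp = len(loci) * params.locus_len

    # backward migration: probability a gamete's parent resides in pop j
    src_prob = params.mig.copy()
    for i in range(4):
        src_prob[i, i] = 0.0
        src_prob[i, i] = 1.0 - src_prob[i].sum()

    for gen in range(params.t_split):
        weights = []
        for i in range(4):
            rows = pop_inds[i]
            w = np.ones(len(rows))
            for t in sel_targets:
                col = genome.find(t["chrom_idx"], t["pos"])
                if col < 0:
                    continue
                dos = genome.H[2 * rows, col].astype(np.int64) + genome.H[2 * rows + 1, col]
                if t["kind"] == "sweep" and t["pop_idx"] == i and gen >= t["start_gen"]:
                    w = w * (1.0 + t["s"]) ** dos
                elif t["kind"] == "stabilize" and t["targets"][i] is not None:
                    p = dos.sum() / (2.0 * len(rows))
                    s_t = params.stabilize_gain * (t["targets"][i] - p)
                    w = w * np.clip(1.0 + s_t, 0.05, None) ** dos
            weights.append(w / w.sum())

        parent1 = np.empty(N_tot, dtype=np.int64)
        parent2 = np.empty(N_tot, dtype=np.int64)
        for i in range(4):
            rows = pop_inds[i]
            for out in (parent1, parent2):
                src = rng.choice(4, size=len(rows), p=src_prob[i])
                for j in range(4):
                    m = src == j
                    if m.any():
                        out[rows[m]] = rng.choice(pop_inds[j], size=int(m.sum()),
                                                  p=weights[j])

        g1, _ = _meiosis(genome, parent1, rng, chrom_lens, params.recomb_rate, inversions)
        g2, _ = _meiosis(genome, parent2, rng, chrom_lens, params.recomb_rate, inversions)
        H_new = np.empty((2 * N_tot, genome.H.shape[1]), dtype=np.int8)
        H_new[0::2] = g1
        H_new[1::2] = g2
        genome.H = H_new

        # new mutations on this generation's gametes (infinite sites within
        # RAD loci; recurrent hits flip the existing allele)
        n_mut = rng.poisson(2 * N_tot * total_bp * params.mu)
        if n_mut:
            m_rows = rng.integers(0, 2 * N_tot, size=n_mut)
            li = rng.integers(0, len(loci), size=n_mut)
            off = rng.integers(0, params.locus_len, size=n_mut)
            chrom_i = loci_chrom_idx[li]
            pos = loci_start[li] + off
            new_cols = {}
            for r, c_i, p in zip(m_rows, chrom_i, pos):
                col = genome.find(c_i, p)
                if col >= 0:
                    if genome.kind[col] == KIND_SNP:
                        genome.H[r, col] ^= 1
                else:
                    new_cols.setdefault((int(c_i), int(p)), []).append(int(r))
            if new_cols:
                keys = sorted(new_cols)
                cols = np.zeros((2 * N_tot, len(keys)), dtype=np.int8)
                for j, kk in enumerate(keys):
                    for r in new_cols[kk]:
                        cols[r, j] ^= 1
                genome.add_sites([k[0] for k in keys], [k[1] for k in keys],
                                 np.zeros(len(keys), dtype=np.int8),
                                 np.zeros(len(keys), dtype=bool), cols)

        if (gen + 1) % params.prune_every == 0:
            genome.prune()

    genome.prune()
    return pop_of_ind


# ---------------------------------------------------------------------------
# scenario initialization
# ---------------------------------------------------------------------------


def _coalescent_standing_variation(params: SimParams, rng) -> _Genome:
    """Neutral ancestral standing variation for the founder generation."""
    import msprime

    N_tot = sum(params.pop_sizes)
    mats, chroms, poss = [], [], []
    for c, (_name, length, starts) in enumerate(params.chrom_layout):
        edges = [0.0]
        rates = []
        for s in sorted(set(starts)):
            a, b = float(s - 1), float(s - 1 + params.locus_len)
            if edges[-1] < a:
                edges.append(a)
                rates.append(0.0)
            if b > edges[-1]:
                edges.append(b)
                rates.append(params.mu)
        if edges[-1] < length:
            edges.append(float(length))
            rates.append(0.0)
        rate_map = msprime.RateMap(position=edges, rate=rates)
        ts = msprime.sim_ancestry(
            samples=N_tot, population_size=params.N_anc,
            sequence_length=length, recombination_rate=params.recomb_rate,
            random_seed=int(rng.integers(1, 2**31 - 1)))
        ts = msprime.sim_mutations(ts, rate=rate_map,
                                   model=msprime.BinaryMutationModel(),
                                   random_seed=int(rng.integers(1, 2**31 - 1)))
        gm = ts.genotype_matrix().astype(np.int8).T        # (2N, S_c)
        pos = ts.tables.sites.position.astype(np.int64) + 1
        mats.append(gm)
        chroms.append(np.full(len(pos), c, dtype=np.int32))
        poss.append(pos)
    H = np.concatenate(mats, axis=1) if mats else np.zeros((2 * N_tot, 0), np.int8)
    return _Genome(H, np.concatenate(chroms), np.concatenate(poss),
                   np.zeros(H.shape[1], dtype=np.int8),
                   np.zeros(H.shape[1], dtype=bool))


def _free_position(genome, chrom_idx, pos):
    """Nudge pos upward until no site occupies it (avoids key collisions)."""
    while genome.find(chrom_idx, pos) >= 0:
        pos += 1
    return pos


def _introduce_allele(genome, rng, rows_by_pop, chrom_idx, pos, freqs, tract):
    """Create (or reuse) a biallelic site and place the derived allele on
    copies of a single founder haplotype at per-population target
    frequencies. Copying a founder tract around the site emulates the
    recent single origin of the allele (long shared haplotype)."""
    col = genome.find(chrom_idx, pos)
    if col < 0:
        new = np.zeros((genome.H.shape[0], 1), dtype=np.int8)
        genome.add_sites([chrom_idx], [pos], [KIND_SNP], [True], new)
        col = genome.find(chrom_idx, pos)
    genome.protected[col] = True
    genome.kind[col] = KIND_SNP
    genome.H[:, col] = 0
    carriers = []
    for pop_i, rows in enumerate(rows_by_pop):
        k = int(round(freqs[pop_i] * len(rows)))
        if k:
            carriers.append(rng.choice(rows, size=k, replace=False))
    carriers = np.concatenate(carriers) if carriers else np.array([], dtype=int)
    if carriers.size:
        template = int(carriers[0])
        seg = np.flatnonzero((genome.chrom_idx == chrom_idx)
                             & (genome.pos >= pos - tract)
                             & (genome.pos <= pos + tract)
                             & (genome.kind == KIND_SNP))
        genome.H[np.ix_(carriers, seg)] = genome.H[template, seg]
        genome.H[carriers, genome.find(chrom_idx, pos)] = 1


def simulate_populations(params: SimParams):
    """Run the full scenario; returns a sampled (HaplotypeSet, TruthLedger)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    chrom_names = params.chrom_names
    loci = params.loci_table()
    ledger = TruthLedger(loci=loci)

    genome = _coalescent_standing_variation(params, rng)
    sizes = params.pop_sizes
    pop_of_ind = np.repeat(np.arange(4), sizes)
    hap_rows_by_pop = [np.flatnonzero(np.repeat(pop_of_ind, 2) == i) for i in range(4)]

    sel_targets = []
    inversions = []

    # --- inversions: single-origin inverted arrangement + fixed divergence
    for inv in params.inversion_specs:
        ci = chrom_names.index(inv.chrom)
        mid = _free_position(genome, ci, (inv.start + inv.end) // 2)
        freqs = [inv.lake_freq] + [inv.stream_freq] * 3
        genome.add_sites([ci], [mid], [KIND_KARYOTYPE], [True],
                         np.zeros((genome.H.shape[0], 1), dtype=np.int8))
        carriers = []
        for pop_i, rows in enumerate(hap_rows_by_pop):
            k = int(round(freqs[pop_i] * len(rows)))
            if k:
                carriers.append(rng.choice(rows, size=k, replace=False))
        carriers = np.concatenate(carriers) if carriers else np.array([], dtype=int)
        if carriers.size:
            interior = np.flatnonzero((genome.chrom_idx == ci) & (genome.pos >= inv.start)
                                      & (genome.pos <= inv.end) & (genome.kind == KIND_SNP))
            template = int(carriers[0])
            genome.H[np.ix_(carriers, interior)] = genome.H[template, interior]
            genome.H[carriers, genome.find(ci, mid)] = 1
            # fixed inter-arrangement divergence restricted to RAD locus bp
            in_inv = loci[(loci.chrom == inv.chrom) & (loci.start >= inv.start)
                          & (loci.end <= inv.end)]
            div_sites = []
            for start in in_inv.start:
                hits = np.flatnonzero(rng.random(params.locus_len) < inv.divergence)
                for off in hits:
                    p = int(start) + int(off)
                    if genome.find(ci, p) < 0:
                        div_sites.append(p)
            if div_sites:
                div_sites = sorted(set(div_sites))
                cols = np.zeros((genome.H.shape[0], len(div_sites)), dtype=np.int8)
                cols[carriers] = 1
                genome.add_sites(np.full(len(div_sites), ci), div_sites,
                                 np.zeros(len(div_sites), dtype=np.int8),
                                 np.ones(len(div_sites), dtype=bool), cols)
        inv_d = {"chrom": inv.chrom, "chrom_idx": ci, "start": inv.start,
                 "end": inv.end, "midpoint": mid, "divergence": inv.divergence,
                 "flux_rate": inv.flux_rate, "stream_freq": inv.stream_freq,
                 "lake_freq": inv.lake_freq}
        inversions.append(inv_d)
        ledger.inversions.append(inv_d)
        sel_targets.append({"kind": "stabilize", "chrom_idx": ci, "pos": mid,
                            "targets": freqs})

    # --- plate phenotype locus
    if params.pheno_locus is not None:
        pl = params.pheno_locus
        ci = chrom_names.index(pl.chrom)
        freqs = [pl.freqs.get("lake", 0.8)] + [pl.freqs.get("stream", 0.3)] * 3
        for i, name in enumerate(params.pop_names):
            if name in pl.freqs:
                freqs[i] = pl.freqs[name]
        _introduce_allele(genome, rng, hap_rows_by_pop, ci, pl.pos, freqs,
                          params.sweep_tract)
        sel_targets.append({"kind": "stabilize", "chrom_idx": ci, "pos": pl.pos,
                            "targets": freqs})

    # --- sweeps from a single standing founder haplotype
    for sw in params.sweeps:
        ci = chrom_names.index(sw.chrom)
        pop_i = params.pop_names.index(sw.population)
        freqs = [0.0] * 4
        freqs[pop_i] = sw.init_freq
        _introduce_allele(genome, rng, hap_rows_by_pop, ci, sw.pos, freqs,
                          params.sweep_tract)
        sel_targets.append({"kind": "sweep", "chrom_idx": ci, "pos": sw.pos,
                            "pop_idx": pop_i, "s": sw.s, "start_gen": sw.start_gen})

    # --- optional panmictic forward burn-in before the split
    if params.burnin:
        burn = dataclasses.replace(params, t_split=params.burnin,
                                   mig=np.zeros((4, 4)), sweeps=[],
                                   inversion_specs=[], pheno_locus=None)
        _forward_phase(genome, burn, rng, [], [])

    pop_of_ind = _forward_phase(genome, params, rng, inversions, sel_targets)

    # --- sample individuals
    sample_idx, pops, names = [], [], []
    for i, (pname, n) in enumerate(zip(params.pop_names, sizes)):
        rows = np.flatnonzero(pop_of_ind == i)
        chosen = np.sort(rng.choice(rows, size=params.n_sample, replace=False))
        sample_idx.extend(chosen.tolist())
        pops.extend([pname] * params.n_sample)
        names.extend(f"{pname}_{k:02d}" for k in range(params.n_sample))
    hap_rows = np.repeat(np.array(sample_idx) * 2, 2)
    hap_rows[1::2] += 1
    Hs = genome.H[hap_rows]

    # keep sites segregating in the sample, plus protected scenario sites
    seg = Hs.sum(axis=0, dtype=np.int64)
    keep = np.flatnonzero(genome.protected | ((seg > 0) & (seg < Hs.shape[0])))
    haps = HaplotypeSet(np.ascontiguousarray(Hs[:, keep]),
                        genome.chrom_idx[keep], genome.pos[keep],
                        genome.kind[keep], chrom_names, names,
                        np.array(pops, dtype=object))

    # --- sweep outcomes in the full populations
    for t in (t for t in sel_targets if t["kind"] == "sweep"):
        col = genome.find(t["chrom_idx"], t["pos"])
        rows = np.flatnonzero(np.repeat(pop_of_ind, 2) == t["pop_idx"])
        f = float(genome.H[rows, col].mean())
        ledger.sweeps.append({"population": params.pop_names[t["pop_idx"]],
                              "chrom": chrom_names[t["chrom_idx"]],
                              "pos": t["pos"], "s": t["s"], "final_freq": f,
                              "fixed": f == 1.0})
    if params.pheno_locus is not None:
        ledger.phenotypes = assign_phenotypes(haps, params)
    return haps, ledger


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def assign_phenotypes(haps: HaplotypeSet, params: SimParams) -> pd.Series:
    """Lateral-plate phenotype from the genotype at the plate locus.

    The map is over dosage of the dominant C allele; the default is
    complete dominance (CC, CL -> complete; LL -> low)."""
    pl = params.pheno_locus
    if pl is None:
        raise ValueError("params.pheno_locus is not set")
    ci = haps.chrom_names.index(pl.chrom)
    hit = np.flatnonzero((haps.site_chrom == ci) & (haps.site_pos == pl.pos)
                         & (haps.site_kind == KIND_SNP))
    if hit.size != 1:
        raise ValueError(f"phenotype locus {pl.chrom}:{pl.pos} absent from simulated sites")
    col = int(hit[0])
    dos = haps.haps[0::2, col] + haps.haps[1::2, col]
    return pd.Series([pl.geno_map[int(d)] for d in dos], index=haps.individuals,
                     name="phenotype")


# ---------------------------------------------------------------------------
# F2 intercross
# ---------------------------------------------------------------------------


def make_f2_cross(haps: HaplotypeSet, ledger: TruthLedger, parent_a: str,
                  parent_b: str, params: SimParams, n_offspring: int = 282,
                  inv_index: int = 0, n_f1: int = 20, seed: int | None = None):
    """F2 intercross between two parents homozygous for alternative
    arrangements of an inversion.

    F1s are heterokaryotypes; crossovers inside the inversion are suppressed
    in F1 meiosis (double-crossover flux at the inversion's configured rate).
    Returns ``(genotype table, TruthLedger)`` where the table holds diploid
    dosages per marker with the phased F2 gametes in ``table.attrs``.
    """
    if not ledger.inversions:
        raise ValueError("no inversion in the scenario")
    inv = dict(ledger.inversions[inv_index])
    rng = np.random.default_rng(params.seed + 7777 if seed is None else seed)

    ia, ib = haps.individuals.index(parent_a), haps.individuals.index(parent_b)
    col = _karyotype_column(haps, inv)
    ka = int(haps.haps[2 * ia, col]) + int(haps.haps[2 * ia + 1, col])
    kb = int(haps.haps[2 * ib, col]) + int(haps.haps[2 * ib + 1, col])
    if {ka, kb} != {0, 2}:
        raise ValueError("parents must be homokaryotypic for alternative inversion types")

    chrom_lens = np.array([L for _, L, _ in params.chrom_layout], dtype=np.int64)
    genome = _Genome(haps.haps[[2 * ia, 2 * ia + 1, 2 * ib, 2 * ib + 1]].copy(),
                     haps.site_chrom, haps.site_pos, haps.site_kind,
                     np.ones(haps.n_sites, dtype=bool))

    cross_ledger = TruthLedger(loci=ledger.loci, inversions=[inv])
    idx = pd.MultiIndex.from_arrays([haps.site_chrom_names(), haps.site_pos],
                                    names=["chrom", "pos"])
    if n_offspring == 0:
        table = pd.DataFrame(index=idx)
        table.attrs["gametes"] = np.zeros((0, haps.n_sites), dtype=np.int8)
        return table, cross_ledger

    # F1 pool: one gamete from each parent per F1
    ga, _ = _meiosis(genome, np.zeros(n_f1, dtype=int), rng, chrom_lens,
                     params.recomb_rate, [inv])
    gb, _ = _meiosis(genome, np.ones(n_f1, dtype=int), rng, chrom_lens,
                     params.recomb_rate, [inv])
    f1 = np.empty((2 * n_f1, genome.H.shape[1]), dtype=np.int8)
    f1[0::2] = ga
    f1[1::2] = gb
    f1_genome = _Genome(f1, genome.chrom_idx, genome.pos, genome.kind,
                        np.ones(genome.H.shape[1], dtype=bool))

    p1 = rng.integers(0, n_f1, size=n_offspring)
    p2 = rng.integers(0, n_f1, size=n_offspring)
    g1, cx1 = _meiosis(f1_genome, p1, rng, chrom_lens, params.recomb_rate,
                       [inv], record_crossovers=True)
    g2, cx2 = _meiosis(f1_genome, p2, rng, chrom_lens, params.recomb_rate,
                       [inv], record_crossovers=True)
    cross_ledger.f2_crossovers = cx1 + cx2

    gametes = np.empty((2 * n_offspring, genome.H.shape[1]), dtype=np.int8)
    gametes[0::2] = g1
    gametes[1::2] = g2
    table = pd.DataFrame((g1 + g2).T.astype(np.int8),
                         columns=[f"F2_{k:03d}" for k in range(n_offspring)])
    table.index = idx
    table.attrs["gametes"] = gametes
    table.attrs["founder_genotypes"] = (
        haps.haps[[2 * ia, 2 * ia + 1]].copy(),
        haps.haps[[2 * ib, 2 * ib + 1]].copy())
    return table, cross_ledger


# ---------------------------------------------------------------------------
# RAD coverage model
# ---------------------------------------------------------------------------


@dataclass
class ReadTable:
    """Per (individual, RAD locus) counts of distinct read haplotypes.

    Read haplotypes are stored compactly as substitutions against a
    per-locus reference sequence. Haplotype codes are sorted by
    (locus, sequence), so a code is also the lexicographic rank of its
    sequence within the locus -- the genotyper's tie-break relies on this.
    """

    individuals: list
    loci: pd.DataFrame                       # locus_id, chrom, start, end
    ind_idx: np.ndarray
    locus_idx: np.ndarray
    hap_code: np.ndarray
    count: np.ndarray
    hap_locus: np.ndarray                    # locus index per hap code
    sub_indptr: np.ndarray                   # CSR over hap codes
    sub_off: np.ndarray
    sub_base: np.ndarray
    ref_seqs: np.ndarray                     # (n_loci, locus_len) uint8 base codes
    error_haps: np.ndarray = None            # bool per hap code: sequencing-error read
    repeat_loci: np.ndarray = None           # truth: locus indices with paralog pooling

    @property
    def locus_len(self):
        return self.ref_seqs.shape[1]

    @property
    def n_haps(self):
        return len(self.hap_locus)

    def hap_matrix(self, codes=None) -> np.ndarray:
        """Realize read-haplotype sequences as base-code rows."""
        codes = np.arange(self.n_haps) if codes is None else np.asarray(codes)
        out = self.ref_seqs[self.hap_locus[codes]].copy()
        lens = self.sub_indptr[codes + 1] - self.sub_indptr[codes]
        rows = np.repeat(np.arange(len(codes)), lens)
        take = _csr_take(self.sub_indptr, codes, lens)
        out[rows, self.sub_off[take]] = self.sub_base[take]
        return out

    def hap_seq(self, code) -> str:
        return self.hap_matrix([code])[0].tobytes().translate(_BASE2ASCII).decode()

    def cell_counts(self, individual, locus_id) -> dict:
        """{read sequence: count} for one individual x locus."""
        ii = self.individuals.index(individual)
        li = int(np.flatnonzero(self.loci.locus_id.to_numpy() == locus_id)[0])
        m = (self.ind_idx == ii) & (self.locus_idx == li)
        return {self.hap_seq(c): int(n) for c, n in zip(self.hap_code[m], self.count[m])}

    def depth_matrix(self) -> np.ndarray:
        """Total read counts per (individual, locus)."""
        out = np.zeros((len(self.individuals), len(self.loci)), dtype=np.int64)
        np.add.at(out, (self.ind_idx, self.locus_idx), self.count)
        return out

    def to_tsv(self, path):
        names = np.asarray(self.individuals, dtype=object)
        mats = self.hap_matrix()
        seqs = np.array([m.tobytes().translate(_BASE2ASCII).decode() for m in mats],
                        dtype=object)
        pd.DataFrame({
            "individual": names[self.ind_idx],
            "locus_id": self.loci.locus_id.to_numpy()[self.locus_idx],
            "chrom": self.loci.chrom.to_numpy()[self.locus_idx],
            "pos": self.loci.start.to_numpy()[self.locus_idx],
            "read_seq": seqs[self.hap_code],
            "count": self.count,
        }).to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path) -> "ReadTable":
        df = pd.read_csv(path, sep="\t")
        individuals = sorted(df.individual.unique())
        loci = (df[["locus_id", "chrom", "pos"]].drop_duplicates("locus_id")
                .rename(columns={"pos": "start"}).sort_values(["chrom", "start"])
                .reset_index(drop=True))
        L = int(df.read_seq.str.len().max())
        loci["end"] = loci.start + L - 1
        ind_map = {v: i for i, v in enumerate(individuals)}
        loc_map = {v: i for i, v in enumerate(loci.locus_id)}
        li = df.locus_id.map(loc_map).to_numpy(np.int64)
        seq_codes = np.frombuffer("".join(df.read_seq).encode().translate(_ASCII2BASE),
                                  dtype=np.uint8).reshape(len(df), L)
        code_of_row, loc_u, seq_u = _unique_locus_seqs(li, seq_codes)
        # reference = first haplotype of each locus (compression device only)
        ref = np.zeros((len(loci), L), dtype=np.uint8)
        seen = np.zeros(len(loci), dtype=bool)
        for h in range(len(loc_u)):
            if not seen[loc_u[h]]:
                seen[loc_u[h]] = True
                ref[loc_u[h]] = seq_u[h]
        indptr, off, base = _subs_csr(seq_u, ref[loc_u])
        return ReadTable(
            individuals=individuals, loci=loci,
            ind_idx=df.individual.map(ind_map).to_numpy(np.int64),
            locus_idx=li, hap_code=code_of_row,
            count=df["count"].to_numpy(np.int64),
            hap_locus=loc_u, sub_indptr=indptr, sub_off=off, sub_base=base,
            ref_seqs=ref)


def _csr_take(indptr, codes, lens):
    """Flat indices into CSR data arrays for the given row codes."""
    nz = lens > 0
    codes, lens = np.asarray(codes)[nz], np.asarray(lens)[nz]
    total = int(lens.sum())
    if total == 0:
        return np.array([], dtype=np.int64)
    starts = indptr[codes]
    d = np.ones(total, dtype=np.int64)
    head = np.zeros(len(codes), dtype=np.int64)
    np.cumsum(lens[:-1], out=head[1:])
    d[head[0]] = starts[0]
    d[head[1:]] = starts[1:] - (starts[:-1] + lens[:-1] - 1)
    return np.cumsum(d)


def _unique_locus_seqs(locus_of_row, seq_codes):
    """Deduplicate (locus, sequence) pairs; codes sorted by locus then sequence."""
    n, L = seq_codes.shape
    buf = np.empty((n, 8 + L), dtype=np.uint8)
    buf[:, :8] = locus_of_row.astype(">i8").view(np.uint8).reshape(n, 8)
    buf[:, 8:] = seq_codes
    v = np.ascontiguousarray(buf).view([("v", np.void, 8 + L)]).ravel()
    _, first, inverse = np.unique(v, return_index=True, return_inverse=True)
    return inverse.astype(np.int64), locus_of_row[first], seq_codes[first]


def _subs_csr(seqs, refs):
    """CSR substitution lists for sequences against per-row references."""
    diffs = seqs != refs
    lens = diffs.sum(axis=1)
    indptr = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum(lens, out=indptr[1:])
    rr, oo = np.nonzero(diffs)
    return indptr, oo.astype(np.int64), seqs[rr, oo]


def _derived_base(ref_base, global_pos):
    """Deterministic non-reference base for the derived allele of a site."""
    return (ref_base.astype(np.int64) + 1 + (global_pos * 1000003) % 3) % 4


def apply_coverage_model(haps: HaplotypeSet, params: SimParams,
                         ledger: TruthLedger | None = None,
                         seed: int | None = None) -> ReadTable:
    """Generate RAD read-haplotype counts for each (individual, locus).

    Total depth per cell is negative binomial; the allelic split is
    beta-binomial with intraclass correlation rho; each read is
    independently mutated at the per-base error probability; a
    repeat_fraction of loci additionally pool reads from 3-5 diverged
    paralog copies; and reads from inverted arrangements drop out at loci
    whose restriction site is disrupted by inter-type divergence.
    """
    cov = params.coverage
    rng = np.random.default_rng(params.seed + 10_001 if seed is None else seed)
    loci = ledger.loci if ledger is not None else params.loci_table()
    L = len(loci)
    n = haps.n_ind
    locus_len = params.locus_len
    name_to_ci = {name: c for c, name in enumerate(haps.chrom_names)}
    loci_ci = loci.chrom.map(name_to_ci).to_numpy(np.int64)
    loci_start = loci.start.to_numpy(np.int64)
    loci_end = loci.end.to_numpy(np.int64)

    ref_rng = np.random.default_rng([params.seed, 424242])
    ref_seqs = ref_rng.integers(0, 4, size=(L, locus_len), dtype=np.uint8)

    # --- per-locus site columns and distinct sample haplotype patterns
    site_key = haps.site_key
    snp = haps.site_kind == KIND_SNP
    lo = np.searchsorted(site_key, loci_ci * _CHROM_KEY + loci_start)
    hi = np.searchsorted(site_key, loci_ci * _CHROM_KEY + loci_end, side="right")

    H = haps.haps
    pat_of_row = np.zeros((2 * n, L), dtype=np.int64)   # global clean-pattern code
    pat_seqs = []                                       # per locus (d, locus_len)
    pat_locus = []
    base = 0
    for l in range(L):
        cols = np.arange(lo[l], hi[l])
        cols = cols[snp[cols]]
        if len(cols) == 0:
            inv = np.zeros(2 * n, dtype=np.int64)
            seqs = ref_seqs[l][None, :].copy()
        else:
            if len(cols) <= 62:
                codes = H[:, cols].astype(np.int64) @ (1 << np.arange(len(cols), dtype=np.int64))
                _, first, inv = np.unique(codes, return_index=True, return_inverse=True)
                pat = H[first][:, cols]
            else:
                pat, inv = np.unique(H[:, cols], axis=0, return_inverse=True)
            d = pat.shape[0]
            seqs = np.repeat(ref_seqs[l][None, :], d, axis=0)
            offs = (haps.site_pos[cols] - loci_start[l]).astype(np.int64)
            der = _derived_base(ref_seqs[l, offs], haps.site_pos[cols])
            for k in range(pat.shape[1]):
                seqs[pat[:, k] == 1, offs[k]] = der[k]
        pat_of_row[:, l] = inv.ravel() + base
        base += seqs.shape[0]
        pat_seqs.append(seqs)
        pat_locus.append(np.full(seqs.shape[0], l, dtype=np.int64))
    n_clean = base

    # --- repeat paralogs (high-copy repeat families)
    n_repeat = int(round(cov.repeat_fraction * L))
    repeat_loci = np.sort(rng.choice(L, size=n_repeat, replace=False)) \
        if n_repeat else np.array([], dtype=np.int64)
    par_seqs, par_locus = [], []
    for l in repeat_loci:
        n_copies = int(rng.integers(cov.repeat_copies[0], cov.repeat_copies[1] + 1))
        for _ in range(n_copies - 1):
            s = ref_seqs[l].copy()
            nm = max(1, rng.binomial(locus_len, cov.paralog_divergence))
            offs = rng.choice(locus_len, size=nm, replace=False)
            s[offs] = (s[offs] + rng.integers(1, 4, size=nm)) % 4
            par_seqs.append(s)
            par_locus.append(l)
    n_par = len(par_seqs)

    seq_bank = np.concatenate([np.concatenate(pat_seqs, axis=0)]
                              + ([np.stack(par_seqs)] if n_par else []), axis=0)
    bank_locus = np.concatenate([np.concatenate(pat_locus)]
                                + ([np.array(par_locus, dtype=np.int64)] if n_par else []))

    # --- inversion dropout loci (restriction-site disruption on the
    #     diverged arrangement removes its reads entirely at those loci)
    inv_list = ledger.inversions if ledger is not None else []
    inverted_rows = np.zeros((2 * n, len(inv_list)), dtype=bool)
    dropout = np.zeros((L, len(inv_list)), dtype=bool)
    for v, inv in enumerate(inv_list):
        col = _karyotype_column(haps, inv)
        inverted_rows[:, v] = haps.haps[:, col] == 1
        ci = name_to_ci[inv["chrom"]]
        inside = np.flatnonzero((loci_ci == ci) & (loci_start >= inv["start"])
                                & (loci_end <= inv["end"]))
        # two alignment-failure routes for reads of the diverged arrangement:
        # a disrupted restriction site (no read at all), or more inherited
        # mismatches against the reference than unique alignment tolerates
        p_drop = 1.0 - (1.0 - inv["divergence"]) ** cov.site_span
        dropout[inside, v] = rng.random(len(inside)) < p_drop
        if inverted_rows[:, v].any() and not inverted_rows[:, v].all():
            f_inv = H[inverted_rows[:, v]].mean(axis=0)
            f_std = H[~inverted_rows[:, v]].mean(axis=0)
            fixed_diff = np.abs(f_inv - f_std) > 0.8
            for li in inside:
                cols = np.arange(lo[li], hi[li])
                cols = cols[snp[cols]]
                if fixed_diff[cols].sum() > cov.max_mismatches:
                    dropout[li, v] = True
        if ledger is not None:
            ledger.dropout_loci[v] = loci.locus_id.to_numpy()[
                inside[dropout[inside, v]]].tolist()
    if ledger is not None:
        ledger.repeat_loci = loci.locus_id.to_numpy()[repeat_loci].tolist()

    # --- depths
    k = cov.nb_dispersion
    p_nb = k / (k + cov.mean_depth)
    D = rng.negative_binomial(k, p_nb, size=(n, L))
    if cov.rho > 0:
        a = (1.0 / cov.rho - 1.0) / 2.0
        q = rng.beta(a, a, size=(n, L))
    else:
        q = np.full((n, L), 0.5)
    D1 = rng.binomial(D, q)
    D2 = D - D1

    for v in range(len(inv_list)):
        drop_l = np.flatnonzero(dropout[:, v])
        if len(drop_l):
            D1[:, drop_l] = np.where(inverted_rows[0::2, v][:, None], 0, D1[:, drop_l])
            D2[:, drop_l] = np.where(inverted_rows[1::2, v][:, None], 0, D2[:, drop_l])

    # --- source rows: (individual, locus, source haplotype in bank, depth)
    ii = np.repeat(np.arange(n), L)
    ll = np.tile(np.arange(L), n)
    src_ind = [ii, ii]
    src_loc = [ll, ll]
    src_bank = [pat_of_row[2 * ii, ll], pat_of_row[2 * ii + 1, ll]]
    src_depth = [D1[ii, ll], D2[ii, ll]]
    for j in range(n_par):
        l = par_locus[j]
        src_ind.append(np.arange(n))
        src_loc.append(np.full(n, l))
        src_bank.append(np.full(n, n_clean + j))
        src_depth.append(rng.negative_binomial(k, p_nb, size=n))
    src_ind = np.concatenate(src_ind)
    src_loc = np.concatenate(src_loc)
    src_bank = np.concatenate(src_bank)
    src_depth = np.concatenate(src_depth)
    keep = src_depth > 0
    src_ind, src_loc, src_bank, src_depth = (x[keep] for x in
                                             (src_ind, src_loc, src_bank, src_depth))

    # --- sequencing errors: iid per-base errors on every read
    p_any = 1.0 - (1.0 - cov.error) ** locus_len
    n_err = rng.binomial(src_depth, p_any)
    clean_depth = src_depth - n_err
    total_err = int(n_err.sum())
    err_src = np.repeat(np.arange(len(src_depth)), n_err)
    if total_err:
        mm = np.arange(1, 7)
        pm = stats.binom.pmf(mm, locus_len, cov.error)
        pm /= pm.sum()
        m_per_read = rng.choice(mm, size=total_err, p=pm)
        err_off = rng.integers(0, locus_len, size=int(m_per_read.sum()))
        err_read_id = np.repeat(np.arange(total_err), m_per_read)
        err_seqs = seq_bank[src_bank[err_src]].copy()
        cur = err_seqs[err_read_id, err_off]
        err_seqs[err_read_id, err_off] = (cur + rng.integers(1, 4, size=len(err_off))) % 4
    else:
        err_seqs = np.zeros((0, locus_len), dtype=np.uint8)

    # --- global haplotype codes: identical (locus, sequence) pairs merge,
    #     so an error that recreates a true haplotype is counted with it
    all_seq = np.concatenate([seq_bank, err_seqs], axis=0)
    all_loc = np.concatenate([bank_locus, src_loc[err_src]])
    inverse, hap_locus_u, hap_seq_u = _unique_locus_seqs(all_loc, all_seq)
    n_bank = seq_bank.shape[0]

    rows_ind = np.concatenate([src_ind, src_ind[err_src]])
    rows_loc = np.concatenate([src_loc, src_loc[err_src]])
    rows_cnt = np.concatenate([clean_depth, np.ones(total_err, dtype=np.int64)])
    rows_code = np.concatenate([inverse[:n_bank][src_bank], inverse[n_bank:]])

    is_err = np.ones(len(hap_locus_u), dtype=bool)
    is_err[np.unique(inverse[:n_bank])] = False

    # --- aggregate counts per (individual, locus, haplotype)
    n_uniq = len(hap_locus_u)
    key = (rows_ind * L + rows_loc) * n_uniq + rows_code
    nz = rows_cnt > 0
    key, rows_cnt = key[nz], rows_cnt[nz]
    order = np.argsort(key, kind="stable")
    key, rows_cnt = key[order], rows_cnt[order]
    grp = np.flatnonzero(np.concatenate([[True], np.diff(key) > 0]))
    agg_key = key[grp]
    agg_cnt = np.add.reduceat(rows_cnt, grp)
    out_code = agg_key % n_uniq
    cell = agg_key // n_uniq
    out_loc = cell % L
    out_ind = cell // L

    indptr, sub_off, sub_base = _subs_csr(hap_seq_u, ref_seqs[hap_locus_u])
    return ReadTable(individuals=list(haps.individuals), loci=loci.copy(),
                     ind_idx=out_ind, locus_idx=out_loc, hap_code=out_code,
                     count=agg_cnt.astype(np.int64), hap_locus=hap_locus_u,
                     sub_indptr=indptr, sub_off=sub_off, sub_base=sub_base,
                     ref_seqs=ref_seqs, error_haps=is_err, repeat_loci=repeat_loci)
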