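"""Inversion detection and characterization.

Large, diverged inversions leave a multi-layered footprint in RAD data:

1. differential read-alignment success of the two arrangements distorts
   the stream:lake locus coverage ratio over many adjacent 20-kb windows;
2. SNPs fixed between the arrangements segregate at a minor-allele
   frequency mirroring the minor arrangement's frequency, producing an
   enriched, narrow MAF class;
3. those MAF-class SNPs form an extended block of near-perfect LD whose
   outermost members refine the physical breakpoints;
4. diagnostic SNPs inside the refined region (away from the breakpoints)
   genotype each individual's karyotype, enabling Hardy-Weinberg checks,
   homozygote-pool differentiation scans for central double-crossover gene
   flux, and crossover counting in an F2 intercross.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .radgeno import SnpMatrix
from .simcore import ReadTable
from .popdiv import _fst_vec, find_loner_snps
from .ldstats import _pair_r2


# ---------------------------------------------------------------------------
# coverage-ratio scan
# ---------------------------------------------------------------------------


def coverage_ratio_track(rt: ReadTable, pop_map: dict, stream_pop, lake_pop,
                         window: int = 20_000, min_total: int = 200,
                         chrom_lengths: dict | None = None) -> pd.DataFrame:
    """Mean per-locus normalized stream:lake coverage ratio in
    non-overlapping windows.

    Per-locus coverage is normalized by each population's library total
    before the ratio, removing sequencing-effort differences; loci with
    pooled raw coverage below `min_total` are excluded. Windows without
    retained loci are absent (missing).
    """
    pops = np.array([pop_map[i] for i in rt.individuals], dtype=object)
    depth = rt.depth_matrix()                      # (n_ind, L)
    s_mask = np.isin(pops, [stream_pop] if isinstance(stream_pop, str) else stream_pop)
    l_mask = np.isin(pops, [lake_pop] if isinstance(lake_pop, str) else lake_pop)
    if not s_mask.any() or not l_mask.any():
        raise ValueError("empty population group")
    s_cov = depth[s_mask].sum(axis=0).astype(float)
    l_cov = depth[l_mask].sum(axis=0).astype(float)
    total = depth.sum(axis=0)
    keep = (total >= min_total) & (l_cov > 0)
    s_norm = s_cov / s_cov.sum()
    l_norm = l_cov / l_cov.sum()
    ratio = np.full(len(keep), np.nan)
    ratio[keep] = s_norm[keep] / l_norm[keep]

    loci = rt.loci
    mid = (loci.start.to_numpy() + loci.end.to_numpy()) // 2
    win = (mid - 1) // window
    df = pd.DataFrame({"chrom": loci.chrom, "win": win, "ratio": ratio}).dropna()
    g = df.groupby(["chrom", "win"], sort=True)["ratio"].agg(["mean", "size"]).reset_index()
    out = pd.DataFrame({
        "chrom": g.chrom, "start": g.win * window + 1, "end": (g.win + 1) * window,
        "ratio": g["mean"], "log2_ratio": np.log2(g["mean"]), "n_loci": g["size"],
    })
    out.attrs["window"] = window
    return out


def detect_distortions(track: pd.DataFrame, min_run: int = 5,
                       robust_z: float = 3.0) -> list:
    """Candidate inversion regions: maximal runs of >= `min_run` adjacent
    windows whose |log2 ratio - genome median| exceeds `robust_z` scaled
    MADs. Runs separated by a single missing window are merged.
    """
    if len(track) < min_run:
        return []
    window = track.attrs.get("window",
                             int(track.end.iloc[0] - track.start.iloc[0] + 1))
    x = track.log2_ratio.to_numpy(float)
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    if mad == 0:
        return []
    deviant = np.abs(x - med) > robust_z * mad

    regions = []
    for chrom in pd.unique(track.chrom):
        sub = track[track.chrom == chrom]
        widx = (sub.start.to_numpy() - 1) // window
        present = set(widx.tolist())
        dev = deviant[track.chrom.to_numpy() == chrom]
        run = []          # row positions of the current run
        last_w = None
        for k in range(len(sub)):
            w = widx[k]
            if dev[k]:
                if run:
                    gap = w - last_w - 1       # windows between deviant ones
                    missing_gap = sum(1 for g in range(last_w + 1, w)
                                      if g not in present)
                    # a present non-deviant window breaks the run; up to one
                    # missing window is bridged
                    if gap - missing_gap > 0 or missing_gap > 1:
                        _close_run(regions, run, sub, chrom, min_run)
                        run = []
                run.append(k)
                last_w = w
            elif run:
                _close_run(regions, run, sub, chrom, min_run)
                run = []
        if run:
            _close_run(regions, run, sub, chrom, min_run)
    return regions


def _close_run(regions, run, sub, chrom, min_run):
    if len(run) < min_run:
        return
    rows = sub.iloc[run]
    regions.append({
        "chrom": chrom,
        "start": int(rows.start.iloc[0]),
        "end": int(rows.end.iloc[-1]),
        "n_windows": len(run),
        "mean_log2_ratio": float(rows.log2_ratio.mean()),
        "direction": "deficit" if rows.log2_ratio.mean() < 0 else "excess",
    })


# ---------------------------------------------------------------------------
# MAF-class analysis
# ---------------------------------------------------------------------------


def _region_snps(matrix: SnpMatrix, region, population, min_minor: int = 2):
    """One SNP per RAD locus inside the region, called in the population:
    the SNP with the highest within-population haplotype diversity."""
    chrom, start, end = region
    mask = matrix.pop_mask(population)
    in_reg = (matrix.chrom == chrom) & (matrix.pos >= start) & (matrix.pos <= end)
    ac = matrix.allele_counts(mask)
    tot = ac.sum(axis=1)
    minor = tot - ac.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ac / tot[:, None]
        h = 1 - np.nansum(p ** 2, axis=1)
    keep = in_reg & (minor >= min_minor) & (tot > 0)
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        return idx, np.array([])
    df = pd.DataFrame({"i": idx, "lid": matrix.locus_id[idx], "h": h[idx]})
    df = (df.sort_values(["lid", "h"], ascending=[True, False])
            .groupby("lid", as_index=False).head(1))
    idx = np.sort(df.i.to_numpy())
    maf = minor[idx] / tot[idx]
    return idx, maf


def maf_peak_class(matrix: SnpMatrix, region, population, width: float = 0.15,
                   bin_width: float = 0.025, min_snps: int = 5):
    """MAF interval (`width` wide) centred on the frequency bin most
    enriched in the region relative to the population's genome-wide MAF
    distribution.

    Returns ``(lo, hi, peak)``; raises ValueError when the region has too
    few polymorphic SNPs or shows no enriched peak (e.g. the population is
    fixed for one arrangement).
    """
    idx, maf_region = _region_snps(matrix, region, population)
    if len(idx) < min_snps:
        raise ValueError("too few polymorphic SNPs in region for MAF analysis")
    _, maf_genome = _genome_mafs(matrix, population)
    edges = np.arange(0.0, 0.5 + bin_width, bin_width)
    h_reg, _ = np.histogram(maf_region, bins=edges)
    h_gen, _ = np.histogram(maf_genome, bins=edges)
    p_reg = h_reg / h_reg.sum()
    p_gen = h_gen / max(h_gen.sum(), 1)
    enrich = p_reg - p_gen
    b = int(np.argmax(enrich))
    if enrich[b] <= 0:
        raise ValueError("no enriched MAF peak in region")
    peak = float((edges[b] + edges[b + 1]) / 2)
    lo = max(peak - width / 2, np.nextafter(0.0, 1.0))
    hi = min(peak + width / 2, 0.5)
    return lo, hi, peak


def _genome_mafs(matrix: SnpMatrix, population):
    mask = matrix.pop_mask(population)
    ac = matrix.allele_counts(mask)
    tot = ac.sum(axis=1)
    minor = tot - ac.max(axis=1)
    keep = (minor >= 2) & (tot > 0)
    df = pd.DataFrame({"lid": matrix.locus_id[keep],
                       "maf": minor[keep] / tot[keep]})
    df = df.groupby("lid", as_index=False).head(1)
    return None, df.maf.to_numpy()


# ---------------------------------------------------------------------------
# LD-block breakpoint refinement
# ---------------------------------------------------------------------------


def ld_block_breakpoints(matrix: SnpMatrix, region, population, maf_class,
                         padding: int = 500_000, block_threshold: float = 0.8,
                         min_block: int = 3):
    """Refine inversion breakpoints as the outermost SNPs of the longest
    contiguous block of MAF-class SNPs with mean pairwise R2 >=
    `block_threshold` (unphased dosage correlation).
    """
    chrom, start, end = region
    lo, hi = maf_class
    mask = matrix.pop_mask(population)
    idx, maf = _region_snps(matrix, (chrom, start - padding, end + padding),
                            population)
    sel = (maf >= lo) & (maf <= hi)
    idx = idx[sel]
    if len(idx) == 0:
        raise ValueError("no MAF-class SNPs in padded region")
    order = np.argsort(matrix.pos[idx])
    idx = idx[order]
    m = len(idx)
    D = matrix.dosage(mask)
    ii, jj = np.triu_indices(m, k=1)
    r2 = _pair_r2(D, idx[ii], idx[jj])
    R = np.zeros((m, m))
    R[ii, jj] = np.nan_to_num(r2)
    R += R.T

    # MAF-class membership is necessary but not sufficient: neutral SNPs
    # whose MAF happens to fall in the class dilute the block. Keep only
    # SNPs tightly linked (R2 >= threshold) to the most connected class
    # SNP before searching for the contiguous block.
    if m > 2:
        seed = int(np.argmax(R.sum(axis=1)))
        keep = (R[seed] >= block_threshold) | (np.arange(m) == seed)
        if keep.sum() >= min_block:
            idx = idx[keep]
            R = R[np.ix_(keep, keep)]
            m = len(idx)

    # 2D prefix sums give O(1) block pair-sums; pick the longest block
    # (ties: highest mean) with mean pairwise R2 above threshold
    P = np.zeros((m + 1, m + 1))
    P[1:, 1:] = np.cumsum(np.cumsum(R, axis=0), axis=1)
    best = None
    for a in range(m):
        for b in range(a + min_block - 1, m):
            npairs = (b - a + 1) * (b - a) / 2
            s = (P[b + 1, b + 1] - P[a, b + 1] - P[b + 1, a] + P[a, a]) / 2
            mean = s / npairs
            if mean >= block_threshold:
                key = (b - a, mean)
                if best is None or key > best[0]:
                    best = (key, a, b)
    if best is None:
        return None
    _, a, b = best
    return {
        "chrom": chrom,
        "start": int(matrix.pos[idx[a]]),
        "end": int(matrix.pos[idx[b]]),
        "n_snps": b - a + 1,
        "mean_r2": float(best[0][1]),
        "snp_idx": idx[a:b + 1],
    }


# ---------------------------------------------------------------------------
# karyotyping and diagnostics
# ---------------------------------------------------------------------------


def assign_inversion_genotypes(matrix: SnpMatrix, refined_region, maf_class,
                               focal_pop, exclusion: int = 20_000,
                               min_snps: int = 10) -> pd.Series:
    """Per-individual karyotype from diagnostic SNPs.

    Diagnostic SNPs are MAF-class SNPs (in the focal stream population)
    inside the refined region, at least `exclusion` bp from either
    breakpoint. An individual heterozygous at the majority of its callable
    diagnostic SNPs is a heterokaryotype (SL); otherwise the majority
    homozygous state votes SS (minor/inverted arrangement) or LL.
    Individuals with fewer than `min_snps` callable diagnostic SNPs are
    'unknown'.
    """
    chrom, start, end = refined_region["chrom"], refined_region["start"], refined_region["end"]
    lo, hi = maf_class
    idx, maf = _region_snps(matrix, (chrom, start + exclusion, end - exclusion),
                            focal_pop)
    idx = idx[(maf >= lo) & (maf <= hi)]
    if len(idx) == 0:
        raise ValueError("no diagnostic SNPs after breakpoint exclusion")
    # the minor allele in the focal population marks the inverted arrangement
    ac = matrix.allele_counts(matrix.pop_mask(focal_pop))[idx]
    inv_allele = np.argmin(np.where(ac > 0, ac, np.iinfo(np.int64).max), axis=1)

    G = matrix.G[idx]                       # (s, n, 2)
    dip = (G >= 0).all(axis=2)
    het = dip & (G[:, :, 0] != G[:, :, 1])
    hom_inv = dip & (G[:, :, 0] == inv_allele[:, None]) & (G[:, :, 1] == inv_allele[:, None])
    hom_std = dip & ~het & ~hom_inv
    n_call = dip.sum(axis=0)
    n_het = het.sum(axis=0)
    n_inv = hom_inv.sum(axis=0)
    n_std = hom_std.sum(axis=0)

    out = np.full(matrix.n_ind, "unknown", dtype=object)
    callable_ = n_call >= min_snps
    sl = callable_ & (n_het * 2 > n_call)
    ss = callable_ & ~sl & (n_inv >= n_std)
    ll = callable_ & ~sl & (n_inv < n_std)
    out[sl], out[ss], out[ll] = "SL", "SS", "LL"
    return pd.Series(out, index=matrix.individuals, name="karyotype")


def homozygote_group_scan(matrix: SnpMatrix, karyotypes: pd.Series, region,
                          min_group: int = 5):
    """F_ST between SS and LL homozygote pools across the region, plus a
    shared/unique classification of the region's loner SNPs.

    Classes: 'fixed-difference' (alternatively fixed), 'shared'
    (polymorphic in both pools), 'unique-S' / 'unique-L' (polymorphic in
    one pool only).
    """
    kt = karyotypes.reindex(matrix.individuals).to_numpy(dtype=object)
    mask_s = kt == "SS"
    mask_l = kt == "LL"
    if mask_s.sum() < min_group or mask_l.sum() < min_group:
        raise ValueError(f"need >= {min_group} homozygotes of each karyotype")
    chrom, start, end = region
    in_reg = np.flatnonzero((matrix.chrom == chrom) & (matrix.pos >= start)
                            & (matrix.pos <= end))
    ac_s = matrix.allele_counts(mask_s)[in_reg]
    ac_l = matrix.allele_counts(mask_l)[in_reg]
    ok = (ac_s.sum(axis=1) > 0) & (ac_l.sum(axis=1) > 0)
    fst = np.full(len(in_reg), np.nan)
    fst[ok] = _fst_vec(ac_s[ok], ac_l[ok])
    track = pd.DataFrame({"chrom": chrom, "pos": matrix.pos[in_reg],
                          "snp_idx": in_reg, "fst": fst})

    loners = find_loner_snps(matrix)
    loners = loners[(loners.chrom == chrom) & (loners.pos >= start)
                    & (loners.pos <= end)]
    classes = []
    for i in loners.snp_idx:
        k = np.flatnonzero(in_reg == i)
        if len(k) == 0 or not ok[k[0]]:
            classes.append("uncalled")
            continue
        poly_s = (ac_s[k[0]] > 0).sum() >= 2
        poly_l = (ac_l[k[0]] > 0).sum() >= 2
        if poly_s and poly_l:
            classes.append("shared")
        elif poly_s:
            classes.append("unique-S")
        elif poly_l:
            classes.append("unique-L")
        else:
            same = np.argmax(ac_s[k[0]]) == np.argmax(ac_l[k[0]])
            classes.append("monomorphic" if same else "fixed-difference")
    loners = loners.assign(**{"class": classes})
    return track, loners.reset_index(drop=True)


def hwe_check(karyotype_counts) -> tuple:
    """Hardy-Weinberg test on (n_SS, n_SL, n_LL) karyotype counts.

    Returns (chi-square statistic, P). A 1-df chi-square is used unless an
    expected class count falls below 5, in which case the Levene-Haldane
    exact test P-value is returned (statistic NaN).
    """
    if isinstance(karyotype_counts, dict):
        n_ss = karyotype_counts.get("SS", 0)
        n_sl = karyotype_counts.get("SL", 0)
        n_ll = karyotype_counts.get("LL", 0)
    else:
        n_ss, n_sl, n_ll = karyotype_counts
    n = n_ss + n_sl + n_ll
    if n == 0:
        raise ValueError("no karyotyped individuals")
    p = (2 * n_ss + n_sl) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_ss, n_sl, n_ll], dtype=float)
    if exp.min() < 5:
        return float("nan"), _hwe_exact(n_ss, n_sl, n_ll)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _hwe_exact(n_ss, n_sl, n_ll) -> float:
    """Levene-Haldane exact HWE test (two-sided, by probability ordering)."""
    from math import lgamma

    n = n_ss + n_sl + n_ll
    na = 2 * n_ss + n_sl                 # copies of the S arrangement

    def logp(h):                         # P(n_het = h | n, na)
        a = (na - h) // 2
        b = n - a - h
        return (h * np.log(2) + lgamma(n + 1) - lgamma(a + 1) - lgamma(h + 1)
                - lgamma(b + 1) + lgamma(na + 1) + lgamma(2 * n - na + 1)
                - lgamma(2 * n + 1))

    hs = [h for h in range(na % 2, min(na, 2 * n - na) + 1, 2)]
    probs = {h: np.exp(logp(h)) for h in hs}
    p_obs = probs[n_sl]
    return float(min(1.0, sum(q for q in probs.values() if q <= p_obs + 1e-12)))


# ---------------------------------------------------------------------------
# F2 crossover counting
# ---------------------------------------------------------------------------


def count_crossovers(f2_table: pd.DataFrame, marker_idx=None) -> pd.DataFrame:
    """Count crossovers between adjacent informative markers across all F2
    gametes.

    Markers default to sites where the two founders of the cross were
    homozygous for different alleles (phase-known through the F1
    heterokaryotypes). Returns per-interval crossover counts and the
    recombination fraction count / (2 x n_offspring).
    """
    gametes = f2_table.attrs["gametes"]
    chroms = f2_table.index.get_level_values("chrom").to_numpy()
    pos = f2_table.index.get_level_values("pos").to_numpy()
    ga, gb = f2_table.attrs["founder_genotypes"]
    if marker_idx is None:
        marker_idx = np.flatnonzero((ga[0] == ga[1]) & (gb[0] == gb[1])
                                    & (ga[0] != gb[0]))
    marker_idx = np.asarray(marker_idx)
    n_gam = gametes.shape[0]
    rows = []
    for c in pd.unique(chroms[marker_idx]):
        mi = marker_idx[chroms[marker_idx] == c]
        mi = mi[np.argsort(pos[mi])]
        if len(mi) < 2:
            continue
        # parental origin of each gamete allele (informative markers only)
        origin = gametes[:, mi] == gb[0, mi][None, :]
        switches = (origin[:, 1:] != origin[:, :-1]).sum(axis=0)
        for k in range(len(mi) - 1):
            rows.append((c, int(pos[mi[k]]), int(pos[mi[k + 1]]),
                         int(switches[k]), switches[k] / n_gam))
    return pd.DataFrame(rows, columns=["chrom", "pos_left", "pos_right",
                                       "crossovers", "rec_fraction"])
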