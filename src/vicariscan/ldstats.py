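"""Linkage disequilibrium: pairwise composite R2, distance-binned decay
profiles, windowed LD along the genome, Delta R2, and the
between-population window-correlation permutation test.

R2 is the squared Pearson correlation of unphased genotype dosages
(composite LD); diploid calls contribute dosage 0/1/2 and haploid consensus
calls 0/1 with equal weight. This matches an analysis of correlation among
unphased SNP alleles and keeps a single estimator throughout (it differs
slightly from a phased/EM r^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .radgeno import SnpMatrix


# ---------------------------------------------------------------------------
# pairwise R2
# ---------------------------------------------------------------------------


def r2_unphased(dosage_1, dosage_2) -> float:
    """Squared Pearson correlation of two dosage vectors (NaN = no call).

    Requires >= 2 individuals called at both SNPs and polymorphism among
    them; returns NaN otherwise.
    """
    x = np.asarray(dosage_1, dtype=float)
    y = np.asarray(dosage_2, dtype=float)
    m = ~np.isnan(x) & ~np.isnan(y)
    if m.sum() < 2:
        return float("nan")
    x, y = x[m], y[m]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pair_r2(D: np.ndarray, pi: np.ndarray, pj: np.ndarray,
             chunk: int = 20_000) -> np.ndarray:
    """Vectorized pairwise-complete R2 for SNP index pairs over dosage
    matrix D (S, n) with NaN missing."""
    V = ~np.isnan(D)
    X = np.where(V, D, 0.0)
    out = np.empty(len(pi))
    for a in range(0, len(pi), chunk):
        i = pi[a:a + chunk]
        j = pj[a:a + chunk]
        Vi, Vj = V[i], V[j]
        Xi, Xj = X[i], X[j]
        Vij = Vi & Vj
        n = Vij.sum(axis=1)
        sx = np.where(Vij, Xi, 0).sum(axis=1)
        sy = np.where(Vij, Xj, 0).sum(axis=1)
        sxx = np.where(Vij, Xi * Xi, 0).sum(axis=1)
        syy = np.where(Vij, Xj * Xj, 0).sum(axis=1)
        sxy = np.where(Vij, Xi * Xj, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            num = (n * sxy - sx * sy) ** 2
            den = (n * sxx - sx * sx) * (n * syy - sy * sy)
            r2 = np.where((n >= 2) & (den > 0), num / den, np.nan)
        out[a:a + chunk] = r2
    return out


# ---------------------------------------------------------------------------
# SNP selection shared by the LD analyses
# ---------------------------------------------------------------------------


def _ld_snp_set(matrix: SnpMatrix, pop, maf_range, max_missing: float,
                sister_pairs: bool, rng) -> np.ndarray:
    """Indices of SNPs usable for LD in one population, applying the
    tri-allelic / missingness / MAF-range / sister-locus filters."""
    mask = matrix.pop_mask(pop) if pop is not None else np.ones(matrix.n_ind, bool)
    keep = matrix.n_alleles() <= 2
    called = (matrix.G[:, mask, 0] >= 0).mean(axis=1)
    keep &= called >= 1.0 - max_missing
    maf = matrix.maf(mask)
    lo, hi = maf_range
    keep &= np.isfinite(maf) & (maf >= lo) & (maf <= hi)
    idx = np.flatnonzero(keep)
    if sister_pairs and len(idx):
        # sister RAD loci flank the same restriction site; one random SNP
        # per sister pair (locus ids pair consecutively in the generator's
        # layout: L000000/L000001, L000002/L000003, ...)
        sid = np.array([_sister_site(l) for l in matrix.locus_id[idx]])
        order = rng.permutation(len(idx))
        _, first = np.unique(sid[order], return_index=True)
        idx = np.sort(idx[order[first]])
    return idx


def _sister_site(locus_id) -> str:
    s = str(locus_id)
    if s.startswith("L") and s[1:].isdigit():
        return f"S{int(s[1:]) // 2}"
    return s


def equalize_markers(snp_sets: dict, rng) -> dict:
    """Downsample each population's SNP set to the common minimum size."""
    m = min(len(v) for v in snp_sets.values())
    return {p: np.sort(rng.choice(v, size=m, replace=False)) if len(v) > m else v
            for p, v in snp_sets.items()}


# ---------------------------------------------------------------------------
# decay profile
# ---------------------------------------------------------------------------

MAF_RANGES = ((0.05, 0.275), (0.275, 0.5))


def decay_profile(matrix: SnpMatrix, population, maf_range=None,
                  max_dist: int = 100_000, bin_width: int = 1000,
                  max_missing: float = 0.25, snp_idx=None,
                  seed: int = 0) -> pd.DataFrame:
    """Mean R2 per 1-kb distance bin (1..100 kb) within one population.

    With ``maf_range=None`` the full-range profile pools the pairs of the
    two sub-ranges (0.05-0.275 and 0.275-0.5) before binning.
    """
    rng = np.random.default_rng(seed)
    if maf_range is None and snp_idx is None:
        parts = []
        for mr in MAF_RANGES:
            parts.append(_decay_pairs(matrix, population, mr, max_dist,
                                      max_missing, None, rng))
        d, r2 = (np.concatenate(x) for x in zip(*parts))
    else:
        d, r2 = _decay_pairs(matrix, population, maf_range, max_dist,
                             max_missing, snp_idx, rng)
    bins = (d - 1) // bin_width      # 0-based bin index; bin k = ((k)kb, (k+1)kb]
    n_bins = max_dist // bin_width
    ok = np.isfinite(r2)
    mean = np.full(n_bins, np.nan)
    cnt = np.zeros(n_bins, dtype=np.int64)
    np.add.at(cnt, bins[ok], 1)
    s = np.zeros(n_bins)
    np.add.at(s, bins[ok], r2[ok])
    nz = cnt > 0
    mean[nz] = s[nz] / cnt[nz]
    return pd.DataFrame({"bin_kb": np.arange(1, n_bins + 1),
                         "mean_r2": mean, "n_pairs": cnt})


def _decay_pairs(matrix, population, maf_range, max_dist, max_missing,
                 snp_idx, rng):
    if snp_idx is None:
        snp_idx = _ld_snp_set(matrix, population, maf_range, max_missing,
                              True, rng)
    pi, pj = _pairs_within(matrix, snp_idx, 1, max_dist)
    D = matrix.dosage(matrix.pop_mask(population))
    r2 = _pair_r2(D, pi, pj)
    d = np.abs(matrix.pos[pj] - matrix.pos[pi])
    return d, r2


def _pairs_within(matrix, idx, min_dist, max_dist):
    """Intra-chromosome index pairs with min_dist <= distance <= max_dist."""
    pi, pj = [], []
    chrom = matrix.chrom[idx]
    pos = matrix.pos[idx]
    for c in pd.unique(chrom):
        sub = idx[chrom == c]
        p = pos[chrom == c]
        order = np.argsort(p)
        sub, p = sub[order], p[order]
        j_hi = np.searchsorted(p, p + max_dist, side="right")
        j_lo = np.searchsorted(p, p + min_dist, side="left")
        for a in range(len(sub)):
            if j_hi[a] > j_lo[a]:
                pi.append(np.full(j_hi[a] - j_lo[a], sub[a]))
                pj.append(sub[j_lo[a]:j_hi[a]])
    if not pi:
        return np.array([], int), np.array([], int)
    return np.concatenate(pi), np.concatenate(pj)


# ---------------------------------------------------------------------------
# windowed LD and Delta R2
# ---------------------------------------------------------------------------


def windowed_r2(matrix: SnpMatrix, population, window: int = 200_000,
                min_dist: int = 2000, max_dist: int = 50_000,
                maf_range=(0.05, 0.5), max_missing: float = 0.25,
                snp_idx=None, seed: int = 0) -> pd.DataFrame:
    """Mean R2 in non-overlapping windows along the genome.

    Pairs more than `min_dist` and less than `max_dist` apart (strict)
    are assigned to the window containing their physical midpoint.
    Windows without pairs are absent (missing, not zero).
    """
    rng = np.random.default_rng(seed)
    if snp_idx is None:
        snp_idx = _ld_snp_set(matrix, population, maf_range, max_missing,
                              True, rng)
    pi, pj = _pairs_within(matrix, snp_idx, min_dist + 1, max_dist - 1)
    D = matrix.dosage(matrix.pop_mask(population))
    r2 = _pair_r2(D, pi, pj)
    ok = np.isfinite(r2)
    pi, pj, r2 = pi[ok], pj[ok], r2[ok]
    mid = (matrix.pos[pi] + matrix.pos[pj]) // 2
    win = (mid - 1) // window
    df = pd.DataFrame({"chrom": matrix.chrom[pi], "win": win, "r2": r2})
    g = df.groupby(["chrom", "win"], sort=True)["r2"].agg(["mean", "size"]).reset_index()
    return pd.DataFrame({
        "chrom": g.chrom, "start": g.win * window + 1,
        "end": (g.win + 1) * window, "value": g["mean"], "n": g["size"],
    })


def delta_r2(track_a: pd.DataFrame, track_b: pd.DataFrame) -> pd.DataFrame:
    """Per-window difference A - B; windows missing in either are missing."""
    m = track_a.merge(track_b, on=["chrom", "start", "end"],
                      suffixes=("_a", "_b"))
    return pd.DataFrame({
        "chrom": m.chrom, "start": m.start, "end": m.end,
        "value": m.value_a - m.value_b,
        "n": np.minimum(m.n_a, m.n_b),
    })


def window_correlation_permutation(track_a: pd.DataFrame, track_b: pd.DataFrame,
                                   n_perm: int = 10_000, seed: int = 0):
    """Pearson correlation of two window tracks over shared windows, with an
    empirical permutation P-value.

    P = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1), never exactly zero.
    """
    m = track_a.merge(track_b, on=["chrom", "start", "end"],
                      suffixes=("_a", "_b")).dropna(subset=["value_a", "value_b"])
    x = m.value_a.to_numpy(float)
    y = m.value_b.to_numpy(float)
    if len(x) < 3:
        raise ValueError("fewer than 3 shared windows")
    r_obs = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    perm = np.empty(n_perm)
    W = len(x)
    idx = np.argsort(rng.random((n_perm, W)), axis=1)
    perm = (xs[idx] @ ys) / W
    p = (1 + int((np.abs(perm) >= abs(r_obs)).sum())) / (n_perm + 1)
    return r_obs, float(p)
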