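"""Haplotype-sharing statistics: EHH, EHHS, iHH, iES, iHS, Rsb, and the
phenotype-contrast Delta-iHS.

Definitions (n chromosomes, n_h copies of extended haplotype h spanning
[core, x]):

* EHH(x)  = sum_h C(n_h, 2) / C(n_a, 2) over the n_a carriers of the core
  allele -- the probability that two random carrier chromosomes are
  identical from the core out to x.
* EHHS(x) = homozygosity of extended site haplotypes across all
  chromosomes, normalized to 1 at the core. The Tang-style unbiased
  homozygosity (sum n_h^2 - n) / (n (n-1)) and the Sabeti-style
  sum C(n_h,2) / C(n,2) yield the same normalized curve, so one
  implementation serves both conventions.
* iHH / iES = trapezoid integral (bp) of the decay curve on both sides of
  the core, truncated where the curve drops below 0.05, with inter-marker
  gaps capped at 20 kb.
* iHS = ln(iHH_major / iHH_minor), standardized to zero mean and unit SD
  within minor-allele-frequency bins (the major allele serves as the
  ancestral proxy for unpolarized data).
* Rsb = ln(iES_pop1 / iES_pop2), median-centered and SD-scaled over all
  shared SNPs; |Rsb| > 4 marks a sweep candidate.

All statistics reduce to pairwise haplotype identity over intervals, so
they are computed from per-pair mismatch positions: for every chromosome
pair the next/previous mismatch index is precomputed, and a core's entire
decay curve follows from one pass over the pairs. Phased haplotypes are
assumed (synthetic data are phased by construction; real data must be
phased externally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simcore import HaplotypeSet, KIND_SNP


@dataclass
class EhhCurve:
    """Decay curve around a core SNP; positions ascending, value 1 at core."""

    core_pos: int
    allele: int | None            # None for EHHS
    pos: np.ndarray               # marker positions, both sides, ascending
    value: np.ndarray

    @property
    def core_index(self):
        return int(np.searchsorted(self.pos, self.core_pos))


class _PairEngine:
    """Pairwise-identity machinery for one chromosome's haplotype block.

    For every chromosome pair (i, j), ``NM[p, x]`` is the smallest marker
    index >= x at which the pair mismatches (m if none) and ``PM[p, x]``
    the largest index <= x (-1 if none). A pair is identical over the
    closed marker interval [a, b] iff NM[p, a] > b (equivalently
    PM[p, b] < a).
    """

    def __init__(self, rows: np.ndarray, pos: np.ndarray):
        self.rows = rows
        self.pos = np.asarray(pos, dtype=np.int64)
        n, m = rows.shape
        self.n = n
        self.m = m
        ii, jj = np.triu_indices(n, k=1)
        self.ii, self.jj = ii, jj
        B = rows[ii] != rows[jj]                       # (P, m) mismatches
        idx = np.arange(m, dtype=np.int32)
        nm = np.where(B, idx, m).astype(np.int32)
        self.NM = np.minimum.accumulate(nm[:, ::-1], axis=1)[:, ::-1]
        pm = np.where(B, idx, -1).astype(np.int32)
        self.PM = np.maximum.accumulate(pm, axis=1)

    def curve(self, k: int, pair_mask=None) -> EhhCurve | None:
        """Normalized identity-decay curve around marker k over the chosen
        pairs (all pairs = EHHS; both-carrier pairs = EHH)."""
        f = self.NM[:, k] if pair_mask is None else self.NM[pair_mask, k]
        g = self.PM[:, k] if pair_mask is None else self.PM[pair_mask, k]
        c0 = int((f > k).sum())
        if c0 == 0:
            return None
        m = self.m
        # right side: value at x = #(f > x) / c0,
        # #(f > x) = c0 - #(k < f <= x)
        cnt_f = np.bincount(f, minlength=m + 1)
        sx = c0 - np.cumsum(cnt_f[k + 1:m + 1])        # x = k+1 .. m
        vr = sx[:m - 1 - k] / c0 if m - 1 > k else np.array([])
        # left side: value at x = #(g < x) / c0
        cnt_g = np.bincount(g + 1, minlength=m + 1)
        px = np.cumsum(cnt_g)                          # px[v] = #(g < v)
        vl = px[k - 1::-1] / c0 if k > 0 else np.array([])   # x = k-1 .. 0
        pos = np.concatenate([self.pos[k - len(vl):k], [self.pos[k]],
                              self.pos[k + 1:k + 1 + len(vr)]])
        val = np.concatenate([vl[::-1], [1.0], vr])
        return EhhCurve(int(self.pos[k]), None, pos, val)


def _block_engine(haps: HaplotypeSet, rows: np.ndarray, chrom_idx: int):
    cols = np.flatnonzero((haps.site_chrom == chrom_idx)
                          & (haps.site_kind == KIND_SNP))
    return _PairEngine(np.ascontiguousarray(rows[:, cols]),
                       haps.site_pos[cols]), cols


def _locate(haps, core):
    c = int(haps.site_chrom[core])
    cols = np.flatnonzero((haps.site_chrom == c) & (haps.site_kind == KIND_SNP))
    k = int(np.searchsorted(cols, core))
    if k >= len(cols) or cols[k] != core:
        raise ValueError("core must be a SNP site")
    return c, cols, k


def ehh(haps: HaplotypeSet, core: int, allele: int, pop=None,
        truncation: float = 0.0) -> EhhCurve:
    """Allele-specific extended haplotype homozygosity around the site
    index `core`. Requires >= 2 carrier chromosomes."""
    rows = haps.haps if pop is None else haps.haps[haps.hap_rows(haps.pop_mask(pop))]
    c, cols, k = _locate(haps, core)
    carriers = rows[:, core] == allele
    if carriers.sum() < 2:
        raise ValueError("fewer than 2 carriers of the core allele")
    eng = _PairEngine(np.ascontiguousarray(rows[carriers][:, cols]),
                      haps.site_pos[cols])
    curve = eng.curve(k)
    curve.allele = allele
    return _truncate(curve, truncation)


def ehhs(haps: HaplotypeSet, core: int, pop=None, truncation: float = 0.0,
         variant: str = "tang") -> EhhCurve:
    """Site-level EHH across all chromosomes, normalized to 1 at the core.

    `variant` ("tang" or "sabeti") is accepted for interface parity; the
    two normalized curves coincide (see module docstring)."""
    if variant not in ("tang", "sabeti"):
        raise ValueError("variant must be 'tang' or 'sabeti'")
    rows = haps.haps if pop is None else haps.haps[haps.hap_rows(haps.pop_mask(pop))]
    if rows.shape[0] < 2:
        raise ValueError("fewer than 2 chromosomes")
    c, cols, k = _locate(haps, core)
    eng = _PairEngine(np.ascontiguousarray(rows[:, cols]), haps.site_pos[cols])
    curve = eng.curve(k)
    if curve is None:
        raise ValueError("core homozygosity is zero")
    return _truncate(curve, truncation)


def _truncate(curve: EhhCurve, truncation: float) -> EhhCurve:
    """Trim the curve one point past the truncation threshold on each side."""
    if truncation <= 0:
        return curve
    k = curve.core_index
    v = curve.value
    right = np.flatnonzero(v[k:] < truncation)
    hi = k + right[0] + 1 if len(right) else len(v)
    left = np.flatnonzero(v[:k + 1][::-1] < truncation)
    lo = k - left[0] if len(left) else 0
    return EhhCurve(curve.core_pos, curve.allele, curve.pos[lo:hi], v[lo:hi])


def integrate_curve(curve: EhhCurve, truncation: float = 0.05,
                    max_gap: int = 20_000) -> float:
    """Trapezoid integral (bp) of the decay curve on both sides of the
    core, outward until the curve drops below `truncation`; inter-marker
    gaps larger than `max_gap` contribute `max_gap` only."""
    k = curve.core_index
    pos, val = curve.pos, curve.value
    total = 0.0
    for p, v in ((pos[k:], val[k:]), (pos[:k + 1][::-1], val[:k + 1][::-1])):
        if len(v) < 2:
            continue
        below = np.flatnonzero(v[1:] < truncation)
        stop = below[0] + 1 if len(below) else len(v)
        gaps = np.minimum(np.abs(np.diff(p[:stop])), max_gap)
        total += float((gaps * 0.5 * (v[:stop - 1] + v[1:stop])).sum())
    return total


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _resolve_rows(haps, population, ind_mask):
    if ind_mask is None:
        ind_mask = haps.pop_mask(population)
    return haps.haps[haps.hap_rows(ind_mask)]


def ihs_scan(haps: HaplotypeSet, population=None, min_maf: float = 0.05,
             bin_width: float = 0.05, truncation: float = 0.05,
             max_gap: int = 20_000, ind_mask=None) -> pd.DataFrame:
    """Standardized iHS per SNP within one population (or explicit
    individual mask, e.g. a phenotype pool).

    raw = ln(iHH_major / iHH_minor); standardization subtracts the mean
    and divides by the SD within minor-allele-frequency bins of
    `bin_width`. SNPs with undefined or zero integrals are dropped.
    """
    rows = _resolve_rows(haps, population, ind_mask)
    rec = []
    for c in range(len(haps.chrom_names)):
        eng, cols = _block_engine(haps, rows, c)
        if eng.m == 0:
            continue
        freq = eng.rows.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        carr1 = eng.rows == 1
        for k in np.flatnonzero(maf >= min_maf):
            major = 1 if freq[k] > 0.5 else 0
            ihh = {}
            for al in (major, 1 - major):
                m_carr = carr1[:, k] if al == 1 else ~carr1[:, k]
                if m_carr.sum() < 2:
                    break
                pair_mask = m_carr[eng.ii] & m_carr[eng.jj]
                curve = eng.curve(k, pair_mask)
                if curve is None:
                    break
                v = integrate_curve(curve, truncation, max_gap)
                if v <= 0:
                    break
                ihh[al] = v
            if len(ihh) == 2:
                rec.append((cols[k], maf[k], np.log(ihh[major] / ihh[1 - major])))
    if not rec:
        return pd.DataFrame(columns=["chrom", "pos", "site", "maf", "bin",
                                     "raw", "score"])
    core_i, maf_a, raw_a = (np.asarray(x) for x in zip(*rec))
    core_i = core_i.astype(int)
    bins = np.minimum((maf_a / bin_width).astype(int), int(0.5 / bin_width) - 1)
    score = np.full(len(raw_a), np.nan)
    for b in np.unique(bins):
        m = bins == b
        if m.sum() < 2 or raw_a[m].std() == 0:
            continue
        score[m] = (raw_a[m] - raw_a[m].mean()) / raw_a[m].std()
    df = pd.DataFrame({
        "chrom": haps.site_chrom_names()[core_i], "pos": haps.site_pos[core_i],
        "site": core_i, "maf": maf_a, "bin": bins, "raw": raw_a, "score": score,
    })
    return df.dropna(subset=["score"]).reset_index(drop=True)


def rsb_scan(haps: HaplotypeSet, pop1, pop2, min_maf: float = 0.05,
             truncation: float = 0.05, max_gap: int = 20_000,
             ind_mask1=None, ind_mask2=None) -> pd.DataFrame:
    """Standardized Rsb per SNP between two populations.

    raw = ln(iES_pop1 / iES_pop2) at SNPs with MAF >= `min_maf` in the
    pooled pair; standardized by median-centering and SD-scaling. Positive
    extremes indicate longer haplotypes (a sweep) in pop1.
    """
    rows1 = _resolve_rows(haps, pop1, ind_mask1)
    rows2 = _resolve_rows(haps, pop2, ind_mask2)
    pooled = np.concatenate([rows1, rows2])
    rec = []
    for c in range(len(haps.chrom_names)):
        eng1, cols = _block_engine(haps, rows1, c)
        eng2, _ = _block_engine(haps, rows2, c)
        if eng1.m == 0:
            continue
        freq = pooled[:, cols].mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        for k in np.flatnonzero(maf >= min_maf):
            vals = []
            for eng in (eng1, eng2):
                curve = eng.curve(k)
                if curve is None:
                    break
                v = integrate_curve(curve, truncation, max_gap)
                if v <= 0:
                    break
                vals.append(v)
            if len(vals) == 2:
                rec.append((cols[k], maf[k], np.log(vals[0] / vals[1])))
    if not rec:
        return pd.DataFrame(columns=["chrom", "pos", "site", "maf", "raw", "score"])
    core_i, maf_a, raw_a = (np.asarray(x) for x in zip(*rec))
    core_i = core_i.astype(int)
    sd = raw_a.std()
    score = (raw_a - np.median(raw_a)) / sd if sd > 0 else np.zeros_like(raw_a)
    return pd.DataFrame({
        "chrom": haps.site_chrom_names()[core_i], "pos": haps.site_pos[core_i],
        "site": core_i, "maf": maf_a, "raw": raw_a, "score": score,
    })


def find_rsb_extremes(track: pd.DataFrame, threshold: float = 4.0) -> pd.DataFrame:
    """SNPs with |standardized score| strictly above `threshold`, annotated
    with the direction of the long-haplotype signal."""
    ext = track[np.abs(track.score) > threshold].copy()
    ext["direction"] = np.where(ext.score > 0, "pop1", "pop2")
    return ext.reset_index(drop=True)


def delta_ihs(track_1: pd.DataFrame, track_2: pd.DataFrame,
              window: int = 100_000) -> pd.DataFrame:
    """Per-SNP iHS difference (group 2 - group 1), averaged in
    non-overlapping windows. With group 1 = completely plated and group 2 =
    low-plated, high positive values mark long complete-allele haplotypes."""
    m = track_1.merge(track_2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    diff = m.score_2 - m.score_1
    win = (m.pos - 1) // window
    df = pd.DataFrame({"chrom": m.chrom, "win": win, "d": diff})
    g = df.groupby(["chrom", "win"], sort=True)["d"].agg(["mean", "size"]).reset_index()
    return pd.DataFrame({
        "chrom": g.chrom, "start": g.win * window + 1,
        "end": (g.win + 1) * window, "value": g["mean"], "n": g["size"],
    })
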