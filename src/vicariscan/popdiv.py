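"""Diversity and differentiation statistics on the RAD SNP matrix.

F_ST is computed from haplotype diversity (h = 1 - sum p_i^2, an analogue
of heterozygosity with maximum 0.5 for biallelic sites):

    H_S = (h_A + h_B) / 2,    H_T = 1 - sum(p_bar_i^2),
    F_ST = (H_T - H_S) / H_T           (0 where H_T = 0),

with p_bar the unweighted mean allele frequency of the two populations
(no sample-size correction; an unbiased Nei 1987 variant is available via
``corrected=True``). Negative values are reported as computed, so a
genome-wide median of 0 is representable.

"Loner SNPs" -- the only polymorphism on their RAD locus -- underpin the
diversity comparisons, avoiding pseudo-SNP bias from micro-indels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .radgeno import SnpMatrix


# ---------------------------------------------------------------------------
# loner SNPs and diversity
# ---------------------------------------------------------------------------


def find_loner_snps(matrix: SnpMatrix, min_minor_count: int = 2) -> pd.DataFrame:
    """SNPs that are the only polymorphism on their RAD locus.

    Loners with a pooled minor-allele count below `min_minor_count` are
    excluded (sequencing artifacts). Tri-allelic loners are flagged when
    their least frequent allele also reaches `min_minor_count`.
    """
    lid = matrix.locus_id
    _, inv, cnt = np.unique(lid, return_inverse=True, return_counts=True)
    alone = cnt[inv] == 1
    ac = matrix.allele_counts()
    srt = np.sort(ac, axis=1)[:, ::-1]
    minor_total = ac.sum(axis=1) - srt[:, 0]
    keep = alone & (minor_total >= min_minor_count)
    tri = keep & (srt[:, 2] >= min_minor_count)
    idx = np.flatnonzero(keep)
    return pd.DataFrame({
        "snp_idx": idx,
        "chrom": matrix.chrom[idx],
        "pos": matrix.pos[idx],
        "locus_id": lid[idx],
        "tri_allelic": tri[idx],
    })


def diversity_summary(matrix: SnpMatrix, loners: pd.DataFrame, population):
    """(proportion of loner SNPs polymorphic within the population,
    proportion of tri-allelic loners displaying all three alleles there).

    Denominators are the pooled loner totals, so the values compare
    directly across populations.
    """
    mask = matrix.pop_mask(population)
    idx = loners.snp_idx.to_numpy()
    ac = matrix.allele_counts(mask)[idx]
    n_alleles = (ac > 0).sum(axis=1)
    poly = n_alleles >= 2
    tri_idx = loners.tri_allelic.to_numpy()
    prop_poly = float(poly.mean()) if len(idx) else 0.0
    if tri_idx.any():
        prop_tri = float((n_alleles[tri_idx] >= 3).mean())
    else:
        prop_tri = 0.0
    return prop_poly, prop_tri


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def snp_fst(counts_a, counts_b, corrected: bool = False) -> float:
    """Haplotype-diversity F_ST from per-population allele counts."""
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    na, nb = ca.sum(), cb.sum()
    if na == 0 or nb == 0:
        raise ValueError("empty allele counts")
    pa, pb = ca / na, cb / nb
    if corrected:
        ha = (1.0 - (pa ** 2).sum()) * na / (na - 1.0)
        hb = (1.0 - (pb ** 2).sum()) * nb / (nb - 1.0)
    else:
        ha = 1.0 - (pa ** 2).sum()
        hb = 1.0 - (pb ** 2).sum()
    hs = 0.5 * (ha + hb)
    pbar = 0.5 * (pa + pb)
    ht = 1.0 - (pbar ** 2).sum()
    if ht == 0.0:
        return 0.0
    return float((ht - hs) / ht)


def _fst_vec(ac_a: np.ndarray, ac_b: np.ndarray,
             corrected: bool = False) -> np.ndarray:
    """Vectorized haplotype-diversity F_ST over (S, n_alleles) count arrays."""
    na = ac_a.sum(axis=1, keepdims=True).astype(float)
    nb = ac_b.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = ac_a / na
        pb = ac_b / nb
        ca = na[:, 0] / (na[:, 0] - 1) if corrected else 1.0
        cb = nb[:, 0] / (nb[:, 0] - 1) if corrected else 1.0
        hs = 0.5 * (ca * (1 - (pa ** 2).sum(axis=1))
                    + cb * (1 - (pb ** 2).sum(axis=1)))
        pbar = 0.5 * (pa + pb)
        ht = 1 - (pbar ** 2).sum(axis=1)
        fst = np.where(ht > 0, (ht - hs) / ht, 0.0)
    fst[(na[:, 0] == 0) | (nb[:, 0] == 0)] = np.nan
    return fst


def _fst_track(matrix: SnpMatrix, mask_a, mask_b, label_a: str, label_b: str,
               min_coverage: int = 21, min_maf: float = 0.2,
               one_per_locus: bool = True, corrected: bool = False) -> pd.DataFrame:
    ac_a = matrix.allele_counts(mask_a)
    ac_b = matrix.allele_counts(mask_b)
    cov_ok = (ac_a.sum(axis=1) >= min_coverage) & (ac_b.sum(axis=1) >= min_coverage)
    pool = ac_a + ac_b
    tot = pool.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(tot > 0, (tot - pool.max(axis=1)) / tot, 0.0)
    keep = cov_ok & (maf >= min_maf)
    fst = _fst_vec(ac_a, ac_b, corrected)
    keep &= np.isfinite(fst)
    idx = np.flatnonzero(keep)
    df = pd.DataFrame({
        "chrom": matrix.chrom[idx], "pos": matrix.pos[idx],
        "locus_id": matrix.locus_id[idx], "fst": fst[idx], "maf": maf[idx],
        "n_a": ac_a.sum(axis=1)[idx], "n_b": ac_b.sum(axis=1)[idx],
        "pair": f"{label_a}:{label_b}",
    })
    if one_per_locus and len(df):
        # one SNP per RAD locus: the one with the highest F_ST (ties: first
        # position, deterministic)
        df = (df.sort_values(["locus_id", "fst", "pos"],
                             ascending=[True, False, True])
                .groupby("locus_id", as_index=False).head(1))
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    df.attrs["baseline"] = float(df.fst.median()) if len(df) else np.nan
    return df


def fst_scan(matrix: SnpMatrix, pop_a, pop_b, min_coverage: int = 21,
             min_maf: float = 0.2, corrected: bool = False) -> pd.DataFrame:
    """Per-SNP F_ST track between two populations.

    Filters, in order: nucleotide coverage of at least `min_coverage`
    called haploid genotypes in each population; MAF >= `min_maf` across
    the focal two-population pool; one SNP per RAD locus (highest F_ST).
    The genome-wide median is attached as ``df.attrs['baseline']``.
    """
    return _fst_track(matrix, matrix.pop_mask(pop_a), matrix.pop_mask(pop_b),
                      str(pop_a), str(pop_b), min_coverage, min_maf,
                      corrected=corrected)


def select_extremes(tracks, k: int = 25, spacing: int = 200_000,
                    exclude_chroms=()) -> pd.DataFrame:
    """Greedy selection of the `k` strongest independent differentiation
    extremes across one or more F_ST tracks.

    Candidates are pooled over tracks (duplicate positions deduplicated,
    keeping the highest value) and accepted in descending F_ST order,
    skipping SNPs within `spacing` bp of an accepted SNP on the same
    chromosome.
    """
    if isinstance(tracks, pd.DataFrame):
        tracks = [tracks]
    pool = pd.concat(tracks, ignore_index=True)
    if exclude_chroms:
        pool = pool[~pool.chrom.isin(exclude_chroms)]
    pool = (pool.sort_values("fst", ascending=False)
                .drop_duplicates(["chrom", "pos"], keep="first"))
    accepted = []
    by_chrom = {}
    for row in pool.itertuples(index=False):
        near = by_chrom.get(row.chrom, [])
        if any(abs(row.pos - p) < spacing for p in near):
            continue
        accepted.append(row)
        by_chrom.setdefault(row.chrom, []).append(row.pos)
        if len(accepted) == k:
            break
    return pd.DataFrame(accepted).reset_index(drop=True)


# ---------------------------------------------------------------------------
# bulk segregant analysis
# ---------------------------------------------------------------------------


def bsa_fst_scan(matrix: SnpMatrix, phenotypes: pd.Series, pheno_a: str,
                 pheno_b: str, pops=None, n_per_group: int = 24,
                 min_coverage: int = 21, min_maf: float = 0.2,
                 seed: int = 0) -> pd.DataFrame:
    """F_ST scan treating two phenotypic pools as populations.

    Individuals are pooled across the stream populations (`pops`) by
    phenotype; `n_per_group` individuals per phenotype are drawn at random
    (seeded) and the standard F_ST filters and conventions apply.
    """
    rng = np.random.default_rng(seed)
    if pops is None:
        pops = [p for p in pd.unique(matrix.pops)]
    in_pops = matrix.pop_mask(pops)
    ph = phenotypes.reindex(matrix.individuals).to_numpy(dtype=object)
    masks = {}
    for name in (pheno_a, pheno_b):
        cand = np.flatnonzero(in_pops & (ph == name))
        if n_per_group <= 0 or len(cand) == 0:
            raise ValueError(f"empty phenotype group {name!r}")
        if len(cand) < n_per_group:
            raise ValueError(
                f"only {len(cand)} individuals with phenotype {name!r}; "
                f"{n_per_group} requested")
        chosen = rng.choice(cand, size=n_per_group, replace=False)
        m = np.zeros(matrix.n_ind, dtype=bool)
        m[chosen] = True
        masks[name] = m
    return _fst_track(matrix, masks[pheno_a], masks[pheno_b],
                      f"pheno={pheno_a}", f"pheno={pheno_b}",
                      min_coverage, min_maf)
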