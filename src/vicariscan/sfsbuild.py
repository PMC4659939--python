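"""Joint and marginal minor-allele site frequency spectra from RAD consensus
genotypes, with fastsimcoal-compatible observed-SFS export.

Per RAD locus and focal population, exactly ``n`` (default 30) haploid
consensus genotypes are drawn at random; loci with fewer available haploid
copies in any focal population are dropped. The spectra count the minor
allele at each of the 89 positions of every retained locus -- monomorphic
positions contribute to the (0, 0) cell -- with the minor allele defined on
the pool of all four populations. A SNP whose pooled minor-allele frequency
is exactly 0.5 enters in both orientations with weight 0.5 each.

Loci carrying more than two polymorphisms with an identical minor-allele
count within the last 30 positions are excluded as micro-indel pseudo-SNP
artifacts; loci with a tri-allelic panel column are excluded entirely so
that the conservation identity (total weight = 89 x retained loci) holds
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radgeno import SnpMatrix

log = logging.getLogger(__name__)


@dataclass
class LocusPanels:
    """Per-locus haploid allele panels for a set of populations.

    ``panels[locus_id][pop]`` is an (n, n_snps) int8 array of allele codes;
    ``col_offset[locus_id]`` gives each SNP column's 0-based offset within
    the locus.
    """

    pops: tuple
    n: int
    locus_len: int
    panels: dict = field(default_factory=dict)
    col_offset: dict = field(default_factory=dict)

    @property
    def loci(self):
        return list(self.panels)

    def drop(self, locus_ids):
        for lid in locus_ids:
            self.panels.pop(lid, None)
            self.col_offset.pop(lid, None)


def subsample_haploids(matrix: SnpMatrix, pops=None, n: int = 30,
                       loci: pd.DataFrame | None = None,
                       locus_len: int = 89, seed: int = 0) -> LocusPanels:
    """Draw exactly ``n`` haploid consensus genotypes per RAD locus for each
    focal population; loci with fewer available copies in any population
    are dropped. Deterministic for a given seed."""
    if pops is None:
        pops = tuple(pd.unique(matrix.pops))
    rng = np.random.default_rng(seed)

    start_of = {}
    if loci is not None:
        start_of = dict(zip(loci.locus_id, loci.start))

    out = LocusPanels(pops=tuple(pops), n=n, locus_len=locus_len)
    order = np.lexsort((matrix.pos, matrix.locus_id))
    lids = matrix.locus_id[order]
    if len(lids) == 0:
        return out
    boundaries = np.flatnonzero(np.concatenate([[True], lids[1:] != lids[:-1]]))
    boundaries = np.append(boundaries, len(lids))
    masks = {p: matrix.pop_mask(p) for p in pops}

    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        rows = order[b0:b1]
        lid = lids[b0]
        G = matrix.G[rows]                       # (s, n_ind, 2)
        # a haploid copy is usable only if called at every SNP of the locus
        usable = (G >= 0).all(axis=0)            # (n_ind, 2)
        panel = {}
        ok = True
        for p in pops:
            cols = np.argwhere(usable & masks[p][:, None])    # (m, 2): ind, slot
            if len(cols) < n:
                ok = False
                break
            pick = cols[rng.choice(len(cols), size=n, replace=False)]
            panel[p] = G[:, pick[:, 0], pick[:, 1]].T.astype(np.int8)  # (n, s)
        if not ok:
            continue
        start = start_of.get(lid)
        if start is None:
            start = int(matrix.pos[rows].min())
        out.panels[lid] = panel
        out.col_offset[lid] = (matrix.pos[rows] - start).astype(np.int64)
    if not out.panels:
        log.warning("no locus provides %d haploid genotypes in every population", n)
    return out


def is_pseudo_snp_locus(col_offsets, pooled_panel, locus_len: int = 89,
                        window: int = 30) -> bool:
    """True if more than two polymorphisms within the final `window`
    positions of the locus share an identical minor-allele count (the
    signature of sequential pseudo-SNPs caused by a micro-indel)."""
    pooled_panel = np.asarray(pooled_panel)
    col_offsets = np.asarray(col_offsets)
    tail = col_offsets >= locus_len - window
    counts = []
    for k in np.flatnonzero(tail):
        col = pooled_panel[:, k]
        cnt = np.bincount(col[col >= 0].astype(np.int64), minlength=2)
        cnt = np.sort(cnt[cnt > 0])[::-1]
        if len(cnt) >= 2:
            counts.append(int(cnt[1:].sum()))
    if not counts:
        return False
    _, reps = np.unique(counts, return_counts=True)
    return bool((reps > 2).any())


def filter_pseudo_snp_loci(panels: LocusPanels, window: int = 30) -> list:
    """Drop pseudo-SNP loci in place; returns the dropped locus ids."""
    dropped = []
    for lid in list(panels.panels):
        pooled = np.concatenate([panels.panels[lid][p] for p in panels.pops])
        if is_pseudo_snp_locus(panels.col_offset[lid], pooled,
                               panels.locus_len, window):
            dropped.append(lid)
    panels.drop(dropped)
    return dropped


@dataclass
class JointSFS:
    """(n+1) x (n+1) grid of weighted minor-allele co-occurrence counts."""

    pops: tuple                   # (A, B); grid[i, j]: minor count i in A, j in B
    grid: np.ndarray
    n_loci: int
    n_positions: float            # positions contributing

    @property
    def total_weight(self):
        return float(self.grid.sum())

    def marginal(self, which: int = 0) -> np.ndarray:
        return self.grid.sum(axis=1 - which)


def build_joint_sfs(panels: LocusPanels, pop_a: str, pop_b: str) -> JointSFS:
    """Joint minor-allele SFS for a population pair from shared panels.

    The minor allele is defined on the pool of every population in
    `panels`; pooled-MAF-0.5 ties enter both orientations with weight 0.5.
    Loci with a tri-allelic column are excluded entirely.
    """
    for p in (pop_a, pop_b):
        if p not in panels.pops:
            raise ValueError(f"population {p!r} absent from panels")
    n = panels.n
    grid = np.zeros((n + 1, n + 1))
    n_loci = 0
    for lid, panel in panels.panels.items():
        pooled = np.concatenate([panel[p] for p in panels.pops])   # (N, s)
        s = pooled.shape[1]
        tri = False
        entries = []
        for k in range(s):
            cnt = np.bincount(pooled[:, k].astype(np.int64), minlength=2)
            if (cnt > 0).sum() > 2:
                tri = True
                break
            if cnt[1] == 0:                     # monomorphic in the panels
                entries.append((0, 0, 1.0))
            elif cnt[0] == cnt[1]:              # pooled MAF exactly 0.5
                ia = int((panel[pop_a][:, k] == 0).sum())
                ib = int((panel[pop_b][:, k] == 0).sum())
                entries.append((ia, ib, 0.5))
                entries.append((n - ia, n - ib, 0.5))
            else:
                minor = int(np.argmin(cnt[:2])) if cnt[0] > 0 else 1
                ia = int((panel[pop_a][:, k] == minor).sum())
                ib = int((panel[pop_b][:, k] == minor).sum())
                entries.append((ia, ib, 1.0))
        if tri:
            continue
        n_loci += 1
        for ia, ib, w in entries:
            grid[ia, ib] += w
        grid[0, 0] += panels.locus_len - s      # monomorphic positions
    return JointSFS((pop_a, pop_b), grid, n_loci, float(n_loci * panels.locus_len))


def marginal_sfs(panels: LocusPanels, pop: str) -> np.ndarray:
    """Population-specific minor-allele SFS on the same panels (minor allele
    defined on the pooled panels, consistent with the joint spectra)."""
    return build_joint_sfs(panels, pop, pop).marginal(0)


# ---------------------------------------------------------------------------
# fastsimcoal observed-SFS files
# ---------------------------------------------------------------------------


def write_obs(sfs: JointSFS, path):
    """Write the fastsimcoal 2D observed-SFS dialect.

    Rows (``d1_*``) are the population listed second in the pair, columns
    (``d0_*``) the first, matching the ``<A>_<B>_jointMAFpop1_0.obs``
    convention where pop0 = A and pop1 = B.
    """
    if not np.all(np.isfinite(sfs.grid)):
        raise ValueError("non-finite weights in SFS grid")
    n = sfs.grid.shape[0] - 1
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t" + "\t".join(f"d0_{j}" for j in range(n + 1)) + "\n")
        for i in range(n + 1):
            row = sfs.grid[:, i]        # row i of pop1 = B; columns run over A
            fh.write(f"d1_{i}\t" + "\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_obs(path, pops=("pop0", "pop1")) -> JointSFS:
    """Round-trip reader for `write_obs` output."""
    with open(path) as fh:
        header = fh.readline()
        if "observations" not in header:
            raise ValueError("not an observed-SFS file")
        cols = fh.readline().split()
        n = len(cols) - 1
        grid = np.zeros((n + 1, n + 1))
        for i in range(n + 1):
            parts = fh.readline().split()
            if not parts or parts[0] != f"d1_{i}":
                raise ValueError("malformed observed-SFS row labels")
            grid[:, i] = [float(x) for x in parts[1:]]
    return JointSFS(tuple(pops), grid, 0, float(grid.sum()))
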