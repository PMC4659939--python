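"""Stage orchestration: run the simulate -> genotype -> scan pipeline from a
single YAML config with one global seed, and write a manifest recording
inputs, parameters and output checksums.

Config schema (all keys optional except where noted)::

    seed: 1                      # global seed; every stochastic stage derives
    outdir: out                  # output directory (created)
    stages: [simulate, reads, genotype, sfs, popdiv, ldstats, haploscan, invscan]
    inputs:                      # start mid-pipeline from files
      reads: reads.tsv
      vcf: calls.vcf
      pops: pops.tsv             # individual <tab> population
    sim: {}                      # SimParams overrides (n_loci, t_split, mig, ...)
    genotype:                    # every printed calling threshold by name
      min_diploid: 15
      het_ratio: 0.25
      depth_factor: 3.0
      top2_fraction: 0.70
      max_snps_per_locus: 6
      min_pooled_coverage: 80
    sfs: {n_haploids: 30, pairs: all}
    popdiv: {min_coverage: 21, min_maf: 0.2, k_extremes: 25, spacing: 200000}
    ldstats: {window: 200000, min_dist: 2000, max_dist: 50000, n_perm: 10000}
    haploscan: {min_maf: 0.05, bin_width: 0.05, rsb_threshold: 4.0}
    invscan: {window: 20000, min_total: 200, min_run: 5, robust_z: 3.0,
              maf_class_width: 0.15, exclusion: 20000}
"""

from __future__ import annotations

import hashlib
import itertools
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simcore, radgeno, sfsbuild, popdiv, ldstats, haploscan, invscan

STAGE_ORDER = ["simulate", "reads", "genotype", "sfs", "popdiv", "ldstats",
               "haploscan", "invscan"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict):
    unknown = [s for s in cfg.get("stages", []) if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    for key in cfg:
        if key not in {"seed", "outdir", "stages", "inputs", "sim", "genotype",
                       "sfs", "popdiv", "ldstats", "haploscan", "invscan",
                       "reads"}:
            raise ValueError(f"unknown config key: {key}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _sim_params(cfg: dict) -> simcore.SimParams:
    sim = dict(cfg.get("sim", {}))
    sim.setdefault("seed", cfg.get("seed", 1))
    for key, cls in (("sweeps", simcore.SweepSpec),
                     ("inversion_specs", simcore.InversionSpec)):
        if key in sim:
            sim[key] = [v if not isinstance(v, dict) else cls(**v)
                        for v in sim[key]]
    if isinstance(sim.get("pheno_locus"), dict):
        sim["pheno_locus"] = simcore.PhenoLocusSpec(**sim["pheno_locus"])
    if isinstance(sim.get("coverage"), dict):
        sim["coverage"] = simcore.CoverageParams(**sim["coverage"])
    return simcore.SimParams(**sim)


def run(config: dict | str | Path, outdir=None) -> dict:
    """Execute the configured stages in dependency order; returns (and
    writes) the run manifest. Re-running with an identical config produces
    identical outputs and checksums."""
    cfg = config if isinstance(config, dict) else load_config(config)
    validate_config(cfg)
    out = Path(outdir or cfg.get("outdir", "vicariscan_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 1))
    stages = [s for s in STAGE_ORDER if s in cfg.get("stages", [])]
    state: dict = {}
    from . import __version__ as version

    manifest = {"version": version, "seed": seed, "stages": stages,
                "config": {k: v for k, v in cfg.items() if k != "outdir"},
                "outputs": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    for stage in stages:
        outputs = _STAGES[stage](cfg, state, out, seed)
        manifest["outputs"][stage] = {
            str(p.relative_to(out)): _sha256(p) for p in outputs}

    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _require(state, key, stage):
    if key not in state:
        raise RuntimeError(f"stage '{stage}' requires '{key}' from an earlier "
                           "stage or from config inputs")
    return state[key]


def _load_inputs(cfg, state):
    inputs = cfg.get("inputs", {})
    if "reads" in inputs and "read_table" not in state:
        state["read_table"] = simcore.ReadTable.from_tsv(inputs["reads"])
    if "pops" in inputs and "pops" not in state:
        df = pd.read_csv(inputs["pops"], sep="\t", header=None,
                         names=["individual", "population"])
        state["pops"] = dict(zip(df.individual, df.population))
    if "vcf" in inputs and "matrix" not in state:
        state["matrix"] = radgeno.SnpMatrix.read_vcf(inputs["vcf"],
                                                     state.get("pops"))


def _stage_simulate(cfg, state, out, seed):
    params = _sim_params(cfg)
    haps, ledger = simcore.simulate_populations(params)
    state.update(params=params, haps=haps, ledger=ledger,
                 pops=dict(zip(haps.individuals, haps.pops)))
    truth_vcf = out / "truth.vcf"
    haps.write_vcf(truth_vcf)
    pops_tsv = out / "pops.tsv"
    pd.DataFrame({"individual": haps.individuals, "population": haps.pops}
                 ).to_csv(pops_tsv, sep="\t", index=False, header=False)
    files = [truth_vcf, pops_tsv]
    if ledger.phenotypes is not None:
        f = out / "phenotypes.tsv"
        ledger.phenotypes.rename_axis("individual").to_csv(f, sep="\t")
        state["phenotypes"] = ledger.phenotypes
        files.append(f)
    return files


def _stage_reads(cfg, state, out, seed):
    _load_inputs(cfg, state)
    if "read_table" not in state:
        haps = _require(state, "haps", "reads")
        state["read_table"] = simcore.apply_coverage_model(
            haps, state["params"], state["ledger"])
    files = []
    if cfg.get("reads", {}).get("write_tsv", False):
        f = out / "reads.tsv"
        state["read_table"].to_tsv(f)
        files.append(f)
    return files


def _stage_genotype(cfg, state, out, seed):
    _load_inputs(cfg, state)
    rt = _require(state, "read_table", "genotype")
    g = cfg.get("genotype", {})
    calls = radgeno.genotype_read_table(
        rt, min_diploid=g.get("min_diploid", 15),
        het_ratio=g.get("het_ratio", 0.25),
        depth_factor=g.get("depth_factor", 3.0),
        top2_fraction=g.get("top2_fraction", 0.70))
    matrix = radgeno.build_snp_matrix(
        calls, pops=state.get("pops"),
        max_snps_per_locus=g.get("max_snps_per_locus", 6),
        min_pooled_coverage=g.get("min_pooled_coverage", 80))
    state.update(calls=calls, matrix=matrix)
    vcf = out / "calls.vcf"
    matrix.write_vcf(vcf)
    sidecar = out / "effective_coverage.tsv"
    calls.coverage_sidecar().to_csv(sidecar, sep="\t", index=False)
    return [vcf, sidecar]


def _stage_sfs(cfg, state, out, seed):
    _load_inputs(cfg, state)
    matrix = _require(state, "matrix", "sfs")
    s = cfg.get("sfs", {})
    loci = state["ledger"].loci if "ledger" in state else None
    panels = sfsbuild.subsample_haploids(matrix, n=s.get("n_haploids", 30),
                                         loci=loci, seed=seed + 11)
    sfsbuild.filter_pseudo_snp_loci(panels)
    files = []
    pops = list(panels.pops)
    pairs = list(itertools.combinations(pops, 2))
    for a, b in pairs:
        sfs = sfsbuild.build_joint_sfs(panels, a, b)
        f = out / f"{a}_{b}_jointMAFpop1_0.obs"
        sfsbuild.write_obs(sfs, f)
        files.append(f)
    marg = pd.DataFrame({p: sfsbuild.marginal_sfs(panels, p) for p in pops})
    f = out / "marginal_sfs.tsv"
    marg.rename_axis("minor_count").to_csv(f, sep="\t")
    files.append(f)
    state["panels"] = panels
    return files


def _lake_stream_pairs(pops):
    lake = pops[0]
    return [(lake, p) for p in pops[1:]]


def _pop_list(state):
    return list(pd.unique(np.asarray(list(state["pops"].values()), dtype=object))) \
        if "pops" in state else list(pd.unique(state["matrix"].pops))


def _stage_popdiv(cfg, state, out, seed):
    _load_inputs(cfg, state)
    matrix = _require(state, "matrix", "popdiv")
    p = cfg.get("popdiv", {})
    pops = _pop_list(state)
    tracks = []
    files = []
    for a, b in _lake_stream_pairs(pops):
        tr = popdiv.fst_scan(matrix, a, b, min_coverage=p.get("min_coverage", 21),
                             min_maf=p.get("min_maf", 0.2))
        f = out / f"fst_{a}_{b}.tsv"
        tr.to_csv(f, sep="\t", index=False)
        tracks.append(tr)
        files.append(f)
    ext = popdiv.select_extremes(tracks, k=p.get("k_extremes", 25),
                                 spacing=p.get("spacing", 200_000))
    bed = out / "fst_extremes.bed"
    with open(bed, "w") as fh:
        for r in ext.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.pair}\t{r.fst:.4f}\n")
    files.append(bed)
    state["fst_tracks"] = tracks
    return files


def _stage_ldstats(cfg, state, out, seed):
    _load_inputs(cfg, state)
    matrix = _require(state, "matrix", "ldstats")
    p = cfg.get("ldstats", {})
    pops = _pop_list(state)
    files = []
    tracks = {}
    for pop in pops:
        tr = ldstats.windowed_r2(matrix, pop, window=p.get("window", 200_000),
                                 min_dist=p.get("min_dist", 2000),
                                 max_dist=p.get("max_dist", 50_000),
                                 seed=seed + 23)
        tracks[pop] = tr
        f = out / f"ld_windows_{pop}.tsv"
        tr.to_csv(f, sep="\t", index=False)
        files.append(f)
    lake = pops[0]
    rows = []
    for pop in pops[1:]:
        d = ldstats.delta_r2(tracks[lake], tracks[pop])
        f = out / f"delta_r2_{lake}_{pop}.tsv"
        d.to_csv(f, sep="\t", index=False)
        files.append(f)
        r, pv = ldstats.window_correlation_permutation(
            tracks[lake], tracks[pop], n_perm=p.get("n_perm", 10_000),
            seed=seed + 31)
        rows.append((lake, pop, r, pv))
    f = out / "ld_window_correlations.tsv"
    pd.DataFrame(rows, columns=["pop_a", "pop_b", "r", "p"]).to_csv(
        f, sep="\t", index=False)
    files.append(f)
    state["ld_tracks"] = tracks
    return files


def _stage_haploscan(cfg, state, out, seed):
    haps = _require(state, "haps", "haploscan")
    p = cfg.get("haploscan", {})
    pops = list(pd.unique(haps.pops))
    files = []
    for pop in pops:
        tr = haploscan.ihs_scan(haps, pop, min_maf=p.get("min_maf", 0.05),
                                bin_width=p.get("bin_width", 0.05))
        f = out / f"ihs_{pop}.tsv"
        tr.to_csv(f, sep="\t", index=False)
        files.append(f)
    lake = pops[0]
    for pop in pops[1:]:
        tr = haploscan.rsb_scan(haps, lake, pop, min_maf=p.get("min_maf", 0.05))
        f = out / f"rsb_{lake}_{pop}.tsv"
        tr.to_csv(f, sep="\t", index=False)
        ext = haploscan.find_rsb_extremes(tr, p.get("rsb_threshold", 4.0))
        fe = out / f"rsb_extremes_{lake}_{pop}.tsv"
        ext.to_csv(fe, sep="\t", index=False)
        files.extend([f, fe])
    return files


def _stage_invscan(cfg, state, out, seed):
    _load_inputs(cfg, state)
    rt = _require(state, "read_table", "invscan")
    matrix = _require(state, "matrix", "invscan")
    p = cfg.get("invscan", {})
    pops = _pop_list(state)
    pop_map = state["pops"] if "pops" in state else \
        dict(zip(matrix.individuals, matrix.pops))
    lake = pops[0]
    files = []
    all_regions = []
    for pop in pops[1:]:
        track = invscan.coverage_ratio_track(rt, pop_map, pop, lake,
                                             window=p.get("window", 20_000),
                                             min_total=p.get("min_total", 200))
        f = out / f"coverage_ratio_{pop}_{lake}.tsv"
        track.to_csv(f, sep="\t", index=False)
        files.append(f)
        for reg in invscan.detect_distortions(track,
                                              min_run=p.get("min_run", 5),
                                              robust_z=p.get("robust_z", 3.0)):
            reg["population"] = pop
            all_regions.append(reg)
    bed = out / "inversion_candidates.bed"
    with open(bed, "w") as fh:
        for reg in all_regions:
            fh.write(f"{reg['chrom']}\t{reg['start'] - 1}\t{reg['end']}\t"
                     f"{reg['population']}\t{reg['mean_log2_ratio']:.3f}\n")
    files.append(bed)

    rows = []
    for reg in all_regions:
        region = (reg["chrom"], reg["start"], reg["end"])
        pop = reg["population"]
        try:
            lo, hi, peak = invscan.maf_peak_class(
                matrix, region, pop, width=p.get("maf_class_width", 0.15))
            refined = invscan.ld_block_breakpoints(matrix, region, pop, (lo, hi))
            if refined is None:
                continue
            kt = invscan.assign_inversion_genotypes(
                matrix, refined, (lo, hi), pop,
                exclusion=p.get("exclusion", 20_000))
            counts = kt.value_counts()
            chi2, pv = invscan.hwe_check((counts.get("SS", 0),
                                          counts.get("SL", 0),
                                          counts.get("LL", 0)))
            rows.append((reg["chrom"], reg["start"], reg["end"], pop, peak,
                         refined["start"], refined["end"], refined["n_snps"],
                         counts.get("SS", 0), counts.get("SL", 0),
                         counts.get("LL", 0), pv))
            fk = out / f"karyotypes_{reg['chrom']}_{refined['start']}.tsv"
            kt.rename_axis("individual").to_csv(fk, sep="\t")
            files.append(fk)
        except ValueError:
            continue
    f = out / "inversions.tsv"
    pd.DataFrame(rows, columns=["chrom", "cand_start", "cand_end", "population",
                                "maf_peak", "refined_start", "refined_end",
                                "n_block_snps", "n_SS", "n_SL", "n_LL",
                                "hwe_p"]).to_csv(f, sep="\t", index=False)
    files.append(f)
    return files


_STAGES = {
    "simulate": _stage_simulate,
    "reads": _stage_reads,
    "genotype": _stage_genotype,
    "sfs": _stage_sfs,
    "popdiv": _stage_popdiv,
    "ldstats": _stage_ldstats,
    "haploscan": _stage_haploscan,
    "invscan": _stage_invscan,
}


def demo_config(seed: int = 1, outdir: str = "vicariscan_demo") -> dict:
    """Small end-to-end scenario: sweep + inversion + plate locus."""
    loci = simcore.SimParams(seed=seed).loci_table()
    return {
        "seed": seed,
        "outdir": outdir,
        "stages": STAGE_ORDER,
        "sim": {
            "sweeps": [{"population": "lake", "chrom": "chr1",
                        "pos": simcore.locus_position(loci, "chr1", 1_250_000),
                        "s": 0.5}],
            "inversion_specs": [{"chrom": "chr2", "start": 3_000_000,
                                 "end": 3_500_000, "stream_freq": 0.3}],
            "pheno_locus": {"chrom": "chr1",
                            "pos": simcore.locus_position(loci, "chr1", 3_750_000)},
        },
    }
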