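"""End-to-end orchestration: simulate -> qc -> discovery -> differentiation
-> selection -> medical -> structure, with hierarchical seeding and a
reproducible report directory.

Every stochastic stage draws its generator from a child of the root seed
(``numpy.random.SeedSequence.spawn``), so adding or reordering stages never
changes another stage's randomness and a fixed config + seed reproduces the
report byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differentiation, discovery, io, medical, qc, selection, structure
from .frequencies import derived_counts, population_daf
from .simulate import SimConfig, SweepSpec, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "discovery", "diff", "select", "medical", "structure")

# fixed stream index per stage keeps stage randomness independent of the
# subset of stages requested
_STREAM = {name: i for i, name in enumerate(STAGES)}


def _stage_seed(root_seed: int, stage: str) -> int:
    child = np.random.SeedSequence(root_seed).spawn(len(STAGES))[_STREAM[stage]]
    return int(child.generate_state(1)[0] % (2**31))


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _sim_config(cfg: dict, seed: int) -> SimConfig:
    sim = dict(cfg.get("simulate", {}))
    sweep = sim.pop("sweep", None)
    if sweep is not None:
        sweep = SweepSpec(**sweep)
        return SimConfig(seed=seed, sweep=sweep, **sim)
    return SimConfig(seed=seed, **sim)


def run_pipeline(
    config_path: str | Path | None,
    seed: int,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> Path:
    """Run the requested stages in dependency order; returns the report dir."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages = tuple(s for s in STAGES if s in stages)

    state: dict = {}
    manifest_entries = {}

    if "simulate" in stages:
        sim_cfg = _sim_config(cfg, _stage_seed(seed, "simulate"))
        sites, geno, haps, manifest, truth = simulate_cohort(sim_cfg)
        state.update(sites=sites, geno=geno, haps=haps, manifest=manifest, truth=truth)
        io.write_vcf(sites, geno, out / "cohort.vcf", haps=haps)
        io.write_manifest(manifest, out / "manifest.tsv")
        io.write_annotations(sites, out / "annotations.tsv")
        manifest_entries["simulate"] = ["cohort.vcf", "manifest.tsv", "annotations.tsv"]
    else:
        inputs = cfg.get("inputs", {})
        if not inputs:
            raise ValueError("stage needs upstream output: no simulate stage "
                             "and no 'inputs' section in config")
        sites, geno, haps, manifest = io.read_cohort(
            inputs["vcf"], inputs["manifest"], inputs.get("annotations")
        )
        state.update(sites=sites, geno=geno, haps=haps, manifest=manifest, truth=None)

    def require(key: str, stage: str):
        if key not in state or state[key] is None:
            raise ValueError(f"stage {stage!r} missing upstream input {key!r}")
        return state[key]

    if "qc" in stages:
        qcfg = cfg.get("qc", {})
        geno_f, sites_f, report = qc.filter_sites(
            state["geno"], state["sites"],
            call_rate_min=qcfg.get("call_rate_min", 0.99),
            hwe_p_min=qcfg.get("hwe_p_min", 1e-6),
            maf_min=qcfg.get("maf_min", 0.01),
            drop_ambiguous=qcfg.get("drop_ambiguous", True),
        )
        state["geno_qc"], state["sites_qc"] = geno_f, sites_f
        pd.DataFrame(
            [(k, v) for k, v in report.removed.items()],
            columns=["filter", "n_removed"],
        ).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        logger.info("QC removed %s of %d sites", report.removed, report.n_input)
        manifest_entries["qc"] = ["qc_report.tsv"]

    geno_use = state.get("geno_qc", state["geno"])
    sites_use = state.get("sites_qc", state["sites"])
    man = state["manifest"]

    if "discovery" in stages:
        dcfg = cfg.get("discovery", {})
        dseed = _stage_seed(seed, "discovery")
        dafs = population_daf(state["geno"], state["sites"], man)
        counts = pd.DataFrame({
            pop: derived_counts(state["geno"], state["sites"], man.members(pop))[0]
            for pop in man.population_ids
        })
        novel = discovery.flag_novel(state["sites"], dcfg.get("catalogues", ["simdb"]), dafs)
        # subsample to the smallest population, capped at the configured n
        smallest = min(len(man.members(p)) for p in man.population_ids)
        per_ind = discovery.per_individual_novel_counts(
            state["geno"], novel, man,
            subsample_n=min(dcfg.get("subsample_n", 24), smallest), seed=dseed,
        )
        sets_all = discovery.novel_sets_per_population(novel, dafs)
        order = dcfg.get("order", man.population_ids)
        curve = discovery.cumulative_discovery(sets_all, order)
        sharing = discovery.singleton_sharing(counts, dafs)
        per_ind.to_csv(out / "novel_per_individual.tsv", sep="\t")
        curve.to_csv(out / "discovery_curve.tsv", sep="\t", index=False)
        sharing.to_csv(out / "singleton_sharing.tsv", sep="\t")
        manifest_entries["discovery"] = [
            "novel_per_individual.tsv", "discovery_curve.tsv", "singleton_sharing.tsv",
        ]

    if "diff" in stages:
        fcfg = cfg.get("diff", {})
        dafs = population_daf(geno_use, sites_use, man)
        fst = differentiation.pairwise_fst_matrix(geno_use, sites_use, man)
        hdvs, hist = differentiation.hdv_scan(
            dafs, sites_use, threshold=fcfg.get("hdv_threshold", 0.40)
        )
        fst.to_csv(out / "fst_matrix.tsv", sep="\t")
        hdvs.drop(columns=["site"]).to_csv(out / "hdvs.tsv", sep="\t", index=False)
        hist.to_csv(out / "hdv_histogram.tsv", sep="\t", index=False)
        state["fst_matrix"] = fst
        manifest_entries["diff"] = ["fst_matrix.tsv", "hdvs.tsv", "hdv_histogram.tsv"]

    if "select" in stages:
        scfg = cfg.get("select", {})
        sseed = _stage_seed(seed, "select")
        haps_full = require("haps", "select")
        window = scfg.get("window", 10_000)
        chrom = sites_use.df["chrom"].iloc[0]
        chrom_length = int(cfg.get("simulate", {}).get("chrom_length_bp", 8_000_000))
        tracks = []
        for pop in man.population_ids:
            rows = haps_full.haplotypes_of(man.members(pop))
            derived = rows.sum(axis=0)
            track, _ = selection.clr_scan(
                derived, haps_full.positions, rows.shape[0], chrom, chrom_length,
                population=pop, window=window,
                grid_spacing=scfg.get("grid_spacing", 2000),
                n_alpha=scfg.get("n_alpha", 64),
            )
            tracks.append(track)
        thr = selection.empirical_threshold(
            tracks, n_sample=scfg.get("n_sample", 10_000),
            p=scfg.get("clr_p", 0.001), seed=sseed,
        )
        for track in tracks:
            flagged = selection.flag_outliers(track, thr)
            io.write_track(flagged, out / f"clr_{track.population}.tsv")
        with open(out / "clr_threshold.txt", "w") as fh:
            fh.write(f"{thr:.6g}\n")
        manifest_entries["select"] = [f"clr_{t.population}.tsv" for t in tracks] + [
            "clr_threshold.txt"
        ]

    if "medical" in stages:
        mcfg = cfg.get("medical", {})
        mseed = _stage_seed(seed, "medical")
        truth = state.get("truth")
        if mcfg.get("gene_sets"):
            direct = set(mcfg["gene_sets"]["direct"])
            indirect = set(mcfg["gene_sets"]["indirect"])
        elif truth:
            direct, indirect = truth["direct_genes"], truth["indirect_genes"]
        else:
            raise ValueError("medical stage needs gene_sets in config")
        gene_counts = medical.plof_gene_counts(state["sites"], state["geno"], man)
        disease = mcfg.get("disease", "sim")
        result = medical.burden_mortality_test(
            gene_counts, direct, indirect, man.mortality(disease),
            n_iter=mcfg.get("n_iter", 1000), seed=mseed,
        )
        summary = {
            "observed_r2": result["observed_r2"],
            "null_mean": result["null_mean"],
            "null_sem": result["null_sem"],
            "wilcoxon_p": result["wilcoxon_p"],
            "empirical_p": result["empirical_p"],
        }
        with open(out / "burden_mortality.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest_entries["medical"] = ["burden_mortality.json"]

    if "structure" in stages:
        stcfg = cfg.get("structure", {})
        stseed = _stage_seed(seed, "structure")
        fst = state.get("fst_matrix")
        if fst is None:
            fst = differentiation.pairwise_fst_matrix(geno_use, sites_use, man)
        pro = structure.procrustes_test(
            man.coordinates(), fst,
            n_perm=stcfg.get("n_perm", 10_000), seed=stseed,
        )
        roh = structure.detect_roh(state["geno"], state["sites"])
        roh.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        with open(out / "procrustes.json", "w") as fh:
            json.dump(
                {"t0": pro.t0, "p_value": pro.p_value, "n_perm": pro.n_perm},
                fh, indent=2, sort_keys=True,
            )
        manifest_entries["structure"] = ["roh_segments.tsv", "procrustes.json"]

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "stages": list(stages),
                "config": cfg,
                "outputs": manifest_entries,
            },
            fh, indent=2, sort_keys=True,
        )
    return out
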