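"""End-to-end pipeline orchestration with a run manifest.

A single config dict (or YAML file) drives the stages
filter -> stats -> abc -> outliers -> adaptive -> gdm -> gf -> vulnerability;
each stage can be toggled, reads only earlier stages' outputs, and writes its
results under its own subdirectory of ``outdir``.  The manifest records the
config hash, per-stage seeds (derived from the master seed by stable
hashing), output paths, checksums, and wall-clock times, so identical
config+seed reproduces identical checksums for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_io as gio
from . import popgen_stats, env_association, gdm as gdm_mod
from .rasters import ClimateGrid

__all__ = ["RunManifest", "run_pipeline", "default_config", "stage_seed"]

STAGES = ["filter", "stats", "abc", "outliers", "adaptive", "gdm", "gf",
          "vulnerability"]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int]
    stages_run: list[str] = field(default_factory=list)
    outputs: dict[str, dict[str, str]] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def default_config() -> dict:
    return {
        "seed": 0,
        "stages": {s: True for s in STAGES},
        "filter": {"min_samples": 1, "min_pop_frac": 0.6, "maf": 0.01,
                   "one_per_locus": True},
        "stats": {"amova_levels": 3, "n_perm": 1000, "min_n": 5},
        "abc": {"n_per_scenario": 200, "n_loci": 300, "tolerance": 0.05,
                "method": "mnlogit", "scenarios": ["S1", "S2", "S3", "S4", "S5"]},
        "outliers": {"method": "both", "q": 0.001, "fdr": 0.01,
                     "bayescan": {"n_iter": 300, "thin": 2, "n_pilot": 5,
                                  "pilot_len": 100, "burnin": 500},
                     "fdist": {"n_sims": 5000, "n_demes": 20}},
        "adaptive": {"r2_threshold": 0.5, "alpha": 0.05},
        "gdm": {"n_perm": 50, "alpha": 0.05},
        "gf": {"n_trees": 100},
    }


def _sha1(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()


def run_pipeline(
    config: dict,
    snps: gio.SNPMatrix,
    pmap: gio.PopulationMap,
    predictors=None,
    grid_now: ClimateGrid | None = None,
    grid_future: ClimateGrid | None = None,
    outdir="pipeline_out",
) -> RunManifest:
    """Run the enabled stages on in-memory inputs; returns the manifest.

    Stage failures raise after the manifest (with completed stages) is saved,
    preserving partial outputs and diagnostics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    seed = int(cfg["seed"])
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        master_seed=seed,
        stage_seeds={s: stage_seed(seed, s) for s in STAGES},
    )
    state: dict = {"snps": snps, "pmap": pmap, "predictors": predictors}

    def record(stage: str, files: dict[str, Path], t0: float) -> None:
        manifest.stages_run.append(stage)
        manifest.outputs[stage] = {k: f"{p}:{_sha1(p)}" for k, p in files.items()}
        manifest.wall_clock[stage] = round(time.time() - t0, 3)

    try:
        if cfg["stages"].get("filter"):
            t0 = time.time()
            d = outdir / "filter"
            d.mkdir(exist_ok=True)
            f = cfg["filter"]
            m = gio.filter_within_pop_presence(snps, pmap, f["min_pop_frac"])
            m = gio.filter_sample_coverage(m, f["min_samples"])
            m = gio.filter_maf(m, f["maf"])
            if f.get("one_per_locus"):
                m = gio.one_snp_per_radlocus(m)
            state["snps"] = m
            gio.write_genotypes(m, d / "filtered.vcf")
            record("filter", {"filtered_vcf": d / "filtered.vcf"}, t0)

        if cfg["stages"].get("stats"):
            t0 = time.time()
            d = outdir / "stats"
            d.mkdir(exist_ok=True)
            s = cfg["stats"]
            div = popgen_stats.diversity(state["snps"], pmap, min_n=s["min_n"])
            div.table.to_csv(d / "diversity.csv")
            am = popgen_stats.amova(
                state["snps"], pmap, levels=s["amova_levels"],
                n_perm=s["n_perm"], seed=manifest.stage_seeds["stats"],
            )
            pd.Series({
                "phi_st": am.phi_st, "phi_sc": am.phi_sc, "phi_ct": am.phi_ct,
                **{f"sigma2_{k}": v for k, v in am.sigma2.items()},
                **{f"p_{k}": v for k, v in am.p_values.items()},
            }).to_csv(d / "amova.csv", header=False)
            phist = popgen_stats.pairwise_phist(state["snps"], pmap)
            phist.to_csv(d / "pairwise_phist.csv")
            state["phist"] = phist
            record("stats", {"diversity": d / "diversity.csv",
                             "amova": d / "amova.csv",
                             "phist": d / "pairwise_phist.csv"}, t0)

        if cfg["stages"].get("abc"):
            t0 = time.time()
            d = outdir / "abc"
            d.mkdir(exist_ok=True)
            from . import abc as rabc
            from .coalescent_sim import builtin_scenarios

            a = cfg["abc"]
            scen = builtin_scenarios()["divergence"]
            specs = [scen[k] for k in a["scenarios"]]
            rng = np.random.default_rng(manifest.stage_seeds["abc"])
            ref = rabc.build_reference(specs, a["n_per_scenario"],
                                       a["n_loci"], rng)
            obs = rabc.summarize(state["snps"], pmap)
            post = rabc.model_posterior(ref, obs, a["tolerance"], a["method"])
            with open(d / "model_posterior.json", "w") as fh:
                json.dump(post["probabilities"], fh, indent=1)
            best = max(post["probabilities"], key=post["probabilities"].get)
            est = rabc.estimate_params(ref.restrict(best), obs,
                                       tolerance=min(4 * a["tolerance"], 1.0))
            est.table.to_csv(d / "posterior_params.csv")
            record("abc", {"posterior": d / "model_posterior.json",
                           "params": d / "posterior_params.csv"}, t0)

        flagged_ids: set[str] | None = None
        if cfg["stages"].get("outliers"):
            t0 = time.time()
            d = outdir / "outliers"
            d.mkdir(exist_ok=True)
            from . import outlier_scan

            o = cfg["outliers"]
            files = {}
            rng = np.random.default_rng(manifest.stage_seeds["outliers"])
            res_b = res_f = None
            if o["method"] in ("bayes", "both"):
                res_b = outlier_scan.bayescan_scan(
                    state["snps"], pmap, rng=rng, q_threshold=o["q"],
                    **o["bayescan"],
                )
                res_b.table.to_csv(d / "bayescan.csv")
                files["bayescan"] = d / "bayescan.csv"
            if o["method"] in ("fdist", "both"):
                res_f = outlier_scan.fdist_scan(
                    state["snps"], pmap, fdr=o["fdr"], rng=rng, **o["fdist"]
                )
                res_f.table.to_csv(d / "fdist.csv")
                files["fdist"] = d / "fdist.csv"
            if res_b is not None and res_f is not None:
                flagged_ids = outlier_scan.intersect_outliers(res_b, res_f)
            elif res_b is not None:
                flagged_ids = set(res_b.flagged)
            elif res_f is not None:
                flagged_ids = set(res_f.flagged)
            (d / "intersection.txt").write_text(
                "\n".join(sorted(flagged_ids or set()))
            )
            files["intersection"] = d / "intersection.txt"
            state["outliers"] = flagged_ids or set()
            record("outliers", files, t0)

        if cfg["stages"].get("adaptive") and predictors is not None:
            t0 = time.time()
            d = outdir / "adaptive"
            d.mkdir(exist_ok=True)
            a = cfg["adaptive"]
            target = state.get("outliers") or set(state["snps"].locus_ids)
            cols = [j for j, l in enumerate(state["snps"].locus_ids)
                    if l in target]
            sub = state["snps"].take_loci(cols) if cols else state["snps"]
            freqs = env_association.population_allele_freqs(sub, pmap)
            scan = env_association.mlr_adaptive_scan(
                freqs, predictors, r2_threshold=a["r2_threshold"],
                alpha=a["alpha"],
            )
            scan.table.to_csv(d / "adaptive_scan.csv")
            state["freqs"] = env_association.population_allele_freqs(
                state["snps"], pmap
            )
            record("adaptive", {"scan": d / "adaptive_scan.csv"}, t0)

        if cfg["stages"].get("gdm") and predictors is not None:
            t0 = time.time()
            d = outdir / "gdm"
            d.mkdir(exist_ok=True)
            g = cfg["gdm"]
            phist = state.get("phist")
            if phist is None:
                phist = popgen_stats.pairwise_phist(state["snps"], pmap)
            model, trace = gdm_mod.backward_eliminate(
                phist, predictors, coords=pmap.pop_coords,
                n_perm=g["n_perm"], alpha=g["alpha"],
                rng=manifest.stage_seeds["gdm"],
            )
            pd.DataFrame([
                {"predictor": p, "importance": model.importance.get(p),
                 "p_value": model.p_values.get(p)} for p in model.predictors
            ]).to_csv(d / "gdm_model.csv", index=False)
            with open(d / "trace.json", "w") as fh:
                json.dump(trace, fh, indent=1, default=str)
            record("gdm", {"model": d / "gdm_model.csv",
                           "trace": d / "trace.json"}, t0)

        gf_model = None
        if cfg["stages"].get("gf") and predictors is not None:
            t0 = time.time()
            d = outdir / "gf"
            d.mkdir(exist_ok=True)
            from . import gradient_forest

            freqs = state.get("freqs")
            if freqs is None:
                freqs = env_association.population_allele_freqs(
                    state["snps"], pmap
                )
            gf_model = gradient_forest.fit_gf(
                freqs, predictors, n_trees=cfg["gf"]["n_trees"],
                rng=manifest.stage_seeds["gf"],
            )
            pd.Series(gf_model.importance).to_csv(d / "importance.csv",
                                                  header=False)
            record("gf", {"importance": d / "importance.csv"}, t0)

        if (cfg["stages"].get("vulnerability") and gf_model is not None
                and grid_now is not None and grid_future is not None):
            t0 = time.time()
            d = outdir / "vulnerability"
            d.mkdir(exist_ok=True)
            from . import gradient_forest
            from .rasters import write_ascii_grid

            vuln = gradient_forest.genomic_vulnerability(
                gf_model, grid_now, grid_future
            )
            write_ascii_grid(d / "vulnerability.asc", np.nan_to_num(vuln),
                             grid_now.x, grid_now.y, grid_now.mask)
            record("vulnerability", {"map": d / "vulnerability.asc"}, t0)
    finally:
        manifest.save(outdir / "manifest.json")
    return manifest
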