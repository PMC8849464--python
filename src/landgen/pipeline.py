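"""Configuration, orchestration and manifests for end-to-end runs.

A single YAML config with per-stage sections drives the pipeline
simulate -> popgen -> outliers -> ibd -> optimize -> current. Unknown keys are
hard errors; every stage derives its random stream from the global seed; a
JSON manifest records the config hash, per-stage output checksums, timings
and seeds. Deterministic stages rerun byte-identically under the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .datatypes import ConfigurationError, DistanceMatrix, GenotypeMatrix
from .ibd import fit_mlpe, geographic_distances, mantel_test, pair_table, slope_contrast
from .outliers import (
    consensus,
    fsthet_scan,
    outflank_scan,
    rda_scan,
    rf_backwards_purge,
    rf_rank,
    spatial_covariates,
)
from .popgen import (
    diversity_stats,
    gst_hedrick,
    hierarchical_f,
    matrix_correlation,
    pairwise_fst_nei,
    rarefied_allelic_richness,
)
from .resistance import (
    GAConfig,
    SurfaceModel,
    SurfaceSpec,
    bootstrap_rank,
    compose_resistance,
    current_map,
    fit_surface_model,
    ga_optimise,
    model_selection,
    rescale_surface,
)
from .rng import child_seed
from .synthetic import SimulationConfig, simulate_dataset

STAGES = ("simulate", "popgen", "outliers", "ibd", "optimize", "current")

_DEFAULTS: dict[str, dict] = {
    "simulate": {f.name: None for f in dataclasses.fields(SimulationConfig)},
    "popgen": {"n_perm": 199, "hier_perm": 99, "hier_boot": 100, "max_hier_loci": 1000},
    "outliers": {
        "n_trees": 1000,
        "n_runs": 3,
        "threshold": 3.0,
        "rda_perm": 999,
        "trim_low": 0.06,
        "trim_high": 0.35,
        "he_min": 0.1,
        "q_cut": 0.05,
        "alpha": 0.05,
        "rf_spatial_correction": "residualise",
    },
    "ibd": {"mantel_perm": 9999},
    "optimize": {
        "generations": 12,
        "pop_mult": 20,
        "patience": 6,
        "bootstrap_iterations": 200,
        "bootstrap_frac": 0.85,
        "aicc_n": "sites",
    },
    "current": {},
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "landgen_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sections: dict[str, dict] = field(default_factory=dict)

    def section(self, name: str) -> dict:
        merged = dict(_DEFAULTS.get(name, {}))
        merged.update(self.sections.get(name, {}))
        return merged


def validate_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Parse and validate a YAML/JSON config; collect *all* problems."""
    if data is None:
        if path is None:
            data = {}
        else:
            text = Path(path).read_text()
            data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    problems: list[str] = []
    known_top = {"seed", "out_dir", "stages"} | set(STAGES)
    for key in data:
        if key not in known_top:
            problems.append(f"unknown key '{key}'")
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        problems.append("seed must be an integer")
    stages = data.get("stages", list(STAGES))
    for s in stages:
        if s not in STAGES:
            problems.append(f"unknown stage '{s}'")
    sections: dict[str, dict] = {}
    for stage in STAGES:
        sect = data.get(stage, {})
        if sect is None:
            sect = {}
        if not isinstance(sect, dict):
            problems.append(f"section '{stage}' must be a mapping")
            continue
        allowed = set(_DEFAULTS[stage])
        for key in sect:
            if key not in allowed:
                problems.append(f"unknown key '{stage}.{key}'")
        sections[stage] = {k: v for k, v in sect.items() if k in allowed}
    out = sections.get("outliers", {})
    for frac_key in ("trim_low", "trim_high", "he_min", "q_cut", "alpha"):
        if frac_key in out and not 0.0 <= float(out[frac_key]) < 1.0:
            problems.append(f"outliers.{frac_key} must lie in [0, 1)")
    if problems:
        raise ConfigurationError("invalid config: " + "; ".join(problems))
    return RunConfig(
        seed=int(seed),
        out_dir=str(data.get("out_dir", "landgen_out")),
        stages=list(stages),
        sections=sections,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    canon = json.dumps(
        {"seed": cfg.seed, "stages": cfg.stages, "sections": cfg.sections},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _simulation_config(cfg: RunConfig) -> SimulationConfig:
    overrides = {k: v for k, v in cfg.section("simulate").items() if v is not None}
    if "grid_shape" in overrides:
        overrides["grid_shape"] = tuple(overrides["grid_shape"])
    if "true_transform" in overrides:
        from .resistance import TransformParams

        overrides["true_transform"] = TransformParams(**overrides["true_transform"])
    overrides.setdefault("seed", cfg.seed)
    return SimulationConfig(**overrides)


class PipelineRun:
    """Executes stages in dependency order, tracking outputs and timings."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "stages": {},
            "completed": False,
        }
        self.state: dict = {}

    # -- stage bodies ------------------------------------------------------
    def stage_simulate(self) -> list[Path]:
        sim_cfg = _simulation_config(self.cfg)
        gm, truth, sites, elev = simulate_dataset(sim_cfg)
        self.state.update(gm=gm, truth=truth, sites=sites, elevation=elev)
        d = self.out
        io.write_vcf(gm, d / "genotypes.vcf")
        io.write_genotype_csv(gm, d / "genotypes.csv")
        io.write_metadata(gm, d / "metadata.csv")
        sites.to_csv(d / "sites.csv", index=False)
        io.write_ascii_grid(elev, d / "elevation.asc")
        io.write_ascii_grid(truth.true_resistance, d / "true_resistance.asc")
        io.write_distance_matrix(truth.true_effective_distances, d / "true_effective.csv")
        io.write_json(
            {
                "outlier_locus_ids": truth.outlier_locus_ids,
                "covariance_scale": truth.covariance_scale,
                "p0": truth.p0,
            },
            d / "truth.json",
        )
        return [
            d / n
            for n in (
                "genotypes.vcf", "genotypes.csv", "metadata.csv", "sites.csv",
                "elevation.asc", "true_resistance.asc", "true_effective.csv",
                "truth.json",
            )
        ]

    def _require_data(self) -> GenotypeMatrix:
        if "gm" not in self.state:
            meta = io.read_metadata(self.out / "metadata.csv")
            self.state["gm"] = io.read_genotype_csv(self.out / "genotypes.csv", meta)
            self.state["sites"] = pd.read_csv(self.out / "sites.csv")
        return self.state["gm"]

    def stage_popgen(self) -> list[Path]:
        gm = self._require_data()
        p = self.cfg.section("popgen")
        seed = child_seed(self.cfg.seed, "popgen")
        d = self.out
        div = diversity_stats(gm, "site_id")
        ar, _, g_used = rarefied_allelic_richness(gm, "site_id")
        div["A_r"] = ar
        div.to_csv(d / "diversity.csv")
        fst, pmat, qmat = pairwise_fst_nei(
            gm, "site_ecotope", n_perm=p["n_perm"], seed=seed, test_pairs="within_site"
        )
        io.write_distance_matrix(fst, d / "fst_nei_groups.csv")
        pmat.to_csv(d / "fst_p.csv")
        qmat.to_csv(d / "fst_q.csv")
        gst = gst_hedrick(gm, "site_id")
        io.write_distance_matrix(gst, d / "gst_hedrick_sites.csv")
        from .popgen import fst_meirmans

        fpr = fst_meirmans(gm, "site_id")
        io.write_distance_matrix(fpr, d / "fst_meirmans_sites.csv")
        fst_sites, _, _ = pairwise_fst_nei(gm, "site_id", n_perm=0, test_pairs=[])
        io.write_distance_matrix(fst_sites, d / "fst_nei_sites.csv")
        cors = {
            "gst_vs_meirmans": matrix_correlation(gst, fpr, seed=seed),
            "gst_vs_fst": matrix_correlation(gst, fst_sites, seed=seed),
        }
        n_loci = min(gm.n_loci, int(p["max_hier_loci"]))
        gm_h = gm.subset(loci=np.arange(n_loci))
        hier = hierarchical_f(
            gm_h, ["site_id", "ecotope"], n_perm=p["hier_perm"],
            n_boot=p["hier_boot"], seed=seed,
        )
        io.write_json(
            {
                "matrix_correlations": cors,
                "hierarchical_f": {
                    "f_stats": hier.f_stats,
                    "components": hier.components,
                    "ci": hier.ci,
                    "p": hier.p,
                },
                "rarefaction_g": g_used,
            },
            d / "popgen_summary.json",
        )
        self.state["gst"] = gst
        return [
            d / n
            for n in (
                "diversity.csv", "fst_nei_groups.csv", "fst_p.csv", "fst_q.csv",
                "gst_hedrick_sites.csv", "fst_meirmans_sites.csv",
                "fst_nei_sites.csv", "popgen_summary.json",
            )
        ]

    def stage_outliers(self) -> list[Path]:
        gm = self._require_data()
        o = self.cfg.section("outliers")
        seed = child_seed(self.cfg.seed, "outliers")
        d = self.out
        covs = spatial_covariates(gm, k=3)
        rank = rf_rank(
            gm, covs, n_trees=o["n_trees"], n_runs=o["n_runs"],
            threshold=o["threshold"], seed=seed,
            spatial_correction=o["rf_spatial_correction"],
        )
        purge = None
        if len(rank.ranked_loci) >= 3:
            purge = rf_backwards_purge(
                gm, rank.ranked_loci, covs, n_trees=o["n_trees"], seed=seed,
                spatial_correction=o["rf_spatial_correction"],
            )
        rda = rda_scan(gm, covs, n_perm=o["rda_perm"], seed=seed)
        of = outflank_scan(
            gm, "ecotope", trim_low=o["trim_low"], trim_high=o["trim_high"],
            he_min=o["he_min"], q_cut=o["q_cut"],
        )
        fh = fsthet_scan(gm, "ecotope", alpha=o["alpha"])
        rf_flags = pd.Series(False, index=gm.locus_ids)
        best = purge.best_subset if purge is not None else rank.ranked_loci
        rf_flags[best] = True
        report = consensus(
            {"rf": rf_flags, "rda": rda.flags_2sd, "outflank": of.flags, "fsthet": fh.flags}
        )
        tidy = pd.DataFrame(
            {
                "importance": rank.importance,
                "z_loading": rda.z_loadings,
                "fst": of.table["fst"],
                "het": of.table["het"],
                "p_outflank": of.table["p"],
                "q_outflank": of.table["q"],
            }
        ).join(report.per_locus)
        tidy.to_csv(d / "outliers.tsv", sep="\t", index_label="locus_id")
        io.write_json(
            {
                "rf": {
                    "mean_run_correlation": rank.mean_correlation,
                    "oob_error": rank.oob_error,
                    "n_ranked": len(rank.ranked_loci),
                    "best_subset": best,
                    "best_oob_error": purge.best_oob_error if purge else None,
                },
                "rda": {
                    "variance_explained": rda.variance_explained,
                    "p_axis": rda.p_axis,
                    "n_2sd": int(rda.flags_2sd.sum()),
                    "n_3sd": int(rda.flags_3sd.sum()),
                },
                "outflank": of.extras | {"n_flagged": int(of.flags.sum())},
                "fsthet": fh.extras | {"n_flagged": int(fh.flags.sum())},
                "consensus": {
                    str(k): sorted(v) for k, v in report.at_least.items()
                },
            },
            d / "outliers_summary.json",
        )
        return [d / "outliers.tsv", d / "outliers_summary.json"]

    def stage_ibd(self) -> list[Path]:
        gm = self._require_data()
        sites = self.state["sites"]
        p = self.cfg.section("ibd")
        seed = child_seed(self.cfg.seed, "ibd")
        d = self.out
        geo = geographic_distances(sites)
        results: dict = {}
        pairs_frames = []
        for eco in ("domestic", "wild"):
            rows = np.flatnonzero(gm.meta["ecotope"].to_numpy() == eco)
            if len(rows) == 0:
                continue
            sub = gm.subset(samples=rows)
            counts = sub.meta.groupby("site_id").size()
            keep_sites = list(counts[counts >= 2].index)
            sub = sub.subset(
                samples=np.flatnonzero(sub.meta["site_id"].isin(keep_sites))
            )
            fst, _, _ = pairwise_fst_nei(sub, "site_id", n_perm=0, test_pairs=[])
            geo_sub = fst.align(geo)
            if fst.n >= 4:
                results[f"mantel_{eco}"] = mantel_test(
                    fst, geo_sub, n_perm=p["mantel_perm"], seed=seed
                )
            pt = pair_table(fst, geo_sub)
            pt["stratum"] = eco
            pairs_frames.append(pt)
        pairs = pd.concat(pairs_frames, ignore_index=True)
        fit_int = fit_mlpe(pairs, stratum_effect=True, interaction=True)
        fit_main = fit_mlpe(pairs, stratum_effect=True, interaction=False)
        contrast = slope_contrast(fit_int, reduced=fit_main)
        results["mlpe_interaction"] = fit_int.summary()
        results["mlpe_main"] = fit_main.summary()
        results["slope_contrast"] = contrast
        io.write_json(results, d / "ibd_summary.json")
        coef = pd.DataFrame({"coef": fit_int.coef, "se": fit_int.se})
        coef.to_csv(d / "ibd_coefficients.csv", index_label="term")
        io.write_distance_matrix(geo, d / "geographic_km.csv")
        return [d / "ibd_summary.json", d / "ibd_coefficients.csv", d / "geographic_km.csv"]

    def stage_optimize(self) -> list[Path]:
        gm = self._require_data()
        sites = self.state["sites"]
        o = self.cfg.section("optimize")
        seed = child_seed(self.cfg.seed, "optimize")
        d = self.out
        if "gst" in self.state:
            gst = self.state["gst"]
        else:
            gst = gst_hedrick(self._require_data(), "site_id")
        if "elevation" in self.state:
            elev = self.state["elevation"]
        else:
            elev = io.read_ascii_grid(self.out / "elevation.asc")
        spec = SurfaceSpec("elevation", rescale_surface(elev), "continuous")
        ga_cfg = GAConfig(
            pop_mult=o["pop_mult"], generations=o["generations"],
            patience=o["patience"], seed=seed,
        )
        models: list[SurfaceModel] = []
        # null and distance-only baselines
        null_fit = fit_surface_model(None, gst)
        models.append(SurfaceModel("null", "null", k=1, fit=null_fit))
        ones = elev.copy_with(np.ones(elev.shape))
        from .resistance import build_conductance_graph, commute_distance

        focal_cells = [
            ones.nearest_cell(float(r["x"]), float(r["y"])) for _, r in sites.iterrows()
        ]
        graph = build_conductance_graph(ones, 8, focal_cells)
        eff_dist = commute_distance(graph, sites, ones)
        dist_fit = fit_surface_model(eff_dist, gst)
        models.append(
            SurfaceModel("distance", "distance", k=2, fit=dist_fit, effective_dm=eff_dist)
        )
        models.append(ga_optimise([spec], gst, sites, ga_cfg, name="elevation"))
        n_sites = len(sites)
        table = model_selection(models, n=n_sites)
        table.to_csv(d / "model_selection.csv", index=False)
        boot = bootstrap_rank(
            models, gst, sites, frac=o["bootstrap_frac"],
            n_boot=o["bootstrap_iterations"], seed=seed, aicc_n=o["aicc_n"],
        )
        boot.to_csv(d / "bootstrap_rank.csv", index=False)
        best_surface = max(
            (m for m in models if m.kind == "surface"), key=lambda m: m.fit.loglik
        )
        opt_resistance = compose_resistance(best_surface.components)
        io.write_ascii_grid(opt_resistance, d / "optimised_resistance.asc")
        params = []
        for spec_i, pr in best_surface.components:
            params.append({"surface": spec_i.name, "params": dataclasses.asdict(pr)
                           if dataclasses.is_dataclass(pr) else str(pr)})
        io.write_json(
            {"best_model": table["model"].iloc[0], "parameters": params,
             "converged": best_surface.converged},
            d / "optimised_parameters.json",
        )
        self.state["opt_resistance"] = opt_resistance
        return [
            d / n
            for n in (
                "model_selection.csv", "bootstrap_rank.csv",
                "optimised_resistance.asc", "optimised_parameters.json",
            )
        ]

    def stage_current(self) -> list[Path]:
        sites = self.state.get("sites")
        if sites is None:
            sites = pd.read_csv(self.out / "sites.csv")
        res = self.state.get("opt_resistance")
        if res is None:
            res = io.read_ascii_grid(self.out / "optimised_resistance.asc")
        cm = current_map(res, sites)
        io.write_ascii_grid(cm.raster, self.out / "current_map.asc")
        io.write_distance_matrix(cm.pair_resistance, self.out / "pair_resistance.csv")
        return [self.out / "current_map.asc", self.out / "pair_resistance.csv"]

    # -- driver ------------------------------------------------------------
    def run(self) -> dict:
        bodies = {
            "simulate": self.stage_simulate,
            "popgen": self.stage_popgen,
            "outliers": self.stage_outliers,
            "ibd": self.stage_ibd,
            "optimize": self.stage_optimize,
            "current": self.stage_current,
        }
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            t0 = time.perf_counter()
            try:
                outputs = bodies[stage]()
            except Exception as exc:
                self.manifest["stages"][stage] = {
                    "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                }
                io.write_json(self.manifest, self.out / "manifest.json")
                raise
            self.manifest["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                "seed": child_seed(self.cfg.seed, stage),
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        self.manifest["completed"] = True
        io.write_json(self.manifest, self.out / "manifest.json")
        return self.manifest


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the manifest."""
    return PipelineRun(cfg).run()
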