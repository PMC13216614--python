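"""Pipeline orchestration: simulate -> qc -> grid -> diversity -> gradients
-> models, with YAML configuration, per-stage accounting and a run manifest.

Every numeric constant of the analysis (50 m depth margin, 100 km
uncertainty ceiling, 200/500 m zone edges, 5° bands, ES50 n=50, 50-record
gap threshold, 10°/20 m KDE bandwidths, ΔAIC <= 2) lives in the
configuration with its standard value as default.  Stages exchange data
through files in the output directory, so each stage is independently
runnable on the outputs of the previous one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import divstats, ecomodels, geogrid, gradmode, occqc, synthworld
from .io import read_occurrences, read_registry, write_occurrences, write_registry
from .rasters import Raster, read_esri_ascii, read_raster, write_esri_ascii

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "read_occurrences",
           "read_raster", "STAGES"]

log = logging.getLogger("oceangap")

STAGES = ("simulate", "qc", "grid", "diversity", "gradients", "model")

_REALM_OF_ZONE = {"shallow": "surface", "mesopelagic": "mesopelagic", "deep": "benthic"}
_VARS = ("temperature", "o2", "nitrate", "productivity", "radiation",
         "current_velocity")


@dataclass
class PipelineConfig:
    out_dir: str = "oceangap_run"
    seed: int = 0
    # inputs: either paths to existing data, or synthesize
    occurrences_path: str | None = None
    registry_path: str | None = None
    bathymetry_path: str | None = None
    layer_paths: dict = field(default_factory=dict)   # name -> raster path
    synth: dict = field(default_factory=dict)         # WorldConfig overrides
    # analysis constants (defaults are the standard values)
    grid_resolution: int = 3
    es_size: int = 50
    gap_threshold: int = 50
    margin_m: float = occqc.DEPTH_MARGIN_M
    max_uncertainty_m: float = occqc.MAX_UNCERTAINTY_M
    flag_zero_zero: bool = False
    kde_bandwidth_lat: float = 10.0
    kde_bandwidth_depth: float = 20.0
    n_boot: int = 2000
    delta_aic: float = ecomodels.DELTA_AIC_RULE
    collinearity_threshold: float = 0.95
    run_gam: bool = True
    gam_zones: tuple = ("shallow", "mesopelagic", "deep")
    gam_theta_grid: tuple = (0.3, 1.0, 3.0, 10.0, 100.0)
    gam_lambda_grid: tuple = (0.01, 0.3, 10.0, 300.0, 10000.0)

    def __post_init__(self) -> None:
        for name in ("margin_m", "max_uncertainty_m", "es_size", "gap_threshold",
                     "kde_bandwidth_lat", "kde_bandwidth_depth", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.grid_resolution < 0:
            raise ValueError("grid_resolution must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gam_zones"] = list(self.gam_zones)
        d["gam_theta_grid"] = list(self.gam_theta_grid)
        d["gam_lambda_grid"] = list(self.gam_lambda_grid)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True)
                              .encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str = ""
    seed: int = 0
    version: str = "0.1.0"
    stages: dict = field(default_factory=dict)   # name -> {seconds, rows, error}
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Stage runner bound to one output directory."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
        self._cache: dict = {}

    # -- helpers -----------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.out / name

    def _layers_for_zone(self, layers: dict, zone: str) -> dict:
        realm = _REALM_OF_ZONE[zone]
        sel = {v: layers[f"{v}_{realm}"] for v in _VARS if f"{v}_{realm}" in layers}
        if "hii_surface" in layers:
            sel["hii"] = layers["hii_surface"]
        if zone == "shallow" and "ice_cover_surface" in layers:
            sel["ice_cover"] = layers["ice_cover_surface"]
        return sel

    def _load_layers(self) -> dict:
        if "layers" in self._cache:
            return self._cache["layers"]
        layers = {}
        for name, p in self.cfg.layer_paths.items():
            layers[name] = read_raster(p)
        for p in sorted(self.out.glob("layer_*.asc")):
            name = p.stem[len("layer_"):]
            if name not in layers:
                layers[name] = read_esri_ascii(p)
        self._cache["layers"] = layers
        return layers

    def _bathymetry(self) -> Raster:
        if "bathy" in self._cache:
            return self._cache["bathy"]
        p = self.cfg.bathymetry_path or self.path("bathymetry.asc")
        bathy = read_raster(p)
        self._cache["bathy"] = bathy
        return bathy

    def _grid(self):
        return geogrid.build_grid(self.cfg.grid_resolution)

    # -- stages ------------------------------------------------------------
    def simulate(self) -> dict:
        wc_kw = dict(self.cfg.synth)
        wc_kw.setdefault("seed", self.cfg.seed)
        wc = synthworld.WorldConfig(**wc_kw)
        bathy, layers, registry, truth, occ = synthworld.generate_dataset(wc)
        write_esri_ascii(bathy, self.path("bathymetry.asc"))
        write_esri_ascii(truth.effort_surface, self.path("effort.asc"))
        for name, layer in layers.items():
            write_esri_ascii(layer, self.path(f"layer_{name}.asc"))
        write_registry(registry, self.path("registry.csv"))
        write_occurrences(occ, self.path("occurrences_raw.csv"))
        truth.to_json(self.path("ground_truth.json"))
        self._cache.update(bathy=bathy, layers=layers)
        return {"n_records": int(len(occ)), "n_species": int(wc.n_species)}

    def qc(self) -> dict:
        reg_path = self.cfg.registry_path or self.path("registry.csv")
        occ_path = self.cfg.occurrences_path or self.path("occurrences_raw.csv")
        registry = read_registry(reg_path)
        records, n_rejected = read_occurrences(occ_path)
        clean, report = occqc.run_qc(records, registry, self._bathymetry(),
                                     margin_m=self.cfg.margin_m,
                                     max_uncertainty_m=self.cfg.max_uncertainty_m,
                                     flag_zero_zero=self.cfg.flag_zero_zero)
        report.to_json(self.path("qc_report.json"))
        write_occurrences(clean, self.path("occurrences_clean.csv"))
        return {"rows_in": report.records_in, "rows_out": report.records_out,
                "rejected_rows": n_rejected, "species_out": report.species_out}

    def grid(self) -> dict:
        grid = self._grid()
        grid.to_geojson(self.path("grid.geojson"))
        bathy = self._bathymetry()
        layers = self._load_layers()
        for zone in geogrid.DEPTH_ZONES:
            sel = self._layers_for_zone(layers, zone)
            for frame, name in ((grid, "cell"), ("bands", "band")):
                tab = geogrid.aggregate_covariates(frame, bathy, sel)
                tab.to_csv(self.path(f"{name}_covariates_{zone}.csv"))
        return {"n_cells": len(grid)}

    def _clean_records(self) -> pd.DataFrame:
        if "clean" not in self._cache:
            df, _ = read_occurrences(self.path("occurrences_clean.csv"))
            if "accepted_species" not in df.columns:
                df["accepted_species"] = df["raw_name"]
            self._cache["clean"] = df
        return self._cache["clean"]

    def diversity(self) -> dict:
        records = self._clean_records()
        grid = self._grid()
        cells = divstats.summarize(records, grid, by="cell", es_size=self.cfg.es_size)
        bands = divstats.summarize(records, by="band", es_size=self.cfg.es_size)
        cells.to_csv(self.path("cell_summary.csv"), index=False)
        bands.to_csv(self.path("band_summary.csv"), index=False)
        per_phy = []
        for phy in sorted(records["phylum"].dropna().unique()):
            per_phy.append(divstats.summarize(records, by="band",
                                              phylum_filter=phy,
                                              es_size=self.cfg.es_size))
        if per_phy:
            pd.concat(per_phy).to_csv(self.path("band_summary_by_phylum.csv"), index=False)
        # gap accounting needs zero-record cells too
        gaps = []
        for zone in geogrid.DEPTH_ZONES:
            cov = pd.read_csv(self.path(f"cell_covariates_{zone}.csv"), index_col=0)
            full = divstats.complete_cell_table(cells[cells["depth_zone"] == zone],
                                                cov, zones=(zone,))
            gaps.append(geogrid.gap_summary(full[full["ocean_area_km2"] > 0],
                                            threshold=self.cfg.gap_threshold))
        gap = pd.concat(gaps, ignore_index=True)
        gap.to_csv(self.path("gap_summary.csv"), index=False)
        return {"cell_rows": int(len(cells)), "band_rows": int(len(bands))}

    def gradients(self) -> dict:
        records = self._clean_records()
        out = {}
        for axis in ("latitude", "depth"):
            prof, modality = gradmode.profile(records, axis=axis,
                                              es_size=self.cfg.es_size,
                                              n_boot=self.cfg.n_boot,
                                              seed=self.cfg.seed)
            prof.to_frame().to_csv(self.path(f"profile_{axis}.csv"), index=False)
            out[axis] = {k: v.to_dict() for k, v in modality.items()}
        with open(self.path("modality.json"), "w") as fh:
            json.dump(out, fh, indent=2)
        return {"axes": list(out)}

    def model(self) -> dict:
        cells = pd.read_csv(self.path("cell_summary.csv"))
        bands = pd.read_csv(self.path("band_summary.csv"))
        suites = []
        curves = []
        for zone in geogrid.DEPTH_ZONES:
            bcov = pd.read_csv(self.path(f"band_covariates_{zone}.csv"), index_col=0)
            btab = bands[bands["depth_zone"] == zone].merge(
                bcov.reset_index(), on="band_index", how="right")
            btab["n_records"] = btab["n_records"].fillna(0)
            btab["s_obs"] = btab["s_obs"].fillna(0)
            covs = self._zone_covariates(zone, btab.columns)
            for response in ("s_obs", "es50"):
                try:
                    suite = ecomodels.candidate_suite(
                        btab, response, covs,
                        threshold=self.cfg.collinearity_threshold)
                except ValueError as exc:
                    log.warning("GLM suite %s/%s skipped: %s", zone, response, exc)
                    continue
                t = suite.table()
                t.insert(0, "zone", zone)
                t.insert(1, "engine", "glm")
                suites.append(t)
            if self.cfg.run_gam and zone in self.cfg.gam_zones:
                ccov = pd.read_csv(self.path(f"cell_covariates_{zone}.csv"), index_col=0)
                ctab = divstats.complete_cell_table(
                    cells[cells["depth_zone"] == zone], ccov, zones=(zone,))
                ctab = ctab[ctab["ocean_area_km2"] > 0]
                covs = self._zone_covariates(zone, ctab.columns)
                for response in ("s_obs", "es50"):
                    try:
                        suite = ecomodels.gam_suite(
                            ctab, response, covs,
                            threshold=self.cfg.collinearity_threshold,
                            theta_grid=np.array(self.cfg.gam_theta_grid),
                            lambda_grid=np.array(self.cfg.gam_lambda_grid))
                    except ValueError as exc:
                        log.warning("GAM suite %s/%s skipped: %s", zone, response, exc)
                        continue
                    t = suite.table()
                    t.insert(0, "zone", zone)
                    t.insert(1, "engine", "gam")
                    suites.append(t)
                    best = suite.fits[0]
                    if isinstance(best, ecomodels.GamFit):
                        for term in best.design.smooth_terms:
                            c = best.term_curve(term)
                            c.insert(0, "zone", zone)
                            c.insert(1, "response", response)
                            c.insert(2, "term", term)
                            curves.append(c)
        if suites:
            pd.concat(suites, ignore_index=True).to_csv(self.path("model_suites.csv"),
                                                        index=False)
        if curves:
            pd.concat(curves, ignore_index=True).to_csv(self.path("gam_curves.csv"),
                                                        index=False)
        return {"n_suites": len(suites)}

    def _zone_covariates(self, zone: str, columns) -> list[str]:
        base = ["ocean_area_km2", "max_depth_m", "hii_mean",
                "temperature_mean", "current_velocity_mean", "nitrate_mean",
                "productivity_mean", "radiation_mean", "o2_mean"]
        if zone == "shallow":
            base = ["shelf_area_km2", "ice_cover_mean"] + base
        else:
            base = ["margin_area_km2"] + base
        return [c for c in base if c in columns]

    def report(self) -> None:
        lines = ["# oceangap run report", "",
                 f"- config hash: `{self.manifest.config_hash}`",
                 f"- seed: {self.manifest.seed}", ""]
        for name, info in self.manifest.stages.items():
            lines.append(f"## {name}")
            for k, v in info.items():
                lines.append(f"- {k}: {v}")
            lines.append("")
        try:
            with open(self.path("report.md"), "w") as fh:
                fh.write("\n".join(lines))
        except OSError:                      # report generation never fails a run
            log.exception("could not write report")


def run_pipeline(config: PipelineConfig, stages=STAGES) -> RunManifest:
    """Run the requested stages in order; any failure is recorded in the
    manifest and later stages are skipped."""
    run = _Run(config)
    failed = False
    for name in STAGES:
        if name not in stages:
            continue
        if failed:
            run.manifest.stages[name] = {"skipped": True}
            continue
        t0 = time.time()
        try:
            info = getattr(run, name)() or {}
            info["seconds"] = round(time.time() - t0, 3)
            run.manifest.stages[name] = info
            log.info("stage %s done in %.1fs", name, info["seconds"])
        except Exception as exc:
            failed = True
            run.manifest.stages[name] = {"error": f"{type(exc).__name__}: {exc}",
                                         "seconds": round(time.time() - t0, 3)}
            log.error("stage %s failed:\n%s", name, traceback.format_exc())
    run.report()
    for p in sorted(run.out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            run.manifest.outputs[p.name] = _sha256(p)
    run.manifest.to_json(run.path("manifest.json"))
    return run.manifest
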