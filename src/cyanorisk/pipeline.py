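"""End-to-end pipeline: synthesize/ingest → retrieve → coverage → SMR →
spatial statistics → NB-CAR regression.

A single YAML config drives the whole chain.  Every stage writes its
outputs into the run directory in the module interchange formats (GeoJSON,
CSV, npz-with-sidecar), and a manifest records the config, derived
per-stage seeds, and content checksums, so a rerun with the same master
seed is reproducible and ``resume=True`` can rebuild any deleted
intermediate identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bloom_map, mortality, spatial_stats, cluster_scan
from .geo_synth import (SyntheticScenario, make_county_grid, make_pigment_field,
                        make_covariates, forward_reflectance, simulate_mortality)
from .nbcar import NegativeBinomialCAR
from .rasters import PigmentRaster, ReflectanceScene
from .regions import CountyMap
from .retrieval import OpticalConstants, retrieve_pigments, max_value_composite

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("synth", "retrieve", "coverage", "smr", "spatial", "model")


@dataclass
class PipelineConfig:
    """All pipeline parameters plus the master seed.

    Per-stage seeds are derived from ``master_seed`` through a fixed
    ``SeedSequence`` schedule, so stages can be rerun independently yet
    reproducibly.
    """

    mode: str = "synthetic"                    # "synthetic" | "real"
    outdir: str = "runs/run"
    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)
    paths: dict = field(default_factory=dict)  # real mode inputs
    pc_threshold: float = 4.0
    coverage_denominator: str = "county_area"
    lisa_permutations: int = 999
    lisa_alpha: float = 0.05
    scan_K: int = 5
    scan_mc: int = 999
    scan_alpha: float = 0.01
    mcmc_burn: int = 5000
    mcmc_iter: int = 10000
    master_seed: int = 17

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if isinstance(self.scenario, dict):
            self.scenario = SyntheticScenario(**self.scenario)
        if self.mode == "real":
            for key in ("counties", "mortality"):
                p = self.paths.get(key)
                if not p or not Path(p).exists():
                    raise ValueError(f"real mode requires existing path for {key!r}")

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.master_seed)
        state = ss.generate_state(len(STAGES)).astype(np.uint64)
        return {name: int(s % (2 ** 31)) for name, s in zip(STAGES, state)}

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["scenario"]["true_beta"] = list(self.scenario.true_beta)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _digest(path: Path) -> str:
    """Content checksum; npz bundles are hashed by array contents so the
    digest is stable across re-writes (zip headers carry timestamps)."""
    if path.suffix == ".npz":
        h = hashlib.sha256()
        with np.load(path) as data:
            for key in sorted(data.files):
                h.update(key.encode())
                h.update(np.ascontiguousarray(data[key]).tobytes())
        return h.hexdigest()
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Stage-by-stage execution with manifest bookkeeping."""

    def __init__(self, config: PipelineConfig, resume: bool = False):
        self.config = config
        self.resume = resume
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seeds = config.stage_seeds()
        self.manifest = {"config": self._config_dict(), "seeds": self.seeds,
                         "stages": {}}

    def _config_dict(self) -> dict:
        d = asdict(self.config)
        d["scenario"]["true_beta"] = list(self.config.scenario.true_beta)
        return d

    def _outputs_exist(self, names: list[str]) -> bool:
        return all((self.outdir / n).exists() for n in names)

    def _record(self, stage: str, names: list[str]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {n: _digest(self.outdir / n) for n in names}}

    def _run_stage(self, stage: str, names: list[str], fn) -> None:
        if self.resume and self._outputs_exist(names):
            logger.info("stage %s: outputs present, skipping", stage)
        else:
            logger.info("stage %s: running", stage)
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        self._record(stage, names)

    # ------------------------------------------------------------- stages

    def stage_synth(self) -> None:
        cfg = self.config
        out = self.outdir
        if cfg.mode == "real":
            shutil.copy(cfg.paths["counties"], out / "counties.geojson")
            shutil.copy(cfg.paths["mortality"], out / "mortality.csv")
            if cfg.paths.get("covariates"):
                shutil.copy(cfg.paths["covariates"], out / "covariates.csv")
            return
        rng = np.random.default_rng(self.seeds["synth"])
        scen = cfg.scenario
        counties = make_county_grid(scen.grid_nx, scen.grid_ny, scen.cell_size)
        counties.to_geojson(out / "counties.geojson")
        pig, coverage_true = make_pigment_field(counties, scen, rng=rng,
                                                pc_threshold=cfg.pc_threshold)
        pig.save(out / "pigments_true.npz")
        cov = make_covariates(counties, scen, rng=rng, coverage_pct=coverage_true)
        cov.to_csv(out / "covariates.csv", index=False)
        sim = simulate_mortality(counties, cov, scen, rng=rng)
        sim.table.to_csv(out / "mortality.csv", index=False)
        truth = pd.DataFrame({"county_id": counties.ids,
                              "coverage_true_pct": coverage_true,
                              "expected_true": sim.expected,
                              "mu_true": sim.mu, "phi_true": sim.phi,
                              "e_true": sim.e})
        truth.to_csv(out / "truth.csv", index=False)

    def stage_retrieve(self) -> None:
        cfg = self.config
        out = self.outdir
        consts = OpticalConstants()
        if cfg.mode == "real":
            scene_paths = cfg.paths.get("scenes") or [cfg.paths["scene"]]
            scenes = [ReflectanceScene.load(p) for p in scene_paths]
        else:
            pig_true = PigmentRaster.load(out / "pigments_true.npz")
            scene = forward_reflectance(pig_true, b_b=0.2, consts=consts)
            scene.save(out / "scene.npz")
            scenes = [scene]
        retrieved = [retrieve_pigments(s, consts) for s in scenes]
        composite = max_value_composite(retrieved)
        composite.save(out / "pigments.npz")

    def stage_coverage(self) -> None:
        cfg = self.config
        out = self.outdir
        counties = CountyMap.from_geojson(out / "counties.geojson")
        pig = PigmentRaster.load(out / "pigments.npz")
        thr = bloom_map.BloomThreshold(pc_threshold_ug_L=cfg.pc_threshold)
        mask = bloom_map.bloom_mask(pig, thr)
        cov = bloom_map.county_coverage(mask, counties, pig.grid,
                                        water_mask=pig.water_mask,
                                        denominator=cfg.coverage_denominator)
        cov.to_csv(out / "coverage.csv", index=False)

    def stage_smr(self) -> None:
        out = self.outdir
        table = pd.read_csv(out / "mortality.csv")
        smr = mortality.smr_table(table)
        smr.to_csv(out / "smr.csv", index=False)

    def stage_spatial(self) -> None:
        cfg = self.config
        out = self.outdir
        counties = CountyMap.from_geojson(out / "counties.geojson")
        smr = pd.read_csv(out / "smr.csv")
        cov = pd.read_csv(out / "coverage.csv")
        df = smr.merge(cov[["county_id", "coverage_pct"]], on="county_id")
        keep = df[~df["suppressed"].astype(bool)].reset_index(drop=True)

        idx = [counties.index_of(c) for c in keep["county_id"].astype(str)]
        pos = {old: new for new, old in enumerate(idx)}
        sub_neighbors = [np.array([pos[j] for j in counties.neighbors[old]
                                   if j in pos], dtype=int) for old in idx]
        W = spatial_stats.SpatialWeights(neighbors=sub_neighbors)

        x = keep["smr"].to_numpy(dtype=float)
        yv = keep["coverage_pct"].to_numpy(dtype=float)
        moran = spatial_stats.bivariate_moran(x, yv, W)
        lisa = spatial_stats.bivariate_lisa(
            x, yv, W, n_perm=cfg.lisa_permutations, alpha=cfg.lisa_alpha,
            seed=self.seeds["spatial"], ids=keep["county_id"].tolist())
        lisa.to_csv(out / "lisa.csv", index=False)

        sub_polys = [counties.polygons[i] for i in idx]
        sub_map = CountyMap(ids=keep["county_id"].tolist(), polygons=sub_polys,
                            neighbors=[list(nb) for nb in sub_neighbors])
        scan = cluster_scan.flex_scan(
            sub_map, keep["observed"].to_numpy(float),
            keep["expected"].to_numpy(float), K=cfg.scan_K, n_mc=cfg.scan_mc,
            alpha=cfg.scan_alpha, seed=self.seeds["spatial"] + 1)
        rows = [{"rank": k + 1, "members": ";".join(c.region_ids),
                 "n_Z": c.n_Z, "e_Z": c.e_Z, "llr": c.llr, "p": c.p_value}
                for k, c in enumerate(scan.clusters)]
        pd.DataFrame(rows, columns=["rank", "members", "n_Z", "e_Z",
                                    "llr", "p"]).to_csv(
            out / "scan_clusters.csv", index=False)

        in_cluster = set()
        for c in scan.significant:
            in_cluster.update(c.region_ids)
        flag = keep["county_id"].isin(in_cluster).to_numpy()
        if flag.any() and (~flag).any():
            stat, p = spatial_stats.rank_test(yv[flag], yv[~flag])
        else:
            stat, p = float("nan"), float("nan")
        summary = {"global_moran_I": moran,
                   "n_significant_clusters": len(scan.significant),
                   "cluster_rank_test": {"statistic": stat, "p": p}}
        with open(out / "spatial_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)

    def stage_model(self) -> None:
        cfg = self.config
        out = self.outdir
        counties = CountyMap.from_geojson(out / "counties.geojson")
        smr = pd.read_csv(out / "smr.csv")
        cov = pd.read_csv(out / "coverage.csv")
        extra = pd.read_csv(out / "covariates.csv")
        df = (smr.merge(cov[["county_id", "coverage_pct"]], on="county_id")
                 .merge(extra[["county_id", "education", "race"]], on="county_id"))
        model = NegativeBinomialCAR.from_dataframe(
            df, counties, covariates=["coverage_pct", "education", "race"])
        post = model.fit(n_burn=cfg.mcmc_burn, n_iter=cfg.mcmc_iter,
                         seed=self.seeds["model"])
        post.summary().to_csv(out / "posterior_summary.csv")
        post.risk_ratios().to_csv(out / "risk_ratios.csv")
        post.to_frame().to_csv(out / "draws.csv", index=False)

    # ---------------------------------------------------------------- run

    def run(self) -> dict:
        cfg = self.config
        stage_outputs = {
            "synth": (["counties.geojson", "mortality.csv", "covariates.csv"]
                      + (["pigments_true.npz", "truth.csv"]
                         if cfg.mode == "synthetic" else [])),
            "retrieve": (["pigments.npz"]
                         + (["scene.npz"] if cfg.mode == "synthetic" else [])),
            "coverage": ["coverage.csv"],
            "smr": ["smr.csv"],
            "spatial": ["lisa.csv", "scan_clusters.csv", "spatial_summary.json"],
            "model": ["posterior_summary.csv", "risk_ratios.csv", "draws.csv"],
        }
        fns = {"synth": self.stage_synth, "retrieve": self.stage_retrieve,
               "coverage": self.stage_coverage, "smr": self.stage_smr,
               "spatial": self.stage_spatial, "model": self.stage_model}
        for stage in STAGES:
            self._run_stage(stage, stage_outputs[stage], fns[stage])
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)
        return self.manifest


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full chain; returns the manifest dict."""
    return PipelineRun(config, resume=resume).run()
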