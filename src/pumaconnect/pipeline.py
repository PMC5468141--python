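"""End-to-end orchestration: synthetic data -> screened telemetry ->
movement surfaces -> habitat model -> connectivity -> risk overlay.

All tunables live in :class:`RunConfig`, whose defaults are the analysis
constants (PDOP cap 10, 200-m cluster radius, 26.2-m location error,
24-h maximum lag, 1e-5 surface extent threshold, 95th/90th percentiles,
3000/5000 vehicles-per-day thresholds, 1-km marker radius). Every source
of randomness funnels through named per-stage seeds derived from one base
seed, so a run is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bbmm, circuit, habitat, risk, synthetic, telemetry
from .covariates import CovariateStack, screen_collinearity
from .raster import RasterGrid

log = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "covariates", "bbmm", "fit", "predict",
          "connect", "risk")


@dataclass
class RunConfig:
    """All pipeline tunables, defaulting to the analysis constants."""

    # telemetry screening
    max_pdop: float = 10.0
    cluster_radius_m: float = 200.0
    max_lag_h: float = 24.0
    # movement surfaces
    location_error_m: float = 26.2
    extent_threshold: float = 1e-5
    n_time_steps: int = 25
    # habitat model
    response_floor: float = 1e-5
    conductance_epsilon: float = 1e-3
    # connectivity & risk
    neighborhood: int = 8
    solver: str = "direct"
    pinch_percentile: float = 95.0
    development_percentile: float = 90.0
    aadt_low: float = 3000.0
    aadt_marginal: float = 5000.0
    marker_radius_m: float = 1000.0
    # synthetic scenario (desk scale)
    n_rows: int = 64
    n_cols: int = 64
    cell_size: float = 270.0
    autocorrelation_range_m: float = 1500.0
    n_individuals: int = 8
    n_fixes: int = 300
    seed: int = 0
    # paths
    out_dir: str = "scratch/run"

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed below 2**31 derived from the base seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def with_overrides(self, overrides: dict) -> "RunConfig":
        return replace(self, **overrides)


@dataclass
class RunResult:
    """In-memory artifacts of a full run."""

    config: RunConfig
    stack: CovariateStack
    tracks: list
    screened: list
    filter_report: pd.DataFrame
    surfaces: list
    design: pd.DataFrame
    components: "habitat.VarianceComponents"
    fits: list
    averaged: "habitat.AveragedHabitatModel"
    global_null: dict
    quality: RasterGrid
    conductance: RasterGrid
    currents: dict
    pinch: "risk.PinchPointSet"
    risk_sites: list
    manifest: dict = field(default_factory=dict)


def _boundary_mask(shape: tuple[int, int]) -> np.ndarray:
    """Irregular in-study region: the rectangle minus clipped corners.

    Stands in for a study boundary inside the rectangular map extent so
    the random boundary fill has work to do.
    """
    nr, nc = shape
    mask = np.ones(shape, dtype=bool)
    cut = max(2, min(nr, nc) // 8)
    for r in range(cut):
        mask[r, :cut - r] = False
        mask[nr - 1 - r, nc - (cut - r):] = False
    return mask


def run_all(config: RunConfig, save_artifacts: bool = True) -> RunResult:
    """Execute every stage on a synthetic scenario; see module docstring."""
    out = Path(config.out_dir)
    timings: dict[str, float] = {}
    manifest: dict = {"seeds": {s: config.stage_seed(s) for s in STAGES},
                      "config": asdict(config), "stage_timings_s": timings}

    def _stage(name):
        t0 = time.perf_counter()
        log.info("[%s] starting", name)
        return t0

    def _done(name, t0):
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("[%s] done in %.1fs", name, timings[name])

    # -- simulate ------------------------------------------------------
    t0 = _stage("simulate")
    spec = synthetic.LandscapeSpec(
        n_rows=config.n_rows, n_cols=config.n_cols,
        cell_size=config.cell_size,
        autocorrelation_range_m=config.autocorrelation_range_m,
        seed=config.stage_seed("simulate"))
    stack = synthetic.gen_covariate_stack(spec)
    model = synthetic.TrueMovementModel()
    tracks = synthetic.simulate_tracks(stack, model, config.n_individuals,
                                       config.n_fixes,
                                       config.stage_seed("simulate") + 1)
    roads, markers, imperv_2010, imperv_2030 = \
        synthetic.gen_roads_and_projections(stack,
                                            config.stage_seed("simulate") + 2)
    _done("simulate", t0)

    # -- filter --------------------------------------------------------
    t0 = _stage("filter")
    screened, reports = [], []
    for tr in tracks:
        s, rep = telemetry.screen_track(tr, config.max_pdop,
                                        config.cluster_radius_m)
        screened.append(s)
        reports.append(rep)
    filter_report = pd.DataFrame(reports)
    _done("filter", t0)

    # -- covariates (standardization done by generator; screen here) ---
    t0 = _stage("covariates")
    screening = screen_collinearity(stack, seed=config.stage_seed("covariates"))
    manifest["covariate_screening"] = {
        "max_abs_r": screening["max_abs_r"],
        "max_vif": max(screening["vif"].values()),
        "flagged_pairs": screening["flagged_pairs"],
        "flagged_vif": screening["flagged_vif"]}
    _done("covariates", t0)

    # -- bbmm ----------------------------------------------------------
    t0 = _stage("bbmm")
    grid = stack.grid
    surfaces = []
    for tr in screened:
        s2 = bbmm.estimate_brownian_variance(tr, config.location_error_m,
                                             config.max_lag_h)
        surfaces.append(bbmm.occurrence_surface(
            tr, s2, config.location_error_m, grid, config.extent_threshold,
            config.max_lag_h, config.n_time_steps))
    _done("bbmm", t0)

    # -- fit -----------------------------------------------------------
    t0 = _stage("fit")
    design_parts = []
    for i, (tr, surf) in enumerate(zip(screened, surfaces)):
        buf = bbmm.buffered_extent(surf, telemetry.max_step_length(
            tr, config.max_lag_h))
        design_parts.append(habitat.sample_design(
            surf, buf, stack, tr, len(tr),
            (config.stage_seed("fit") + i) % (2 ** 31),
            config.response_floor))
    design = pd.concat(design_parts, ignore_index=True)
    components = habitat.estimate_variance_components(design)
    fits = habitat.fit_all_subsets(design, components)
    averaged = habitat.model_average(fits)
    global_terms = habitat.HABITAT_TERMS + (habitat.QUADRATIC_TERM,)
    global_fit = next(f for f in fits if f.terms == global_terms)
    null_fit = habitat.fit_lmm(design, ())
    global_null = habitat.compare_global_null(global_fit, null_fit)
    _done("fit", t0)

    # -- predict -------------------------------------------------------
    t0 = _stage("predict")
    quality = habitat.predict_quality(averaged, stack)
    conductance = habitat.quality_to_conductance(
        quality, stack.water_mask, epsilon=config.conductance_epsilon)
    _done("predict", t0)

    # -- connect -------------------------------------------------------
    t0 = _stage("connect")
    boundary = _boundary_mask(grid.shape)
    currents = circuit.omnidirectional(conductance, boundary,
                                       config.stage_seed("connect"),
                                       config.neighborhood, config.solver)
    _done("connect", t0)

    # -- risk ----------------------------------------------------------
    t0 = _stage("risk")
    pinch = risk.pinch_points(currents["SUM"], boundary,
                              config.pinch_percentile)
    sites = []
    sites += risk.development_risk(pinch, imperv_2010, imperv_2030,
                                   config.development_percentile)
    sites += risk.traffic_current_barriers(
        pinch, markers, radius_m=config.marker_radius_m,
        threshold=config.aadt_marginal)
    sites += risk.traffic_future_risk(
        pinch, markers, low=config.aadt_low, marginal=config.aadt_marginal,
        radius_m=config.marker_radius_m)
    _done("risk", t0)

    result = RunResult(config, stack, tracks, screened, filter_report,
                       surfaces, design, components, fits, averaged,
                       global_null, quality, conductance, currents, pinch,
                       sites, manifest)
    manifest["coefficient_table"] = averaged.table().to_dict("records")
    manifest["global_vs_null_delta_aic"] = global_null["delta_aic"]
    manifest["risk_site_counts"] = _risk_counts(sites)
    manifest["content_hash"] = _manifest_hash(result)

    if save_artifacts:
        _write_artifacts(result, out, roads, markers, imperv_2010,
                         imperv_2030)
    return result


def _risk_counts(sites) -> dict[str, int]:
    counts = {"development": 0, "traffic_current": 0, "traffic_future": 0}
    for s in sites:
        counts[s.risk_class] += 1
    return counts


def _manifest_hash(result: RunResult) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(result.quality.values).tobytes())
    h.update(np.ascontiguousarray(result.currents["SUM"].current.values)
             .tobytes())
    h.update(result.filter_report.to_csv(index=False).encode())
    return h.hexdigest()


def _write_artifacts(result: RunResult, out: Path, roads, markers,
                     imperv_2010, imperv_2030) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    synthetic.write_telemetry_csv(result.tracks, out / "telemetry.csv",
                                  out / "attributes.csv")
    synthetic.write_roads_geojson(roads, markers, out / "roads.geojson",
                                  out / "markers.geojson")
    result.filter_report.to_csv(out / "filter_report.csv", index=False)
    result.design.to_csv(out / "design.csv", index=False)
    result.averaged.table().to_csv(out / "model_table.csv", index=False)
    result.quality.write_ascii(out / "quality.asc")
    result.conductance.write_ascii(out / "conductance.asc")
    for name, cm in result.currents.items():
        cm.current.write_ascii(out / f"current_{name.lower()}.asc")
    imperv_2010.write_ascii(out / "impervious_2010.asc")
    imperv_2030.write_ascii(out / "impervious_2030.asc")
    risk.risk_sites_frame(result.risk_sites).to_csv(out / "risk_sites.csv",
                                                    index=False)
    surf_rows = [{"animal_id": s.animal_id, "sigma2_m": s.sigma2_m,
                  "n_bridges": s.n_bridges, "retained_mass": s.retained_mass}
                 for s in result.surfaces]
    pd.DataFrame(surf_rows).to_csv(out / "bbmm_summary.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def report(result: RunResult, out_dir=None, thumbnails: bool = True) -> dict:
    """Summary of a completed run: ordered coefficient table, risk-site
    counts by class (zeros included) and, optionally, PNG map thumbnails."""
    if result.averaged is None:
        raise ValueError("run manifest lacks a completed fit stage")
    table = result.averaged.table()
    counts = _risk_counts(result.risk_sites)
    summary = {"coefficient_table": table,
               "risk_site_counts": counts,
               "global_vs_null_delta_aic": result.global_null["delta_aic"],
               "n_candidate_models": len(result.fits)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "report_table.csv", index=False)
        with open(out / "report_summary.json", "w") as fh:
            json.dump({k: v for k, v in summary.items()
                       if k != "coefficient_table"}, fh, indent=2)
        if thumbnails:
            _thumbnails(result, out)
    return summary


def _thumbnails(result: RunResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("quality", result.quality.values),
              ("conductance", result.conductance.values),
              ("current_sum", result.currents["SUM"].current.values)]
    for name, vals in panels:
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(vals, cmap="viridis")
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(name)
        ax.set_axis_off()
        fig.savefig(out / f"{name}.png", dpi=100, bbox_inches="tight")
        plt.close(fig)
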