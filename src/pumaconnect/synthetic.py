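"""Synthetic landscapes, telemetry, roads and land-use projections.

The generator produces inputs with the statistical structure the analysis
assumes, so every downstream stage is testable without real GIS or collar
data: spatially autocorrelated covariate rasters with bounded pairwise
correlations, multi-individual GPS tracks driven by a known
habitat-selection model (ground truth for parameter recovery), and toy
road networks with traffic counts at two epochs plus impervious-surface
rasters whose growth clusters near existing human modification.

Random fields use FFT (circulant-spectrum) synthesis with an exponential
covariance, matching the exponential spatial covariance assumed by the
habitat model's residual structure. Track steps are drawn from a discrete
redistribution kernel over nearby cells so that selection expectations
are exactly computable by brute force in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, mapping

from .covariates import CovariateStack, distance_to_water, standardize
from .raster import RasterGrid

CONTINUOUS_LAYERS = ("ruggedness", "tpi", "dist_water")
COVER_LAYERS = ("forest", "riparian", "shrub")
ALL_LAYERS = CONTINUOUS_LAYERS + COVER_LAYERS + ("human_mod",)

SEXES = ("F", "M")
AGE_CLASSES = ("young_adult", "adult")
CAPTURE_AREAS = ("A", "B", "C")


@dataclass
class LandscapeSpec:
    """Dimensions and statistical targets for a synthetic landscape."""

    n_rows: int = 64
    n_cols: int = 64
    cell_size: float = 270.0
    autocorrelation_range_m: float = 1500.0
    max_pairwise_r: float = 0.5
    water_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 16 or self.n_cols < 16:
            raise ValueError("landscape must be at least 16x16 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not 0 < self.max_pairwise_r <= 1:
            raise ValueError("max_pairwise_r must be in (0, 1]")


@dataclass
class TrueMovementModel:
    """Ground-truth habitat selection driving simulated tracks.

    ``coefficients`` act on standardized layers inside an exponential
    selection weight; the step kernel is Gaussian in distance with scale
    ``step_scale_m``. Stationary clusters (den/kill-site stand-ins) are
    injected at ``cluster_rate`` per 100 fixes with all cluster fixes
    within ``cluster_radius_m`` of the anchor fix.
    """

    coefficients: dict[str, float] = field(
        default_factory=lambda: {"ruggedness": 1.5, "shrub": 1.0,
                                 "human_mod": -1.0})
    step_scale_m: float = 600.0
    fix_interval_h: float = 4.15
    cluster_rate: float = 2.0        # clusters per 100 fixes
    cluster_radius_m: float = 80.0
    pdop_exceed_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.step_scale_m <= 0:
            raise ValueError("step-kernel scale must be positive")
        if not self.cluster_radius_m < 200.0:
            raise ValueError("cluster radius must be < 200 m so injected "
                             "clusters are removable by the screening rule")


# ---------------------------------------------------------------------------
# Gaussian random fields
# ---------------------------------------------------------------------------

def gaussian_random_field(n_rows: int, n_cols: int, range_cells: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian field with exponential covariance, unit variance.

    FFT synthesis: the torus covariance exp(-d/range) is diagonalized by
    the 2-D DFT; white noise is colored by the square root of its (clipped)
    spectrum. ``range_cells`` -> 0 degenerates to white noise.
    """
    noise = rng.standard_normal((n_rows, n_cols))
    if range_cells <= 1e-9:
        return (noise - noise.mean()) / noise.std()
    ii = np.minimum(np.arange(n_rows), n_rows - np.arange(n_rows))
    jj = np.minimum(np.arange(n_cols), n_cols - np.arange(n_cols))
    d = np.hypot(ii[:, None], jj[None, :])
    cov = np.exp(-d / range_cells)
    spectrum = np.fft.fft2(cov).real
    spectrum = np.clip(spectrum, 0.0, None)
    fld = np.fft.ifft2(np.sqrt(spectrum) * np.fft.fft2(noise)).real
    return (fld - fld.mean()) / fld.std()


def _pairwise_max_abs_r(layers: dict[str, np.ndarray]) -> float:
    mat = np.stack([v.ravel() for v in layers.values()])
    corr = np.corrcoef(mat)
    np.fill_diagonal(corr, 0.0)
    return float(np.abs(corr).max())


def gen_covariate_stack(spec: LandscapeSpec,
                        max_attempts: int = 25) -> CovariateStack:
    """Generate the named covariate stack plus a water mask.

    Continuous layers (ruggedness, tpi, dist_water) are z-standardized
    random fields; cover layers (forest, riparian, shrub) are fields
    mapped into [0, 1] before standardization; human_mod derives from a
    [0, 1] intensity field. dist_water is the distance transform of the
    water mask. The stack is resampled (fresh draws) until all pairwise
    Pearson |r| <= spec.max_pairwise_r, failing after ``max_attempts``.
    """
    rng = np.random.default_rng(spec.seed)
    range_cells = spec.autocorrelation_range_m / spec.cell_size
    shape = (spec.n_rows, spec.n_cols)
    base = RasterGrid(np.zeros(shape), cell_size=spec.cell_size)

    for _ in range(max_attempts):
        raw: dict[str, np.ndarray] = {}
        for name in ("ruggedness", "tpi"):
            raw[name] = gaussian_random_field(*shape, range_cells, rng)
        water_field = gaussian_random_field(*shape, range_cells, rng)
        water_mask = water_field >= np.quantile(water_field,
                                                1 - spec.water_fraction)
        raw["dist_water"] = distance_to_water(water_mask, base).values
        for name in COVER_LAYERS:
            g = gaussian_random_field(*shape, range_cells, rng)
            raw[name] = np.clip(0.5 + 0.25 * g, 0.0, 1.0)
        human_intensity = np.clip(
            0.35 + 0.25 * gaussian_random_field(*shape, range_cells, rng),
            0.0, 1.0)
        raw["human_mod"] = human_intensity

        zs = {k: (v - v.mean()) / v.std() for k, v in raw.items()}
        if _pairwise_max_abs_r(zs) <= spec.max_pairwise_r:
            layers = {k: base.like(raw[k]) for k in ALL_LAYERS}
            stack = standardize(CovariateStack(layers, water_mask=water_mask))
            stack.human_intensity = human_intensity  # kept for projections
            return stack
    raise RuntimeError(
        f"could not satisfy pairwise |r| <= {spec.max_pairwise_r} "
        f"in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def step_kernel_offsets(step_scale_m: float, cell_size: float):
    """Offsets and Gaussian distance weights of the discrete step kernel
    (cells within radius 3 * step_scale_m)."""
    r = int(np.ceil(3.0 * step_scale_m / cell_size))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    dist = np.hypot(dr, dc) * cell_size
    inside = dist <= 3.0 * step_scale_m
    w = np.exp(-0.5 * (dist[inside] / step_scale_m) ** 2)
    return dr[inside], dc[inside], w


def selection_weight(stack: CovariateStack,
                     coefficients: dict[str, float]) -> np.ndarray:
    """exp(sum coef * standardized layer), the habitat term of the kernel."""
    lin = np.zeros(stack.grid.shape)
    for name, coef in coefficients.items():
        if name not in stack.layers:
            raise KeyError(f"unknown layer {name!r} in movement model")
        lin += coef * stack.layers[name].values
    return np.exp(lin)


def simulate_tracks(stack: CovariateStack, model: TrueMovementModel,
                    n_individuals: int, n_fixes: int, seed: int,
                    start_iso: str = "2006-01-01T00:00:00Z"):
    """Simulate GPS tracks from the discrete redistribution kernel.

    Each step moves to a cell within 3 * step_scale of the current cell
    with weight Gaussian(distance) * exp(sum coef * layer). Timestamps
    are regular at the fix interval; PDOP exceeds 10 for a configurable
    fraction of fixes; stationary clusters are injected at the configured
    rate, with ground-truth indices stored in ``track.meta``. Attributes
    (sex, age class, capture area) are assigned round-robin.
    """
    from .telemetry import Track

    if n_fixes < 20:
        raise ValueError("need at least 20 fixes per individual")
    grid = stack.grid
    dr, dc, wdist = step_kernel_offsets(model.step_scale_m, grid.cell_size)
    if int(np.ceil(3 * model.step_scale_m / grid.cell_size)) * 2 + 1 \
            > min(grid.shape):
        raise ValueError("arena too small for the step-kernel radius")
    habitat = selection_weight(stack, model.coefficients)
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(start_iso)

    tracks = []
    for k in range(n_individuals):
        rows = np.empty(n_fixes, dtype=int)
        cols = np.empty(n_fixes, dtype=int)
        rows[0] = rng.integers(0, grid.n_rows)
        cols[0] = rng.integers(0, grid.n_cols)
        for i in range(1, n_fixes):
            rr = rows[i - 1] + dr
            cc = cols[i - 1] + dc
            ok = (rr >= 0) & (rr < grid.n_rows) & (cc >= 0) & (cc < grid.n_cols)
            w = wdist[ok] * habitat[rr[ok], cc[ok]]
            j = rng.choice(np.count_nonzero(ok), p=w / w.sum())
            rows[i], cols[i] = rr[ok][j], cc[ok][j]
        x, y = grid.cell_center(rows, cols)
        x = x.astype(float)
        y = y.astype(float)

        # inject stationary clusters: runs of fixes near an anchor point
        n_clusters = rng.poisson(model.cluster_rate * n_fixes / 100.0)
        cluster_spans = []
        for _ in range(n_clusters):
            length = int(rng.integers(3, 7))
            start = int(rng.integers(1, max(2, n_fixes - length - 1)))
            span = (start, min(start + length, n_fixes - 1))
            if any(s < span[1] and span[0] < e for s, e in cluster_spans):
                continue  # keep injected clusters disjoint
            cluster_spans.append(span)
            ax, ay = x[span[0]], y[span[0]]
            for i in range(span[0] + 1, span[1]):
                # all cluster fixes within radius/2 of the anchor, so every
                # pairwise distance stays below the cluster radius
                rad = rng.uniform(0, model.cluster_radius_m / 2)
                theta = rng.uniform(0, 2 * np.pi)
                x[i] = ax + rad * np.cos(theta)
                y[i] = ay + rad * np.sin(theta)
        cluster_spans.sort()

        exceed = rng.random(n_fixes) < model.pdop_exceed_fraction
        pdop = np.where(exceed, rng.uniform(10.5, 18.0, n_fixes),
                        rng.uniform(1.5, 9.5, n_fixes))
        times = t0 + pd.to_timedelta(
            np.arange(n_fixes) * model.fix_interval_h, unit="h")
        fixes = pd.DataFrame({"timestamp": times, "x": x, "y": y,
                              "pdop": pdop})
        tracks.append(Track(
            animal_id=f"puma{k:02d}", fixes=fixes,
            sex=SEXES[k % 2], age_class=AGE_CLASSES[(k // 2) % 2],
            capture_area=CAPTURE_AREAS[k % 3],
            meta={"cluster_spans": cluster_spans,
                  "true_coefficients": dict(model.coefficients)}))
    return tracks


# ---------------------------------------------------------------------------
# roads, traffic and impervious-surface projections
# ---------------------------------------------------------------------------

AADT_EPOCHS = (2010, 2013, 2030)
MARKER_SPACING_M = 1600.0


def gen_roads_and_projections(stack: CovariateStack, seed: int):
    """Toy road network with traffic counts and impervious projections.

    Returns ``(roads, markers, imperv_2010, imperv_2030)``. Roads are a
    DataFrame of segments (shapely LineString + AADT per epoch) spanning
    the low (<3000), marginal (3000-5000) and high (>5000 vehicles/day)
    traffic classes at the current epoch, with at least one segment
    crossing from the low into the high class by 2030. Markers sit every
    1.6 km along each segment. Impervious rasters are percent cover in
    [0, 100] with 2030 >= 2010 everywhere and growth concentrated where
    the human-modification intensity is high.
    """
    rng = np.random.default_rng(seed)
    g = stack.grid
    width = g.n_cols * g.cell_size
    height = g.n_rows * g.cell_size

    # three roads crossing the arena: one per traffic class
    aadt_2010 = [1500.0, 4000.0, 9000.0]
    aadt_2013 = [1800.0, 4300.0, 10000.0]
    aadt_2030 = [6500.0, 8000.0, 15000.0]  # low->high, marginal->high, high
    fractions = (0.25, 0.55, 0.8)
    segments = []
    for i, frac in enumerate(fractions):
        if i % 2 == 0:  # east-west road
            y0 = g.yll + frac * height
            jitter = rng.uniform(-0.05, 0.05) * height
            line = LineString([(g.xll, y0), (g.xll + width, y0 + jitter)])
        else:           # north-south road
            x0 = g.xll + frac * width
            jitter = rng.uniform(-0.05, 0.05) * width
            line = LineString([(x0, g.yll), (x0 + jitter, g.yll + height)])
        segments.append({"segment_id": f"R{i}", "geometry": line,
                         "aadt_2010": aadt_2010[i], "aadt_2013": aadt_2013[i],
                         "aadt_2030": aadt_2030[i]})
    roads = pd.DataFrame(segments)

    markers = []
    for _, seg in roads.iterrows():
        line = seg["geometry"]
        n_marks = int(line.length // MARKER_SPACING_M) + 1
        for m in range(n_marks):
            pt = line.interpolate(m * MARKER_SPACING_M)
            markers.append({"marker_id": f"{seg['segment_id']}-{m}",
                            "segment_id": seg["segment_id"],
                            "x": pt.x, "y": pt.y,
                            "aadt_2010": seg["aadt_2010"],
                            "aadt_2013": seg["aadt_2013"],
                            "aadt_2030": seg["aadt_2030"]})
    markers = pd.DataFrame(markers)

    intensity = getattr(stack, "human_intensity", None)
    if intensity is None:
        hm = stack.layers["human_mod"].values
        intensity = (hm - hm.min()) / (hm.max() - hm.min())
    base = np.clip(60.0 * intensity + rng.uniform(0, 5, g.shape), 0.0, 100.0)
    growth = np.where(intensity > np.quantile(intensity, 0.7),
                      rng.uniform(5.0, 25.0, g.shape), 0.0)
    imperv_2010 = g.like(base)
    imperv_2030 = g.like(np.clip(base + growth, 0.0, 100.0))
    return roads, markers, imperv_2010, imperv_2030


# ---------------------------------------------------------------------------
# file output (text formats)
# ---------------------------------------------------------------------------

def write_telemetry_csv(tracks, telemetry_path, attributes_path) -> None:
    """Write tracks to the telemetry + attributes CSV schemas."""
    rows = []
    attr_rows = []
    for tr in tracks:
        for _, f in tr.fixes.iterrows():
            rows.append({"animal_id": tr.animal_id,
                         "timestamp": f["timestamp"].isoformat(),
                         "x": f["x"], "y": f["y"], "pdop": f["pdop"]})
        attr_rows.append({"animal_id": tr.animal_id, "sex": tr.sex,
                          "age_class": tr.age_class,
                          "capture_area": tr.capture_area})
    pd.DataFrame(rows).to_csv(telemetry_path, index=False)
    pd.DataFrame(attr_rows).to_csv(attributes_path, index=False)


def write_roads_geojson(roads: pd.DataFrame, markers: pd.DataFrame,
                        roads_path, markers_path) -> None:
    """Write roads and mile markers as GeoJSON feature collections."""
    feats = []
    for _, seg in roads.iterrows():
        props = {k: seg[k] for k in ("segment_id", "aadt_2010", "aadt_2013",
                                     "aadt_2030")}
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(seg["geometry"])})
    with open(roads_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    feats = []
    for _, mk in markers.iterrows():
        props = {k: mk[k] for k in ("marker_id", "segment_id", "aadt_2010",
                                    "aadt_2013", "aadt_2030")}
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(Point(mk["x"], mk["y"]))})
    with open(markers_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
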