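"""Derivation, aggregation, standardization and screening of habitat covariates.

Terrain metrics (Horn slope, windowed ruggedness, multiscale topographic
position), distance-to-water, focal cover proportions and block-mean
aggregation are computed on :class:`~pumaconnect.raster.RasterGrid` layers.
A :class:`CovariateStack` keeps named layers on one common grid together
with the standardization parameters needed to map between raw and z-scored
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterGrid

#: default multiscale TPI neighborhood radii (m), spanning 720-21870 m
TPI_RADII_M = (720.0, 2430.0, 7290.0, 14580.0, 21870.0)


@dataclass
class CovariateStack:
    """Named raster layers sharing one grid, plus standardization state."""

    layers: dict[str, RasterGrid]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    water_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.same_grid(grids[0]):
                raise ValueError("all stack layers must share one grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    @property
    def is_standardized(self) -> bool:
        return bool(self.standardization)

    def values_at(self, x, y) -> pd.DataFrame:
        """Layer values at point coordinates, one column per layer."""
        g = self.grid
        row, col = g.index_of(x, y)
        row = np.clip(row, 0, g.n_rows - 1)
        col = np.clip(col, 0, g.n_cols - 1)
        return pd.DataFrame(
            {name: layer.values[row, col] for name, layer in self.layers.items()}
        )


# ---------------------------------------------------------------------------
# terrain metrics
# ---------------------------------------------------------------------------

def slope(dem: RasterGrid) -> RasterGrid:
    """Slope in degrees by Horn's 3x3 weighted finite differences.

    Border cells (incomplete 3x3 neighborhood) are set to nodata.
    """
    z = dem.values
    cs = dem.cell_size
    # Horn (1981) weights: dz/dx = ((c+2f+i) - (a+2d+g)) / (8*cs)
    p = np.pad(z, 1, mode="edge")
    a = p[:-2, :-2]; b = p[:-2, 1:-1]; c = p[:-2, 2:]
    d = p[1:-1, :-2];                   f = p[1:-1, 2:]
    g = p[2:, :-2];  h = p[2:, 1:-1];   i = p[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    out = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out[0, :] = out[-1, :] = dem.nodata
    out[:, 0] = out[:, -1] = dem.nodata
    return dem.like(out)


def ruggedness(slope_grid: RasterGrid, window: int = 9) -> RasterGrid:
    """Terrain ruggedness: population SD of slope in a centered moving window.

    Nodata cells are excluded from each window's statistic; a cell whose
    window holds no valid neighbor is nodata.
    """
    if window > min(slope_grid.shape):
        raise ValueError("window larger than grid")
    v = slope_grid.values
    valid = slope_grid.mask
    # center on the global mean before the one-pass variance to avoid
    # catastrophic cancellation on near-constant slopes
    center = v[valid].mean() if valid.any() else 0.0
    x = np.where(valid, v - center, 0.0)
    size = (window, window)
    cnt = ndimage.uniform_filter(valid.astype(float), size=size, mode="constant")
    s1 = ndimage.uniform_filter(x, size=size, mode="constant")
    s2 = ndimage.uniform_filter(x * x, size=size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = s2 / cnt - mean ** 2
    var = np.clip(var, 0.0, None)
    out = np.sqrt(var)
    out[cnt <= 0] = slope_grid.nodata
    out[~valid] = slope_grid.nodata
    return slope_grid.like(out)


def _circular_footprint(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy ** 2 + xx ** 2) <= radius_cells ** 2


def tpi(dem: RasterGrid, radius_m: float) -> RasterGrid:
    """Topographic position at one scale: focal elevation minus the mean
    elevation within a circular neighborhood of the given radius."""
    if radius_m < dem.cell_size:
        raise ValueError("TPI radius smaller than one cell")
    fp = _circular_footprint(radius_m / dem.cell_size)
    valid = dem.mask
    z = np.where(valid, dem.values, 0.0)
    s = ndimage.correlate(z, fp.astype(float), mode="constant")
    n = ndimage.correlate(valid.astype(float), fp.astype(float), mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        neigh_mean = s / n
    out = dem.values - neigh_mean
    out[~valid] = dem.nodata
    return dem.like(out)


def tpi_multiscale(dem: RasterGrid, radii_m=TPI_RADII_M) -> RasterGrid:
    """Composite multiscale topographic position index.

    Each single-scale TPI is z-standardized over valid cells and the
    composite is the arithmetic mean of the standardized scales. Adding a
    constant to the DEM leaves the composite unchanged.
    """
    acc = np.zeros_like(dem.values, dtype=float)
    valid = dem.mask
    for r in radii_m:
        t = tpi(dem, r).values
        vals = t[valid]
        sd = vals.std()
        if sd == 0:
            z = np.zeros_like(t)
        else:
            z = (t - vals.mean()) / sd
        acc += np.where(valid, z, 0.0)
    out = acc / len(radii_m)
    out[~valid] = dem.nodata
    return dem.like(out)


# ---------------------------------------------------------------------------
# water, cover, aggregation
# ---------------------------------------------------------------------------

def distance_to_water(water_mask: np.ndarray, grid: RasterGrid) -> RasterGrid:
    """Euclidean distance (m) from each cell center to the nearest water cell."""
    water_mask = np.asarray(water_mask, dtype=bool)
    if water_mask.shape != grid.shape:
        raise ValueError("water mask shape mismatch")
    if not water_mask.any():
        raise ValueError("empty water set")
    dist = ndimage.distance_transform_edt(~water_mask) * grid.cell_size
    return grid.like(dist)


def focal_proportion(class_mask: RasterGrid, window: int = 9) -> RasterGrid:
    """Fraction in [0, 1] of valid window cells where the binary mask is 1."""
    v = class_mask.values
    valid = class_mask.mask
    vals = v[valid]
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("focal_proportion requires a binary mask")
    x = np.where(valid, v, 0.0)
    size = (window, window)
    s = ndimage.uniform_filter(x, size=size, mode="constant")
    n = ndimage.uniform_filter(valid.astype(float), size=size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s / n
    out[n <= 0] = class_mask.nodata
    out[~valid] = class_mask.nodata
    return class_mask.like(out)


def aggregate_to_target(grid: RasterGrid, factor: int = 9) -> RasterGrid:
    """Block-mean aggregation by an integer factor (e.g. 30 m -> 270 m).

    Grids whose dimensions are not multiples of the factor are padded with
    nodata first; block means ignore nodata cells.
    """
    v = grid.values
    valid = grid.mask
    nr = -(-grid.n_rows // factor) * factor
    nc = -(-grid.n_cols // factor) * factor
    vp = np.full((nr, nc), 0.0)
    mp = np.zeros((nr, nc), dtype=bool)
    vp[:grid.n_rows, :grid.n_cols] = np.where(valid, v, 0.0)
    mp[:grid.n_rows, :grid.n_cols] = valid
    vb = vp.reshape(nr // factor, factor, nc // factor, factor)
    mb = mp.reshape(nr // factor, factor, nc // factor, factor)
    cnt = mb.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = vb.sum(axis=(1, 3)) / cnt
    out[cnt == 0] = grid.nodata
    # padded rows sit at high array indices, i.e. south of the original
    # extent, so the lower-left anchor shifts down by the padding
    pad_rows = nr - grid.n_rows
    return RasterGrid(out, grid.xll, grid.yll - pad_rows * grid.cell_size,
                      grid.cell_size * factor, grid.crs, grid.nodata)


# ---------------------------------------------------------------------------
# standardization and screening
# ---------------------------------------------------------------------------

def standardize(stack: CovariateStack) -> CovariateStack:
    """Z-score every layer over its valid cells, storing raw mean/SD.

    Re-standardizing an already standardized stack is a no-op.
    """
    if stack.is_standardized:
        return stack
    new_layers: dict[str, RasterGrid] = {}
    params: dict[str, tuple[float, float]] = {}
    for name, layer in stack.layers.items():
        valid = layer.mask
        vals = layer.values[valid]
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0:
            raise ValueError(f"layer '{name}' has zero variance")
        z = np.where(valid, (layer.values - mu) / sd, layer.nodata)
        new_layers[name] = layer.like(z)
        params[name] = (mu, sd)
    return CovariateStack(new_layers, params, stack.water_mask)


def unstandardize(stack: CovariateStack) -> CovariateStack:
    """Invert :func:`standardize` using the stored parameters."""
    if not stack.is_standardized:
        return stack
    new_layers = {}
    for name, layer in stack.layers.items():
        mu, sd = stack.standardization[name]
        valid = layer.mask
        raw = np.where(valid, layer.values * sd + mu, layer.nodata)
        new_layers[name] = layer.like(raw)
    return CovariateStack(new_layers, {}, stack.water_mask)


def screen_collinearity(stack: CovariateStack, sample_points=None,
                        r_cutoff: float = 0.7, vif_cutoff: float = 4.0,
                        n_sample: int = 2000, seed: int = 0) -> dict:
    """Pairwise Pearson correlations and variance inflation factors.

    Values are computed at sample points (random valid cells by default).
    Returns a dict with the correlation matrix, per-layer VIFs, and the
    flagged pairs/layers exceeding the cutoffs.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least two layers to screen")
    g = stack.grid
    if sample_points is None:
        rng = np.random.default_rng(seed)
        valid = np.ones(g.shape, dtype=bool)
        for layer in stack.layers.values():
            valid &= layer.mask
        rows, cols = np.nonzero(valid)
        idx = rng.choice(len(rows), size=min(n_sample, len(rows)), replace=False)
        x, y = g.cell_center(rows[idx], cols[idx])
    else:
        x, y = np.asarray(sample_points[0]), np.asarray(sample_points[1])
    if len(np.atleast_1d(x)) < 30:
        raise ValueError("need at least 30 sample points")
    df = stack.values_at(x, y)
    corr = df.corr(method="pearson")
    vifs = {}
    mat = df.to_numpy()
    mat = (mat - mat.mean(axis=0)) / mat.std(axis=0)
    for j, name in enumerate(names):
        others = np.delete(mat, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, mat[:, j], rcond=None)
        resid = mat[:, j] - others @ beta
        r2 = 1.0 - resid.var() / mat[:, j].var()
        vifs[name] = float(np.inf) if r2 >= 1.0 else 1.0 / (1.0 - r2)
    flagged_pairs = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(names) for b in names[i + 1:]
        if abs(corr.loc[a, b]) > r_cutoff
    ]
    flagged_vif = [n for n in names if vifs[n] > vif_cutoff]
    return {"pearson": corr, "vif": vifs,
            "flagged_pairs": flagged_pairs, "flagged_vif": flagged_vif,
            "max_abs_r": float(np.nanmax(np.abs(corr.to_numpy()
                                                - np.eye(len(names)))))}
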