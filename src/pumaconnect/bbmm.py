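"""Brownian bridge movement models (BBMM).

Each between-fix step is modeled as a Brownian bridge conditioned on its
endpoints, elapsed time T, a Brownian motion variance sigma2_m (the
mobility parameter) and a per-coordinate telemetry location-error SD
delta. At time fraction alpha in (0, 1) the animal's position is normal
around the time-interpolated point between the endpoints with isotropic
variance

    var(alpha) = T * alpha * (1 - alpha) * sigma2_m
                 + ((1 - alpha)**2 + alpha**2) * delta**2.

The occurrence surface for a track integrates this density over alpha for
every bridge and averages the bridges weighted by their elapsed times.
sigma2_m is estimated by the leave-one-out likelihood of the odd-numbered
fixes under bridges spanned by their even-numbered neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .raster import RasterGrid
from .telemetry import Bridge, Track, build_bridges

#: default per-coordinate location error SD (m) for GPS fixes
DEFAULT_LOCATION_ERROR_M = 26.2
#: default movement-probability extent threshold
DEFAULT_EXTENT_THRESHOLD = 1e-5


@dataclass
class BBMMSurface:
    """Per-individual movement-probability raster plus its parameters."""

    probability: RasterGrid
    sigma2_m: float            # Brownian motion variance, m^2 / h
    location_error_m: float
    threshold: float
    animal_id: str
    retained_mass: float = 1.0  # probability mass surviving the threshold
    n_bridges: int = 0

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of cells inside the surface extent."""
        return self.probability.values > 0


# ---------------------------------------------------------------------------
# mobility estimation
# ---------------------------------------------------------------------------

def _loo_triples(track: Track, max_lag_h: float):
    """Odd-fix triples (z_prev, z_obs, z_next, t0, t1, t2) usable for the
    leave-one-out likelihood: both spanning lags within the cap."""
    xy = track.xy
    hrs = track.hours
    triples = []
    for i in range(1, len(xy) - 1, 2):
        lag1 = hrs[i] - hrs[i - 1]
        lag2 = hrs[i + 1] - hrs[i]
        if lag1 <= 0 or lag2 <= 0:
            continue
        if lag1 > max_lag_h or lag2 > max_lag_h:
            continue
        triples.append((xy[i - 1], xy[i], xy[i + 1],
                        hrs[i - 1], hrs[i], hrs[i + 1]))
    return triples


def estimate_brownian_variance(track: Track,
                               location_error_m: float = DEFAULT_LOCATION_ERROR_M,
                               max_lag_h: float = 24.0,
                               bounds: tuple[float, float] = (1e-3, 1e7)
                               ) -> float:
    """ML estimate of the Brownian motion variance (m^2/h).

    Every odd-numbered fix is left out and scored under the bridge spanned
    by its even-numbered neighbors: normal around the time-interpolated
    position with variance T*a*(1-a)*sigma2_m + ((1-a)^2 + a^2)*delta^2,
    a the elapsed-time fraction. The summed log-likelihood is maximized
    over sigma2_m by bounded 1-D search.
    """
    triples = _loo_triples(track, max_lag_h)
    if not triples:
        raise ValueError(
            f"track {track.animal_id}: no usable leave-one-out triples")
    delta2 = location_error_m ** 2
    obs = []
    for z0, z, z1, t0, t1, t2 in triples:
        T = t2 - t0
        a = (t1 - t0) / T
        mu = (1 - a) * z0 + a * z1
        obs.append((float(np.sum((z - mu) ** 2)), T * a * (1 - a),
                    ((1 - a) ** 2 + a ** 2) * delta2))
    sq, ta, err = map(np.array, zip(*obs))

    def nll(log_s2: float) -> float:
        var = ta * np.exp(log_s2) + err
        # bivariate isotropic normal: two coordinates per fix
        return float(np.sum(np.log(var) + 0.5 * sq / var))

    res = optimize.minimize_scalar(nll, bounds=np.log(bounds), method="bounded",
                                   options={"xatol": 1e-8})
    if not np.isfinite(res.fun):
        raise ValueError("non-finite leave-one-out likelihood")
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# bridge and occurrence densities
# ---------------------------------------------------------------------------

def bridge_density(bridge: Bridge, sigma2_m: float, location_error_m: float,
                   grid: RasterGrid, n_time_steps: int = 25) -> np.ndarray:
    """Gridded density of one Brownian bridge, normalized to sum 1.

    Midpoint quadrature over alpha with ``n_time_steps`` slices; each
    slice contributes an isotropic bivariate normal evaluated at cell
    centers, times the cell area. Computed on a bounding box around the
    step for speed and embedded in a full-grid array.
    """
    delta2 = location_error_m ** 2
    T = bridge.elapsed_h
    alphas = (np.arange(n_time_steps) + 0.5) / n_time_steps
    variances = T * alphas * (1 - alphas) * sigma2_m \
        + ((1 - alphas) ** 2 + alphas ** 2) * delta2
    if np.all(variances <= 0):
        if bridge.length == 0:
            raise ValueError("degenerate bridge: zero variance and zero length")
        variances = np.full_like(variances, 1e-6)

    # bounding box: step extent +/- 6 SD of the widest slice
    pad = 6.0 * np.sqrt(variances.max()) + grid.cell_size
    xmin = min(bridge.start[0], bridge.end[0]) - pad
    xmax = max(bridge.start[0], bridge.end[0]) + pad
    ymin = min(bridge.start[1], bridge.end[1]) - pad
    ymax = max(bridge.start[1], bridge.end[1]) + pad
    r0, c0 = grid.index_of(xmin, ymax)
    r1, c1 = grid.index_of(xmax, ymin)
    r0 = max(int(r0), 0); c0 = max(int(c0), 0)
    r1 = min(int(r1), grid.n_rows - 1); c1 = min(int(c1), grid.n_cols - 1)
    rows, cols = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    cx, cy = grid.cell_center(rows, cols)

    dens = np.zeros(cx.shape)
    for a, var in zip(alphas, variances):
        mx = (1 - a) * bridge.start[0] + a * bridge.end[0]
        my = (1 - a) * bridge.start[1] + a * bridge.end[1]
        d2 = (cx - mx) ** 2 + (cy - my) ** 2
        dens += np.exp(-0.5 * d2 / var) / (2 * np.pi * var)
    dens *= grid.cell_size ** 2 / n_time_steps

    out = np.zeros(grid.shape)
    out[r0:r1 + 1, c0:c1 + 1] = dens
    total = out.sum()
    if total <= 0:
        raise ValueError("bridge density has no mass on the grid")
    return out / total


def occurrence_surface(track: Track, sigma2_m: float,
                       location_error_m: float, grid: RasterGrid,
                       threshold: float = DEFAULT_EXTENT_THRESHOLD,
                       max_lag_h: float = 24.0,
                       n_time_steps: int = 25) -> BBMMSurface:
    """Track-level BBMM: time-weighted average of bridge densities.

    Bridge i receives weight T_i / sum(T); the average is normalized to
    sum 1 and cells at or below ``threshold`` are zeroed (the surface
    extent follows the movement path, not the map rectangle). The
    fraction of mass surviving the threshold is recorded.
    """
    bridges = build_bridges(track, max_lag_h)
    if not bridges:
        raise ValueError(f"track {track.animal_id}: no bridges")
    weights = np.array([b.elapsed_h for b in bridges], dtype=float)
    weights /= weights.sum()
    acc = np.zeros(grid.shape)
    for w, b in zip(weights, bridges):
        acc += w * bridge_density(b, sigma2_m, location_error_m, grid,
                                  n_time_steps)
    acc /= acc.sum()
    kept = acc > threshold
    retained = float(acc[kept].sum())
    surf = np.where(kept, acc, 0.0)
    return BBMMSurface(grid.like(surf), float(sigma2_m), location_error_m,
                       threshold, track.animal_id, retained, len(bridges))


def buffered_extent(surface: BBMMSurface, buffer_m: float) -> np.ndarray:
    """Cells within ``buffer_m`` (Euclidean) of any surface-support cell."""
    if buffer_m < 0:
        raise ValueError("buffer must be non-negative")
    support = surface.support
    if buffer_m == 0 or not support.any():
        return support
    cs = surface.probability.cell_size
    dist = ndimage.distance_transform_edt(~support) * cs
    return dist <= buffer_m
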