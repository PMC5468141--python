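"""Pinch-point identification and exposure to development and traffic.

Pinch points are in-boundary cells at or above a percentile (default
95th) of summed current flow. Three risk classes are scored against them:

* ``development`` — pinch cells whose projected impervious-surface
  increase is in the 90th percentile of increases among pinch cells with
  any increase;
* ``traffic_current`` — mile markers on roads already carrying a barrier
  traffic volume (> 5000 vehicles/day) whose 1-km disc touches a pinch
  point;
* ``traffic_future`` — markers whose roads are currently below the
  deterrence threshold (< 3000) or in the marginal band (3000-5000) but
  are projected to cross it.

Because current drops precisely where a high-resistance road cuts a
pinch point, markers are assigned the highest current within 1 km.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import CurrentMap

log = logging.getLogger(__name__)

AADT_LOW = 3000.0
AADT_MARGINAL = 5000.0
MARKER_RADIUS_M = 1000.0


@dataclass
class PinchPointSet:
    """Cells at or above the current-flow percentile threshold."""

    mask: np.ndarray
    percentile: float
    threshold: float
    grid: "object"  # RasterGrid of the source current map


def pinch_points(current: CurrentMap, boundary_mask: np.ndarray | None = None,
                 percentile: float = 95.0) -> PinchPointSet:
    """Threshold the summed current map at a linear-interpolation percentile.

    Cells >= the threshold are pinch points; with a constant map every
    in-boundary cell qualifies (degenerate, logged).
    """
    grid = current.current
    vals = grid.values
    if boundary_mask is None:
        boundary_mask = np.ones(vals.shape, dtype=bool)
    inside = vals[boundary_mask]
    if inside.size == 0:
        raise ValueError("empty current map")
    thr = float(np.percentile(inside, percentile))
    if inside.max() == inside.min():
        log.warning("constant current map: every cell is a pinch point")
    mask = boundary_mask & (vals >= thr)
    return PinchPointSet(mask, percentile, thr, grid)


@dataclass(frozen=True)
class RiskSite:
    """One at-risk location: a cell or a mile marker."""

    kind: str                 # "cell" or "marker"
    risk_class: str           # development / traffic_current / traffic_future
    x: float
    y: float
    exposure: float           # delta % impervious, or vehicles/day
    assigned_current: float
    label: str = ""


def development_risk(pp: PinchPointSet, imperv_start, imperv_end,
                     inner_percentile: float = 90.0) -> list[RiskSite]:
    """Pinch cells in the top decile of projected impervious increase.

    The percentile is conditioned on pinch cells with a positive increase,
    so adding high-growth cells outside pinch points changes nothing.
    """
    if not (pp.grid.same_grid(imperv_start) and pp.grid.same_grid(imperv_end)):
        raise ValueError("impervious rasters not aligned with current map")
    delta = imperv_end.values - imperv_start.values
    candidates = pp.mask & (delta > 0)
    if not candidates.any():
        return []
    thr = float(np.percentile(delta[candidates], inner_percentile))
    chosen = candidates & (delta >= thr)
    rows, cols = np.nonzero(chosen)
    xs, ys = pp.grid.cell_center(rows, cols)
    cur = pp.grid.values
    return [RiskSite("cell", "development", float(x), float(y),
                     float(delta[r, c]), float(cur[r, c]))
            for x, y, r, c in zip(xs, ys, rows, cols)]


def _disc_max_current(pp: PinchPointSet, x: float, y: float,
                      radius_m: float) -> tuple[bool, float]:
    """(touches pinch mask, max current) within the disc around a point.

    Disc membership is by cell-center distance <= radius.
    """
    g = pp.grid
    cx, cy = g.center_grids()
    within = (cx - x) ** 2 + (cy - y) ** 2 <= radius_m ** 2
    if not within.any():
        raise ValueError("marker lies off the grid")
    touches = bool((within & pp.mask).any())
    return touches, float(g.values[within].max())


def traffic_current_barriers(pp: PinchPointSet, markers: pd.DataFrame,
                             aadt_col: str = "aadt_2013",
                             radius_m: float = MARKER_RADIUS_M,
                             threshold: float = AADT_MARGINAL
                             ) -> list[RiskSite]:
    """Markers on high-traffic roads (strictly > threshold) whose 1-km
    disc intersects a pinch point; assigned the disc's maximum current."""
    sites = []
    for _, mk in markers.iterrows():
        if not mk[aadt_col] > threshold:
            continue
        touches, cur = _disc_max_current(pp, mk["x"], mk["y"], radius_m)
        if touches:
            sites.append(RiskSite("marker", "traffic_current",
                                  float(mk["x"]), float(mk["y"]),
                                  float(mk[aadt_col]), cur,
                                  str(mk.get("marker_id", ""))))
    return sites


def traffic_future_risk(pp: PinchPointSet, markers: pd.DataFrame,
                        aadt_start_col: str = "aadt_2010",
                        aadt_end_col: str = "aadt_2030",
                        low: float = AADT_LOW,
                        marginal: float = AADT_MARGINAL,
                        radius_m: float = MARKER_RADIUS_M) -> list[RiskSite]:
    """Markers whose traffic is projected to cross a deterrence threshold.

    Included when start < low and end > low, or start in [low, marginal]
    and end > marginal; exposure is the projected AADT change. Roads
    already above both thresholds belong to the current-barrier class.
    """
    sites = []
    for _, mk in markers.iterrows():
        start, end = float(mk[aadt_start_col]), float(mk[aadt_end_col])
        if start < 0 or end < 0:
            raise ValueError("negative AADT")
        crosses = (start < low and end > low) or \
                  (low <= start <= marginal and end > marginal)
        if not crosses:
            continue
        touches, cur = _disc_max_current(pp, mk["x"], mk["y"], radius_m)
        if touches:
            sites.append(RiskSite("marker", "traffic_future",
                                  float(mk["x"]), float(mk["y"]),
                                  end - start, cur,
                                  str(mk.get("marker_id", ""))))
    return sites


def risk_sites_frame(sites: list[RiskSite]) -> pd.DataFrame:
    """Tabular view of risk sites (CSV-ready)."""
    return pd.DataFrame([{
        "kind": s.kind, "class": s.risk_class, "x": s.x, "y": s.y,
        "exposure": s.exposure, "assigned_current": s.assigned_current,
        "label": s.label} for s in sites])
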