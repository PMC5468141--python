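"""Reading, screening and segmenting GPS telemetry.

The screening pipeline has a fixed order: quality filter on positional
dilution of precision (PDOP), then iterative removal of stationary
clusters (putative den/kill sites), then segmentation of each individual's
retained fixes into Brownian-bridge steps subject to a maximum time lag.

A fix belongs to a stationary cluster when it lies within a distance
threshold (default 200 m) of BOTH its retained temporal neighbors; such
fixes are removed one at a time (earliest first) until none qualifies. An
endpoint is evaluated against its single neighbor. This interior-removal
reading keeps the entry and exit fixes of a cluster, so legitimate slow
travel through an area is never deleted wholesale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FIX_COLUMNS = ["animal_id", "timestamp", "x", "y", "pdop"]
ATTR_COLUMNS = ["animal_id", "sex", "age_class", "capture_area"]


@dataclass
class Track:
    """Ordered GPS fixes for one individual, with its attributes.

    ``fixes`` is a DataFrame with columns timestamp (tz-aware UTC), x, y,
    pdop, time-sorted. ``meta`` carries arbitrary provenance (e.g. the
    ground-truth indices of injected stationary clusters in synthetic data).
    """

    animal_id: str
    fixes: pd.DataFrame
    sex: str = "F"
    age_class: str = "adult"
    capture_area: str = "A"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.fixes
        if not f["timestamp"].is_monotonic_increasing:
            raise ValueError(f"track {self.animal_id}: timestamps not sorted")
        if f["timestamp"].duplicated().any():
            raise ValueError(f"track {self.animal_id}: duplicate timestamps")
        if not np.isfinite(f[["x", "y"]].to_numpy()).all():
            raise ValueError(f"track {self.animal_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    @property
    def hours(self) -> np.ndarray:
        """Fix times in hours from the first fix."""
        t = self.fixes["timestamp"]
        return ((t - t.iloc[0]).dt.total_seconds() / 3600.0).to_numpy()


@dataclass(frozen=True)
class Bridge:
    """One movement step between consecutive retained fixes."""

    start: np.ndarray          # (x, y) of the first fix
    end: np.ndarray            # (x, y) of the second fix
    elapsed_h: float           # time between the fixes, hours

    @property
    def length(self) -> float:
        return float(np.hypot(*(self.end - self.start)))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_fixes(telemetry_path, attributes_path) -> list[Track]:
    """Read telemetry + attribute CSVs into per-individual Tracks.

    Fixes are grouped by animal and time-sorted; every animal in the
    telemetry file must have an attribute row and vice versa.
    """
    fixes = pd.read_csv(telemetry_path)
    missing = set(FIX_COLUMNS) - set(fixes.columns)
    if missing:
        raise ValueError(f"telemetry CSV missing columns: {sorted(missing)}")
    bad = fixes["pdop"].isna()
    if bad.any():
        raise ValueError(
            f"telemetry CSV has missing pdop at rows {list(fixes.index[bad][:5])}")
    try:
        fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True,
                                            format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed timestamp in telemetry CSV: {exc}") from exc
    dup = fixes.duplicated(subset=["animal_id", "timestamp"])
    if dup.any():
        raise ValueError(
            f"duplicate (animal, timestamp) at rows {list(fixes.index[dup][:5])}")

    attrs = pd.read_csv(attributes_path)
    missing = set(ATTR_COLUMNS) - set(attrs.columns)
    if missing:
        raise ValueError(f"attributes CSV missing columns: {sorted(missing)}")
    attrs = attrs.set_index("animal_id")
    unknown = set(attrs.index) - set(fixes["animal_id"])
    if unknown:
        raise ValueError(f"attributes reference unknown animal_id: {sorted(unknown)}")

    tracks = []
    for animal, grp in fixes.groupby("animal_id", sort=True):
        if animal not in attrs.index:
            raise ValueError(f"no attributes for animal_id {animal!r}")
        row = attrs.loc[animal]
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        tracks.append(Track(str(animal), grp[["timestamp", "x", "y", "pdop"]],
                            sex=row["sex"], age_class=row["age_class"],
                            capture_area=row["capture_area"]))
    return tracks


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def filter_pdop(track: Track, max_pdop: float = 10.0) -> tuple[Track, int]:
    """Drop fixes whose PDOP exceeds the threshold (strictly greater).

    Returns the filtered track and the number of fixes removed.
    """
    keep = track.fixes["pdop"].to_numpy() <= max_pdop
    removed = int((~keep).sum())
    out = track.fixes.loc[keep].reset_index(drop=True)
    if out.empty:
        log.warning("track %s: all fixes exceed PDOP %.1f", track.animal_id,
                    max_pdop)
    return replace(track, fixes=out), removed


def _stationary_candidate(xy: np.ndarray, radius: float) -> int | None:
    """Index of the earliest fix within radius of both retained neighbors.

    Endpoints have a single neighbor and qualify on that neighbor alone.
    """
    n = len(xy)
    if n < 2:
        return None
    d = np.hypot(*(np.diff(xy, axis=0).T))  # consecutive distances
    for i in range(n):
        if i == 0:
            qualifies = d[0] < radius
        elif i == n - 1:
            qualifies = d[n - 2] < radius
        else:
            qualifies = d[i - 1] < radius and d[i] < radius
        if qualifies:
            return i
    return None


def remove_stationary(track: Track, radius: float = 200.0) -> tuple[Track, int]:
    """Iteratively remove fixes associated with stationary clusters.

    A fix qualifies when both its current temporal neighbors lie within
    ``radius``; endpoints are judged against their single neighbor. The
    earliest qualifying fix is removed and distances recomputed, until no
    fix qualifies. Returns the filtered track and the removal count.
    """
    df = track.fixes.reset_index(drop=True)
    keep = list(range(len(df)))
    xy = df[["x", "y"]].to_numpy(dtype=float)
    removed = 0
    while True:
        cand = _stationary_candidate(xy[keep], radius)
        if cand is None:
            break
        del keep[cand]
        removed += 1
    out = df.loc[keep].reset_index(drop=True)
    return replace(track, fixes=out), removed


def screen_track(track: Track, max_pdop: float = 10.0,
                 radius: float = 200.0) -> tuple[Track, dict]:
    """PDOP filter then stationary-cluster removal, with a stage report."""
    n0 = len(track)
    t1, n_pdop = filter_pdop(track, max_pdop)
    t2, n_clust = remove_stationary(t1, radius)
    report = {"animal_id": track.animal_id, "n_raw": n0,
              "n_pdop_removed": n_pdop, "n_cluster_removed": n_clust,
              "n_retained": len(t2)}
    return t2, report


# ---------------------------------------------------------------------------
# bridge construction
# ---------------------------------------------------------------------------

def build_bridges(track: Track, max_lag_h: float = 24.0) -> list[Bridge]:
    """One bridge per consecutive retained pair with lag <= max_lag_h.

    Pairs whose elapsed time exceeds the cap contribute no bridge, but
    both fixes stay available for the neighboring pairs.
    """
    if len(track) < 2:
        return []
    xy = track.xy
    hrs = track.hours
    bridges = []
    for i in range(len(xy) - 1):
        dt = hrs[i + 1] - hrs[i]
        if dt <= 0:
            raise ValueError("non-increasing timestamps")
        if dt <= max_lag_h:
            bridges.append(Bridge(xy[i], xy[i + 1], float(dt)))
    return bridges


def max_step_length(track: Track, max_lag_h: float = 24.0) -> float:
    """Greatest Euclidean step length over the track's bridges."""
    bridges = build_bridges(track, max_lag_h)
    if not bridges:
        raise ValueError(f"track {track.animal_id}: no bridges")
    return max(b.length for b in bridges)
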