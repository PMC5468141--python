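import numpy as np
import pandas as pd
import pytest

from pumaconnect.raster import RasterGrid
from pumaconnect.telemetry import Track


def make_track(xy, interval_h=4.15, pdop=None, animal_id="puma00", **attrs):
    """Track from an (n, 2) coordinate array with regular timestamps."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    times = pd.Timestamp("2006-01-01T00:00:00Z") + pd.to_timedelta(
        np.arange(n) * interval_h, unit="h")
    if pdop is None:
        pdop = np.full(n, 4.0)
    fixes = pd.DataFrame({"timestamp": times, "x": xy[:, 0], "y": xy[:, 1],
                          "pdop": np.asarray(pdop, dtype=float)})
    return Track(animal_id, fixes, **attrs)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture(scope="session")
def small_stack():
    """Deterministic 32x32 synthetic covariate stack."""
    from pumaconnect.synthetic import LandscapeSpec, gen_covariate_stack
    return gen_covariate_stack(LandscapeSpec(n_rows=32, n_cols=32, seed=7))


@pytest.fixture
def unit_grid():
    """16x16 grid of ones with 100 m cells at the origin."""
    return RasterGrid(np.ones((16, 16)), cell_size=100.0)
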