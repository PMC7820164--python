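import numpy as np
import pandas as pd
import pytest

from firestand import PlotWindow, StemMap


def make_map(coords, window, dbh=None, species="ABCO", **extra) -> StemMap:
    """Assemble a StemMap from raw coordinates for tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if dbh is None:
        dbh = np.full(n, 30.0)
    df = pd.DataFrame(
        {
            "id": [f"t{i}" for i in range(n)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "species": species,
            "dbh": np.asarray(dbh, dtype=float),
        }
    )
    for key, val in extra.items():
        df[key] = val
    return StemMap(df, window)


def csr_map(rng, intensity, window, dbh=30.0) -> StemMap:
    """Homogeneous Poisson pattern in the window."""
    n = rng.poisson(intensity * window.area_m2)
    n = max(n, 2)
    xs = rng.uniform(window.x_min, window.x_max, n)
    ys = rng.uniform(window.y_min, window.y_max, n)
    return make_map(np.column_stack([xs, ys]), window, dbh=np.full(n, dbh))


@pytest.fixture
def unit_window() -> PlotWindow:
    return PlotWindow(0, 100, 0, 100)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
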