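"""Second-order and mark statistics for marked tree point patterns.

Implements the estimators the analysis is built on:

* a kernel intensity field (2-D Epanechnikov, edge-renormalized);
* univariate and bivariate pair correlation functions g(r) with
  translation (Ohser) edge correction on a rectangular window;
* the two mortality difference statistics
  g_cluster(r)  = g_{dead,dead}(r)  - g_{alive,dead}(r)   (clustering of
  fire-killed trees; 0 under random labeling) and
  g_densdep(r)  = g_{dead,all}(r)   - g_{alive,all}(r)    (density
  dependence of mortality; 0 under random labeling);
* the r-mark correlation function k_dbh(r) (mean dbh of trees found at
  distance r from another tree, in cm) and the (normalized) mark variogram
  gamma_dbh(r) (mean semivariance 0.5*(m_i-m_j)^2 of dbh over pairs at
  distance r, divided by the sample mark variance so that spatially
  independent marks give 1).

Distances are binned into annuli of width ``ring`` (default 1 m) with
centers 0.5, 1.5, ..., r_max - 0.5; no estimate is reported at r = 0.
All pair statistics carry translation weights 1/T(dx, dy) with
T = (Lx - |dx|)(Ly - |dy|), the area of overlap between the window and its
copy shifted by the pair displacement — the exact closed form on
rectangles.  The pair-correlation estimator is

    g_hat(r_k) = sum_{i != j, d_ij in ring k} 1 / (lambda_i lambda_j T_ij)
                 / A_k,

with A_k the annulus area; for a (in)homogeneous Poisson process with the
plugged-in intensity this has expectation exactly 1 at every r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .stem_data import PlotWindow, StemMap

__all__ = [
    "IntensityField",
    "CorrelationFunction",
    "estimate_intensity",
    "points_lambda",
    "pair_correlation",
    "bivariate_pair_correlation",
    "mortality_difference_statistics",
    "r_mark_correlation",
    "mark_variogram",
]

LAMBDA_FLOOR = 1e-9  # guards division in empty regions of an intensity field


# ---------------------------------------------------------------------------
# intensity


@dataclass
class IntensityField:
    """First-order intensity lambda(x) on a regular grid over the window.

    ``values[iy, ix]`` is trees/m^2 at the cell center
    (x_min + (ix+0.5)*resolution, y_min + (iy+0.5)*resolution).  Kernel
    mass leaking outside the window is renormalized per point, so the field
    integrates to the number of points.
    """

    values: np.ndarray
    window: PlotWindow
    bandwidth: float
    resolution: float = 1.0
    kernel: str = "epanechnikov"

    @property
    def integral(self) -> float:
        return float(self.values.sum() * self.resolution**2)

    def at(self, coords: np.ndarray) -> np.ndarray:
        """lambda at the nearest grid-cell center, floored at LAMBDA_FLOOR."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        ny, nx = self.values.shape
        ix = np.clip(
            ((coords[:, 0] - self.window.x_min) / self.resolution).astype(int), 0, nx - 1
        )
        iy = np.clip(
            ((coords[:, 1] - self.window.y_min) / self.resolution).astype(int), 0, ny - 1
        )
        return np.maximum(self.values[iy, ix], LAMBDA_FLOOR)


def points_lambda(
    stem_map: StemMap,
    field: IntensityField | None = None,
    bandwidth: float = 20.0,
    resolution: float = 1.0,
    leave_one_out: bool = True,
) -> np.ndarray:
    """Intensity at the map's own points, for inhomogeneous normalization.

    Reads the gridded estimate at each tree's nearest cell center and, with
    ``leave_one_out`` (recommended when the field was estimated from this
    same pattern), subtracts the tree's own kernel peak k_e(0)/w_i — without
    this, every point inflates its own intensity and the pair correlation
    is biased low everywhere.
    """
    if field is None:
        field = estimate_intensity(stem_map, bandwidth, resolution)
    lam = field.at(stem_map.coords)
    if leave_one_out:
        w = _kernel_masses(stem_map, field.bandwidth, field.resolution)
        k0 = 2.0 / (np.pi * field.bandwidth**2)
        lam = lam - k0 / w
    return np.maximum(lam, LAMBDA_FLOOR)


def _kernel_masses(
    stem_map: StemMap, bandwidth: float, resolution: float
) -> np.ndarray:
    """Per-point kernel mass inside the window (the edge renormalizer w_i)."""
    win = stem_map.window
    nx = int(round(win.width / resolution))
    ny = int(round(win.height / resolution))
    xc = win.x_min + (np.arange(nx) + 0.5) * resolution
    yc = win.y_min + (np.arange(ny) + 0.5) * resolution
    cell_area = resolution**2
    masses = np.empty(stem_map.n)
    for i, (x0, y0) in enumerate(stem_map.coords):
        jx = np.nonzero(np.abs(xc - x0) <= bandwidth)[0]
        jy = np.nonzero(np.abs(yc - y0) <= bandwidth)[0]
        d2 = (xc[jx][None, :] - x0) ** 2 + (yc[jy][:, None] - y0) ** 2
        masses[i] = _epanechnikov_2d(d2, bandwidth).sum() * cell_area
    return masses


def _epanechnikov_2d(d2: np.ndarray, h: float) -> np.ndarray:
    """2-D Epanechnikov kernel on squared distance; integrates to 1 on R^2."""
    out = (2.0 / (np.pi * h**2)) * (1.0 - d2 / h**2)
    return np.where(d2 <= h**2, out, 0.0)


def estimate_intensity(
    stem_map: StemMap, bandwidth: float = 20.0, resolution: float = 1.0
) -> IntensityField:
    """Edge-renormalized Epanechnikov kernel intensity estimate.

    Each point contributes k_e(||x - x_i||)/w_i, where w_i is the kernel
    mass that falls inside the window (evaluated on the same grid), so mass
    is conserved: the discrete integral equals the point count.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if stem_map.n == 0:
        raise ValueError("need at least one point")
    win = stem_map.window
    nx = int(round(win.width / resolution))
    ny = int(round(win.height / resolution))
    xc = win.x_min + (np.arange(nx) + 0.5) * resolution
    yc = win.y_min + (np.arange(ny) + 0.5) * resolution
    values = np.zeros((ny, nx))
    cell_area = resolution**2
    coords = stem_map.coords
    for x0, y0 in coords:
        jx = np.nonzero(np.abs(xc - x0) <= bandwidth)[0]
        jy = np.nonzero(np.abs(yc - y0) <= bandwidth)[0]
        if len(jx) == 0 or len(jy) == 0:
            continue
        d2 = (xc[jx][None, :] - x0) ** 2 + (yc[jy][:, None] - y0) ** 2
        k = _epanechnikov_2d(d2, bandwidth)
        mass = k.sum() * cell_area
        if mass > 0:
            values[np.ix_(jy, jx)] += k / mass
    return IntensityField(values, win, bandwidth, resolution)


# ---------------------------------------------------------------------------
# correlation-function container


@dataclass
class CorrelationFunction:
    """A distance-indexed statistic: value per annulus center r.

    ``kind`` names the statistic (g_all, g_alive, g_dd, g_ad, g_d_all,
    g_a_all, g_cluster, g_densdep, k_dbh, gamma_dbh).  Bins where the
    statistic is undefined (no pairs, for mark statistics) hold NaN.
    """

    kind: str
    r: np.ndarray
    values: np.ndarray
    ring: float
    n: int
    correction: str = "translation"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r.shape != self.values.shape:
            raise ValueError("r grid and values must align")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")

    def mean_over(self, r_lo: float = 0.0, r_hi: float = np.inf) -> float:
        """Mean value over bins with center in [r_lo, r_hi], ignoring NaN."""
        sel = (self.r >= r_lo) & (self.r <= r_hi)
        return float(np.nanmean(self.values[sel]))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} ring={self.ring} "
                     f"correction={self.correction} n={self.n}\n")
            for key, val in self.meta.items():
                fh.write(f"# {key}={val}\n")
            fh.write("r,value\n")
            for r, v in zip(self.r, self.values):
                fh.write(f"{r},{v}\n")


def _bin_grid(r_max: float, ring: float) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(0.0, r_max + 0.5 * ring, ring)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def _ring_areas(edges: np.ndarray) -> np.ndarray:
    return np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)


# ---------------------------------------------------------------------------
# pair correlation functions


def pair_correlation(
    stem_map: StemMap,
    r_max: float = 15.0,
    ring: float = 1.0,
    intensity: "IntensityField | np.ndarray | None" = None,
    kind: str = "g_all",
) -> CorrelationFunction:
    """Univariate pair correlation function with translation edge correction.

    ``intensity=None`` gives the homogeneous estimator (constant intensity,
    pair-count normalization n(n-1)/|W|^2, so CSR gives exactly 1 in
    expectation).  Passing an :class:`IntensityField` gives the
    inhomogeneous estimator with lambda read at the nearest grid cell;
    passing a length-n array uses those per-point lambda values directly
    (see :func:`points_lambda` for the leave-one-out evaluation).
    """
    if stem_map.n < 2:
        raise ValueError("need at least two points")
    win = stem_map.window
    if r_max > min(win.width, win.height) / 2:
        import warnings

        warnings.warn("r_max exceeds half the shorter window side; "
                      "estimator variance will be high", stacklevel=2)
    edges, centers = _bin_grid(r_max, ring)
    coords = stem_map.coords
    if intensity is None:
        # homogeneous case = bivariate with type1 = type2 = all points,
        # shared code path so the reduction identity is bit-exact
        every = np.ones(stem_map.n, dtype=bool)
        out = bivariate_pair_correlation(stem_map, every, every, r_max, ring, kind)
        out.meta = {"estimator": "homogeneous"}
        return out
    else:
        if isinstance(intensity, IntensityField):
            lam = intensity.at(coords)
        else:
            lam = np.maximum(np.asarray(intensity, dtype=float), LAMBDA_FLOOR)
            if lam.shape != (stem_map.n,):
                raise ValueError("per-point intensity must have length n")
        bins, invT, lam_prod = _pair_lambda_products(coords, win, edges, lam)
        contrib = invT / lam_prod
    sums = np.bincount(bins, weights=contrib, minlength=len(centers))
    values = sums / _ring_areas(edges)
    return CorrelationFunction(
        kind, centers, values, ring, stem_map.n,
        meta={"estimator": "inhomogeneous"},
    )


def _pair_lambda_products(coords, win, edges, lam):
    """Binned pairs plus per-pair lambda_i*lambda_j for the inhom estimator."""
    d = cdist(coords, coords)
    adx = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
    ady = np.abs(coords[:, 1][:, None] - coords[:, 1][None, :])
    keep = (d > 0) & (d <= edges[-1])
    np.fill_diagonal(keep, False)
    ii, jj = np.nonzero(keep)
    d = d[keep]
    T = (win.width - adx[keep]) * (win.height - ady[keep])
    bins = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, len(edges) - 2)
    return bins, 1.0 / T, lam[ii] * lam[jj]


def bivariate_pair_correlation(
    stem_map: StemMap,
    mask1: np.ndarray,
    mask2: np.ndarray,
    r_max: float = 15.0,
    ring: float = 1.0,
    kind: str = "g_12",
) -> CorrelationFunction:
    """Bivariate g_12(r): type-2 density at distance r from type-1 points.

    ``mask1``/``mask2`` are boolean selectors over the map's rows; a tree
    may belong to both subsets (e.g. type2 = all trees), in which case
    self-pairs are excluded.  Normalization divides by the type-2 intensity,
    so the statistic is not symmetric in its arguments.
    """
    mask1 = np.asarray(mask1, dtype=bool)
    mask2 = np.asarray(mask2, dtype=bool)
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both subsets must be non-empty")
    win = stem_map.window
    edges, centers = _bin_grid(r_max, ring)
    coords = stem_map.coords
    c1, c2 = coords[mask1], coords[mask2]
    idx1 = np.nonzero(mask1)[0]
    idx2 = np.nonzero(mask2)[0]

    d = cdist(c1, c2)
    same = idx1[:, None] == idx2[None, :]
    keep = (d > 0) & (d <= edges[-1]) & ~same
    adx = np.abs(c1[:, 0][:, None] - c2[:, 0][None, :])[keep]
    ady = np.abs(c1[:, 1][:, None] - c2[:, 1][None, :])[keep]
    dk = d[keep]
    T = (win.width - adx) * (win.height - ady)
    bins = np.clip(np.searchsorted(edges, dk, side="left") - 1, 0, len(edges) - 2)

    n_overlap = int((mask1 & mask2).sum())
    lam2 = (n1 * n2 - n_overlap) / win.area_m2**2
    sums = np.bincount(bins, weights=1.0 / T, minlength=len(centers))
    values = sums / lam2 / _ring_areas(edges)
    return CorrelationFunction(
        kind, centers, values, ring, stem_map.n,
        meta={"n1": n1, "n2": n2},
    )


def mortality_difference_statistics(
    stem_map: StemMap, r_max: float = 15.0, ring: float = 1.0
) -> tuple[CorrelationFunction, CorrelationFunction]:
    """The two fire-mortality contrasts, both 0 under random labeling.

    g_cluster(r) = g_{dead,dead}(r) - g_{alive,dead}(r): positive where
    killed trees cluster among themselves more than around survivors.
    g_densdep(r) = g_{dead,all}(r) - g_{alive,all}(r): positive where killed
    trees sit in locally denser neighborhoods than survivors.
    """
    if not stem_map.has_statuses():
        raise ValueError("map must carry alive/killed statuses for every tree")
    status = stem_map.trees["status"].to_numpy()
    dead = status == "killed"
    alive = ~dead
    if dead.all() or alive.all():
        raise ValueError("mortality statistics undefined: need both statuses")
    every = np.ones_like(dead)
    g_dd = bivariate_pair_correlation(stem_map, dead, dead, r_max, ring, "g_dd")
    g_ad = bivariate_pair_correlation(stem_map, alive, dead, r_max, ring, "g_ad")
    g_d_all = bivariate_pair_correlation(stem_map, dead, every, r_max, ring, "g_d_all")
    g_a_all = bivariate_pair_correlation(stem_map, alive, every, r_max, ring, "g_a_all")
    g_cluster = CorrelationFunction(
        "g_cluster", g_dd.r, g_dd.values - g_ad.values, ring, stem_map.n,
        meta={"reference_level": 0.0},
    )
    g_densdep = CorrelationFunction(
        "g_densdep", g_d_all.r, g_d_all.values - g_a_all.values, ring, stem_map.n,
        meta={"reference_level": 0.0},
    )
    return g_cluster, g_densdep


# ---------------------------------------------------------------------------
# mark statistics


def r_mark_correlation(
    stem_map: StemMap,
    mark: str = "dbh",
    r_max: float = 15.0,
    ring: float = 1.0,
) -> CorrelationFunction:
    """r-mark correlation k(r): mean mark of the point found at distance r.

    Reported in mark units (cm for dbh); the stand mean mark is stored in
    ``meta['mean_mark']`` as the aspatial reference level.  Translation
    weights enter numerator and denominator (ratio estimator).
    """
    if stem_map.n < 2:
        raise ValueError("need at least two marked points")
    marks = stem_map.marks(mark)
    edges, centers = _bin_grid(r_max, ring)
    coords = stem_map.coords
    win = stem_map.window
    d = cdist(coords, coords)
    keep = (d > 0) & (d <= edges[-1])
    np.fill_diagonal(keep, False)
    ii, jj = np.nonzero(keep)
    dk = d[keep]
    T = (win.width - np.abs(coords[ii, 0] - coords[jj, 0])) * (
        win.height - np.abs(coords[ii, 1] - coords[jj, 1])
    )
    w = 1.0 / T
    bins = np.clip(np.searchsorted(edges, dk, side="left") - 1, 0, len(edges) - 2)
    num = np.bincount(bins, weights=w * marks[jj], minlength=len(centers))
    den = np.bincount(bins, weights=w, minlength=len(centers))
    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return CorrelationFunction(
        "k_" + mark, centers, values, ring, stem_map.n,
        meta={"mean_mark": float(marks.mean()), "mark": mark},
    )


def mark_variogram(
    stem_map: StemMap,
    mark: str = "dbh",
    r_max: float = 15.0,
    ring: float = 1.0,
    normalized: bool = True,
) -> CorrelationFunction:
    """Mark variogram gamma(r): mean semivariance 0.5*(m_i - m_j)^2 at lag r.

    With ``normalized=True`` the curve is divided by the sample mark
    variance (ddof=1), which is exactly the expectation of the pairwise
    semivariance under independent marks, so spatially independent marks
    give 1 at every r.
    """
    if stem_map.n < 2:
        raise ValueError("need at least two marked points")
    marks = stem_map.marks(mark)
    var = float(np.var(marks, ddof=1))
    if normalized and var == 0.0:
        raise ValueError(
            "mark variance is zero; use normalized=False for constant marks"
        )
    edges, centers = _bin_grid(r_max, ring)
    coords = stem_map.coords
    win = stem_map.window
    d = cdist(coords, coords)
    keep = (d > 0) & (d <= edges[-1])
    np.fill_diagonal(keep, False)
    ii, jj = np.nonzero(keep)
    dk = d[keep]
    T = (win.width - np.abs(coords[ii, 0] - coords[jj, 0])) * (
        win.height - np.abs(coords[ii, 1] - coords[jj, 1])
    )
    w = 1.0 / T
    semiv = 0.5 * (marks[ii] - marks[jj]) ** 2
    bins = np.clip(np.searchsorted(edges, dk, side="left") - 1, 0, len(edges) - 2)
    num = np.bincount(bins, weights=w * semiv, minlength=len(centers))
    den = np.bincount(bins, weights=w, minlength=len(centers))
    values = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if normalized:
        values = values / var
    return CorrelationFunction(
        "gamma_" + mark, centers, values, ring, stem_map.n,
        meta={"normalized": normalized, "mark_variance": var, "mark": mark},
    )
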