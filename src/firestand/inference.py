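"""Monte Carlo null models and studentized global-envelope inference.

A summary function (pair correlation, mark statistic, mortality contrast)
is computed on the observed map and on ``n_sim`` simulations of a null
model.  All curves are studentized bin-wise,

    z(r) = (T(r) - m(r)) / s(r),

with m, s the pooled mean and sd across {observed} + nulls (pooling makes
the observed curve exchangeable with the nulls under the null hypothesis,
so the test has exact size).  The global envelope uses a single critical
value c = the k-th smallest of the null statistics M_j = max_r |z_j(r)|,
k = ceil((n_sim + 1)(1 - alpha)); the observed curve is significant when
M_0 = max_r |z_0(r)| exceeds c, i.e. when it escapes the back-transformed
band m(r) +/- c*s(r) at ANY distance.  With the conventional n_sim = 399
and alpha = 0.05, c is the 380th order statistic and the test has size
exactly 20/400 = 0.05.

The r-averaged z (mean of z_0(r) over the distance grid, signed) condenses
each curve into one effect-size number for cross-scenario comparison; the
mean of |z| is also reported.

Null models
-----------
inhom_poisson
    points redistributed by an inhomogeneous Poisson process whose
    intensity is the Epanechnikov kernel estimate of the observed pattern
    (bandwidth 20 m, 1 m grid); by default conditioned on the observed
    point count.  Null for g_all / g_alive.
random_label
    alive/killed labels permuted over fixed locations — the null for the
    mortality contrasts, conditioning on the prefire pattern.
random_mark
    quantitative marks (dbh) permuted over fixed locations — the null for
    the r-mark correlation and mark variogram.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .spatial_stats import CorrelationFunction, IntensityField, estimate_intensity
from .stem_data import StemMap

__all__ = [
    "NullModelSpec",
    "EnvelopeResult",
    "simulate_null",
    "global_envelope",
    "run_envelope",
    "NULL_FOR_KIND",
]

#: which null model each statistic kind calls for
NULL_FOR_KIND = {
    "g_all": "inhom_poisson",
    "g_alive": "inhom_poisson",
    "g_cluster": "random_label",
    "g_densdep": "random_label",
    "k_dbh": "random_mark",
    "gamma_dbh": "random_mark",
}


@dataclass
class NullModelSpec:
    kind: str                      # inhom_poisson | random_label | random_mark
    n_sim: int = 399
    seed: int = 0
    bandwidth: float = 20.0        # intensity bandwidth (inhom_poisson)
    resolution: float = 1.0
    mark: str = "dbh"              # permuted column (random_mark)
    condition_on_n: bool = True    # inhom_poisson: fix the point count

    def __post_init__(self) -> None:
        if self.kind not in {"inhom_poisson", "random_label", "random_mark"}:
            raise ValueError(f"unknown null model kind {self.kind!r}")
        if self.n_sim < 39:
            raise ValueError("n_sim must be at least 39 for alpha = 0.05")


def _sample_inhom(
    rng: np.random.Generator, field_: IntensityField, n: int
) -> np.ndarray:
    """Draw n points with density proportional to the gridded intensity."""
    lam = np.maximum(field_.values, 0.0).ravel()
    p = lam / lam.sum()
    cells = rng.choice(len(p), size=n, p=p)
    ny, nx = field_.values.shape
    iy, ix = np.divmod(cells, nx)
    res = field_.resolution
    x = field_.window.x_min + (ix + rng.uniform(0, 1, n)) * res
    y = field_.window.y_min + (iy + rng.uniform(0, 1, n)) * res
    return np.column_stack([x, y])


def simulate_null(
    stem_map: StemMap, spec: NullModelSpec
) -> Iterator[StemMap]:
    """Yield ``spec.n_sim`` null stem maps, reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "random_label":
        if not stem_map.has_statuses():
            raise ValueError("random_label needs alive/killed statuses")
        status = stem_map.trees["status"].to_numpy()
        for _ in range(spec.n_sim):
            yield stem_map.with_columns(status=rng.permutation(status))
    elif spec.kind == "random_mark":
        marks = stem_map.trees[spec.mark].to_numpy()
        for _ in range(spec.n_sim):
            yield stem_map.with_columns(**{spec.mark: rng.permutation(marks)})
    else:  # inhom_poisson
        field_ = estimate_intensity(stem_map, spec.bandwidth, spec.resolution)
        n_obs = stem_map.n
        for _ in range(spec.n_sim):
            n = n_obs if spec.condition_on_n else max(2, rng.poisson(n_obs))
            xy = _sample_inhom(rng, field_, n)
            df = stem_map.trees.sample(
                n=n, replace=n > n_obs, random_state=int(rng.integers(2**31))
            ).reset_index(drop=True)
            df = df.assign(x=xy[:, 0], y=xy[:, 1], id=[f"n{i}" for i in range(n)])
            yield StemMap(df, stem_map.window, stem_map.label + "/null")


@dataclass
class EnvelopeResult:
    """Outcome of a studentized global-envelope test for one statistic."""

    kind: str
    r: np.ndarray
    empirical: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z: np.ndarray                 # studentized empirical curve
    lower: np.ndarray             # back-transformed global band
    upper: np.ndarray
    critical: float               # c, the global critical value on the z scale
    significant: bool
    r_averaged_z: float           # mean signed z over the distance grid
    r_averaged_abs_z: float
    n_sim: int
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# kind={self.kind} significant={self.significant} "
                f"r_averaged_z={self.r_averaged_z:.6g} c={self.critical:.6g} "
                f"n_sim={self.n_sim} alpha={self.alpha}\n"
            )
            fh.write("r,empirical,mean,lo,hi,z\n")
            for row in zip(
                self.r, self.empirical, self.null_mean, self.lower, self.upper, self.z
            ):
                fh.write(",".join(f"{v:.8g}" for v in row) + "\n")


def global_envelope(
    empirical: CorrelationFunction,
    nulls: Sequence[CorrelationFunction],
    alpha: float = 0.05,
) -> EnvelopeResult:
    """Two-sided max-|z| global envelope from null-model simulations.

    All curves must share the empirical statistic's r grid.  Bins with zero
    pooled sd contribute z = 0 (degenerate bin, warned); bins that are NaN
    in any curve (no pairs at that lag) are dropped from the test.
    """
    nulls = list(nulls)
    n_sim = len(nulls)
    if n_sim < 39:
        raise ValueError("need at least 39 null curves")
    r = empirical.r
    for nc in nulls:
        if nc.r.shape != r.shape or not np.allclose(nc.r, r):
            raise ValueError("null curves must share the empirical r grid")
    V = np.vstack([empirical.values] + [nc.values for nc in nulls])  # (n_sim+1, nr)
    valid = ~np.isnan(V).any(axis=0)
    m = np.full(r.shape, np.nan)
    s = np.full(r.shape, np.nan)
    m[valid] = V[:, valid].mean(axis=0)
    s[valid] = V[:, valid].std(axis=0, ddof=1)
    degenerate = valid & (s == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate bins with zero null sd; z set to 0",
            stacklevel=2,
        )
    Z = np.zeros_like(V)
    ok = valid & (s > 0)
    Z[:, ok] = (V[:, ok] - m[ok]) / s[ok]
    use = valid  # degenerate bins contribute z = 0
    M = np.max(np.abs(Z[:, use]), axis=1) if use.any() else np.zeros(V.shape[0])
    k = math.ceil((n_sim + 1) * (1.0 - alpha))
    c = float(np.sort(M[1:])[k - 1])
    significant = bool(M[0] > c)
    z_emp = np.where(valid, Z[0], np.nan)
    return EnvelopeResult(
        kind=empirical.kind,
        r=r,
        empirical=empirical.values,
        null_mean=m,
        null_sd=s,
        z=z_emp,
        lower=m - c * s,
        upper=m + c * s,
        critical=c,
        significant=significant,
        r_averaged_z=float(np.nanmean(z_emp)),
        r_averaged_abs_z=float(np.nanmean(np.abs(z_emp))),
        n_sim=n_sim,
        alpha=alpha,
        meta=dict(empirical.meta),
    )


def run_envelope(
    stem_map: StemMap,
    statistic: Callable[[StemMap], CorrelationFunction],
    spec: NullModelSpec,
    alpha: float = 0.05,
    check_kind: bool = True,
) -> EnvelopeResult:
    """Compute a statistic on the map and under a null model, then test it.

    ``statistic`` maps a StemMap to a CorrelationFunction.  When
    ``check_kind`` is set, the statistic's declared kind must call for the
    requested null model (e.g. the mortality contrasts demand random
    labeling, not a Poisson resample).
    """
    emp = statistic(stem_map)
    expected = NULL_FOR_KIND.get(emp.kind)
    if check_kind and expected is not None and expected != spec.kind:
        raise ValueError(
            f"statistic {emp.kind!r} requires the {expected!r} null model, "
            f"got {spec.kind!r}"
        )
    nulls = [statistic(null_map) for null_map in simulate_null(stem_map, spec)]
    return global_envelope(emp, nulls, alpha=alpha)
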