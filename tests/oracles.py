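"""Independent brute-force oracles for the estimators.

Everything here is written as explicit Python loops over ordered point
pairs, sharing only the binning convention (edges at multiples of the ring
width; a distance exactly on an edge falls in the lower ring) with the
production code.  The production estimators must reproduce these values
exactly on small maps.
"""

from __future__ import annotations

import bisect
import math

import numpy as np


def _bin_of(d: float, edges: list[float]) -> int:
    """Ring index of distance d; on-edge distances fall in the lower ring."""
    return bisect.bisect_left(edges, d) - 1


def _translation_area(dx: float, dy: float, width: float, height: float) -> float:
    return (width - abs(dx)) * (height - abs(dy))


def naive_pair_correlation(coords, window, r_max=15.0, ring=1.0):
    """Homogeneous pcf with translation correction, O(n^2) loops."""
    n = len(coords)
    edges = [k * ring for k in range(int(round(r_max / ring)) + 1)]
    n_bins = len(edges) - 1
    sums = [0.0] * n_bins
    W, H = window.width, window.height
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = coords[i][0] - coords[j][0]
            dy = coords[i][1] - coords[j][1]
            d = math.hypot(dx, dy)
            if d <= 0 or d > r_max:
                continue
            k = _bin_of(d, edges)
            if k < 0:
                k = 0
            sums[k] += 1.0 / _translation_area(dx, dy, W, H)
    lam2 = n * (n - 1) / (W * H) ** 2
    out = []
    for k in range(n_bins):
        area = math.pi * (edges[k + 1] ** 2 - edges[k] ** 2)
        out.append(sums[k] / lam2 / area)
    return np.array(out)


def naive_bivariate_pcf(coords, idx1, idx2, window, r_max=15.0, ring=1.0):
    """Bivariate pcf over row-index subsets of one map; self-pairs excluded."""
    edges = [k * ring for k in range(int(round(r_max / ring)) + 1)]
    n_bins = len(edges) - 1
    sums = [0.0] * n_bins
    W, H = window.width, window.height
    for i in idx1:
        for j in idx2:
            if i == j:
                continue
            dx = coords[i][0] - coords[j][0]
            dy = coords[i][1] - coords[j][1]
            d = math.hypot(dx, dy)
            if d <= 0 or d > r_max:
                continue
            k = max(_bin_of(d, edges), 0)
            sums[k] += 1.0 / _translation_area(dx, dy, W, H)
    overlap = len(set(idx1) & set(idx2))
    lam2 = (len(idx1) * len(idx2) - overlap) / (W * H) ** 2
    out = []
    for k in range(n_bins):
        area = math.pi * (edges[k + 1] ** 2 - edges[k] ** 2)
        out.append(sums[k] / lam2 / area)
    return np.array(out)


def naive_mark_stats(coords, marks, window, r_max=15.0, ring=1.0):
    """Translation-weighted r-mark correlation and raw mark semivariance.

    Returns (k_mark, gamma_raw): per-ring weighted mean of the second
    point's mark, and weighted mean of 0.5*(m_i - m_j)^2 (unnormalized).
    Rings with no pairs hold NaN.
    """
    n = len(coords)
    edges = [k * ring for k in range(int(round(r_max / ring)) + 1)]
    n_bins = len(edges) - 1
    num_k = [0.0] * n_bins
    num_g = [0.0] * n_bins
    den = [0.0] * n_bins
    W, H = window.width, window.height
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = coords[i][0] - coords[j][0]
            dy = coords[i][1] - coords[j][1]
            d = math.hypot(dx, dy)
            if d <= 0 or d > r_max:
                continue
            k = max(_bin_of(d, edges), 0)
            w = 1.0 / _translation_area(dx, dy, W, H)
            num_k[k] += w * marks[j]
            num_g[k] += w * 0.5 * (marks[i] - marks[j]) ** 2
            den[k] += w
    k_mark = np.array(
        [num_k[k] / den[k] if den[k] > 0 else np.nan for k in range(n_bins)]
    )
    gamma = np.array(
        [num_g[k] / den[k] if den[k] > 0 else np.nan for k in range(n_bins)]
    )
    return k_mark, gamma


def transitive_closure_groups(coords, linkage):
    """Group labels by boolean transitive closure over the distance matrix."""
    n = len(coords)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        adj[i][i] = True
        for j in range(n):
            d = math.hypot(coords[i][0] - coords[j][0], coords[i][1] - coords[j][1])
            if d <= linkage:
                adj[i][j] = True
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if adj[i][j]:
                    for k in range(n):
                        if adj[j][k] and not adj[i][k]:
                            adj[i][k] = True
                            changed = True
    labels = [-1] * n
    next_label = 0
    for i in range(n):
        if labels[i] == -1:
            for j in range(n):
                if adj[i][j]:
                    labels[j] = next_label
            next_label += 1
    return np.array(labels)


def grid_profile_slrt(x, y, taus=None):
    """Signed LRT statistic for CV equality via dense grid over the common CV."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def free_ll(s):
        n = len(s)
        v = np.mean((s - s.mean()) ** 2)
        return -0.5 * n * (math.log(2 * math.pi * v) + 1.0)

    def constrained_ll(tau):
        total = 0.0
        for s in (x, y):
            n = len(s)
            m1, m2 = s.sum(), float(np.sum(s**2))
            mu = (-m1 + math.sqrt(m1**2 + 4 * n * tau**2 * m2)) / (2 * n * tau**2)
            ss = m2 - 2 * m1 * mu + n * mu**2
            total += -0.5 * n * math.log(2 * math.pi * tau**2 * mu**2) - ss / (
                2 * tau**2 * mu**2
            )
        return total

    cvs = [np.std(s) / np.mean(s) for s in (x, y)]
    if taus is None:
        taus = np.linspace(min(cvs) * 0.2 + 1e-9, max(cvs) * 5, 20001)
    l0 = max(constrained_ll(t) for t in taus)
    l1 = free_ll(x) + free_ll(y)
    T = max(0.0, 2 * (l1 - l0))
    return math.copysign(math.sqrt(T), cvs[0] - cvs[1])
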