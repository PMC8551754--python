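"""Independent brute-force oracles used to pin the fast implementations.

These deliberately share no code with the package internals: the dip
oracle minimizes the sup-distance over piecewise-linear unimodal CDFs by
exhaustive mode enumeration + linear programming, and the quantile-fit
oracle minimizes the penalized pinball objective exactly by enumerating
every kink-hyperplane vertex of the piecewise-linear convex objective.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_brute_force(x, pad_factor: float = 1e7) -> float:
    """Dip by definition: min over unimodal CDFs G of sup |F_n - G|.

    G is piecewise linear with node values G_i at the data points plus
    virtual anchor points far outside the data where G = 0 and G = 1.
    For each candidate mode at point index m, slopes must be
    nondecreasing on segments left of m and nonincreasing right of m
    (unlinked across m: a unimodal CDF may break slope at its mode).
    The sup distance to the ECDF reduces to the tube constraint
    i/n - t <= G_i <= (i-1)/n + t.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    rng_w = max(x[-1] - x[0], 1.0)
    pts = np.r_[x[0] - pad_factor * rng_w, x, x[-1] + pad_factor * rng_w]
    dx = np.diff(pts)  # widths of segments 0..n
    nv = n + 1  # variables: G_1..G_n, t

    def gvec(i):
        v = np.zeros(nv)
        if i == 0:
            return v, 0.0
        if i == n + 1:
            return v, 1.0
        v[i - 1] = 1.0
        return v, 0.0

    A0, b0 = [], []
    for i in range(1, n + 1):
        v, _ = gvec(i)
        r = -v.copy()
        r[n] = -1.0  # G_i >= i/n - t
        A0.append(r)
        b0.append(-i / n)
        r = v.copy()
        r[n] = -1.0  # G_i <= (i-1)/n + t
        A0.append(r)
        b0.append((i - 1) / n)
    for i in range(0, n + 1):  # monotone
        v1, c1 = gvec(i)
        v2, c2 = gvec(i + 1)
        A0.append(v1 - v2)
        b0.append(c2 - c1)

    def slope_pair(i):
        """row, const encoding s_i - s_{i+1} <= 0 (cross-multiplied)."""
        v1, c1 = gvec(i)
        v2, c2 = gvec(i + 1)
        v3, c3 = gvec(i + 2)
        row = (v2 - v1) * dx[i + 1] - (v3 - v2) * dx[i]
        const = (c2 - c1) * dx[i + 1] - (c3 - c2) * dx[i]
        return row, const

    cost = np.zeros(nv)
    cost[n] = 1.0
    bounds = [(0, 1)] * n + [(0, None)]
    best = np.inf
    for m in range(0, n + 2):
        A, b = list(A0), list(b0)
        for i in range(0, m - 1):  # convex side: s_i <= s_{i+1}
            row, const = slope_pair(i)
            A.append(row)
            b.append(-const)
        for i in range(m, n):  # concave side: s_i >= s_{i+1}
            row, const = slope_pair(i)
            A.append(-row)
            b.append(const)
        res = linprog(cost, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                      method="highs")
        if res.status == 0 and res.fun < best:
            best = res.fun
    return float(best)


def pinball_sum(residuals, tau: float) -> float:
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def scalar_quantile_minimizer(values, tau: float, grid=None) -> float:
    """argmin over constants c of sum of check losses, by grid search."""
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = np.linspace(values.min() - 1, values.max() + 1, 20001)
    losses = [pinball_sum(values - c, tau) for c in grid]
    return float(grid[int(np.argmin(losses))])


def brute_force_min_objective(B: np.ndarray, y: np.ndarray, tau: float,
                              lam: float) -> float:
    """Exact minimum of the penalized pinball objective for <= 3
    coefficients, by exhaustive vertex enumeration.

    The objective sum_i rho_tau(y_i - (Bc)_i) + lam * sum_j |(Dc)_j| is
    piecewise-linear convex in c, so a minimizer exists where p
    independent kink hyperplanes meet ({(Bc)_i = y_i} interpolation
    conditions and {(Dc)_j = 0} penalty kinks). Enumerate every subset of
    p hyperplanes, solve the p x p system, evaluate, take the minimum.
    """
    from itertools import combinations

    n, p = B.shape
    assert p <= 3
    D = np.zeros((max(p - 2, 0), p))
    for j in range(p - 2):
        D[j, j: j + 3] = (1.0, -2.0, 1.0)
    planes = [(B[i], y[i]) for i in range(n)]
    planes += [(D[j], 0.0) for j in range(p - 2)]

    def objective(c):
        r = y - B @ c
        val = float(np.sum(r * (tau - (r < 0))))
        if p >= 3:
            val += lam * float(np.abs(D @ c).sum())
        return val

    best = np.inf
    for subset in combinations(range(len(planes)), p):
        A = np.array([planes[i][0] for i in subset])
        b = np.array([planes[i][1] for i in subset])
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        c = np.linalg.solve(A, b)
        best = min(best, objective(c))
    return best
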