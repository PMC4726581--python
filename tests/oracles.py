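"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, dense solves, fine-grid
quadrature) and shares no code path with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import root


def variogram_pairs(locations, values, lag_width, max_lag):
    """O(n^2) pair enumeration of the experimental semivariogram."""
    locations = np.asarray(locations, float)
    values = np.asarray(values, float)
    n = len(values)
    n_bins = int(np.ceil(max_lag / lag_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            h = float(np.hypot(*(locations[i] - locations[j])))
            k = int(h // lag_width)
            if k < n_bins:
                sums[k] += (values[i] - values[j]) ** 2
                counts[k] += 1
    gamma = np.where(counts > 0, sums / np.maximum(2 * counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * lag_width
    return centers, gamma, counts


def cross_variogram_pairs(locations, z, y, lag_width, max_lag):
    """O(n^2) pair enumeration of the experimental cross-variogram."""
    locations = np.asarray(locations, float)
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    n = len(z)
    n_bins = int(np.ceil(max_lag / lag_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            h = float(np.hypot(*(locations[i] - locations[j])))
            k = int(h // lag_width)
            if k < n_bins:
                sums[k] += (z[i] - z[j]) * (y[i] - y[j])
                counts[k] += 1
    gamma = np.where(counts > 0, sums / np.maximum(2 * counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * lag_width
    return centers, gamma, counts


def gamma_of(model, h):
    """Variogram evaluation written independently of the package."""
    h = np.asarray(h, float)
    c0, c, a = model.nugget, model.partial_sill, model.range_
    if model.kind == "gaussian":
        g = c0 + c * (1 - np.exp(-3 * h**2 / a**2))
    else:
        hr = np.minimum(h / a, 1.0)
        g = c0 + c * (1.5 * hr - 0.5 * hr**3)
    return np.where(h <= 1e-12, 0.0, g)


def dense_ok_solve(locations, values, model, target):
    """Full ordinary-kriging system assembled entry-by-entry and solved densely."""
    locations = np.asarray(locations, float)
    n = len(values)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            A[i, j] = 0.0 if i == j else gamma_of(
                model, np.hypot(*(locations[i] - locations[j]))
            )
        A[i, n] = A[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        b[i] = gamma_of(model, np.hypot(*(locations[i] - np.asarray(target, float))))
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    lam = sol[:n]
    est = float(lam @ np.asarray(values, float))
    var = float(lam @ b[:n] + sol[n])
    return lam, est, var


def dense_cok_solve(loc1, z1, loc2, z2, coreg, target, q=0.0):
    """Full cokriging system assembled entry-by-entry and solved densely."""
    loc1, loc2 = np.asarray(loc1, float), np.asarray(loc2, float)
    m1, m2 = len(z1), len(z2)
    n = m1 + m2
    A = np.zeros((n + 2, n + 2))
    locs = np.vstack([loc1, loc2])

    def g(i, j):
        h = float(np.hypot(*(locs[i] - locs[j])))
        if i < m1 and j < m1:
            return 0.0 if i == j else gamma_of(coreg.primary_model, h)
        if i >= m1 and j >= m1:
            return 0.0 if i == j else gamma_of(coreg.secondary_model, h)
        return gamma_of(coreg.cross_model, h)

    for i in range(n):
        for j in range(n):
            A[i, j] = g(i, j)
    A[:m1, n] = A[n, :m1] = 1.0
    A[m1:n, n + 1] = A[n + 1, m1:n] = 1.0
    b = np.zeros(n + 2)
    t = np.asarray(target, float)
    for i in range(m1):
        b[i] = gamma_of(coreg.primary_model, float(np.hypot(*(loc1[i] - t))))
    for j in range(m2):
        b[m1 + j] = gamma_of(coreg.cross_model, float(np.hypot(*(loc2[j] - t))))
    b[n], b[n + 1] = 1.0, q
    sol = np.linalg.solve(A, b)
    lam1, lam2 = sol[:m1], sol[m1:n]
    est = float(lam1 @ np.asarray(z1, float) + lam2 @ np.asarray(z2, float))
    return lam1, lam2, est


def bme_posterior_fine_grid(mean, cov, hard_value, soft_pdf, soft_bounds, support, n_soft_grid=2000):
    """Posterior at the estimation point by brute-force double integration.

    ``mean``/``cov`` are the trivariate prior moments ordered
    (estimation point, hard point, soft point); the soft density is integrated
    on a ``n_soft_grid``-point fine grid between ``soft_bounds``.
    """
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    s_grid = np.linspace(*soft_bounds, n_soft_grid)
    dens = np.zeros_like(support, dtype=float)
    for ix, xk in enumerate(support):
        vec = np.column_stack(
            [np.full_like(s_grid, xk), np.full_like(s_grid, hard_value), s_grid]
        )
        fg = stats.multivariate_normal(mean, cov, allow_singular=True).pdf(vec)
        dens[ix] = np.trapezoid(soft_pdf(s_grid) * fg, s_grid)
    total = np.trapezoid(dens, support)
    return dens / total


def maxent_density_1d(support, target_mean, target_var, tol=1e-12):
    """Maximum-entropy density on a discrete support given mean and variance.

    Solves the Lagrange-multiplier system for the constrained entropy maximum:
    p(x) proportional to exp(l1*x + l2*x^2) with multipliers chosen so that the
    discretized density reproduces the requested first two moments.
    """
    x = np.asarray(support, float)

    def moments(lams):
        l1, l2 = lams
        logp = l1 * x + l2 * x**2
        logp -= logp.max()
        p = np.exp(logp)
        p /= np.trapezoid(p, x)
        m = np.trapezoid(x * p, x)
        v = np.trapezoid((x - m) ** 2 * p, x)
        return np.array([m - target_mean, v - target_var]), p

    sol = root(lambda l: moments(l)[0], x0=[target_mean / target_var, -0.5 / target_var], tol=tol)
    if not sol.success:
        raise RuntimeError("max-entropy multiplier solve failed")
    return moments(sol.x)[1]


def entropy_of_density(support, density):
    p = np.clip(np.asarray(density, float), 1e-300, None)
    return float(-np.trapezoid(p * np.log(p), support))
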