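"""Ordinary kriging and ordinary cokriging in semivariance form.

Both solvers work on a per-target neighborhood of nearest data (ties broken by
lexicographic (x, y) order for determinism) and build the classical
Lagrange-augmented systems from variogram values, with gamma(0) = 0 so that
estimation at a sampled location returns the sample exactly.

Ordinary kriging: weights lambda_i solve

    [Gamma 1; 1' 0] [lambda; mu] = [gamma0; 1]

so that the estimate sum(lambda_i Z_i) is unbiased (weights sum to 1) and of
minimum variance.  Cokriging augments the system with a co-located secondary
attribute through its auto- and cross-variograms; the secondary weights are
constrained to sum to 0 by default (the traditional unbiasedness condition) or
to 1 under the ``"paper"`` convention some texts print.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .variogram import PointSamples, VariogramModel


@dataclass
class KrigingResult:
    location: tuple[float, float]
    estimate: float
    kriging_variance: float
    weights: np.ndarray  # per contributing datum (primary first, then secondary)
    indices: np.ndarray  # positions of the contributing data in the input samples


@dataclass
class Coregionalization:
    """Auto-variograms of two attributes plus their cross-variogram."""

    primary_model: VariogramModel
    secondary_model: VariogramModel
    cross_model: VariogramModel

    def __post_init__(self) -> None:
        bound = np.sqrt(self.primary_model.sill * self.secondary_model.sill)
        if abs(self.cross_model.sill) > bound + 1e-12:
            warnings.warn(
                "cross sill exceeds sqrt(primary sill * secondary sill); the "
                "linear model of coregionalization is violated and the joint "
                "covariance may not be positive definite"
            )


def _nearest(locations: np.ndarray, target: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest data, ties broken lexicographically by (x, y)."""
    d = cdist(locations, target[None, :]).ravel()
    order = np.lexsort((locations[:, 1], locations[:, 0], d))
    return order[: min(k, len(d))]


def _check_duplicates(locations: np.ndarray) -> None:
    d = cdist(locations, locations)
    np.fill_diagonal(d, np.inf)
    ii, jj = np.where(d < 1e-9)
    if len(ii):
        i, j = int(ii[0]), int(jj[0])
        a = (float(locations[i][0]), float(locations[i][1]))
        b = (float(locations[j][0]), float(locations[j][1]))
        raise ValueError(
            f"duplicate data locations {a} and {b} make the kriging system singular"
        )


def ordinary_kriging(
    hard: PointSamples,
    model: VariogramModel,
    targets,
    n_neighbors: int = 16,
) -> list[KrigingResult]:
    """Ordinary-kriging estimates at each target location."""
    if len(hard) < 2 and n_neighbors > 1:
        raise ValueError("ordinary kriging needs at least 2 hard data")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    results = []
    for t in targets:
        idx = _nearest(hard.locations, t, n_neighbors)
        loc = hard.locations[idx]
        _check_duplicates(loc)
        m = len(idx)
        gam = model.gamma(cdist(loc, loc))
        np.fill_diagonal(gam, 0.0)
        A = np.zeros((m + 1, m + 1))
        A[:m, :m] = gam
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        rhs = np.zeros(m + 1)
        g0 = model.gamma(cdist(loc, t[None, :]).ravel())
        rhs[:m] = g0
        rhs[m] = 1.0
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular ordinary-kriging system at target {tuple(t)}") from exc
        lam, mu = sol[:m], sol[m]
        est = float(lam @ hard.values[idx])
        var = float(lam @ g0 + mu)
        results.append(KrigingResult(tuple(t), est, max(var, 0.0), lam, idx))
    return results


def cokriging(
    primary: PointSamples,
    secondary: PointSamples,
    coreg: Coregionalization,
    targets,
    n_neighbors_primary: int = 16,
    n_neighbors_secondary: int = 16,
    secondary_constraint: str = "traditional",
) -> list[KrigingResult]:
    """Ordinary-cokriging estimates using a co-located secondary attribute.

    ``secondary_constraint`` is ``"traditional"`` (secondary weights sum to 0,
    unbiased regardless of the secondary's mean) or ``"paper"`` (sum to 1, the
    convention printed in some sources; only sensible if the secondary is
    rescaled to the primary's mean).
    """
    if secondary_constraint not in ("traditional", "paper"):
        raise ValueError("secondary_constraint must be 'traditional' or 'paper'")
    q = 0.0 if secondary_constraint == "traditional" else 1.0
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    results = []
    for t in targets:
        i1 = _nearest(primary.locations, t, n_neighbors_primary)
        i2 = _nearest(secondary.locations, t, n_neighbors_secondary)
        loc1, loc2 = primary.locations[i1], secondary.locations[i2]
        _check_duplicates(loc1)
        _check_duplicates(loc2)
        m1, m2 = len(i1), len(i2)
        g11 = coreg.primary_model.gamma(cdist(loc1, loc1))
        g22 = coreg.secondary_model.gamma(cdist(loc2, loc2))
        g12 = coreg.cross_model.gamma(cdist(loc1, loc2))
        np.fill_diagonal(g11, 0.0)
        np.fill_diagonal(g22, 0.0)
        n = m1 + m2
        A = np.zeros((n + 2, n + 2))
        A[:m1, :m1] = g11
        A[:m1, m1:n] = g12
        A[m1:n, :m1] = g12.T
        A[m1:n, m1:n] = g22
        A[:m1, n] = 1.0
        A[n, :m1] = 1.0
        A[m1:n, n + 1] = 1.0
        A[n + 1, m1:n] = 1.0
        rhs = np.zeros(n + 2)
        g10 = coreg.primary_model.gamma(cdist(loc1, t[None, :]).ravel())
        g20 = coreg.cross_model.gamma(cdist(loc2, t[None, :]).ravel())
        rhs[:m1] = g10
        rhs[m1:n] = g20
        rhs[n] = 1.0
        rhs[n + 1] = q
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular cokriging system at target {tuple(t)}; check the "
                "coregionalization (cross sill vs auto sills) and data layout"
            ) from exc
        lam1, lam2 = sol[:m1], sol[m1:n]
        mu1 = sol[n]
        est = float(lam1 @ primary.values[i1] + lam2 @ secondary.values[i2])
        var = float(lam1 @ g10 + lam2 @ g20 + mu1)
        results.append(
            KrigingResult(tuple(t), est, max(var, 0.0), sol[:n], np.concatenate([i1, i2]))
        )
    return results
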