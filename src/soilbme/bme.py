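"""Bayesian Maximum Entropy estimation with hard and soft data.

The estimation framework has three stages:

1. *Prior*: from general knowledge — a constant mean and a variogram-implied
   covariance C(h) = sill - gamma(h) — the maximum-entropy joint density over
   the estimation point, the hard-data points and the soft-data points is the
   multivariate Gaussian with those moments (entropy maximization under mean
   and covariance constraints has this closed form; a discretized
   Lagrange-multiplier solver validating it lives in the test suite).
2. *Meta-prior*: site-specific knowledge enters as exact hard values and as
   soft probability densities (here truncated Student-t densities from the
   temperature regression).
3. *Posterior*: Bayes' rule integrates the soft densities against the prior,

       f_K(x_k) = A^-1 * integral f_S(chi_soft) f_G(x_k, chi_hard, chi_soft) dchi_soft

   evaluated by fixed-order Gauss-Legendre tensor quadrature over each soft
   datum's truncated support.  The posterior mean (default) or mode summarizes
   the density; with no soft data the posterior reduces exactly to the
   Gaussian conditional given the hard data, i.e. simple kriging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.special import logsumexp

from .grids import GridField, GridSpec
from .softdata import SoftDatum
from .variogram import PointSamples, VariogramModel

_JITTER = 1e-10
_COINCIDENT = 1e-9


@dataclass
class GeneralKnowledge:
    """Constant mean + variogram model: the moment constraints of the prior."""

    mean: float
    variogram: VariogramModel

    def __post_init__(self) -> None:
        if not self.variogram.sill > 0:
            raise ValueError("general knowledge requires a positive sill")


@dataclass
class BMEPosterior:
    """Posterior flux density at one estimation point, on a discrete support."""

    support: np.ndarray
    density: np.ndarray
    normalizer: float
    posterior_mean: float
    posterior_mode: float
    posterior_sd: float


def build_prior(gk: GeneralKnowledge, locations) -> tuple[np.ndarray, np.ndarray]:
    """Max-entropy (Gaussian) prior moments over a set of locations.

    Returns ``(mean_vector, covariance_matrix)`` with a constant mean and
    C(h) = sill - gamma(h); coincident locations get the full sill (they are
    treated as the same random variable).  The matrix is symmetrized and
    jittered; a residual negative eigenvalue raises an error naming the
    offending location pair.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    n = locations.shape[0]
    vg = gk.variogram
    cov = squareform(vg.covariance(pdist(locations))) if n > 1 else np.zeros((1, 1))
    np.fill_diagonal(cov, vg.sill)
    cov = 0.5 * (cov + cov.T) + _JITTER * np.eye(n)
    eigmin = float(np.linalg.eigvalsh(cov)[0])
    if eigmin < -1e-8:
        od = np.abs(cov - np.diag(np.diag(cov)))
        i, j = np.unravel_index(np.argmax(od), od.shape)
        raise ValueError(
            f"prior covariance not PSD (min eigenvalue {eigmin:.3e}); strongest "
            f"coupling between locations {tuple(locations[i])} and {tuple(locations[j])}"
        )
    mean = np.full(n, gk.mean)
    return mean, cov


def _condition(mean, cov, idx_keep, idx_given, given_values):
    """Gaussian conditional moments of ``idx_keep`` given ``idx_given``."""
    if len(idx_given) == 0:
        return mean[idx_keep].copy(), cov[np.ix_(idx_keep, idx_keep)].copy()
    Cgg = cov[np.ix_(idx_given, idx_given)]
    Ckg = cov[np.ix_(idx_keep, idx_given)]
    sol = np.linalg.solve(Cgg, (np.asarray(given_values) - mean[idx_given]))
    m = mean[idx_keep] + Ckg @ sol
    S = cov[np.ix_(idx_keep, idx_keep)] - Ckg @ np.linalg.solve(Cgg, Ckg.T)
    return m, 0.5 * (S + S.T)


def _hard_log_density(mean, cov, idx_hard, hard_values) -> float:
    if len(idx_hard) == 0:
        return 0.0
    C = cov[np.ix_(idx_hard, idx_hard)]
    r = np.asarray(hard_values) - mean[idx_hard]
    L = np.linalg.cholesky(C)
    z = np.linalg.solve(L, r)
    return float(
        -0.5 * z @ z - np.sum(np.log(np.diag(L))) - 0.5 * len(r) * np.log(2 * np.pi)
    )


def _soft_quadrature(soft: list[SoftDatum], n_quad: int, cond_means, cond_sds):
    """Tensor Gauss-Legendre nodes over each soft dimension.

    Per dimension the interval is the overlap of the soft datum's truncated
    99.9% support with the +/- 8 SD region of its Gaussian conditional given
    the hard data (``cond_means``/``cond_sds``): outside that overlap the
    integrand f_S * f_G is negligible, and resolving only the overlap keeps
    21-node quadrature accurate when the two densities have very different
    widths.  Returns ``(chi, logw)``: node matrix (Q, s) and per-node
    log-weights that already include the soft densities.
    """
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_quad)
    nodes, logws = [], []
    for sd, pm, ps in zip(soft, cond_means, cond_sds):
        slo, shi = sd.support(0.999)
        lo = max(slo, pm - 8.0 * ps, sd.lower_trunc)
        hi = min(shi, pm + 8.0 * ps)
        if lo >= hi:  # disjoint densities: quadrature across the gap
            lo, hi = max(hi - ps, sd.lower_trunc), lo + ps
        x = 0.5 * (hi - lo) * gl_x + 0.5 * (hi + lo)
        w = 0.5 * (hi - lo) * gl_w * sd.pdf(x)
        nodes.append(x)
        with np.errstate(divide="ignore"):
            logws.append(np.log(w))
    mesh = np.meshgrid(*nodes, indexing="ij")
    chi = np.column_stack([m.ravel() for m in mesh])
    wmesh = np.meshgrid(*logws, indexing="ij")
    logw = np.sum([m.ravel() for m in wmesh], axis=0)
    return chi, logw


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(cov + _JITTER * np.eye(len(mean)))
    z = np.linalg.solve(L, (x - mean).T)
    return (
        -0.5 * np.sum(z**2, axis=0)
        - np.sum(np.log(np.diag(L)))
        - 0.5 * len(mean) * np.log(2 * np.pi)
    )


def _summaries(support: np.ndarray, density: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.trapezoid(support * density, support))
    var = float(np.trapezoid((support - mean) ** 2 * density, support))
    i = int(np.argmax(density))
    mode = support[i]
    if 0 < i < len(support) - 1:  # parabolic refinement (spacing may be uneven)
        xs, ys = support[i - 1 : i + 2], density[i - 1 : i + 2]
        a2, a1, _ = np.polyfit(xs - xs[1], ys, 2)
        if a2 < 0:
            cand = xs[1] - a1 / (2 * a2)
            if xs[0] <= cand <= xs[2]:
                mode = cand
    return mean, float(mode), float(np.sqrt(max(var, 0.0)))


def posterior_density(
    prior: tuple[np.ndarray, np.ndarray],
    hard_values,
    soft: list[SoftDatum],
    xk_support: np.ndarray | None = None,
    n_quad: int = 21,
    support_floor: float | None = None,
    colocated_soft: list[SoftDatum] | None = None,
) -> BMEPosterior:
    """BME posterior at the estimation point (index 0 of the prior).

    The prior moments must be ordered ``[estimation point, hard..., soft...]``.
    ``colocated_soft`` are soft densities at the estimation point itself; they
    multiply the posterior directly (the exact limit of quadrature over a
    perfectly correlated soft coordinate).  The support auto-widens (down to
    ``support_floor``) until the truncated mixture mass is negligible.
    """
    mean, cov = prior
    hard_values = np.asarray(hard_values, dtype=float).ravel()
    ns = len(soft)
    if 1 + len(hard_values) + ns != len(mean):
        raise ValueError("prior dimension does not match 1 + n_hard + n_soft")
    if ns > 4:
        raise ValueError("at most 4 soft data per neighborhood (quadrature cap)")
    idx_hard = list(range(1, 1 + len(hard_values)))
    idx_ks = [0] + list(range(1 + len(hard_values), len(mean)))
    m, S = _condition(mean, cov, idx_ks, idx_hard, hard_values)
    m_k, v_kk = m[0], S[0, 0]

    if ns == 0:
        means_mix = np.array([m_k])
        logw = np.array([0.0])
        v = v_kk
    else:
        S_ss = S[1:, 1:]
        S_ks = S[0, 1:]
        chi, logw_q = _soft_quadrature(soft, n_quad, m[1:], np.sqrt(np.diag(S_ss)))
        logw = logw_q + _mvn_logpdf(chi, m[1:], S_ss)
        B = np.linalg.solve(S_ss + _JITTER * np.eye(ns), S_ks)
        v = float(v_kk - B @ S_ks)
        means_mix = m_k + (chi - m[1:]) @ B
    v = max(v, _JITTER)
    sd = np.sqrt(v)

    shift = float(np.max(logw))
    if not np.isfinite(shift):
        raise ValueError(
            "soft-data quadrature produced no finite weight; check soft scales "
            f"{[s.scale for s in (soft or [])]}"
        )
    w = np.exp(logw - shift)
    w_tot = float(np.sum(w))

    if xk_support is None:
        # cover the mixture's own mass region: all non-negligible component
        # means +/- 8 kernel SDs, resolved to a fraction of the kernel SD
        keep = w > 1e-12 * w.max()
        lo = float(means_mix[keep].min()) - 8.0 * sd
        hi = float(means_mix[keep].max()) + 8.0 * sd
        if support_floor is not None:
            lo = max(lo, support_floor)
            hi = max(hi, lo + 16.0 * sd)
        n_pts = int(np.clip(np.ceil((hi - lo) / (sd / 3.0)) + 1, 281, 4001))
        support = np.linspace(lo, hi, n_pts)
        if colocated_soft:
            # refine locally around each co-located density (it may be much
            # narrower than the mixture kernels, e.g. near-noiseless fits) and
            # make sure its mass region is covered even outside [lo, hi]
            floor = -np.inf if support_floor is None else support_floor
            extra = [
                np.linspace(
                    max(c.center - 12.0 * c.scale, floor), c.center + 12.0 * c.scale, 241
                )
                for c in colocated_soft
            ]
            support = np.unique(np.concatenate([support] + extra))
    else:
        support = np.asarray(xk_support, dtype=float)
        dx = support[1] - support[0]
        if sd < 2.0 * dx:  # resolve narrow kernels on a user-provided support
            n_pts = min(int(np.ceil((support[-1] - support[0]) / (sd / 2.0))) + 1, 4001)
            support = np.linspace(support[0], support[-1], n_pts)

    def mixture_on(sup: np.ndarray) -> np.ndarray:
        dens = np.zeros_like(sup)
        step = max(1, int(2e6 / max(len(sup), 1)))
        for s0 in range(0, len(means_mix), step):
            mm = means_mix[s0 : s0 + step]
            ww = w[s0 : s0 + step]
            dens += np.exp(-0.5 * ((sup[:, None] - mm[None, :]) / sd) ** 2) @ ww
        return dens / (np.sqrt(2 * np.pi) * sd)

    def log_mixture_on(sup: np.ndarray) -> np.ndarray:
        out = np.full(len(sup), -np.inf)
        step = max(1, int(2e6 / max(len(sup), 1)))
        logw_sh = logw - shift
        for s0 in range(0, len(means_mix), step):
            mm = means_mix[s0 : s0 + step]
            ex = logw_sh[s0 : s0 + step][None, :] - 0.5 * ((sup[:, None] - mm[None, :]) / sd) ** 2
            out = np.logaddexp(out, logsumexp(ex, axis=1))
        return out - np.log(np.sqrt(2 * np.pi) * sd)

    if colocated_soft:
        # multiply in log space: the product of a narrow mixture and a narrow
        # co-located density must survive underflow
        with np.errstate(divide="ignore"):
            logd = log_mixture_on(support)
            for sdat in colocated_soft:
                logd = logd + np.log(sdat.pdf(support))
        peak = float(np.max(logd))
        if not np.isfinite(peak):
            raise ValueError(
                "co-located soft density does not overlap the hard-data "
                "conditional; prior and soft data incompatible"
            )
        dens = np.exp(logd - peak)
        total = float(np.trapezoid(dens, support))
        if not (np.isfinite(total) and total > 0):
            raise ValueError(
                "zero/non-finite posterior normalizer: prior and soft data incompatible"
            )
        density = dens / total
        log_f_hard = _hard_log_density(mean, cov, idx_hard, hard_values)
        normalizer = float(np.exp(log_f_hard + shift) * w_tot)
        pm, pmode, psd = _summaries(support, density)
        return BMEPosterior(support, density, normalizer, pm, pmode, psd)

    for _ in range(6):
        dens = mixture_on(support)
        mass_in = float(np.trapezoid(dens, support)) / w_tot
        lo_ok = dens[0] < 1e-12 * dens.max() or (
            support_floor is not None and support[0] <= support_floor + 1e-12
        )
        hi_ok = dens[-1] < 1e-12 * dens.max()
        if (lo_ok and hi_ok) and mass_in > 1.0 - 1e-6:
            break
        span = support[-1] - support[0]
        lo = support[0] - (0.0 if lo_ok else 0.5 * span)
        hi = support[-1] + (0.0 if hi_ok else 0.5 * span)
        if support_floor is not None:
            lo = max(lo, support_floor)
        support = np.linspace(lo, hi, len(support))

    total = float(np.trapezoid(dens, support))
    if not (np.isfinite(total) and total > 0):
        raise ValueError("zero/non-finite posterior normalizer: prior and soft data incompatible")
    density = dens / total

    log_f_hard = _hard_log_density(mean, cov, idx_hard, hard_values)
    normalizer = float(np.exp(log_f_hard + shift) * w_tot)

    pm, pmode, psd = _summaries(support, density)
    return BMEPosterior(support, density, normalizer, pm, pmode, psd)


def posterior_mean(p: BMEPosterior) -> float:
    """Expected value of the posterior density (trapezoid rule)."""
    return float(np.trapezoid(p.support * p.density, p.support))


def posterior_mode(p: BMEPosterior) -> float:
    """Argmax of the posterior density, refined by quadratic interpolation."""
    return p.posterior_mode


def bme_points(
    hard: PointSamples,
    soft: list[SoftDatum],
    gk: GeneralKnowledge,
    targets,
    n_hard_neighbors: int = 16,
    n_soft_neighbors: int = 3,
    estimator: str = "mean",
    n_quad: int = 21,
    clip_zero: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """BME estimates and posterior SDs at arbitrary target locations.

    Per target the nearest hard and soft data form the neighborhood; a target
    coinciding with a hard datum returns that value with SD 0 (exactness).
    ``estimator`` selects the posterior mean (default) or mode.
    """
    if estimator not in ("mean", "mode"):
        raise ValueError("estimator must be 'mean' or 'mode'")
    if n_soft_neighbors > 4:
        raise ValueError("n_soft_neighbors capped at 4 (quadrature dimension)")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    soft_locs = (
        np.array([s.location for s in soft]) if soft else np.zeros((0, 2))
    )
    est = np.empty(len(targets))
    sds = np.empty(len(targets))
    floor = 0.0 if clip_zero else None
    for ti, t in enumerate(targets):
        dh = cdist(hard.locations, t[None, :]).ravel()
        hit = np.where(dh < _COINCIDENT)[0]
        if len(hit):
            est[ti], sds[ti] = hard.values[hit[0]], 0.0
            continue
        order = np.lexsort((hard.locations[:, 1], hard.locations[:, 0], dh))
        ih = order[:n_hard_neighbors]
        colocated: list[SoftDatum] = []
        nb_soft: list[SoftDatum] = []
        if len(soft_locs) and n_soft_neighbors > 0:
            ds = cdist(soft_locs, t[None, :]).ravel()
            so = np.lexsort((soft_locs[:, 1], soft_locs[:, 0], ds))
            for si in so[:n_soft_neighbors]:
                if ds[si] < _COINCIDENT:
                    colocated.append(soft[si])
                else:
                    nb_soft.append(soft[si])
        locs = np.vstack(
            [t[None, :], hard.locations[ih]]
            + ([np.array([s.location for s in nb_soft])] if nb_soft else [])
        )
        prior = build_prior(gk, locs)
        post = posterior_density(
            prior,
            hard.values[ih],
            nb_soft,
            n_quad=n_quad,
            support_floor=floor,
            colocated_soft=colocated,
        )
        est[ti] = post.posterior_mean if estimator == "mean" else post.posterior_mode
        sds[ti] = post.posterior_sd
    return est, sds


def bme_map(
    hard: PointSamples,
    soft: list[SoftDatum],
    gk: GeneralKnowledge,
    targets: GridSpec,
    n_hard_neighbors: int = 16,
    n_soft_neighbors: int = 3,
    estimator: str = "mean",
    n_quad: int = 21,
    clip_zero: bool = True,
) -> tuple[GridField, GridField]:
    """BME estimate and posterior-SD rasters over a target grid."""
    coords = targets.node_coordinates()
    est, sds = bme_points(
        hard,
        soft,
        gk,
        coords,
        n_hard_neighbors=n_hard_neighbors,
        n_soft_neighbors=n_soft_neighbors,
        estimator=estimator,
        n_quad=n_quad,
        clip_zero=clip_zero,
    )
    shape = (targets.n_y, targets.n_x)
    return GridField(targets, est.reshape(shape)), GridField(targets, sds.reshape(shape))
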