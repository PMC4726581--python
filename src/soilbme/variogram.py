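"""Experimental variography and permissible model fitting.

The semivariogram gamma(h) is half the mean squared increment of an attribute
at separation h; the cross-variogram is the analogous half mean product of
increments of two co-located attributes.  Two permissible isotropic models are
supported:

* gaussian:  gamma(h) = C0 + C * (1 - exp(-3 h^2 / a^2))
* spherical: gamma(h) = C0 + C * (1.5 h/a - 0.5 (h/a)^3)  for h <= a,
             C0 + C otherwise

with nugget C0, partial sill C (sill = C0 + C) and range a.  Models are fitted
to binned experimental values by pair-count-weighted least squares from a small
deterministic multi-start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist


@dataclass
class PointSamples:
    """Point measurements of one attribute: locations (n, 2) metres + values (n,)."""

    locations: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.locations.shape != (self.values.size, 2):
            raise ValueError(
                f"locations {self.locations.shape} and values {self.values.shape} disagree"
            )
        if not (np.all(np.isfinite(self.locations)) and np.all(np.isfinite(self.values))):
            raise ValueError("point samples contain non-finite entries")
        uniq = {(round(x, 9), round(y, 9)) for x, y in self.locations}
        if len(uniq) != len(self.values):
            raise ValueError("duplicate sample locations are not allowed")

    def __len__(self) -> int:
        return self.values.size

    def subset(self, idx) -> "PointSamples":
        idx = np.asarray(idx)
        return PointSamples(self.locations[idx], self.values[idx])


@dataclass
class EmpiricalVariogram:
    """Binned experimental (cross-)variogram.

    Bins with no pairs are kept (pair_counts == 0, semivariance NaN) so that
    gaps in the lag structure stay visible.
    """

    lag_centers: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.lag_centers = np.asarray(self.lag_centers, dtype=float)
        self.semivariances = np.asarray(self.semivariances, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if not (self.lag_centers.shape == self.semivariances.shape == self.pair_counts.shape):
            raise ValueError("lag_centers, semivariances and pair_counts must align")
        if np.any(np.diff(self.lag_centers) <= 0):
            raise ValueError("lag centers must be strictly increasing")
        if np.any(self.pair_counts < 0):
            raise ValueError("pair counts must be non-negative")
        occupied = self.pair_counts > 0
        if not np.all(np.isfinite(self.semivariances[occupied])):
            raise ValueError("semivariances must be finite where pairs exist")

    def nonempty(self) -> "EmpiricalVariogram":
        keep = self.pair_counts > 0
        return EmpiricalVariogram(
            self.lag_centers[keep], self.semivariances[keep], self.pair_counts[keep]
        )


@dataclass
class VariogramModel:
    """Fitted (or assumed) variogram model; the spatial-continuity law."""

    kind: str  # "gaussian" | "spherical"
    nugget: float
    partial_sill: float
    range_: float
    fit_r2: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "spherical"):
            raise ValueError(f"unknown variogram model kind {self.kind!r}")
        if self.nugget < 0:
            raise ValueError(f"nugget must be >= 0, got {self.nugget}")
        if self.partial_sill < 0:
            raise ValueError(f"partial sill must be >= 0, got {self.partial_sill}")
        if not self.range_ > 0:
            raise ValueError(f"range must be > 0, got {self.range_}")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h) -> np.ndarray:
        """Semivariance at separation h; gamma(0) = 0 exactly (exact-interpolator
        convention), jumping to the nugget for any h > 0."""
        h = np.asarray(h, dtype=float)
        if self.kind == "gaussian":
            g = self.nugget + self.partial_sill * (1.0 - np.exp(-3.0 * h**2 / self.range_**2))
        else:
            hr = np.minimum(h / self.range_, 1.0)
            g = self.nugget + self.partial_sill * (1.5 * hr - 0.5 * hr**3)
        return np.where(h <= 1e-12, 0.0, g)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h); C(0) = sill."""
        return self.sill - self.gamma(h)


def _pair_data(locations: np.ndarray) -> np.ndarray:
    return pdist(locations)


def _bin_pairs(
    dists: np.ndarray, products: np.ndarray, lag_width: float, max_lag: float
) -> EmpiricalVariogram:
    n_bins = int(np.ceil(max_lag / lag_width))
    if n_bins < 1:
        raise ValueError(f"max_lag {max_lag} admits no lag bin of width {lag_width}")
    which = np.floor(dists / lag_width).astype(int)
    use = which < n_bins
    which, products = which[use], products[use]
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=products, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    centers = (np.arange(n_bins) + 0.5) * lag_width
    return EmpiricalVariogram(centers, gamma, counts)


def empirical_variogram(
    samples: PointSamples, lag_width: float, max_lag: float | None = None
) -> EmpiricalVariogram:
    """Experimental semivariogram with half-open lag bins [k*w, (k+1)*w).

    ``max_lag`` defaults to half the maximum pairwise distance.  If every value
    is identical a warning is issued and all semivariances are zero.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples for a variogram")
    if not lag_width > 0:
        raise ValueError(f"lag_width must be positive, got {lag_width}")
    dists = _pair_data(samples.locations)
    if max_lag is None:
        max_lag = float(dists.max()) / 2.0
    if not max_lag > 0:
        raise ValueError(f"max_lag must be positive, got {max_lag}")
    if np.ptp(samples.values) == 0:
        warnings.warn("all sample values identical; variogram is identically zero")
    sq = pdist(samples.values[:, None], metric="sqeuclidean")
    return _bin_pairs(dists, sq, lag_width, max_lag)


def empirical_cross_variogram(
    primary: PointSamples,
    secondary: PointSamples,
    lag_width: float,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Experimental cross-variogram of two co-located attributes.

    Both sample sets must share identical locations (extract the secondary
    attribute at the primary sites first if necessary).
    """
    if len(primary) != len(secondary) or not np.allclose(
        primary.locations, secondary.locations, atol=1e-9
    ):
        raise ValueError(
            "cross-variogram requires co-located samples: extract the secondary "
            "attribute at the primary locations first"
        )
    if not lag_width > 0:
        raise ValueError(f"lag_width must be positive, got {lag_width}")
    dists = _pair_data(primary.locations)
    if max_lag is None:
        max_lag = float(dists.max()) / 2.0
    if not max_lag > 0:
        raise ValueError(f"max_lag must be positive, got {max_lag}")
    n = len(primary)
    iu, ju = np.triu_indices(n, k=1)
    prod = (primary.values[iu] - primary.values[ju]) * (
        secondary.values[iu] - secondary.values[ju]
    )
    return _bin_pairs(dists, prod, lag_width, max_lag)


def _model_curve(kind: str, h: np.ndarray, c0: float, c: float, a: float) -> np.ndarray:
    if kind == "gaussian":
        return c0 + c * (1.0 - np.exp(-3.0 * h**2 / a**2))
    hr = np.minimum(h / a, 1.0)
    return c0 + c * (1.5 * hr - 0.5 * hr**3)


def fit_variogram_model(emp: EmpiricalVariogram, kind: str) -> VariogramModel:
    """Fit a gaussian or spherical model by pair-count-weighted least squares.

    Five deterministic starting points span the empirical sill and lag span;
    ties break on lowest weighted SSE, then smallest range.  A flat empirical
    variogram (pure nugget) is returned flagged ``degenerate`` with an
    unidentifiable range, rather than raising.
    """
    if kind not in ("gaussian", "spherical"):
        raise ValueError(f"unknown variogram model kind {kind!r}")
    used = emp.nonempty()
    h, g, w = used.lag_centers, used.semivariances, used.pair_counts.astype(float)
    if h.size < 3:
        raise ValueError(f"need >= 3 non-empty lag bins to fit a model, got {h.size}")
    sw = np.sqrt(w)
    s_emp = float(np.max(np.abs(g)))
    span = float(h.max())

    if np.ptp(g) < 1e-14 * max(1.0, s_emp):
        warnings.warn("flat empirical variogram: pure-nugget fit, range unidentifiable")
        return VariogramModel(kind, float(g[0]), 0.0, span, fit_r2=float("nan"), degenerate=True)

    def resid(p):
        c0, c, a = p
        return sw * (_model_curve(kind, h, c0, c, a) - g)

    s0 = max(s_emp, 1e-12)
    starts = [
        (0.0, s0, 0.5 * span),
        (0.0, s0, 0.25 * span),
        (0.25 * s0, 0.75 * s0, 0.5 * span),
        (0.5 * s0, 0.5 * s0, 0.75 * span),
        (0.0, s0, span),
    ]
    best = None
    lo = [0.0, 1e-12, 1e-6 * span]
    hi = [np.inf, np.inf, 100.0 * span]
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        key = (round(sse, 12), float(sol.x[2]))
        if best is None or key < best[0]:
            best = (key, sol.x, sse)
    if best is None:
        raise RuntimeError("variogram model optimization failed from every start")
    (_, x, sse) = best
    gbar = np.sum(w * g) / np.sum(w)
    ss_tot = float(np.sum(w * (g - gbar) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")
    return VariogramModel(kind, float(x[0]), float(x[1]), float(x[2]), fit_r2=r2)


def nugget_sill_ratio(model: VariogramModel) -> tuple[float, str]:
    """Nugget-to-sill ratio C0/(C0+C) and the spatial-dependence class.

    Ratio < 0.25 indicates strong spatial dependence, 0.25-0.75 moderate,
    above 0.75 weak.
    """
    if model.sill == 0:
        raise ValueError("nugget-to-sill ratio undefined for zero sill")
    ratio = model.nugget / model.sill
    if ratio < 0.25:
        cls = "strong"
    elif ratio <= 0.75:
        cls = "moderate"
    else:
        cls = "weak"
    return ratio, cls
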