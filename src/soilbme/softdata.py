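"""Temperature-to-flux soft data via an exponential regression.

Soil CO2 efflux responds to soil temperature roughly exponentially
(Arrhenius-type): ``Rs = a * exp(b * T)``.  Fitting this response to the
co-located hard measurements yields, at any temperature reading, a predicted
flux and a Student-t prediction interval

    Rs_hat +/- t_{n-2, 0.025} * S_TP * sqrt(1 + 1/n + (T - T_bar)^2 / S_TT)

where S_TP is the residual standard deviation of the fit and S_TT the sum of
squared temperature deviations.  Each dense temperature reading thus becomes a
*soft datum*: a truncated, scaled and shifted Student-t probability density for
the unmeasured flux at that location, ready for Bayesian Maximum Entropy
fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .grids import GridField


def _link(T, a, b):
    return a * np.exp(b * T)


@dataclass
class ArrheniusFit:
    """Fitted exponential flux-temperature response and its interval statistics."""

    a: float
    b: float
    n: int
    CR: float          # correlation between observed and fitted fluxes
    S_TP: float        # residual SD of the fit, flux units
    S_TT: float        # sum of squared temperature deviations, degC^2
    T_bar: float       # mean temperature, degC
    t_crit: float      # two-sided 95% Student-t critical value, df = n - 2
    cov_ab: np.ndarray | None = None  # 2x2 covariance of (a, b) from the fit

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("Arrhenius fit needs n >= 3")
        if self.S_TP < 0 or not self.S_TT > 0 or not self.t_crit > 0:
            raise ValueError("invalid interval statistics in ArrheniusFit")

    def predict(self, T) -> np.ndarray:
        return _link(np.asarray(T, dtype=float), self.a, self.b)

    def scale(self, T) -> np.ndarray:
        """Prediction-interval half-width divided by t_crit (the t scale)."""
        T = np.asarray(T, dtype=float)
        return self.S_TP * np.sqrt(1.0 + 1.0 / self.n + (T - self.T_bar) ** 2 / self.S_TT)


def fit_arrhenius(
    temps, fluxes, t_crit_override: float | None = None
) -> ArrheniusFit:
    """Nonlinear least-squares fit of ``Rs = a * exp(b * T)``.

    Initialized by linear regression of log-flux on temperature (with a fixed
    fallback when fluxes are not all positive).  ``t_crit_override`` substitutes
    a hand-picked critical value for the computed Student-t quantile, e.g. to
    reproduce published arithmetic.
    """
    T = np.asarray(temps, dtype=float).ravel()
    R = np.asarray(fluxes, dtype=float).ravel()
    if T.size != R.size:
        raise ValueError("temperature and flux vectors must have equal length")
    n = T.size
    if n < 3:
        raise ValueError("need n >= 3 points to fit the response")
    if np.ptp(T) == 0:
        raise ValueError("temperatures are all equal; the response is unidentifiable")

    if np.all(R > 0):
        b0, loga0 = np.polyfit(T, np.log(R), 1)
        p0 = (float(np.exp(loga0)), float(b0))
    else:
        b0 = 0.1
        p0 = (float(np.mean(R) * np.exp(-b0 * np.mean(T))), b0)
    popt, pcov = curve_fit(_link, T, R, p0=p0, maxfev=20000)
    a, b = float(popt[0]), float(popt[1])

    fitted = _link(T, a, b)
    sse = float(np.sum((R - fitted) ** 2))
    s_tp = float(np.sqrt(sse / (n - 2)))
    t_bar = float(np.mean(T))
    s_tt = float(np.sum((T - t_bar) ** 2))
    if np.std(fitted) > 0 and np.std(R) > 0:
        cr = float(np.corrcoef(R, fitted)[0, 1])
    else:
        cr = 0.0
    t_crit = float(stats.t.ppf(0.975, n - 2)) if t_crit_override is None else float(t_crit_override)
    return ArrheniusFit(a, b, n, cr, s_tp, s_tt, t_bar, t_crit, cov_ab=pcov)


def prediction_interval(fit: ArrheniusFit, T: float) -> tuple[float, float]:
    """95% prediction interval for a new flux observation at temperature T."""
    center = float(fit.predict(T))
    half = fit.t_crit * float(fit.scale(T))
    return center - half, center + half


@dataclass
class SoftDatum:
    """Truncated Student-t flux density at one location.

    ``center`` and ``scale`` are the location and scale of the t density with
    ``df`` degrees of freedom; mass below ``lower_trunc`` (default 0: fluxes
    are physically non-negative) is cut off and the density renormalized.
    """

    location: tuple[float, float]
    center: float
    scale: float
    df: int
    lower_trunc: float = 0.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("soft-datum scale must be positive")
        if self.df < 1:
            raise ValueError("soft-datum df must be >= 1")
        self._trunc_mass = float(
            stats.t.sf((self.lower_trunc - self.center) / self.scale, self.df)
        )
        if self._trunc_mass <= 0:
            raise ValueError("truncation removes all soft-datum mass")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        dens = stats.t.pdf((x - self.center) / self.scale, self.df) / self.scale
        return np.where(x >= self.lower_trunc, dens / self._trunc_mass, 0.0)

    def interval(self, prob: float = 0.95) -> tuple[float, float]:
        """Central probability interval of the *untruncated* t density."""
        q = stats.t.ppf(0.5 + prob / 2.0, self.df)
        return self.center - q * self.scale, self.center + q * self.scale

    def support(self, prob: float = 0.999) -> tuple[float, float]:
        """Interval carrying ``prob`` of the untruncated mass, clipped below."""
        lo, hi = self.interval(prob)
        return max(lo, self.lower_trunc), hi


def make_soft_data(
    fit: ArrheniusFit,
    temp_field: GridField,
    exclude=None,
    lower_trunc: float = 0.0,
) -> list[SoftDatum]:
    """One soft datum per temperature-grid node not listed in ``exclude``.

    ``exclude`` is typically the hard-data locations, where an exact flux
    measurement supersedes the temperature-derived density.
    """
    skip = set()
    if exclude is not None:
        for x, y in np.atleast_2d(np.asarray(exclude, dtype=float)):
            skip.add((round(float(x), 6), round(float(y), 6)))
    coords = temp_field.spec.node_coordinates()
    temps = temp_field.flat_values()
    out: list[SoftDatum] = []
    for (x, y), T in zip(coords, temps):
        if (round(float(x), 6), round(float(y), 6)) in skip:
            continue
        out.append(
            SoftDatum(
                location=(float(x), float(y)),
                center=float(fit.predict(T)),
                scale=float(fit.scale(T)),
                df=fit.n - 2,
                lower_trunc=lower_trunc,
            )
        )
    return out
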