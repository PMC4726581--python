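"""Synthetic coupled temperature/flux fields and nested sampling designs.

The generator emulates a 35 m x 35 m grassland plot: a smooth soil-temperature
field on a dense 1-m grid (35 x 35 = 1225 nodes), a soil CO2 efflux field tied
to temperature through an exponential (Arrhenius-type) response
``Rs = a * exp(b * T)`` plus a spatially correlated residual, and a 7 x 7
hard-data grid at 5-m spacing from which nested symmetric subsets of 9, 21, 37
or 49 sampling points are drawn.

Gaussian random fields are drawn exactly by dense Cholesky factorization of
the covariance matrix implied by a variogram model, which is practical at this
plot scale (<= a few thousand nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .grids import GridField, GridSpec
from .variogram import PointSamples, VariogramModel

_JITTER = 1e-10

#: Default exponential flux-temperature link coefficients (flux units, per degC).
DEFAULT_LINK_A = 0.1331
DEFAULT_LINK_B = 0.1370


@dataclass
class FieldModel:
    """Simulation truth for a stationary Gaussian field: constant mean + variogram."""

    mean: float
    variogram: VariogramModel


def default_temperature_grid() -> GridSpec:
    """Dense 1-m temperature grid: 35 x 35 nodes, cell centres at 0.5 .. 34.5 m."""
    return GridSpec(0.5, 0.5, 35, 35, 1.0)


def default_flux_grid() -> GridSpec:
    """Hard-data 5-m grid: 7 x 7 nodes, cell centres at 2.5 .. 32.5 m."""
    return GridSpec(2.5, 2.5, 7, 7, 5.0)


def default_temperature_model() -> FieldModel:
    """Warm-season plot regime: mean 27.18 degC, SD ~0.4 degC, smooth 20-m structure."""
    return FieldModel(27.18, VariogramModel("gaussian", 0.01, 0.15, 20.0))


def default_residual_model() -> FieldModel:
    """Flux residual not explained by temperature: SD ~0.41, 15-m spherical."""
    return FieldModel(0.0, VariogramModel("spherical", 0.02, 0.15, 15.0))


def simulate_gaussian_field(spec: GridSpec, model: FieldModel, seed: int) -> GridField:
    """One realization of a stationary Gaussian random field on a grid.

    The covariance is C(h) = sill - gamma(h) implied by ``model.variogram``
    (the nugget appears as spatially uncorrelated variance).  Dense Cholesky
    with a tiny diagonal jitter; identical seeds give bit-identical fields.
    """
    coords = spec.node_coordinates()
    n = coords.shape[0]
    if n > 5000:
        raise ValueError(f"dense simulation path limited to ~5000 nodes, got {n}")
    vg = model.variogram
    rng = np.random.default_rng(seed)
    if vg.sill < 1e-12:
        values = np.full(n, model.mean)
    else:
        cov = squareform(vg.covariance(pdist(coords)))
        np.fill_diagonal(cov, vg.sill + _JITTER)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "covariance not positive semi-definite after jitter for variogram "
                f"{vg.kind}(nugget={vg.nugget}, partial_sill={vg.partial_sill}, "
                f"range={vg.range_})"
            ) from exc
        values = model.mean + chol @ rng.standard_normal(n)
    return GridField(spec, values.reshape(spec.n_y, spec.n_x))


def simulate_flux_from_temperature(
    temp: GridField,
    a: float,
    b: float,
    residual: FieldModel,
    seed: int,
    clip_negative: bool = False,
) -> tuple[GridField, int]:
    """Soil CO2 efflux field ``a * exp(b * T) + eps`` on the temperature grid.

    ``eps`` is a zero-mean Gaussian field drawn from ``residual``.  Gaussian
    residuals can produce negative fluxes; by default they are kept (and
    counted) so the generator's distributional assumptions stay transparent.
    Returns ``(flux_field, n_negative)`` where ``n_negative`` counts nodes that
    were negative before any clipping.
    """
    bt = b * temp.values
    if np.max(np.abs(bt)) > 700.0:
        raise OverflowError(
            "b * T overflows exp(); rescale the link parameters or temperatures"
        )
    eps = simulate_gaussian_field(
        temp.spec, FieldModel(0.0, residual.variogram), seed
    ).values + residual.mean
    flux = a * np.exp(bt) + eps
    n_negative = int(np.sum(flux < 0))
    if clip_negative:
        flux = np.maximum(flux, 0.0)
    return GridField(temp.spec, flux), n_negative


# Nested sampling schemes on the 7x7 hard-data grid.  The plot is split into
# four quadrants by the centre row and column (the "axes"); points are added
# per quadrant (1 -> 3 -> 6 -> 9, in a frame rotated with the quadrant) and per
# half-axis (1 -> 2 -> 3 -> 3), plus the centre, giving 9 / 21 / 37 / 49 point
# schemes that are nested and symmetric under 90-degree rotation of the plot.
_QUADRANT_ORDER = [(1, 1), (0, 0), (2, 2), (0, 2), (2, 0), (0, 1), (1, 0), (1, 2), (2, 1)]
_ARM_ORDER = [1, 0, 2]
_SCHEME_COUNTS = {9: (1, 1), 21: (3, 2), 37: (6, 3), 49: (9, 3)}


def _rotate_index(rc: tuple[int, int], k: int, n: int) -> tuple[int, int]:
    r, c = rc
    for _ in range(k):
        r, c = c, (n - 1) - r
    return r, c


def sample_scheme(spec: GridSpec, n_points: int) -> np.ndarray:
    """Locations (n_points, 2) of the nested symmetric sampling scheme.

    Supported sizes are 9, 21, 37 and 49 on an odd x odd grid (the canonical
    7 x 7 hard-data grid); 49 is the full grid and every smaller scheme is a
    subset of every larger one.
    """
    if n_points not in _SCHEME_COUNTS:
        raise ValueError(
            f"unsupported scheme size {n_points}; supported sizes are "
            f"{sorted(_SCHEME_COUNTS)}"
        )
    if spec.n_x != spec.n_y or spec.n_x % 2 == 0 or spec.n_x < 3:
        raise ValueError("sampling schemes require an odd x odd square grid")
    n = spec.n_x
    half = n // 2
    if n != 7 and n_points != 9:
        raise ValueError("schemes 21/37/49 are defined for the 7x7 grid")
    if n < 5:
        raise ValueError("sampling schemes need at least a 5x5 grid")
    n_quad, n_arm = _SCHEME_COUNTS[n_points]
    # quadrant cells are given as global indices in the top-left quadrant and
    # rotated about the centre; rotation keeps them off the axes
    cells: set[tuple[int, int]] = {(half, half)}
    for rc in _QUADRANT_ORDER[:n_quad]:
        for k in range(4):
            cells.add(_rotate_index(rc, k, n))
    for off in _ARM_ORDER[:n_arm]:
        for k in range(4):
            cells.add(_rotate_index((off, half), k, n))
    assert len(cells) == n_points
    rows = sorted(cells)
    coords = np.array(
        [
            (spec.origin_x + c * spec.spacing, spec.origin_y + r * spec.spacing)
            for r, c in rows
        ]
    )
    return coords


def hard_samples_from_field(field: GridField, locations: np.ndarray) -> PointSamples:
    """Read point samples off a simulated field at exact node locations."""
    vals = [field.value_at(x, y) for x, y in np.atleast_2d(locations)]
    return PointSamples(np.atleast_2d(locations), np.asarray(vals))
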