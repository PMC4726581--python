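"""Hold-out validation statistics and the method-comparison experiments.

Three accuracy statistics compare estimates ``x*`` with observations ``x``:
root mean squared error RMSE = sqrt(mean((x* - x)^2)), Pearson correlation CR,
and mean bias = mean(x* - x).  On top of these sit two experiment drivers:

* :func:`compare_methods` — a single-plot cross-validation of ordinary
  kriging, cokriging (temperature as secondary attribute) and BME (temperature
  as soft data) on held-out hard data;
* :func:`sampling_density_experiment` — the shrinking-design study: estimate
  the plot from nested 9/21/37/49-point schemes and score each method against
  the simulated truth at the non-sampled grid nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .bme import GeneralKnowledge, bme_points
from .grids import GridField, GridSpec
from .kriging import Coregionalization, cokriging, ordinary_kriging
from .simulate import (
    DEFAULT_LINK_A,
    DEFAULT_LINK_B,
    FieldModel,
    default_flux_grid,
    default_residual_model,
    default_temperature_grid,
    default_temperature_model,
    hard_samples_from_field,
    sample_scheme,
    simulate_flux_from_temperature,
    simulate_gaussian_field,
)
from .softdata import fit_arrhenius, make_soft_data
from .variogram import (
    EmpiricalVariogram,
    PointSamples,
    VariogramModel,
    empirical_cross_variogram,
    empirical_variogram,
    fit_variogram_model,
)


@dataclass
class ValidationReport:
    method: str
    rmse: float
    bias: float
    cr: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("RMSE cannot be negative")
        if np.isfinite(self.cr) and not -1.0 - 1e-12 <= self.cr <= 1.0 + 1e-12:
            raise ValueError("correlation out of [-1, 1]")


def rmse(estimates, observations) -> float:
    e = np.asarray(estimates, dtype=float).ravel()
    o = np.asarray(observations, dtype=float).ravel()
    if e.size != o.size or e.size == 0:
        raise ValueError("estimates and observations must have equal non-zero length")
    return float(np.sqrt(np.mean((e - o) ** 2)))


def correlation(estimates, observations) -> float:
    e = np.asarray(estimates, dtype=float).ravel()
    o = np.asarray(observations, dtype=float).ravel()
    if e.size != o.size or e.size == 0:
        raise ValueError("estimates and observations must have equal non-zero length")
    if np.ptp(e) == 0 or np.ptp(o) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(e, o)[0, 1])


def bias(estimates, observations) -> float:
    e = np.asarray(estimates, dtype=float).ravel()
    o = np.asarray(observations, dtype=float).ravel()
    if e.size != o.size or e.size == 0:
        raise ValueError("estimates and observations must have equal non-zero length")
    return float(np.mean(e - o))


def holdout_split(
    samples: PointSamples, n_holdout: int, seed: int, spacing: float | None = None
) -> tuple[PointSamples, PointSamples]:
    """Random hold-out of interior, mutually non-adjacent grid points.

    Selected points avoid the outer boundary of the sampling grid and no two
    lie within one grid spacing of each other, mirroring cross-validation
    practice that avoids edge points and contiguous runs.  Uniform over the
    feasible sets via seeded rejection sampling.
    """
    n = len(samples)
    if not 0 <= n_holdout < n:
        raise ValueError("n_holdout must be in [0, n)")
    if n_holdout == 0:
        return samples, samples.subset(np.array([], dtype=int))
    loc = samples.locations
    if spacing is None:
        d = cdist(loc, loc)
        np.fill_diagonal(d, np.inf)
        spacing = float(d.min())
    xs, ys = np.unique(np.round(loc[:, 0], 9)), np.unique(np.round(loc[:, 1], 9))
    interior = np.where(
        (loc[:, 0] > xs[0]) & (loc[:, 0] < xs[-1]) & (loc[:, 1] > ys[0]) & (loc[:, 1] < ys[-1])
    )[0]
    rng = np.random.default_rng(seed)
    best = 0
    for _ in range(10000):
        cand = rng.choice(interior, size=min(n_holdout, len(interior)), replace=False)
        if len(cand) < n_holdout:
            break
        dd = cdist(loc[cand], loc[cand])
        np.fill_diagonal(dd, np.inf)
        if dd.min() > spacing + 1e-9:
            test_idx = np.sort(cand)
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            return samples.subset(train_idx), samples.subset(test_idx)
        best = max(best, _greedy_feasible(loc, cand, spacing))
    feasible = _max_feasible(loc, interior, spacing, n_holdout)
    raise ValueError(
        f"cannot place {n_holdout} interior non-adjacent hold-out points; "
        f"at most ~{feasible} are feasible"
    )


def _greedy_feasible(loc, cand, spacing) -> int:
    chosen: list[int] = []
    for c in cand:
        if all(np.linalg.norm(loc[c] - loc[k]) > spacing + 1e-9 for k in chosen):
            chosen.append(c)
    return len(chosen)


def _max_feasible(loc, interior, spacing, cap) -> int:
    best = 0
    rng = np.random.default_rng(0)
    for _ in range(200):
        order = rng.permutation(interior)
        best = max(best, _greedy_feasible(loc, order, spacing))
        if best >= cap:
            break
    return best


@dataclass
class ComparisonConfig:
    """Knobs for the cross-validation comparison of OK / Co-OK / BME."""

    n_holdout: int = 5
    lag_width: float = 5.0
    variogram_kind: str = "gaussian"
    cross_kind: str = "spherical"
    n_neighbors: int = 16
    n_soft_neighbors: int = 3
    methods: tuple[str, ...] = ("OK", "Co-OK", "BME")
    temp_subsample: int = 200  # cap on points used for the temperature variogram


def _colocated_temperatures(hard: PointSamples, temp_grid: GridField) -> PointSamples:
    vals = [temp_grid.value_at(x, y) for x, y in hard.locations]
    return PointSamples(hard.locations, np.asarray(vals))


def _fit_or_fallback(emp: EmpiricalVariogram, kind: str, fallback_sill: float) -> VariogramModel:
    try:
        model = fit_variogram_model(emp, kind)
        if model.degenerate or not model.partial_sill > 0:
            raise ValueError
        return model
    except Exception:
        # too few informative bins (tiny schemes): fall back to a sensible default
        span = float(emp.lag_centers[-1])
        return VariogramModel(kind, 0.0, max(fallback_sill, 1e-8), max(span, 1e-6))


def _temperature_samples(temp_grid: GridField, cap: int) -> PointSamples:
    coords = temp_grid.spec.node_coordinates()
    vals = temp_grid.flat_values()
    if len(vals) > cap:
        step = int(np.ceil(len(vals) / cap))
        coords, vals = coords[::step], vals[::step]
    return PointSamples(coords, vals)


def _condition_nugget(model: VariogramModel) -> VariogramModel:
    """Floor the nugget at a tiny fraction of the sill.

    Zero-nugget gaussian covariance matrices are numerically near-singular at
    short lags; a 1e-4-of-sill nugget is standard conditioning and does not
    visibly change the model."""
    floor = 1e-4 * model.sill
    if model.nugget >= floor or model.sill == 0:
        return model
    return VariogramModel(
        model.kind, floor, max(model.partial_sill - floor, 1e-12), model.range_,
        fit_r2=model.fit_r2, degenerate=model.degenerate,
    )


def fit_plot_models(
    hard: PointSamples, temp_grid: GridField, cfg: ComparisonConfig
) -> tuple[VariogramModel, Coregionalization]:
    """Variogram structures for one plot: flux auto-model + coregionalization.

    The three structures are fitted independently, then the cross structure is
    shrunk (if needed) so that |cross sill| <= 0.95 * sqrt(sill_1 * sill_2):
    independently fitted (cross-)variograms routinely violate the linear model
    of coregionalization, which makes the cokriging system indefinite and the
    weights explode.
    """
    emp = empirical_variogram(hard, cfg.lag_width)
    flux_model = _condition_nugget(
        _fit_or_fallback(emp, cfg.variogram_kind, float(np.var(hard.values)))
    )
    temp_pts = _temperature_samples(temp_grid, cfg.temp_subsample)
    emp_t = empirical_variogram(temp_pts, cfg.lag_width)
    temp_model = _condition_nugget(
        _fit_or_fallback(emp_t, cfg.variogram_kind, float(np.var(temp_pts.values)))
    )
    temps_at_hard = _colocated_temperatures(hard, temp_grid)
    emp_x = empirical_cross_variogram(hard, temps_at_hard, cfg.lag_width)
    cross_fallback = 0.5 * np.sqrt(flux_model.sill * temp_model.sill)
    cross_fit = _fit_or_fallback(emp_x, cfg.cross_kind, cross_fallback)
    # intrinsic coregionalization: all three structures share the primary's
    # correlation shape; only the sills differ, with the cross sill bounded by
    # 0.95 * sqrt of the auto partial sills so the joint covariance stays PSD
    temp_intrinsic = VariogramModel(
        flux_model.kind,
        max(1e-4 * temp_model.sill, temp_model.nugget),
        max(temp_model.sill - max(1e-4 * temp_model.sill, temp_model.nugget), 1e-12),
        flux_model.range_,
        fit_r2=temp_model.fit_r2,
    )
    bound = 0.95 * np.sqrt(flux_model.partial_sill * temp_intrinsic.partial_sill)
    # positive flux-temperature coupling; the model container carries C > 0
    cross_sill = float(np.clip(cross_fit.sill, 1e-12, bound))
    cross_model = VariogramModel(
        flux_model.kind, 0.0, cross_sill, flux_model.range_, fit_r2=cross_fit.fit_r2
    )
    return flux_model, Coregionalization(flux_model, temp_intrinsic, cross_model)


def _run_methods(
    methods,
    train: PointSamples,
    targets: np.ndarray,
    temp_grid: GridField,
    flux_model: VariogramModel,
    coreg: Coregionalization,
    cfg: ComparisonConfig,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    if "OK" in methods:
        res = ordinary_kriging(train, flux_model, targets, n_neighbors=cfg.n_neighbors)
        out["OK"] = np.array([r.estimate for r in res])
    if "Co-OK" in methods:
        temp_pts = _temperature_samples(temp_grid, cfg.temp_subsample)
        res = cokriging(
            train,
            temp_pts,
            coreg,
            targets,
            n_neighbors_primary=cfg.n_neighbors,
            n_neighbors_secondary=cfg.n_neighbors,
        )
        out["Co-OK"] = np.array([r.estimate for r in res])
    if "BME" in methods:
        temps_at_train = _colocated_temperatures(train, temp_grid)
        fit = fit_arrhenius(temps_at_train.values, train.values)
        soft = make_soft_data(fit, temp_grid, exclude=train.locations)
        gk = GeneralKnowledge(float(np.mean(train.values)), flux_model)
        est, _ = bme_points(
            train,
            soft,
            gk,
            targets,
            n_hard_neighbors=cfg.n_neighbors,
            n_soft_neighbors=cfg.n_soft_neighbors,
        )
        out["BME"] = est
    return out


def compare_methods(
    hard: PointSamples,
    temp_grid: GridField,
    cfg: ComparisonConfig | None = None,
    seed: int = 0,
) -> list[ValidationReport]:
    """Cross-validate OK, Co-OK and BME on one plot of hard data.

    Holds out ``cfg.n_holdout`` interior points, fits all spatial structure on
    the remaining hard data, estimates the held-out fluxes with each method and
    scores RMSE / bias / CR against the measurements.
    """
    cfg = cfg or ComparisonConfig()
    train, test = holdout_split(hard, cfg.n_holdout, seed)
    flux_model, coreg = fit_plot_models(train, temp_grid, cfg)
    estimates = _run_methods(
        cfg.methods, train, test.locations, temp_grid, flux_model, coreg, cfg
    )
    reports = []
    for method in cfg.methods:
        e = estimates[method]
        try:
            cr = correlation(e, test.values)
        except ValueError:
            cr = float("nan")
        reports.append(ValidationReport(method, rmse(e, test.values), bias(e, test.values), cr))
    return reports


@dataclass
class WorldConfig:
    """Simulation truth for the synthetic plot (defaults: the warm-day regime)."""

    temperature: FieldModel = field(default_factory=default_temperature_model)
    residual: FieldModel = field(default_factory=default_residual_model)
    link_a: float = DEFAULT_LINK_A
    link_b: float = DEFAULT_LINK_B
    temp_grid: GridSpec = field(default_factory=default_temperature_grid)
    flux_grid: GridSpec = field(default_factory=default_flux_grid)


def simulate_world(world: WorldConfig, seed: int) -> tuple[GridField, GridField]:
    """Draw one coupled (temperature, flux) truth realization."""
    ss = np.random.SeedSequence(seed)
    s_temp, s_res = [int(s) for s in ss.generate_state(2) >> 1]
    temp = simulate_gaussian_field(world.temp_grid, world.temperature, s_temp)
    flux, _ = simulate_flux_from_temperature(
        temp, world.link_a, world.link_b, world.residual, s_res
    )
    return temp, flux


def sampling_density_experiment(
    world: WorldConfig | None = None,
    schemes=(9, 21, 37, 49),
    seeds=range(30),
    methods=("OK", "BME"),
    cfg: ComparisonConfig | None = None,
    target_stride: int = 2,
) -> pd.DataFrame:
    """Score OK and BME against simulated truth under shrinking designs.

    For each seed a coupled truth is simulated; for each nested scheme the
    hard data are read off the flux field at the scheme nodes, every method
    estimates the non-sampled nodes of the dense grid (thinned by
    ``target_stride`` along each axis to keep runtime desk-scale), and
    RMSE / CR are computed against the simulated truth there.  Returns a tidy
    DataFrame with columns ``scheme, method, seed, rmse, cr``.
    """
    world = world or WorldConfig()
    cfg = cfg or ComparisonConfig()
    rows = []
    tg = world.temp_grid
    ii, jj = np.meshgrid(np.arange(tg.n_x), np.arange(tg.n_y))
    keep = ((ii % target_stride == 0) & (jj % target_stride == 0)).ravel()
    all_coords = tg.node_coordinates()
    for seed in seeds:
        temp, flux = simulate_world(world, int(seed))
        all_truth = flux.flat_values()
        for scheme in schemes:
            pts = sample_scheme(world.flux_grid, int(scheme))
            hard = hard_samples_from_field(flux, pts)
            sampled = {(round(x, 6), round(y, 6)) for x, y in pts}
            target_mask = keep & np.array(
                [(round(x, 6), round(y, 6)) not in sampled for x, y in all_coords]
            )
            targets = all_coords[target_mask]
            if len(targets) == 0:
                continue
            truth = all_truth[target_mask]
            flux_model, coreg = fit_plot_models(hard, temp, cfg)
            estimates = _run_methods(
                methods, hard, targets, temp, flux_model, coreg, cfg
            )
            for method in methods:
                e = estimates[method]
                try:
                    cr = correlation(e, truth)
                except ValueError:
                    cr = float("nan")
                rows.append(
                    {
                        "scheme": int(scheme),
                        "method": method,
                        "seed": int(seed),
                        "rmse": rmse(e, truth),
                        "cr": cr,
                    }
                )
    return pd.DataFrame(rows)


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of RMSE / CR per (scheme, method) across seeds."""
    return (
        table.groupby(["scheme", "method"])[["rmse", "cr"]]
        .agg(["mean", "std"])
        .reset_index()
    )
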