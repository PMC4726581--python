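"""Stage orchestration: simulate -> variography -> soft data -> maps -> validation.

``run_pipeline`` executes the requested stages in dependency order, writing all
artifacts (CSV tables, .asc rasters, JSON summaries) under the configured
output directory with deterministic formatting, so identical configurations
and seeds yield byte-identical files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as sio
from .bme import GeneralKnowledge, bme_map
from .config import PipelineConfig
from .grids import GridSpec
from .kriging import ordinary_kriging
from .simulate import (
    FieldModel,
    hard_samples_from_field,
    sample_scheme,
    simulate_flux_from_temperature,
    simulate_gaussian_field,
)
from .softdata import fit_arrhenius, make_soft_data
from .validation import (
    ComparisonConfig,
    compare_methods,
    sampling_density_experiment,
    summarize_experiment,
)
from .variogram import (
    PointSamples,
    VariogramModel,
    empirical_variogram,
    fit_variogram_model,
    nugget_sill_ratio,
)

log = logging.getLogger("soilbme.pipeline")

STAGES = ("simulate", "variogram", "softdata", "krige", "bme", "validate", "experiment")
_DEPS = {
    "variogram": ("simulate",),
    "softdata": ("simulate",),
    "krige": ("simulate", "variogram"),
    "bme": ("simulate", "variogram", "softdata"),
    "validate": ("simulate",),
    "experiment": (),
}


def _grid_spec(block) -> GridSpec:
    return GridSpec(block.origin_x, block.origin_y, block.n_x, block.n_y, block.spacing)


def _field_model(mean: float, block) -> FieldModel:
    return FieldModel(
        mean,
        VariogramModel(block.kind, block.nugget, block.sill - block.nugget, block.range),
    )


def _model_json(model: VariogramModel) -> dict:
    ratio, cls = nugget_sill_ratio(model)
    return {
        "kind": model.kind,
        "nugget": round(model.nugget, 6),
        "sill": round(model.sill, 6),
        "nugget_sill_ratio": round(ratio, 6),
        "dependence": cls,
        "range": round(model.range_, 6),
        "r2": round(model.fit_r2, 6) if np.isfinite(model.fit_r2) else None,
    }


def run_pipeline(
    config: PipelineConfig, stages=None, dry_run: bool = False
) -> int:
    """Run the requested ``stages`` (default: all but ``experiment``).

    Returns 0 on success; raises on configuration or data errors.  With
    ``dry_run`` the execution plan is logged and nothing is computed.
    """
    stages = list(stages) if stages is not None else [s for s in STAGES if s != "experiment"]
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; stages are {STAGES}")
    outdir = Path(config.outdir)
    if dry_run:
        log.info("plan: %s -> artifacts under %s", " -> ".join(stages), outdir)
        return 0
    outdir.mkdir(parents=True, exist_ok=True)
    done: set[str] = set()
    artifacts: dict[str, object] = {}
    for stage in stages:
        missing = [d for d in _DEPS.get(stage, ()) if d not in done and d not in stages]
        for dep in _DEPS.get(stage, ()):
            if dep not in done:
                if dep in stages:
                    raise ValueError(f"stage {stage!r} listed before its dependency {dep!r}")
                raise ValueError(f"stage {stage!r} requires stage {dep!r} to run first")
        t0 = time.perf_counter()
        _run_stage(stage, config, outdir, artifacts)
        done.add(stage)
        log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
    return 0


def _run_stage(stage: str, config: PipelineConfig, outdir: Path, art: dict) -> None:
    sim = config.simulate
    if stage == "simulate":
        ss = np.random.SeedSequence(config.seed)
        s_temp, s_res = [int(s) for s in ss.generate_state(2) >> 1]
        temp = simulate_gaussian_field(_grid_spec(sim.grid), _field_model(sim.mean, sim.variogram), s_temp)
        flux, n_neg = simulate_flux_from_temperature(
            temp,
            sim.link.a,
            sim.link.b,
            _field_model(0.0, sim.residual),
            s_res,
            clip_negative=sim.clip_negative,
        )
        hard_grid = _grid_spec(sim.hard_grid)
        hard = hard_samples_from_field(flux, sample_scheme(hard_grid, 49))
        sio.write_ascii_grid(outdir / "temperature.asc", temp)
        sio.write_ascii_grid(outdir / "flux.asc", flux)
        sio.write_point_csv(outdir / "hard.csv", hard)
        art.update(temp=temp, flux=flux, hard=hard, hard_grid=hard_grid)
        log.info("simulated fields (%d negative flux nodes)", n_neg)
    elif stage == "variogram":
        hard: PointSamples = art["hard"]
        emp = empirical_variogram(hard, config.variogram.lag_width)
        model = fit_variogram_model(emp, config.variogram.kind)
        used = emp.nonempty()
        with open(outdir / "variogram.csv", "w") as fh:
            fh.write("lag,gamma,npairs\n")
            for l, g, n in zip(used.lag_centers, used.semivariances, used.pair_counts):
                fh.write(f"{l:.6g},{g:.6g},{n}\n")
        (outdir / "variogram_model.json").write_text(json.dumps(_model_json(model), indent=2))
        art["flux_model"] = model
    elif stage == "softdata":
        hard, temp = art["hard"], art["temp"]
        temps_at_hard = [temp.value_at(x, y) for x, y in hard.locations]
        fit = fit_arrhenius(
            temps_at_hard, hard.values, t_crit_override=config.softdata.t_crit_override
        )
        soft = make_soft_data(
            fit, temp, exclude=hard.locations, lower_trunc=config.softdata.lower_trunc
        )
        with open(outdir / "soft.csv", "w") as fh:
            fh.write("x,y,center,scale,df,lower_trunc\n")
            for s in soft:
                fh.write(
                    f"{s.location[0]:.6g},{s.location[1]:.6g},{s.center:.6g},"
                    f"{s.scale:.6g},{s.df},{s.lower_trunc:.6g}\n"
                )
        summary = {
            "a": round(fit.a, 6),
            "b": round(fit.b, 6),
            "n": fit.n,
            "CR": round(fit.CR, 6),
            "S_TP": round(fit.S_TP, 6),
            "S_TT": round(fit.S_TT, 6),
            "T_bar": round(fit.T_bar, 6),
            "t_crit": round(fit.t_crit, 6),
        }
        (outdir / "arrhenius_fit.json").write_text(json.dumps(summary, indent=2))
        art.update(fit=fit, soft=soft)
    elif stage == "krige":
        hard, model = art["hard"], art["flux_model"]
        grid: GridSpec = art["hard_grid"]
        res = ordinary_kriging(
            hard, model, grid.node_coordinates(), n_neighbors=config.krige.n_neighbors
        )
        est = np.array([r.estimate for r in res]).reshape(grid.n_y, grid.n_x)
        var = np.array([r.kriging_variance for r in res]).reshape(grid.n_y, grid.n_x)
        sio.write_ascii_grid(outdir / "ok_estimate.asc", type(art["flux"])(grid, est))
        sio.write_ascii_grid(outdir / "ok_variance.asc", type(art["flux"])(grid, var))
    elif stage == "bme":
        hard, soft, model = art["hard"], art["soft"], art["flux_model"]
        grid: GridSpec = art["hard_grid"]
        gk = GeneralKnowledge(float(np.mean(hard.values)), model)
        est, sd = bme_map(
            hard,
            soft,
            gk,
            grid,
            n_hard_neighbors=config.bme.n_hard_neighbors,
            n_soft_neighbors=config.bme.n_soft_neighbors,
            estimator=config.bme.estimator,
        )
        sio.write_ascii_grid(outdir / "bme_estimate.asc", est)
        sio.write_ascii_grid(outdir / "bme_sd.asc", sd)
    elif stage == "validate":
        hard, temp = art["hard"], art["temp"]
        cfg = ComparisonConfig(
            n_holdout=config.validate_.n_holdout,
            methods=tuple(config.validate_.methods),
            n_neighbors=config.krige.n_neighbors,
            n_soft_neighbors=config.bme.n_soft_neighbors,
        )
        reports = compare_methods(hard, temp, cfg, seed=config.seed)
        with open(outdir / "validation.csv", "w") as fh:
            fh.write("method,rmse,bias,cr,seed\n")
            for r in reports:
                fh.write(f"{r.method},{r.rmse:.6g},{r.bias:.6g},{r.cr:.6g},{config.seed}\n")
    elif stage == "experiment":
        table = sampling_density_experiment(
            schemes=tuple(config.experiment.schemes),
            seeds=range(config.seed, config.seed + config.experiment.reps),
        )
        table.to_csv(outdir / "experiment.csv", index=False, float_format="%.6g")
        summary = summarize_experiment(table)
        summary.to_csv(outdir / "experiment_summary.csv", float_format="%.6g")
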