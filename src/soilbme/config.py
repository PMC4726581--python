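"""Validated pipeline configuration (YAML-loadable, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridBlock(_Strict):
    origin_x: float = 0.5
    origin_y: float = 0.5
    n_x: int = Field(35, ge=1)
    n_y: int = Field(35, ge=1)
    spacing: float = Field(1.0, gt=0)


class VariogramBlock(_Strict):
    kind: Literal["gaussian", "spherical"] = "gaussian"
    nugget: float = Field(0.01, ge=0)
    sill: float = Field(0.16, gt=0)  # total sill C0 + C
    range: float = Field(20.0, gt=0)


class LinkBlock(_Strict):
    a: float = 0.1331
    b: float = 0.1370


class SimulateBlock(_Strict):
    grid: GridBlock = GridBlock()
    hard_grid: GridBlock = GridBlock(origin_x=2.5, origin_y=2.5, n_x=7, n_y=7, spacing=5.0)
    mean: float = 27.18
    variogram: VariogramBlock = VariogramBlock()
    link: LinkBlock = LinkBlock()
    residual: VariogramBlock = VariogramBlock(kind="spherical", nugget=0.02, sill=0.17, range=15.0)
    clip_negative: bool = False


class VariogramStage(_Strict):
    lag_width: float = Field(5.0, gt=0)
    kind: Literal["gaussian", "spherical"] = "gaussian"


class SoftdataBlock(_Strict):
    t_crit_override: float | None = None
    lower_trunc: float = 0.0


class KrigeBlock(_Strict):
    n_neighbors: int = Field(16, ge=1)


class BMEBlock(_Strict):
    n_hard_neighbors: int = Field(16, ge=1)
    n_soft_neighbors: int = Field(3, ge=0, le=4)
    estimator: Literal["mean", "mode"] = "mean"


class ValidateBlock(_Strict):
    n_holdout: int = Field(5, ge=0)
    methods: tuple[Literal["OK", "Co-OK", "BME"], ...] = ("OK", "Co-OK", "BME")


class ExperimentBlock(_Strict):
    schemes: tuple[int, ...] = (9, 21, 37, 49)
    reps: int = Field(30, ge=1)


class PipelineConfig(_Strict):
    """All pipeline knobs; every numeric field is range-checked on load."""

    seed: int = 0
    outdir: str = "out"
    simulate: SimulateBlock = SimulateBlock()
    variogram: VariogramStage = VariogramStage()
    softdata: SoftdataBlock = SoftdataBlock()
    krige: KrigeBlock = KrigeBlock()
    bme: BMEBlock = BMEBlock()
    validate_: ValidateBlock = Field(default=ValidateBlock(), alias="validate")
    experiment: ExperimentBlock = ExperimentBlock()

    model_config = ConfigDict(extra="forbid", populate_by_name=True)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
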