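"""Plain-text file formats: point-sample CSV and ESRI ASCII grids.

Point samples travel as CSV with header ``x,y,value``; rasters as ESRI ASCII
grid (.asc: ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value header, then
the value matrix north-to-south).  Coordinates are plain metres under the
0-based cell-centre convention of :class:`~soilbme.grids.GridSpec`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridField, GridSpec
from .variogram import PointSamples

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


def read_point_csv(path) -> PointSamples:
    """Read ``x,y,value`` samples; malformed rows fail with their line number."""
    df = pd.read_csv(path)
    expected = ["x", "y", "value"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(df.columns)}")
    for col in expected:
        bad = pd.to_numeric(df[col], errors="coerce").isna() | ~np.isfinite(
            pd.to_numeric(df[col], errors="coerce")
        )
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
    return PointSamples(df[["x", "y"]].to_numpy(float), df["value"].to_numpy(float))


def write_point_csv(path, samples: PointSamples) -> None:
    df = pd.DataFrame(
        {"x": samples.locations[:, 0], "y": samples.locations[:, 1], "value": samples.values}
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_ascii_grid(path, field: GridField, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid; rows run north to south in the file."""
    spec = field.spec
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_x}\n")
        fh.write(f"nrows {spec.n_y}\n")
        fh.write(f"xllcorner {spec.origin_x - spec.spacing / 2:.6g}\n")
        fh.write(f"yllcorner {spec.origin_y - spec.spacing / 2:.6g}\n")
        fh.write(f"cellsize {spec.spacing:.6g}\n")
        fh.write(f"NODATA_value {nodata:.6g}\n")
        for row in field.values[::-1]:  # north first
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[GridField, float]:
    """Read an ESRI ASCII grid; returns (field, nodata value)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2:
                raise ValueError(f"{path}: malformed header line {line}")
            header[line[0]] = float(line[1])
        for key in _HEADER_KEYS:
            if key not in header:
                raise ValueError(f"{path}: missing header key {key!r}")
        values = np.loadtxt(fh, ndmin=2)
    n_x, n_y = int(header["ncols"]), int(header["nrows"])
    spacing = header["cellsize"]
    spec = GridSpec(
        header["xllcorner"] + spacing / 2,
        header["yllcorner"] + spacing / 2,
        n_x,
        n_y,
        spacing,
    )
    if values.shape != (n_y, n_x):
        raise ValueError(f"{path}: body shape {values.shape} disagrees with header")
    return GridField(spec, values[::-1]), header["NODATA_value"]
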