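"""Regular-grid containers used throughout the package.

Coordinates follow a cell-centre convention: node (i, j) of a grid sits at
``(origin_x + i * spacing, origin_y + j * spacing)`` with 0-based indices,
x increasing eastward and y northward.  Field values are stored as an
``(n_y, n_x)`` matrix whose row ``j`` is the j-th row *from the south*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular 2-D grid (metres)."""

    origin_x: float
    origin_y: float
    n_x: int
    n_y: int
    spacing: float

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError(f"grid must have at least one node per axis, got {self.n_x}x{self.n_y}")
        if not self.spacing > 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def n_nodes(self) -> int:
        return self.n_x * self.n_y

    def x_coords(self) -> np.ndarray:
        return self.origin_x + self.spacing * np.arange(self.n_x)

    def y_coords(self) -> np.ndarray:
        return self.origin_y + self.spacing * np.arange(self.n_y)

    def node_coordinates(self) -> np.ndarray:
        """All node (x, y) pairs, shape (n_nodes, 2), row-major over (j, i)."""
        xx, yy = np.meshgrid(self.x_coords(), self.y_coords())
        return np.column_stack([xx.ravel(), yy.ravel()])

    def index_of(self, x: float, y: float, atol: float = 1e-9) -> tuple[int, int]:
        """Return (i, j) of the node at (x, y); raise if not a grid node."""
        fi = (x - self.origin_x) / self.spacing
        fj = (y - self.origin_y) / self.spacing
        i, j = round(fi), round(fj)
        if abs(fi - i) > atol or abs(fj - j) > atol or not (0 <= i < self.n_x and 0 <= j < self.n_y):
            raise KeyError(f"({x}, {y}) is not a node of {self}")
        return i, j


@dataclass
class GridField:
    """A raster of one attribute on a :class:`GridSpec`."""

    spec: GridSpec
    values: np.ndarray  # (n_y, n_x)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_y, self.spec.n_x):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_y}, {self.spec.n_x})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid field contains non-finite values")

    def value_at(self, x: float, y: float) -> float:
        i, j = self.spec.index_of(x, y)
        return float(self.values[j, i])

    def flat_values(self) -> np.ndarray:
        """Values in the same row-major (j, i) order as ``spec.node_coordinates``."""
        return self.values.ravel()
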