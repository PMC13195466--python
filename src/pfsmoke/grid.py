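"""Rectangular model-grid geometry.

The concentration fields, burn records and monitor sites all live on a
regular row/column grid of square cells (12 km cells by default, matching
the resolution commonly used for regional chemical-transport modelling).
Cell centres carry planar coordinates in km; no map projection is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["GridDefinition"]


@dataclass(frozen=True)
class GridDefinition:
    """Geometry of a regular rectangular grid of square cells.

    Parameters
    ----------
    n_rows, n_cols:
        Grid shape; both must be >= 1.
    cell_size_km:
        Edge length of each (square) cell in km.
    origin:
        Planar (x, y) coordinate, in km, of the lower-left corner of cell
        (row=0, col=0). Rows increase with y, columns with x.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 12.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if self.cell_size_km <= 0:
            raise ConfigurationError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        """Area of one cell in km^2 (cells are square)."""
        return self.cell_size_km**2

    def contains(self, row: np.ndarray | int, col: np.ndarray | int) -> np.ndarray | bool:
        r = np.asarray(row)
        c = np.asarray(col)
        ok = (r >= 0) & (r < self.n_rows) & (c >= 0) & (c < self.n_cols)
        return bool(ok) if ok.ndim == 0 else ok

    def validate_cells(self, row, col, what: str = "cell") -> None:
        ok = self.contains(row, col)
        if not np.all(ok):
            raise ConfigurationError(f"{what} index off the {self.n_rows}x{self.n_cols} grid")

    def cell_centers_km(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates in km, each shaped (n_rows, n_cols)."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size_km
        rows = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size_km
        xx, yy = np.meshgrid(cols, rows)
        return xx, yy

    def cell_center_km(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size_km,
            y0 + (row + 0.5) * self.cell_size_km,
        )

    def extent_km(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid in km."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size_km,
            y0 + self.n_rows * self.cell_size_km,
        )
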