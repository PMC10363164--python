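"""Analysis-grid geometry.

The mapping unit everywhere in this package is a 0.009° x 0.009° cell
(~1 km² near the equator) on a regular WGS84 lon/lat grid.  Registration
convention: cell (row, col) spans the half-open interval
``[origin_lon + col*s, origin_lon + (col+1)*s)`` in longitude and descends
from the north edge in latitude, so row 0 is the northernmost row and the
grid is "north-up" like a raster.  Centroids sit at cell midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_CELL_SIZE_DEG = 0.009


@dataclass(frozen=True)
class Grid:
    """Regular WGS84 lon/lat analysis grid (north-up, half-open cells)."""

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float  # latitude of the NORTH edge
    cell_size_deg: float = DEFAULT_CELL_SIZE_DEG

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid_shape must be positive")
        if self.cell_size_deg <= 0:
            raise ValueError("cell_size_deg must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_id(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, cell_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def centroid(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = self.cell_size_deg
        lon = self.origin_lon + (np.asarray(col) + 0.5) * s
        lat = self.origin_lat - (np.asarray(row) + 0.5) * s
        return lon, lat

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of one cell."""
        s = self.cell_size_deg
        min_lon = self.origin_lon + col * s
        max_lat = self.origin_lat - row * s
        return (min_lon, max_lat - s, min_lon + s, max_lat)

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col); cells are half-open so boundaries are
        assigned to the cell east/south of the edge."""
        s = self.cell_size_deg
        col = np.floor((np.asarray(lon, dtype=float) - self.origin_lon) / s).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat, dtype=float)) / s).astype(int)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def all_cells_frame(self):
        """Flat table of every cell: cell_id, row, col, centroid_lon/lat."""
        import pandas as pd

        row, col = np.divmod(np.arange(self.n_cells), self.n_cols)
        lon, lat = self.centroid(row, col)
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "row": row,
                "col": col,
                "centroid_lon": lon,
                "centroid_lat": lat,
            }
        )
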