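"""Electrode-array geometry.

The recordings this package targets come from a 120-electrode
multi-electrode array (MEA) laid out as a 12x10 grid with 1.0 mm vertical
and 1.5 mm horizontal pitch.  Electrodes are indexed row-major: electrode
``i`` sits at ``(row, col) = divmod(i, cols)``, physical position
``(x, y) = (col * dx_mm, row * dy_mm)`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Physical layout of the recording electrodes.

    Attributes
    ----------
    rows, cols : int
        Grid dimensions (12 x 10 for the standard array).
    dy_mm, dx_mm : float
        Vertical and horizontal pitch in millimetres.
    coords : ndarray, shape (n_electrodes, 2)
        Per-electrode (x, y) position in mm, row-major electrode order.
    """

    rows: int
    cols: int
    dy_mm: float
    dx_mm: float
    coords: np.ndarray = field(repr=False)

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    def index_to_rowcol(self, index: int) -> tuple[int, int]:
        return divmod(int(index), self.cols)

    def rowcol_to_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"(row={row}, col={col}) outside {self.rows}x{self.cols} grid")
        return row * self.cols + col

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in mm."""
        return (0.0, (self.cols - 1) * self.dx_mm, 0.0, (self.rows - 1) * self.dy_mm)


def make_geometry(rows: int = 12, cols: int = 10,
                  dy_mm: float = 1.0, dx_mm: float = 1.5) -> ElectrodeGeometry:
    """Build a regular-grid electrode geometry.

    Parameters follow the standard 120-electrode array: 12 rows spaced
    1 mm apart and 10 columns spaced 1.5 mm apart.

    Raises
    ------
    ValueError
        If grid dimensions are < 1 or pitches are not positive.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {rows}x{cols}")
    if dy_mm <= 0 or dx_mm <= 0:
        raise ValueError(f"electrode pitches must be positive, got dy={dy_mm}, dx={dx_mm}")
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    coords = np.column_stack([cc * dx_mm, rr * dy_mm]).astype(float)
    coords.setflags(write=False)
    return ElectrodeGeometry(rows=rows, cols=cols, dy_mm=dy_mm, dx_mm=dx_mm, coords=coords)
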