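"""Two-compartment CPP arena geometry and spatial binning.

The apparatus is two square compartments joined side by side along the
midline, connected through a door opening centred on the joint wall. All
coordinates are in cm with the origin at the south-west corner of the left
compartment; x increases eastward (toward the right compartment), y
northward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LEFT = "left"
RIGHT = "right"

DEFAULT_BIN_CM = 1.8


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the two-compartment CPP box.

    Parameters
    ----------
    compartment_w, compartment_h : float
        Width and height of each compartment, cm.
    door_width : float
        Width of the opening in the midline wall, cm.
    """

    compartment_w: float = 25.0
    compartment_h: float = 25.0
    door_width: float = 6.5

    def __post_init__(self) -> None:
        if self.door_width >= min(self.compartment_w, self.compartment_h):
            raise ValueError("door_width must be smaller than the compartment side")
        if self.compartment_w <= 0 or self.compartment_h <= 0:
            raise ValueError("compartment dimensions must be positive")

    @property
    def width(self) -> float:
        """Total east-west extent (both compartments), cm."""
        return 2.0 * self.compartment_w

    @property
    def height(self) -> float:
        return self.compartment_h

    @property
    def midline_x(self) -> float:
        return self.compartment_w

    @property
    def door_lo(self) -> float:
        return self.compartment_h / 2.0 - self.door_width / 2.0

    @property
    def door_hi(self) -> float:
        return self.compartment_h / 2.0 + self.door_width / 2.0

    def compartment_of(self, x: np.ndarray) -> np.ndarray:
        """Label each x coordinate 'left' or 'right' by midline position."""
        return np.where(np.asarray(x) < self.midline_x, LEFT, RIGHT)

    def in_door(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        return (y >= self.door_lo) & (y <= self.door_hi)

    # ---- binning -----------------------------------------------------

    def n_bins(self, bin_cm: float = DEFAULT_BIN_CM) -> tuple[int, int]:
        """(nx, ny) count of half-open bins covering the arena."""
        nx = int(np.ceil(self.width / bin_cm))
        ny = int(np.ceil(self.height / bin_cm))
        return nx, ny

    def bin_edges(self, bin_cm: float = DEFAULT_BIN_CM) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.n_bins(bin_cm)
        return (np.arange(nx + 1) * bin_cm, np.arange(ny + 1) * bin_cm)

    def bin_index(
        self, x: np.ndarray, y: np.ndarray, bin_cm: float = DEFAULT_BIN_CM
    ) -> np.ndarray:
        """Flat bin index (row-major over (ix, iy)) for each position.

        Positions are clipped into the arena so boundary samples fall in the
        last bin rather than outside the grid.
        """
        nx, ny = self.n_bins(bin_cm)
        ix = np.clip((np.asarray(x) / bin_cm).astype(int), 0, nx - 1)
        iy = np.clip((np.asarray(y) / bin_cm).astype(int), 0, ny - 1)
        return ix * ny + iy

    def bin_centers(self, bin_cm: float = DEFAULT_BIN_CM) -> np.ndarray:
        """(n_bins, 2) array of (x, y) bin centre coordinates, flat order."""
        nx, ny = self.n_bins(bin_cm)
        cx = (np.arange(nx) + 0.5) * bin_cm
        cy = (np.arange(ny) + 0.5) * bin_cm
        xx, yy = np.meshgrid(cx, cy, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])
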