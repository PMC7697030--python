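"""Regular-grid geometry for the simulation domain.

The study domain is a rectangular strip of beach discretised into square
cells, with one node per cell centre.  Coordinates are metric and local:
``x`` runs cross-shore (toward the ocean at low ``x`` in the study setting)
and ``y`` runs along-shore.  Azimuths used elsewhere in the package are
degrees clockwise from "grid north", i.e. from the +y axis, so azimuth 0 is
the along-shore direction.

Node storage order is x-fastest (GSLIB scan order): node ``k`` sits at
``ix = k % nx``, ``iy = k // nx``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """A regular 2-D grid with nodes at cell centres.

    Defaults describe the 50 m x 150 m study strip at 1 m resolution
    (7500 nodes).
    """

    nx: int = 50
    ny: int = 150
    cell: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")
        if not self.cell > 0:
            raise ValueError("cell size must be positive")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def area(self) -> float:
        """Total grid area in m^2."""
        return self.n_nodes * self.cell**2

    @property
    def cell_area(self) -> float:
        return self.cell**2

    def node_coords(self) -> np.ndarray:
        """(n_nodes, 2) cell-centre coordinates in x-fastest scan order."""
        ix = np.arange(self.nx)
        iy = np.arange(self.ny)
        x = self.origin[0] + (ix + 0.5) * self.cell
        y = self.origin[1] + (iy + 0.5) * self.cell
        xx, yy = np.meshgrid(x, y)  # shape (ny, nx)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def node_index(self, xy) -> np.ndarray:
        """Indices of the nodes nearest to the given points (snapping)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ix = np.clip(
            np.floor((xy[:, 0] - self.origin[0]) / self.cell).astype(int), 0, self.nx - 1
        )
        iy = np.clip(
            np.floor((xy[:, 1] - self.origin[1]) / self.cell).astype(int), 0, self.ny - 1
        )
        return iy * self.nx + ix

    def snap(self, xy) -> np.ndarray:
        """Coordinates of the nearest cell centres."""
        return self.node_coords()[self.node_index(xy)]

    def contains(self, xy) -> np.ndarray:
        """Boolean mask of points lying within the outer cell edges."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x0, y0 = self.origin
        return (
            (xy[:, 0] >= x0)
            & (xy[:, 0] <= x0 + self.nx * self.cell)
            & (xy[:, 1] >= y0)
            & (xy[:, 1] <= y0 + self.ny * self.cell)
        )

    def to_image(self, values) -> np.ndarray:
        """Reshape a flat node vector to a (ny, nx) array (row = constant y)."""
        values = np.asarray(values)
        if values.shape[0] != self.n_nodes:
            raise ValueError(
                f"expected {self.n_nodes} node values, got {values.shape[0]}"
            )
        return values.reshape(self.ny, self.nx, *values.shape[1:])
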