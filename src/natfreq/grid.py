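"""Regular voxel grids with radius-based neighbourhood lookup.

Source-level analyses in this package operate on a set of voxels with
known 3-D coordinates (centimetres).  Real MEG source grids are masked to
the brain volume; here a grid is any table of voxel centres, and the only
spatial operation the pipeline needs is "all voxels within ``r`` cm of a
centre voxel", which backs both the map-smoothing stage and the voxel
contribution analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["VoxelGrid", "make_voxel_grid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A set of voxels with 3-D centre coordinates in centimetres.

    Voxel ids are the 0-based row indices of ``coords``.  ``shape`` is
    retained when the grid is a full rectangular lattice (it enables
    raster export and field smoothing); irregular grids leave it None.
    """

    coords: np.ndarray  # (V, 3) float, cm
    spacing: float = 1.0
    shape: tuple[int, int, int] | None = None
    _tree: cKDTree = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be a (V, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("voxel coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "_tree", cKDTree(coords))

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_voxels

    def neighbors(self, voxel_id: int, radius_cm: float) -> np.ndarray:
        """Ids of all voxels within ``radius_cm`` of ``voxel_id`` (inclusive).

        The centre voxel itself is always part of the result.  Ids are
        returned sorted ascending.
        """
        if not 0 <= voxel_id < self.n_voxels:
            raise IndexError(f"voxel_id {voxel_id} out of range [0, {self.n_voxels})")
        idx = self._tree.query_ball_point(self.coords[voxel_id], r=float(radius_cm))
        return np.asarray(sorted(idx), dtype=np.intp)

    def all_neighbors(self, radius_cm: float) -> list[np.ndarray]:
        """Neighbour lists for every voxel (one KD-tree pass)."""
        lists = self._tree.query_ball_point(self.coords, r=float(radius_cm))
        return [np.asarray(sorted(ix), dtype=np.intp) for ix in lists]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel_id": np.arange(self.n_voxels),
                "x_cm": self.coords[:, 0],
                "y_cm": self.coords[:, 1],
                "z_cm": self.coords[:, 2],
            }
        )


def make_voxel_grid(
    grid_shape: tuple[int, int, int], spacing_cm: float = 1.0
) -> VoxelGrid:
    """Build a full rectangular lattice of voxel centres.

    Voxels are ordered with the x index varying fastest, then y, then z,
    so ``voxel_id = ix + nx * (iy + ny * iz)``.  Coordinates start at the
    origin and advance in steps of ``spacing_cm``.
    """
    shape = tuple(int(n) for n in grid_shape)
    if len(shape) != 3 or any(n < 1 for n in shape):
        raise ValueError(f"grid_shape must be three integers >= 1, got {grid_shape}")
    if not spacing_cm > 0:
        raise ValueError("spacing_cm must be positive")
    nx, ny, nz = shape
    iz, iy, ix = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    coords = (
        np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1).astype(float)
        * spacing_cm
    )
    return VoxelGrid(coords=coords, spacing=float(spacing_cm), shape=shape)
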