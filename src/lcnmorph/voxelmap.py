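"""Spatially dependent varicosity-density voxel maps.

The axonal tree's bounding box is partitioned into cubic voxels (default
edge 100 μm), the varicosities falling in each voxel are counted, and counts
are normalized to the per-cell maximum; the normalized value doubles as the
color and opacity channel when the grid is exported for 3-D viewing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AXON, MorphologyError, Reconstruction


@dataclass
class VoxelGrid:
    """Axis-aligned voxel partition of the axonal bounding box.

    ``counts[ix, iy, iz]`` is the number of varicosities in voxel (ix,iy,iz);
    ``intensity`` is counts normalized to the grid maximum (all zeros when the
    grid is empty).  Binning uses half-open intervals
    [origin + k·edge, origin + (k+1)·edge), with points exactly on the outer
    boundary assigned to the last voxel.  ``n_outside`` counts markers that
    fell strictly outside the box (normally zero, since markers are attached
    to axon nodes within a small tolerance).
    """

    origin: np.ndarray
    edge: float
    dims: tuple[int, int, int]
    counts: np.ndarray
    n_outside: int = 0

    @property
    def intensity(self) -> np.ndarray:
        m = self.counts.max() if self.counts.size else 0
        if m <= 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / float(m)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def bin_points(
    points: np.ndarray, origin: np.ndarray, edge: float, dims: tuple[int, int, int]
) -> tuple[np.ndarray, int]:
    """Count points per voxel; returns (counts, n_outside).

    Points on an internal boundary go to the higher-index voxel (floor
    division); points exactly on the outer box boundary go to the last voxel.
    """
    counts = np.zeros(dims, dtype=int)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.size == 0:
        return counts, 0
    rel = (pts - np.asarray(origin, dtype=float)) / edge
    idx = np.floor(rel).astype(int)
    dims_arr = np.array(dims)
    # outer-boundary points belong to the last voxel
    on_outer = (idx == dims_arr) & np.isclose(rel, dims_arr)
    idx[on_outer] -= 1
    inside = np.all((idx >= 0) & (idx < dims_arr), axis=1)
    np.add.at(counts, tuple(idx[inside].T), 1)
    return counts, int((~inside).sum())


def compute_voxel_grid(recon: Reconstruction, edge: float = 100.0) -> VoxelGrid:
    """Build the varicosity-count voxel grid over the axon bounding box."""
    if edge <= 0:
        raise MorphologyError("voxel edge must be positive")
    axon_pts = recon.coords_of(AXON)
    if axon_pts.size == 0:
        raise MorphologyError("reconstruction has no axon nodes")
    origin = axon_pts.min(axis=0)
    span = axon_pts.max(axis=0) - origin
    dims = tuple(int(v) for v in np.maximum(1, np.ceil(span / edge - 1e-12)))
    markers = np.array([[v.x, v.y, v.z] for v in recon.varicosities]).reshape(-1, 3)
    counts, n_outside = bin_points(markers, origin, edge, dims)
    return VoxelGrid(origin=origin, edge=float(edge), dims=dims, counts=counts, n_outside=n_outside)


def grid_summary(grid: VoxelGrid) -> tuple[int, int, np.ndarray]:
    """(max per-voxel count, number of occupied voxels, count-weighted centroid).

    The centroid of an empty grid is reported at the grid origin.
    """
    max_count = int(grid.counts.max()) if grid.counts.size else 0
    occupied = int((grid.counts > 0).sum())
    if max_count == 0:
        return 0, 0, np.asarray(grid.origin, dtype=float)
    ix, iy, iz = np.nonzero(grid.counts)
    centers = (np.stack([ix, iy, iz], axis=1) + 0.5) * grid.edge + grid.origin
    weights = grid.counts[ix, iy, iz]
    centroid = (centers * weights[:, None]).sum(axis=0) / weights.sum()
    return max_count, occupied, centroid
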