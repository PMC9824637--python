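"""Voxelization of TLS plot clouds and stratified Plant Density Index (PDI).

A clipped plot cloud is binned into a regular grid of 0.5 x 0.5 x 0.25 m
voxels; a voxel is "vegetated" when it holds at least ``occupancy_threshold``
points (default 5, which also suppresses phase-shift ghost points).  PDI for a
height stratum is the fraction of vegetated voxels among all voxels whose base
lies in the stratum, so it is a dimensionless density in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PlotGeometry, PointCloud

#: Default understory strata (name, z_low, z_high) in metres above ground:
#: forest floor, shrubs, lower understory, upper understory, subcanopy.
DEFAULT_STRATA: tuple[tuple[str, float, float], ...] = (
    ("FF", 0.5, 1.0),
    ("Sh", 1.0, 2.0),
    ("LU", 2.0, 5.0),
    ("UU", 5.0, 10.0),
    ("Sc", 10.0, 15.5),
)

_ALIGN_TOL = 1e-9


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D count grid exactly tiling a plot box.

    ``counts[i, j, k]`` is the number of points in the half-open voxel
    ``[x_i, x_i+dx) x [y_j, y_j+dy) x [z_k, z_k+dz)`` anchored at the box's
    lower corner.
    """

    origin_x: float
    origin_y: float
    origin_z: float
    dx: float
    dy: float
    dz: float
    counts: np.ndarray  # int64, shape (nx, ny, nz)
    occupancy_threshold: int = 5

    @property
    def nx(self) -> int:
        return self.counts.shape[0]

    @property
    def ny(self) -> int:
        return self.counts.shape[1]

    @property
    def nz(self) -> int:
        return self.counts.shape[2]

    @property
    def vegetated(self) -> np.ndarray:
        """Boolean grid: voxel holds at least the occupancy threshold."""
        return self.counts >= self.occupancy_threshold

    def layer_z(self, k: int) -> float:
        """Base height of voxel layer ``k``."""
        return self.origin_z + k * self.dz


@dataclass(frozen=True)
class StrataProfile:
    """Per-stratum and per-slice PDI values for one plot."""

    plot_id: str
    strata: tuple[tuple[str, float, float], ...]
    pdi_by_stratum: dict[str, float]
    slice_pdi: tuple[tuple[float, float], ...] = ()  # (z_mid, pdi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": self.plot_id,
                "stratum": [s[0] for s in self.strata],
                "z_low": [s[1] for s in self.strata],
                "z_high": [s[2] for s in self.strata],
                "pdi": [self.pdi_by_stratum[s[0]] for s in self.strata],
            }
        )

    def slices_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": self.plot_id,
                "z_mid": [s[0] for s in self.slice_pdi],
                "pdi": [s[1] for s in self.slice_pdi],
            }
        )


def _n_cells(extent: float, step: float, what: str) -> int:
    n = extent / step
    if abs(n - round(n)) > 1e-6:
        raise ValueError(f"{what} size {step} does not evenly divide extent {extent}")
    return int(round(n))


def voxelize(
    cloud: PointCloud,
    geom: PlotGeometry,
    dx: float = 0.5,
    dy: float = 0.5,
    dz: float = 0.25,
    occupancy_threshold: int = 5,
) -> VoxelGrid:
    """Bin a clipped plot cloud into a voxel count grid.

    The grid is anchored at the box's lower corner and must tile the box
    exactly; with the defaults (27 m side, 0.5-15.5 m, 0.5/0.5/0.25 m voxels)
    it is 54 x 54 x 60.  The cloud must already be clipped to ``geom`` — every
    point is required to fall inside the box.
    """
    nx = _n_cells(geom.square_side, dx, "voxel x")
    ny = _n_cells(geom.square_side, dy, "voxel y")
    nz = _n_cells(geom.height_span, dz, "voxel z")
    x0, y0, z0 = geom.x_min, geom.y_min, geom.z_min

    i = np.floor((cloud.x - x0) / dx).astype(np.int64)
    j = np.floor((cloud.y - y0) / dy).astype(np.int64)
    k = np.floor((cloud.z - z0) / dz).astype(np.int64)
    inside = (i >= 0) & (i < nx) & (j >= 0) & (j < ny) & (k >= 0) & (k < nz)
    if not inside.all():
        raise ValueError(
            f"{int((~inside).sum())} points fall outside the plot box; "
            "clip the cloud with clip_to_plot first"
        )
    counts = np.zeros((nx, ny, nz), dtype=np.int64)
    np.add.at(counts, (i, j, k), 1)
    return VoxelGrid(x0, y0, z0, dx, dy, dz, counts, occupancy_threshold)


def _layer_range(grid: VoxelGrid, z_low: float, z_high: float) -> tuple[int, int]:
    k_low = (z_low - grid.origin_z) / grid.dz
    k_high = (z_high - grid.origin_z) / grid.dz
    if abs(k_low - round(k_low)) > 1e-6 or abs(k_high - round(k_high)) > 1e-6:
        raise ValueError(
            f"stratum bounds [{z_low}, {z_high}) are not aligned to "
            f"voxel layers of height {grid.dz}"
        )
    return int(round(k_low)), int(round(k_high))


def pdi_by_stratum(
    grid: VoxelGrid,
    strata: tuple[tuple[str, float, float], ...] = DEFAULT_STRATA,
    plot_id: str = "",
) -> StrataProfile:
    """PDI per stratum: vegetated voxels / all voxels with base in the stratum."""
    veg = grid.vegetated
    pdi: dict[str, float] = {}
    for name, z_low, z_high in strata:
        k0, k1 = _layer_range(grid, z_low, z_high)
        k0 = max(k0, 0)
        k1 = min(k1, grid.nz)
        total = grid.nx * grid.ny * (k1 - k0)
        pdi[name] = float(veg[:, :, k0:k1].sum() / total) if total else 0.0
    return StrataProfile(plot_id, tuple(strata), pdi)


def slice_profile(grid: VoxelGrid, slice_height: float = 0.5) -> list[tuple[float, float]]:
    """PDI per contiguous height slice (default 0.5 m, i.e. two voxel layers).

    Returns ``(z_mid, pdi)`` pairs spanning the grid bottom-up.
    """
    ratio = slice_height / grid.dz
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(f"slice_height {slice_height} is not a multiple of dz {grid.dz}")
    per = int(round(ratio))
    n_slices = grid.nz // per
    if n_slices * per != grid.nz:
        raise ValueError("slice_height does not evenly divide the grid height")
    veg = grid.vegetated
    out = []
    for s in range(n_slices):
        k0 = s * per
        block = veg[:, :, k0:k0 + per]
        z_mid = grid.origin_z + (s + 0.5) * slice_height
        out.append((float(z_mid), float(block.mean())))
    return out


def profiles_to_frame(profiles: list[StrataProfile]) -> pd.DataFrame:
    """Stack per-plot stratum PDI tables into one tidy frame."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
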