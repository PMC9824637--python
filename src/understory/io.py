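"""Point-cloud containers, LAS ingestion, height normalization and plot clipping.

Every downstream stage (voxelization, ALS metrics, gridded prediction) consumes
the :class:`PointCloud` produced here.  Heights are normalized with a
grid-minimum ground model: the lowest point (preferring classified ground
points where present) per horizontal cell defines a ground surface that is
bilinearly interpolated and subtracted, so ``z`` becomes height above ground.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from . import lasio

GROUND_CLASS = 2  # LAS classification code for ground returns


@dataclass(frozen=True)
class PointCloud:
    """Immutable columnar point cloud (coordinates in metres).

    After :func:`normalize_heights`, ``z`` is height above ground; small
    negative values can remain near the ground surface until clipped.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray = field(default=None)  # type: ignore[assignment]
    classification: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=np.float64))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=np.float64))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=np.float64))
        n = self.x.size
        rn = self.return_number
        cl = self.classification
        rn = np.ones(n, dtype=np.int64) if rn is None else np.asarray(rn, dtype=np.int64)
        cl = np.ones(n, dtype=np.int64) if cl is None else np.asarray(cl, dtype=np.int64)
        object.__setattr__(self, "return_number", rn)
        object.__setattr__(self, "classification", cl)
        if not (self.y.size == self.z.size == rn.size == cl.size == n):
            raise ValueError("all point attribute arrays must have the same length")

    @property
    def n_points(self) -> int:
        return self.x.size

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.x[mask], self.y[mask], self.z[mask],
                          self.return_number[mask], self.classification[mask])

    def first_returns(self) -> "PointCloud":
        return self.select(self.return_number == 1)


@dataclass(frozen=True)
class PlotGeometry:
    """Axis-aligned analysis box for one field plot.

    The box is a ``square_side`` square centred on the plot centre, spanning
    heights ``[z_min, z_max)``.  ``plot_radius`` is the circular field-plot
    radius, kept only for linking with field tree records.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    square_side: float = 27.0
    z_min: float = 0.5
    z_max: float = 15.5
    plot_radius: float = 15.0

    def __post_init__(self) -> None:
        if self.square_side <= 0:
            raise ValueError("square_side must be positive")
        if not (self.z_max > self.z_min >= 0):
            raise ValueError("need z_max > z_min >= 0")

    @property
    def x_min(self) -> float:
        return self.center_x - self.square_side / 2.0

    @property
    def y_min(self) -> float:
        return self.center_y - self.square_side / 2.0

    @property
    def height_span(self) -> float:
        return self.z_max - self.z_min


def read_point_cloud(path: str | Path, first_returns_only: bool = False) -> PointCloud:
    """Read a LAS file into a :class:`PointCloud`.

    With ``first_returns_only`` only points whose return number is 1 are kept
    (the convention for all ALS processing here).  An empty file yields an
    empty cloud rather than an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"point cloud file not found: {path}")
    try:
        cols = lasio.read_las(path)
    except lasio.LasFormatError:
        raise
    except Exception as exc:  # unreadable/corrupt container
        raise lasio.LasFormatError(f"could not read {path}: {exc}") from exc
    cloud = PointCloud(cols["x"], cols["y"], cols["z"],
                       cols["return_number"], cols["classification"])
    return cloud.first_returns() if first_returns_only else cloud


def write_point_cloud(path: str | Path, cloud: PointCloud) -> None:
    """Write a cloud as LAS 1.2 (coordinates quantized to 1 mm)."""
    lasio.write_las(path, cloud.x, cloud.y, cloud.z,
                    cloud.return_number, cloud.classification)


def normalize_heights(cloud: PointCloud, ground_resolution: float = 1.0) -> PointCloud:
    """Convert elevations to heights above ground.

    A ground elevation model is built on a square grid of ``ground_resolution``
    cells: within each cell the lowest point is taken (restricted to
    classified ground points when any are present in the cloud), empty cells
    are filled from their nearest populated neighbour, and the resulting
    surface is bilinearly interpolated at each point's x/y before being
    subtracted from ``z``.  x/y and point count are preserved exactly.
    """
    if cloud.n_points < 3:
        raise ValueError("need at least 3 points to estimate a ground surface")
    if ground_resolution <= 0:
        raise ValueError("ground_resolution must be positive")

    has_ground_class = bool(np.any(cloud.classification == GROUND_CLASS))
    gx = cloud.x[cloud.classification == GROUND_CLASS] if has_ground_class else cloud.x
    gy = cloud.y[cloud.classification == GROUND_CLASS] if has_ground_class else cloud.y
    gz = cloud.z[cloud.classification == GROUND_CLASS] if has_ground_class else cloud.z

    x0 = cloud.x.min()
    y0 = cloud.y.min()
    nx = max(int(np.ceil((cloud.x.max() - x0) / ground_resolution)), 1)
    ny = max(int(np.ceil((cloud.y.max() - y0) / ground_resolution)), 1)
    ci = np.clip(((gx - x0) / ground_resolution).astype(np.int64), 0, nx - 1)
    cj = np.clip(((gy - y0) / ground_resolution).astype(np.int64), 0, ny - 1)

    surf = np.full((nx, ny), np.inf)
    np.minimum.at(surf, (ci, cj), gz)
    empty = ~np.isfinite(surf)
    if empty.all():
        raise ValueError("no points available for ground estimation")
    if empty.any():
        # fill holes from the nearest populated cell
        idx = ndimage.distance_transform_edt(empty, return_distances=False,
                                             return_indices=True)
        surf = surf[tuple(idx)]

    xc = x0 + (np.arange(nx) + 0.5) * ground_resolution
    yc = y0 + (np.arange(ny) + 0.5) * ground_resolution
    if nx == 1 or ny == 1:
        ground = surf[np.clip(((cloud.x - x0) / ground_resolution).astype(np.int64), 0, nx - 1),
                      np.clip(((cloud.y - y0) / ground_resolution).astype(np.int64), 0, ny - 1)]
    else:
        interp = RegularGridInterpolator((xc, yc), surf, method="linear",
                                         bounds_error=False, fill_value=None)
        ground = interp(np.column_stack([cloud.x, cloud.y]))
    return replace(cloud, z=cloud.z - ground)


def clip_to_plot(cloud: PointCloud, geom: PlotGeometry) -> PointCloud:
    """Clip a normalized cloud to the plot box.

    Horizontal bounds are open (strictly inside the square); the height
    interval is half-open, ``z_min <= z < z_max``, so the lower clipping plane
    is included and the upper one excluded — no point can be counted in two
    stacked boxes.
    """
    half = geom.square_side / 2.0
    mask = (
        (np.abs(cloud.x - geom.center_x) < half)
        & (np.abs(cloud.y - geom.center_y) < half)
        & (cloud.z >= geom.z_min)
        & (cloud.z < geom.z_max)
    )
    return cloud.select(mask)
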