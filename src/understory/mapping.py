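"""Wall-to-wall prediction: gridded ALS metrics and understory density rasters.

The full ALS coverage is tiled into square cells (default 25 m), the model's
predictor metrics are computed per cell from the prepared first-return cloud,
and a fitted plot-level model is applied to every populated cell.  Cells with
too few returns are left as NoData; predictions are clamped to [0, 1] since
PDI is a voxel fraction.

Rasters are written as ESRI ASCII grid (.asc) — a plain-text raster format any
GIS reads — plus a tidy per-cell CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PointCloud
from .metrics import MetricVector, compute_metrics
from .model import FittedModel

NODATA = -9999.0


@dataclass(frozen=True)
class PredictionRaster:
    """Per-cell predicted PDI on a regular grid.

    ``values[i, j]`` covers the half-open square
    ``[origin_x + j*s, origin_x + (j+1)*s) x [origin_y + i*s, origin_y + (i+1)*s)``
    — row index grows northward from ``origin_y``.  NoData cells hold -9999.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray  # float32, shape (n_rows, n_cols)
    layer_name: str
    crs: str = ""

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell table (cell lower-left corners, NoData rows omitted)."""
        ii, jj = np.nonzero(self.values != NODATA)
        return pd.DataFrame({
            "cell_x": self.origin_x + jj * self.cell_size,
            "cell_y": self.origin_y + ii * self.cell_size,
            self.layer_name: self.values[ii, jj].astype(float),
        })


def grid_metrics(
    cloud: PointCloud,
    cell_size: float = 25.0,
    min_points: int = 10,
) -> pd.DataFrame:
    """Per-cell ALS metric table for a prepared (capped/floored) cloud.

    The grid origin is snapped down to a multiple of ``cell_size`` so tiling
    does not depend on the cloud's exact bounding box.  Cells holding fewer
    than ``min_points`` returns are omitted.  The index is
    ``cell_<x>_<y>`` from each cell's lower-left corner; ``cell_x``/``cell_y``
    columns carry the corner coordinates.
    """
    if cloud.n_points == 0:
        return pd.DataFrame()
    j = np.floor(cloud.x / cell_size).astype(np.int64)
    i = np.floor(cloud.y / cell_size).astype(np.int64)
    order = np.lexsort((i, j))
    keys = np.stack([j[order], i[order]], axis=1)
    boundaries = np.nonzero(np.any(np.diff(keys, axis=0) != 0, axis=1))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(order)]])

    rows: list[MetricVector] = []
    xs, ys = [], []
    for s, e in zip(starts, ends):
        if e - s < min_points:
            continue
        sel = order[s:e]
        cx = float(keys[s, 0] * cell_size)
        cy = float(keys[s, 1] * cell_size)
        sub = cloud.select(sel)
        # cloud is already prepared; pass it as its own prepared version
        rows.append(compute_metrics(sub, unit_id=f"cell_{cx:.0f}_{cy:.0f}", prepared=sub))
        xs.append(cx)
        ys.append(cy)
    if not rows:
        return pd.DataFrame()
    frame = pd.DataFrame([v.to_series() for v in rows])
    frame.index.name = "unit_id"
    frame.insert(0, "cell_x", xs)
    frame.insert(1, "cell_y", ys)
    return frame


def predict_map(
    cell_metrics: pd.DataFrame,
    model: FittedModel,
    cell_size: float = 25.0,
    clamp: bool = True,
    crs: str = "",
) -> PredictionRaster:
    """Apply a fitted model to every populated cell and rasterize.

    Raster extent is the bounding box of populated cells; unpopulated cells
    inside it become NoData.  With ``clamp`` (default) predictions are limited
    to the [0, 1] PDI range.
    """
    if cell_metrics.empty:
        raise ValueError("no populated cells to predict")
    preds = model.predict(cell_metrics)
    if clamp:
        preds = preds.clip(0.0, 1.0)
    cx = cell_metrics["cell_x"].to_numpy(dtype=float)
    cy = cell_metrics["cell_y"].to_numpy(dtype=float)
    origin_x = float(cx.min())
    origin_y = float(cy.min())
    jj = np.round((cx - origin_x) / cell_size).astype(np.int64)
    ii = np.round((cy - origin_y) / cell_size).astype(np.int64)
    grid = np.full((int(ii.max()) + 1, int(jj.max()) + 1), NODATA, dtype=np.float32)
    grid[ii, jj] = preds.to_numpy(dtype=np.float32)
    return PredictionRaster(origin_x, origin_y, cell_size, grid,
                            layer_name=model.response_name, crs=crs)


def write_ascii_grid(raster: PredictionRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc); rows are emitted north-to-south."""
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin_x:.3f}\n"
        f"yllcorner {raster.origin_y:.3f}\n"
        f"cellsize {raster.cell_size:.3f}\n"
        f"NODATA_value {NODATA:.0f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in raster.values[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def rasters_to_csv(rasters: list[PredictionRaster], path: str | Path) -> pd.DataFrame:
    """Merge layer rasters on cell corners and write one tidy CSV."""
    merged: pd.DataFrame | None = None
    for r in rasters:
        frame = r.to_frame()
        merged = frame if merged is None else merged.merge(
            frame, on=["cell_x", "cell_y"], how="outer")
    assert merged is not None
    merged = merged.sort_values(["cell_y", "cell_x"]).reset_index(drop=True)
    merged.to_csv(path, index=False)
    return merged
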