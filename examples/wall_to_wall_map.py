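"""Predict understory density wall-to-wall over a 100 x 100 m scene.

Fits a UU model on simulated calibration plots, then tiles a separate scene
(whose understory density rises from west to east) into 25 m cells, computes
the model's predictor per cell and writes the prediction raster as an ESRI
ASCII grid plus a tidy CSV.  The printed correlation compares predicted and
true per-cell PDI.
"""

from pathlib import Path

import numpy as np

from understory import (compute_metrics, fit_linear_model, grid_metrics,
                        predict_map, prepare_als, sample_als, write_ascii_grid)
from understory.mapping import rasters_to_csv
from understory.metrics import metrics_to_frame
from understory.simulate import gradient_scene, linear_link_study

study = linear_link_study(n_plots=12, seed=3)
vectors = [compute_metrics(sample_als(s, region=s.plot_geometry, seed=4),
                           unit_id=pid)
           for pid, s in zip(study.truth.index, study.scenes)]
model = fit_linear_model(metrics_to_frame(vectors), study.truth["true_uu"],
                         ["HM_1_3"], "UU")

scene = gradient_scene(seed=5, extent=100.0)
cloud = sample_als(scene, pulse_density=2.0, seed=6)
cells = grid_metrics(prepare_als(cloud), cell_size=25.0)
raster = predict_map(cells, model, cell_size=25.0)

out = Path("scratch")
out.mkdir(exist_ok=True)
write_ascii_grid(raster, out / "map_UU.asc")
rasters_to_csv([raster], out / "map_cells.csv")

merged = raster.to_frame().merge(
    scene.truth_cells(25.0)[["cell_x", "cell_y", "UU"]],
    on=["cell_x", "cell_y"], suffixes=("_pred", "_true"))
r = np.corrcoef(merged["UU_pred"], merged["UU_true"])[0, 1]
print(f"{len(merged)} cells predicted; r(pred, truth) = {r:.3f}")
print(f"rasters written to {out}/map_UU.asc and {out}/map_cells.csv")
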