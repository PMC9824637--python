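# Methods

This note documents the models, conventions and numerical choices behind the
package, and what its simulated tests do and do not establish.

## Height normalization

Lidar elevations are converted to heights above ground with a grid-minimum
ground model: the lowest point per horizontal cell (default 1 m) defines a
ground sample — restricted to LAS class-2 points whenever any are present —
holes are filled from the nearest populated cell, and the surface is
bilinearly interpolated at each point before subtraction. This is a
deliberately simple, deterministic model, adequate for the gentle terrain the
pipeline assumes; on steep or heavily occluded ground a proper DTM should be
supplied instead (clouds that are already normalized pass through the rest of
the pipeline untouched). Normalization preserves point count and x/y exactly.

## Boundary conventions

All spatial binning uses half-open intervals — closed on the lower bound,
open on the upper — for plot boxes, voxels, strata, profile slices and grid
cells, so no point or voxel is ever counted twice. The one exception is the
top band of the ALS "thirds" ([2H/3, H] closed), so the maximum return
belongs to exactly one band. The voxel grid is anchored at the plot box's
lower corner; the 25 m prediction grid is snapped to multiples of the cell
size, making tilings independent of bounding-box jitter.

## Plant Density Index

A voxel (0.5 × 0.5 × 0.25 m) is vegetated when it holds ≥ 5 points; the
threshold doubles as a ghost-point filter for phase-shift scanners. Stratum
PDI divides vegetated voxels by *all* voxels of the stratum inside the
clipped box — occluded-but-empty voxels are not excluded from the
denominator, so PDI is a conservative geometric density. Profile slices
(default 0.5 m) aggregate two 0.25 m voxel layers.

## ALS metrics

Metrics are computed on first returns with a 22 m cap and 0.5 m floor. The
"maximum height" defining the thirds is the unit's own maximum after the
cap, not the cap itself. Dispersion uses the sample standard deviation
(ddof = 1); skewness and kurtosis are the biased moment estimators g1 and b2
(kurtosis non-excess, i.e. 3 for a normal), the dominant convention in lidar
metric suites. OGP is computed *before* the height floor so ground returns
remain in its denominator: with classification codes it is the fraction of
first returns not classed as ground, otherwise the fraction above 0.5 m.
Empty units yield missing metrics; single-point units yield missing
dispersion metrics; RHMEAN is missing when the maximum height is 0.

## Screening, fitting, cross-validation

Screening selects metrics with |Pearson r| > 0.7 and test p < 0.05 against
the plot PDI (absolute value, so inversely related metrics are not silently
lost); no multiplicity correction is applied, matching common practice for
this screening style. Models are OLS with intercept; reported R² is the
adjusted R² of the full-data fit. LOOCV uses the exact hat-matrix identity
(held-out residual = residual / (1 − leverage)), verified in the tests
against n explicit refits to 1e−10; RMSE and nRMSE = RMSE/(y_max − y_min)
are computed from the held-out predictions, with the range taken from the
observed response. Rank validation counts trees with DBH < 9 cm against LU
PDI and 9–20 cm against UU PDI (Spearman).

## Wall-to-wall prediction

Cells with fewer than 10 first returns (default) are left as NoData;
predictions are clamped to [0, 1] because PDI is a fraction. Rasters are
written as ESRI ASCII grid — a plain-text format any GIS ingests — plus a
tidy per-cell CSV; the raster row order is north-to-south in the file,
south-to-north in memory.

## The synthetic forest

The simulator's purpose is controlled ground truth, not photorealism. A
scene is a ground plane (optional uniform slope), canopy stems from a
Poisson process carrying ellipsoidal crowns, and understory foliage laid out
as occupied cells of the same 0.5 × 0.5 × 0.25 m lattice the analysis bins
into — so the scene's per-stratum PDI is known exactly and the requested
intensities are met to within one lattice cell. Two archetypes set the
canopy contrast that matters for airborne sensing: `beech_like` (crown
transmission 0.25 per crossing, larger crowns) and `pine_like` (0.55,
smaller crowns). Crown bases sit at/above 10 m, as in the mature stands
emulated, so crowns never intrude into the understory strata. Small
(2–5 m) and intermediate (5–10 m) trees are generated with counts
proportional to the LU/UU intensities, giving the field-validation ranks
real signal.

TLS emulation places at least 5 points (at default density) uniformly inside
every occupied cell, with a Poisson surplus thinned by height and range,
plus classified ground returns; with zero coordinate noise the voxelized PDI
therefore reproduces scene truth exactly, and the tests' tolerances
(±0.03–0.05) absorb normalization shifts and noise. ALS emulation is
top-down per pulse: each crown crossed intercepts with probability
1 − transmission; survivors are intercepted per occupied understory cell
(probability 0.35, top-down through the column, via an exact per-column CDF);
the rest return from ground. Occlusion is probabilistic per crown crossing
rather than ray-traced — enough to reproduce the beech-vs-pine penetration
contrast at desk-scale speed.

What the simulator does *not* emulate: waveform radiometry, foliage
phenology, ghost-point noise structure, scanner trajectory effects, stem
surfaces as TLS targets (trunks are represented in the field table, not the
point cloud), and co-registration error between the two instruments.
Passing tests therefore demonstrate correctness of the computation and
recoverability of a known density–structure relation under idealized
sampling; they do not certify accuracy on real scans.

## The linear-link family

Parameter-recovery tests need a known regression truth. Each linear-link
plot has a low foliage band at heights ~ Normal(h, 0.5 m) with h spread over
1.5–3.5 m across plots, and true UU PDI generated as 0.12·h + 0.02 + ε,
ε ~ N(0, 0.03). HM_1/3 of the airborne cloud measures h (canopy base 10 m
and top 15 m keep crowns above H/3 and the maximum height at ~15 m, so the
lowest third is populated by the band alone). The defaults give a
correlation of ≈ 0.93 between HM_1/3 and UU — comfortably past the 0.7
screen — and a slope standard error that makes the 95 % CI an honest
coverage test. Top-down interception biases the measured band height
slightly upward, but the bias is constant across plots and is absorbed by
the intercept, leaving the slope estimate unbiased (empirically ≈ 2 %
attenuation, well inside one standard error).

## Problem sizes

Default simulated campaigns use 24 plots of 35 × 35 m (27 m analysis box),
TLS at the default density (≈ 10⁵–10⁶ points per plot), ALS at 2 pulses/m²,
and mapping demonstrations on 100 × 100 m scenes with 16 cells of 25 m —
sizes chosen so a full calibration replicate runs in well under a second and
the complete acceptance computation in under a minute, while every stage
still operates above the regimes where its estimators degenerate.

## Known limitations

- The grid-minimum ground model biases heights slightly upward in dense
  vegetation with no ground returns per cell; supply pre-normalized clouds
  where this matters.
- Compressed LAZ is not read; decompress externally.
- Screening + OLS is the deliberate scope: no regularization, no nonlinear
  terms. Curvature in residuals (visible for dense-canopy cases) is exposed
  through the residuals field, not modeled.
- Prediction rasters carry no uncertainty layer; the LOOCV nRMSE is the
  global error summary.
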