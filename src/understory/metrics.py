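"""The 17 airborne-lidar metrics used to predict understory density.

All metrics are computed on height-normalized *first returns*.  Twelve are
height-based: mean (HMEAN), relative mean (RHMEAN = mean / max), standard
deviation (SDH), coefficient of variation (HCV), skewness (HS), kurtosis (HK),
and the mean/SD within the lower, middle and upper thirds of the height range
(HM_1_3..SD_3_3).  Five are density-based: fraction of over-ground returns
(OGP), total count (PTN), and the point proportions per third (PP_1_3..3_3).

Before metric computation the cloud is capped at 22 m and floored at 0.5 m
(:func:`prepare_als`), matching the height window over which terrestrial and
airborne views of the stand are comparable.  "Thirds" are thirds of the
prepared cloud's own maximum height H: bands [floor, H/3), [H/3, 2H/3) and
[2H/3, H] (top band closed so the highest return is counted once).

Statistical conventions: SDH and the per-band SDs are sample standard
deviations (ddof=1); HS is the moment skewness g1 and HK the non-excess
moment kurtosis b2 (both biased/moment estimators, the dominant convention in
lidar metric suites).  OGP is computed before the 0.5 m floor so that ground
returns stay in its denominator: with classification codes present it is the
fraction of first returns not classified as ground, otherwise the fraction
above 0.5 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUND_CLASS, PointCloud

#: Canonical column order for metric tables.
METRIC_NAMES = (
    "HMEAN", "RHMEAN", "SDH", "HCV", "HS", "HK",
    "HM_1_3", "HM_2_3", "HM_3_3", "SD_1_3", "SD_2_3", "SD_3_3",
    "OGP", "PTN", "PP_1_3", "PP_2_3", "PP_3_3",
)

DEFAULT_CAP = 22.0
DEFAULT_FLOOR = 0.5


@dataclass(frozen=True)
class MetricVector:
    """The 17 ALS metrics for one spatial unit (plot or grid cell).

    Metrics that cannot be computed (empty cloud; dispersion on a single
    point; RHMEAN when max height is 0) are NaN.
    """

    unit_id: str
    HMEAN: float = math.nan
    RHMEAN: float = math.nan
    SDH: float = math.nan
    HCV: float = math.nan
    HS: float = math.nan
    HK: float = math.nan
    HM_1_3: float = math.nan
    HM_2_3: float = math.nan
    HM_3_3: float = math.nan
    SD_1_3: float = math.nan
    SD_2_3: float = math.nan
    SD_3_3: float = math.nan
    OGP: float = math.nan
    PTN: float = math.nan
    PP_1_3: float = math.nan
    PP_2_3: float = math.nan
    PP_3_3: float = math.nan

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)
                          if f.name != "unit_id"}, name=self.unit_id)[list(METRIC_NAMES)]


def prepare_als(cloud: PointCloud, cap: float = DEFAULT_CAP,
                floor: float = DEFAULT_FLOOR) -> PointCloud:
    """First returns with ``floor <= z <= cap`` (normalized heights)."""
    fr = cloud.first_returns()
    return fr.select((fr.z >= floor) & (fr.z <= cap))


def _band_stats(z: np.ndarray) -> tuple[float, float]:
    if z.size == 0:
        return math.nan, math.nan
    mean = float(z.mean())
    sd = float(z.std(ddof=1)) if z.size >= 2 else math.nan
    return mean, sd


def compute_metrics(cloud: PointCloud, unit_id: str = "",
                    prepared: PointCloud | None = None,
                    cap: float = DEFAULT_CAP, floor: float = DEFAULT_FLOOR) -> MetricVector:
    """Compute all 17 metrics for one unit.

    ``cloud`` is the normalized first-return cloud *before* the height floor
    (needed for OGP's denominator); ``prepared`` is its capped/floored version
    and is derived on the fly when omitted.
    """
    fr = cloud.first_returns()
    fr = fr.select(fr.z <= cap)
    prep = prepared if prepared is not None else fr.select(fr.z >= floor)
    z = prep.z

    out: dict[str, float] = {}
    # OGP over all first returns, ground included in the denominator
    if fr.n_points > 0:
        if np.any(fr.classification == GROUND_CLASS):
            non_ground = int((fr.classification != GROUND_CLASS).sum())
        else:
            non_ground = int((fr.z > floor).sum())
        out["OGP"] = non_ground / fr.n_points
    out["PTN"] = float(z.size)
    if z.size == 0:
        return MetricVector(unit_id=unit_id, **out)

    h_max = float(z.max())
    out["HMEAN"] = float(z.mean())
    if h_max > 0:
        out["RHMEAN"] = out["HMEAN"] / h_max
    if z.size >= 2:
        out["SDH"] = float(z.std(ddof=1))
        out["HCV"] = out["SDH"] / out["HMEAN"] if out["HMEAN"] > 0 else math.nan
        if out["SDH"] > 0:  # shape moments undefined for a constant cloud
            out["HS"] = float(stats.skew(z, bias=True))
            out["HK"] = float(stats.kurtosis(z, fisher=False, bias=True))

    b1, b2 = h_max / 3.0, 2.0 * h_max / 3.0
    lower = z[z < b1]
    middle = z[(z >= b1) & (z < b2)]
    upper = z[z >= b2]
    for band, (name_m, name_s, name_p) in zip(
        (lower, middle, upper),
        (("HM_1_3", "SD_1_3", "PP_1_3"),
         ("HM_2_3", "SD_2_3", "PP_2_3"),
         ("HM_3_3", "SD_3_3", "PP_3_3")),
    ):
        mean, sd = _band_stats(band)
        out[name_m] = mean
        out[name_s] = sd
        out[name_p] = band.size / z.size
    return MetricVector(unit_id=unit_id, **out)


def metrics_to_frame(vectors: list[MetricVector]) -> pd.DataFrame:
    """Metric table indexed by unit_id, columns in canonical order."""
    frame = pd.DataFrame([v.to_series() for v in vectors])
    frame.index.name = "unit_id"
    return frame
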