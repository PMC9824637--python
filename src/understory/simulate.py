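"""Synthetic forest scenes with known understory density, sampled as lidar.

A scene is a small stand on a (possibly sloping) ground plane: canopy stems
placed by a Poisson process carry ellipsoidal crowns, and understory foliage
is laid out as clumped occupied cells of the same 0.5 x 0.5 x 0.25 m lattice
the analysis voxelizes on, so the scene's true per-stratum Plant Density
Index (PDI) is known exactly from geometry, independent of any sampled cloud.

Two stand archetypes are provided: ``beech_like`` (dense, low-transmission
canopy) and ``pine_like`` (open canopy) — the contrast that drives how well
airborne lidar sees the understory.

Sampling emulates the two instruments:

* :func:`sample_tls` — a ground-based scanner viewing from below: every
  occupied cell yields points (at least 5 at default density, so the
  vegetated-voxel rule is exercised), with distance-based thinning and
  optional coordinate noise, plus ground returns.
* :func:`sample_als` — airborne first returns generated top-down per pulse:
  each crown crossed intercepts the pulse with probability
  ``1 - transmission``; surviving pulses can be intercepted per occupied
  understory cell, and otherwise return from the ground.

The ``linear-link`` scene family builds a controlled linear relation between
lower-canopy height structure and upper-understory density: each plot gets a
low foliage band centred at a height h, and its true UU PDI is generated as
``slope * h + intercept + noise``.  The airborne metric HM_1_3 measures h, so
the full pipeline should recover the known slope — the package's stand-in for
field calibration data.

All randomness flows from integer seeds through ``numpy`` SeedSequences; the
same seed always reproduces the same scene and clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io import PlotGeometry, PointCloud
from .voxel import DEFAULT_STRATA, StrataProfile

DX = DY = 0.5
DZ = 0.25
Z0 = 0.5    # occupancy lattice spans [Z0, Z1) above ground
Z1 = 15.5

#: stand-type defaults: (canopy_base m, canopy_top m, crown radius mean m,
#: crown radius sd m, canopy transmission per crown crossing)
STAND_DEFAULTS = {
    "beech_like": (10.0, 18.0, 2.8, 0.4, 0.25),
    "pine_like": (10.5, 16.0, 2.0, 0.3, 0.55),
}

_EL_HIT_P = 0.35  # per-occupied-cell interception probability for ALS pulses


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic stand.

    Understory intensities are target vegetated-cell fractions (the stratum
    PDI the scene should have); ``ground_slope`` is a rise fraction along x.
    ``canopy_base``/``canopy_top`` default per stand type when None.
    """

    extent_x: float = 35.0
    extent_y: float = 35.0
    stand_type: Literal["beech_like", "pine_like"] = "beech_like"
    stem_density: float = 350.0  # canopy stems per hectare
    canopy_base: float | None = None
    canopy_top: float | None = None
    understory_intensity_LU: float = 0.2
    understory_intensity_UU: float = 0.2
    ground_slope: float = 0.0
    ground_elevation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stand_type not in STAND_DEFAULTS:
            raise ValueError(f"unknown stand_type {self.stand_type!r}")
        for p in (self.understory_intensity_LU, self.understory_intensity_UU):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"understory intensity {p} outside [0, 1]")
        base, top = self.resolved_canopy()
        if not top > base > 0:
            raise ValueError("need canopy_top > canopy_base > 0")

    def resolved_canopy(self) -> tuple[float, float]:
        d = STAND_DEFAULTS[self.stand_type]
        return (self.canopy_base if self.canopy_base is not None else d[0],
                self.canopy_top if self.canopy_top is not None else d[1])

    @property
    def default_transmission(self) -> float:
        return STAND_DEFAULTS[self.stand_type][4]


@dataclass
class Scene:
    """A realized stand: occupancy lattice, stems, crowns, and ground plane."""

    spec: SceneSpec
    occ_foliage: np.ndarray  # bool (nx, ny, nz): foliage + stems
    occ_crown: np.ndarray    # bool, same shape: crown interiors below Z1
    stems: pd.DataFrame      # x, y, dbh_cm, height, kind
    crowns: pd.DataFrame     # x, y, z_center, r_h, r_z
    h_center: float | None = None   # linear-link low-band centre, if any
    true_uu: float | None = None    # linear-link generated UU target, if any

    @property
    def occupancy(self) -> np.ndarray:
        return self.occ_foliage | self.occ_crown

    @property
    def plot_geometry(self) -> PlotGeometry:
        """Default 27 m analysis box centred in the scene."""
        return PlotGeometry(self.spec.extent_x / 2.0, self.spec.extent_y / 2.0)

    def ground_z(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (self.spec.ground_elevation
                + self.spec.ground_slope * (np.asarray(x) - self.spec.extent_x / 2.0))

    def _box_index(self, geom: PlotGeometry) -> tuple[slice, slice]:
        i0 = int(round(geom.x_min / DX))
        j0 = int(round(geom.y_min / DY))
        ni = int(round(geom.square_side / DX))
        nj = int(round(geom.square_side / DY))
        nx, ny = self.occ_foliage.shape[:2]
        if i0 < 0 or j0 < 0 or i0 + ni > nx or j0 + nj > ny:
            raise ValueError("plot box extends beyond the scene extent")
        return slice(i0, i0 + ni), slice(j0, j0 + nj)

    def truth_profile(self, geom: PlotGeometry | None = None,
                      strata=DEFAULT_STRATA, plot_id: str = "truth") -> StrataProfile:
        """Exact per-stratum PDI of the scene inside the plot box."""
        geom = geom or self.plot_geometry
        si, sj = self._box_index(geom)
        occ = self.occupancy[si, sj]
        pdi = {}
        for name, z_low, z_high in strata:
            k0 = int(round((z_low - Z0) / DZ))
            k1 = int(round((z_high - Z0) / DZ))
            block = occ[:, :, k0:k1]
            pdi[name] = float(block.mean()) if block.size else 0.0
        return StrataProfile(plot_id, tuple(strata), pdi)

    def truth_cells(self, cell_size: float = 25.0,
                    strata=DEFAULT_STRATA) -> pd.DataFrame:
        """Exact per-stratum PDI on a cell grid (full cells only)."""
        per = int(round(cell_size / DX))
        nx, ny = self.occupancy.shape[:2]
        rows = []
        occ = self.occupancy
        for ci in range(nx // per):
            for cj in range(ny // per):
                block = occ[ci * per:(ci + 1) * per, cj * per:(cj + 1) * per]
                row = {"cell_x": ci * cell_size, "cell_y": cj * cell_size}
                for name, z_low, z_high in strata:
                    k0 = int(round((z_low - Z0) / DZ))
                    k1 = int(round((z_high - Z0) / DZ))
                    row[name] = float(block[:, :, k0:k1].mean())
                rows.append(row)
        return pd.DataFrame(rows)


def _lattice_shape(spec: SceneSpec) -> tuple[int, int, int]:
    nx = int(round(spec.extent_x / DX))
    ny = int(round(spec.extent_y / DY))
    nz = int(round((Z1 - Z0) / DZ))
    if abs(nx * DX - spec.extent_x) > 1e-9 or abs(ny * DY - spec.extent_y) > 1e-9:
        raise ValueError("scene extent must be a multiple of 0.5 m")
    return nx, ny, nz


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *tags]))


def _place_stems(spec: SceneSpec, rng: np.random.Generator) -> pd.DataFrame:
    area_ha = spec.extent_x * spec.extent_y / 1e4
    base, top = spec.resolved_canopy()
    n_canopy = rng.poisson(spec.stem_density * area_ha)
    frames = []
    if n_canopy:
        frames.append(pd.DataFrame({
            "x": rng.uniform(0, spec.extent_x, n_canopy),
            "y": rng.uniform(0, spec.extent_y, n_canopy),
            "dbh_cm": rng.lognormal(np.log(34.0), 0.25, n_canopy),
            "height": top * rng.uniform(0.85, 1.0, n_canopy),
            "kind": "canopy",
        }))
    # small and intermediate trees track the understory intensities, so the
    # field-data rank validation has signal by construction
    n_small = rng.poisson(600.0 * spec.understory_intensity_LU * area_ha)
    if n_small:
        frames.append(pd.DataFrame({
            "x": rng.uniform(0, spec.extent_x, n_small),
            "y": rng.uniform(0, spec.extent_y, n_small),
            "dbh_cm": rng.uniform(2.0, 8.9, n_small),
            "height": rng.uniform(2.0, 5.0, n_small),
            "kind": "small",
        }))
    n_mid = rng.poisson(500.0 * spec.understory_intensity_UU * area_ha)
    if n_mid:
        frames.append(pd.DataFrame({
            "x": rng.uniform(0, spec.extent_x, n_mid),
            "y": rng.uniform(0, spec.extent_y, n_mid),
            "dbh_cm": rng.uniform(9.0, 20.0, n_mid),
            "height": rng.uniform(5.0, 10.0, n_mid),
            "kind": "intermediate",
        }))
    if not frames:
        return pd.DataFrame(columns=["x", "y", "dbh_cm", "height", "kind"])
    return pd.concat(frames, ignore_index=True)


def _make_crowns(spec: SceneSpec, stems: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    base, top = spec.resolved_canopy()
    _, _, r_mean, r_sd, _ = STAND_DEFAULTS[spec.stand_type]
    canopy = stems[stems["kind"] == "canopy"]
    n = len(canopy)
    if n == 0:
        return pd.DataFrame(columns=["x", "y", "z_center", "r_h", "r_z"])
    # crown base held at the stand's canopy base so crowns stay above the
    # understory strata, as in the mature stands being emulated
    z_base = np.full(n, base)
    z_top = np.maximum(canopy["height"].to_numpy(), base + 1.0)
    return pd.DataFrame({
        "x": canopy["x"].to_numpy(),
        "y": canopy["y"].to_numpy(),
        "z_center": (z_base + z_top) / 2.0,
        "r_h": np.maximum(rng.normal(r_mean, r_sd, n), 0.8),
        "r_z": (z_top - z_base) / 2.0,
    })


def _mark_crowns(occ: np.ndarray, crowns: pd.DataFrame) -> None:
    nx, ny, nz = occ.shape
    zc_layers = Z0 + (np.arange(nz) + 0.5) * DZ
    for row in crowns.itertuples(index=False):
        i0 = max(int((row.x - row.r_h) / DX), 0)
        i1 = min(int((row.x + row.r_h) / DX) + 1, nx)
        j0 = max(int((row.y - row.r_h) / DY), 0)
        j1 = min(int((row.y + row.r_h) / DY) + 1, ny)
        if i0 >= i1 or j0 >= j1:
            continue
        xc = (np.arange(i0, i1) + 0.5) * DX
        yc = (np.arange(j0, j1) + 0.5) * DY
        dx2 = ((xc - row.x) / row.r_h) ** 2
        dy2 = ((yc - row.y) / row.r_h) ** 2
        dz2 = ((zc_layers - row.z_center) / row.r_z) ** 2
        inside = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :] <= 1.0
        occ[i0:i1, j0:j1, :] |= inside


_STRATUM_LAYERS = {"LU": (2.0, 5.0), "UU": (5.0, 10.0)}


def _fill_stratum(occ_foliage: np.ndarray, occ_other: np.ndarray,
                  stratum: str, target_intensity: float,
                  box: tuple[slice, slice], rng: np.random.Generator) -> None:
    """Add clumped foliage so box occupancy in the stratum hits the target."""
    z_low, z_high = _STRATUM_LAYERS[stratum]
    k0 = int(round((z_low - Z0) / DZ))
    k1 = int(round((z_high - Z0) / DZ))
    si, sj = box
    existing = occ_foliage[si, sj, k0:k1] | occ_other[si, sj, k0:k1]
    n_box = existing.size
    target = int(round(target_intensity * n_box))
    have = int(existing.sum())
    if target < have:
        raise ValueError(
            f"understory intensity {target_intensity:.3f} for {stratum} is below the "
            f"occupancy already imposed by stems/crowns; feasible range is "
            f"[{have / n_box:.3f}, 1.0]"
        )
    nx, ny, nz = occ_foliage.shape
    added = np.zeros_like(occ_foliage[:, :, k0:k1])
    guard = 0
    while int((added[si, sj] | existing).sum()) - have < target - have:
        cx = rng.uniform(0, nx * DX)
        cy = rng.uniform(0, ny * DY)
        cz = rng.uniform(z_low, z_high)
        r_h, r_z = 1.5, 0.8
        i0, i1 = max(int((cx - r_h) / DX), 0), min(int((cx + r_h) / DX) + 1, nx)
        j0, j1 = max(int((cy - r_h) / DY), 0), min(int((cy + r_h) / DY) + 1, ny)
        xc = (np.arange(i0, i1) + 0.5) * DX
        yc = (np.arange(j0, j1) + 0.5) * DY
        zc = Z0 + (np.arange(k0, k1) + 0.5) * DZ
        inside = (((xc[:, None, None] - cx) / r_h) ** 2
                  + ((yc[None, :, None] - cy) / r_h) ** 2
                  + ((zc[None, None, :] - cz) / r_z) ** 2) <= 1.0
        keep = inside & (rng.random(inside.shape) < 0.6)
        added[i0:i1, j0:j1, :] |= keep
        guard += 1
        if guard > 200000:  # pragma: no cover - safety valve
            raise RuntimeError("clump filling failed to reach the target intensity")
    # trim overshoot inside the box back to the exact target
    new_in_box = added[si, sj] & ~existing
    excess = int(new_in_box.sum()) - (target - have)
    if excess > 0:
        idx = np.flatnonzero(new_in_box.ravel())
        drop = rng.choice(idx, size=excess, replace=False)
        flat = new_in_box.ravel()
        flat[drop] = False
        new_in_box = flat.reshape(new_in_box.shape)
    sub = added[si, sj]
    sub[:] = new_in_box
    occ_foliage[:, :, k0:k1] |= added


def generate_scene(spec: SceneSpec) -> Scene:
    """Build a stand whose strata occupancies match the requested intensities.

    Stems and crowns are placed first; clumped foliage then tops the LU and
    UU strata up to the requested vegetated fractions, measured over the
    central 27 m plot box (so the scene's true PDI there equals the request
    to within one lattice cell).  Intensities below what stems/crowns already
    occupy are infeasible and raise with the feasible range.
    """
    rng = _rng(spec.seed, 1)
    nx, ny, nz = _lattice_shape(spec)
    occ_foliage = np.zeros((nx, ny, nz), dtype=bool)
    occ_crown = np.zeros((nx, ny, nz), dtype=bool)

    stems = _place_stems(spec, rng)
    crowns = _make_crowns(spec, stems, rng)
    _mark_crowns(occ_crown, crowns)

    scene = Scene(spec, occ_foliage, occ_crown, stems, crowns)
    box = scene._box_index(scene.plot_geometry)
    _fill_stratum(occ_foliage, occ_crown, "LU", spec.understory_intensity_LU, box, rng)
    _fill_stratum(occ_foliage, occ_crown, "UU", spec.understory_intensity_UU, box, rng)
    return scene


# ---------------------------------------------------------------------------
# linear-link scene family


@dataclass(frozen=True)
class LinearLink:
    """Generating relation of the linear-link family: UU = slope*h + intercept + e."""

    slope: float = 0.12
    intercept: float = 0.02
    noise_sd: float = 0.03
    h_range: tuple[float, float] = (1.5, 3.5)
    low_band_intensity: float = 0.15
    low_band_sd: float = 0.5


def linear_link_scene(seed: int, h_center: float, true_uu: float,
                      link: LinearLink = LinearLink(),
                      stand_type: str = "pine_like",
                      extent: float = 35.0) -> Scene:
    """One plot of the linear-link family.

    The low foliage band (heights ~ Normal(h_center, sd), within 0.5-5 m) is
    what HM_1_3 measures; the UU stratum is filled column-wise by independent
    Bernoulli cells at rate ``true_uu`` so its realized PDI is binomially
    tight around the target.
    """
    spec = SceneSpec(extent_x=extent, extent_y=extent, stand_type=stand_type,
                     stem_density=120.0, canopy_base=10.0, canopy_top=15.0,
                     understory_intensity_LU=0.0, understory_intensity_UU=0.0,
                     seed=seed)
    rng = _rng(seed, 2)
    nx, ny, nz = _lattice_shape(spec)
    occ_foliage = np.zeros((nx, ny, nz), dtype=bool)
    occ_crown = np.zeros((nx, ny, nz), dtype=bool)

    stems = _place_stems(spec, rng)
    crowns = _make_crowns(spec, stems, rng)
    _mark_crowns(occ_crown, crowns)

    # UU stratum: iid cells at the target rate
    k0 = int(round((5.0 - Z0) / DZ))
    k1 = int(round((10.0 - Z0) / DZ))
    occ_foliage[:, :, k0:k1] = rng.random((nx, ny, k1 - k0)) < true_uu

    # low band: per-column occupied cells at heights ~ N(h_center, sd)
    k_low1 = int(round((5.0 - Z0) / DZ))
    n_low = int(round(link.low_band_intensity * nx * ny * k_low1))
    ci = rng.integers(0, nx, n_low)
    cj = rng.integers(0, ny, n_low)
    zs = rng.normal(h_center, link.low_band_sd, n_low)
    zs = np.clip(zs, Z0 + 0.01, 5.0 - 0.01)
    ck = ((zs - Z0) / DZ).astype(int)
    occ_foliage[ci, cj, ck] = True

    return Scene(spec, occ_foliage, occ_crown, stems, crowns,
                 h_center=h_center, true_uu=true_uu)


@dataclass
class LinkStudy:
    """A set of linear-link plots plus their generating truth."""

    scenes: list[Scene]
    truth: pd.DataFrame  # plot_id, h_center, true_uu
    link: LinearLink


def linear_link_study(n_plots: int = 24, seed: int = 0,
                      link: LinearLink = LinearLink()) -> LinkStudy:
    """Generate the linear-link calibration study (default 24 plots)."""
    rng = _rng(seed, 3)
    h = np.linspace(link.h_range[0], link.h_range[1], n_plots)
    eps = rng.normal(0.0, link.noise_sd, n_plots)
    uu = np.clip(link.slope * h + link.intercept + eps, 0.005, 0.95)
    scenes = []
    rows = []
    for i in range(n_plots):
        plot_seed = int(rng.integers(0, 2**31 - 1))
        stand = "beech_like" if i % 2 else "pine_like"
        scenes.append(linear_link_scene(plot_seed, float(h[i]), float(uu[i]),
                                        link=link, stand_type=stand))
        rows.append({"plot_id": f"plot{i + 1:02d}", "h_center": float(h[i]),
                     "true_uu": float(uu[i]), "stand_type": stand})
    return LinkStudy(scenes, pd.DataFrame(rows).set_index("plot_id"), link)


def gradient_scene(seed: int = 0, extent: float = 100.0,
                   link: LinearLink = LinearLink()) -> Scene:
    """Scene whose low-band height (and hence true UU PDI) rises along x.

    Used to check that wall-to-wall prediction tracks a known spatial
    gradient in understory density.
    """
    spec = SceneSpec(extent_x=extent, extent_y=extent, stand_type="pine_like",
                     stem_density=80.0, canopy_base=10.0, canopy_top=15.0,
                     understory_intensity_LU=0.0, understory_intensity_UU=0.0,
                     seed=seed)
    rng = _rng(seed, 4)
    nx, ny, nz = _lattice_shape(spec)
    occ_foliage = np.zeros((nx, ny, nz), dtype=bool)
    occ_crown = np.zeros((nx, ny, nz), dtype=bool)
    stems = _place_stems(spec, rng)
    crowns = _make_crowns(spec, stems, rng)
    _mark_crowns(occ_crown, crowns)

    h0, h1 = link.h_range
    xfrac = (np.arange(nx) + 0.5) / nx
    h_col = h0 + (h1 - h0) * xfrac                       # per-column band centre
    uu_col = np.clip(link.slope * h_col + link.intercept, 0.005, 0.95)

    k0 = int(round((5.0 - Z0) / DZ))
    k1 = int(round((10.0 - Z0) / DZ))
    occ_foliage[:, :, k0:k1] = (
        rng.random((nx, ny, k1 - k0)) < uu_col[:, None, None]
    )
    k_low1 = int(round((5.0 - Z0) / DZ))
    n_low = int(round(link.low_band_intensity * nx * ny * k_low1))
    ci = rng.integers(0, nx, n_low)
    cj = rng.integers(0, ny, n_low)
    zs = np.clip(rng.normal(h_col[ci], link.low_band_sd), Z0 + 0.01, 5.0 - 0.01)
    occ_foliage[ci, cj, ((zs - Z0) / DZ).astype(int)] = True
    return Scene(spec, occ_foliage, occ_crown, stems, crowns)


# ---------------------------------------------------------------------------
# instrument emulation


def sample_tls(scene: Scene, geom: PlotGeometry | None = None,
               density_scale: float = 1.0, noise_sd: float = 0.0,
               seed: int = 0) -> PointCloud:
    """Terrestrial (below-canopy) sampling of a scene.

    Every occupied lattice cell emits points uniformly within the cell —
    at least 5 at default density, with a Poisson surplus thinned by height
    and by horizontal distance from the plot centre (emulating range
    fall-off) — plus a 0.5 m grid of ground returns (classification 2).
    Coordinates optionally get Gaussian noise; z values are absolute
    elevations (ground plane included).
    """
    geom = geom or scene.plot_geometry
    rng = _rng(scene.spec.seed, 5, seed)
    occ = scene.occupancy
    idx = np.argwhere(occ)
    parts_x, parts_y, parts_z, parts_c = [], [], [], []
    if idx.size:
        vx = (idx[:, 0] + 0.5) * DX
        vy = (idx[:, 1] + 0.5) * DY
        vz = Z0 + (idx[:, 2] + 0.5) * DZ
        dist = np.hypot(vx - geom.center_x, vy - geom.center_y)
        lam = 3.0 * np.exp(-vz / 12.0) * np.exp(-dist / 40.0) * density_scale
        n = rng.poisson(lam)
        if density_scale >= 1.0:
            n = np.maximum(n, 5)
        rep = np.repeat(np.arange(len(idx)), n)
        u = rng.random((rep.size, 3))
        parts_x.append((idx[rep, 0] + u[:, 0]) * DX)
        parts_y.append((idx[rep, 1] + u[:, 1]) * DY)
        parts_z.append(Z0 + (idx[rep, 2] + u[:, 2]) * DZ)
        parts_c.append(np.ones(rep.size, dtype=np.int64))
    # ground returns
    gx, gy = np.meshgrid(np.arange(0.25, scene.spec.extent_x, 0.5),
                         np.arange(0.25, scene.spec.extent_y, 0.5))
    gx = gx.ravel() + rng.uniform(-0.2, 0.2, gx.size)
    gy = gy.ravel() + rng.uniform(-0.2, 0.2, gy.size)
    parts_x.append(gx)
    parts_y.append(gy)
    parts_z.append(np.abs(rng.normal(0.0, 0.01, gx.size)))
    parts_c.append(np.full(gx.size, 2, dtype=np.int64))

    x = np.concatenate(parts_x)
    y = np.concatenate(parts_y)
    z = np.concatenate(parts_z)
    c = np.concatenate(parts_c)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, x.size)
        y = y + rng.normal(0, noise_sd, y.size)
        z = z + rng.normal(0, noise_sd, z.size)
    z = z + scene.ground_z(x, y)
    return PointCloud(x, y, z, np.ones(x.size, dtype=np.int64), c)


def sample_als(scene: Scene, pulse_density: float = 2.0,
               canopy_transmission: float | None = None,
               region: PlotGeometry | None = None,
               seed: int = 0) -> PointCloud:
    """Airborne first-return sampling, top-down with canopy occlusion.

    Pulses arrive as a Poisson process over the region footprint (default:
    whole scene).  A pulse crossing m crowns is intercepted by the canopy
    with probability 1 - transmission**m; survivors can be intercepted by
    each occupied understory cell in their column (probability 0.35 per
    cell, top-down), and otherwise return from the ground (classification 2).
    ``canopy_transmission`` defaults to the stand type's value (beech-like
    canopies transmit less than pine-like ones).
    """
    if pulse_density <= 0:
        raise ValueError("pulse_density must be positive")
    t = (scene.spec.default_transmission if canopy_transmission is None
         else canopy_transmission)
    if not 0.0 < t <= 1.0:
        raise ValueError("canopy_transmission must be in (0, 1]")
    rng = _rng(scene.spec.seed, 6, seed)
    if region is None:
        x_lo, x_hi = 0.0, scene.spec.extent_x
        y_lo, y_hi = 0.0, scene.spec.extent_y
    else:
        half = region.square_side / 2.0
        x_lo, x_hi = region.center_x - half, region.center_x + half
        y_lo, y_hi = region.center_y - half, region.center_y + half
    area = (x_hi - x_lo) * (y_hi - y_lo)
    n_pulses = rng.poisson(pulse_density * area)
    if n_pulses == 0:
        return PointCloud(np.zeros(0), np.zeros(0), np.zeros(0))
    px = rng.uniform(x_lo, x_hi, n_pulses)
    py = rng.uniform(y_lo, y_hi, n_pulses)

    z_out = np.empty(n_pulses)
    cls_out = np.ones(n_pulses, dtype=np.int64)
    resolved = np.zeros(n_pulses, dtype=bool)

    # canopy interception
    crowns = scene.crowns
    if len(crowns) and t < 1.0:
        cx = crowns["x"].to_numpy()
        cy = crowns["y"].to_numpy()
        rh = crowns["r_h"].to_numpy()
        d2 = (px[:, None] - cx[None, :]) ** 2 + (py[:, None] - cy[None, :]) ** 2
        crossed = d2 < (rh[None, :] ** 2)
        m = crossed.sum(axis=1)
        hit_canopy = rng.random(n_pulses) > t ** m
        if hit_canopy.any():
            # pick a random crossed crown per intercepted pulse
            score = np.where(crossed, rng.random(crossed.shape), -1.0)
            pick = np.argmax(score, axis=1)
            sel = np.flatnonzero(hit_canopy)
            k = pick[sel]
            zc = crowns["z_center"].to_numpy()[k]
            rz = crowns["r_z"].to_numpy()[k]
            chord = np.sqrt(np.maximum(1.0 - d2[sel, k] / rh[k] ** 2, 0.0))
            z_out[sel] = zc + rz * chord * rng.uniform(-1.0, 1.0, sel.size)
            resolved[sel] = True

    # understory interception, top-down through the occupancy column
    open_idx = np.flatnonzero(~resolved)
    if open_idx.size:
        occ = scene.occ_foliage
        nx, ny, nz = occ.shape
        ci = np.clip((px[open_idx] / DX).astype(int), 0, nx - 1)
        cj = np.clip((py[open_idx] / DY).astype(int), 0, ny - 1)
        p = occ.astype(np.float64) * _EL_HIT_P
        surv_rev = np.cumprod(1.0 - p[:, :, ::-1], axis=2)
        s_above = np.concatenate(
            [np.ones((nx, ny, 1)), surv_rev[:, :, :-1]], axis=2)
        hit_rev = s_above * p[:, :, ::-1]
        cdf_rev = np.cumsum(hit_rev, axis=2)
        col_cdf = cdf_rev[ci, cj, :]                     # (n_open, nz)
        u = rng.random(open_idx.size)
        hit = u < col_cdf[:, -1]
        pos = (u[:, None] >= col_cdf).sum(axis=1)        # first layer (rev order)
        k = nz - 1 - pos
        sel = open_idx[hit]
        z_out[sel] = Z0 + (k[hit] + rng.random(sel.size)) * DZ
        resolved[sel] = True

    ground = ~resolved
    z_out[ground] = np.abs(rng.normal(0.0, 0.01, int(ground.sum())))
    cls_out[ground] = 2

    z_out = z_out + scene.ground_z(px, py)
    return PointCloud(px, py, z_out, np.ones(n_pulses, dtype=np.int64), cls_out)


# ---------------------------------------------------------------------------
# study-level convenience


@dataclass
class Study:
    """A simulated multi-plot field campaign."""

    scenes: list[Scene]
    plots: pd.DataFrame        # plot_id, stand_type, intensities
    field_trees: pd.DataFrame  # plot_id, dbh_cm


def simulate_study(n_plots: int = 24, seed: int = 0,
                   lu_range: tuple[float, float] = (0.05, 0.45),
                   uu_range: tuple[float, float] = (0.05, 0.50)) -> Study:
    """Simulate the reference campaign: half beech-like, half pine-like plots
    with understory intensities spread over the given ranges, plus the
    per-plot field tree lists (DBH in cm) inside the 15 m circular plots.
    """
    rng = _rng(seed, 7)
    scenes: list[Scene] = []
    plot_rows = []
    tree_rows = []
    for i in range(n_plots):
        stand = "beech_like" if i < n_plots // 2 else "pine_like"
        lu = float(rng.uniform(*lu_range))
        uu = float(rng.uniform(*uu_range))
        spec = SceneSpec(stand_type=stand, understory_intensity_LU=lu,
                         understory_intensity_UU=uu,
                         seed=int(rng.integers(0, 2**31 - 1)))
        scene = generate_scene(spec)
        scenes.append(scene)
        pid = f"plot{i + 1:02d}"
        plot_rows.append({"plot_id": pid, "stand_type": stand,
                          "intensity_LU": lu, "intensity_UU": uu,
                          "center_x": scene.plot_geometry.center_x,
                          "center_y": scene.plot_geometry.center_y})
        geom = scene.plot_geometry
        st = scene.stems
        if len(st):
            d = np.hypot(st["x"] - geom.center_x, st["y"] - geom.center_y)
            inside = st.loc[d <= geom.plot_radius, "dbh_cm"]
            tree_rows.extend({"plot_id": pid, "dbh_cm": float(v)} for v in inside)
    return Study(scenes, pd.DataFrame(plot_rows).set_index("plot_id"),
                 pd.DataFrame(tree_rows, columns=["plot_id", "dbh_cm"]))
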