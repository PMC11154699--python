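"""Synthetic-scene generator: every input the pipeline consumes, with
known truth for parameter-recovery tests.

The generator emulates the statistical structure of the real inputs — an
8-day composite year of surface reflectance whose derived EVI/LSWI follow
class-specific seasonal cycles (monsoon-peaked for croplands and
deciduous forest, flat for evergreen forest), seasonal meteorology, a
fine-resolution (0.05°) SIF product and a coarse (0.1°) one related by a
per-class multiplicative factor plus additive noise, soil moisture and
temperature fields, and a reference respiration field built from known
(τ₀, ν₀, κ₀) so every fitting operation has a recoverable target.  It
makes no attempt at radiative-transfer realism or real amplitude matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import (
    VEG_CLASSES,
    CompositeCalendar,
    Grid,
    GriddedField,
    VegMap,
    class_mask,
)
from .params import TemperatureLimits, VPRMParams, packaged_table
from .vprm import reco_vprm

__all__ = ["SceneConfig", "Scene", "generate_scene", "make_toy_tables"]

# (min, max, peak day-of-year) of the seasonal cycle per class.  Monsoon-
# peaked greenness (~DOY 240) for herbaceous and deciduous classes, a flat
# high cycle for evergreen forest.
_SEASONALITY = {
    #                 EVI                LSWI                SIF
    "Grassland":       ((0.10, 0.45, 240), (0.00, 0.35, 240), (0.05, 0.45, 240)),
    "Cropland":        ((0.15, 0.70, 240), (0.05, 0.50, 240), (0.10, 0.90, 240)),
    "Savanna":         ((0.15, 0.50, 230), (0.00, 0.40, 230), (0.10, 0.60, 230)),
    "Shrubland":       ((0.10, 0.40, 220), (-0.05, 0.30, 220), (0.05, 0.50, 220)),
    "DeciduousForest": ((0.20, 0.70, 250), (0.05, 0.50, 250), (0.15, 1.00, 250)),
    "EvergreenForest": ((0.45, 0.75, 200), (0.25, 0.55, 200), (0.60, 1.30, 200)),
    "MixedForest":     ((0.30, 0.65, 230), (0.15, 0.50, 230), (0.30, 1.00, 230)),
}

_BLUE = 0.04
_RED = 0.08


def _default_s0() -> dict[str, float]:
    tab = packaged_table("sif_scaling")
    return dict(zip(tab["class"], tab["s"]))


def _default_reco_truth() -> dict[str, tuple[float, float, float]]:
    # (tau0, nu0, kappa0) per class, sized so each term contributes a flux
    # of order 1 umol m-2 s-1 with ST ~ 300 K and SM ~ 0.1-0.4 m3 m-3
    return {
        cls: (0.010 + 0.002 * i, 3.0 + 1.5 * i, 0.4 + 0.1 * i)
        for i, cls in enumerate(VEG_CLASSES)
    }


@dataclass
class SceneConfig:
    """Configuration of a synthetic scene.

    The defaults define a 1.6° × 2.1° domain at 0.1° (0.05° for the fine
    SIF product) over one composite year, a block class layout covering
    all seven biomes plus a few ``Other`` cells, cross-sensor factors s₀
    set to the packaged per-class reference values, SIF noise σ = 0.1
    mW m⁻² sr⁻¹ nm⁻¹ and respiration noise 0.1 µmol CO2 m⁻² s⁻¹.
    """

    lat_start: float = 18.0
    lon_start: float = 74.0
    nlat: int = 16
    nlon: int = 21
    resolution: float = 0.1
    year: int = 2019
    layout: str = "blocks"  # uniform | blocks | checkerboard
    sif_noise: float = 0.1
    reco_noise: float = 0.1
    tair_range: tuple[float, float] = (12.0, 34.0)  # degC
    swdown_range: tuple[float, float] = (80.0, 850.0)
    sm_range: tuple[float, float] = (0.08, 0.42)  # m3 m-3
    st_range: tuple[float, float] = (291.0, 309.0)  # K
    spatial_cv: float = 0.05
    s0: dict = field(default_factory=_default_s0)
    reco_truth: dict = field(default_factory=_default_reco_truth)
    parameter_set: str = "tropical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("uniform", "blocks", "checkerboard"):
            raise ValueError("layout must be uniform, blocks or checkerboard")
        if self.sif_noise < 0 or self.reco_noise < 0:
            raise ValueError("noise levels must be non-negative")
        if self.layout == "blocks" and self.nlon < len(VEG_CLASSES):
            raise ValueError(
                f"blocks layout needs at least {len(VEG_CLASSES)} longitude "
                f"columns, got {self.nlon}"
            )


@dataclass
class Scene:
    """Bundle of generated inputs plus the truth tables behind them."""

    config: SceneConfig
    grid: Grid
    fine_grid: Grid
    calendar: CompositeCalendar
    vegmap: VegMap
    vegmap_fine: VegMap
    red: GriddedField
    nir: GriddedField
    blue: GriddedField
    swir: GriddedField
    tair: GriddedField
    swdown: GriddedField
    gosif: GriddedField  # fine grid
    troposif: GriddedField  # coarse grid
    sm: GriddedField
    st: GriddedField
    reco_ref: GriddedField
    truth_s0: pd.DataFrame
    truth_reco: pd.DataFrame
    site_index: tuple[int, int]

    def site_series(self, fld: GriddedField) -> np.ma.MaskedArray:
        """Time series at the designated pseudo eddy-covariance cell."""
        iy, ix = self.site_index
        return fld.values[:, iy, ix]

    def fields(self) -> dict[str, GriddedField]:
        return {
            f.name: f
            for f in (
                self.red, self.nir, self.blue, self.swir, self.tair,
                self.swdown, self.gosif, self.troposif, self.sm, self.st,
                self.reco_ref,
            )
        }


def _class_codes(cfg: SceneConfig) -> np.ndarray:
    from .grids import ALL_CLASSES

    n7 = len(VEG_CLASSES)
    if cfg.layout == "uniform":
        codes = np.zeros((cfg.nlat, cfg.nlon), dtype=np.int16)
    elif cfg.layout == "checkerboard":
        iy, ix = np.indices((cfg.nlat, cfg.nlon))
        codes = ((iy + ix) % n7).astype(np.int16)
    else:  # blocks: longitude bands, one per class
        band = cfg.nlon // n7
        cols = np.minimum(np.arange(cfg.nlon) // band, n7 - 1)
        codes = np.broadcast_to(cols, (cfg.nlat, cfg.nlon)).astype(np.int16).copy()
        # a few water/unclassified cells in the north-west corner
        codes[0, : min(3, cfg.nlon)] = ALL_CLASSES.index("Other")
    return codes


def _seasonal(doys: np.ndarray, vmin: float, vmax: float, peak: float) -> np.ndarray:
    phase = 2.0 * np.pi * (doys - peak) / 365.25
    return vmin + (vmax - vmin) * 0.5 * (1.0 + np.cos(phase))


def generate_scene(cfg: SceneConfig | None = None) -> Scene:
    """Generate a deterministic synthetic scene from its configuration.

    Identical configurations (including the seed) yield bit-identical
    scenes.
    """
    cfg = replace(cfg) if cfg is not None else SceneConfig()
    rng = np.random.default_rng(cfg.seed)

    grid = Grid.regular(cfg.lat_start, cfg.lon_start, cfg.nlat, cfg.nlon, cfg.resolution)
    fine_grid = Grid.regular(
        cfg.lat_start, cfg.lon_start, 2 * cfg.nlat, 2 * cfg.nlon, cfg.resolution / 2
    )
    cal = CompositeCalendar(cfg.year)
    times = cal.period_starts
    doys = ((times - np.datetime64(f"{cfg.year}-01-01", "D")).astype(int) + 1).astype(float)

    codes = _class_codes(cfg)
    vegmap = VegMap(grid, codes)
    vegmap_fine = VegMap(fine_grid, np.repeat(np.repeat(codes, 2, axis=0), 2, axis=1))

    ny, nx = grid.shape
    nt = times.size

    def texture(shape):
        return np.clip(1.0 + cfg.spatial_cv * rng.standard_normal(shape), 0.5, 1.5)

    # --- vegetation indices by class, inverted to reflectance bands -----
    evi = np.zeros((nt, ny, nx))
    lswi = np.zeros((nt, ny, nx))
    tex = texture((ny, nx))
    for cls, (evi_p, lswi_p, _) in _SEASONALITY.items():
        m = class_mask(vegmap, cls)
        if not m.any():
            continue
        evi[:, m] = _seasonal(doys, *evi_p)[:, None] * tex[m]
        lswi[:, m] = _seasonal(doys, *lswi_p)[:, None] * tex[m]
    evi = np.clip(evi, 0.02, 0.85)
    lswi = np.clip(lswi, -0.3, 0.7)

    blue = np.full((nt, ny, nx), _BLUE)
    red = np.full((nt, ny, nx), _RED)
    aux = 6.0 * _RED - 7.5 * _BLUE + 1.0
    nir = (2.5 * _RED + evi * aux) / (2.5 - evi)
    swir = nir * (1.0 - lswi) / (1.0 + lswi)

    def fld(vals, units, name, g=grid, t=times):
        return GriddedField(g, t, np.ma.asarray(vals), units, name)

    # --- meteorology ----------------------------------------------------
    lat_w = np.linspace(1.0, 0.9, ny)[:, None] * np.ones((1, nx))
    tair = _seasonal(doys, *cfg.tair_range, peak=150)[:, None, None] * lat_w
    swdown = np.clip(
        _seasonal(doys, *cfg.swdown_range, peak=135)[:, None, None] * texture((ny, nx)),
        0.0,
        None,
    )

    # --- SIF products ---------------------------------------------------
    gosif = np.zeros((nt, 2 * ny, 2 * nx))
    tex_f = texture((2 * ny, 2 * nx))
    for cls, (_, _, sif_p) in _SEASONALITY.items():
        m = class_mask(vegmap_fine, cls)
        if not m.any():
            continue
        gosif[:, m] = _seasonal(doys, *sif_p)[:, None] * tex_f[m]
    gosif = np.clip(gosif, 0.0, None)
    gosif_f = fld(gosif, "mW m-2 sr-1 nm-1", "gosif", g=fine_grid)

    from .grids import regrid_block_mean

    gosif_coarse = regrid_block_mean(gosif_f, grid)
    s0_map = np.zeros((ny, nx))
    for cls in VEG_CLASSES:
        s0_map[class_mask(vegmap, cls)] = cfg.s0[cls]
    troposif = s0_map * np.ma.getdata(gosif_coarse.values)
    if cfg.sif_noise > 0:
        troposif = troposif + cfg.sif_noise * rng.standard_normal(troposif.shape)
    troposif = np.ma.masked_array(troposif, mask=class_mask(vegmap, "Other")[None, :, :] | np.zeros((nt, ny, nx), bool))

    # --- soils and reference respiration --------------------------------
    sm = np.clip(
        _seasonal(doys, *cfg.sm_range, peak=245)[:, None, None] * texture((ny, nx)),
        0.01,
        0.6,
    )
    st = _seasonal(doys, *cfg.st_range, peak=160)[:, None, None] * np.clip(
        1.0 + 0.005 * rng.standard_normal((ny, nx)), 0.98, 1.02
    )

    tair_f = fld(tair, "degC", "tair")
    sm_f = fld(sm, "m3 m-3", "sm")
    st_f = fld(st, "K", "st")

    vprm_params = VPRMParams.packaged(cfg.parameter_set)
    baseline = reco_vprm(tair_f, vegmap, vprm_params, TemperatureLimits())
    reco = np.zeros((nt, ny, nx))
    for cls, (tau0, nu0, kappa0) in cfg.reco_truth.items():
        m = np.broadcast_to(class_mask(vegmap, cls), reco.shape)
        vals = tau0 * st + nu0 * sm + kappa0 * np.ma.getdata(baseline.values)
        reco[m] = vals[m]
    if cfg.reco_noise > 0:
        reco = reco + cfg.reco_noise * rng.standard_normal(reco.shape)
    reco = np.ma.masked_array(
        reco, mask=np.broadcast_to(class_mask(vegmap, "Other"), reco.shape).copy()
    )

    truth_s0 = pd.DataFrame(
        {"class": list(cfg.s0), "s0": [cfg.s0[c] for c in cfg.s0]}
    )
    truth_reco = pd.DataFrame(
        [
            {"class": c, "tau0": t0, "nu0": n0, "kappa0": k0}
            for c, (t0, n0, k0) in cfg.reco_truth.items()
        ]
    )

    # pseudo eddy-covariance site: a deciduous-forest cell when present
    dec = np.argwhere(class_mask(vegmap, "DeciduousForest"))
    site = tuple(dec[len(dec) // 2]) if dec.size else (ny // 2, nx // 2)

    return Scene(
        config=cfg,
        grid=grid,
        fine_grid=fine_grid,
        calendar=cal,
        vegmap=vegmap,
        vegmap_fine=vegmap_fine,
        red=fld(red, "1", "red"),
        nir=fld(nir, "1", "nir"),
        blue=fld(blue, "1", "blue"),
        swir=fld(swir, "1", "swir"),
        tair=tair_f,
        swdown=fld(swdown, "umol m-2 s-1", "swdown"),
        gosif=gosif_f,
        troposif=fld(troposif, "mW m-2 sr-1 nm-1", "troposif"),
        sm=sm_f,
        st=st_f,
        reco_ref=fld(reco, "umol CO2 m-2 s-1", "reco_ref"),
        truth_s0=truth_s0,
        truth_reco=truth_reco,
        site_index=(int(site[0]), int(site[1])),
    )


def make_toy_tables() -> dict[str, pd.DataFrame]:
    """The packaged per-class constant tables, for worked examples.

    Returns the model parameter sets (λ, SWdown0, α, β), the cross-sensor
    SIF scaling factors, the SIF→GPP coefficients for both products, the
    reference GPP-refinement η values and the reference refined-respiration
    coefficients, keyed by table name.
    """
    return {name: packaged_table(name) for name in (
        "vprm_params", "sif_scaling", "sif_gpp_coeffs", "gpp_refine_eta",
        "reco_refine_params",
    )}
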