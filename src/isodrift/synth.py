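"""Synthetic landscapes, samples, wind scenarios and trap events.

This module generates data with the statistical structure the downstream
analysis assumes, so every stage is testable without field data:

* a coastal landscape whose true foliar δ³⁴S field declines sharply over
  the first few kilometres from the coast, plateaus between ~10 and
  ~100 km, then declines gradually inland — producing a bimodal value
  distribution spanning roughly −8.5‰ to 18.6‰;
* six environmental covariates (sea-salt deposition, distance to coast,
  mineral-dust deposition, potential evapotranspiration, wind speed,
  aridity) that jointly determine the noiseless field;
* foliar site samples with analytical noise, and known-origin moths
  generated from foliage through an affine calibration relation with
  intra-site scatter;
* analytic wind scenarios (uniform, rotating, a channel that carries
  virtual moths from a source zone to a trap, and a cold-pocket variant).

All generators are deterministic given their seed (named child-stream
scheme, see :mod:`isodrift._rng`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import child_rng
from .calibrate import CalibrationFit
from .covariates import COVARIATE_NAMES, CovariateStack
from .raster import Raster
from .tables import validate_samples
from .wind import WindField

__all__ = [
    "LandscapeConfig",
    "CovariateStack",
    "COVARIATE_NAMES",
    "make_landscape",
    "sample_foliar",
    "sample_known_origin_moths",
    "make_wind_scenario",
    "defoliation_mask",
    "WIND_SCENARIOS",
]

# metres per degree of latitude / of longitude at the equator (WGS84 mean sphere)
M_PER_DEG_LAT = 110_574.0
M_PER_DEG_LON_EQ = 111_320.0

#: Paper-scale defaults: analytical noise on foliar measurements (mean
#: duplicate difference 0.16‰) and intra-site moth scatter (average SD 0.59‰).
ANALYTICAL_SD_FOLIAR = 0.16
INTRA_SITE_SD_MOTH = 0.59
#: Default calibration relation used to generate known-origin moths.
DEFAULT_CALIBRATION = (-0.08, 0.94)


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic coastal landscape.

    The foliar-field constants are chosen so that, at the defaults, the
    noiseless field spans approximately [−8.5, 18.6] ‰ with a sharp
    coastal decline, a 10–100 km plateau, and a gradual inland decline.
    """

    grid_shape: tuple[int, int] = (120, 120)
    cell_size: float = 4.0            # km; cells are approximately square in km
    lat_top: float = 49.0             # northern edge, degrees
    lon_west: float = -66.0           # western edge, degrees
    # coastline: sea occupies the west, with a sinusoidal boundary
    coast_frac: float = 0.12          # mean fraction of columns that are sea
    coast_amp_frac: float = 0.05      # amplitude of the coastline wiggle
    coast_waves: float = 2.5          # wiggle periods over the grid height
    # foliar field:  plateau + coastal logistic − inland decline − dust effect
    plateau: float = 8.0              # ‰, value on the 10–100 km plateau
    coastal_amp: float = 10.6         # ‰, extra enrichment at the coast
    coastal_mid_km: float = 5.0       # logistic midpoint of the coastal decline
    coastal_width_km: float = 2.0     # logistic width of the coastal decline
    plateau_end_km: float = 100.0     # where the gradual inland decline starts
    inland_slope: float = 0.055       # ‰ per km beyond the plateau
    dust_coef: float = 0.8            # ‰ per unit of (dust − mean dust)
    noise_sd_foliar: float = 1.0      # ‰, i.i.d. spatial micro-variation
    seed: int = 0

    def __post_init__(self) -> None:
        nr, nc = self.grid_shape
        if nr < 20 or nc < 20:
            raise ValueError("grid_shape must be at least (20, 20)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.noise_sd_foliar < 0:
            raise ValueError("noise_sd_foliar must be non-negative")

    def grid(self) -> Raster:
        """Empty raster with the configured geometry (approx. square cells)."""
        nr, nc = self.grid_shape
        dlat = self.cell_size * 1000.0 / M_PER_DEG_LAT
        lat_mid = self.lat_top - 0.5 * nr * dlat
        dlon = self.cell_size * 1000.0 / (M_PER_DEG_LON_EQ * np.cos(np.radians(lat_mid)))
        return Raster(np.full(self.grid_shape, np.nan), lat0=self.lat_top,
                      lon0=self.lon_west, dlat=dlat, dlon=dlon)


def _coastline_sea_mask(cfg: LandscapeConfig) -> np.ndarray:
    """Boolean sea mask: sea on the west of a sinusoidal coastline."""
    nr, nc = cfg.grid_shape
    rows = np.arange(nr)
    boundary = nc * (cfg.coast_frac
                     + cfg.coast_amp_frac * np.sin(2 * np.pi * cfg.coast_waves * rows / nr))
    cols = np.arange(nc)
    sea = cols[None, :] < boundary[:, None]
    return sea


def make_landscape(cfg: LandscapeConfig | None = None):
    """Generate the covariate stack and the true foliar δ³⁴S field.

    Returns ``(CovariateStack, Raster)``. The noiseless field is an exact
    deterministic function of the covariates (distance to coast and dust
    deposition); seeded i.i.d. Gaussian micro-variation of SD
    ``noise_sd_foliar`` is added on top.
    """
    cfg = cfg or LandscapeConfig()
    grid = cfg.grid()
    nr, nc = cfg.grid_shape
    sea = _coastline_sea_mask(cfg)
    land = ~sea
    if land.all() or sea.all():
        raise ValueError("degenerate coastline: grid is entirely land or entirely sea")

    # distance to coast, km: Euclidean distance to the nearest sea cell,
    # shifted so cells that touch the sea sit at 0
    edt = ndimage.distance_transform_edt(land, sampling=(cfg.cell_size, cfg.cell_size))
    dist = np.clip(edt - cfg.cell_size, 0.0, None)

    lats = grid.lats[:, None] * np.ones((1, nc))
    latnorm = (lats - lats.min()) / (lats.max() - lats.min())

    covs = {
        "dist_coast": dist,
        "sea_salt_dep": 20.0 * np.exp(-dist / 15.0),
        "dust_dep": 0.5 + 2.0 * latnorm,          # broad gradient increasing northward
        "pet": 420.0 + 260.0 * (1.0 - np.exp(-dist / 120.0)),
        "wind_speed": 4.0 + 6.0 * np.exp(-dist / 40.0),
        "aridity": 0.5 + 0.9 * np.exp(-dist / 60.0),
    }

    dust = covs["dust_dep"]
    coastal = cfg.coastal_amp / (1.0 + np.exp((dist - cfg.coastal_mid_km) / cfg.coastal_width_km))
    inland = cfg.inland_slope * np.clip(dist - cfg.plateau_end_km, 0.0, None)
    dust_effect = cfg.dust_coef * (dust - dust[land].mean())
    true = cfg.plateau + coastal - inland - dust_effect

    if cfg.noise_sd_foliar > 0:
        rng = child_rng(cfg.seed, "landscape", "foliar-noise")
        true = true + rng.normal(0.0, cfg.noise_sd_foliar, size=true.shape)

    units = {"dist_coast": "km", "sea_salt_dep": "kg/ha/yr", "dust_dep": "g/m2/yr",
             "pet": "mm/yr", "wind_speed": "m/s", "aridity": "P/PET"}
    stack = {}
    for name, vals in covs.items():
        v = np.where(land, vals, np.nan)
        stack[name] = grid.like(v, units=units[name])
    true_foliar = grid.like(np.where(land, true, np.nan), units="permil VCDT")
    return CovariateStack(stack), true_foliar


def _stratified_site_cells(dist: np.ndarray, land: np.ndarray, n_sites: int,
                           band_edges, rng: np.random.Generator):
    """Pick land cells without replacement, stratified over distance bands.

    Sites are allocated proportionally to band area with at least one site
    per non-empty band, so coastal and inland extremes are represented.
    """
    edges = [0.0, *band_edges, np.inf]
    rows_all, cols_all = np.nonzero(land)
    d = dist[rows_all, cols_all]
    band_of = np.digitize(d, edges[1:-1])
    bands = [np.nonzero(band_of == b)[0] for b in range(len(edges) - 1)]
    bands = [b for b in bands if len(b) > 0]
    counts = np.array([len(b) for b in bands], dtype=float)
    alloc = np.maximum(1, np.floor(n_sites * counts / counts.sum()).astype(int))
    alloc = np.minimum(alloc, counts.astype(int))
    # distribute the remainder to the largest bands that still have room
    while alloc.sum() < n_sites:
        room = counts - alloc
        i = int(np.argmax(room))
        if room[i] <= 0:
            break
        alloc[i] += 1
    while alloc.sum() > n_sites:
        i = int(np.argmax(alloc))
        alloc[i] -= 1
    picks = []
    for b, k in zip(bands, alloc):
        if k > 0:
            picks.append(rng.choice(b, size=k, replace=False))
    idx = np.concatenate(picks)
    return rows_all[idx], cols_all[idx]


def sample_foliar(true_foliar: Raster, covs: CovariateStack, n_sites: int, seed: int,
                  noise_sd: float = ANALYTICAL_SD_FOLIAR,
                  band_edges=(10.0, 100.0, 300.0)) -> pd.DataFrame:
    """Draw foliar site samples from the true field.

    Sites are drawn without replacement over land, stratified by
    distance-to-coast bands; measured δ³⁴S is the raster value plus seeded
    analytical noise (default SD 0.16‰, the mean duplicate difference).
    """
    if n_sites < 5:
        raise ValueError("n_sites must be at least 5 to support model fitting")
    land = true_foliar.mask
    if n_sites > land.sum():
        raise ValueError("n_sites exceeds the number of land cells")
    rng = child_rng(seed, "sample-foliar")
    dist = covs["dist_coast"].values
    rows, cols = _stratified_site_cells(dist, land, n_sites, band_edges, rng)
    lat, lon = true_foliar.latlon_of(rows, cols)
    vals = true_foliar.values[rows, cols]
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    df = pd.DataFrame({
        "site_id": [f"F{i:03d}" for i in range(len(rows))],
        "lat": lat, "lon": lon,
        "tissue": "foliar", "species": "conifer",
        "d34S": vals, "n_replicates": 1,
        "row": rows, "col": cols,
    })
    return validate_samples(df)


def sample_known_origin_moths(true_foliar: Raster, covs: CovariateStack, n_sites: int,
                              moths_per_site, cal: CalibrationFit | tuple, seed: int,
                              intra_site_sd: float = INTRA_SITE_SD_MOTH,
                              band_edges=(10.0, 100.0, 300.0)) -> pd.DataFrame:
    """Generate known-origin moths from foliage via the calibration relation.

    Each moth's δ³⁴S is ``intercept + slope × foliar_truth(site)`` plus
    Normal(0, ``intra_site_sd``) scatter (default 0.59‰, the average
    intra-site moth SD). ``moths_per_site`` is an int or an inclusive
    ``(lo, hi)`` range sampled per site; values must lie in [1, 10].
    The generating foliar truth is kept in a ``foliar_truth`` column.
    """
    if isinstance(cal, tuple):
        intercept, slope = cal
    else:
        intercept, slope = cal.intercept, cal.slope
    if np.isscalar(moths_per_site):
        lo = hi = int(moths_per_site)
    else:
        lo, hi = (int(moths_per_site[0]), int(moths_per_site[1]))
    if not (1 <= lo <= hi <= 10):
        raise ValueError("moths_per_site must lie in [1, 10]")
    if intra_site_sd < 0:
        raise ValueError("intra_site_sd must be non-negative")
    land = true_foliar.mask
    if n_sites > land.sum():
        raise ValueError("n_sites exceeds the number of land cells")
    rng = child_rng(seed, "sample-moths")
    dist = covs["dist_coast"].values
    rows, cols = _stratified_site_cells(dist, land, n_sites, band_edges, rng)
    lat, lon = true_foliar.latlon_of(rows, cols)
    foliar = true_foliar.values[rows, cols]
    records = []
    for i in range(len(rows)):
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        mu = intercept + slope * foliar[i]
        vals = mu + rng.normal(0.0, intra_site_sd, size=k) if intra_site_sd > 0 \
            else np.full(k, mu)
        for v in vals:
            records.append({
                "site_id": f"M{i:03d}", "lat": lat[i], "lon": lon[i],
                "tissue": "moth", "species": "C. fumiferana",
                "d34S": v, "n_replicates": 1,
                "row": rows[i], "col": cols[i], "foliar_truth": foliar[i],
            })
    return validate_samples(pd.DataFrame.from_records(records))


def defoliation_mask(grid: Raster, centers_rc, half_size: int = 1) -> Raster:
    """Binary defoliation raster: square patches around the given cells.

    Patches are clipped to the grid and to land (cells that are nodata in
    ``grid`` stay nodata). Used as the release mask for dispersal runs.
    """
    nr, nc = grid.shape
    vals = np.zeros((nr, nc))
    for r, c in centers_rc:
        r0, r1 = max(0, r - half_size), min(nr, r + half_size + 1)
        c0, c1 = max(0, c - half_size), min(nc, c + half_size + 1)
        vals[r0:r1, c0:c1] = 1.0
    vals = np.where(grid.mask, vals, np.nan)
    out = grid.like(vals, units="defoliated")
    return out


# -- wind scenarios --------------------------------------------------------

WIND_SCENARIOS = ("uniform", "rotating", "channel_to_trap", "cold_pocket")


def _local_xy_m(grid: Raster):
    """East/north metres of every cell center from the grid center."""
    lats, lons = grid.lats, grid.lons
    lat_c, lon_c = lats.mean(), lons.mean()
    y = (lats - lat_c) * M_PER_DEG_LAT
    x = (lons - lon_c) * M_PER_DEG_LON_EQ * np.cos(np.radians(lat_c))
    return np.meshgrid(x, y)  # (X, Y) each (ny, nx)


def make_wind_scenario(name: str, grid: Raster, t0, duration_h: float = 12.0,
                       seed: int = 0, **kw) -> WindField:
    """Build an analytic wind/temperature scenario on the landscape grid.

    Scenarios
    ---------
    ``uniform``
        Constant wind (``u``, ``v`` keywords, default 10 m/s eastward).
    ``rotating``
        Solid-body rotation about the grid center (``omega`` rad/s).
    ``channel_to_trap``
        Uniform wind blowing from a source cell toward a trap location,
        fast enough that a release at the source reaches the trap within
        the flight duration. Metadata carries ``source_rc`` and
        ``trap_latlon``.
    ``cold_pocket``
        Same as ``channel_to_trap`` with a sub-15 °C disk embedded midway
        between source and trap.
    """
    if name not in WIND_SCENARIOS:
        raise ValueError(f"unknown wind scenario {name!r}; options: {', '.join(WIND_SCENARIOS)}")
    nr, nc = grid.shape
    t0 = np.datetime64(t0, "s")
    nt = int(np.ceil(duration_h)) + 1
    times = t0 + np.arange(nt) * np.timedelta64(3600, "s")
    # warm-night default: with the −6.5 °C/km lapse the 300–900 m release
    # levels stay inside the 15–20.5 °C flight envelope
    temp = float(kw.get("temp", 22.0))
    T = np.full((nt, nr, nc), temp)
    meta: dict = {"scenario": name}

    if name == "uniform":
        u = np.full((nt, nr, nc), float(kw.get("u", 10.0)))
        v = np.full((nt, nr, nc), float(kw.get("v", 0.0)))
    elif name == "rotating":
        omega = float(kw.get("omega", 1.4e-4))  # rad/s, period ~12.5 h
        X, Y = _local_xy_m(grid)
        u = np.broadcast_to(-omega * Y, (nt, nr, nc)).copy()
        v = np.broadcast_to(omega * X, (nt, nr, nc)).copy()
        meta["omega"] = omega
    else:  # channel_to_trap / cold_pocket
        land = grid.mask
        source_rc = kw.get("source_rc")
        trap_rc = kw.get("trap_rc")
        if source_rc is None:
            source_rc = (nr // 2, min(nc - 2, int(nc * 0.55)))
        if trap_rc is None:
            row = source_rc[0]
            land_cols = np.nonzero(land[row])[0] if land.any() else np.arange(nc)
            trap_rc = (row, int(land_cols[0] + 1) if len(land_cols) else 1)
        s_lat, s_lon = grid.latlon_of(*source_rc)
        t_lat, t_lon = grid.latlon_of(*trap_rc)
        lat_m = 0.5 * (s_lat + t_lat)
        dx = (t_lon - s_lon) * M_PER_DEG_LON_EQ * np.cos(np.radians(lat_m))
        dy = (t_lat - s_lat) * M_PER_DEG_LAT
        dist_m = float(np.hypot(dx, dy))
        if dist_m == 0:
            raise ValueError("source and trap coincide")
        speed = kw.get("speed")
        if speed is None:
            # reach the trap at ~70% of the window even against the 2.5 m/s
            # airspeed boost being absent
            speed = max(5.0, 1.3 * dist_m / (duration_h * 3600.0))
        ux, vy = speed * dx / dist_m, speed * dy / dist_m
        u = np.full((nt, nr, nc), ux)
        v = np.full((nt, nr, nc), vy)
        meta.update(source_rc=tuple(map(int, source_rc)), trap_rc=tuple(map(int, trap_rc)),
                    trap_latlon=(float(t_lat), float(t_lon)), speed=float(speed))
        if name == "cold_pocket":
            m_lat = 0.5 * (s_lat + t_lat)
            m_lon = 0.5 * (s_lon + t_lon)
            radius_km = float(kw.get("pocket_radius_km", 25.0))
            cold_t = float(kw.get("pocket_temp", 10.0))
            glat = grid.lats[:, None]
            glon = grid.lons[None, :]
            dkm = np.hypot((glat - m_lat) * M_PER_DEG_LAT,
                           (glon - m_lon) * M_PER_DEG_LON_EQ * np.cos(np.radians(m_lat))) / 1000.0
            T[:, dkm <= radius_km] = cold_t
            meta.update(pocket_center=(float(m_lat), float(m_lon)), pocket_radius_km=radius_km)

    return WindField(times=times, u=u, v=v, T=T, grid=grid, meta=meta)
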