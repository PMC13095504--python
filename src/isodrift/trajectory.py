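"""Kinematic wind-assisted flight trajectories with biological filters.

A desk-scale Lagrangian transport model for nocturnal moth dispersal:
released virtual moths are advected by the gridded wind, with a constant
airspeed added collinear with the instantaneous wind (downwind-boosted
transport; zero wind means no displacement). Integration is explicit
Euler on the sphere at a fixed step, altitude held at the release level,
and the per-vertex air temperature taken from the gridded field with a
fixed lapse-rate adjustment.

Biological filters mirror the flight envelope of the spruce budworm moth:
a trajectory that passes within the trap radius is *retained* unless, at
any vertex strictly before its first intersection, temperature fell below
the 15 °C flight threshold (``discarded_cold``) or altitude dropped below
250 m (``discarded_low``); trajectories that never intersect a trap are
``no_intersection``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import Raster
from .wind import WindField

__all__ = [
    "FlightParams", "Release", "Trajectory", "Trap",
    "great_circle_km", "simulate_trajectory", "simulate_batch",
    "batch_release", "apply_filters", "trajectories_to_geojson",
    "verdict_table", "read_traps",
]

EARTH_RADIUS_KM = 6371.0088
VERDICTS = ("retained", "discarded_cold", "discarded_low", "no_intersection")


@dataclass
class FlightParams:
    """Biophysical and numerical parameters of the dispersal simulation.

    Defaults encode the moth flight envelope: 2.5 m/s self-powered
    airspeed, releases at 19:00/21:00/23:00 local time and 300/600/900 m,
    9-h flight duration, 10-km trap radius, a 15 °C flight threshold and
    a 250-m minimum altitude.
    """

    airspeed: float = 2.5                 # m/s, added along the wind
    t_min: float = 15.0                   # °C flight threshold
    alt_min: float = 250.0                # m
    release_times: tuple = (19, 21, 23)   # local clock hours
    release_alts: tuple = (300.0, 600.0, 900.0)   # m
    duration_h: float = 9.0
    trap_radius_km: float = 10.0
    dt: float = 60.0                      # s, integration step
    utc_offset_h: float = 0.0             # local = UTC + offset

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 600:
            raise ValueError("dt must be in (0, 600] s")
        for name in ("airspeed", "alt_min", "duration_h", "trap_radius_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Release:
    lat: float
    lon: float
    alt_m: float
    time: np.datetime64
    cell: tuple[int, int] | None = None


@dataclass(frozen=True)
class Trap:
    trap_id: str
    lat: float
    lon: float
    radius_km: float | None = None   # overrides FlightParams.trap_radius_km


@dataclass
class Trajectory:
    """Time-stamped flight path with release metadata and filter verdict."""

    release: Release
    times: np.ndarray      # datetime64[s] per vertex
    lats: np.ndarray
    lons: np.ndarray
    alts: np.ndarray       # m
    temps: np.ndarray      # °C at flight altitude
    verdict: str | None = None
    first_intersection: tuple | None = None   # (trap_id, time)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def vertices(self):
        """Iterator of (time, lat, lon, alt, T) tuples."""
        return zip(self.times, self.lats, self.lons, self.alts, self.temps)


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in km on the mean-radius sphere (WGS84 degrees)."""
    for la in (lat1, lat2):
        if abs(la) > 90:
            raise ValueError(f"latitude {la} outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = np.radians(lat2 - lat1)
    dl = np.radians(lon2 - lon1)
    h = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1))))


def _frac_indices(grid: Raster, lats, lons):
    """Fractional cell-center indices, clamped to the grid interior."""
    rowf = (grid.lat0 - np.asarray(lats)) / grid.dlat - 0.5
    colf = (np.asarray(lons) - grid.lon0) / grid.dlon - 0.5
    nr, nc = grid.shape
    return np.clip(rowf, 0, nr - 1), np.clip(colf, 0, nc - 1)


def _interp_field(field3d: np.ndarray, tsec: np.ndarray, t: float,
                  grid: Raster, lats, lons):
    """Bilinear in space, linear in time."""
    it = int(np.clip(np.searchsorted(tsec, t) - 1, 0, len(tsec) - 2))
    w = (t - tsec[it]) / (tsec[it + 1] - tsec[it])
    w = float(np.clip(w, 0.0, 1.0))
    plane = (1 - w) * field3d[it] + w * field3d[it + 1]
    rowf, colf = _frac_indices(grid, lats, lons)
    r0 = np.floor(rowf).astype(int)
    c0 = np.floor(colf).astype(int)
    r0 = np.clip(r0, 0, grid.shape[0] - 2)
    c0 = np.clip(c0, 0, grid.shape[1] - 2)
    fr = rowf - r0
    fc = colf - c0
    return ((1 - fr) * (1 - fc) * plane[r0, c0]
            + (1 - fr) * fc * plane[r0, c0 + 1]
            + fr * (1 - fc) * plane[r0 + 1, c0]
            + fr * fc * plane[r0 + 1, c0 + 1])


def simulate_batch(releases: list[Release], wind: WindField, p: FlightParams):
    """Integrate many trajectories sharing a release time in lock-step.

    Releases may differ in position and altitude (altitude only affects
    the recorded temperature). Trajectories stop at the flight duration
    or on grid exit, whichever comes first.
    """
    if not releases:
        return []
    t0 = np.datetime64(releases[0].time, "s")
    if any(np.datetime64(r.time, "s") != t0 for r in releases):
        raise ValueError("simulate_batch requires a common release time")
    if not wind.covers(t0):
        raise ValueError(f"release time {t0} outside the wind time span "
                         f"[{wind.times[0]}, {wind.times[-1]}]")
    grid = wind.grid
    tsec = wind.t_seconds
    t0s = float((t0 - wind.times[0]).astype("timedelta64[s]").astype(float))
    n_steps = int(round(p.duration_h * 3600.0 / p.dt))
    end_s = min(t0s + n_steps * p.dt, tsec[-1])

    n = len(releases)
    lat = np.array([r.lat for r in releases], float)
    lon = np.array([r.lon for r in releases], float)
    alt = np.array([r.alt_m for r in releases], float)
    active = np.ones(n, dtype=bool)

    R_m = EARTH_RADIUS_KM * 1000.0
    lat_min = grid.lat0 - grid.shape[0] * grid.dlat
    lon_max = grid.lon0 + grid.shape[1] * grid.dlon

    path_lat = [lat.copy()]
    path_lon = [lon.copy()]
    path_t = [np.full(n, t0s)]
    alive = [active.copy()]

    t = t0s
    while t < end_s - 1e-9:
        dt = min(p.dt, end_s - t)
        u = _interp_field(wind.u, tsec, t, grid, lat, lon)
        v = _interp_field(wind.v, tsec, t, grid, lat, lon)
        wspd = np.hypot(u, v)
        boost = np.where(wspd > 0, (wspd + p.airspeed) / np.where(wspd > 0, wspd, 1.0), 0.0)
        vx = u * boost
        vy = v * boost
        dlat = np.degrees(vy * dt / R_m)
        dlon = np.degrees(vx * dt / (R_m * np.cos(np.radians(lat))))
        lat = np.where(active, lat + dlat, lat)
        lon = np.where(active, lon + dlon, lon)
        inside = (lat <= grid.lat0) & (lat >= lat_min) & (lon >= grid.lon0) & (lon <= lon_max)
        active = active & inside
        t += dt
        path_lat.append(lat.copy())
        path_lon.append(lon.copy())
        path_t.append(np.full(n, t))
        alive.append(active.copy())

    LAT = np.array(path_lat)   # (n_vert, n)
    LON = np.array(path_lon)
    TT = np.array(path_t)
    ALIVE = np.array(alive)

    out = []
    for i, rel in enumerate(releases):
        # vertices up to and including the last in-grid position
        ok = ALIVE[:, i]
        last = int(np.nonzero(ok)[0][-1]) if ok.any() else 0
        sl = slice(0, last + 1)
        lats_i = LAT[sl, i]
        lons_i = LON[sl, i]
        ts_i = TT[sl, i]
        temps = np.empty(len(lats_i))
        for j, (tj, laj, loj) in enumerate(zip(ts_i, lats_i, lons_i)):
            T_ref = _interp_field(wind.T, tsec, tj, grid,
                                  np.array([laj]), np.array([loj]))[0]
            temps[j] = wind.temperature_at_altitude(T_ref, rel.alt_m)
        times = wind.times[0] + (ts_i).astype("timedelta64[s]")
        out.append(Trajectory(
            release=rel, times=times, lats=lats_i, lons=lons_i,
            alts=np.full(len(lats_i), rel.alt_m), temps=temps,
        ))
    return out


def simulate_trajectory(release: Release, wind: WindField, p: FlightParams) -> Trajectory:
    """Integrate a single trajectory (see :func:`simulate_batch`)."""
    return simulate_batch([release], wind, p)[0]


def batch_release(defoliation: Raster, wind: WindField, p: FlightParams,
                  dates) -> list[Trajectory]:
    """One trajectory per (defoliated cell × release time × altitude × date).

    ``dates`` are calendar dates (anything ``numpy.datetime64`` accepts at
    day precision); release clock times are local hours mapped to UTC with
    ``p.utc_offset_h``.
    """
    vals = defoliation.values
    cells = np.argwhere(np.isfinite(vals) & (vals > 0))
    if len(cells) == 0:
        raise ValueError("empty defoliation mask: no release cells")
    trajs: list[Trajectory] = []
    for date in np.atleast_1d(np.asarray(dates, dtype="datetime64[D]")):
        for hour in p.release_times:
            t_rel = (np.datetime64(date, "s")
                     + np.timedelta64(int((hour - p.utc_offset_h) * 3600), "s"))
            releases = []
            for (r, c) in cells:
                la, lo = defoliation.latlon_of(r, c)
                for alt in p.release_alts:
                    releases.append(Release(lat=float(la), lon=float(lo), alt_m=float(alt),
                                            time=t_rel, cell=(int(r), int(c))))
            trajs.extend(simulate_batch(releases, wind, p))
    return trajs


def _local_km(lat0: float, lon0: float, lats, lons):
    """Equirectangular km offsets around (lat0, lon0)."""
    ky = np.pi / 180.0 * EARTH_RADIUS_KM
    kx = ky * np.cos(np.radians(lat0))
    return kx * (np.asarray(lons) - lon0), ky * (np.asarray(lats) - lat0)


def _first_intersection_time(traj: Trajectory, trap: Trap, radius_km: float):
    """Earliest time the path enters the trap circle, or None.

    Checks vertices and linearly interpolated segment points, so a fast
    trajectory cannot step across the circle between vertices.
    """
    x, y = _local_km(trap.lat, trap.lon, traj.lats, traj.lons)
    d2 = x * x + y * y
    r2 = radius_km ** 2
    t = traj.times.astype("datetime64[s]").astype("int64").astype(float)
    if d2[0] <= r2:
        return float(t[0])
    for i in range(len(x) - 1):
        ax, ay, bx, by = x[i], y[i], x[i + 1], y[i + 1]
        dx, dy = bx - ax, by - ay
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            if d2[i] <= r2:
                return float(t[i])
            continue
        # smallest s in [0,1] with |a + s·d|² = r²
        b_half = ax * dx + ay * dy
        c = d2[i] - r2
        disc = b_half * b_half - seg2 * c
        if disc < 0:
            continue
        sq = np.sqrt(disc)
        s = (-b_half - sq) / seg2
        if s < 0:
            s = (-b_half + sq) / seg2
        if 0 <= s <= 1:
            return float(t[i] + s * (t[i + 1] - t[i]))
    return None


def apply_filters(traj: Trajectory, traps, p: FlightParams) -> Trajectory:
    """Set the verdict from trap intersections and the flight envelope.

    Pure function of the vertices and traps: re-applying is idempotent.
    Cold or low vertices *after* the first intersection do not discard.
    """
    best = None
    for trap in traps:
        radius = trap.radius_km if trap.radius_km is not None else p.trap_radius_km
        t_hit = _first_intersection_time(traj, trap, radius)
        if t_hit is not None and (best is None or t_hit < best[1]):
            best = (trap.trap_id, t_hit)
    if best is None:
        return replace(traj, verdict="no_intersection", first_intersection=None)
    t_vert = traj.times.astype("datetime64[s]").astype("int64").astype(float)
    before = t_vert < best[1] - 1e-9
    hit = (best[0], np.datetime64(int(best[1]), "s"))
    if np.any(traj.temps[before] < p.t_min):
        return replace(traj, verdict="discarded_cold", first_intersection=hit)
    if np.any(traj.alts[before] < p.alt_min):
        return replace(traj, verdict="discarded_low", first_intersection=hit)
    return replace(traj, verdict="retained", first_intersection=hit)


# -- I/O -------------------------------------------------------------------


def read_traps(path: str | Path) -> list[Trap]:
    """Traps CSV: columns id, lat, lon, optional radius_km."""
    df = pd.read_csv(path)
    for col in ("id", "lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"traps CSV is missing column {col!r}")
    return [Trap(trap_id=str(r["id"]), lat=float(r["lat"]), lon=float(r["lon"]),
                 radius_km=float(r["radius_km"]) if "radius_km" in df.columns
                 and np.isfinite(r.get("radius_km", np.nan)) else None)
            for _, r in df.iterrows()]


def verdict_table(trajs) -> pd.DataFrame:
    """One row per trajectory: release metadata, verdict, intersection."""
    rows = []
    for k, tr in enumerate(trajs):
        rows.append({
            "traj_id": k,
            "release_lat": tr.release.lat, "release_lon": tr.release.lon,
            "release_alt_m": tr.release.alt_m, "release_time": str(tr.release.time),
            "release_row": tr.release.cell[0] if tr.release.cell else np.nan,
            "release_col": tr.release.cell[1] if tr.release.cell else np.nan,
            "n_vertices": len(tr), "verdict": tr.verdict,
            "trap_id": tr.first_intersection[0] if tr.first_intersection else "",
            "t_intersect": str(tr.first_intersection[1]) if tr.first_intersection else "",
        })
    return pd.DataFrame(rows)


def trajectories_to_geojson(trajs, path: str | Path, decimate: int = 1) -> Path:
    """Write trajectories as GeoJSON LineStrings with per-vertex properties."""
    feats = []
    for k, tr in enumerate(trajs):
        sl = slice(None, None, max(1, decimate))
        feats.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[round(float(lo), 6), round(float(la), 6)]
                                for lo, la in zip(tr.lons[sl], tr.lats[sl])],
            },
            "properties": {
                "traj_id": k, "verdict": tr.verdict,
                "release_time": str(tr.release.time),
                "release_alt_m": tr.release.alt_m,
                "times": [str(t) for t in tr.times[sl]],
                "temps_c": [round(float(x), 2) for x in tr.temps[sl]],
                "alts_m": [float(x) for x in tr.alts[sl]],
            },
        })
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    return path
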