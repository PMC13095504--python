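"""Gridded time-varying wind and temperature fields.

A :class:`WindField` carries eastward/northward wind components (m/s) and
air temperature (°C, at a reference altitude) on the landscape grid at a
strictly increasing sequence of times. Temperature at flight altitude is
obtained with a fixed lapse-rate adjustment (default −6.5 °C/km), since a
horizontal temperature field alone does not determine the vertical profile.

Serialization follows NetCDF conventions (dims time, y, x; variables
u, v, T) via xarray.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

from .raster import Raster

__all__ = ["WindField", "read_windfield", "write_windfield"]

DEFAULT_LAPSE_RATE = -6.5  # °C per km of altitude above the reference level


@dataclass
class WindField:
    """Time-varying (u, v, T) fields on a shared geographic grid."""

    times: np.ndarray          # datetime64[s], strictly increasing
    u: np.ndarray              # (nt, ny, nx) eastward wind, m/s
    v: np.ndarray              # (nt, ny, nx) northward wind, m/s
    T: np.ndarray              # (nt, ny, nx) temperature at ref altitude, °C
    grid: Raster               # geometry template (values unused)
    lapse_rate: float = DEFAULT_LAPSE_RATE   # °C/km
    ref_alt_m: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        nt = len(self.times)
        ny, nx = self.grid.shape
        for name in ("u", "v", "T"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (nt, ny, nx):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(nt, ny, nx)}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if nt < 2 or np.any(np.diff(self.times.astype("int64")) <= 0):
            raise ValueError("times must be strictly increasing with length >= 2")

    @property
    def t_seconds(self) -> np.ndarray:
        """Times as seconds since the first frame."""
        return (self.times - self.times[0]).astype("timedelta64[s]").astype(float)

    def covers(self, t: np.datetime64) -> bool:
        t = np.datetime64(t, "s")
        return self.times[0] <= t <= self.times[-1]

    def temperature_at_altitude(self, T_ref: np.ndarray | float, alt_m: float):
        """Lapse-rate adjusted temperature at ``alt_m``."""
        return T_ref + self.lapse_rate * (alt_m - self.ref_alt_m) / 1000.0


def write_windfield(wf: WindField, path: str | Path) -> Path:
    path = Path(path)
    ds = xr.Dataset(
        {
            "u": (("time", "y", "x"), wf.u.astype(np.float32)),
            "v": (("time", "y", "x"), wf.v.astype(np.float32)),
            "T": (("time", "y", "x"), wf.T.astype(np.float32)),
        },
        coords={
            "time": wf.times,
            "lat": ("y", wf.grid.lats),
            "lon": ("x", wf.grid.lons),
        },
        attrs={
            "lapse_rate": wf.lapse_rate,
            "ref_alt_m": wf.ref_alt_m,
            "lat0": wf.grid.lat0, "lon0": wf.grid.lon0,
            "dlat": wf.grid.dlat, "dlon": wf.grid.dlon,
            "crs": wf.grid.crs,
        },
    )
    ds.to_netcdf(path, engine="scipy")  # NetCDF3 classic
    return path


def read_windfield(path: str | Path) -> WindField:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    ny, nx = ds.sizes["y"], ds.sizes["x"]
    grid = Raster(
        np.zeros((ny, nx)),
        lat0=float(ds.attrs["lat0"]), lon0=float(ds.attrs["lon0"]),
        dlat=float(ds.attrs["dlat"]), dlon=float(ds.attrs["dlon"]),
        crs=str(ds.attrs.get("crs", "EPSG:4326")),
    )
    return WindField(
        times=ds["time"].values,
        u=ds["u"].values.astype(float),
        v=ds["v"].values.astype(float),
        T=ds["T"].values.astype(float),
        grid=grid,
        lapse_rate=float(ds.attrs.get("lapse_rate", DEFAULT_LAPSE_RATE)),
        ref_alt_m=float(ds.attrs.get("ref_alt_m", 0.0)),
    )
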