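"""Georeferenced raster grids.

A :class:`Raster` is the carrier for every gridded quantity in the package:
environmental covariates, isoscape mean and uncertainty, posterior
probability surfaces, and defoliation masks. Grids are geographic (WGS84
lat/lon), north-up, cell-center registered, with row 0 the northernmost row.
Nodata is represented internally as NaN.

I/O: GeoTIFF is the primary on-disk format (georeferencing written as
ModelPixelScale / ModelTiepoint / GeoKeyDirectory TIFF tags, readable by
GDAL-based stacks); an ESRI ASCII-grid fallback with a JSON sidecar is
provided for fully text-based workflows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Raster", "read_raster", "write_raster"]

# TIFF tag codes for geo-registration
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

#: GeoKeyDirectory declaring a geographic (lat/lon) CRS on EPSG:4326,
#: pixel-is-area raster space.
_GEOKEYS_4326 = (
    1, 1, 0, 3,
    1024, 0, 1, 2,      # GTModelTypeGeoKey = geographic
    1025, 0, 1, 1,      # GTRasterTypeGeoKey = PixelIsArea
    2048, 0, 1, 4326,   # GeographicTypeGeoKey = WGS84
)


@dataclass
class Raster:
    """A 2-D grid of values with geographic registration.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata cells.
    lat0, lon0
        North and west edges of the grid (degrees).
    dlat, dlon
        Cell height and width in degrees (both positive; rows run south).
    crs
        CRS tag; only ``"EPSG:4326"`` is supported.
    units
        Free-text unit tag (e.g. ``"permil VCDT"``, ``"km"``).
    """

    values: np.ndarray
    lat0: float
    lon0: float
    dlat: float
    dlon: float
    crs: str = "EPSG:4326"
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.dlat <= 0 or self.dlon <= 0:
            raise ValueError("cell sizes must be positive (north-up convention)")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes per row (north to south)."""
        n = self.shape[0]
        return self.lat0 - (np.arange(n) + 0.5) * self.dlat

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes per column (west to east)."""
        n = self.shape[1]
        return self.lon0 + (np.arange(n) + 0.5) * self.dlon

    def latlon_of(self, row: int | np.ndarray, col: int | np.ndarray):
        lat = self.lat0 - (np.asarray(row) + 0.5) * self.dlat
        lon = self.lon0 + (np.asarray(col) + 0.5) * self.dlon
        return lat, lon

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises if off-grid."""
        row = int(math.floor((self.lat0 - lat) / self.dlat))
        col = int(math.floor((lon - self.lon0) / self.dlon))
        nr, nc = self.shape
        if not (0 <= row < nr and 0 <= col < nc):
            raise ValueError(f"point ({lat}, {lon}) falls outside the grid")
        return row, col

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of valid (finite) cells."""
        return np.isfinite(self.values)

    def congruent_with(self, other: "Raster") -> bool:
        """Exact grid congruence: shape, geotransform and CRS all match."""
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and math.isclose(self.lat0, other.lat0, rel_tol=0, abs_tol=1e-9)
            and math.isclose(self.lon0, other.lon0, rel_tol=0, abs_tol=1e-9)
            and math.isclose(self.dlat, other.dlat, rel_tol=1e-12, abs_tol=1e-12)
            and math.isclose(self.dlon, other.dlon, rel_tol=1e-12, abs_tol=1e-12)
        )

    def require_congruent(self, other: "Raster", what: str = "raster") -> None:
        if not self.congruent_with(other):
            raise ValueError(f"{what} grid is not congruent (shape/geotransform/CRS must match)")

    def like(self, values: np.ndarray, units: str | None = None) -> "Raster":
        """A new raster on this grid carrying ``values``."""
        if np.shape(values) != self.shape:
            raise ValueError("values shape does not match grid")
        out = replace(self, values=np.asarray(values, dtype=float))
        if units is not None:
            out.units = units
        out.meta = dict(self.meta)
        return out


# -- I/O -------------------------------------------------------------------


def write_raster(rast: Raster, path: str | Path, nodata: float = -9999.0) -> Path:
    """Write a raster to GeoTIFF (``.tif``/``.tiff``) or ESRI ASCII (``.asc``).

    float32 storage; nodata cells written as ``nodata``. ASCII output gains a
    ``<name>.asc.json`` sidecar carrying the full geotransform (the ASCII
    header only holds a single square cell size) plus units and CRS.
    """
    path = Path(path)
    vals = rast.values.astype(np.float32)
    vals = np.where(np.isfinite(vals), vals, np.float32(nodata))
    if path.suffix.lower() in (".tif", ".tiff"):
        desc = json.dumps({"units": rast.units, "crs": rast.crs})
        extratags = [
            (_MODEL_PIXEL_SCALE, "d", 3, (rast.dlon, rast.dlat, 0.0)),
            (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, rast.lon0, rast.lat0, 0.0)),
            (_GEO_KEY_DIRECTORY, "H", len(_GEOKEYS_4326), _GEOKEYS_4326),
            (_GDAL_NODATA, "s", 0, str(nodata)),
        ]
        tifffile.imwrite(path, vals, extratags=extratags, description=desc)
    elif path.suffix.lower() == ".asc":
        nr, nc = rast.shape
        header = (
            f"ncols {nc}\nnrows {nr}\n"
            f"xllcorner {rast.lon0!r}\nyllcorner {rast.lat0 - nr * rast.dlat!r}\n"
            f"cellsize {rast.dlat!r}\nNODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.9g")  # 9 sig. digits round-trip float32
        sidecar = {
            "lat0": rast.lat0, "lon0": rast.lon0, "dlat": rast.dlat,
            "dlon": rast.dlon, "crs": rast.crs, "units": rast.units,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r} (use .tif or .asc)")
    return path


def read_raster(path: str | Path) -> Raster:
    """Read a GeoTIFF or ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            vals = page.asarray().astype(float)
            tags = page.tags
            scale = tags[_MODEL_PIXEL_SCALE].value
            tie = tags[_MODEL_TIEPOINT].value
            nodata = float(tags[_GDAL_NODATA].value) if _GDAL_NODATA in tags else -9999.0
            desc = tags.get("ImageDescription")
            units, crs = "", "EPSG:4326"
            if desc is not None:
                try:
                    d = json.loads(desc.value)
                    units, crs = d.get("units", ""), d.get("crs", crs)
                except (ValueError, TypeError):
                    pass
        vals[vals == nodata] = np.nan
        return Raster(vals, lat0=float(tie[4]), lon0=float(tie[3]),
                      dlat=float(scale[1]), dlon=float(scale[0]), crs=crs, units=units)
    if path.suffix.lower() == ".asc":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals).astype(np.float32).astype(float)
        nodata = hdr.get("nodata_value", -9999.0)
        vals[vals == nodata] = np.nan
        dlat = dlon = hdr["cellsize"]
        lat0 = hdr["yllcorner"] + hdr["nrows"] * dlat
        lon0 = hdr["xllcorner"]
        units, crs = "", "EPSG:4326"
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            d = json.loads(sidecar.read_text())
            lat0, lon0 = d["lat0"], d["lon0"]
            dlat, dlon = d["dlat"], d["dlon"]
            units, crs = d.get("units", ""), d.get("crs", crs)
        return Raster(vals, lat0=lat0, lon0=lon0, dlat=dlat, dlon=dlon, crs=crs, units=units)
    raise ValueError(f"unsupported raster format: {path.suffix!r} (use .tif or .asc)")
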