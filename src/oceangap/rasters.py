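"""Regular latitude-longitude rasters.

A :class:`Raster` is a regular global (or regional) grid of values indexed by
latitude row and longitude column, stored with latitude ascending.  It is the
in-memory form of bathymetry and environmental covariate layers (temperature,
nitrate, O2, productivity, radiation, current velocity, ice cover, human
influence).  I/O covers the ESRI ASCII grid text format and, optionally,
NetCDF3 files with ``lat``/``lon`` axes (read through xarray's scipy backend).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "Raster",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_netcdf",
    "read_raster",
    "cell_areas_km2",
]


@dataclass
class Raster:
    """A regular lat/lon grid.

    values[i, j] is the cell centred at ``(lat_min + (i + 0.5) * res,
    lon_min + (j + 0.5) * res)``; latitude ascends with ``i``.  Missing data
    is NaN.
    """

    values: np.ndarray            # (nrows, ncols) float, NaN = nodata
    lat_min: float = -90.0
    lon_min: float = -180.0
    resolution: float = 1.0       # degrees, same in both axes
    realm: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.nrows) + 0.5) * self.resolution

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncols) + 0.5) * self.resolution

    def index_of(self, lat, lon):
        """Row/column of the cell containing each point.

        Half-open cells: a point on a shared edge belongs to the cell with
        the larger index (floor convention).  The top latitude edge and the
        right longitude edge are clamped into the last cell so the poles and
        lon = lon_max remain addressable.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        j = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        i_ok = (i >= 0) & (i <= self.nrows)
        j_ok = (j >= 0) & (j <= self.ncols)
        if not (np.all(i_ok) and np.all(j_ok)):
            raise ValueError("point outside raster domain")
        i = np.clip(i, 0, self.nrows - 1)
        j = np.clip(j, 0, self.ncols - 1)
        return i, j

    def sample(self, lat, lon):
        """Value of the cell containing each point (NaN where nodata)."""
        i, j = self.index_of(lat, lon)
        return self.values[i, j]

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(values=np.asarray(values, dtype=float),
                      lat_min=self.lat_min, lon_min=self.lon_min,
                      resolution=self.resolution, realm=self.realm)


def cell_areas_km2(raster: Raster, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Spherical area of every raster cell in km².

    Area of a lat/lon quad on a sphere: R² * dlon * (sin(lat2) - sin(lat1)).
    Returned as (nrows, ncols); constant along rows.
    """
    res = np.deg2rad(raster.resolution)
    lat_lower = np.deg2rad(raster.lat_min + np.arange(raster.nrows) * raster.resolution)
    band = radius_km ** 2 * res * (np.sin(lat_lower + np.deg2rad(raster.resolution)) - np.sin(lat_lower))
    return np.repeat(band[:, None], raster.ncols, axis=1)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_NODATA = -9999.0


def write_esri_ascii(raster: Raster, path: str | Path) -> None:
    """Write in the plain-text ESRI ASCII grid format (rows north to south)."""
    vals = np.flipud(raster.values)  # file stores northernmost row first
    out = np.where(np.isfinite(vals), vals, _NODATA)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.lon_min:.10g}\n"
        f"yllcorner {raster.lat_min:.10g}\n"
        f"cellsize {raster.resolution:.10g}\n"
        f"NODATA_value {_NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_esri_ascii(path: str | Path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "xllcenter", "yllcenter"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, ndmin=2)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    res = header["cellsize"]
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid body {data.shape} does not match header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    lon_min = header.get("xllcorner", header.get("xllcenter", 0.0) - res / 2)
    lat_min = header.get("yllcorner", header.get("yllcenter", 0.0) - res / 2)
    return Raster(values=np.flipud(data), lat_min=lat_min, lon_min=lon_min, resolution=res)


def read_netcdf(path: str | Path, var: str | None = None) -> Raster:
    """Read a NetCDF3 raster with regular ``lat``/``lon`` coordinate axes.

    Latitude is flipped to ascending if stored descending.  Requires xarray
    (scipy backend); raises a clear error when the spacing is irregular.
    """
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    try:
        if var is None:
            cands = [v for v in ds.data_vars if ds[v].ndim == 2]
            if len(cands) != 1:
                raise ValueError(f"specify var=; candidates: {cands}")
            var = cands[0]
        da = ds[var]
        lat_name = "lat" if "lat" in da.dims else "latitude"
        lon_name = "lon" if "lon" in da.dims else "longitude"
        da = da.transpose(lat_name, lon_name)
        lat = np.asarray(da[lat_name])
        lon = np.asarray(da[lon_name])
        vals = np.asarray(da, dtype=float)
    finally:
        ds.close()
    if lat[0] > lat[-1]:
        lat = lat[::-1]
        vals = np.flipud(vals)
    dlat = np.diff(lat)
    dlon = np.diff(lon)
    if dlat.size == 0 or dlon.size == 0:
        raise ValueError("raster must have at least 2 rows and columns")
    if not (np.allclose(dlat, dlat[0], rtol=1e-6) and np.allclose(dlon, dlon[0], rtol=1e-6)
            and np.isclose(dlat[0], dlon[0], rtol=1e-6)):
        raise ValueError("irregular lat/lon spacing")
    res = float(dlat[0])
    return Raster(values=vals, lat_min=float(lat[0]) - res / 2,
                  lon_min=float(lon[0]) - res / 2, resolution=res)


def read_raster(path: str | Path, var: str | None = None) -> Raster:
    """Dispatch on file suffix: ``.asc`` → ESRI ASCII, ``.nc`` → NetCDF."""
    p = Path(path)
    if p.suffix.lower() in {".nc", ".cdf", ".netcdf"}:
        return read_netcdf(p, var=var)
    return read_esri_ascii(p)
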