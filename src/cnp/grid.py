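"""Gridding: project county rates onto rasters and write GeoTIFFs.

County membership of a pixel comes from a supplied county-ID raster
(never re-derived from polygon geometry), and a crop growing-area mask
selects the pixels that actually grow the crop; everything else is
NoData.  Rasters are north-up WGS84 (EPSG:4326) grids with a
pixel-center convention for coordinate lookups.

GeoTIFFs are written through :mod:`tifffile` with the standard GeoTIFF
tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory with the EPSG
geographic key, and the GDAL NoData tag), single-band Float32, NoData
-9999.0, and the dataset naming convention ``CNP_<crop>_<year>.tif``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import GridMismatchError, SchemaError
from .tables import CountyRates, Status

NODATA = -9999.0

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKeyDirectory: version 1.1.0, 3 keys: model=geographic(2),
# raster=PixelIsArea(1), geographic CRS = EPSG:4326
_WGS84_GEOKEYS = (1, 1, 0, 3,
                  1024, 0, 1, 2,
                  1025, 0, 1, 1,
                  2048, 0, 1, 4326)


@dataclass(frozen=True)
class GridGeometry:
    """North-up geographic grid: origin is the outer corner of pixel (0, 0)."""

    west: float
    north: float
    pixel_size: float
    rows: int
    cols: int

    def __eq__(self, other):
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (self.rows == other.rows and self.cols == other.cols
                and np.isclose(self.west, other.west)
                and np.isclose(self.north, other.north)
                and np.isclose(self.pixel_size, other.pixel_size))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def pixel_center(self, row, col):
        """Longitude/latitude of a pixel center."""
        lon = self.west + (np.asarray(col) + 0.5) * self.pixel_size
        lat = self.north - (np.asarray(row) + 0.5) * self.pixel_size
        return lon, lat


@dataclass
class RateMap:
    """One crop-year grid of P2O5 rates (g/m2), NoData outside the crop."""

    values: np.ndarray
    geom: GridGeometry
    crop: str
    year: int
    nodata: float = NODATA
    n_unknown_county: int = 0

    @property
    def finite_mask(self) -> np.ndarray:
        return self.values != np.float32(self.nodata)

    def filename(self) -> str:
        return f"CNP_{self.crop}_{self.year}.tif"


def _check_geometry(a_shape, geom: GridGeometry, what: str) -> None:
    if tuple(a_shape) != geom.shape:
        raise GridMismatchError(f"{what}: array shape {a_shape} != grid {geom.shape}")


def rasterize_rates(
    rates: CountyRates,
    county_raster: np.ndarray,
    crop_mask: np.ndarray,
    geom: GridGeometry,
    crop: str,
    year: int,
) -> RateMap:
    """Paint each crop pixel with its county's P2O5 rate for one year.

    ``county_raster`` holds integer county ids (values <= 0 mean no
    county); ``crop_mask`` is a boolean presence grid of identical
    geometry.  Pixels whose county has no defined rate — dropped
    records, or county ids absent from the table — come out NoData; the
    absent-id pixels are additionally counted in ``n_unknown_county``.
    """
    if rates.p2o5 is None:
        raise SchemaError("rasterize_rates needs a converted table (p2o5 set)")
    _check_geometry(county_raster.shape, geom, "county raster")
    if crop_mask.shape != county_raster.shape:
        raise GridMismatchError(
            f"crop mask shape {crop_mask.shape} != county raster "
            f"{county_raster.shape}")

    sel = rates.p2o5
    sel = sel[(sel["crop"] == crop) & (sel["year"] == year)
              & (sel["status"] != Status.DROPPED) & sel["p2o5_rate"].notna()]
    ids = sel["county"].to_numpy()
    if len(ids) and not np.issubdtype(np.asarray(ids).dtype, np.integer):
        raise SchemaError("gridding requires integer county ids")

    max_id = int(max(county_raster.max(), ids.max() if len(ids) else 0))
    lut = np.full(max_id + 1, NODATA, dtype=np.float32)
    known = np.zeros(max_id + 1, dtype=bool)
    if len(ids):
        lut[ids] = sel["p2o5_rate"].to_numpy(dtype=np.float32)
        known[ids] = True

    county = np.clip(county_raster, 0, max_id)
    in_county = county_raster > 0
    active = np.asarray(crop_mask, bool) & in_county
    values = np.full(geom.shape, NODATA, dtype=np.float32)
    values[active] = lut[county[active]]
    n_unknown = int((active & ~known[county]).sum())
    return RateMap(values=values, geom=geom, crop=crop, year=int(year),
                   n_unknown_county=n_unknown)


def _extratags(geom: GridGeometry, nodata) -> list:
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, (geom.pixel_size, geom.pixel_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geom.west, geom.north, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS),
        (_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]


def write_grid(
    array: np.ndarray, geom: GridGeometry, path: str | Path,
    nodata: float = NODATA,
) -> Path:
    """Write any single-band array as a WGS84 GeoTIFF."""
    _check_geometry(array.shape, geom, "write_grid")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, array, extratags=_extratags(geom, nodata))
    return path


def read_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry, float]:
    """Read a GeoTIFF written by :func:`write_grid`; returns array, geometry, nodata."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        try:
            scale = page.tags[_MODEL_PIXEL_SCALE].value
            tie = page.tags[_MODEL_TIEPOINT].value
        except KeyError:
            raise SchemaError(f"{path}: not a georeferenced TIFF") from None
        nodata_tag = page.tags.get(_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else NODATA
    geom = GridGeometry(west=float(tie[3]), north=float(tie[4]),
                        pixel_size=float(scale[0]),
                        rows=arr.shape[0], cols=arr.shape[1])
    return arr, geom, nodata


_NAME_RE = re.compile(r"^CNP_(?P<crop>[a-z]+)_(?P<year>\d{4})\.tif$")


def write_ratemap(ratemap: RateMap, directory: str | Path) -> Path:
    """Write one rate map as ``CNP_<crop>_<year>.tif`` in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return write_grid(ratemap.values.astype(np.float32), ratemap.geom,
                      directory / ratemap.filename(), nodata=ratemap.nodata)


def read_ratemap(path: str | Path) -> RateMap:
    """Read a ``CNP_<crop>_<year>.tif`` back into a :class:`RateMap`."""
    path = Path(path)
    m = _NAME_RE.match(path.name)
    if not m:
        raise SchemaError(f"{path.name}: not a CNP_<crop>_<year>.tif filename")
    arr, geom, nodata = read_grid(path)
    return RateMap(values=arr, geom=geom, crop=m["crop"], year=int(m["year"]),
                   nodata=nodata)
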