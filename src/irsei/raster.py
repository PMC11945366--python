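"""Geospatial data model and raster I/O.

Rasters are plain numpy grids with an axis-aligned affine georeference,
read from and written to GeoTIFF via :mod:`tifffile` using the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the
GDAL_NODATA convention.  Grids are row-major with (row, col) indexing and
pixel-center registration; north-up transforms only (no rotation terms).

The sensor model maps semantic band names (BLUE .. SWIR2, THERMAL) to file
band indices and carries the sensor-specific tasselled-cap wetness
coefficients and thermal calibration constants.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError, ContractError, DataError

__all__ = [
    "Affine",
    "SensorProfile",
    "ThermalConstants",
    "Scene",
    "IndicatorRaster",
    "LandCoverMap",
    "DEFAULT_LEGEND",
    "builtin_profile",
    "load_profile",
    "read_scene",
    "read_indicator",
    "write_indicator",
    "read_landcover",
    "write_landcover",
    "write_multiband",
]

OPTICAL_BANDS = ("BLUE", "GREEN", "RED", "NIR", "SWIR1", "SWIR2")

# Table-2 classes, codes 1..8 in table order.
DEFAULT_LEGEND: dict[int, str] = {
    1: "cultivated land",
    2: "forest",
    3: "water",
    4: "grassland",
    5: "shrubland",
    6: "bare land",
    7: "aquaculture pond",
    8: "artificial surface",
}

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Affine:
    """North-up affine georeference: world = origin + pixel * size.

    ``a`` is the pixel width, ``e`` the (negative) pixel height, ``c``/``f``
    the world coordinates of the outer corner of pixel (0, 0).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "Affine":
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    @property
    def pixel_width(self) -> float:
        return abs(self.a)

    @property
    def pixel_height(self) -> float:
        return abs(self.e)

    def xy(self, row: float, col: float, offset: str = "center") -> tuple[float, float]:
        """World coordinates of a (row, col) pixel (center by default)."""
        shift = 0.5 if offset == "center" else 0.0
        x = self.c + (col + shift) * self.a + (row + shift) * self.b
        y = self.f + (col + shift) * self.d + (row + shift) * self.e
        return x, y

    def index(self, x: float, y: float) -> tuple[int, int]:
        """Pixel (row, col) containing world point (x, y)."""
        col = (x - self.c) / self.a
        row = (y - self.f) / self.e
        return int(math.floor(row)), int(math.floor(col))

    def pixel_area_km2(self) -> float:
        return self.pixel_width * self.pixel_height / 1e6


@dataclass(frozen=True)
class ThermalConstants:
    """Single-channel thermal calibration: DN -> radiance -> temperature.

    gain/bias convert digital numbers to at-sensor spectral radiance;
    K1 (radiance) and K2 (kelvin) invert Planck's law for the band;
    wavelength_m is the band effective wavelength; rho = h*c/sigma is
    fixed at 1.438e-2 m K; emissivity corrects brightness temperature
    to surface temperature.
    """

    gain: float
    bias: float
    K1: float
    K2: float
    wavelength_m: float
    emissivity: float = 0.95
    rho: float = 1.438e-2

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0:
            raise ConfigurationError("thermal calibration requires K1 > 0 and K2 > 0")
        if self.wavelength_m <= 0:
            raise ConfigurationError("wavelength_m must be positive")
        if not (0.0 < self.emissivity <= 1.0):
            raise ConfigurationError("emissivity must lie in (0, 1]")


@dataclass(frozen=True)
class SensorProfile:
    """Sensor description: band layout, wetness coefficients, thermal constants.

    ``band_map`` maps semantic band names to 1-based file band indices.
    ``wet_coefficients`` are ordered (BLUE, GREEN, RED, NIR, SWIR1, SWIR2).
    ``reflectance_scale`` divides stored pixel values to reach [0, 1]
    reflectance (1.0 for float files, 10000.0 for integer-scaled products).
    """

    name: str
    band_map: Mapping[str, int]
    wet_coefficients: tuple[float, ...]
    thermal_calibration: Optional[ThermalConstants] = None
    reflectance_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.wet_coefficients) != 6:
            raise ConfigurationError(
                f"wet_coefficients must have 6 entries, got {len(self.wet_coefficients)}"
            )
        indices = list(self.band_map.values())
        if any(i < 1 for i in indices):
            raise ConfigurationError("band indices are 1-based and must be positive")
        if len(set(indices)) != len(indices):
            raise ConfigurationError("band_map indices must be distinct")
        if self.reflectance_scale <= 0:
            raise ConfigurationError("reflectance_scale must be positive")

    def require_bands(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.band_map]
        if missing:
            raise ConfigurationError(f"sensor profile {self.name!r} lacks bands: {missing}")


def _canonical_band_map(thermal: bool) -> dict[str, int]:
    m = {name: i + 1 for i, name in enumerate(OPTICAL_BANDS)}
    if thermal:
        m["THERMAL"] = 7
    return m


# Sensor-specific tasselled-cap wetness coefficient vectors,
# order (BLUE, GREEN, RED, NIR, SWIR1, SWIR2).
_WET_COEFFICIENTS: dict[str, tuple[float, ...]] = {
    "TM": (0.03, 0.22, 0.29, 0.17, -0.68, -0.58),
    "OLI": (0.16, 0.20, 0.32, 0.35, -0.70, -0.45),
    "S2": (0.15, 0.18, 0.34, 0.33, -0.72, -0.48),
}


def builtin_profile(name: str) -> SensorProfile:
    """Built-in profile for Landsat TM, Landsat OLI or Sentinel-2 MSI.

    Band maps follow the package's canonical layout (file bands 1..6 =
    BLUE..SWIR2, band 7 thermal where the sensor has one); mission-specific
    layouts are supplied through :func:`load_profile`.
    """
    key = name.upper()
    if key not in _WET_COEFFICIENTS:
        raise ConfigurationError(f"unknown sensor profile {name!r}; choose from TM, OLI, S2")
    has_thermal = key in ("TM", "OLI")
    return SensorProfile(
        name=key,
        band_map=_canonical_band_map(thermal=has_thermal),
        wet_coefficients=_WET_COEFFICIENTS[key],
        thermal_calibration=None,
        reflectance_scale=1.0,
    )


def load_profile(path: str | Path) -> SensorProfile:
    """Load a SensorProfile from a YAML file.

    Expected keys: name, band_map, wet_coefficients (6 reals,
    BLUE..SWIR2 order), optional thermal_calibration (gain, bias, K1, K2,
    wavelength_m, emissivity), optional reflectance_scale.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"profile file {path} is not a YAML mapping")
    known = {"name", "band_map", "wet_coefficients", "thermal_calibration", "reflectance_scale"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigurationError(f"unknown profile keys: {sorted(unknown)}")
    thermal = None
    if cfg.get("thermal_calibration") is not None:
        thermal = ThermalConstants(**cfg["thermal_calibration"])
    try:
        return SensorProfile(
            name=str(cfg["name"]),
            band_map={str(k).upper(): int(v) for k, v in cfg["band_map"].items()},
            wet_coefficients=tuple(float(v) for v in cfg["wet_coefficients"]),
            thermal_calibration=thermal,
            reflectance_scale=float(cfg.get("reflectance_scale", 1.0)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"profile file {path} missing key {exc}") from exc


@dataclass
class Scene:
    """Multiband reflectance scene with optional thermal DN band.

    ``reflectance`` maps semantic band names to float grids in [0, ~1.5];
    ``nodata_mask`` is True where any required band is missing or invalid.
    """

    reflectance: dict[str, np.ndarray]
    transform: Affine
    crs: int
    nodata_mask: np.ndarray
    sensor: SensorProfile
    thermal_dn: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.reflectance.values()}
        if self.thermal_dn is not None:
            shapes.add(self.thermal_dn.shape)
        shapes.add(self.nodata_mask.shape)
        if len(shapes) != 1:
            raise ContractError(f"scene band grids disagree in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nodata_mask.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def band(self, name: str) -> np.ndarray:
        if name not in self.reflectance:
            raise ConfigurationError(f"scene has no {name!r} band")
        return self.reflectance[name]


@dataclass
class IndicatorRaster:
    """Single-band float indicator with a polarity tag.

    polarity "benefit": higher is ecologically better (greenness, wetness);
    polarity "cost": higher is worse (dryness, heat, land-use intensity).
    Invalid cells are NaN in ``values`` and False in ``valid_mask``.
    """

    values: np.ndarray
    polarity: str
    valid_mask: np.ndarray
    name: str = ""
    transform: Optional[Affine] = None
    crs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.polarity not in ("benefit", "cost"):
            raise ConfigurationError(f"polarity must be 'benefit' or 'cost', got {self.polarity!r}")
        if self.values.shape != self.valid_mask.shape:
            raise ContractError("values and valid_mask shapes differ")

    def masked(self) -> np.ndarray:
        """Valid values as a 1-D array."""
        return self.values[self.valid_mask]


@dataclass
class LandCoverMap:
    """Integer-coded categorical raster with legend and pixel-area accounting.

    Code 0 is reserved for nodata.
    """

    codes: np.ndarray
    legend: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    pixel_area_km2: float = 0.0009  # 30 m pixels
    transform: Optional[Affine] = None
    crs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pixel_area_km2 <= 0:
            raise ConfigurationError("pixel_area_km2 must be positive")
        present = set(np.unique(self.codes).tolist()) - {0}
        unknown = present - set(self.legend)
        if unknown:
            raise DataError(f"land-cover codes without legend entry: {sorted(unknown)}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != 0


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _geo_tags(transform: Affine, crs: Optional[int], nodata: Optional[float]) -> list:
    if transform.b != 0.0 or transform.d != 0.0:
        raise ConfigurationError("only north-up (axis-aligned) transforms are supported")
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (transform.pixel_width, transform.pixel_height, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.c, transform.f, 0.0), True),
    ]
    if crs is not None:
        # Minimal GeoKeyDirectory: projected model, EPSG code.
        keys = (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, int(crs))
        tags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(keys), keys, True))
    if nodata is not None:
        txt = repr(int(nodata)) if float(nodata).is_integer() else repr(float(nodata))
        tags.append((_TAG_GDAL_NODATA, "s", 0, txt, True))
    return tags


def _read_geo(page: "tifffile.TiffPage") -> tuple[Affine, Optional[int], Optional[float]]:
    scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
    tiepoint = page.tags.get(_TAG_MODEL_TIEPOINT)
    if scale is not None and tiepoint is not None:
        sx, sy = scale.value[0], scale.value[1]
        i, j, _, x, y, _ = tiepoint.value[:6]
        # tiepoint anchors raster point (i, j) at world (x, y)
        transform = Affine(sx, 0.0, x - i * sx, 0.0, -sy, y + j * sy)
    else:
        transform = Affine.from_origin(0.0, float(page.imagelength), 1.0, 1.0)
    crs: Optional[int] = None
    geokeys = page.tags.get(_TAG_GEO_KEY_DIRECTORY)
    if geokeys is not None:
        v = geokeys.value
        for k in range(4, len(v), 4):
            if v[k] in (3072, 2048) and v[k + 1] == 0:
                crs = int(v[k + 3])
                break
    nodata = None
    nd = page.tags.get(_TAG_GDAL_NODATA)
    if nd is not None:
        try:
            nodata = float(nd.value)
        except ValueError:
            nodata = None
    return transform, crs, nodata


def write_multiband(
    path: str | Path,
    bands: np.ndarray,
    transform: Affine,
    crs: Optional[int] = None,
    nodata: Optional[float] = None,
) -> None:
    """Write a (count, rows, cols) or (rows, cols) array as GeoTIFF."""
    arr = np.asarray(bands)
    kwargs = {}
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim == 3:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(
        str(path),
        arr,
        photometric="minisblack",
        extratags=_geo_tags(transform, crs, nodata),
        **kwargs,
    )


def _read_tiff(path: str | Path) -> tuple[np.ndarray, Affine, Optional[int], Optional[float]]:
    try:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            transform, crs, nodata = _read_geo(tf.pages[0])
    except (FileNotFoundError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[0] > arr.shape[2]:
        # interleaved (rows, cols, count) -> (count, rows, cols)
        arr = np.moveaxis(arr, -1, 0)
    return arr, transform, crs, nodata


def read_scene(path: str | Path, sensor: SensorProfile) -> Scene:
    """Read a multiband GeoTIFF into a Scene using the profile's band map.

    Reflectance is divided by the profile's ``reflectance_scale``; the
    nodata mask combines the file's declared nodata with non-finite values
    in any mapped optical band.
    """
    arr, transform, crs, nodata = _read_tiff(path)
    count = arr.shape[0]
    needed = max(sensor.band_map.values())
    if needed > count:
        raise ConfigurationError(
            f"profile {sensor.name!r} expects band index {needed} but file has {count} band(s)"
        )
    reflectance: dict[str, np.ndarray] = {}
    mask = np.zeros(arr.shape[1:], dtype=bool)
    for name, idx in sensor.band_map.items():
        band = arr[idx - 1].astype(np.float64)
        if nodata is not None:
            mask |= band == nodata
        mask |= ~np.isfinite(band)
        if name == "THERMAL":
            continue
        reflectance[name] = band / sensor.reflectance_scale
    thermal_dn = None
    if "THERMAL" in sensor.band_map:
        thermal_dn = arr[sensor.band_map["THERMAL"] - 1].astype(np.float64)
    return Scene(
        reflectance=reflectance,
        transform=transform,
        crs=crs if crs is not None else 0,
        nodata_mask=mask,
        sensor=sensor,
        thermal_dn=thermal_dn,
    )


_INDICATOR_NODATA = -9999.0


def write_indicator(r: IndicatorRaster, path: str | Path) -> None:
    """Write an indicator as a single-band float64 GeoTIFF with nodata."""
    out = np.array(r.values, dtype=np.float64, copy=True)
    out[~r.valid_mask] = _INDICATOR_NODATA
    out[~np.isfinite(out)] = _INDICATOR_NODATA
    transform = r.transform if r.transform is not None else Affine.from_origin(0, out.shape[0], 1, 1)
    write_multiband(path, out, transform, r.crs, nodata=_INDICATOR_NODATA)


def read_indicator(path: str | Path, polarity: str = "benefit", name: str = "") -> IndicatorRaster:
    """Read a single-band float GeoTIFF back into an IndicatorRaster."""
    arr, transform, crs, nodata = _read_tiff(path)
    values = arr[0].astype(np.float64)
    valid = np.isfinite(values)
    if nodata is not None:
        valid &= values != nodata
    values = np.where(valid, values, np.nan)
    return IndicatorRaster(values, polarity, valid, name=name, transform=transform, crs=crs)


def write_landcover(m: LandCoverMap, path: str | Path) -> None:
    transform = m.transform if m.transform is not None else Affine.from_origin(0, m.codes.shape[0], 1, 1)
    write_multiband(path, m.codes.astype(np.int32), transform, m.crs, nodata=0)


def read_landcover(
    path: str | Path,
    legend: Optional[Mapping[int, str]] = None,
    pixel_area_km2: Optional[float] = None,
) -> LandCoverMap:
    arr, transform, crs, _ = _read_tiff(path)
    codes = arr[0].astype(np.int64)
    if pixel_area_km2 is None:
        pixel_area_km2 = transform.pixel_area_km2()
    return LandCoverMap(
        codes=codes,
        legend=dict(legend) if legend is not None else dict(DEFAULT_LEGEND),
        pixel_area_km2=pixel_area_km2,
        transform=transform,
        crs=crs,
    )
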