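"""Spectral and thermal ecological indicators.

Greenness (NDVI/GNDVI), water (NDWI, AWEI), built-up (NDBI), tasselled-cap
wetness with sensor-specific coefficients, the modified dryness index
M-NDBSI built from the soil index SI and the index-based built-up index IBI,
and the single-channel land-surface-temperature chain
(DN -> radiance -> brightness temperature -> emissivity-corrected LST ->
min-max normalized heat indicator).

All operations propagate the scene's nodata mask: a cell is invalid in the
output whenever any contributing band is invalid, plus wherever the formula
itself degenerates (zero denominators, non-positive radiance).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, ContractError, DegenerateRangeError
from .raster import IndicatorRaster, Scene, ThermalConstants

__all__ = [
    "normalized_difference",
    "ndvi",
    "ndwi",
    "ndbi",
    "gndvi",
    "wet",
    "si",
    "ibi",
    "m_ndbsi",
    "awei",
    "radiance",
    "brightness_temperature",
    "lst",
    "tir_normalize",
]


def _ratio(num: np.ndarray, den: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """num/den with zero denominators masked out."""
    ok = valid & (den != 0) & np.isfinite(num) & np.isfinite(den)
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=ok)
    return out, ok


def _indicator(scene: Scene, values: np.ndarray, ok: np.ndarray, polarity: str, name: str) -> IndicatorRaster:
    values = np.where(ok, values, np.nan)
    return IndicatorRaster(values, polarity, ok, name=name, transform=scene.transform, crs=scene.crs)


def normalized_difference(
    a: np.ndarray, b: np.ndarray, valid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(a - b) / (a + b) per cell; returns (values, valid_mask).

    Cells where a + b == 0 become NaN/invalid.  On nonnegative inputs the
    result lies in [-1, 1].
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ContractError(f"band shapes differ: {a.shape} vs {b.shape}")
    if valid is None:
        valid = np.ones(a.shape, dtype=bool)
    return _ratio(a - b, a + b, valid)


def _nd_indicator(scene: Scene, plus: str, minus: str, polarity: str, name: str) -> IndicatorRaster:
    scene.sensor.require_bands([plus, minus])
    vals, ok = normalized_difference(scene.band(plus), scene.band(minus), scene.valid_mask)
    return _indicator(scene, vals, ok, polarity, name)


def ndvi(scene: Scene) -> IndicatorRaster:
    """Normalized difference vegetation index (NIR - RED)/(NIR + RED)."""
    return _nd_indicator(scene, "NIR", "RED", "benefit", "NDVI")


def ndwi(scene: Scene) -> IndicatorRaster:
    """Normalized difference water index (GREEN - NIR)/(GREEN + NIR)."""
    return _nd_indicator(scene, "GREEN", "NIR", "benefit", "NDWI")


def ndbi(scene: Scene) -> IndicatorRaster:
    """Normalized difference built-up index (SWIR1 - NIR)/(SWIR1 + NIR)."""
    return _nd_indicator(scene, "SWIR1", "NIR", "cost", "NDBI")


def gndvi(scene: Scene) -> IndicatorRaster:
    """Green NDVI (NIR - GREEN)/(NIR + GREEN): greenness input of the composite."""
    return _nd_indicator(scene, "NIR", "GREEN", "benefit", "GNDVI")


def wet(scene: Scene) -> IndicatorRaster:
    """Tasselled-cap wetness: dot product of the six optical bands with the
    sensor profile's coefficient vector (BLUE..SWIR2 order)."""
    from .raster import OPTICAL_BANDS

    scene.sensor.require_bands(OPTICAL_BANDS)
    coeffs = scene.sensor.wet_coefficients
    vals = np.zeros(scene.shape, dtype=np.float64)
    for c, band in zip(coeffs, OPTICAL_BANDS):
        vals = vals + c * scene.band(band)
    ok = scene.valid_mask & np.isfinite(vals)
    return _indicator(scene, vals, ok, "benefit", "WET")


def si(scene: Scene) -> IndicatorRaster:
    """Soil index (SWIR1 + RED - NIR - BLUE)/(SWIR1 + RED + NIR + BLUE), in [-1, 1]."""
    scene.sensor.require_bands(["SWIR1", "RED", "NIR", "BLUE"])
    s1, r, n, b = (scene.band(x) for x in ("SWIR1", "RED", "NIR", "BLUE"))
    vals, ok = _ratio(s1 + r - n - b, s1 + r + n + b, scene.valid_mask)
    return _indicator(scene, vals, ok, "cost", "SI")


def ibi(scene: Scene) -> IndicatorRaster:
    """Index-based built-up index (SWIR2 + SWIR1 + NIR)/(RED + GREEN + BLUE), >= 0."""
    scene.sensor.require_bands(["SWIR2", "SWIR1", "NIR", "RED", "GREEN", "BLUE"])
    s2, s1, n = (scene.band(x) for x in ("SWIR2", "SWIR1", "NIR"))
    r, g, b = (scene.band(x) for x in ("RED", "GREEN", "BLUE"))
    vals, ok = _ratio(s2 + s1 + n, r + g + b, scene.valid_mask)
    return _indicator(scene, vals, ok, "cost", "IBI")


def _minmax(vals: np.ndarray, ok: np.ndarray, what: str) -> np.ndarray:
    v = vals[ok]
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        raise DegenerateRangeError(f"{what} is constant over the valid mask; cannot normalize")
    return (vals - lo) / (hi - lo)


def m_ndbsi(
    si_r: IndicatorRaster, ibi_r: IndicatorRaster, dispersion_mode: str = "pixel"
) -> IndicatorRaster:
    """Modified dryness index: mean of normalized SI and IBI plus a dispersion term.

    SI and IBI are each min-max normalized to [0, 1] over the shared valid
    mask before combination (their native scales are incommensurate: SI is a
    normalized difference in [-1, 1], IBI an unbounded band ratio).

    dispersion_mode "pixel" adds the per-cell population standard deviation
    of the two normalized values, |SI' - IBI'| / 2, which makes the result
    identically max(SI', IBI'); mode "scene" adds one scalar, the population
    standard deviation of the pooled normalized values, uniformly.
    """
    if si_r.values.shape != ibi_r.values.shape:
        raise ContractError("SI and IBI rasters differ in shape")
    if dispersion_mode not in ("pixel", "scene"):
        raise ConfigurationError(f"dispersion_mode must be 'pixel' or 'scene', got {dispersion_mode!r}")
    ok = si_r.valid_mask & ibi_r.valid_mask
    if not ok.any():
        raise ContractError("SI and IBI share no valid cells")
    si_n = _minmax(si_r.values, ok, "SI")
    ibi_n = _minmax(ibi_r.values, ok, "IBI")
    mean = (si_n + ibi_n) / 2.0
    if dispersion_mode == "pixel":
        sigma = np.abs(si_n - ibi_n) / 2.0
    else:
        pooled = np.concatenate([si_n[ok], ibi_n[ok]])
        sigma = float(np.std(pooled))
    vals = np.where(ok, mean + sigma, np.nan)
    return IndicatorRaster(
        vals, "cost", ok, name="M-NDBSI", transform=si_r.transform, crs=si_r.crs
    )


def awei(scene: Scene) -> IndicatorRaster:
    """Automated water extraction index:
    4 (GREEN - SWIR1) - (0.25 NIR + 2.75 SWIR2); higher = more water-like."""
    scene.sensor.require_bands(["GREEN", "SWIR1", "NIR", "SWIR2"])
    g, s1, n, s2 = (scene.band(x) for x in ("GREEN", "SWIR1", "NIR", "SWIR2"))
    vals = 4.0 * (g - s1) - (0.25 * n + 2.75 * s2)
    ok = scene.valid_mask & np.isfinite(vals)
    return _indicator(scene, vals, ok, "benefit", "AWEI")


# ---------------------------------------------------------------------------
# Thermal chain
# ---------------------------------------------------------------------------

def radiance(dn: np.ndarray, c: ThermalConstants) -> np.ndarray:
    """At-sensor spectral radiance L = gain * DN + bias."""
    return c.gain * np.asarray(dn, dtype=np.float64) + c.bias


def brightness_temperature(L: np.ndarray, c: ThermalConstants) -> np.ndarray:
    """Inverse-Planck brightness temperature T = K2 / ln(K1/L + 1), kelvin.

    Non-positive radiance yields NaN.
    """
    L = np.asarray(L, dtype=np.float64)
    out = np.full(L.shape, np.nan)
    ok = L > 0
    np.divide(c.K1, L, out=out, where=ok)
    with np.errstate(invalid="ignore"):
        out = c.K2 / np.log1p(out)
    out[~ok] = np.nan
    return out


def lst(T: np.ndarray, c: ThermalConstants) -> np.ndarray:
    """Emissivity-corrected land surface temperature.

    LST = T / (1 + (lambda * T / rho) * ln(emissivity)); with emissivity < 1
    the denominator is < 1 so LST >= T.  Cells where the denominator is not
    positive become NaN.
    """
    T = np.asarray(T, dtype=np.float64)
    den = 1.0 + (c.wavelength_m * T / c.rho) * np.log(c.emissivity)
    out = np.full(T.shape, np.nan)
    ok = np.isfinite(den) & (den > 0) & np.isfinite(T)
    np.divide(T, den, out=out, where=ok)
    return out


def tir_normalize(lst_grid: np.ndarray, mask: np.ndarray) -> IndicatorRaster:
    """Min-max normalize an LST grid to [0, 1] over the mask (heat indicator)."""
    lst_grid = np.asarray(lst_grid, dtype=np.float64)
    ok = np.asarray(mask, dtype=bool) & np.isfinite(lst_grid)
    if np.count_nonzero(ok) < 2:
        raise DegenerateRangeError("need at least two valid LST cells to normalize")
    vals = _minmax(lst_grid, ok, "LST")
    vals = np.where(ok, vals, np.nan)
    return IndicatorRaster(vals, "cost", ok, name="TIR")
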