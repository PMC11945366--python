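"""End-to-end orchestration: scene + land cover -> indicators -> water mask
-> composite index -> grading, and multi-epoch change products."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import engine, indices, landcover, shoreline
from .errors import ConfigurationError
from .raster import IndicatorRaster, LandCoverMap, Scene, ThermalConstants


@dataclass
class EpochProducts:
    """Everything the pipeline derives for one epoch."""

    label: str
    indicators: dict[str, IndicatorRaster]
    water: shoreline.WaterMask
    stack: engine.IndicatorStack
    irsei: engine.IrseiResult
    shoreline: shoreline.ShorelineSet
    areas: landcover.ClassAreaTable
    lui: float


def compute_indicators(
    scene: Scene,
    lcm: LandCoverMap,
    thermal_constants: Optional[ThermalConstants] = None,
    lst_raster: Optional[np.ndarray] = None,
    dispersion_mode: str = "pixel",
) -> dict[str, IndicatorRaster]:
    """All indicator layers for one scene.

    LST comes from the scene's thermal DN band via the calibration chain
    when ``thermal_constants`` is given, or from a precomputed ``lst_raster``
    (kelvin grid) for sensors without a thermal band.
    """
    out: dict[str, IndicatorRaster] = {}
    out["GNDVI"] = indices.gndvi(scene)
    out["NDVI"] = indices.ndvi(scene)
    out["NDWI"] = indices.ndwi(scene)
    out["WET"] = indices.wet(scene)
    out["AWEI"] = indices.awei(scene)
    si_r = indices.si(scene)
    ibi_r = indices.ibi(scene)
    out["M-NDBSI"] = indices.m_ndbsi(si_r, ibi_r, dispersion_mode=dispersion_mode)
    if lst_raster is not None:
        lst_grid = np.asarray(lst_raster, dtype=np.float64)
    elif thermal_constants is not None:
        if scene.thermal_dn is None:
            raise ConfigurationError("scene has no thermal band; supply lst_raster instead")
        L = indices.radiance(scene.thermal_dn, thermal_constants)
        T = indices.brightness_temperature(L, thermal_constants)
        lst_grid = indices.lst(T, thermal_constants)
    else:
        raise ConfigurationError("need thermal_constants (DN chain) or lst_raster for the heat layer")
    out["TIR"] = indices.tir_normalize(lst_grid, scene.valid_mask)
    out["LUI"] = landcover.lui_raster(lcm)
    return out


def run_epoch(
    scene: Scene,
    lcm: LandCoverMap,
    thermal_constants: Optional[ThermalConstants] = None,
    lst_raster: Optional[np.ndarray] = None,
    label: str = "",
    mode: str = "pca",
    dispersion_mode: str = "pixel",
    water_threshold: "float | str" = "otsu",
    min_water_size: int = 0,
    breaks: Sequence[float] = engine.DEFAULT_BREAKS,
    simplify_tol: Optional[float] = None,
) -> EpochProducts:
    """Run the full single-epoch pipeline."""
    ind = compute_indicators(scene, lcm, thermal_constants, lst_raster, dispersion_mode)
    water = shoreline.water_mask(ind["AWEI"], threshold=water_threshold, min_size=min_water_size)
    stack = engine.build_stack(
        ind["GNDVI"], ind["WET"], ind["M-NDBSI"], ind["TIR"], ind["LUI"], water
    )
    if mode == "pca":
        result = engine.irsei_from_pca(engine.pca(stack), stack)
    elif mode == "equal":
        result = engine.irsei_equal_weight(stack, ind["NDWI"])
    else:
        raise ConfigurationError(f"mode must be 'pca' or 'equal', got {mode!r}")
    engine.apply_grading(result, breaks=breaks, pixel_area_km2=lcm.pixel_area_km2)
    coast = shoreline.extract_shoreline(
        water, scene.transform, simplify_tol=simplify_tol, epoch=label
    )
    return EpochProducts(
        label=label,
        indicators=ind,
        water=water,
        stack=stack,
        irsei=result,
        shoreline=coast,
        areas=landcover.class_areas(lcm),
        lui=landcover.lui_scalar(landcover.class_areas(lcm)),
    )


def epoch_intervals(labels: Sequence[str]) -> list[tuple[int, int]]:
    """Consecutive epoch pairs plus (first, last)."""
    pairs = [(i, i + 1) for i in range(len(labels) - 1)]
    if len(labels) > 2:
        pairs.append((0, len(labels) - 1))
    return pairs
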