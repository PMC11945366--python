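"""Synthetic multiband scenes with exact ground truth.

Scenes are built from a class-code layout grid: each pixel draws its six
optical reflectances (and optionally a thermal DN) from its class's
signature with independent per-band Gaussian noise, clipped to [0, 1.2].
The land-cover map returned alongside is the layout itself, so area,
transition and accuracy statistics have exact expected values.  Island
fixtures with analytic perimeters and multi-epoch change scripts
(reclamation growing the coastline, farmland converting to built-up,
vegetation fractions declining) exercise the shoreline and composite-index
pipelines end to end.

All generators are deterministic functions of (parameters, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, ContractError, DataError
from .raster import (
    DEFAULT_LEGEND,
    Affine,
    LandCoverMap,
    OPTICAL_BANDS,
    Scene,
    SensorProfile,
    builtin_profile,
)
from .shoreline import WaterMask

__all__ = [
    "ClassSignature",
    "ChangeScript",
    "load_signatures",
    "make_scene",
    "make_island",
    "make_timeseries",
    "degradation_script",
    "reclamation_script",
]

_NAME_TO_CODE = {name: code for code, name in DEFAULT_LEGEND.items()}
_WATER_CODE = _NAME_TO_CODE["water"]
PIXEL_SIZE_M = 30.0


@dataclass(frozen=True)
class ClassSignature:
    """Mean reflectance per band plus noise level for one land-cover class."""

    name: str
    reflectance: tuple[float, ...]  # BLUE..SWIR2
    noise_sd: float = 0.012
    thermal_dn_mean: Optional[float] = None
    thermal_dn_sd: float = 2.0

    def __post_init__(self) -> None:
        if len(self.reflectance) != 6:
            raise ConfigurationError(f"{self.name}: signature needs 6 band means")
        if any(not 0.0 <= m <= 1.0 for m in self.reflectance):
            raise ConfigurationError(f"{self.name}: band means must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def load_signatures(path=None) -> dict[str, ClassSignature]:
    """Load the packaged (or a user-supplied) signature fixture."""
    if path is None:
        source = importlib.resources.files("irsei").joinpath("data/signatures.yaml")
        cfg = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    noise_sd = float(cfg.get("noise_sd", 0.012))
    th_sd = float(cfg.get("thermal_dn_sd", 2.0))
    out = {}
    for name, entry in cfg["classes"].items():
        out[name] = ClassSignature(
            name=name,
            reflectance=tuple(float(v) for v in entry["reflectance"]),
            noise_sd=float(entry.get("noise_sd", noise_sd)),
            thermal_dn_mean=float(entry["thermal_dn"]) if "thermal_dn" in entry else None,
            thermal_dn_sd=float(entry.get("thermal_dn_sd", th_sd)),
        )
    return out


def _default_transform(shape: tuple[int, int]) -> Affine:
    # UTM-like meters, arbitrary origin
    return Affine.from_origin(500000.0, 4_300_000.0, PIXEL_SIZE_M, PIXEL_SIZE_M)


def make_scene(
    layout: np.ndarray,
    signatures: Optional[Mapping[str, ClassSignature]] = None,
    seed: int = 0,
    sensor: Optional[SensorProfile] = None,
    noise: bool = True,
    thermal: bool = True,
    transform: Optional[Affine] = None,
    crs: int = 32651,
) -> tuple[Scene, LandCoverMap]:
    """Render a class-code layout grid into a Scene plus ground-truth map.

    ``layout`` holds legend codes (0 = nodata).  Reflectances are the class
    signature means plus N(0, noise_sd) per band (``noise=False`` disables
    the noise), clipped to [0, 1.2].
    """
    layout = np.asarray(layout)
    if layout.ndim != 2:
        raise ContractError("layout must be a 2-D class-code grid")
    signatures = load_signatures() if signatures is None else signatures
    sensor = builtin_profile("TM") if sensor is None else sensor
    transform = _default_transform(layout.shape) if transform is None else transform
    rng = np.random.default_rng(seed)
    present = [int(c) for c in np.unique(layout) if c != 0]
    unknown = [c for c in present if c not in DEFAULT_LEGEND]
    if unknown:
        raise DataError(f"layout codes without legend entry: {unknown}")
    missing = [DEFAULT_LEGEND[c] for c in present if DEFAULT_LEGEND[c] not in signatures]
    if missing:
        raise ConfigurationError(f"no signature for classes: {missing}")

    reflectance = {b: np.zeros(layout.shape) for b in OPTICAL_BANDS}
    thermal_dn = np.zeros(layout.shape)
    have_thermal = thermal
    for code in present:
        sig = signatures[DEFAULT_LEGEND[code]]
        sel = layout == code
        n = int(sel.sum())
        for bi, band in enumerate(OPTICAL_BANDS):
            vals = np.full(n, sig.reflectance[bi])
            if noise and sig.noise_sd > 0:
                vals = vals + rng.normal(0.0, sig.noise_sd, size=n)
            reflectance[band][sel] = np.clip(vals, 0.0, 1.2)
        if sig.thermal_dn_mean is None:
            have_thermal = False
        else:
            tv = np.full(n, sig.thermal_dn_mean)
            if noise and sig.thermal_dn_sd > 0:
                tv = tv + rng.normal(0.0, sig.thermal_dn_sd, size=n)
            thermal_dn[sel] = np.clip(tv, 0.0, None)

    nodata = layout == 0
    scene = Scene(
        reflectance=reflectance,
        transform=transform,
        crs=crs,
        nodata_mask=nodata,
        sensor=sensor,
        thermal_dn=thermal_dn if have_thermal else None,
    )
    lcm = LandCoverMap(
        codes=layout.astype(np.int64),
        legend=dict(DEFAULT_LEGEND),
        pixel_area_km2=transform.pixel_area_km2(),
        transform=transform,
        crs=crs,
    )
    return scene, lcm


def _disc(shape: tuple[int, int], radius_px: float, center=None) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    cr, cc = center if center is not None else ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= radius_px**2


def make_island(
    radius_px: float,
    grid: tuple[int, int] = (256, 256),
    seed: int = 0,
    land_class: str = "grassland",
    signatures: Optional[Mapping[str, ClassSignature]] = None,
) -> tuple[Scene, LandCoverMap, WaterMask, dict]:
    """Circular island amid open water, with the analytic perimeter recorded.

    Returns (scene, land-cover map, ground-truth water mask, meta) where
    meta carries the analytic circumference 2*pi*r and land fraction.
    """
    if radius_px <= 0:
        raise ContractError("radius must be positive")
    if 2 * radius_px >= min(grid) - 4:
        raise ContractError("island does not fit in the grid")
    land = _disc(grid, radius_px)
    layout = np.where(land, _NAME_TO_CODE[land_class], _WATER_CODE)
    scene, lcm = make_scene(layout, signatures=signatures, seed=seed)
    wm = WaterMask(mask=~land, threshold=float("nan"), source="ground truth")
    meta = {
        "radius_px": radius_px,
        "perimeter_km": 2.0 * np.pi * radius_px * PIXEL_SIZE_M / 1000.0,
        "land_fraction": float(land.mean()),
    }
    return scene, lcm, wm, meta


@dataclass
class ChangeScript:
    """Deterministic multi-epoch layout script.

    Per epoch: an island of ``island_radius_px`` (grassland base) is drawn
    amid water, a farmland block occupies the island's west side, and a
    built-up block grows from the island's center east side; block widths
    are given per epoch in pixels.  ``veg_fraction`` optionally converts the
    grassland base into forest for the given fraction of rows (a monotone
    vegetation-quality dial for degradation experiments).
    """

    epochs: tuple[str, ...]
    grid: tuple[int, int] = (200, 200)
    island_radius_px: tuple[float, ...] = ()
    farmland_halfwidth_px: tuple[int, ...] = ()
    builtup_halfwidth_px: tuple[int, ...] = ()
    veg_fraction: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.epochs)
        if n < 2:
            raise ConfigurationError("a change script needs at least two epochs")
        for name in ("island_radius_px", "farmland_halfwidth_px", "builtup_halfwidth_px", "veg_fraction"):
            v = getattr(self, name)
            if v and len(v) != n:
                raise ConfigurationError(f"{name} must have one entry per epoch")

    def layout(self, k: int) -> np.ndarray:
        """Class-code grid for epoch index k."""
        shape = self.grid
        r = self.island_radius_px[k] if self.island_radius_px else min(shape) * 0.35
        land = _disc(shape, r)
        codes = np.where(land, _NAME_TO_CODE["grassland"], _WATER_CODE)
        cr, cc = (shape[0] - 1) / 2, (shape[1] - 1) / 2
        if self.veg_fraction:
            # convert the top veg_fraction of land rows to forest
            nrows = int(round(self.veg_fraction[k] * shape[0]))
            sel = np.zeros(shape, dtype=bool)
            sel[:nrows, :] = True
            codes[land & sel] = _NAME_TO_CODE["forest"]
        if self.farmland_halfwidth_px:
            w = self.farmland_halfwidth_px[k]
            if w > 0:
                sel = np.zeros(shape, dtype=bool)
                sel[int(cr - w) : int(cr + w), : int(cc)] = True
                codes[land & sel] = _NAME_TO_CODE["cultivated land"]
        if self.builtup_halfwidth_px:
            # built-up square grows westward into the farmland belt over time
            w = self.builtup_halfwidth_px[k]
            if w > 0:
                sel = np.zeros(shape, dtype=bool)
                sel[int(cr - w) : int(cr + w), int(cc - w) :] = True
                codes[land & sel] = _NAME_TO_CODE["artificial surface"]
        return codes.astype(np.int64)


def make_timeseries(
    script: ChangeScript,
    seed: int = 0,
    signatures: Optional[Mapping[str, ClassSignature]] = None,
) -> list[tuple[Scene, LandCoverMap]]:
    """Render every epoch of a change script onto a shared georeference."""
    out = []
    for k in range(len(script.epochs)):
        layout = script.layout(k)
        out.append(make_scene(layout, signatures=signatures, seed=seed + k))
    return out


def reclamation_script(
    epochs: Sequence[str] = ("2002", "2007", "2013", "2017", "2022"),
    grid: tuple[int, int] = (220, 220),
    r0: float = 60.0,
    growth_px: float = 5.0,
) -> ChangeScript:
    """Island radius growing by ``growth_px`` per epoch: shoreline length
    grows by ~2*pi*growth_px pixels per interval."""
    n = len(epochs)
    return ChangeScript(
        epochs=tuple(epochs),
        grid=grid,
        island_radius_px=tuple(r0 + growth_px * k for k in range(n)),
    )


def degradation_script(
    epochs: Sequence[str] = ("2002", "2007", "2013", "2017", "2022"),
    grid: tuple[int, int] = (200, 200),
) -> ChangeScript:
    """Monotone ecological degradation: forest cover shrinks while the
    built-up block widens every epoch (farmland partly converting)."""
    n = len(epochs)
    veg = tuple(0.8 - 0.6 * k / (n - 1) for k in range(n))
    farm = tuple(int(round(30 - 10 * k / (n - 1))) for k in range(n))
    built = tuple(int(round(6 + 30 * k / (n - 1))) for k in range(n))
    return ChangeScript(
        epochs=tuple(epochs),
        grid=grid,
        island_radius_px=tuple(min(grid) * 0.38 for _ in range(n)),
        farmland_halfwidth_px=farm,
        builtup_halfwidth_px=built,
        veg_fraction=veg,
    )
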