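"""Land/water segmentation and shoreline change analytics.

Water is segmented from a water indicator (AWEI by default) with Otsu's
histogram threshold, the land/water boundary is traced as sub-pixel
contours at the 0.5 level (marching squares), simplified with
Douglas-Peucker, and measured in projected kilometres.  Change between
epochs is summarised as the length difference, the coastline change
intensity CCI = (L_t2 - L_t1) / T in km/year, and the relative change in
percent of the earlier length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString
from skimage import measure, morphology

from .errors import ConfigurationError, ContractError, DataError, DegenerateRangeError
from .raster import Affine, IndicatorRaster

__all__ = [
    "WaterMask",
    "ShorelineSet",
    "ChangeRecord",
    "otsu_threshold",
    "water_mask",
    "extract_shoreline",
    "change_metrics",
]


@dataclass
class WaterMask:
    """Boolean water mask (True = water) with the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    source: str = "AWEI"


@dataclass
class ShorelineSet:
    """Vectorised land/water boundaries for one epoch, in projected units."""

    epoch: str
    polylines: list[LineString]
    total_length_km: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_length_km = float(sum(p.length for p in self.polylines)) / 1000.0

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"epoch": self.epoch, "length_km": line.length / 1000.0},
                "geometry": {"type": "LineString", "coordinates": [list(c) for c in line.coords]},
            }
            for line in self.polylines
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


@dataclass
class ChangeRecord:
    """Shoreline change between two epochs."""

    t1: str
    t2: str
    delta_km: float
    cci_km_per_year: float
    intensity_percent: float
    interval_years: float


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    Candidate thresholds are the interior histogram bin edges; the returned
    edge separates the two classes (values <= edge vs > edge).  Ties are
    broken toward the lower edge.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or np.min(v) == np.max(v):
        raise DegenerateRangeError("Otsu threshold requires at least two distinct values")
    if bins < 2:
        raise ConfigurationError("bins must be >= 2")
    counts, edges = np.histogram(v, bins=bins)
    # between-class variance at each interior edge: w0 w1 (mu0 - mu1)^2
    p = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    cummean = np.cumsum(p * centers)[:-1]
    total_mean = float(np.sum(p * centers))
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cummean / w0
        mu1 = (total_mean - cummean) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv = np.where(np.isfinite(bcv), bcv, -np.inf)
    # ties (to floating-point precision) break toward the lower threshold
    top = float(np.max(bcv))
    best = int(np.argmax(bcv >= top - 1e-12 * max(abs(top), 1.0)))
    return float(edges[1:-1][best])


def water_mask(
    awei_r: IndicatorRaster,
    threshold: float | str = "otsu",
    min_size: int = 0,
    bins: int = 256,
) -> WaterMask:
    """Threshold a water indicator into a water mask (water where value > t).

    ``threshold`` is either a number or "otsu".  ``min_size`` removes
    connected components (both water specks and land specks) smaller than
    that many pixels.
    """
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ConfigurationError(f"threshold must be a number or 'otsu', got {threshold!r}")
        t = otsu_threshold(awei_r.masked(), bins=bins)
    else:
        t = float(threshold)
    mask = awei_r.valid_mask & (awei_r.values > t)
    if min_size > 0:
        # remove components strictly smaller than min_size, both phases
        mask = morphology.remove_small_objects(mask, max_size=min_size - 1)
        mask = ~morphology.remove_small_objects(~mask, max_size=min_size - 1)
    if mask.all() or not mask.any():
        import warnings

        warnings.warn("thresholding produced a single-phase (all-water or all-land) mask")
    return WaterMask(mask=mask, threshold=t, source=awei_r.name or "AWEI")


def extract_shoreline(
    wm: WaterMask,
    transform: Affine,
    simplify_tol: Optional[float] = None,
    epoch: str = "",
    largest_only: bool = False,
) -> ShorelineSet:
    """Trace land/water boundaries as polylines in the projected CRS.

    Contours are found at the 0.5 level of the binary mask (pixel-center
    registration) and Douglas-Peucker simplified; ``simplify_tol`` defaults
    to one pixel length.  With ``largest_only`` only the longest boundary
    (the outer coast of the main island) is kept; otherwise every land/water
    edge, including inland ponds, contributes to the total length.
    """
    mask = wm.mask
    if mask.all() or not mask.any():
        import warnings

        warnings.warn("single-phase mask: no shoreline to extract")
        return ShorelineSet(epoch=epoch, polylines=[])
    if simplify_tol is None:
        simplify_tol = transform.pixel_width
    lines: list[LineString] = []
    for contour in measure.find_contours(mask.astype(np.float64), 0.5):
        if len(contour) < 2:
            continue
        coords = [transform.xy(r, c) for r, c in contour]
        line = LineString(coords)
        if simplify_tol > 0:
            line = line.simplify(simplify_tol, preserve_topology=False)
        if line.length > 0:
            lines.append(line)
    if largest_only and lines:
        lines = [max(lines, key=lambda l: l.length)]
    return ShorelineSet(epoch=epoch, polylines=lines)


def change_metrics(
    l1: "ShorelineSet | float",
    l2: "ShorelineSet | float",
    interval_years: float,
    t1: str = "",
    t2: str = "",
) -> ChangeRecord:
    """Shoreline change between two epochs.

    Accepts ShorelineSet objects or plain lengths in km.  CCI is the length
    change per year; intensity the change relative to the earlier length.
    """
    if interval_years <= 0:
        raise DataError("interval_years must be positive")
    len1 = l1.total_length_km if isinstance(l1, ShorelineSet) else float(l1)
    len2 = l2.total_length_km if isinstance(l2, ShorelineSet) else float(l2)
    if len1 <= 0:
        raise DataError("change intensity undefined for zero initial length")
    delta = len2 - len1
    return ChangeRecord(
        t1=t1 or (l1.epoch if isinstance(l1, ShorelineSet) else ""),
        t2=t2 or (l2.epoch if isinstance(l2, ShorelineSet) else ""),
        delta_km=delta,
        cci_km_per_year=delta / interval_years,
        intensity_percent=100.0 * delta / len1,
        interval_years=interval_years,
    )
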