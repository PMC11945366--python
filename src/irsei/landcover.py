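"""Land-cover accounting: class areas, change and transition statistics,
classification-accuracy assessment (overall accuracy and kappa), and the
land-use-intensity index LUI.

LUI is an area-weighted mean of per-class intensity levels: bare land 1;
water, forest, grassland, shrubland 2; cultivated land and aquaculture
ponds 3; artificial surfaces 4.  The landscape scalar uses areas directly;
the per-pixel layer assigns each pixel its class weight rescaled to [0, 1]
so it can enter the composite index alongside the spectral indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, DataError
from .raster import IndicatorRaster, LandCoverMap

__all__ = [
    "ClassAreaTable",
    "ConfusionMatrix",
    "DEFAULT_LUI_WEIGHTS",
    "class_areas",
    "percent_change",
    "transition_matrix",
    "accuracy",
    "sample_reference",
    "lui_scalar",
    "lui_raster",
]

# Default intensity levels, keyed by class name.
DEFAULT_LUI_WEIGHTS: dict[str, int] = {
    "bare land": 1,
    "water": 2,
    "forest": 2,
    "grassland": 2,
    "shrubland": 2,
    "cultivated land": 3,
    "aquaculture pond": 3,
    "artificial surface": 4,
}


@dataclass
class ClassAreaTable:
    """Per-class areas (km^2) for one epoch."""

    areas: dict[str, float]
    total_km2: float = field(init=False)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.areas.values()):
            raise DataError("class areas must be nonnegative")
        self.total_km2 = float(sum(self.areas.values()))

    def to_series(self) -> pd.Series:
        return pd.Series(self.areas, name="area_km2")


@dataclass
class ConfusionMatrix:
    """Predicted x reference class counts."""

    counts: pd.DataFrame  # rows: predicted, columns: reference

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def class_areas(m: LandCoverMap) -> ClassAreaTable:
    """Area per legend class: pixel count x pixel_area_km2 (nodata excluded)."""
    codes, counts = np.unique(m.codes[m.valid_mask], return_counts=True)
    tally = dict(zip(codes.tolist(), counts.tolist()))
    areas = {name: tally.get(code, 0) * m.pixel_area_km2 for code, name in m.legend.items()}
    return ClassAreaTable(areas)


def percent_change(a1: float, a2: float) -> float:
    """Signed percent change 100 (a2 - a1) / a1 between two areas or lengths."""
    if a1 <= 0:
        raise DataError("percent change is undefined for a nonpositive baseline")
    return 100.0 * (a2 - a1) / a1


def transition_matrix(m1: LandCoverMap, m2: LandCoverMap) -> pd.DataFrame:
    """Class-by-class area cross-tabulation (km^2) from epoch 1 to epoch 2.

    Computed over the common valid domain, so row sums equal epoch-1 class
    areas and column sums epoch-2 class areas restricted to that domain.
    """
    if m1.codes.shape != m2.codes.shape:
        raise ContractError("land-cover grids differ in shape")
    if dict(m1.legend) != dict(m2.legend):
        raise ContractError("land-cover legends differ")
    both = m1.valid_mask & m2.valid_mask
    c1 = m1.codes[both]
    c2 = m2.codes[both]
    codes = sorted(m1.legend)
    k = len(codes)
    lut = np.full(max(codes) + 1, -1, dtype=np.int64)
    for i, c in enumerate(codes):
        lut[c] = i
    lin = lut[c1] * k + lut[c2]
    flat = np.bincount(lin, minlength=k * k)
    names = [m1.legend[c] for c in codes]
    return pd.DataFrame(flat.reshape(k, k) * m1.pixel_area_km2, index=names, columns=names)


def accuracy(cm: ConfusionMatrix) -> dict[str, float]:
    """Overall accuracy and Cohen's kappa from a confusion matrix.

    OA = trace / n; kappa = (p_o - p_e) / (1 - p_e) with chance agreement
    p_e = sum_k row_k * col_k / n^2.
    """
    counts = cm.counts.to_numpy(dtype=np.float64)
    n = counts.sum()
    if n <= 0:
        raise DataError("empty confusion matrix")
    p_o = np.trace(counts) / n
    p_e = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0))) / n**2
    if p_e >= 1.0:
        raise DataError("kappa undefined: chance agreement is 1 (single-class matrix)")
    return {"overall_accuracy": float(p_o), "kappa": float((p_o - p_e) / (1.0 - p_e))}


def sample_reference(
    m: LandCoverMap, points: Iterable[tuple[float, float, int]]
) -> ConfusionMatrix:
    """Cross-tabulate map predictions against labelled reference points.

    Each point is (x, y, reference class code) in the map's CRS; the
    predicted class is read at the containing pixel.  Out-of-bounds points
    are excluded (a DataError is raised if none remain).
    """
    if m.transform is None:
        raise ConfigurationError("land-cover map lacks a georeference")
    nrow, ncol = m.codes.shape
    pred, ref = [], []
    dropped = 0
    for x, y, cls in points:
        row, col = m.transform.index(x, y)
        if 0 <= row < nrow and 0 <= col < ncol and m.codes[row, col] != 0:
            pred.append(int(m.codes[row, col]))
            ref.append(int(cls))
        else:
            dropped += 1
    if not pred:
        raise DataError(f"all {dropped} reference points fall outside the map")
    codes = sorted(m.legend)
    names = [m.legend[c] for c in codes]
    tab = pd.crosstab(
        pd.Categorical([m.legend[p] for p in pred], categories=names),
        pd.Categorical([m.legend.get(r, str(r)) for r in ref], categories=names),
        dropna=False,
    ).reindex(index=names, columns=names, fill_value=0)
    return ConfusionMatrix(tab)


def _weights_by_code(m: LandCoverMap, w: Mapping[str, int]) -> dict[int, int]:
    missing = [name for name in m.legend.values() if name not in w]
    if missing:
        raise ConfigurationError(f"classes without LUI weight: {missing}")
    return {code: w[name] for code, name in m.legend.items()}


def lui_scalar(t: ClassAreaTable, w: Mapping[str, int] | None = None) -> float:
    """Landscape land-use-intensity scalar: sum(A_i W_i) / sum(A_i)."""
    w = DEFAULT_LUI_WEIGHTS if w is None else w
    missing = [name for name in t.areas if name not in w]
    if missing:
        raise ConfigurationError(f"classes without LUI weight: {missing}")
    if t.total_km2 <= 0:
        raise DataError("LUI undefined for zero total area")
    return sum(a * w[name] for name, a in t.areas.items()) / t.total_km2


def lui_raster(m: LandCoverMap, w: Mapping[str, int] | None = None) -> IndicatorRaster:
    """Per-pixel land-use-intensity layer.

    Each pixel gets its class weight rescaled to [0, 1] by
    (W - Wmin) / (Wmax - Wmin) over the weight table; polarity cost.
    """
    w = DEFAULT_LUI_WEIGHTS if w is None else w
    by_code = _weights_by_code(m, w)
    wmin, wmax = min(w.values()), max(w.values())
    if wmax == wmin:
        raise ConfigurationError("LUI weights are all equal; rescale undefined")
    lut = np.full(max(by_code) + 1, np.nan)
    for code, weight in by_code.items():
        lut[code] = (weight - wmin) / (wmax - wmin)
    ok = m.valid_mask
    vals = np.where(ok, lut[np.where(ok, m.codes, 0)], np.nan)
    return IndicatorRaster(vals, "cost", ok, name="LUI", transform=m.transform, crs=m.crs)
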