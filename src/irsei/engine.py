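"""Composite ecological index construction.

Five indicators — greenness (GNDVI), wetness (WET), dryness (M-NDBSI),
heat (normalized LST) and land-use intensity (LUI) — are min-max
normalized to [0, 1] over the water-masked valid domain and stacked.  The
headline index is built from the first principal component of their 5x5
covariance matrix: PC1 is sign-oriented so that greenness loads
non-positively, the raw index is 1 - PC1, and the result is min-max
rescaled to [0, 1].  Values near 1 mean good ecological condition.  An
equal-weight variant averages the five benefit-oriented terms directly
(using NDWI in place of WET as the moisture term).

The index is graded into five levels (poor .. excellent) at configurable
breakpoints, and epoch means are summarised into interval and cumulative
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, DataError, DegenerateRangeError
from .raster import Affine, IndicatorRaster
from .shoreline import WaterMask

__all__ = [
    "LAYER_ORDER",
    "IndicatorStack",
    "PcaResult",
    "IrseiResult",
    "minmax_normalize",
    "build_stack",
    "pca",
    "irsei_from_pca",
    "irsei_equal_weight",
    "grade",
    "summarize_epochs",
]

LAYER_ORDER = ("GNDVI", "WET", "M-NDBSI", "TIR", "LUI")
DEFAULT_BREAKS = (0.2, 0.4, 0.6, 0.8)
GRADE_NAMES = {1: "poor", 2: "fair", 3: "moderate", 4: "good", 5: "excellent"}


@dataclass
class IndicatorStack:
    """The five normalized indicator layers over a shared analysis mask."""

    layers: dict[str, IndicatorRaster]
    analysis_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in LAYER_ORDER:
            if name not in self.layers:
                raise ConfigurationError(f"stack is missing layer {name!r}")
        shapes = {r.values.shape for r in self.layers.values()} | {self.analysis_mask.shape}
        if len(shapes) != 1:
            raise ContractError(f"stack layers disagree in shape: {shapes}")

    def matrix(self) -> np.ndarray:
        """Masked pixels as an (n, 5) matrix in LAYER_ORDER."""
        return np.column_stack([self.layers[n].values[self.analysis_mask] for n in LAYER_ORDER])


@dataclass
class PcaResult:
    """Eigendecomposition of the indicator covariance.

    ``loadings[k]`` is the k-th orthonormal loading vector (LAYER_ORDER
    component order); ``pc1`` is the projection of each pixel onto the first
    loading (NaN off-mask).
    """

    loadings: np.ndarray  # (n_components, 5)
    eigenvalues: np.ndarray  # nonincreasing, >= 0
    pc1: np.ndarray


@dataclass
class IrseiResult:
    """Composite index raster with grading and summary statistics."""

    irsei: np.ndarray  # [0, 1] on mask, NaN elsewhere
    mask: np.ndarray
    mean: float
    std: float
    grades: Optional[np.ndarray] = None
    level_areas_km2: Optional[dict[int, float]] = None
    level_proportions: Optional[dict[int, float]] = None
    pca: Optional[PcaResult] = None
    transform: Optional[Affine] = None
    crs: Optional[int] = None


def minmax_normalize(r: IndicatorRaster, mask: Optional[np.ndarray] = None) -> IndicatorRaster:
    """Affine map of an indicator to [0, 1] using min/max under the mask."""
    ok = r.valid_mask if mask is None else (r.valid_mask & mask)
    finite = ok & np.isfinite(r.values)
    v = r.values[finite]
    if v.size < 2:
        raise DegenerateRangeError(f"{r.name or 'indicator'}: too few valid cells to normalize")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegenerateRangeError(f"{r.name or 'indicator'} is constant; zero range")
    vals = np.where(finite, (r.values - lo) / (hi - lo), np.nan)
    return IndicatorRaster(vals, r.polarity, finite, name=r.name, transform=r.transform, crs=r.crs)


def build_stack(
    gndvi: IndicatorRaster,
    wet: IndicatorRaster,
    m_ndbsi: IndicatorRaster,
    tir: IndicatorRaster,
    lui: IndicatorRaster,
    water: Optional[WaterMask] = None,
) -> IndicatorStack:
    """Normalize the five indicators over the non-water valid domain.

    The analysis mask is the intersection of all layer validity masks minus
    water pixels; each layer is min-max normalized over that mask so large
    water bodies cannot stretch the indicator ranges.
    """
    raw = dict(zip(LAYER_ORDER, (gndvi, wet, m_ndbsi, tir, lui)))
    shapes = {r.values.shape for r in raw.values()}
    if len(shapes) != 1:
        raise ContractError(f"indicator shapes disagree: {shapes}")
    mask = np.ones(next(iter(shapes)), dtype=bool)
    for r in raw.values():
        mask &= r.valid_mask
    if water is not None:
        if water.mask.shape != mask.shape:
            raise ContractError("water mask shape differs from indicators")
        mask &= ~water.mask
    if not mask.any():
        raise DataError("analysis mask is empty (all pixels invalid or water)")
    layers: dict[str, IndicatorRaster] = {}
    for name, r in raw.items():
        try:
            layers[name] = minmax_normalize(r, mask)
        except DegenerateRangeError as exc:
            raise DegenerateRangeError(f"layer {name}: {exc}") from exc
    return IndicatorStack(layers=layers, analysis_mask=mask)


def pca(stack: IndicatorStack) -> PcaResult:
    """Eigendecomposition of the 5x5 covariance of the masked pixel vectors.

    Data are centered but not re-standardized (the layers are already on a
    common [0, 1] scale).  Loadings are orthonormal; eigenvalues are sorted
    nonincreasing.  PC1's sign is fixed in :func:`irsei_from_pca`.
    """
    X = stack.matrix()
    if X.shape[0] < 5:
        raise DataError("PCA needs at least 5 masked pixels")
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    loadings = evecs[:, order].T
    if evals[0] <= 0:
        raise DataError("indicator stack has zero variance; PC1 undefined")
    scores = (X - mean) @ loadings[0]
    pc1 = np.full(stack.analysis_mask.shape, np.nan)
    pc1[stack.analysis_mask] = scores
    return PcaResult(loadings=loadings, eigenvalues=evals, pc1=pc1)


def _rescale01(vals: np.ndarray, mask: np.ndarray, what: str) -> np.ndarray:
    v = vals[mask]
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        raise DegenerateRangeError(f"{what} is constant; cannot rescale to [0, 1]")
    out = np.full(vals.shape, np.nan)
    out[mask] = (v - lo) / (hi - lo)
    return out


def irsei_from_pca(p: PcaResult, stack: IndicatorStack) -> IrseiResult:
    """Orient PC1, form the raw index 1 - PC1, and rescale to [0, 1].

    Orientation rule: flip the first loading so its greenness component is
    non-positive, which makes 1 - PC1 (and hence the final index) correlate
    non-negatively with GNDVI.  The rule is invariant to the arbitrary sign
    of the eigendecomposition.
    """
    loading1 = p.loadings[0]
    pc1 = p.pc1
    if loading1[LAYER_ORDER.index("GNDVI")] > 0:
        loading1 = -loading1
        pc1 = -pc1
    mask = stack.analysis_mask
    irsei0 = 1.0 - pc1
    irsei = _rescale01(irsei0, mask, "raw composite index")
    # Guard: if greenness is (near-)absent from PC1 the loading sign is
    # uninformative; fall back to the realised correlation.
    g = stack.layers["GNDVI"].values[mask]
    if np.std(g) > 0 and np.std(irsei[mask]) > 0:
        if np.corrcoef(irsei[mask], g)[0, 1] < 0:
            # min-max rescaling commutes with negation as x -> 1 - x
            irsei = np.where(mask, 1.0 - irsei, np.nan)
            loading1 = -loading1
            pc1 = -pc1
    gndvi_layer = stack.layers["GNDVI"]
    return IrseiResult(
        irsei=irsei,
        mask=mask,
        mean=float(np.mean(irsei[mask])),
        std=float(np.std(irsei[mask])),
        pca=PcaResult(
            loadings=np.vstack([loading1, p.loadings[1:]]), eigenvalues=p.eigenvalues, pc1=pc1
        ),
        transform=gndvi_layer.transform,
        crs=gndvi_layer.crs,
    )


def irsei_equal_weight(stack: IndicatorStack, ndwi_r: IndicatorRaster) -> IrseiResult:
    """Equal-weight composite:
    (GNDVI + NDWI + (1 - M-NDBSI) + (1 - TIR) + (1 - LUI)) / 5.

    All five terms must be normalized to [0, 1]; the result lies in [0, 1]
    by construction.  NDWI replaces WET as the moisture term in this
    variant.
    """
    if ndwi_r is None:
        raise ConfigurationError("equal-weight composite requires an NDWI layer")
    if ndwi_r.values.shape != stack.analysis_mask.shape:
        raise ContractError("NDWI shape differs from stack")
    mask = stack.analysis_mask & ndwi_r.valid_mask
    if not mask.any():
        raise DataError("empty mask for equal-weight composite")
    ndwi_n = minmax_normalize(ndwi_r, mask)
    g = stack.layers["GNDVI"].values
    d = stack.layers["M-NDBSI"].values
    h = stack.layers["TIR"].values
    u = stack.layers["LUI"].values
    vals = (g + ndwi_n.values + (1.0 - d) + (1.0 - h) + (1.0 - u)) / 5.0
    vals = np.where(mask, vals, np.nan)
    gndvi_layer = stack.layers["GNDVI"]
    return IrseiResult(
        irsei=vals,
        mask=mask,
        mean=float(np.mean(vals[mask])),
        std=float(np.std(vals[mask])),
        transform=gndvi_layer.transform,
        crs=gndvi_layer.crs,
    )


def grade(
    irsei_grid: np.ndarray,
    mask: np.ndarray,
    breaks: Sequence[float] = DEFAULT_BREAKS,
    pixel_area_km2: float = 0.0009,
) -> tuple[np.ndarray, dict[int, float], dict[int, float]]:
    """Grade the index into five levels and account per-level areas.

    Level 1 (poor) = [0, b1), ..., level 5 (excellent) = [b4, 1].  Returns
    (grades grid with 0 off-mask, level areas in km^2, level percentages of
    the masked area).
    """
    breaks = tuple(float(b) for b in breaks)
    if len(breaks) != 4 or any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ConfigurationError("breaks must be 4 strictly ascending values in (0, 1)")
    if any(not 0.0 < b < 1.0 for b in breaks):
        raise ConfigurationError("breaks must lie strictly inside (0, 1)")
    grades = np.zeros(irsei_grid.shape, dtype=np.int8)
    grades[mask] = 1 + np.searchsorted(breaks, irsei_grid[mask], side="right")
    total = int(np.count_nonzero(mask))
    if total == 0:
        raise DataError("empty mask; nothing to grade")
    areas = {}
    props = {}
    for level in range(1, 6):
        count = int(np.count_nonzero(grades == level))
        areas[level] = count * pixel_area_km2
        props[level] = 100.0 * count / total
    return grades, areas, props


def apply_grading(result: IrseiResult, breaks: Sequence[float] = DEFAULT_BREAKS,
                  pixel_area_km2: float = 0.0009) -> IrseiResult:
    """Fill the grading fields of an IrseiResult in place (and return it)."""
    grades, areas, props = grade(result.irsei, result.mask, breaks, pixel_area_km2)
    result.grades = grades
    result.level_areas_km2 = areas
    result.level_proportions = props
    return result


def level_shares(level_areas_km2: "dict[int | str, float]") -> "dict[int | str, float]":
    """Percent share of each grade level in the total graded area."""
    total = float(sum(level_areas_km2.values()))
    if total <= 0:
        raise DataError("level areas sum to zero")
    return {k: 100.0 * v / total for k, v in level_areas_km2.items()}


def summarize_epochs(
    means: Sequence[float],
    labels: Optional[Sequence[str]] = None,
    stds: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Epoch-mean table with interval differences and the cumulative change.

    Row k carries the difference from the previous epoch; the ``cumulative``
    column is the running difference from the first epoch, so its last entry
    is the total change over the study period.
    """
    means = [float(m) for m in means]
    if len(means) < 2:
        raise DataError("need at least two epochs to summarise")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(means))]
    rows = []
    for i, m in enumerate(means):
        rows.append(
            {
                "epoch": labels[i],
                "mean": m,
                "std": float(stds[i]) if stds is not None else np.nan,
                "delta": m - means[i - 1] if i > 0 else np.nan,
                "cumulative": m - means[0],
            }
        )
    return pd.DataFrame(rows)
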