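# Methods

This note documents the models, numerical choices and limitations behind
the `irsei` package. It describes what the code computes; every number
shown elsewhere (README, tests) is produced by running the code.

## Data model

Rasters are row-major numpy grids with pixel-center (row, col) indexing
and a north-up affine georeference; GeoTIFF I/O goes through `tifffile`
using the standard ModelPixelScale/ModelTiepoint/GeoKeyDirectory tags and
the GDAL_NODATA convention. Rotated (non-axis-aligned) transforms are not
supported; reprojection, mosaicking and atmospheric correction are out of
scope — inputs are assumed preprocessed surface reflectance. Reflectance
may be stored as [0, 1] floats or integer-scaled (e.g. ×10000); a
profile-level `reflectance_scale` converts at read time. Any cell that is
nodata in any input band is nodata in every derived product.

Sensor profiles carry the semantic band map (BLUE..SWIR2, optional
THERMAL), the tasselled-cap wetness coefficients, and thermal calibration.
The built-in TM/OLI/S2 profiles use a canonical band layout (file bands
1–6 in BLUE..SWIR2 order); real mission layouts are supplied via YAML.
Thermal constants (gain, bias, K1, K2, λ, ε) are always configuration:
they are properties of a specific sensor product, not of the method, so
the package ships no claimed defaults.

## Indicators

* **Normalized differences** (NDVI, NDWI, NDBI, GNDVI) mask cells with a
  zero denominator rather than clamping. NDBI follows the SWIR1/NIR
  formula (the built-up reading of the mid-infrared contrast).
* **Wetness** is a per-pixel dot product with the sensor's 6-coefficient
  vector; all three built-in vectors have negative SWIR loadings.
* **Dryness (M-NDBSI)** combines the soil index SI ∈ [−1, 1] and the
  built-up ratio IBI ∈ [0, ∞). Because the two are incommensurate, both
  are min-max normalized to [0, 1] over the shared valid mask before
  combination; without this IBI's scale dominates. The dispersion term
  σ(SI, IBI) defaults to the per-pixel population standard deviation of
  the two values, |SI′ − IBI′|/2 — the only reading that yields a
  spatially varying dryness map — which makes the pixel mode identically
  max(SI′, IBI′); this closed form serves as a test oracle. A scene mode
  (one pooled σ added uniformly) is provided as the alternative reading.
* **Thermal chain**: radiance L = gain·DN + bias; brightness temperature
  T = K2/ln(K1/L + 1) (the standard inverse-Planck form); emissivity
  correction LST = T/(1 + (λT/ρ)·ln ε) with ρ = 1.438×10⁻² m·K fixed.
  Non-positive radiance or a non-positive denominator yields nodata. The
  heat layer is the min-max normalization of LST. For sensors without a
  thermal band (Sentinel-2) the pipeline accepts a precomputed LST grid.

## Composite index

The five layers (GNDVI, WET, M-NDBSI, TIR, LUI — fixed order) are
normalized over the analysis mask, which excludes nodata and water; water
comes from AWEI = 4(GREEN − SWIR1) − (0.25 NIR + 2.75 SWIR2) thresholded
by Otsu's method (fixed thresholds or external masks can be substituted).
PCA is an eigendecomposition of the 5×5 covariance matrix of the masked
pixel vectors — centered but *not* re-standardized, since the layers are
already on a common [0, 1] scale; standardizing again would discard the
relative variance structure the normalization establishes.

The eigendecomposition's sign is arbitrary, so an orientation rule is
required: PC1 is flipped so that its greenness loading is ≤ 0, making
1 − PC1 (and the final index) correlate non-negatively with GNDVI. If the
greenness loading is numerically negligible, the realised correlation is
checked directly and the index flipped if needed. The raw index 1 − PC1
is min-max rescaled to [0, 1] per epoch. PCA is fit per epoch, not pooled
across epochs: loadings are reported per year so their evolution is
visible, at the cost of cross-epoch scale comparability (the per-epoch
rescale mitigates this).

Grading uses five levels at breaks (0.2, 0.4, 0.6, 0.8) by default —
equal-width bins, configurable, since no canonical thresholds exist for
this family of indices. Level 5 includes the value 1.0.

The equal-weight variant averages GNDVI, NDWI, and the complements of
dryness, heat and intensity; it uses NDWI as the moisture term where the
PCA stack uses WET, mirroring the two ingredient lists in circulation for
this index family. The PCA mode is the default headline method.

## Land cover and shoreline

Class areas are pixel counts × pixel area; transition matrices are
cross-tabulated over the common valid domain so marginals conserve area
exactly. Kappa uses the standard chance-corrected closed form; it is
undefined for single-class matrices. LUI enters the composite as a
per-pixel layer (class weight rescaled to [0, 1]) — the only per-pixel
reading compatible with a PCA over pixel vectors — while the landscape
scalar Σ AᵢWᵢ / Σ Aᵢ is reported alongside.

Otsu's threshold is computed on a 256-bin histogram (vectorized
between-class variance over interior bin edges); ties within
floating-point noise resolve to the lowest edge. Shorelines are traced by
marching squares at the 0.5 level of the water mask, giving sub-pixel
boundaries, then Douglas–Peucker simplified with a default tolerance of
one pixel length (the choice is conventional; simplification never
lengthens a polyline). All land/water edges, including inland ponds,
count toward the total length unless `largest_only` keeps just the outer
coast — printed coastline lengths in the literature are ambiguous on this
point, so both are exposed. The change-metric interval T is user-supplied
per pair rather than derived from year labels, because calendar spans and
published annual rates frequently imply different conventions.

## Synthetic scenes

The generator renders class-code layouts into reflectance with
class-typical signatures (versioned in `src/irsei/data/signatures.yaml`):
water bright in GREEN and dark in NIR/SWIR, vegetation bright in NIR,
built-up and bare surfaces bright in SWIR, with hotter thermal DN over
sealed surfaces. Noise is independent per-band Gaussian (σ = 0.012
reflectance, σ = 2 DN) — enough to exercise thresholds and PCA while
keeping class contrasts realistic for the sensors emulated. Scenes use
30 m pixels on a UTM-like grid.

What the generator does **not** emulate: spatial autocorrelation, mixed
pixels at class boundaries, atmospheric or BRDF effects, clouds, tides,
topography. Passing tests therefore demonstrate algorithmic correctness
against known ground truth, not performance on real imagery; in
particular the water/land separability here is sharper than real coastal
scenes with turbid water or tidal flats.

Fixture scales were chosen to keep the full suite fast while leaving the
asymptotic checks meaningful: a 256² island (radius 50 px) for shoreline
recovery, 200²–220² five-epoch series for the composite-index and
transition suites. At these sizes the island shoreline recovers its
analytic circumference within ~0.3% and reclamation growth within ~1%,
comfortably inside the 5%/10% acceptance bands.

## Numerical choices and degenerate inputs

* Min-max normalization of a constant layer raises a degenerate-range
  error naming the layer (a constant LUI on a single-class map is the
  common case) rather than silently producing zeros.
* An all-water or all-land mask yields an empty shoreline with a warning,
  not an error.
* Water-mask cleanup removes connected components (of both phases)
  strictly smaller than `min_size` pixels; default 0 (off).
* PCA requires ≥ 5 masked pixels and nonzero total variance; eigenvalues
  are clipped at 0 against roundoff.
* Percent change and change intensity are undefined for a zero baseline
  and raise, rather than returning infinities.

## Known limitations

* Only north-up affine georeferences; no CRS transformations (all inputs
  of one run must share a grid).
* The per-epoch PCA makes loadings year-specific; comparing raw PC1
  magnitudes across years is not meaningful (means of the rescaled index
  are).
* Shoreline length is resolution-dependent (coastline paradox); lengths
  are comparable only across epochs on the same grid, which is how the
  change metrics use them.
* Kappa is computed from point samples assumed independent; clustered
  sampling would overstate precision.
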