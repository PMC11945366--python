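# irsei

Raster analytics for island ecological-quality monitoring: a library and
command-line tool that builds an **island remote-sensing ecological index
(IRSEI)** from multiband surface-reflectance scenes, tracks land-cover
transitions, and measures shoreline change.

## Who this is for

Remote-sensing ecologists and coastal-zone analysts who already have
preprocessed surface-reflectance rasters (Landsat TM/OLI or Sentinel-2
style band sets) plus classified land-cover maps, and want reproducible,
scriptable ecological-quality products rather than a GIS point-and-click
workflow. A synthetic-scene generator with exact ground truth makes every
stage testable without any satellite downloads.

## The index

Five normalized indicators enter the composite, each min-max scaled to
[0, 1] over the water-masked land area:

| layer | meaning | definition |
|---|---|---|
| GNDVI | greenness | (ρ_NIR − ρ_GREEN)/(ρ_NIR + ρ_GREEN) |
| WET | wetness | tasselled-cap wetness, sensor-specific 6-band coefficients |
| M-NDBSI | dryness | (SI + IBI)/2 + σ(SI, IBI), SI and IBI each normalized first |
| TIR | heat | min-max normalized LST from the single-channel thermal chain L = gain·DN + bias, T = K2/ln(K1/L + 1), LST = T/(1 + (λT/ρ)·ln ε) |
| LUI | land-use intensity | per-pixel class weight (bare 1; water/forest/grass/shrub 2; farmland/ponds 3; built-up 4), rescaled to [0, 1] |

The headline index is PCA-based: with PC1 the first principal component of
the 5×5 covariance of the stacked layers (sign-oriented so greenness loads
non-positively),

    IRSEI₀ = 1 − PC1,   IRSEI = (IRSEI₀ − min)/(max − min) ∈ [0, 1]

so values near 1 mean good ecological condition. An equal-weight variant
`(GNDVI + NDWI + (1 − M-NDBSI) + (1 − TIR) + (1 − LUI))/5` is also
provided. The index is graded into five levels (poor → excellent, default
breaks 0.2/0.4/0.6/0.8) with per-level area accounting.

Around the index the package implements: class-area and percent-change
statistics, class-by-class transition matrices, overall accuracy and
Cohen's kappa against reference samples, AWEI water segmentation with
Otsu's threshold, sub-pixel shoreline vectorization with Douglas–Peucker
simplification, and coastline change intensity CCI = (L_t2 − L_t1)/T.

## Worked example

Run the built-in degradation scenario — a synthetic island whose forest
shrinks while a built-up block expands over five epochs — through the full
pipeline:

```python
from irsei import synth, pipeline, raster, engine

thermal = raster.ThermalConstants(gain=0.055, bias=1.18, K1=607.76, K2=1260.56,
                                  wavelength_m=11.45e-6, emissivity=0.95)
script = synth.degradation_script()
series = synth.make_timeseries(script, seed=42)
products = [pipeline.run_epoch(scene, lcm, thermal, label=label)
            for label, (scene, lcm) in zip(script.epochs, series)]
summary = engine.summarize_epochs([p.irsei.mean for p in products],
                                  [p.label for p in products],
                                  [p.irsei.std for p in products])
print(summary.round(4).to_string(index=False))
```

```
epoch   mean    std   delta  cumulative
 2002 0.7940 0.2285     NaN      0.0000
 2007 0.7155 0.2918 -0.0784     -0.0784
 2013 0.6500 0.3315 -0.0655     -0.1440
 2017 0.5814 0.3686 -0.0687     -0.2126
 2022 0.4839 0.3733 -0.0975     -0.3101
```

The epoch-mean IRSEI falls monotonically as the scripted degradation
proceeds — `delta` is the change per interval and `cumulative` the running
change since the first epoch (−0.31 over the series). The 2022 PC1
loadings `(GNDVI, WET, M-NDBSI, TIR, LUI) = (-0.394, -0.405, 0.217, 0.364,
0.708)` show land-use intensity and heat driving the first component, with
greenness and wetness opposing them, as expected for urbanising land.

The same pipeline runs from the shell:

```bash
irsei synth --script degradation --seed 42 --out-dir scenes/   # also writes config.yaml
irsei run-all scenes/config.yaml --out-dir products/
```

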