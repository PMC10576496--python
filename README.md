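# reefstruct

Colony-scale structural complexity of coral reef digital elevation models
(DEMs), for reef ecologists working with photogrammetric reconstructions of
individual colonies. The package computes five terrain metrics per DEM and
relates them to benthic composition (live coral / dead skeleton / other
substrate) with a compositional-data robust regression, so that the
structural contribution of dead coral can be separated from that of living
tissue. A seeded synthetic-data module generates DEMs, benthic masks and
composition tables with the statistical structure the analysis assumes, so
the whole pipeline is testable without field data.

## The metrics and the model

For an elevation raster on a 1 cm working grid:

- **Surface rugosity** `R = S / A`, the 3-D (geodesic) surface area over the
  planform area of the same footprint; `R ≥ 1`, with 1 a perfect plane.
- **Fractal dimension** `D = 2 − d log S(δ) / d log δ`, where `S(δ)` is the
  geodesic area recomputed after edge-clipping and block-aggregating the DEM
  to cell size `δ ∈ {1, 2, 4, 8, 16, 32} cm`. `D ∈ [2, 3]`; the log–log fit's
  `R²` objectifies the fractality check.
- **Slope**, **planform curvature** and **profile curvature** per cell from
  the Zevenbergen–Thorne quadratic fitted to each 3×3 window, summarised by
  mean / median / min / max / quartiles; the IQR is the dispersion summary
  used in the regressions.

Benthic areas `(live, dead, other)` in m² are parts of a composition.
Below-detection zeros are replaced by `α · GSD²` (α = 0.05, GSD the native
ground sampling distance), the composition is expressed in pivot (ilr)
log-ratio coordinates

`z₁ = √(2/3) · ln( x_j / √(x_k x_l) ),  z₂ = √(1/2) · ln( x_k / x_l )`,

and each metric `y` is regressed on `(z₁, z₂)` by least trimmed squares
(LTS, exact subset enumeration for n ≤ 15, seeded FAST-LTS above), once per
pivot part `j`. The reported effect per part is the predicted change in `y`
when 1 m² of that part is added to the mean composition.

## Worked example

`examples/05_full_study.py` simulates ten colonies sweeping from almost
entirely live to almost entirely dead (dead skeleton generated rougher than
live tissue) and runs the full analysis:

```
| Metric | Benthos | dy/m2 | SEM | p | |
|---|---|---|---|---|---|
| Fractal Dimension | Live | -0.05436 | 0.007955 | 0.0001359 | * |
| Fractal Dimension | Dead | 0.1749 | 0.03931 | 0.004365 | * |
| Fractal Dimension | Other | -0.1267 | 0.03853 | 0.03532 | * |
...
```

The negative Live row means each added m² of live cover predicts a lower
fractal dimension — live tissue smooths the colony relative to bare
skeleton, the qualitative signature the analysis is designed to detect.
The remaining examples each exercise one capability (colony simulation,
terrain metrics, the S(δ) curve, the compositional regression) and print a
line on what the numbers mean.

A thin CLI mirrors the pipeline stages:

```sh
reefstruct simulate study --seed 1 --out-dir study
reefstruct run study --out-dir results
reefstruct figures results/effects.csv --out-dir figures
```

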