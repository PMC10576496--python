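# Methods

## Scope and data model

The package analyses colony-scale DEMs: square-celled elevation grids in
metres, nominally at 1 cm working resolution, paired with a categorical
benthic mask (Live coral tissue / Dead skeleton / Other substrate) on the
same grid. Elevations may be positive-up or negative-down; every metric is
invariant to adding a constant. Grids are stored row-major from the
top-left with the geotransform origin at the lower-left corner. No-data is
NaN in memory and a sentinel on disk.

Native photogrammetric resolution (ground sampling distance, GSD, metres
per pixel; typically ~0.0006) is carried as provenance. It defines the
detection limit for compositional zeros as one native pixel, GSD² m².
DEMs at native resolution are block-mean aggregated to the 1 cm working
grid before any metric; block means preserve integrated elevation, which
is the right invariant for area-based metrics (bilinear would not).

## Edge trimming

Before multiscale analysis the DEM is trimmed with the aggregation rule:
partition into n×n blocks from the top-left; any block containing no-data
or extending past the grid edge is nulled in full at the original
resolution. This guarantees that every aggregation step sees a footprint
aligned with its own block structure, so the surface-area curve is not
contaminated by partially covered coarse cells. The operation never adds
valid cells, is idempotent per factor, and the valid-cell count is
non-increasing in the factor.

## Geodesic surface area

Cell centers are treated as measured nodes. Every 2×2 block of valid
nodes contributes two 3-D triangles (split along the NW–SE diagonal), and
the half-cell strip outside the outermost node ring is completed with
ghost nodes extrapolated linearly (1.5·edge − 0.5·inner). The
triangulated footprint therefore equals the full cell coverage, and the
scheme is exact for planes: a flat raster returns its planform area at
every aggregation — pinning the flat-surface fractal dimension at exactly
2 — and a plane at angle θ returns area/cos θ. On rough surfaces the
interior is a pure node triangulation; it agrees with an independent
8-triangle (Jenness-style) estimate to within 2 % in the tests. Rugosity
divides by the planform area of the identical valid-block footprint, so
`R ≥ 1` holds block-by-block.

## Fractal dimension

`S(δ)` is computed at working cell sizes δ = 1, 2, 4, 8, 16, 32 cm
(aggregation factors 1–32 on the 1 cm grid; the coarsest step must not
exceed a quarter of the shorter grid extent). The six step labels double
in linear resolution, matching how surface-area-based fractal estimators
vary scale. `D = 2 − slope` of the least-squares fit of ln S against
ln δ; natural logs, fixed for bit-reproducibility (the estimate itself is
base-invariant). The fractality prerequisite is made objective: the fit's
R² must reach 0.98 (configurable) for the `is_fractal` flag; D is
reported regardless, flagged. A zero-variance curve (flat surface) is
perfectly linear by convention. Steps whose clipped footprint no longer
contains a valid 2×2 block — common when metrics are restricted to one
scattered mask category — are dropped with a warning; at least three
steps must survive.

## Slope and curvature

Per interior cell, the Zevenbergen–Thorne coefficients of the 9-term
surface on the 3×3 window (an Evans-style 6-point quadratic is available
behind a switch):

- slope = arctan √(G² + H²), degrees;
- profile curvature = −2(DG² + EH² + FGH)/(G² + H²) · 100, positive
  convex-upslope;
- planform curvature = 2(DH² + EG² − FGH)/(G² + H²) · 100.

Cells whose window touches no-data are no-data, including when the
offending neighbour does not enter the formula — the window contract is
all-or-nothing. Cells with a vanishing gradient (G² + H² < 1e−12) take
curvature 0 by convention, keeping dispersion summaries defined on
near-planar sand. Unit caveat: with elevations and cell sizes in metres
the ×100 scaling yields curvature magnitudes of order 10⁴ at centimetre
scales (curvature radii of a few cm); published colony-scale curvature
summaries of order 10²–10³ are consistent with unscaled m⁻¹ values, so
compare magnitudes across studies only after checking units. All
regression results here are invariant to the choice up to a constant
factor on the effect sizes.

Summaries (mean, median, min, max, quartiles, IQR) use linear
interpolation between order statistics; the IQR is the dispersion measure
fed to the regressions, because colony-scale distributions are heavy-tailed
and means flatten exactly the variability of interest.

## Compositional regression

Benthic areas vary independently across colonies (totals differ), so the
composition is not closed to a constant sum. Zeros are rounded zeros —
cover below one native pixel — and are replaced by α · GSD² with α = 0.05;
the default simple substitution leaves nonzero parts untouched (closure is
not assumed), with a closed multiplicative variant available that rescales
nonzero parts to preserve the record's total.

The log-ratio representation is pivot (ilr) coordinates with each part
taking the pivot role in turn; the three coordinate systems are orthogonal
rotations of one another, so the three fits share fitted values, residuals
and objective — asserted at run time to 1e−9 — and only the meaning of the
reported z₁ coefficient changes. clr/alr alternatives are deliberately not
offered: pivot coordinates keep the per-part inference well-defined.

Least trimmed squares minimises the sum of the h smallest squared
residuals, h = ⌊(n + p + 1)/2⌋ by default (maximum breakdown;
configurable). For n ≤ 15 the optimum is exact by enumerating all
h-subsets; above that, seeded FAST-LTS runs concentration steps from 500
random elemental starts. h = n reduces the fit to OLS exactly, including
its classical inference. Standard errors and p-values come from the
reweighted step: observations with |r|/σ̂ ≤ 2.5 under the
consistency-corrected LTS scale are kept and classical weighted-OLS
inference applied. At n = 10 (a realistic colony count) these p-values
rest on ~7–9 effective observations and are fragile; the effect tables
carry `n_retained` so readers can judge.

The reported effect `Δŷ/m²` is a finite-difference prediction: add
1 m² of part j to the part-wise mean composition, others fixed, and take
the change in the fitted response under the pivot-j model. The raw
coordinate coefficient is always reported alongside, because the
conversion from log-ratio coefficients to per-m² effects is a convention,
not an identity.

## Synthetic data: what it emulates and what it does not

`gen_fbm_dem` synthesises fractional Brownian surfaces spectrally
(amplitude spectrum ∝ f^−(H+1), seeded random phases, elevation SD
rescaled exactly to the requested amplitude); theoretical fractal
dimension 3 − H. Grids are powers of two ≥ 64 so the FFT synthesis is
exact and all six aggregation factors divide evenly.

`gen_benthic_mask` rank-thresholds a smoothed Gaussian field, so realised
category fractions match requests to integer rounding; `smoothness` is
the characteristic patch radius in cells (kernel σ = 2·smoothness),
giving of order ten contiguous patches per category on a 256² grid at the
default 8.

`gen_colony` composites category-specific relief through the mask. Live
and Dead share a single phase realisation and differ in spectral slope
and amplitude (defaults H = 0.7 / 0.11 m SD live, H = 0.35 / 0.24 m SD
dead), so the colony keeps one coherent gross morphology while dead
regions carry more fine-scale detail — compositing independent fields
instead produces ~0.3 m walls at category boundaries that dominate the
surface-area curve. Other cells drape over the smoothed gross morphology
(gain 0.75) plus 5 mm noise: sand settles around the colony base rather
than sitting on an absolute plane. The defaults were calibrated once so
whole-colony metrics land in the bands reported for real A. palmata
colonies — fractal dimension ≈ 2.36–2.42 (observed range 2.28–2.46) and
rugosity ≈ 3.7–4.5 (observed 2.64–4.79) — with two known residuals: median
slopes come out near 64°, above the observed 39–60°, and the composite
surface-area curve's R² (~0.96) sits just below the 0.98 fractality
threshold, because a mixture of two power-law surfaces plus flat sand is
not itself a power law. The live/dead roughness contrast is deliberately
much stronger than the small category difference real colonies show; it
exists to make the direction of composition effects detectable at n = 10,
so passing tests demonstrate sign recovery under a favourable
signal-to-noise ratio, not that field data of this size would reach
significance.

`gen_coda_dataset` draws Dirichlet(5, 5, 3) compositions scaled by totals
uniform on 1.2–2.46 m², builds the response from known pivot-coordinate
coefficients plus Gaussian noise, shifts a seeded fraction of responses
(outliers), and can floor a record's smallest part to zero to exercise the
rounded-zero path. The generating coefficients are returned for
assertion. All generators draw from per-generator streams derived from
the user seed with fixed offsets, so adding one generator never perturbs
another's output, and every generator is bit-reproducible for a fixed
seed.

## Problem sizes and numerical choices

Default study simulations use ten 128² colonies at 1 cm cells (1.64 m²
planform, inside the 1.20–2.46 m² survey range); estimator-validation runs
use 256²–512² grids and 200-replicate Monte-Carlo batches at n = 50 —
sizes at which every documented check completes in seconds to a couple of
minutes on one core. Quartiles use linear interpolation; log–log fits use
natural logs; LTS ties between subsets resolve to the first enumerated
optimum; the flat-gradient curvature threshold is 1e−12; CSV output uses a
fixed 10-significant-digit format so repeated runs are byte-identical.

## Known limitations

- Planar-view DEMs only: overhangs and undersides do not exist in a
  single-valued elevation grid, so complexity under ledges is invisible.
- The regression stage assumes one metric value per colony; per-category
  metric regressions are supported as optional output but the default
  pipeline regresses whole-colony metrics on composition.
- Reweighted-LTS inference at n ≈ 10 is fragile (see above); treat
  p-values near the thresholds as indicative.
- fBm is isotropic and Gaussian; real branching corals are neither, so
  generator realism extends to roughness statistics, not morphology.
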