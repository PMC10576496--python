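"""Seeded generators for DEMs, benthic masks and compositional datasets.

The generators emulate the statistical structure of colony-scale coral
photogrammetry: fractional Brownian relief whose roughness depends on the
benthic category (bare skeleton rougher than live tissue, sand nearly
flat), blob-like category masks, and three-part area compositions with
occasional below-detection zeros.  They provide ground-truth inputs for
every downstream stage, with bit-reproducible output for a fixed seed.

Random streams are per-generator: each derives its own stream from the
user seed and a fixed offset, so adding a generator never perturbs
another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .coda import pivot_coordinates
from .rasters import DEAD, LIVE, OTHER, BenthicMask, ElevationRaster

# fixed stream offsets so generators draw independently from one user seed
_STREAM_FBM = 101
_STREAM_MASK = 202
_STREAM_OTHER = 303
_STREAM_CODA = 404

# native photogrammetric resolution carried as provenance (m/pixel);
# defines the detection-limit area GSD^2 for compositional zeros
DEFAULT_GSD = 0.0006


@dataclass
class ColonyParams:
    """Geometry and roughness of one synthetic colony.

    Defaults are calibrated so that whole-colony metrics land in the bands
    observed for real A. palmata colonies (fractal dimension ≈ 2.28–2.46,
    rugosity ≈ 2.6–4.8, planform areas ≈ 1.2–2.5 m²).  Dead skeleton is
    rougher than live tissue (lower Hurst exponent, higher amplitude);
    Other Benthos is near-flat sand.
    """

    live_fraction: float = 0.35
    dead_fraction: float = 0.36
    hurst_live: float = 0.7
    hurst_dead: float = 0.35
    amplitude_live: float = 0.11
    amplitude_dead: float = 0.24
    other_noise_sd: float = 0.005
    other_base_gain: float = 0.75
    grid_cells: int = 128
    cell_size: float = 0.01
    mask_smoothness: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.live_fraction <= 1 and 0 <= self.dead_fraction <= 1):
            raise ValueError("fractions must be in [0,1]")
        if self.live_fraction + self.dead_fraction > 1 + 1e-9:
            raise ValueError("live_fraction + dead_fraction must be <= 1")
        for h in (self.hurst_live, self.hurst_dead):
            if not 0 < h < 1:
                raise ValueError("Hurst exponents must be in (0,1)")


@dataclass
class CodaSimParams:
    """Generating model for compositional regression datasets."""

    n_colonies: int = 50
    coord_coefficients: tuple[float, float] = (0.05, 0.0)
    intercept: float = 2.36
    noise_sd: float = 0.02
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    total_area_range: tuple[float, float] = (1.2, 2.46)
    concentration: tuple[float, float, float] = (5.0, 5.0, 3.0)
    zero_probability: float = 0.0
    gsd: float = DEFAULT_GSD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 5:
            raise ValueError("regression needs at least 5 colonies")
        if not 0 <= self.outlier_fraction <= 0.4:
            raise ValueError("outlier_fraction must be in [0, 0.4]")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.total_area_range
        if not lo < hi:
            raise ValueError("total_area_range must satisfy low < high")


def _spectral_fbm(noise: np.ndarray, hurst: float) -> np.ndarray:
    """Filter complex white noise to a self-affine field, unit-free scale.

    The amplitude spectrum falls as f^-(H+1), i.e. power spectral density
    ∝ f^-(2H+2); the theoretical fractal dimension of the surface is 3 − H.
    """
    n = noise.shape[0]
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    mag = f ** (-(hurst + 1.0))
    mag[0, 0] = 0.0  # zero the mean; absolute elevation is arbitrary
    return np.fft.ifft2(noise * mag).real


def _validate_grid(grid_cells: int) -> None:
    if grid_cells < 64 or grid_cells & (grid_cells - 1) != 0:
        raise ValueError("grid_cells must be a power of two >= 64")


def gen_fbm_dem(
    hurst: float,
    grid_cells: int,
    cell_size: float,
    amplitude: float,
    seed: int,
    gsd: float = DEFAULT_GSD,
) -> ElevationRaster:
    """Fractional Brownian surface with elevation SD rescaled to ``amplitude``.

    Synthesised spectrally with seeded random phases; theoretical fractal
    dimension 3 − hurst.  Deterministic for a fixed seed.
    """
    _validate_grid(grid_cells)
    if not 0 < hurst < 1:
        raise ValueError("hurst must be in (0,1)")
    if not amplitude > 0:
        raise ValueError("amplitude must be positive")
    rng = np.random.default_rng([_STREAM_FBM, seed])
    noise = rng.standard_normal((grid_cells, grid_cells)) + 1j * rng.standard_normal(
        (grid_cells, grid_cells)
    )
    z = _spectral_fbm(noise, hurst)
    sd = z.std()
    if sd == 0:
        raise ValueError("degenerate zero-variance field cannot be rescaled")
    z = z * (amplitude / sd)
    return ElevationRaster(z, cell_size, gsd=gsd)


def gen_benthic_mask(
    grid_cells: int,
    fractions: tuple[float, float, float],
    smoothness: float = 8.0,
    seed: int = 0,
    cell_size: float = 0.01,
) -> BenthicMask:
    """Blob-structured 3-category mask with near-exact category fractions.

    A seeded Gaussian noise field is smoothed and rank-thresholded so the
    realised Live/Dead/Other counts match the requested fractions up to
    integer rounding.  ``smoothness`` is the characteristic patch radius in
    cells (the kernel's σ is 2·smoothness, so patches span several
    smoothness-lengths); smoothness ≥ 4 gives contiguous blobs rather than
    salt-and-pepper labels — of order ten patches per category on a 256²
    grid at the default 8.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9 or (fractions < 0).any():
        raise ValueError("fractions must be non-negative and sum to 1")
    if smoothness < 1:
        raise ValueError("smoothness must be >= 1 cell")
    rng = np.random.default_rng([_STREAM_MASK, seed])
    fieldv = gaussian_filter(
        rng.standard_normal((grid_cells, grid_cells)), 2.0 * smoothness
    )
    order = np.argsort(fieldv, axis=None, kind="stable")
    n = grid_cells * grid_cells
    n_live = int(round(fractions[0] * n))
    n_dead = int(round(fractions[1] * n))
    n_dead = min(n_dead, n - n_live)
    labels = np.empty(n, dtype=np.uint8)
    labels[order[:n_live]] = LIVE
    labels[order[n_live : n_live + n_dead]] = DEAD
    labels[order[n_live + n_dead :]] = OTHER
    return BenthicMask(labels.reshape(grid_cells, grid_cells), cell_size)


def gen_colony(params: ColonyParams) -> tuple[ElevationRaster, BenthicMask]:
    """Composite colony surface: category-specific roughness through one mask.

    Live and Dead relief share a single spectral phase realisation and
    differ only in spectral slope (Hurst) and amplitude, so the composited
    colony keeps a coherent gross morphology while Dead regions carry more
    fine-scale detail.  Other cells drape over the smoothed gross
    morphology (sand settling around the colony base, attenuated by
    ``other_base_gain``) plus low-amplitude noise, which avoids artificial
    cliffs at category boundaries.  Planform area is
    grid_cells² · cell_size².
    """
    p = params
    _validate_grid(p.grid_cells)
    n = p.grid_cells
    rng = np.random.default_rng([_STREAM_FBM, p.seed])
    noise = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))

    def scaled(hurst: float, amplitude: float) -> np.ndarray:
        z = _spectral_fbm(noise, hurst)
        return z * (amplitude / z.std())

    z_live = scaled(p.hurst_live, p.amplitude_live)
    z_dead = scaled(p.hurst_dead, p.amplitude_dead)
    rng_other = np.random.default_rng([_STREAM_OTHER, p.seed])
    z_other = gaussian_filter(rng_other.standard_normal((n, n)), 2.0)
    sd = z_other.std()
    z_other = z_other * (p.other_noise_sd / sd) if sd > 0 else z_other
    z_other = z_other + gaussian_filter(z_live, p.mask_smoothness) * p.other_base_gain

    other_fraction = 1.0 - p.live_fraction - p.dead_fraction
    mask = gen_benthic_mask(
        n,
        (p.live_fraction, p.dead_fraction, max(other_fraction, 0.0)),
        smoothness=p.mask_smoothness,
        seed=p.seed,
        cell_size=p.cell_size,
    )
    z = np.where(
        mask.labels == LIVE, z_live, np.where(mask.labels == DEAD, z_dead, z_other)
    )
    raster = ElevationRaster(z, p.cell_size, gsd=DEFAULT_GSD)
    return raster, mask


def gen_coda_dataset(params: CodaSimParams) -> tuple[pd.DataFrame, dict]:
    """Compositional regression dataset with known generating coefficients.

    Per colony: a Dirichlet 3-part composition scaled by a uniform total
    area; the response is intercept + pivot-coordinates · coord_coefficients
    + Gaussian noise, with a seeded fraction of responses shifted by
    ``outlier_shift``.  Optionally floors a part below the detection limit
    to 0 with probability ``zero_probability`` to exercise the rounded-zero
    path.  Returns (records, truth) where truth holds the generating
    coefficients and outlier flags.
    """
    p = params
    rng = np.random.default_rng([_STREAM_CODA, p.seed])
    n = p.n_colonies
    comp = rng.dirichlet(p.concentration, size=n)
    totals = rng.uniform(*p.total_area_range, size=n)
    areas = comp * totals[:, None]
    z = pivot_coordinates(areas, pivot_part=0)
    response = (
        p.intercept
        + z @ np.asarray(p.coord_coefficients, dtype=float)
        + rng.normal(0.0, p.noise_sd, size=n)
    )
    n_out = int(round(p.outlier_fraction * n))
    outlier_rows = np.sort(rng.choice(n, size=n_out, replace=False)) if n_out else np.array([], int)
    response[outlier_rows] += p.outlier_shift

    dl = p.gsd**2
    if p.zero_probability > 0:
        # structural zero: the record's smallest part drops below detection
        floor_row = rng.random(n) < p.zero_probability
        smallest = np.argmin(areas, axis=1)
        areas[floor_row, smallest[floor_row]] = 0.0

    records = pd.DataFrame(
        {
            "colony_id": [f"sim{i:03d}" for i in range(n)],
            "live_m2": areas[:, 0],
            "dead_m2": areas[:, 1],
            "other_m2": areas[:, 2],
            "detection_limit_m2": dl,
            "response": response,
        }
    )
    truth = {
        "intercept": p.intercept,
        "coord_coefficients": tuple(p.coord_coefficients),
        "outlier_rows": outlier_rows,
    }
    return records, truth


@dataclass
class StudyParams:
    """A sweep of colonies spanning mostly-live to mostly-dead compositions."""

    n_colonies: int = 10
    live_range: tuple[float, float] = (0.05, 0.95)
    dead_share_range: tuple[float, float] = (0.4, 0.7)
    colony: ColonyParams = field(default_factory=ColonyParams)
    seed: int = 0


def gen_study(params: StudyParams) -> list[tuple[str, ElevationRaster, BenthicMask]]:
    """Generate a study's worth of colonies with varying benthic composition.

    Live fraction is swept linearly across ``live_range``; the remainder is
    split between Dead and Other with a seeded random Dead share.  Each
    colony gets its own derived seed.
    """
    p = params
    rng = np.random.default_rng([_STREAM_MASK, p.seed, 7])
    live_fracs = np.linspace(*p.live_range, p.n_colonies)
    out = []
    for i, lf in enumerate(live_fracs):
        share = rng.uniform(*p.dead_share_range)
        cp = ColonyParams(
            live_fraction=float(lf),
            dead_fraction=float((1.0 - lf) * share),
            hurst_live=p.colony.hurst_live,
            hurst_dead=p.colony.hurst_dead,
            amplitude_live=p.colony.amplitude_live,
            amplitude_dead=p.colony.amplitude_dead,
            other_noise_sd=p.colony.other_noise_sd,
            grid_cells=p.colony.grid_cells,
            cell_size=p.colony.cell_size,
            mask_smoothness=p.colony.mask_smoothness,
            seed=p.seed * 1009 + i,
        )
        raster, mask = gen_colony(cp)
        out.append((f"colony{i:02d}", raster, mask))
    return out
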