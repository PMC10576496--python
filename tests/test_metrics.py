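import numpy as np
import pytest

from reefstruct import (
    DEAD,
    LIVE,
    ColonyParams,
    ElevationRaster,
    colony_metrics,
    curvature_cells,
    fractal_dimension,
    gen_colony,
    gen_fbm_dem,
    geodesic_area,
    planform_area,
    slope_cells,
    summarize_cells,
    surface_area_curve,
    surface_rugosity,
)
from reefstruct.errors import DegenerateSurfaceError, EmptyInputError
from reefstruct.metrics import SurfaceAreaCurve

from conftest import make_plane, seeded_rough_raster


class TestPlanformArea:
    def test_full_grid(self, flat_raster):
        assert planform_area(flat_raster) == pytest.approx(1.0)

    def test_nodata_reduces_area(self):
        values = np.zeros((100, 100))
        values.flat[:50] = np.nan
        assert planform_area(ElevationRaster(values, 0.01)) == pytest.approx(0.995)

    def test_default_colony_planform_in_survey_band(self):
        raster, _ = gen_colony(ColonyParams(seed=0))
        assert 1.20 <= planform_area(raster) <= 2.46


class TestGeodesicArea:
    def test_flat_plane_equals_footprint(self, flat_raster):
        assert geodesic_area(flat_raster) == pytest.approx(1.0, abs=1e-12)

    def test_inclined_plane_secant_scaling(self):
        for deg, factor in [(45.0, np.sqrt(2.0)), (60.0, 2.0)]:
            plane = make_plane(deg)
            assert geodesic_area(plane) == pytest.approx(factor, rel=1e-9)

    def test_offset_invariance(self):
        raster = seeded_rough_raster(2)
        shifted = raster.with_values(raster.values + 12.3)
        assert geodesic_area(shifted) == pytest.approx(geodesic_area(raster), rel=1e-12)

    def test_matches_eight_triangle_oracle(self):
        """Independent Jenness-style estimate: 8 triangles per cell spanning
        half the distance to each neighbour, edge rows excluded."""

        def jenness(raster):
            z = raster.values
            d = raster.cell_size
            total = 0.0
            diag = d * np.sqrt(2.0)
            for i in range(1, z.shape[0] - 1):
                for j in range(1, z.shape[1] - 1):
                    zc = z[i, j]
                    neigh = [
                        (z[i - 1, j - 1], diag), (z[i - 1, j], d),
                        (z[i - 1, j + 1], diag), (z[i, j + 1], d),
                        (z[i + 1, j + 1], diag), (z[i + 1, j], d),
                        (z[i + 1, j - 1], diag), (z[i, j - 1], d),
                    ]
                    # 3-D half-distances from the center to each neighbour
                    lengths = [
                        np.hypot(dist / 2, (zn - zc) / 2) for zn, dist in neigh
                    ]
                    for k in range(8):
                        a = lengths[k]
                        b = lengths[(k + 1) % 8]
                        # planar edge between adjacent half-points
                        zn1, d1 = neigh[k]
                        zn2, d2 = neigh[(k + 1) % 8]
                        # coordinates of the two half-points relative to center
                        pts = {
                            0: (-d / 2, -d / 2), 1: (0, -d / 2), 2: (d / 2, -d / 2),
                            3: (d / 2, 0), 4: (d / 2, d / 2), 5: (0, d / 2),
                            6: (-d / 2, d / 2), 7: (-d / 2, 0),
                        }
                        x1, y1 = pts[k]
                        x2, y2 = pts[(k + 1) % 8]
                        c = np.sqrt(
                            (x1 - x2) ** 2 + (y1 - y2) ** 2
                            + ((zn1 - zc) / 2 - (zn2 - zc) / 2) ** 2
                        )
                        s = (a + b + c) / 2
                        total += np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0))
            return total

        raster = gen_fbm_dem(0.6, 64, 0.01, 0.05, seed=4)
        interior = raster.with_values(raster.values[1:-1, 1:-1])
        ours = geodesic_area(interior)
        theirs = jenness(raster)
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_too_sparse_rejected(self):
        values = np.full((4, 4), np.nan)
        values[0, 0] = values[2, 2] = values[3, 0] = values[0, 3] = 1.0
        with pytest.raises(DegenerateSurfaceError):
            geodesic_area(ElevationRaster(values, 0.01))


class TestRugosity:
    def test_flat_is_one(self, flat_raster):
        assert surface_rugosity(flat_raster) == pytest.approx(1.0, abs=1e-12)

    def test_tilted_planes(self):
        assert surface_rugosity(make_plane(45.0)) == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_always_at_least_one(self):
        for seed in range(5):
            assert surface_rugosity(seeded_rough_raster(seed)) >= 1.0


class TestSurfaceAreaCurve:
    def test_flat_slope_zero(self):
        raster = ElevationRaster(np.zeros((256, 256)), 0.01)
        curve = surface_area_curve(raster)
        assert np.allclose(curve.areas, curve.areas[0])
        assert curve.log_slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_manual_pipeline(self):
        from reefstruct import aggregate_clip, resample_to_grid

        raster = gen_fbm_dem(0.5, 128, 0.01, 0.1, seed=2)
        curve = surface_area_curve(raster)
        for f, s in zip((1, 2, 4, 8, 16, 32), curve.areas):
            manual = geodesic_area(
                resample_to_grid(aggregate_clip(raster, f), f * 0.01)
            )
            assert s == manual  # bit-for-bit

    def test_fbm_curve_is_linear_in_loglog(self):
        raster = gen_fbm_dem(0.5, 512, 0.01, 0.5, seed=0)
        curve = surface_area_curve(raster)
        assert curve.r_squared >= 0.98

    def test_oversized_factor_rejected(self):
        raster = ElevationRaster(np.zeros((64, 64)), 0.01)
        with pytest.raises(ValueError, match="32"):
            surface_area_curve(raster, factors=(1, 2, 32))


class TestFractalDimension:
    def test_flat_curve_gives_two(self):
        raster = ElevationRaster(np.zeros((256, 256)), 0.01)
        fit = fractal_dimension(surface_area_curve(raster))
        assert fit.d == pytest.approx(2.0, abs=1e-12)
        assert fit.is_fractal

    def test_injected_power_law_recovered(self):
        deltas = 0.01 * np.array([1, 2, 4, 8, 16, 32], float)
        for exponent, d_true in [(-0.4, 2.4), (-1.0, 3.0), (0.0, 2.0)]:
            areas = 3.7 * deltas**exponent
            ls, r2 = np.polyfit(np.log(deltas), np.log(areas), 1)[0], 1.0
            curve = SurfaceAreaCurve(deltas, areas, ls, r2)
            assert fractal_dimension(curve).d == pytest.approx(d_true, abs=1e-12)

    def test_needs_three_points(self):
        curve = SurfaceAreaCurve(np.array([0.01, 0.02]), np.array([1.0, 0.9]), -0.1, 1.0)
        with pytest.raises(ValueError):
            fractal_dimension(curve)

    def test_nonpositive_area_rejected(self):
        curve = SurfaceAreaCurve(
            np.array([0.01, 0.02, 0.04]), np.array([1.0, 0.0, 0.9]), -0.1, 1.0
        )
        with pytest.raises(ValueError):
            fractal_dimension(curve)


class TestSlopeCurvature:
    def test_unit_gradient_plane_is_45_degrees(self):
        plane = make_plane(45.0)
        s = slope_cells(plane)
        interior = s[1:-1, 1:-1]
        assert np.allclose(interior, 45.0, atol=1e-9)
        assert np.isnan(s[0]).all() and np.isnan(s[:, 0]).all()

    def test_flat_plane_zero_slope_zero_curvature(self, flat_raster):
        assert np.nanmax(slope_cells(flat_raster)) == 0.0
        for kind in ("planform", "profile"):
            assert np.nanmax(np.abs(curvature_cells(flat_raster, kind))) == 0.0

    @pytest.mark.parametrize("method", ["zevenbergen_thorne", "evans"])
    def test_tilted_plane_zero_curvature(self, method):
        plane = make_plane(30.0)
        for kind in ("planform", "profile"):
            curv = curvature_cells(plane, kind, method=method)
            assert np.nanmax(np.abs(curv)) < 1e-6

    def test_parabola_profile_curvature_closed_form(self):
        # z = x²: G = 2x, D = 1, E = F = H = 0
        # profile = −2·D·G²/(G²)·100 = −200 wherever the gradient is nonzero
        n, cell = 64, 0.01
        x = (np.arange(n) + 0.5) * cell
        raster = ElevationRaster(np.tile(x**2, (n, 1)), cell)
        prof = curvature_cells(raster, "profile")
        assert np.allclose(prof[1:-1, 1:-1], -200.0, atol=1e-6)

    def test_saddle_planform_sign_flips_across_axes(self):
        # z = (x² − y²)/2: planform is −100 on the x-axis arms, +100 on y
        n, cell = 65, 0.01
        c = (np.arange(n) - n // 2) * cell
        xx, yy = np.meshgrid(c, c)
        raster = ElevationRaster((xx**2 - yy**2) / 2, cell)
        plan = curvature_cells(raster, "planform")
        mid = n // 2
        assert plan[mid, mid + 10] == pytest.approx(-100.0, abs=1e-6)
        assert plan[mid + 10, mid] == pytest.approx(100.0, abs=1e-6)

    def test_agrees_with_bruteforce_window_loop(self):
        """Independent per-window implementation of the 9-term surface fit."""
        raster = seeded_rough_raster(11, n=32)
        z, L = raster.values, raster.cell_size
        slope = slope_cells(raster)
        prof = curvature_cells(raster, "profile")
        plan = curvature_cells(raster, "planform")
        for i in range(1, 31):
            for j in range(1, 31):
                w = z[i - 1 : i + 2, j - 1 : j + 2]
                G = (w[1, 2] - w[1, 0]) / (2 * L)
                H = (w[0, 1] - w[2, 1]) / (2 * L)
                D = ((w[1, 0] + w[1, 2]) / 2 - w[1, 1]) / L**2
                E = ((w[0, 1] + w[2, 1]) / 2 - w[1, 1]) / L**2
                F = (-w[0, 0] + w[0, 2] + w[2, 0] - w[2, 2]) / (4 * L**2)
                g2 = G * G + H * H
                assert slope[i, j] == pytest.approx(
                    np.degrees(np.arctan(np.sqrt(g2))), abs=1e-9
                )
                assert prof[i, j] == pytest.approx(
                    -2 * (D * G * G + E * H * H + F * G * H) / g2 * 100, abs=1e-9
                )
                assert plan[i, j] == pytest.approx(
                    2 * (D * H * H + E * G * G - F * G * H) / g2 * 100, abs=1e-9
                )

    def test_nodata_window_propagates(self):
        values = np.zeros((8, 8))
        values[4, 4] = np.nan
        s = slope_cells(ElevationRaster(values, 0.01))
        assert np.isnan(s[3:6, 3:6]).all()
        assert s[1, 1] == 0.0


class TestSummarize:
    def test_one_to_hundred(self):
        stats = summarize_cells(np.arange(1.0, 101.0))
        assert stats.median == 50.5
        assert stats.q1 == 25.75
        assert stats.q3 == 75.25
        assert stats.iqr == 49.5

    def test_single_value(self):
        stats = summarize_cells(np.array([7.0]))
        assert (
            stats.mean == stats.median == stats.min == stats.max
            == stats.q1 == stats.q3 == 7.0
        )
        assert stats.iqr == 0.0

    def test_matches_sorted_interpolation_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(size=257)
        stats = summarize_cells(vals)

        def quantile(sorted_v, q):
            pos = q * (len(sorted_v) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(sorted_v) - 1)
            return sorted_v[lo] + (pos - lo) * (sorted_v[hi] - sorted_v[lo])

        sv = np.sort(vals)
        assert stats.q1 == pytest.approx(quantile(sv, 0.25), abs=1e-15)
        assert stats.median == pytest.approx(quantile(sv, 0.5), abs=1e-15)
        assert stats.q3 == pytest.approx(quantile(sv, 0.75), abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize_cells(np.full(5, np.nan))


class TestColonyMetrics:
    def test_flat_colony_all_trivial(self):
        raster = ElevationRaster(np.full((128, 128), 1.0), 0.01)
        mset = colony_metrics(raster, colony_id="flat")
        assert mset.surface_rugosity == pytest.approx(1.0, abs=1e-12)
        assert mset.fractal.d == pytest.approx(2.0, abs=1e-12)
        assert mset.slope_stats.max == 0.0
        assert mset.planform_curv_stats.iqr == 0.0
        assert mset.profile_curv_stats.iqr == 0.0

    def test_dead_regions_rougher_than_live(self):
        diffs = []
        for seed in range(5):
            raster, mask = gen_colony(
                ColonyParams(live_fraction=0.5, dead_fraction=0.4, seed=11 + seed)
            )
            with pytest.warns(UserWarning):
                d_dead = colony_metrics(raster, mask, category=DEAD).fractal.d
                d_live = colony_metrics(raster, mask, category=LIVE).fractal.d
            diffs.append(d_dead - d_live)
        assert np.mean(diffs) > 0

    def test_sparse_category_reports_missing_with_warning(self):
        raster, _ = gen_colony(ColonyParams(seed=0))
        labels = np.full(raster.shape, DEAD, np.uint8)
        labels[10, 10] = LIVE  # a single live cell: no 2x2 block
        from reefstruct import BenthicMask

        mask = BenthicMask(labels, raster.cell_size)
        with pytest.warns(UserWarning):
            mset = colony_metrics(raster, mask, category=LIVE)
        assert np.isnan(mset.surface_rugosity)
        assert np.isnan(mset.fractal.d)

    def test_translation_and_rotation_invariance(self):
        raster = gen_fbm_dem(0.5, 128, 0.01, 0.1, seed=6)
        base = colony_metrics(raster, colony_id="a")
        shifted = colony_metrics(
            raster.with_values(raster.values + 5.0), colony_id="b"
        )
        rotated = colony_metrics(
            raster.with_values(raster.values[::-1, ::-1].copy()), colony_id="c"
        )
        assert shifted.fractal.d == pytest.approx(base.fractal.d, rel=1e-9)
        assert shifted.surface_rugosity == pytest.approx(base.surface_rugosity, rel=1e-9)
        assert rotated.surface_rugosity == pytest.approx(base.surface_rugosity, rel=1e-6)
        assert rotated.slope_stats.median == pytest.approx(
            base.slope_stats.median, rel=1e-6
        )

    def test_fractal_d_increases_with_fbm_roughness(self):
        mean_d = []
        for hurst in (0.8, 0.5, 0.2):
            ds = [
                fractal_dimension(
                    surface_area_curve(gen_fbm_dem(hurst, 128, 0.01, 0.3, seed=s))
                ).d
                for s in range(3)
            ]
            mean_d.append(np.mean(ds))
        assert mean_d[0] < mean_d[1] < mean_d[2]
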