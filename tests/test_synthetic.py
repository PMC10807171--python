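"""Generator contracts: determinism, analytic examples, ground-truth closure."""

import numpy as np
import pytest
from scipy import stats as sps

from gliaquant import synthetic as syn
from gliaquant.filaments import analyze_filaments
from gliaquant.migration import analyze_gap_series, track_mobility
from gliaquant.puncta import detect_objects
from gliaquant.stats import regress_pair
from gliaquant.volume import analyze_trace

FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TestDeterminism:
    """Identical seeds and parameters give bit-identical outputs."""

    def test_cell_mask(self):
        a = syn.gen_cell_mask({"kind": "blob", "radius": 60, "amplitude": 0.4}, 192, seed=5)
        b = syn.gen_cell_mask({"kind": "blob", "radius": 60, "amplitude": 0.4}, 192, seed=5)
        assert np.array_equal(a.cell_mask, b.cell_mask)
        assert np.array_equal(a.nucleus_mask, b.nucleus_mask)

    def test_puncta_stack(self, ellipse_geom):
        s1, t1 = syn.gen_puncta_stack(ellipse_geom, 5, noise_sd=10, seed=11)
        s2, t2 = syn.gen_puncta_stack(ellipse_geom, 5, noise_sd=10, seed=11)
        assert np.array_equal(s1.voxels, s2.voxels)
        assert t1.centers_um == t2.centers_um

    def test_filament_image(self, ellipse_geom):
        i1 = syn.gen_filament_image(ellipse_geom, 20, concentration=3.0, seed=2)
        i2 = syn.gen_filament_image(ellipse_geom, 20, concentration=3.0, seed=2)
        assert np.array_equal(i1.voxels, i2.voxels)

    def test_series_traces_tracks_expression(self):
        g1 = syn.gen_gap_series(v_true=5, noise_sd=100, seed=3)
        g2 = syn.gen_gap_series(v_true=5, noise_sd=100, seed=3)
        assert np.array_equal(g1.areas, g2.areas)
        tr1, _ = syn.gen_calcein_trace(syn.SyntheticTraceTruth(noise_sd=2.0), seed=4)
        tr2, _ = syn.gen_calcein_trace(syn.SyntheticTraceTruth(noise_sd=2.0), seed=4)
        assert np.array_equal(tr1.F, tr2.F)
        k1, _ = syn.gen_tracks(8, 3.0, seed=5)
        k2, _ = syn.gen_tracks(8, 3.0, seed=5)
        assert np.array_equal(k1.positions, k2.positions)
        e1 = syn.gen_expression(seed=6)
        e2 = syn.gen_expression(seed=6)
        assert e1.values.equals(e2.values)


class TestCellMask:
    def test_circle_area_analytic(self):
        g = syn.gen_cell_mask({"kind": "circle", "radius": 100}, 256, pixel_size=0.1, seed=0)
        assert g.cell_area_px == pytest.approx(np.pi * 100**2, rel=0.005)

    def test_ellipse_long_axis_recorded(self):
        g = syn.gen_cell_mask({"kind": "ellipse", "a": 200, "b": 100, "angle": 30}, 512, seed=0)
        assert g.long_axis_angle == pytest.approx(30.0, abs=1e-9)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            syn.gen_cell_mask({"kind": "circle", "radius": 100}, 128, seed=0)

    def test_nucleus_strictly_inside(self):
        g = syn.gen_cell_mask({"kind": "blob", "radius": 70, "amplitude": 0.4}, 224, seed=9)
        assert np.all(g.cell_mask[g.nucleus_mask])
        assert g.nucleus_area_px < g.cell_area_px


class TestPunctaGenerator:
    def test_zero_spots_uniform_background(self, ellipse_geom):
        stack, truth = syn.gen_puncta_stack(ellipse_geom, 0, noise_sd=0, seed=0)
        assert np.all(stack.voxels == 0)
        assert truth.n == 0

    def test_centers_inside_mask(self, ellipse_geom):
        _, truth = syn.gen_puncta_stack(ellipse_geom, 15, min_separation=10, seed=2)
        for cx, cy, _ in truth.centers_um:
            px, py = int(cx / 0.1), int(cy / 0.1)
            assert ellipse_geom.cell_mask[py, px]

    def test_min_separation_respected(self, ellipse_geom):
        _, truth = syn.gen_puncta_stack(ellipse_geom, 12, min_separation=24, seed=2)
        pts = np.array([(x, y) for x, y, _ in truth.centers_um]) / 0.1
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 24

    def test_rendered_fwhm_matches_sigma(self, ellipse_geom):
        stack, _ = syn.gen_puncta_stack(ellipse_geom, 5, sigma=2.0, noise_sd=0,
                                        min_separation=20, seed=6)
        pset = detect_objects(stack, threshold=50.0)
        diam_px = np.mean([o.diameter_um for o in pset.objects]) / stack.pixel_size
        assert diam_px == pytest.approx(FWHM * 2.0, rel=0.02)


class TestFilamentGenerator:
    def test_degenerate_concentration_aligns_segments(self, ellipse_geom):
        img = syn.gen_filament_image(ellipse_geom, 40, mean_angle=30.0,
                                     concentration=5000.0, seed=1)
        m = analyze_filaments(img, ellipse_geom)
        # axis angle is 0, so avgTheta equals the generating angle
        assert m.avg_theta == pytest.approx(30.0, abs=1.5)
        assert m.parallelness > 0.98

    def test_uniform_orientations_give_45_vs_any_axis(self, ellipse_geom):
        thetas = []
        for s in range(10):
            img = syn.gen_filament_image(ellipse_geom, 150, concentration=0.0, seed=s)
            thetas.append(analyze_filaments(img, ellipse_geom).avg_theta)
        assert np.mean(thetas) == pytest.approx(45.0, abs=3.0)


class TestGapGenerator:
    def test_closure_time_analytic(self):
        series = syn.gen_gap_series(gap_width=500, gap_length=1000, v_true=10.0,
                                    dt=1.0, duration=28, noise_sd=0, seed=0)
        closed = series.times[series.areas == 0]
        assert closed.min() == 25.0  # width / (2 v)

    def test_initial_slope(self):
        series = syn.gen_gap_series(v_true=10.0, noise_sd=0, seed=0)
        slope = np.polyfit(series.times[:4], series.areas[:4], 1)[0]
        assert slope == pytest.approx(-20_000.0)

    def test_zero_velocity_constant(self):
        series = syn.gen_gap_series(v_true=0.0, noise_sd=0, seed=0)
        assert np.ptp(series.areas) == 0


class TestTraceGenerator:
    def test_noiseless_trace_is_pure_logistic_after_onset(self):
        truth = syn.SyntheticTraceTruth(Fmax_pct=140, k_true=0.5, t0_true=45,
                                        rvd_rate=0.0, noise_sd=0.0, bleach_slope=0.0)
        tr, _ = syn.gen_calcein_trace(truth, seed=0)
        post = tr.times >= 30.0
        expected = truth.F0_level * (140.0 / 100.0) / (
            1.0 + np.exp(-0.5 * (tr.times[post] - 45.0)))
        assert np.allclose(tr.F[post], expected)
        assert np.allclose(tr.F[~post], truth.F0_level)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            syn.SyntheticTraceTruth(Fmax_pct=90.0)
        with pytest.raises(ValueError):
            syn.SyntheticTraceTruth(rvd_rate=-0.1)


class TestExpressionGenerator:
    def test_noiseless_slope_exact(self):
        mat = syn.gen_expression(10, 50, 0.5, 0.0, seed=1)
        res = regress_pair(mat.values.iloc[0], mat.values.iloc[1])
        assert res.slope == pytest.approx(0.5, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_null_slope_r2_vanishes(self):
        mat = syn.gen_expression(5, 10_000, 0.0, 1.0, seed=2)
        res = regress_pair(mat.values.iloc[0], mat.values.iloc[1])
        assert res.r_squared < 0.01


class TestGroundTruthClosure:
    """Noiseless inputs: every downstream stage recovers its generating
    parameter to 1e-6 relative error (exactly, for counts)."""

    def test_closure_across_stages(self, ellipse_geom):
        stack, truth = syn.gen_puncta_stack(ellipse_geom, 10, noise_sd=0,
                                            min_separation=20, seed=1)
        assert len(detect_objects(stack, threshold=50.0, measure_fwhm=False)) == 10

        series = syn.gen_gap_series(v_true=5.0, noise_sd=0, seed=1)
        assert analyze_gap_series(series).v_migration == pytest.approx(5.0, rel=1e-6)

        track, total = syn.gen_tracks(12, 4.0, seed=1)
        assert track_mobility(track)[0] == pytest.approx(total, rel=1e-6)

        tr, tt = syn.gen_calcein_trace(
            syn.SyntheticTraceTruth(Fmax_pct=125, k_true=0.4, t0_true=45,
                                    rvd_rate=0.0, noise_sd=0.0), seed=1)
        assert analyze_trace(tr).f_max == pytest.approx(125.0, rel=1e-4)

        mat = syn.gen_expression(4, 100, 0.7, 0.0, seed=1)
        assert regress_pair(mat.values.iloc[0],
                            mat.values.iloc[1]).slope == pytest.approx(0.7, rel=1e-6)

    def test_estimator_error_grows_with_noise(self):
        """Gap-slope error increases with noise (Spearman > 0 over 5 levels,
        20 seeds each)."""
        levels = [1_000, 5_000, 10_000, 20_000, 40_000]
        xs, ys = [], []
        for nz in levels:
            for s in range(20):
                series = syn.gen_gap_series(v_true=10.0, noise_sd=nz, seed=s)
                slope = np.polyfit(series.times[:4], series.areas[:4], 1)[0]
                xs.append(nz)
                ys.append(abs(slope + 20_000))
        rho = sps.spearmanr(xs, ys).statistic
        assert rho > 0
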