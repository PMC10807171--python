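"""Calcein trace processing and swelling/RVD parameter extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gliaquant import synthetic as syn
from gliaquant.volume import (
    AnalysisStageError,
    CalceinTrace,
    VolumeConfig,
    analyze_trace,
    bleach_correct,
    fit_swelling,
    normalize,
    rvd_half_time,
    smooth_trace,
)


def make_trace(F, onset=30.0, dt=1.0):
    F = np.asarray(F, float)
    return CalceinTrace(times=np.arange(F.size) * dt, F=F, stimulus_onset=onset)


class TestSmoothing:
    def test_constant_unchanged(self):
        tr = make_trace(np.full(100, 7.0))
        assert np.allclose(smooth_trace(tr).F, 7.0)

    def test_cubic_reproduced_exactly(self):
        t = np.arange(100.0)
        y = 1e-4 * t**3 - 0.02 * t**2 + t + 5
        sm = smooth_trace(make_trace(y), window=11, polyorder=3)
        assert np.allclose(sm.F[5:-5], y[5:-5], atol=1e-9)

    def test_noise_variance_reduced(self, rng):
        y = 100 + rng.normal(0, 5, 200)
        sm = smooth_trace(make_trace(y))
        assert np.std(sm.F - 100) < np.std(y - 100)

    def test_invalid_window_rejected(self):
        tr = make_trace(np.ones(50))
        with pytest.raises(ValueError):
            smooth_trace(tr, window=10)
        with pytest.raises(ValueError):
            smooth_trace(tr, window=3, polyorder=3)


class TestBleachCorrect:
    def test_no_bleach_is_identity(self):
        tr = make_trace(np.full(120, 500.0))
        assert np.allclose(bleach_correct(tr).F, 500.0)

    def test_pure_linear_decline_flattens_to_intercept(self):
        t = np.arange(120.0)
        tr = make_trace(800.0 - 0.5 * t)
        out = bleach_correct(tr)
        assert np.allclose(out.F, 800.0)

    def test_slope_recovery_under_noise(self):
        """Baseline-window slope estimate at 1%-of-F₀ noise: unbiased over
        50 seeds, with spread matching the analytic OLS slope SD
        σ/√Σ(t−t̄)² (≈ 0.21 intensity/s for a 30-sample baseline)."""
        ests = []
        for s in range(50):
            truth = syn.SyntheticTraceTruth(Fmax_pct=140, bleach_slope=-0.5,
                                            noise_sd=1.0, F0_level=1000.0)
            tr, _ = syn.gen_calcein_trace(truth, seed=s)
            ests.append(np.polyfit(tr.baseline_times, tr.baseline, 1)[0])
        tb = np.arange(30.0)
        sd_analytic = 10.0 / np.sqrt(np.sum((tb - tb.mean()) ** 2))
        # mean within 3 standard errors of the truth
        assert abs(np.mean(ests) + 0.5) < 3 * sd_analytic / np.sqrt(50)
        assert np.std(ests) == pytest.approx(sd_analytic, rel=0.5)

    def test_short_baseline_rejected(self):
        tr = CalceinTrace(times=np.arange(40.0), F=np.ones(40), stimulus_onset=3.0)
        with pytest.raises(ValueError):
            bleach_correct(tr)


class TestNormalize:
    def test_baseline_maps_to_100(self):
        F = np.full(120, 500.0)
        F[30:] = 700.0
        out = normalize(make_trace(F))
        assert np.allclose(out.F[:30], 100.0)
        assert np.allclose(out.F[30:], 140.0)

    def test_scale_invariance(self):
        F = np.concatenate([np.full(30, 400.0), np.linspace(400, 600, 90)])
        a = normalize(make_trace(F)).F
        b = normalize(make_trace(3.7 * F)).F
        assert np.allclose(a, b)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize(make_trace(np.zeros(60)))


class TestFitSwelling:
    def test_pure_logistic_recovered_exactly(self):
        t = np.arange(120.0)
        y = 140.0 / (1.0 + np.exp(-0.5 * (t - 40.0)))
        fit = fit_swelling(make_trace(y))
        assert fit.converged
        assert fit.f_max == pytest.approx(140.0, rel=0.01)
        assert fit.k == pytest.approx(0.5, rel=0.01)
        assert fit.t0 == pytest.approx(40.0, rel=0.01)

    def test_flat_trace_flagged_no_swelling(self):
        fit = fit_swelling(make_trace(np.full(120, 100.0)))
        assert fit.no_swelling

    def test_max_slope_identity(self):
        """The fitted logistic's maximal derivative equals F_max·k/4 at t0."""
        t = np.arange(120.0)
        y = 130.0 / (1.0 + np.exp(-0.4 * (t - 50.0)))
        fit = fit_swelling(make_trace(y))
        tt = np.linspace(fit.t0 - 5, fit.t0 + 5, 20001)
        curve = fit.f_max / (1.0 + np.exp(-fit.k * (tt - fit.t0)))
        assert np.gradient(curve, tt).max() == pytest.approx(fit.max_slope, rel=1e-6)

    def test_noisy_k_recovery(self):
        """Median |k̂−k|/k < 10% at 2%-of-F0 noise over 50 seeds."""
        errs = []
        for s in range(50):
            truth = syn.SyntheticTraceTruth(Fmax_pct=140, k_true=0.3, t0_true=45,
                                            rvd_rate=0.0, noise_sd=2.0)
            tr, _ = syn.gen_calcein_trace(truth, seed=s)
            fit = analyze_trace(tr)
            errs.append(abs(fit.k - 0.3) / 0.3 if fit.converged else 1.0)
        assert np.median(errs) < 0.10

    def test_too_short_record_rejected(self):
        tr = CalceinTrace(times=np.arange(45.0), F=np.ones(45), stimulus_onset=30.0)
        with pytest.raises(ValueError):
            fit_swelling(tr)


class TestRVD:
    def test_exponential_decay_half_life(self):
        lam = 0.0231
        t = np.arange(200.0)
        F = np.full(200, 100.0)
        peak = 50
        F[peak:] = 100.0 + 40.0 * np.exp(-lam * (t[peak:] - peak))
        t50, censored = rvd_half_time(make_trace(F), peak_time=50.0)
        assert not censored
        assert t50 == pytest.approx(np.log(2) / lam, abs=0.5)

    def test_linear_decay_interpolation_exact(self):
        F = np.full(120, 100.0)
        F[50] = 140.0
        F[50:] = 140.0 - 1.0 * np.arange(70)  # falls to 120 at exactly t=70
        F = np.clip(F, 100.0, None)
        t50, censored = rvd_half_time(make_trace(F), peak_time=50.0)
        assert not censored
        assert t50 == pytest.approx(20.0, abs=1e-9)

    def test_monotone_rise_censored(self):
        F = np.concatenate([np.full(30, 100.0), np.linspace(100, 150, 90)])
        t50, censored = rvd_half_time(make_trace(F), peak_time=60.0)
        assert censored


class TestFullPipeline:
    def test_noiseless_end_to_end_recovery(self):
        truth = syn.SyntheticTraceTruth(Fmax_pct=140, k_true=0.3, t0_true=45,
                                        rvd_rate=0.03, noise_sd=0.0, bleach_slope=-2.0)
        tr, truth = syn.gen_calcein_trace(truth, seed=1)
        fit = analyze_trace(tr)
        assert fit.converged
        assert fit.f_max == pytest.approx(140.0, rel=0.01)
        assert fit.k == pytest.approx(0.3, rel=0.01)
        assert fit.t0 == pytest.approx(45.0, rel=0.01)
        # time readouts are sampling-limited: 1% or one frame, whichever is larger
        assert fit.t_s_max == pytest.approx(truth.t_s_max_true, abs=max(1.0, 0.01 * truth.t_s_max_true))
        assert fit.t_rvd_50 == pytest.approx(truth.t_rvd50_true, abs=max(1.0, 0.01 * truth.t_rvd50_true))

    def test_fmax_recovery_at_one_percent_noise(self):
        errs = []
        for s in range(20):
            truth = syn.SyntheticTraceTruth(Fmax_pct=140, k_true=0.3, t0_true=45,
                                            rvd_rate=0.03, noise_sd=1.0)
            tr, _ = syn.gen_calcein_trace(truth, seed=s)
            fit = analyze_trace(tr)
            errs.append(abs(fit.f_max - 140.0) / 140.0)
        assert np.median(errs) < 0.02

    def test_pure_bleach_no_swelling(self):
        truth = syn.SyntheticTraceTruth(Fmax_pct=100.0, bleach_slope=-0.5, noise_sd=0.0)
        tr, _ = syn.gen_calcein_trace(truth, seed=0)
        assert np.all(np.diff(tr.F) < 0)  # strictly declining raw trace
        assert analyze_trace(tr).no_swelling

    @given(st.floats(min_value=0.05, max_value=50.0))
    def test_scale_invariance_of_all_outputs(self, c):
        truth = syn.SyntheticTraceTruth(Fmax_pct=130, k_true=0.4, t0_true=42,
                                        rvd_rate=0.03, noise_sd=0.0)
        tr, _ = syn.gen_calcein_trace(truth, seed=3)
        base = analyze_trace(tr)
        scaled = analyze_trace(CalceinTrace(times=tr.times, F=c * tr.F,
                                            stimulus_onset=tr.stimulus_onset))
        assert scaled.f_max == pytest.approx(base.f_max, rel=1e-6)
        assert scaled.k == pytest.approx(base.k, rel=1e-6)
        assert scaled.t_s_max == base.t_s_max
        assert scaled.t_rvd_50 == pytest.approx(base.t_rvd_50, rel=1e-6)

    def test_stage_errors_are_tagged(self):
        tr = make_trace(np.zeros(120))
        with pytest.raises(AnalysisStageError) as exc:
            analyze_trace(tr)
        assert exc.value.stage == "normalize"

    def test_lpr_and_whole_cell_treated_identically(self):
        truth = syn.SyntheticTraceTruth(Fmax_pct=125, k_true=0.3, t0_true=45,
                                        rvd_rate=0.05, noise_sd=0.0)
        tr_wc, _ = syn.gen_calcein_trace(truth, seed=4, label="whole-cell")
        tr_lpr, _ = syn.gen_calcein_trace(truth, seed=4, label="LPR")
        f1, f2 = analyze_trace(tr_wc), analyze_trace(tr_lpr)
        assert f1.f_max == f2.f_max and f1.k == f2.k

    def test_config_equivalence_is_deterministic(self):
        truth = syn.SyntheticTraceTruth(Fmax_pct=130, k_true=0.4, noise_sd=1.0)
        tr, _ = syn.gen_calcein_trace(truth, seed=5)
        c1 = VolumeConfig(sg_window=11, sg_polyorder=3)
        c2 = VolumeConfig(sg_polyorder=3, sg_window=11)
        assert analyze_trace(tr, c1) == analyze_trace(tr, c2)
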