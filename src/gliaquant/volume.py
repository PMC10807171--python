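"""Calcein-trace analysis of cell-volume dynamics.

Hypo-osmotic swelling dilutes cytosolic calcein and dequenches it, so the
fluorescence time course F(t) of a cell (or of a local peripheral region,
LPR) tracks relative volume. The processing chain is:

1. Savitzky–Golay smoothing,
2. photobleaching correction — an OLS line is fitted to the pre-stimulus
   baseline (first 30 s by default) and its slope component subtracted,
3. normalization to the baseline mean, expressed as F/F₀ × 100%,
4. a logistic fit of the swelling phase,

       F/F₀(t) = F_max / (1 + e^{−k (t − t₀)}),

   where F_max is the plateau amplitude (% of F₀), k (1/s) the swelling
   rate constant evaluated at the midpoint t₀ of the swelling phase (the
   curve's maximal slope there is F_max·k/4), and
5. the regulatory volume decrease (RVD) half-time: the time after the peak
   at which fluorescence has recovered half-way back to baseline.

Sign convention: the logistic is written with e^{−k(t−t₀)} so that k > 0
describes the *rising* swelling phase (an equivalent parameterization of
the same curve with the exponent's sign absorbed into k).

The swelling phase is fitted from stimulus onset to the smoothed-trace
peak (the RVD segment is excluded). A configuration switch starts the
window at the detected rise instead — fluorescence first exceeding
baseline noise — for recordings where solution exchange lags the nominal
stimulus mark.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "CalceinTrace",
    "SwellingFit",
    "VolumeConfig",
    "AnalysisStageError",
    "smooth_trace",
    "bleach_correct",
    "normalize",
    "fit_swelling",
    "rvd_half_time",
    "analyze_trace",
]


class AnalysisStageError(ValueError):
    """Raised when a stage of the trace pipeline fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class CalceinTrace:
    """A uniformly sampled fluorescence time series.

    The default acquisition records 30 s of baseline before and 90 s after
    the hypotonic stimulus at 1 frame/s; ``stimulus_onset`` marks the
    solution switch (s).
    """

    times: np.ndarray  # s
    F: np.ndarray  # intensity (or % of F0 after normalization)
    stimulus_onset: float = 30.0
    label: str = "whole-cell"  # or "LPR"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.times.size != self.F.size or self.times.size < 3:
            raise ValueError("need >= 3 matching samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        if not (self.times[0] <= self.stimulus_onset <= self.times[-1]):
            raise ValueError("stimulus_onset must lie within the record")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def baseline(self) -> np.ndarray:
        return self.F[self.times < self.stimulus_onset]

    @property
    def baseline_times(self) -> np.ndarray:
        return self.times[self.times < self.stimulus_onset]


@dataclass
class SwellingFit:
    """Fitted swelling/RVD parameters of one trace (all % units refer to F₀)."""

    f_max: float = np.nan  # % of F0
    k: float = np.nan  # 1/s
    t0: float = np.nan  # s, logistic midpoint
    t_s_max: float = np.nan  # s, swelling duration (onset -> peak)
    t_rvd_50: float = np.nan  # s after the peak
    max_slope: float = np.nan  # %/s, = f_max * k / 4
    rmse: float = np.nan  # % units, on the fit window
    peak_time: float = np.nan  # s, absolute
    rise_time: float = np.nan  # s, absolute, detected swelling start
    converged: bool = False
    no_swelling: bool = False
    rvd_censored: bool = False


@dataclass
class VolumeConfig:
    """Tunables of the trace pipeline."""

    sg_window: int = 11  # samples, odd
    sg_polyorder: int = 3
    rise_sigma: float = 3.0  # rise = baseline + rise_sigma * noise SD
    min_rise_pct: float = 1.0  # ... but at least this many % of F0
    no_swell_pct: float = 2.0  # below this range: no-swelling flag
    t_s_from: str = "onset"  # 'onset' or 'rise'
    window_start: str = "onset"  # fit window start: 'onset' or 'rise'


def smooth_trace(trace: CalceinTrace, window: int = 11, polyorder: int = 3) -> CalceinTrace:
    """Savitzky–Golay smoothing; length-preserving."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if window > trace.F.size:
        raise ValueError("window exceeds trace length")
    return replace(trace, F=savgol_filter(trace.F, window, polyorder))


def bleach_correct(trace: CalceinTrace) -> CalceinTrace:
    """Remove the linear photobleaching trend.

    An OLS line m·t + b is fitted to the baseline window and the slope
    component m·t is subtracted from the whole trace. Only the slope is
    removed (not the full line) so that the baseline *level* survives for
    the subsequent F/F₀ normalization.
    """
    tb = trace.baseline_times
    if tb.size < 5:
        raise ValueError("need >= 5 baseline samples for bleach correction")
    m, _b = np.polyfit(tb, trace.baseline, 1)
    return replace(trace, F=trace.F - m * trace.times)


def normalize(trace: CalceinTrace) -> CalceinTrace:
    """Express the trace as F/F₀ × 100%, F₀ = mean of the (corrected) baseline."""
    f0 = float(trace.baseline.mean())
    if f0 <= 0:
        raise ValueError("nonpositive baseline mean: cannot normalize")
    return replace(trace, F=100.0 * trace.F / f0)


def _logistic(t: np.ndarray, f_max: float, k: float, t0: float) -> np.ndarray:
    return f_max / (1.0 + np.exp(-k * (t - t0)))


def fit_swelling(
    trace: CalceinTrace,
    stimulus_onset: float | None = None,
    config: VolumeConfig | None = None,
    detection_trace: CalceinTrace | None = None,
) -> SwellingFit:
    """Nonlinear least-squares logistic fit of the swelling phase.

    The fit window runs from the detected rise onset (first sample above
    baseline + max(rise_sigma·noise SD, min_rise_pct)) to the trace peak;
    the RVD segment is excluded. Rise and peak are located on
    ``detection_trace`` when given (typically the Savitzky–Golay-smoothed
    copy, which is robust to noise) while the least squares runs on
    ``trace`` itself — fitting pre-smoothed samples would bias the
    parameters. Three jittered initializations are tried and the best-RMSE
    solution kept. A trace whose excursion above baseline is below
    ``no_swell_pct`` of F₀ gets the no-swelling flag and no fit. Expects
    bleach-corrected, normalized traces (% units).
    """
    config = config or VolumeConfig()
    onset = trace.stimulus_onset if stimulus_onset is None else stimulus_onset
    t, y = trace.times, trace.F
    det = detection_trace.F if detection_trace is not None else y
    if det.size != y.size:
        raise ValueError("detection trace must share the trace's sampling")
    if t[-1] - onset < 20.0:
        raise ValueError("trace must extend >= 20 s past stimulus onset")
    post = t >= onset
    i_on = int(np.argmax(post))
    i_peak = i_on + int(np.argmax(det[post]))
    peak_val = det[i_peak]
    fit = SwellingFit(peak_time=float(t[i_peak]))

    if peak_val - 100.0 < config.no_swell_pct:
        fit.no_swelling = True
        return fit

    # baseline noise from the fit trace itself: the detection copy may carry
    # smoothing artifacts at the onset step
    base = y[t < onset]
    noise_sd = float(np.std(base)) if base.size else 0.0
    rise_level = 100.0 + max(config.rise_sigma * noise_sd, config.min_rise_pct)
    above = np.flatnonzero((det >= rise_level) & (np.arange(det.size) >= i_on))
    i_rise = int(above[0]) if above.size else i_on
    fit.rise_time = float(t[i_rise])
    if config.window_start == "rise":
        i_start = max(i_on, i_rise)
        # smoothing spreads the rise backward in time; advance to the first
        # raw sample actually above the rise level so no pre-rise (baseline)
        # samples enter the least squares
        while i_start < i_peak - 3 and y[i_start] < rise_level:
            i_start += 1
    else:
        i_start = i_on
    if i_peak - i_start < 3:
        i_start = max(i_on, i_peak - 3)
    tw = t[i_start : i_peak + 1]
    yw = y[i_start : i_peak + 1]
    if tw.size < 4:
        fit.no_swelling = True
        return fit

    # initialization: plateau from the observed max, t0 from the half-rise,
    # k from the steepest observed slope (logistic max slope = f_max*k/4)
    f0_init = float(peak_val)
    half_level = 0.5 * (yw[0] + peak_val)
    i_half = int(np.argmin(np.abs(yw - half_level)))
    t0_init = float(tw[i_half])
    dy = np.gradient(yw, tw)
    k_init = max(4.0 * float(dy.max()) / f0_init, 1e-3)

    starts = [
        (f0_init, k_init, t0_init),
        (f0_init * 1.1, k_init * 0.5, t0_init - 2.0),
        (f0_init * 1.02, k_init * 2.0, t0_init + 2.0),
    ]
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                _logistic,
                tw,
                yw,
                p0=p0,
                bounds=([1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                xtol=1e-8,
                ftol=1e-8,
                gtol=1e-8,
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rmse = float(np.sqrt(np.mean((_logistic(tw, *popt) - yw) ** 2)))
        if best is None or rmse < best[1]:
            best = (popt, rmse)
    if best is None:
        fit.converged = False
        return fit
    (f_max, k, t0), rmse = best
    fit.f_max = float(f_max)
    fit.k = float(k)
    fit.t0 = float(t0)
    fit.max_slope = float(f_max * k / 4.0)
    fit.rmse = rmse
    fit.converged = True
    ref = onset if config.t_s_from == "onset" else fit.rise_time
    fit.t_s_max = float(t[i_peak] - ref)
    return fit


def rvd_half_time(trace: CalceinTrace, peak_time: float) -> tuple[float, bool]:
    """Half-time of the post-peak fluorescence recovery.

    Returns the first time after the peak at which F falls to
    100 + (F_peak − 100)/2, by linear interpolation between the bracketing
    samples, expressed as time elapsed since the peak. When the trace never
    recovers half-way within the record, returns the remaining record length
    with the censored flag set.

    Returns
    -------
    (t_rvd_50, censored)
    """
    t, y = trace.times, trace.F
    i_peak = int(np.argmin(np.abs(t - peak_time)))
    if t.size - 1 - i_peak < 2:
        raise ValueError("need samples after the peak to evaluate RVD")
    f_peak = y[i_peak]
    target = 100.0 + (f_peak - 100.0) / 2.0
    for j in range(i_peak + 1, t.size):
        if y[j] <= target:
            # interpolate between j-1 (above) and j (at/below)
            if y[j - 1] == y[j]:
                tc = t[j]
            else:
                frac = (y[j - 1] - target) / (y[j - 1] - y[j])
                tc = t[j - 1] + frac * (t[j] - t[j - 1])
            return float(tc - t[i_peak]), False
    return float(t[-1] - t[i_peak]), True


def analyze_trace(trace: CalceinTrace, config: VolumeConfig | None = None) -> SwellingFit:
    """Full pipeline: bleach-correct → normalize → smooth → fit → RVD.

    The bleach slope and F₀ are estimated on the raw baseline (a sharp
    stimulus response smoothed across the onset would otherwise contaminate
    them); the smoothed copy of the normalized trace serves for rise/peak
    detection and the RVD readout, while the logistic is fitted to the
    unsmoothed samples. Since Savitzky–Golay smoothing is linear and exact
    on straight lines, this ordering is equivalent to smoothing first
    whenever the baseline is clean. Whole-cell and LPR traces are treated
    identically. Failures are tagged with the stage that raised them.
    """
    config = config or VolumeConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except AnalysisStageError:
            raise
        except ValueError as e:
            raise AnalysisStageError(name, str(e)) from e

    nm_raw = stage("normalize", normalize, stage("bleach_correct", bleach_correct, trace))
    nm_sm = stage("smooth", smooth_trace, nm_raw, config.sg_window, config.sg_polyorder)
    fit = stage("fit_swelling", fit_swelling, nm_raw, None, config, nm_sm)
    if fit.converged and not fit.no_swelling:
        n_after = int(np.sum(nm_sm.times > fit.peak_time))
        if n_after >= 2:
            t50, censored = stage("rvd_half_time", rvd_half_time, nm_sm, fit.peak_time)
            fit.t_rvd_50 = t50
            fit.rvd_censored = censored
        else:
            fit.t_rvd_50 = np.nan
            fit.rvd_censored = True
    return fit
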