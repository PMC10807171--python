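"""Wound-healing migration kinetics and single-cell mobility.

Collective migration is read from the shrinking cell-free gap of a
wound-healing assay: the gap area A(t) (gap width × gap length l) declines
linearly while both cell fronts advance, so

    v_migration (µm/h) = |slope| / (2 · l),      slope = dA/dt
    t_1/2 gap (h)      = A(0) / (2 · |slope|)

with the slope taken from an ordinary least-squares fit of the first few
time points (four by default, i.e. 0–12 h at 4-h sampling). Single-cell
mobility sums Euclidean nucleus displacements between consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GapSeries",
    "MigrationResult",
    "Track",
    "gap_area_from_mask",
    "fit_gap_closure",
    "migration_speed",
    "t_half_gap",
    "analyze_gap_series",
    "track_mobility",
    "filter_track_by_edge_distance",
]


@dataclass
class GapSeries:
    """Gap area over time for one wound-healing replicate."""

    times: np.ndarray  # h, ascending
    areas: np.ndarray  # µm²
    gap_length: float  # µm, the constant l

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.size != self.areas.size or self.times.size < 2:
            raise ValueError("need >= 2 matching (time, area) points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")
        if self.gap_length <= 0:
            raise ValueError("gap length must be positive")

    @property
    def initial_area(self) -> float:
        return float(self.areas[0])


@dataclass
class MigrationResult:
    slope: float  # µm²/h
    intercept: float  # µm²
    r_squared: float
    v_migration: float  # µm/h
    t_half: float  # h; NaN when the gap is not closing
    fit_points: int
    closing: bool


@dataclass
class Track:
    """Nucleus-center positions of one cell over time."""

    times: np.ndarray  # h
    positions: np.ndarray  # (n, 2) µm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if self.times.size != self.positions.shape[0]:
            raise ValueError("times and positions lengths differ")


def gap_area_from_mask(gap_mask: np.ndarray, pixel_size: float) -> float:
    """Gap area in µm² from a binary gap mask."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return float(np.count_nonzero(np.asarray(gap_mask, dtype=bool))) * pixel_size**2


def fit_gap_closure(series: GapSeries, n_points: int = 4) -> tuple[float, float, float]:
    """OLS of gap area on time over the first ``n_points`` samples.

    Returns (slope µm²/h, intercept µm², r²).
    """
    if n_points < 2 or n_points > series.times.size:
        raise ValueError("n_points must be >= 2 and <= series length")
    t = series.times[:n_points]
    a = series.areas[:n_points]
    if np.ptp(a) == 0:
        # degenerate: constant area; slope 0, r² defined as 0
        return 0.0, float(a[0]), 0.0
    res = stats.linregress(t, a)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def migration_speed(slope: float, gap_length: float) -> float:
    """v_migration = |slope| / (2 · l), µm/h."""
    if gap_length <= 0:
        raise ValueError("gap length must be positive")
    return abs(slope) / (2.0 * gap_length)


def t_half_gap(initial_area: float, slope: float) -> float:
    """t_1/2 = initial area / (2 · |slope|); NaN for a non-closing gap."""
    if slope >= 0:
        return np.nan
    return initial_area / (2.0 * abs(slope))


def analyze_gap_series(series: GapSeries, n_points: int = 4) -> MigrationResult:
    """Fit the closure slope and derive v_migration and t_half."""
    slope, intercept, r2 = fit_gap_closure(series, n_points)
    v = migration_speed(slope, series.gap_length)
    closing = slope < 0
    return MigrationResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        v_migration=v,
        t_half=t_half_gap(series.initial_area, slope) if closing else np.nan,
        fit_points=n_points,
        closing=closing,
    )


def track_mobility(track: Track) -> tuple[float, float]:
    """Total path length (µm) and average speed (µm/h) of one track."""
    if track.times.size < 2:
        raise ValueError("track needs >= 2 positions")
    if np.any(np.diff(track.times) <= 0):
        raise ValueError("track times must be strictly increasing")
    steps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    total = float(steps.sum())
    elapsed = float(track.times[-1] - track.times[0])
    return total, total / elapsed


def filter_track_by_edge_distance(
    track: Track,
    edge_x: np.ndarray,
    band: tuple[float, float] = (150.0, 300.0),
) -> bool:
    """Eligibility filter: keep cells within a distance band of the leading edge.

    ``edge_x`` gives the leading-edge x-coordinate (µm) per frame; a track
    qualifies when its |x - edge_x| distance stays within ``band`` at every
    frame.
    """
    edge_x = np.asarray(edge_x, dtype=float)
    if edge_x.size != track.times.size:
        raise ValueError("edge_x must give one coordinate per frame")
    d = np.abs(track.positions[:, 0] - edge_x)
    return bool(np.all((d >= band[0]) & (d <= band[1])))
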