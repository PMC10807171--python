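"""Seeded synthetic-data generators with known ground truth.

Every input modality of the toolkit can be simulated here so that each
downstream stage is testable by parameter recovery: Gaussian-spot puncta
stacks inside a cell mask, oriented filament textures with controllable
parallelness and intensity skew, linearly closing wound-healing gap series,
calcein swelling/RVD traces, nucleus tracks, and z-score expression
matrices. All randomness flows through one explicitly passed seeded
generator; identical seeds give bit-identical outputs.

What is emulated — and what is not: spots are isotropic 2D Gaussians
replicated over z with a Gaussian axial profile (no real confocal PSF, no
spectral bleed-through); noise is additive Gaussian by default with a
Poisson option; gap fronts advance symmetrically at the true migration
speed; swelling follows exactly the logistic model the fitting stage
assumes, with exponential recovery after the swelling phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CellGeometry, ImageStack
from .geometry import long_axis
from .migration import GapSeries, Track
from .stats import ExpressionMatrix
from .volume import CalceinTrace

__all__ = [
    "SyntheticPunctaTruth",
    "SyntheticTraceTruth",
    "gen_cell_mask",
    "gen_puncta_stack",
    "gen_filament_image",
    "gen_gap_series",
    "gen_calcein_trace",
    "gen_tracks",
    "gen_expression",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SyntheticPunctaTruth:
    """Ground truth of a generated puncta stack."""

    centers_um: list[tuple[float, float, float]]  # (x, y, z) µm
    sigmas_px: list[float]
    amplitudes: list[float]
    cell_area_um2: float

    def __post_init__(self) -> None:
        if not (len(self.centers_um) == len(self.sigmas_px) == len(self.amplitudes)):
            raise ValueError("truth lists must have equal lengths")
        if any(s <= 0 for s in self.sigmas_px):
            raise ValueError("sigmas must be positive")

    @property
    def n(self) -> int:
        return len(self.centers_um)


@dataclass
class SyntheticTraceTruth:
    """Generating parameters of a calcein trace.

    ``Fmax_pct`` is the logistic plateau in % of F₀ (> 100 for a swelling
    trace; exactly 100 means no swelling response); ``k_true`` (1/s) and
    ``t0_true`` (s) are the logistic rate and midpoint; ``rvd_rate`` (1/s)
    the exponential recovery rate after the swelling phase; ``noise_sd`` and
    the bleach slope act on the raw intensity scale (noise as % of F₀).
    """

    F0_level: float = 1000.0
    bleach_slope: float = 0.0  # intensity/s
    Fmax_pct: float = 140.0
    k_true: float = 0.3  # 1/s
    t0_true: float = 45.0  # s
    rvd_rate: float = 0.03  # 1/s
    noise_sd: float = 0.0  # % of F0
    # derived by the generator:
    t_s_max_true: float = field(default=np.nan)  # s from stimulus onset
    t_rvd50_true: float = field(default=np.nan)  # s after the peak

    def __post_init__(self) -> None:
        if self.Fmax_pct < 100.0:
            raise ValueError("Fmax_pct must be >= 100 (100 = no swelling)")
        if self.rvd_rate < 0 or self.noise_sd < 0:
            raise ValueError("rvd_rate and noise_sd must be >= 0")
        if self.F0_level <= 0 or self.k_true <= 0:
            raise ValueError("F0_level and k_true must be positive")


def _shape_radius(spec: dict, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Radius-vs-angle profile of a star-convex shape spec."""
    kind = spec.get("kind", "circle")
    if kind == "circle":
        return np.full_like(phi, float(spec["radius"]))
    if kind == "ellipse":
        a, b = float(spec["a"]), float(spec["b"])
        ang = np.radians(float(spec.get("angle", 0.0)))
        c, s = np.cos(phi - ang), np.sin(phi - ang)
        return a * b / np.sqrt((b * c) ** 2 + (a * s) ** 2)
    if kind == "blob":
        r0 = float(spec["radius"])
        n_h = int(spec.get("n_harmonics", 4))
        amp = float(spec.get("amplitude", 0.25))
        coeffs = rng.uniform(-1, 1, n_h)
        phases = rng.uniform(0, 2 * np.pi, n_h)
        mod = np.zeros_like(phi)
        for m, (cm, pm) in enumerate(zip(coeffs, phases), start=2):
            mod += cm * np.cos(m * phi + pm)
        mod *= amp / max(n_h, 1)
        return r0 * np.clip(1.0 + mod, 0.3, None)
    raise ValueError(f"unknown shape kind {kind!r}")


def gen_cell_mask(
    shape_spec: dict,
    image_size: int | tuple[int, int] = 512,
    pixel_size: float = 0.1,
    nucleus_frac: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> CellGeometry:
    """Rasterize a cell mask with a concentric nucleus.

    ``shape_spec`` selects the outline: ``{'kind': 'circle', 'radius': r}``,
    ``{'kind': 'ellipse', 'a': ..., 'b': ..., 'angle': deg}`` or
    ``{'kind': 'blob', 'radius': r, 'amplitude': ..., 'n_harmonics': ...}``
    (a randomly modulated, possibly concave outline). All lengths in px;
    ``center`` defaults to the image center. The nucleus is the same shape
    scaled by ``nucleus_frac`` (< 1), hence strictly inside the cell. The
    recorded long-axis angle is the ellipse angle when given, otherwise the
    principal axis of the rasterized mask.
    """
    rng = _rng(seed)
    if isinstance(image_size, int):
        image_size = (image_size, image_size)
    h, w = image_size
    if not 0 < nucleus_frac < 1:
        raise ValueError("nucleus_frac must be in (0, 1)")
    cy, cx = shape_spec.get("center", (h / 2.0, w / 2.0))
    yy, xx = np.indices((h, w))
    dx = xx - cx
    dy = yy - cy
    phi = np.arctan2(dy, dx)
    dist = np.hypot(dx, dy)
    r_at = _shape_radius(shape_spec, phi, rng)
    # bounds check on the shape's maximal extent
    rmax = float(r_at.max())
    if cy - rmax < 0 or cx - rmax < 0 or cy + rmax > h - 1 or cx + rmax > w - 1:
        raise ValueError("shape exceeds image bounds")
    cell = dist <= r_at
    nucleus = dist <= nucleus_frac * r_at
    if shape_spec.get("kind") == "ellipse":
        a, b = float(shape_spec["a"]), float(shape_spec["b"])
        ang = float(shape_spec.get("angle", 0.0))
        angle = ang % 180.0 if a >= b else (ang + 90.0) % 180.0
    else:
        angle, _ = long_axis(cell)
    return CellGeometry(cell_mask=cell, nucleus_mask=nucleus, pixel_size=pixel_size,
                        long_axis_angle=angle)


def gen_puncta_stack(
    geom: CellGeometry,
    n: int,
    sigma: float = 2.0,
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    z_planes: int = 5,
    z_step: float = 0.5,
    z_sigma: float = 1.0,
    min_separation: float = 0.0,
    poisson: bool = False,
    seed: int | np.random.Generator = 0,
    max_tries_per_spot: int = 2000,
) -> tuple[ImageStack, SyntheticPunctaTruth]:
    """Render ``n`` Gaussian spots at random in-mask positions.

    Spots are isotropic 2D Gaussians (SD ``sigma`` px, peak ``amplitude``)
    with a Gaussian axial profile (SD ``z_sigma`` planes); lateral centers
    carry sub-pixel jitter and keep a pairwise distance ≥ ``min_separation``
    px. Centers are confined to the mask eroded by ~3σ so the spot mass
    stays inside the cell. Additive Gaussian noise of SD ``noise_sd`` is
    applied (after Poisson resampling of the signal when ``poisson``).

    Raises
    ------
    ValueError
        When ``n`` spots cannot be placed at the requested separation
        within the bounded number of retries.
    """
    rng = _rng(seed)
    if n < 0 or min_separation < 0:
        raise ValueError("n and min_separation must be >= 0")
    mask = geom.cell_mask
    h, w = mask.shape
    margin = int(np.ceil(3 * sigma)) + 1
    from scipy import ndimage as _ndi

    allowed = _ndi.binary_erosion(mask, iterations=margin) if margin > 0 else mask
    ys, xs = np.nonzero(allowed)
    if n > 0 and ys.size == 0:
        raise ValueError("cell mask too small to place spots with this sigma")

    centers: list[tuple[float, float, float]] = []  # (x, y, z_plane)
    tries = 0
    while len(centers) < n:
        if tries > max_tries_per_spot * max(n, 1):
            raise ValueError(
                f"could not place {n} spots with min_separation={min_separation}; "
                f"placed {len(centers)}"
            )
        tries += 1
        i = rng.integers(ys.size)
        cx = xs[i] + rng.uniform(-0.5, 0.5)
        cy = ys[i] + rng.uniform(-0.5, 0.5)
        if min_separation > 0 and any(
            np.hypot(cx - px, cy - py) < min_separation for px, py, _ in centers
        ):
            continue
        lo = min(z_sigma, (z_planes - 1) / 2.0)
        cz = rng.uniform(lo, z_planes - 1 - lo) if z_planes > 1 else 0.0
        centers.append((cx, cy, cz))

    img = np.zeros((z_planes, h, w), dtype=float)
    zi = np.arange(z_planes, dtype=float)
    for cx, cy, cz in centers:
        r = int(np.ceil(4 * sigma))
        x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
        y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
        gx = np.exp(-((np.arange(x0, x1) - cx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((np.arange(y0, y1) - cy) ** 2) / (2 * sigma**2))
        gz = np.exp(-((zi - cz) ** 2) / (2 * z_sigma**2)) if z_planes > 1 else np.ones(1)
        img[:, y0:y1, x0:x1] += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]

    if poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)

    truth = SyntheticPunctaTruth(
        centers_um=[
            (cx * geom.pixel_size, cy * geom.pixel_size, cz * z_step) for cx, cy, cz in centers
        ],
        sigmas_px=[sigma] * len(centers),
        amplitudes=[amplitude] * len(centers),
        cell_area_um2=geom.cell_area_um2,
    )
    return ImageStack(img, pixel_size=geom.pixel_size, z_step=z_step), truth


def gen_filament_image(
    geom: CellGeometry,
    n_filaments: int,
    mean_angle: float = 0.0,
    concentration: float = 0.0,
    width: int = 3,
    intensity_skew: float = 0.0,
    length_px: tuple[float, float] = (30.0, 80.0),
    base_intensity: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> ImageStack:
    """Render straight filament segments inside the cell mask.

    Orientations are drawn from a wrapped (von Mises on doubled angles)
    distribution about ``mean_angle``; ``concentration`` is the von Mises κ
    (0 = uniform orientations, large κ = near-perfect alignment).
    Per-filament intensities follow a gamma distribution whose Fisher
    skewness equals ``intensity_skew`` (0 = constant intensity); segment
    pixels accumulate additively so crossing or bundled filaments become
    brighter.
    """
    rng = _rng(seed)
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    mask = geom.cell_mask
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    img = np.zeros((h, w), dtype=float)
    half_offsets = np.arange(width) - (width - 1) / 2.0

    for _ in range(n_filaments):
        if concentration == 0:
            theta = rng.uniform(0.0, 180.0)
        else:
            theta = (np.degrees(rng.vonmises(np.radians(2 * mean_angle), concentration)) / 2.0) % 180.0
        if intensity_skew > 0:
            shape = (2.0 / intensity_skew) ** 2
            inten = base_intensity * rng.gamma(shape, 1.0 / shape)
        else:
            inten = base_intensity
        i = rng.integers(ys.size)
        cx, cy = float(xs[i]), float(ys[i])
        L = rng.uniform(*length_px)
        th = np.radians(theta)
        ux, uy = np.cos(th), np.sin(th)
        # perpendicular offsets give the stroke width
        px_, py_ = -uy, ux
        ts = np.arange(-L / 2.0, L / 2.0, 0.5)
        for off in half_offsets:
            xi = np.round(cx + ts * ux + off * px_).astype(int)
            yi = np.round(cy + ts * uy + off * py_).astype(int)
            ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            xi, yi = xi[ok], yi[ok]
            ok = mask[yi, xi]
            xi, yi = xi[ok], yi[ok]
            if xi.size:
                flat = np.unique(yi.astype(np.int64) * w + xi)
                img.ravel()[flat] += inten
    return ImageStack(img, pixel_size=geom.pixel_size, z_step=1.0)


def gen_gap_series(
    gap_width: float = 500.0,
    gap_length: float = 1000.0,
    v_true: float = 10.0,
    dt: float = 4.0,
    duration: float = 28.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> GapSeries:
    """Linearly closing wound-healing gap sampled at ``dt`` intervals.

    Both cell fronts advance at ``v_true`` µm/h, so the gap area is
    ``max(0, (width − 2·v_true·t)) × length`` plus Gaussian noise (µm²).
    Defaults follow the usual time-lapse protocol: 4-h intervals for 28 h.
    """
    rng = _rng(seed)
    if min(gap_width, gap_length, dt, duration) <= 0:
        raise ValueError("all dimensions must be positive")
    times = np.arange(0.0, duration + dt / 2.0, dt)
    areas = np.clip(gap_width - 2.0 * v_true * times, 0.0, None) * gap_length
    if noise_sd > 0:
        areas = np.clip(areas + rng.normal(0.0, noise_sd, size=areas.shape), 0.0, None)
    return GapSeries(times=times, areas=areas, gap_length=gap_length)


def gen_calcein_trace(
    truth: SyntheticTraceTruth,
    baseline_s: float = 30.0,
    post_s: float = 90.0,
    rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    label: str = "whole-cell",
) -> tuple[CalceinTrace, SyntheticTraceTruth]:
    """Simulate a calcein fluorescence trace from generating parameters.

    The relative response is 100% during the baseline and, after stimulus
    onset, follows the pure logistic Fmax_pct/(1 + e^{−k(t − t₀)}) — the
    swelling phase is exactly the model curve over its full range, so
    recovery tests exercise the fitter across the complete sigmoid.
    ``Fmax_pct = 100`` means no swelling response (the relative trace stays
    flat at 100%). When ``rvd_rate`` > 0 the response decays exponentially
    back toward baseline once the logistic has reached 99% of its plateau
    (the end of the swelling phase), giving a true RVD half-time of
    ln 2 / rvd_rate. Photobleaching adds ``bleach_slope``·t on the intensity
    scale and Gaussian noise of SD ``noise_sd``% of F₀ is applied last. The
    returned truth carries the derived swelling duration and RVD half-time.
    """
    rng = _rng(seed)
    if baseline_s <= 0 or post_s <= 0 or rate <= 0:
        raise ValueError("baseline_s, post_s and rate must be positive")
    dt = 1.0 / rate
    times = np.arange(0.0, baseline_s + post_s, dt)
    onset = baseline_s
    rel = np.full_like(times, 100.0)
    post = times >= onset
    if truth.Fmax_pct > 100.0:
        logi = truth.Fmax_pct / (1.0 + np.exp(-truth.k_true * (times - truth.t0_true)))
        rel[post] = logi[post]

    t_s_max = np.nan
    t_rvd50 = np.nan
    if truth.rvd_rate > 0 and truth.Fmax_pct > 100.0:
        t_end = truth.t0_true + np.log(99.0) / truth.k_true  # logistic at 99% of plateau
        if onset < t_end < times[-1]:
            peak_rel = truth.Fmax_pct / (1.0 + np.exp(-truth.k_true * (t_end - truth.t0_true)))
            decay = times > t_end
            rel[decay] = 100.0 + (peak_rel - 100.0) * np.exp(
                -truth.rvd_rate * (times[decay] - t_end)
            )
            t_s_max = t_end - onset
            t_rvd50 = np.log(2.0) / truth.rvd_rate
    out = dict(truth.__dict__)
    out["t_s_max_true"] = t_s_max
    out["t_rvd50_true"] = t_rvd50
    truth = SyntheticTraceTruth(**out)

    F = truth.F0_level * rel / 100.0 + truth.bleach_slope * times
    if truth.noise_sd > 0:
        F = F + rng.normal(0.0, truth.noise_sd / 100.0 * truth.F0_level, size=F.shape)
    return CalceinTrace(times=times, F=F, stimulus_onset=onset, label=label), truth


def gen_tracks(
    n_steps: int,
    step_length: float | "callable" = 5.0,
    dt: float = 4.0,
    start: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
) -> tuple[Track, float]:
    """Random-walk nucleus track with known total path length.

    ``step_length`` is either a constant (µm) or a callable
    ``f(rng, n) -> array`` drawing the n step lengths; step directions are
    uniform. Returns the track and the true total distance (the sum of the
    drawn step lengths).
    """
    rng = _rng(seed)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    steps = (
        step_length(rng, n_steps)
        if callable(step_length)
        else np.full(n_steps, float(step_length))
    )
    angles = rng.uniform(0.0, 2 * np.pi, n_steps)
    disp = np.column_stack([steps * np.cos(angles), steps * np.sin(angles)])
    positions = np.vstack([np.array(start, dtype=float), np.array(start) + np.cumsum(disp, axis=0)])
    times = np.arange(n_steps + 1, dtype=float) * dt
    return Track(times=times, positions=positions), float(np.sum(steps))


def gen_expression(
    n_genes: int = 50,
    n_samples: int = 200,
    slope_true: float = 0.35,
    noise_sd: float = 1.0,
    gene_x: str = "GENE_X",
    gene_y: str = "GENE_Y",
    seed: int | np.random.Generator = 0,
) -> ExpressionMatrix:
    """Expression matrix with one linearly related gene pair.

    Row ``gene_x`` is standard normal; row ``gene_y`` is
    ``slope_true · x + noise_sd · ε`` on the z-score scale; all other rows
    are independent standard normal noise.
    """
    rng = _rng(seed)
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    if n_genes < 2:
        raise ValueError("need >= 2 genes for the designated pair")
    x = rng.standard_normal(n_samples)
    y = slope_true * x + noise_sd * rng.standard_normal(n_samples)
    rest = rng.standard_normal((n_genes - 2, n_samples))
    values = np.vstack([x, y, rest])
    genes = [gene_x, gene_y] + [f"G{i:04d}" for i in range(3, n_genes + 1)]
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples),
                            zscored=False)
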