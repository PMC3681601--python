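"""Synthetic FRAP traces, spindle images and congression datasets.

Forward models that emulate the acquisitions the analysis modules expect,
with known ground truth, so every downstream stage can be exercised and
validated without any microscopy data.

* FRAP traces follow the recovery model of :mod:`spindlequant.frap`
  multiplied by the bleach depth and an acquisition-bleaching decay, on
  the standard oocyte protocol grid (3 pre-bleach frames, one frame every
  5 s out to 165 s).  Matched non-bleached control traces decay with the
  same acquisition bleaching; the default rate loses 25% of signal by
  80 s, the level observed for non-bleached control spindles.
* Spindle images are two-channel 2-D grids (0.1 um pixels) drawn directly
  as maximum-intensity projections: a tubulin/Augmin channel whose axial
  profile has tunable pole peaks, per-pole attenuation ("missing or weak"
  poles) and a sub-polar attenuation knob, and a chromosome channel of
  axis-aligned Gaussian blobs whose half-maximum mask has a known axial
  extent (the chromosome spread).  Ground-truth pole coordinates are
  recorded on the image.
* Congression datasets draw a per-spindle pole intensity from a lognormal
  law and set the chromosome spread as a linear function of log intensity
  plus Gaussian noise, so the population Pearson correlation between
  spread and log intensity is known in closed form.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .frap import FrapTrace, RecoveryParams, model_recovery
from .poles import CongressionRecord
from .profile import SpindleImage

__all__ = [
    "TraceSimConfig",
    "ImageSimConfig",
    "bleach_rate_for",
    "gen_frap_trace",
    "gen_trace_ensemble",
    "gen_spindle_image",
    "gen_spindle_stack",
    "congression_noise_for_r",
    "gen_congression_dataset",
]


def bleach_rate_for(loss: float = 0.25, at: float = 80.0) -> float:
    """Per-second acquisition-bleaching rate giving ``loss`` by time ``at``."""
    if not 0 <= loss < 1:
        raise ValueError("loss must be in [0, 1)")
    return -math.log(1.0 - loss) / at


#: Default acquisition bleaching: controls lose 25% of signal by 80 s.
DEFAULT_ACQ_BLEACH_RATE = bleach_rate_for(0.25, 80.0)


@dataclass(frozen=True)
class TraceSimConfig:
    """Acquisition settings for one simulated FRAP experiment.

    Defaults reproduce the oocyte protocol: frames every ``dt = 5`` s out
    to ``t_end = 165`` s with 3 pre-bleach frames.  ``bleach_depth`` is
    the fraction of pre-bleach fluorescence remaining at the bleach
    instant; ``noise_sd`` is Gaussian, expressed as a fraction of
    ``pre_level``.
    """

    params: RecoveryParams
    n_pre: int = 3
    dt: float = 5.0
    t_end: float = 165.0
    pre_level: float = 100.0
    bleach_depth: float = 0.2
    acq_bleach_rate: float = DEFAULT_ACQ_BLEACH_RATE
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end < self.dt:
            raise ValueError("t_end must be at least dt")
        if self.n_pre < 3:
            raise ValueError("n_pre must be at least 3")
        if not 0 <= self.bleach_depth < 1:
            raise ValueError("bleach_depth must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pre_level <= 0:
            raise ValueError("pre_level must be positive")
        if self.acq_bleach_rate < 0:
            raise ValueError("acq_bleach_rate must be non-negative")


def _time_grid(cfg: TraceSimConfig) -> tuple[np.ndarray, int]:
    pre = -cfg.dt * np.arange(cfg.n_pre, 0, -1)
    n_post = int(round(cfg.t_end / cfg.dt)) + 1
    post = cfg.dt * np.arange(n_post)
    return np.concatenate([pre, post]), cfg.n_pre


def gen_frap_trace(cfg: TraceSimConfig) -> tuple[FrapTrace, FrapTrace]:
    """Simulate one bleached trace and its matched non-bleached control.

    Pre-bleach frames sit at negative times (-n_pre*dt .. -dt); t = 0 is
    the first post-bleach frame.  Acquisition bleaching multiplies the
    post-bleach frames by ``exp(-acq_bleach_rate * t)`` (the three quick
    pre-bleach frames are taken as bleaching-free); the control is the
    same decay without the bleach.  Intensities are clipped at 0 so traces
    remain physical at high noise.
    """
    times, n_pre = _time_grid(cfg)
    post = times[n_pre:]
    decay = np.exp(-cfg.acq_bleach_rate * post)

    recovery = model_recovery(post, cfg.params)
    ideal_sample = np.concatenate(
        [
            np.full(n_pre, cfg.pre_level),
            cfg.pre_level
            * (cfg.bleach_depth + (1.0 - cfg.bleach_depth) * recovery)
            * decay,
        ]
    )
    ideal_control = np.concatenate(
        [np.full(n_pre, cfg.pre_level), cfg.pre_level * decay]
    )

    rng = np.random.default_rng(cfg.seed)
    sd = cfg.noise_sd * cfg.pre_level
    sample = np.clip(ideal_sample + rng.normal(0.0, sd, times.size), 0.0, None)
    control = np.clip(ideal_control + rng.normal(0.0, sd, times.size), 0.0, None)
    return (
        FrapTrace(times, sample, n_pre, label="sample"),
        FrapTrace(times, control, n_pre, label="control"),
    )


def gen_trace_ensemble(
    cfg: TraceSimConfig, n: int, seed: int | None = None
) -> list[tuple[FrapTrace, FrapTrace]]:
    """Draw ``n`` independent (sample, control) pairs.

    Per-trace seeds are derived deterministically from the master seed
    (``cfg.seed`` unless ``seed`` overrides it), so a fixed seed yields a
    bitwise-identical ensemble.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    master = cfg.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(n)
    return [gen_frap_trace(replace(cfg, seed=int(s))) for s in child_seeds]


# ---------------------------------------------------------------------------
# spindle images


@dataclass(frozen=True)
class ImageSimConfig:
    """Geometry and intensity settings for one synthetic spindle image.

    The spindle lies along an axis at ``angle_deg`` through the image
    centre.  ``pole_enrichment`` is the ratio of the pole peak to the
    equator plateau of the axial profile; ``pole_asymmetry`` attenuates
    each pole peak individually (0 models a missing pole);
    ``subpolar_scale`` multiplies the profile in the sub-polar zones
    (around fractional positions 0.25 and 0.75), the region where
    Augmin-deficient spindles lose microtubule density.  The chromosome
    channel holds blobs whose half-maximum mask spans
    ``chromosome_spread`` micrometres along the axis; ``include_fourth``
    adds a small extra blob (a 4th-chromosome proxy, well under 10% of
    the main blob area) beyond the main mass.
    """

    spindle_length: float = 10.0
    pixel_size: float = 0.1
    pole_enrichment: float = 1.5
    pole_asymmetry: tuple[float, float] = (1.0, 1.0)
    subpolar_scale: float = 1.0
    chromosome_spread: float = 4.0
    include_fourth: bool = False
    background: float = 20.0
    amplitude: float = 100.0
    chromosome_amplitude: float = 150.0
    chromosome_background: float = 0.0
    blob_radius: float = 0.5
    fourth_radius: float = 0.12
    noise_sd: float = 0.03
    margin: float = 2.0
    angle_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.spindle_length <= 0:
            raise ValueError("spindle_length must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pole_enrichment <= 0:
            raise ValueError("pole_enrichment must be positive")
        if self.chromosome_spread < 0:
            raise ValueError("chromosome_spread must be non-negative")
        if not 0 <= self.subpolar_scale <= 1:
            raise ValueError("subpolar_scale must be in [0, 1]")
        if any(a < 0 for a in self.pole_asymmetry):
            raise ValueError("pole_asymmetry factors must be non-negative")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


# axial-profile shape constants (fractions of spindle length)
_POLE_PEAK_WIDTH = 0.10
_SUBPOLAR_CENTERS = (0.25, 0.75)
_SUBPOLAR_WIDTH = 0.05
_PERP_SIGMA_UM = 1.0


def axial_profile(p: np.ndarray, cfg: ImageSimConfig) -> np.ndarray:
    """Noise-free axial intensity shape at fractional positions ``p``."""
    p = np.asarray(p, float)
    base = np.ones_like(p)
    peak = cfg.pole_enrichment - 1.0
    bumps = peak * (
        cfg.pole_asymmetry[0] * np.exp(-0.5 * (p / _POLE_PEAK_WIDTH) ** 2)
        + cfg.pole_asymmetry[1] * np.exp(-0.5 * ((1 - p) / _POLE_PEAK_WIDTH) ** 2)
    )
    dip = np.zeros_like(p)
    for c in _SUBPOLAR_CENTERS:
        dip += np.exp(-0.5 * ((p - c) / _SUBPOLAR_WIDTH) ** 2)
    modulation = 1.0 - (1.0 - cfg.subpolar_scale) * np.clip(dip, 0.0, 1.0)
    return (base + bumps) * modulation


def _blob(rows, cols, center, sigma_px):
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return np.exp(-0.5 * d2 / sigma_px**2)


def gen_spindle_image(cfg: ImageSimConfig) -> SpindleImage:
    """Render a two-channel spindle projection with ground-truth poles."""
    side_um = cfg.spindle_length + 2 * cfg.margin
    side = int(round(side_um / cfg.pixel_size))
    if cfg.spindle_length / cfg.pixel_size > side:
        raise ValueError("spindle longer than the image")
    rows, cols = np.mgrid[0:side, 0:side].astype(float)
    center = np.array([(side - 1) / 2.0, (side - 1) / 2.0])
    theta = math.radians(cfg.angle_deg)
    u = np.array([math.sin(theta), math.cos(theta)])  # (row, col) axis unit
    normal = np.array([-u[1], u[0]])

    half_px = cfg.spindle_length / (2 * cfg.pixel_size)
    pole0 = center - half_px * u
    pole1 = center + half_px * u

    dr, dc = rows - pole0[0], cols - pole0[1]
    a = dr * u[0] + dc * u[1]  # axial pixel coordinate from pole0
    d = dr * normal[0] + dc * normal[1]  # signed perpendicular offset
    length_px = 2 * half_px
    p = np.clip(a / length_px, 0.0, 1.0)
    excess = np.maximum.reduce([np.zeros_like(a), -a, a - length_px])
    sigma_perp = _PERP_SIGMA_UM / cfg.pixel_size
    envelope = np.exp(-0.5 * (d**2 + excess**2) / sigma_perp**2)

    tub = cfg.background + cfg.amplitude * axial_profile(p, cfg) * envelope

    chrom = np.full((side, side), float(cfg.chromosome_background))
    sigma_blob = cfg.blob_radius / math.sqrt(2 * math.log(2)) / cfg.pixel_size
    spread_px = cfg.chromosome_spread / cfg.pixel_size
    r_px = cfg.blob_radius / cfg.pixel_size
    if cfg.chromosome_spread == 0:
        centers_ax = [0.0]
        sigmas = [sigma_blob]
    elif spread_px < 2 * r_px:
        # single compact mass: half-maximum extent equals the spread
        sigmas = [spread_px / 2 / math.sqrt(2 * math.log(2))]
        centers_ax = [0.0]
    else:
        centers_ax = [-(spread_px / 2 - r_px), spread_px / 2 - r_px]
        sigmas = [sigma_blob, sigma_blob]
    for c_ax, sig in zip(centers_ax, sigmas):
        blob_center = center + c_ax * u
        chrom += cfg.chromosome_amplitude * _blob(rows, cols, blob_center, sig)
    if cfg.include_fourth:
        sigma4 = cfg.fourth_radius / math.sqrt(2 * math.log(2)) / cfg.pixel_size
        off = (spread_px / 2 + 1.0 / cfg.pixel_size) * u + (
            0.3 / cfg.pixel_size
        ) * normal
        chrom += cfg.chromosome_amplitude * _blob(rows, cols, center + off, sigma4)

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        tub = tub + rng.normal(0, cfg.noise_sd * cfg.amplitude, tub.shape)
        chrom = chrom + rng.normal(
            0, cfg.noise_sd * cfg.chromosome_amplitude, chrom.shape
        )
    tub = np.clip(tub, 0.0, None)
    chrom = np.clip(chrom, 0.0, None)

    return SpindleImage(
        channels={"tubulin": tub, "chromosomes": chrom},
        pixel_size=cfg.pixel_size,
        poles=(tuple(pole0), tuple(pole1)),
        provenance="projection",
        meta={
            "config": cfg,
            "true_spread_um": cfg.chromosome_spread,
            "true_subpolar_scale": cfg.subpolar_scale,
        },
    )


def gen_spindle_stack(
    cfg: ImageSimConfig, n_slices: int = 3
) -> dict[str, list[np.ndarray]]:
    """Thin z-stack whose maximum projection is the 2-D image.

    Slices are the projection scaled by an out-of-focus attenuation
    profile peaking at 1 on the central slice; this exercises the
    projection step without modelling optics.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    img = gen_spindle_image(cfg)
    z = np.arange(n_slices) - (n_slices - 1) / 2
    weights = np.exp(-0.5 * (z / max(n_slices / 2.0, 1.0)) ** 2)
    weights = weights / weights.max()
    return {
        name: [w * ch for w in weights] for name, ch in img.channels.items()
    }


# ---------------------------------------------------------------------------
# congression datasets


def congression_noise_for_r(
    slope: float, sigma_log: float, target_r: float
) -> float:
    """Spread noise SD giving population correlation ``target_r``.

    With spread = intercept + slope*ln(A) + eps and ln(A) ~ N(mu,
    sigma_log^2), the population Pearson correlation between spread and
    ln(A) is slope*sigma_log / sqrt(slope^2 sigma_log^2 + noise^2);
    inverting gives the required noise level.
    """
    if not -1 < target_r < 0:
        raise ValueError("target_r must be in (-1, 0)")
    if slope >= 0:
        raise ValueError("slope must be negative")
    return abs(slope) * sigma_log * math.sqrt(1.0 / target_r**2 - 1.0)


#: Default target for the mean *sample* correlation between spread and
#: log pole intensity at the generated dataset size.
DEFAULT_TARGET_R = -0.772


def population_r_for_sample_mean(target_r: float, n: int) -> float:
    """Population correlation whose mean sample r at size ``n`` is ``target_r``.

    The sample Pearson r is attenuated toward 0 in small samples,
    E[r] ~= rho * (1 - (1 - rho^2) / (2 (n - 1))); this inverts that
    first-order relation by fixed-point iteration so a generated dataset's
    expected sample correlation hits the target rather than undershooting
    it by the attenuation.
    """
    if not -1 < target_r < 0:
        raise ValueError("target_r must be in (-1, 0)")
    rho = target_r
    for _ in range(100):
        rho = target_r / (1.0 - (1.0 - rho**2) / (2.0 * (n - 1)))
    return rho


def gen_congression_dataset(
    n: int,
    slope: float = -1.5,
    intercept: float = 12.0,
    noise_sd: float | None = None,
    intensity_law: tuple[float, float] = (5.0, 1.0),
    seed: int = 0,
    floor: float = 0.2,
) -> list[CongressionRecord]:
    """Draw per-spindle (chromosome spread, pole intensity) records.

    Pole intensities follow a lognormal law with parameters
    ``intensity_law = (mu, sigma)`` of the underlying normal; spreads are
    ``intercept + slope * ln(intensity) + eps`` in micrometres, clipped
    below at ``floor``.  When ``noise_sd`` is None it is calibrated so the
    population correlation between spread and log intensity equals
    -0.772 (strong negative association between chromosome spread and
    pole-accumulated Augmin).
    """
    if n < 3:
        raise ValueError("n must be at least 3 (correlation undefined below)")
    if slope > 0:
        raise ValueError("slope must be <= 0 (negative association)")
    mu, sigma = intensity_law
    if sigma <= 0:
        raise ValueError("intensity_law sigma must be positive")
    if noise_sd is None:
        rho = population_r_for_sample_mean(DEFAULT_TARGET_R, n)
        noise_sd = congression_noise_for_r(slope, sigma, rho)
    rng = np.random.default_rng(seed)
    log_a = rng.normal(mu, sigma, n)
    eps = rng.normal(0.0, noise_sd, n)
    spread = np.clip(intercept + slope * log_a + eps, floor, None)
    return [
        CongressionRecord(
            spread=float(sp),
            pole_intensity=float(math.exp(la)),
            oocyte_id=f"sim{i:03d}",
        )
        for i, (sp, la) in enumerate(zip(spread, log_a))
    ]
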