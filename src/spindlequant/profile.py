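"""Axial spindle-fluorescence profiling.

Quantifies how fluorescence (tubulin or an Augmin subunit) is distributed
along the pole-to-pole axis of a spindle: a line scan between the two
poles, normalization of position to spindle length and of intensity to the
profile maximum, medians over 10 equal axial bins, and a sub-polar/equator
statistic.  Bins are numbered 1..10 from pole to pole; bins 3 and 8 sit in
the sub-polar regions and bins 5 and 6 flank the equator, so the ratio

    mean(median_3, median_8) / mean(median_5, median_6)

measures sub-polar enrichment relative to the equator and is symmetric
under reversing the profile orientation.  Groups of per-spindle ratios are
compared with a two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "SpindleImage",
    "IntensityProfile",
    "max_project",
    "extract_line_profile",
    "normalize_profile",
    "bin_medians",
    "region_ratio",
    "compare_groups",
]

N_BINS = 10
SUBPOLAR_BINS = (3, 8)  # 1-based bin numbers
EQUATOR_BINS = (5, 6)


@dataclass
class SpindleImage:
    """A 2-channel spindle image with physical calibration and pole marks.

    ``channels`` maps channel names (e.g. ``"tubulin"``, ``"chromosomes"``)
    to congruent 2-D arrays; ``poles`` holds the two pole coordinates as
    (row, col) pixel positions; ``pixel_size`` is in micrometres per pixel.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    poles: tuple[tuple[float, float], tuple[float, float]]
    provenance: str = "projection"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channel grids must be congruent")
        p0, p1 = (np.asarray(p, dtype=float) for p in self.poles)
        if np.allclose(p0, p1):
            raise ValueError("the two poles must be distinct")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def spindle_length_um(self) -> float:
        p0, p1 = (np.asarray(p, float) for p in self.poles)
        return float(np.linalg.norm(p1 - p0)) * self.pixel_size


@dataclass
class IntensityProfile:
    """A normalized pole-to-pole intensity profile.

    Positions run from 0 (one pole) to 1 (the other); intensities are
    scaled so the profile maximum is 1.
    """

    positions: np.ndarray
    intensities: np.ndarray
    spindle_id: str = ""

    def __post_init__(self):
        pos = np.asarray(self.positions, float)
        ints = np.asarray(self.intensities, float)
        self.positions, self.intensities = pos, ints
        if pos.shape != ints.shape or pos.ndim != 1:
            raise ValueError("positions and intensities must be congruent 1-D")
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be nondecreasing")
        if not (abs(pos[0]) < 1e-9 and abs(pos[-1] - 1.0) < 1e-9):
            raise ValueError("positions must span [0, 1]")


def max_project(stack) -> np.ndarray:
    """Pixelwise maximum-intensity projection of a z-stack."""
    slices = [np.asarray(s) for s in stack]
    if len(slices) == 0:
        raise ValueError("empty stack")
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError("stack slices must share a shape")
    return np.max(np.stack(slices, axis=0), axis=0)


def extract_line_profile(
    image: SpindleImage, channel: str, width: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Sample intensity along the pole-to-pole segment.

    Points are spaced one pixel apart along the segment and interpolated
    bilinearly; with ``width > 1`` (odd) the profile is averaged over that
    many parallel lines offset perpendicular to the axis at one-pixel
    spacing.  Returns ``(positions_um, intensities)``.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be an odd positive integer")
    if channel not in image.channels:
        raise ValueError(f"unknown channel {channel!r}")
    p0, p1 = (np.asarray(p, float) for p in image.poles)
    vec = p1 - p0
    length_px = float(np.linalg.norm(vec))
    if length_px < 1e-9:
        raise ValueError("poles coincide")
    u = vec / length_px
    n = int(np.floor(length_px)) + 1
    ts = np.linspace(0.0, length_px, n)
    pts = p0[None, :] + ts[:, None] * u[None, :]
    normal = np.array([-u[1], u[0]])
    offsets = np.arange(width) - (width - 1) / 2
    data = image.channels[channel]
    acc = np.zeros(n)
    for off in offsets:
        coords = pts + off * normal[None, :]
        acc += ndimage.map_coordinates(
            data.astype(float), coords.T, order=1, mode="nearest"
        )
    return ts * image.pixel_size, acc / width


def normalize_profile(
    positions_um, intensities, spindle_id: str = ""
) -> IntensityProfile:
    """Normalize position to spindle length and intensity to the maximum."""
    pos = np.asarray(positions_um, float)
    ints = np.asarray(intensities, float)
    if pos.size < N_BINS:
        raise ValueError(f"need at least {N_BINS} samples along the line")
    span = pos[-1] - pos[0]
    if span <= 0:
        raise ValueError("profile has zero length")
    peak = float(np.max(ints))
    if peak <= 0:
        raise ValueError("all-zero profile cannot be normalized")
    return IntensityProfile(
        positions=(pos - pos[0]) / span,
        intensities=ints / peak,
        spindle_id=spindle_id,
    )


def bin_medians(profile: IntensityProfile) -> np.ndarray:
    """Median normalized intensity in each of 10 equal axial divisions.

    Bin ``i`` (1..10) covers positions ``[(i-1)/10, i/10)``; the last bin
    is closed so position 1 belongs to bin 10.  Every sample falls in
    exactly one bin, and every bin must contain at least one sample.
    """
    idx = np.minimum((profile.positions * N_BINS).astype(int), N_BINS - 1)
    medians = np.empty(N_BINS)
    for b in range(N_BINS):
        members = profile.intensities[idx == b]
        if members.size == 0:
            raise ValueError(
                f"axial bin {b + 1} is empty; sample the line at >= "
                f"{N_BINS} points spread over the spindle length"
            )
        medians[b] = np.median(members)
    return medians


def region_ratio(medians) -> float:
    """Sub-polar (bins 3, 8) over equator (bins 5, 6) intensity ratio."""
    m = np.asarray(medians, float)
    if m.shape != (N_BINS,):
        raise ValueError(f"expected {N_BINS} bin medians")
    sub = np.mean([m[b - 1] for b in SUBPOLAR_BINS])
    eq = np.mean([m[b - 1] for b in EQUATOR_BINS])
    if eq <= 0:
        raise ValueError("zero equator intensity")
    return float(sub / eq)


def compare_groups(ratios_a, ratios_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two groups of ratios.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, and the normal approximation with tie
    correction otherwise.  Returns ``(U statistic, two-sided p)``.
    """
    a = np.asarray(ratios_a, float)
    b = np.asarray(ratios_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both groups; p = 1")
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
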