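"""Pole-intensity and chromosome-congression measurements.

Two per-spindle quantities and their relationship:

* the background-subtracted per-pixel fluorescence at the spindle poles,
  from two nested regions of interest — a large ROI covering spindle plus
  surrounding cytosol (summed intensity I1 over N1 pixels) and the pole
  ROIs (I2 over N2 pixels).  The cytosol background per pixel is
  ``b = (I1 - I2) / (N1 - N2)`` and the pole signal above background is
  ``I2 / N2 - b``;
* the chromosome spread: the axial extent of the thresholded chromosome
  mass projected onto the pole-to-pole axis, in micrometres.

Across a set of spindles the degree of congression (small spread) is
related to pole-accumulated Augmin by the Pearson correlation between
spread and the natural log of pole intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "PoleMeasurement",
    "CongressionRecord",
    "pole_intensity",
    "chromosome_spread",
    "congression_correlation",
]

#: Blobs smaller than this fraction of the largest blob's area are treated
#: as the 4th chromosome and dropped when exclusion is requested.
FOURTH_AREA_FRACTION = 0.10


@dataclass(frozen=True)
class PoleMeasurement:
    """Summed-ROI intensities and the derived per-pixel pole value."""

    I1: float
    N1: int
    I2: float
    N2: int
    value: float

    def __post_init__(self):
        if not (self.N1 > self.N2 > 0):
            raise ValueError("require N1 > N2 > 0")
        if self.I1 < self.I2 or self.I2 < 0:
            raise ValueError("require I1 >= I2 >= 0")

    @property
    def background_per_pixel(self) -> float:
        return (self.I1 - self.I2) / (self.N1 - self.N2)


@dataclass(frozen=True)
class CongressionRecord:
    """Per-spindle chromosome spread and pole intensity pair."""

    spread: float
    pole_intensity: float
    oocyte_id: str = ""
    include_fourth: bool = False

    def __post_init__(self):
        if self.spread < 0:
            raise ValueError("spread must be non-negative")
        if self.pole_intensity <= 0:
            raise ValueError("pole_intensity must be positive for log transform")


def pole_intensity(
    image: np.ndarray,
    roi_large: np.ndarray,
    roi_poles: np.ndarray,
    literal: bool = False,
) -> PoleMeasurement:
    """Background-subtracted pole intensity from two nested ROI masks.

    ``roi_poles`` must be contained in ``roi_large``.  The per-pixel form
    ``I2/N2 - (I1 - I2)/(N1 - N2)`` is the default; ``literal=True``
    instead returns the summed form ``I2 - (I1 - I2)/(N1 - N2)``, which
    subtracts one pixel's background from the pole sum and is kept only
    for comparison.
    """
    img = np.asarray(image, float)
    large = np.asarray(roi_large, bool)
    poles = np.asarray(roi_poles, bool)
    if img.shape != large.shape or img.shape != poles.shape:
        raise ValueError("image and ROI masks must be congruent")
    if not poles.any() or not large.any():
        raise ValueError("ROI masks must be nonempty")
    if np.any(poles & ~large):
        raise ValueError("pole ROI must be contained in the large ROI")
    n1, n2 = int(large.sum()), int(poles.sum())
    if n1 <= n2:
        raise ValueError("large ROI must contain pixels outside the pole ROI")
    i1 = float(img[large].sum())
    i2 = float(img[poles].sum())
    b = (i1 - i2) / (n1 - n2)
    value = (i2 - b) if literal else (i2 / n2 - b)
    return PoleMeasurement(I1=i1, N1=n1, I2=i2, N2=n2, value=value)


def chromosome_spread(
    channel: np.ndarray,
    axis: tuple[tuple[float, float], tuple[float, float]],
    pixel_size: float,
    exclude_smallest: bool = False,
    threshold: str | float = "otsu",
) -> float:
    """Axial extent of the chromosome mass, in micrometres.

    The channel is thresholded (Otsu by default; ``"half-max"`` uses the
    midpoint between the channel minimum and maximum, matching the
    half-maximum definition of the synthetic blob masks; a float is used
    directly), connected blobs are labelled, optionally blobs smaller
    than 10% of the largest blob's area are dropped (the 4th-chromosome
    proxy), and the surviving mask pixels are projected onto the
    pole-to-pole axis.  The spread is (max - min) projected coordinate
    times ``pixel_size``; a single-pixel mass has spread 0.
    """
    img = np.asarray(channel, float)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    p0, p1 = (np.asarray(p, float) for p in axis)
    vec = p1 - p0
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise ValueError("axis endpoints coincide")
    u = vec / norm

    if threshold == "otsu":
        if np.all(img == img.flat[0]):
            raise ValueError("no chromosome signal: channel is constant")
        thr = threshold_otsu(img)
    elif threshold == "half-max":
        thr = 0.5 * (float(img.min()) + float(img.max()))
    else:
        thr = float(threshold)
    mask = img >= thr * (1 - 1e-12) if threshold == "half-max" else img > thr
    if not mask.any():
        raise ValueError("no chromosome signal above threshold")

    labels = label(mask)
    props = regionprops(labels)
    if exclude_smallest and len(props) > 1:
        largest = max(p.area for p in props)
        keep = {p.label for p in props if p.area >= FOURTH_AREA_FRACTION * largest}
        mask = np.isin(labels, sorted(keep))
        if not mask.any():
            raise ValueError("no chromosome signal after blob exclusion")

    rr, cc = np.nonzero(mask)
    proj = (rr - p0[0]) * u[0] + (cc - p0[1]) * u[1]
    return float(proj.max() - proj.min()) * pixel_size


def congression_correlation(records) -> tuple[float, float, int]:
    """Pearson correlation of spread vs ln(pole intensity).

    Returns ``(r, p, n)`` with a two-sided p-value from the t
    distribution.  The correlation is invariant to the log base.
    """
    records = list(records)
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records")
    spread = np.array([r.spread for r in records], float)
    log_int = np.log(np.array([r.pole_intensity for r in records], float))
    if np.ptp(spread) == 0 or np.ptp(log_int) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(spread, log_int)
    return float(res.statistic), float(res.pvalue), n
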