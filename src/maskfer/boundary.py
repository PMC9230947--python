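"""Landmark detection along the placed infinity curve.

For every triple of consecutive curve points (p_i, p_{i+1}, p_{i+2}) the
two chords are rasterized (Bresenham) and the pixel intensities along the
joined trace form a 1-D profile.  A landmark is declared wherever the
profile shows a peak with both high prominence (the intensity rises from
low to high and falls back) and a wide full width at half prominence
(many pixels crossing a significant edge); the peak's *left base* — the
rising-side valley — marks the low-to-high boundary pixel, which is
mapped back through the trace to image coordinates.

Consecutive triples overlap, so every chord is scanned twice with
different neighbors; the redundancy is deliberate and near-duplicate
landmarks are kept (only exact pixel repeats are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from skimage.draw import line as _bresenham_line

from maskfer.infinity import InfinityPointSet


@dataclass(frozen=True)
class PeakThresholds:
    """Acceptance thresholds for profile peaks.

    Defaults: prominence at 10% of the 8-bit dynamic range, width of at
    least 3 samples (rejects single-pixel noise spikes).
    """

    min_prominence: float = 25.5
    min_width: float = 3.0

    def __post_init__(self) -> None:
        if self.min_prominence < 0 or self.min_width < 0:
            raise ValueError("peak thresholds must be >= 0")


@dataclass(frozen=True)
class Peak:
    apex_index: int
    prominence: float
    width: float
    left_base: int

    def __post_init__(self) -> None:
        if self.left_base >= self.apex_index:
            raise ValueError("left base must precede the apex")
        if self.prominence <= 0 or self.width <= 0:
            raise ValueError("prominence and width must be positive")


@dataclass(frozen=True)
class IntensityProfile:
    samples: np.ndarray
    pixel_trace: np.ndarray  # (m, 2) int, columns x, y
    source_index: int

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.pixel_trace):
            raise ValueError("samples and pixel trace must have equal length")


@dataclass(frozen=True)
class Landmark:
    x: int
    y: int
    source_index: int = 0
    prominence: float = 0.0
    width: float = 0.0


def rasterize_segment(p0: tuple[int, int], p1: tuple[int, int]) -> np.ndarray:
    """Bresenham pixels from p0 to p1 inclusive, as an (m, 2) (x, y) array.

    Reversing the endpoints yields the exact reversed pixel list: the
    segment is always rasterized from its lexicographically smaller
    endpoint and flipped as needed.
    """
    p0 = (int(p0[0]), int(p0[1]))
    p1 = (int(p1[0]), int(p1[1]))
    flip = p1 < p0
    a, b = (p1, p0) if flip else (p0, p1)
    rr, cc = _bresenham_line(a[1], a[0], b[1], b[0])
    pts = np.column_stack([cc, rr])
    return pts[::-1] if flip else pts


def extract_profile(
    image: np.ndarray,
    triple: np.ndarray,
    source_index: int = 0,
) -> IntensityProfile:
    """Intensity profile along the two chords of one point triple.

    The shared midpoint pixel appears exactly once in the joined trace.
    """
    img = np.asarray(image)
    triple = np.asarray(triple, dtype=int)
    if triple.shape != (3, 2):
        raise ValueError("triple must be three (x, y) points")
    h, w = img.shape
    if (triple[:, 0] < 0).any() or (triple[:, 0] >= w).any() or (
        triple[:, 1] < 0
    ).any() or (triple[:, 1] >= h).any():
        raise ValueError("triple points lie outside the image")
    seg1 = rasterize_segment(triple[0], triple[1])
    seg2 = rasterize_segment(triple[1], triple[2])
    trace = np.vstack([seg1, seg2[1:]])
    samples = img[trace[:, 1], trace[:, 0]].astype(float)
    return IntensityProfile(samples, trace, source_index)


def find_profile_peaks(profile: IntensityProfile | np.ndarray) -> list[Peak]:
    """All local maxima with their prominence, FWHM width and left base.

    Prominence is the peak height above the higher of the two bounding
    valleys (to the nearest higher peak or the signal end); width is
    measured at half the prominence below the apex; the left base is the
    rising-side valley index.
    """
    samples = profile.samples if isinstance(profile, IntensityProfile) else np.asarray(profile, float)
    if len(samples) < 3:
        raise ValueError("profile must have at least 3 samples")
    idx, props = find_peaks(samples, prominence=(None, None), width=(None, None), rel_height=0.5)
    return [
        Peak(
            apex_index=int(i),
            prominence=float(p),
            width=float(wd),
            left_base=int(lb),
        )
        for i, p, wd, lb in zip(idx, props["prominences"], props["widths"], props["left_bases"])
    ]


def detect_landmarks(
    image: np.ndarray,
    placed: InfinityPointSet,
    thresholds: PeakThresholds | None = None,
    invert: bool = False,
) -> list[Landmark]:
    """Scan every consecutive point triple and collect peak left bases.

    A peak qualifies when prominence >= min_prominence AND width >=
    min_width.  With `invert` the image is intensity-flipped first, so
    dark valleys become detectable peaks.  Exact coordinate repeats are
    dropped, first occurrence kept.
    """
    th = thresholds or PeakThresholds()
    pts = np.asarray(placed.points, dtype=int)
    if len(pts) < 3:
        raise ValueError("need at least 3 placed points")
    img = np.asarray(image)
    if invert:
        img = 255 - img
    landmarks: list[Landmark] = []
    seen: set[tuple[int, int]] = set()
    for i in range(len(pts) - 2):
        profile = extract_profile(img, pts[i : i + 3], source_index=i)
        if len(profile.samples) < 3:
            continue
        for pk in find_profile_peaks(profile):
            if pk.prominence >= th.min_prominence and pk.width >= th.min_width:
                x, y = profile.pixel_trace[pk.left_base]
                key = (int(x), int(y))
                if key not in seen:
                    seen.add(key)
                    landmarks.append(
                        Landmark(int(x), int(y), i, pk.prominence, pk.width)
                    )
    return landmarks
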