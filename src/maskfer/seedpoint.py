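"""Seed-point localization from intensity projection profiles.

On an upper-face crop the nose bridge is the brightest vertical structure
and the eye/eyebrow band the darkest horizontal one, so

    x_seed = argmax(column sums)        (vertical projection, raw)
    y_seed = argmin(smoothed row sums)  (horizontal projection)

The horizontal projection is smoothed with a Savitzky-Golay filter
(window 31, polynomial order 3) before taking the argmin: depending on
contrast the raw minimum lands on the eyes, on the brows, or between
them, and smoothing merges the three cases into a single stable minimum
in the eye-brow band.  The vertical projection is left raw — the nose
column maximum is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 31
DEFAULT_POLYORDER = 3


@dataclass(frozen=True)
class ProjectionProfile:
    """Per-column (vertical) or per-row (horizontal) intensity sums."""

    axis: Literal["vertical", "horizontal"]
    values: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("profile values must be a non-empty 1-D array")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SeedPoint:
    x: int
    y: int


def project(image: np.ndarray, axis: Literal["vertical", "horizontal"]) -> ProjectionProfile:
    """Exact column sums (vertical) or row sums (horizontal); no normalization."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("project expects a non-empty 2-D intensity grid")
    if axis == "vertical":
        return ProjectionProfile("vertical", img.sum(axis=0))
    if axis == "horizontal":
        return ProjectionProfile("horizontal", img.sum(axis=1))
    raise ValueError(f"unknown projection axis {axis!r}")


def smooth_profile(
    p: ProjectionProfile,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> ProjectionProfile:
    """Savitzky-Golay least-squares smoothing, length preserving.

    If the requested window exceeds the profile length it is reduced to
    the largest valid odd window (logged) rather than failing; short
    profiles then may come back unsmoothed.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    n = len(p.values)
    if window > n:
        reduced = n if n % 2 == 1 else n - 1
        logger.warning(
            "Savitzky-Golay window %d exceeds profile length %d; reducing to %d",
            window, n, reduced,
        )
        window = reduced
    if window <= polyorder:
        # too short to fit the polynomial: the fit would be exact anyway
        smoothed = p.values.copy()
    else:
        smoothed = savgol_filter(p.values, window_length=window, polyorder=polyorder)
    return ProjectionProfile(p.axis, p.values, smoothed)


def find_seed(
    image: np.ndarray,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    smooth_vertical: bool = False,
) -> SeedPoint:
    """Locate the anchor pixel for curve placement.

    Ties in argmax/argmin break to the lowest index.  `smooth_vertical`
    optionally applies the same Savitzky-Golay smoothing to the column
    sums before the argmax.
    """
    vert = project(image, "vertical")
    horiz = smooth_profile(project(image, "horizontal"), window, polyorder)
    v_values = vert.values
    if smooth_vertical:
        v_values = smooth_profile(vert, window, polyorder).smoothed
    # quantize before arg-extremum so float noise from smoothing cannot
    # break exact ties (lowest index wins)
    x_seed = int(np.argmax(np.round(v_values, 6)))
    y_seed = int(np.argmin(np.round(horiz.smoothed, 6)))
    return SeedPoint(x_seed, y_seed)
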