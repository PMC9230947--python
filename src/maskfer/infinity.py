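"""Infinity-shaped (figure-eight) sampling curve.

The curve x = cos(t), y = sin(alpha*t)/beta is sampled at n points over
t in [0, c*pi].  With the defaults alpha=2, beta=2, c=20, n=50 the curve
traverses 10 complete cos-periods ("rounds") with on average 5 points per
round; because the n samples are placed *inclusively* over [0, c*pi]
(step c*pi/(n-1)) the points of consecutive rounds drift rather than
coincide, so repeated traversals probe slightly different pixels — the
redundancy the landmark detector exploits.

The unit-frame point set is then rescaled (min-max per axis) to the upper
face frame and translated so its centroid sits on the seed point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

Frame = Literal["unit", "normalized", "placed"]


@dataclass(frozen=True)
class InfinityConfig:
    """Curve-generation parameters.

    alpha
        Number of circular-like lobes per cos-period (2 gives the classic
        figure-eight).
    beta
        Height divisor; the unit-frame curve spans y in [-1/beta, 1/beta].
    c
        Half-period count: t runs over [0, c*pi], i.e. c/2 cos-periods.
    n
        Number of sample points.
    sampling
        "inclusive" places n points with step c*pi/(n-1) (endpoints
        included; rounds drift).  "algorithm1" uses step c*pi/n with n+1
        values, which makes every round retrace the same 5 points exactly.
    """

    alpha: int = 2
    beta: float = 2.0
    c: float = 20.0
    n: int = 50
    sampling: Literal["inclusive", "algorithm1"] = "inclusive"

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.n < 4:
            raise ValueError("n must be >= 4")

    @property
    def rounds(self) -> float:
        """Number of complete cos-periods the curve traverses (c/2)."""
        return self.c / 2.0

    @property
    def points_per_round(self) -> float:
        """Mean number of sample points per cos-period."""
        return self.n / self.rounds


@dataclass(frozen=True)
class NormalizationRange:
    """Affine range map for one axis: [min_old, max_old] -> [min_new, max_new]."""

    min_old: float
    max_old: float
    min_new: float
    max_new: float

    def __post_init__(self) -> None:
        if not self.max_old > self.min_old:
            raise ValueError("degenerate source range: max_old must exceed min_old")
        if self.max_new < self.min_new:
            raise ValueError("max_new must be >= min_new")

    def apply(self, v: np.ndarray) -> np.ndarray:
        scale = (self.max_new - self.min_new) / (self.max_old - self.min_old)
        return (v - self.min_old) * scale + self.min_new

    def inverse(self) -> "NormalizationRange":
        if self.max_new == self.min_new:
            raise ValueError("cannot invert a collapsed target range")
        return NormalizationRange(self.min_new, self.max_new, self.min_old, self.max_old)


@dataclass(frozen=True)
class InfinityPointSet:
    """Ordered curve samples plus the config that generated them."""

    points: np.ndarray  # (n, 2) float, columns x, y
    config: InfinityConfig
    frame: Frame = "unit"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def centroid(self) -> tuple[float, float]:
        cx, cy = self.points.mean(axis=0)
        return float(cx), float(cy)


def generate_infinity_points(config: InfinityConfig | None = None) -> InfinityPointSet:
    """Sample the curve (cos t, sin(alpha t)/beta) over t in [0, c*pi]."""
    cfg = config or InfinityConfig()
    if cfg.sampling == "inclusive":
        t = np.linspace(0.0, cfg.c * np.pi, cfg.n)
    else:  # "algorithm1": literal grid 0, cpi/n, ..., cpi (n+1 values)
        t = np.arange(cfg.n + 1) * (cfg.c * np.pi / cfg.n)
    pts = np.column_stack([np.cos(t), np.sin(cfg.alpha * t) / cfg.beta])
    return InfinityPointSet(pts, cfg, frame="unit")


def normalize_points(
    ps: InfinityPointSet,
    rng_x: NormalizationRange,
    rng_y: NormalizationRange,
) -> InfinityPointSet:
    """Min-max rescale each axis into a new range (e.g. image width/height)."""
    pts = np.column_stack([rng_x.apply(ps.x), rng_y.apply(ps.y)])
    return InfinityPointSet(pts, ps.config, frame="normalized")


def ranges_for_image(
    ps: InfinityPointSet,
    image_w: int,
    image_h: int,
    height_ratio: float = 1.0,
) -> tuple[NormalizationRange, NormalizationRange]:
    """Ranges mapping the point set's bounding box onto an image frame.

    x maps onto [0, image_w - 1]; y onto [0, round(height_ratio * (image_h - 1))],
    so height_ratio < 1 squashes the curve vertically relative to the crop.
    """
    if not 0 < height_ratio <= 1:
        raise ValueError("height_ratio must lie in (0, 1]")
    rng_x = NormalizationRange(float(ps.x.min()), float(ps.x.max()), 0.0, float(image_w - 1))
    y_new_max = float(np.round(height_ratio * (image_h - 1)))
    rng_y = NormalizationRange(float(ps.y.min()), float(ps.y.max()), 0.0, y_new_max)
    return rng_x, rng_y


def _round_half_away(v: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def place_at_seed(
    ps: InfinityPointSet,
    seed_x: float,
    seed_y: float,
    image_w: int,
    image_h: int,
) -> InfinityPointSet:
    """Translate the normalized curve so its centroid sits on the seed point.

    If the translated bounding box would leave the image, the whole shape is
    shifted back just enough to fit (never clipped pointwise, so the curve
    geometry is preserved).  Coordinates are rounded to integer pixels
    (half away from zero) only at this final step.
    """
    if ps.frame != "normalized":
        raise ValueError("place_at_seed expects a point set in the 'normalized' frame")
    span_x = ps.x.max() - ps.x.min()
    span_y = ps.y.max() - ps.y.min()
    if span_x > image_w - 1 or span_y > image_h - 1:
        raise ValueError(
            "normalized shape exceeds image bounds; normalize to at most the image size"
        )
    cx, cy = ps.centroid()
    dx, dy = seed_x - cx, seed_y - cy
    # pull the shift back so the bounding box stays inside the frame
    dx = min(max(dx, -ps.x.min()), (image_w - 1) - ps.x.max())
    dy = min(max(dy, -ps.y.min()), (image_h - 1) - ps.y.max())
    pts = ps.points + np.array([dx, dy])
    pts = _round_half_away(pts)
    pts[:, 0] = np.clip(pts[:, 0], 0, image_w - 1)  # guards rounding at the border
    pts[:, 1] = np.clip(pts[:, 1], 0, image_h - 1)
    return InfinityPointSet(pts.astype(int), ps.config, frame="placed")
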