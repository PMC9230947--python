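"""Per-landmark HOG descriptors.

Each landmark is described by a 20x20 pixel blob around it.  Gradients
are central differences (replicated edges); orientation is the
quadrant-aware arctangent of (Gy, Gx) on image-frame axes, mapped to
[0, 360).  The blob splits into 2x2 spatial cells of 10x10 pixels; each
cell accumulates an 18-bin signed-orientation histogram (20 degree bins,
magnitude-weighted, linearly interpolated between adjacent bins).  The
four cell histograms are concatenated row-major and L2-normalized as a
single 72-value block.  The full landmark feature is (x, y, d1..d72) —
74 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from maskfer.boundary import Landmark

BLOB_SIZE = 20
N_CELLS = 2  # per axis
N_BINS = 18
BIN_WIDTH = 360.0 / N_BINS
DESCRIPTOR_LEN = N_CELLS * N_CELLS * N_BINS  # 72
FEATURE_LEN = DESCRIPTOR_LEN + 2  # x, y, descriptor
_EPS = 1e-6


@dataclass(frozen=True)
class GradientField:
    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    angle: np.ndarray  # degrees in [0, 360)


@dataclass(frozen=True)
class LandmarkFeature:
    x: int
    y: int
    descriptor: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.descriptor, dtype=float)
        if d.shape != (DESCRIPTOR_LEN,):
            raise ValueError(f"descriptor must have exactly {DESCRIPTOR_LEN} values")
        object.__setattr__(self, "descriptor", d)

    def flatten(self) -> np.ndarray:
        """(x, y, d1..d72) — the 74-value feature vector."""
        return np.concatenate([[float(self.x), float(self.y)], self.descriptor])


def gradient(blob: np.ndarray) -> GradientField:
    """Central-difference gradients with replicated borders.

    Gx(y,x) = Y(y,x+1) - Y(y,x-1), Gy(y,x) = Y(y+1,x) - Y(y-1,x);
    magnitude is the Euclidean norm, angle the four-quadrant arctangent
    of Gy/Gx in degrees, wrapped to [0, 360).
    """
    b = np.asarray(blob, dtype=float)
    if b.ndim != 2 or b.shape[0] < 3 or b.shape[1] < 3:
        raise ValueError("gradient needs a 2-D blob of at least 3x3 pixels")
    padded = np.pad(b, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    magnitude = np.hypot(gx, gy)
    angle = np.degrees(np.arctan2(gy, gx)) % 360.0
    return GradientField(gx, gy, magnitude, angle)


def extract_blob(image: np.ndarray, lm: Landmark, size: int = BLOB_SIZE) -> np.ndarray:
    """The size x size neighborhood whose start is coordinate - size/2.

    The start is clamped at 0 on the near edges; if the far edge runs out
    of image, the blob is zero-padded there so the shape is always exact.
    """
    if size < 4 or size % 2:
        raise ValueError("blob size must be even and >= 4")
    img = np.asarray(image)
    half = size // 2
    x_start = lm.x - half if lm.x > half else 0
    y_start = lm.y - half if lm.y > half else 0
    blob = np.zeros((size, size), dtype=img.dtype)
    patch = img[y_start : y_start + size, x_start : x_start + size]
    blob[: patch.shape[0], : patch.shape[1]] = patch
    return blob


def _cell_histogram(magnitude: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Magnitude-weighted orientation histogram with circular linear
    interpolation between the two adjacent 20-degree bins."""
    pos = (angle / BIN_WIDTH).ravel()
    mag = magnitude.ravel()
    lo = np.floor(pos - 0.5)  # vote split around bin centers
    frac = pos - 0.5 - lo
    bin_lo = (lo.astype(int)) % N_BINS
    bin_hi = (bin_lo + 1) % N_BINS
    hist = np.zeros(N_BINS)
    np.add.at(hist, bin_lo, mag * (1.0 - frac))
    np.add.at(hist, bin_hi, mag * frac)
    return hist


def hog_descriptor(blob: np.ndarray) -> np.ndarray:
    """72-value descriptor: 2x2 cells x 18 signed-orientation bins,
    single-block L2 normalization (epsilon 1e-6)."""
    b = np.asarray(blob, dtype=float)
    if b.shape != (BLOB_SIZE, BLOB_SIZE):
        raise ValueError(f"blob must be {BLOB_SIZE}x{BLOB_SIZE}")
    g = gradient(b)
    cell = BLOB_SIZE // N_CELLS
    hists = []
    for ci in range(N_CELLS):
        for cj in range(N_CELLS):
            sl = (slice(ci * cell, (ci + 1) * cell), slice(cj * cell, (cj + 1) * cell))
            hists.append(_cell_histogram(g.magnitude[sl], g.angle[sl]))
    desc = np.concatenate(hists)
    norm = np.sqrt(np.sum(desc**2) + _EPS**2)
    return desc / norm


def landmark_feature(image: np.ndarray, lm: Landmark) -> LandmarkFeature:
    """The 74-value landmark feature: pixel coordinates + HOG descriptor."""
    blob = extract_blob(image, lm)
    return LandmarkFeature(lm.x, lm.y, hog_descriptor(blob))


def features_for_landmarks(image: np.ndarray, landmarks: list[Landmark]) -> list[LandmarkFeature]:
    return [landmark_feature(image, lm) for lm in landmarks]
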