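"""Synthetic mask overlay and upper-face cropping.

A trapezoidal mask polygon is painted over the lower part of a detected
face box (covering nose, mouth and cheeks); only the crop above it — the
upper face — is passed downstream.  Face detection itself is pluggable:
any callable returning a FaceBox works, and a whole-image detector plus a
CSV sidecar-box reader ship by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from skimage.draw import polygon as _polygon

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])

MIN_UPPER_H = 16
MIN_UPPER_W = 32

DEFAULT_UPPER_FRACTION = 0.42
DEFAULT_MASK_COLOR = (70, 70, 80)


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face bounding box (x, y = top-left corner)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("face box must have positive width and height")


@dataclass(frozen=True)
class UpperFaceImage:
    """Upper-face crop plus its offset into the source image."""

    pixels: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("upper-face pixels must be a 2-D grid")
        if px.shape[0] < MIN_UPPER_H or px.shape[1] < MIN_UPPER_W:
            raise ValueError(
                f"upper-face crop {px.shape} below minimum {MIN_UPPER_H}x{MIN_UPPER_W}"
            )
        object.__setattr__(self, "pixels", px)

    def to_source_coords(self, x: int, y: int) -> tuple[int, int]:
        return self.origin[0] + x, self.origin[1] + y


FaceDetector = Callable[[np.ndarray], FaceBox]


def whole_image_detector(image: np.ndarray) -> FaceBox:
    """Trivial detector: the face box is the full image."""
    h, w = image.shape[:2]
    return FaceBox(0, 0, w, h)


def read_face_boxes(path) -> dict[str, FaceBox]:
    """Read a sidecar CSV (image_id,x,y,w,h) of externally detected boxes."""
    df = pd.read_csv(path)
    required = {"image_id", "x", "y", "w", "h"}
    if not required.issubset(df.columns):
        raise ValueError(f"box table must have columns {sorted(required)}")
    return {
        str(r.image_id): FaceBox(int(r.x), int(r.y), int(r.w), int(r.h))
        for r in df.itertuples(index=False)
    }


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """8-bit grayscale via BT.601 luma; identity on single-channel input."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0].astype(np.uint8, copy=False)
    if img.ndim == 3 and img.shape[2] == 3:
        return np.clip(img.astype(float) @ _LUMA + 0.5, 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported image shape {img.shape}; expected 1 or 3 channels")


def mask_polygon(box: FaceBox, mask_fraction: float, bottom_inset: float = 0.05):
    """Trapezoid over the lower `mask_fraction` of the box, narrowing to the chin.

    Returns (rows, cols) vertex arrays in image coordinates (y, x order).
    """
    if not 0 < mask_fraction < 1:
        raise ValueError("mask_fraction must lie in (0, 1)")
    top = box.y + box.h - round(mask_fraction * box.h)
    bottom = box.y + box.h - 1
    inset = round(bottom_inset * box.w)
    rows = np.array([top, top, bottom, bottom], dtype=float)
    cols = np.array(
        [box.x, box.x + box.w - 1, box.x + box.w - 1 - inset, box.x + inset],
        dtype=float,
    )
    return rows, cols


def overlay_synthetic_mask(
    image: np.ndarray,
    box: FaceBox,
    mask_fraction: float = 0.5,
    mask_color=DEFAULT_MASK_COLOR,
) -> np.ndarray:
    """Paint the trapezoidal mask polygon; pixels outside it are untouched."""
    img = np.asarray(image).copy()
    rows, cols = mask_polygon(box, mask_fraction)
    rr, cc = _polygon(rows, cols, shape=img.shape[:2])
    if img.ndim == 2:
        img[rr, cc] = int(np.mean(mask_color)) if np.ndim(mask_color) else int(mask_color)
    else:
        img[rr, cc] = np.asarray(mask_color, dtype=img.dtype)
    return img


def crop_upper_face(
    image: np.ndarray,
    box: FaceBox,
    upper_fraction: float = DEFAULT_UPPER_FRACTION,
) -> UpperFaceImage:
    """Crop rows [box.y, box.y + round(upper_fraction * box.h)) over all box columns."""
    if not 0 < upper_fraction < 1:
        raise ValueError("upper_fraction must lie in (0, 1)")
    img = np.asarray(image)
    crop_h = round(upper_fraction * box.h)
    y0, y1 = box.y, box.y + crop_h
    x0, x1 = box.x, box.x + box.w
    crop = img[y0:y1, x0:x1]
    return UpperFaceImage(crop, origin=(box.x, box.y))
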