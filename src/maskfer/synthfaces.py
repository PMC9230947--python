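"""Synthetic upper-face fixture generator with ground truth.

Renders the structure the landmark detector assumes: a bright vertical
nose-bridge ridge, two eye regions drawn as a dark elliptical lash
outline around a brighter sclera with a small dark pupil, and two dark
eyebrow arcs, on a lighter skin background with additive Gaussian noise.
Each sample carries its ground-truth boundary mask (the rendered eye
outlines and brow arcs), the true seed point (nose column × midpoint of
the eye-brow band) and an emotion label, so every downstream stage can
be scored without external datasets.

Per-class geometry deformations (brow raise/lowering, eye opening) give
the eight canonical emotion classes distinguishable landmark patterns;
within-class jitter adds ±1 px positional variation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import disk, ellipse, ellipse_perimeter

CLASSES = (
    "neutral",
    "anger",
    "contempt",
    "disgust",
    "fear",
    "happiness",
    "sadness",
    "surprise",
)

# per-class deformation of the neutral geometry:
# (brow_dy, eye_rx_scale, eye_ry_scale, eye_dy); rows grow downward, so a
# negative brow_dy raises the brow.
CLASS_DEFORMATIONS: dict[str, tuple[int, float, float, int]] = {
    "neutral": (0, 1.00, 1.00, 0),
    "anger": (3, 1.00, 0.80, 0),
    "contempt": (1, 0.95, 0.85, 1),
    "disgust": (2, 1.05, 0.80, 1),
    "fear": (-4, 1.00, 1.25, -1),
    "happiness": (-1, 1.05, 0.75, 0),
    "sadness": (2, 0.95, 0.90, 1),
    "surprise": (-6, 1.00, 1.40, -2),
}


@dataclass(frozen=True)
class BrowArc:
    """Circular eyebrow arc: stroke of `thickness` around radius `radius`,
    centered at (cx, cy + dy), spanning the upper sector of the circle."""

    cx: int
    cy: int
    radius: int
    thickness: int = 3
    dy: int = 0

    @property
    def apex_row(self) -> int:
        """Topmost row of the arc centerline."""
        return self.cy + self.dy - self.radius


@dataclass(frozen=True)
class SyntheticFaceSpec:
    width: int = 236
    height: int = 96
    nose_col: int = 118
    eye_centers: tuple[tuple[int, int], tuple[int, int]] = ((59, 56), (177, 56))
    eye_radii: tuple[tuple[int, int], tuple[int, int]] = ((26, 10), (26, 10))
    brow_arcs: tuple[BrowArc, BrowArc] = (
        BrowArc(59, 62, 28),
        BrowArc(177, 62, 28),
    )
    background_level: int = 180
    feature_level: int = 60
    # per-feature contrast overrides (None -> feature_level); these realize
    # the three regimes: eyes darker than brows, brows darker, or blended
    eye_level: int | None = None
    brow_level: int | None = None
    sclera_level: int = 150
    nose_amplitude: int = 15
    nose_sigma: float = 2.0
    noise_sd: float = 4.0
    class_label: str = "neutral"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.feature_level <= 255 and 0 <= self.background_level <= 255):
            raise ValueError("intensity levels must lie in [0, 255]")
        if self.feature_level >= self.background_level:
            raise ValueError("features must be darker than the background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.nose_col < self.width:
            raise ValueError("nose_col outside image")
        for (ex, ey), (rx, ry) in zip(self.eye_centers, self.eye_radii):
            if not (rx <= ex < self.width - rx and ry <= ey < self.height - ry):
                raise ValueError("eye ellipse extends outside the image")
        for arc in self.brow_arcs:
            if arc.apex_row < 0 or arc.apex_row >= self.height:
                raise ValueError("brow arc extends outside the image")

    @property
    def resolved_eye_level(self) -> int:
        return self.feature_level if self.eye_level is None else self.eye_level

    @property
    def resolved_brow_level(self) -> int:
        return self.feature_level if self.brow_level is None else self.brow_level

    @property
    def eye_row(self) -> float:
        return float(np.mean([ey for _, ey in self.eye_centers]))

    @property
    def brow_apex_row(self) -> float:
        return float(np.mean([a.apex_row for a in self.brow_arcs]))


@dataclass(frozen=True)
class SyntheticUpperFace:
    image: np.ndarray  # uint8 (h, w)
    boundary_mask: np.ndarray  # bool (h, w)
    true_seed: tuple[int, int]  # (x, y)
    label: str
    spec: SyntheticFaceSpec

    def __post_init__(self) -> None:
        if self.image.shape != self.boundary_mask.shape:
            raise ValueError("image and boundary mask must share dimensions")
        x, y = self.true_seed
        h, w = self.image.shape
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError("true seed outside image")


def rafdb_spec(**overrides) -> SyntheticFaceSpec:
    """Small-profile spec mirroring in-the-wild 100x46 upper-face crops."""
    base = dict(
        width=100,
        height=46,
        nose_col=50,
        eye_centers=((25, 27), (75, 27)),
        eye_radii=((11, 5), (11, 5)),
        brow_arcs=(BrowArc(25, 30, 12, thickness=2), BrowArc(75, 30, 12, thickness=2)),
        nose_sigma=2.0,
    )
    base.update(overrides)
    return SyntheticFaceSpec(**base)


def _arc_pixels(arc: BrowArc, shape: tuple[int, int], half_span_deg: float = 35.0):
    """Pixels of the stroked brow arc and of its centerline."""
    h, w = shape
    theta = np.deg2rad(np.linspace(270 - half_span_deg, 270 + half_span_deg, 720))
    radii = np.arange(arc.radius - arc.thickness / 2, arc.radius + arc.thickness / 2 + 0.5, 0.5)
    cy = arc.cy + arc.dy
    rr = np.concatenate([np.round(cy + r * np.sin(theta)) for r in radii]).astype(int)
    cc = np.concatenate([np.round(arc.cx + r * np.cos(theta)) for r in radii]).astype(int)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    return (rr[keep], cc[keep])


def generate_upper_face(spec: SyntheticFaceSpec) -> SyntheticUpperFace:
    """Render one upper-face image with its ground truth.

    Deterministic for a fixed spec (noise is seeded by spec.rng_seed).
    """
    h, w = spec.height, spec.width
    canvas = np.full((h, w), float(spec.background_level))
    boundary = np.zeros((h, w), dtype=bool)

    # bright nose-bridge ridge: a sharp specular highlight line (Laplacian
    # profile), mild enough that crossing it is not a boundary-grade edge
    cols = np.arange(w)
    ridge = spec.nose_amplitude * np.exp(-np.abs(cols - spec.nose_col) / spec.nose_sigma)
    canvas += ridge[None, :]

    # eyes: brighter sclera interior, dark lash outline, small dark pupil
    for (ex, ey), (rx, ry) in zip(spec.eye_centers, spec.eye_radii):
        rr, cc = ellipse(ey, ex, ry, rx, shape=(h, w))
        canvas[rr, cc] = spec.sclera_level
        for shrink in (0.0, 0.5, 1.0):  # ~2 px thick outline
            rr, cc = ellipse_perimeter(
                ey, ex, max(int(round(ry - shrink)), 1), max(int(round(rx - shrink)), 1),
                shape=(h, w),
            )
            canvas[rr, cc] = spec.resolved_eye_level
            if shrink == 0.0:
                boundary[rr, cc] = True
        rr, cc = disk((ey, ex), 3, shape=(h, w))
        canvas[rr, cc] = spec.resolved_eye_level

    # eyebrow arcs (fully dark; whole stroke is boundary)
    for arc in spec.brow_arcs:
        rr, cc = _arc_pixels(arc, (h, w))
        canvas[rr, cc] = spec.resolved_brow_level
        boundary[rr, cc] = True

    rng = np.random.default_rng(spec.rng_seed)
    canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    image = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    seed_y = int(round((spec.eye_row + spec.brow_apex_row) / 2.0))
    return SyntheticUpperFace(
        image=image,
        boundary_mask=boundary,
        true_seed=(spec.nose_col, seed_y),
        label=spec.class_label,
        spec=spec,
    )


def apply_class_deformation(spec: SyntheticFaceSpec, class_label: str) -> SyntheticFaceSpec:
    """Deform the neutral geometry into the given emotion class."""
    if class_label not in CLASS_DEFORMATIONS:
        raise ValueError(f"unknown class {class_label!r}; known: {CLASSES}")
    brow_dy, rx_s, ry_s, eye_dy = CLASS_DEFORMATIONS[class_label]
    eye_centers = tuple((ex, ey + eye_dy) for ex, ey in spec.eye_centers)
    eye_radii = tuple(
        (int(round(rx * rx_s)), max(int(round(ry * ry_s)), 2)) for rx, ry in spec.eye_radii
    )
    brow_arcs = tuple(replace(a, dy=a.dy + brow_dy) for a in spec.brow_arcs)
    return replace(
        spec,
        eye_centers=eye_centers,
        eye_radii=eye_radii,
        brow_arcs=brow_arcs,
        class_label=class_label,
    )


def _jitter_spec(spec: SyntheticFaceSpec, rng: np.random.Generator) -> SyntheticFaceSpec:
    """±1 px within-class positional jitter plus a fresh noise seed."""
    j = lambda: int(rng.integers(-1, 2))
    eye_centers = tuple((ex + j(), ey + j()) for ex, ey in spec.eye_centers)
    brow_arcs = tuple(replace(a, dy=a.dy + j()) for a in spec.brow_arcs)
    return replace(
        spec,
        nose_col=spec.nose_col + j(),
        eye_centers=eye_centers,
        brow_arcs=brow_arcs,
        rng_seed=int(rng.integers(2**31)),
    )


def generate_dataset(
    n_per_class: int,
    classes: tuple[str, ...] | list[str],
    base_spec: SyntheticFaceSpec | None = None,
    rng_seed: int = 0,
) -> list[SyntheticUpperFace]:
    """Balanced, deterministic sample set: n_per_class faces per class."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not classes:
        raise ValueError("classes must be non-empty")
    base = base_spec or SyntheticFaceSpec()
    rng = np.random.default_rng(rng_seed)
    out = []
    for label in classes:
        class_spec = apply_class_deformation(base, label)
        for _ in range(n_per_class):
            out.append(generate_upper_face(_jitter_spec(class_spec, rng)))
    return out


def generate_full_face(
    spec: SyntheticFaceSpec | None = None,
    rng_seed: int | None = None,
    upper_fraction: float = 0.42,
):
    """Full-face image whose top rows replicate the upper-face rendering.

    The lower region adds distinct nose-tip and mouth blobs that a mask
    overlay must hide.  Returns (image, face_box, lower_polygon, upper)
    where lower_polygon is a (rows, cols) vertex pair covering every
    lower-region feature pixel and `upper` is the embedded
    SyntheticUpperFace ground truth.
    """
    from maskfer.preprocess import FaceBox  # local import avoids cycle

    spec = spec or SyntheticFaceSpec()
    if rng_seed is not None:
        spec = replace(spec, rng_seed=rng_seed)
    upper = generate_upper_face(spec)
    w = spec.width
    full_h = int(round(spec.height / upper_fraction))
    rng = np.random.default_rng(spec.rng_seed + 1)
    lower = np.full((full_h - spec.height, w), float(spec.background_level))
    lower += rng.normal(0.0, spec.noise_sd, size=lower.shape)

    # nose tip and mouth blobs, in full-image row coordinates
    nose_row = int(round(0.55 * full_h))
    mouth_row = int(round(0.80 * full_h))
    feature = np.zeros_like(lower, dtype=bool)
    rr, cc = ellipse(nose_row - spec.height, spec.nose_col, 8, 12, shape=lower.shape)
    lower[rr, cc] = spec.feature_level + 40
    feature[rr, cc] = True
    rr, cc = ellipse(mouth_row - spec.height, w // 2, 7, w // 5, shape=lower.shape)
    lower[rr, cc] = spec.feature_level
    feature[rr, cc] = True

    image = np.vstack(
        [upper.image, np.clip(np.round(lower), 0, 255).astype(np.uint8)]
    )
    box = FaceBox(0, 0, w, full_h)
    r0, r1 = spec.height + 1, full_h - 1
    c0, c1 = int(0.05 * w), int(0.95 * w)
    polygon = (
        np.array([r0, r0, r1, r1], dtype=float),
        np.array([c0, c1, c1, c0], dtype=float),
    )
    lower_feature_mask = np.zeros(image.shape, dtype=bool)
    lower_feature_mask[spec.height :] = feature
    return image, box, polygon, upper, lower_feature_mask


def write_fixture_set(
    out_dir,
    n_per_class: int,
    classes=CLASSES,
    base_spec: SyntheticFaceSpec | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Write PNG images + boundary masks and a CSV manifest (path,label,seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    faces = generate_dataset(n_per_class, tuple(classes), base_spec, rng_seed)
    rows = []
    for i, face in enumerate(faces):
        name = f"face_{i:04d}_{face.label}"
        img_path = out_dir / f"{name}.png"
        Image.fromarray(face.image).save(img_path)
        Image.fromarray((face.boundary_mask * 255).astype(np.uint8)).save(
            out_dir / f"{name}_boundary.png"
        )
        rows.append(
            {
                "path": img_path.name,
                "label": face.label,
                "seed": face.spec.rng_seed,
                "true_seed_x": face.true_seed[0],
                "true_seed_y": face.true_seed[1],
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
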