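"""End-to-end orchestration: image -> seed -> curve -> landmarks -> features
-> classifier, with reproducible seeding throughout."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from maskfer import boundary, classify, hogfeat, infinity, preprocess, seedpoint, synthfaces
from maskfer.config import PipelineConfig

logger = logging.getLogger(__name__)


def extract_image_features(image: np.ndarray, config: PipelineConfig | None = None):
    """Run the per-image pipeline on an upper-face crop.

    Returns (landmarks, features, seed): the detected boundary landmarks,
    their 74-value features, and the seed point used for placement.
    """
    cfg = config or PipelineConfig()
    gray = preprocess.to_grayscale(image)
    seed = seedpoint.find_seed(
        gray,
        window=cfg.seed.window,
        polyorder=cfg.seed.polyorder,
        smooth_vertical=cfg.seed.smooth_vertical,
    )
    curve = infinity.generate_infinity_points(cfg.infinity.curve())
    h, w = gray.shape
    rng_x, rng_y = infinity.ranges_for_image(curve, w, h, cfg.infinity.height_ratio)
    normalized = infinity.normalize_points(curve, rng_x, rng_y)
    placed = infinity.place_at_seed(normalized, seed.x, seed.y, w, h)
    landmarks = boundary.detect_landmarks(
        gray, placed, cfg.boundary.thresholds(), invert=cfg.boundary.invert
    )
    features = hogfeat.features_for_landmarks(gray, landmarks)
    return landmarks, features, seed


def features_to_frame(image_id: str, landmarks, features) -> pd.DataFrame:
    """One row per landmark: image_id, x, y, prominence, width, d1..d72."""
    rows = []
    for lm, ft in zip(landmarks, features):
        row = {
            "image_id": image_id,
            "x": lm.x,
            "y": lm.y,
            "source_index": lm.source_index,
            "prominence": lm.prominence,
            "width": lm.width,
        }
        row.update({f"d{k+1}": v for k, v in enumerate(ft.descriptor)})
        rows.append(row)
    cols = ["image_id", "x", "y", "source_index", "prominence", "width"] + [
        f"d{k+1}" for k in range(hogfeat.DESCRIPTOR_LEN)
    ]
    return pd.DataFrame(rows, columns=cols)


def run_extract(images, config: PipelineConfig | None = None, out_dir=None):
    """Feature extraction over many images.

    `images` is an iterable of (image_id, array-or-path).  Unreadable or
    failing images are logged and skipped; the return value is
    (tables, n_failed) where tables maps image_id -> feature DataFrame.
    """
    cfg = config or PipelineConfig()
    tables: dict[str, pd.DataFrame] = {}
    n_failed = 0
    for image_id, source in images:
        try:
            img = np.asarray(Image.open(source)) if isinstance(source, (str, Path)) else source
            landmarks, features, _ = extract_image_features(img, cfg)
            tables[image_id] = features_to_frame(image_id, landmarks, features)
        except Exception:  # noqa: BLE001 — partial failure is an expected mode
            logger.exception("feature extraction failed for image %s; skipping", image_id)
            n_failed += 1
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for image_id, table in tables.items():
            path = out_dir / f"{image_id}_features.csv"
            table.to_csv(path, index=False)
            manifest.append({"image_id": image_id, "path": path.name, "n_landmarks": len(table)})
        pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    return tables, n_failed


def sequences_from_faces(
    faces: list[synthfaces.SyntheticUpperFace],
    config: PipelineConfig,
) -> list[classify.FeatureSequence]:
    """Detect landmarks on each synthetic face and assemble labeled sequences."""
    seqs = []
    for k, face in enumerate(faces):
        landmarks, features, _ = extract_image_features(face.image, config)
        saliency = np.array([lm.prominence for lm in landmarks])
        seqs.append(
            classify.assemble_sequence(
                features,
                config.classify.max_landmarks,
                image_id=f"synth_{k:04d}",
                label=face.label,
                saliency=saliency if len(landmarks) else None,
            )
        )
    return seqs


def train_test_split_sequences(seqs, test_fraction: float, rng_seed: int):
    """Stratified shuffle split by label."""
    rng = np.random.default_rng(rng_seed)
    by_label: dict[str, list] = {}
    for s in seqs:
        by_label.setdefault(s.label, []).append(s)
    train, test = [], []
    for label in sorted(by_label):
        group = by_label[label]
        order = rng.permutation(len(group))
        n_test = max(1, int(round(test_fraction * len(group))))
        test.extend(group[i] for i in order[:n_test])
        train.extend(group[i] for i in order[n_test:])
    return train, test


def run_end_to_end(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """gen-fixtures -> extract -> train -> evaluate, all seeded.

    Returns a report with per-class metrics, the training history and the
    resolved configuration.
    """
    cfg = config or PipelineConfig()
    logger.info("pipeline config %s", cfg.config_hash())
    base = synthfaces.rafdb_spec() if cfg.fixtures.profile == "rafdb" else synthfaces.SyntheticFaceSpec()
    faces = synthfaces.generate_dataset(
        cfg.fixtures.n_per_class,
        cfg.classify.class_names,
        base_spec=base,
        rng_seed=cfg.rng_seed,
    )
    seqs = sequences_from_faces(faces, cfg)
    train_set, test_set = train_test_split_sequences(seqs, 0.25, cfg.rng_seed + 1)
    tc = classify.TrainConfig(
        class_names=tuple(cfg.classify.class_names),
        max_landmarks=cfg.classify.max_landmarks,
        hidden_size=cfg.classify.hidden_size,
        conv_channels=tuple(cfg.classify.conv_channels),
        epochs=cfg.classify.epochs,
        batch_size=cfg.classify.batch_size,
        learning_rate=cfg.classify.learning_rate,
        rng_seed=cfg.rng_seed,
    )
    model = classify.build_model(tc)
    history = classify.train(model, train_set, tc)
    metrics = classify.evaluate(model, test_set)
    report = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "n_parameters": model.n_params,
        "n_train": len(train_set),
        "n_test": len(test_set),
        "history": history,
        "metrics": metrics,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
        pd.DataFrame(
            metrics["confusion_matrix"],
            index=list(tc.class_names),
            columns=list(tc.class_names),
        ).to_csv(out_dir / "confusion_matrix.csv")
    return report
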