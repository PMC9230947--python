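"""Sequence classification of landmark features with a small CNN+LSTM.

Each image yields a variable-length, detection-ordered sequence of
74-value landmark features (x, y, 72 HOG values).  Sequences are padded
or truncated to a fixed number of landmark timesteps; a 1-D
convolutional extractor runs over the 74-value axis of every timestep,
the flattened per-timestep features feed an LSTM over the landmark
sequence, and a dense softmax head predicts the emotion.  The LSTM cell
is the standard formulation: the cell state updates as

    c_t = f_t * c_{t-1} + i_t * c~_t

with sigmoid forget/input/output gates and a tanh candidate.

The network is implemented directly in NumPy (forward and backward),
trained with Adam on categorical cross-entropy; training is
deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
)

from maskfer.hogfeat import FEATURE_LEN, LandmarkFeature

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# sequences


@dataclass
class FeatureSequence:
    image_id: str
    rows: np.ndarray  # (max_landmarks, FEATURE_LEN)
    mask: np.ndarray  # (max_landmarks,) bool — real vs padded rows
    label: str | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rows.ndim != 2 or self.rows.shape[1] != FEATURE_LEN:
            raise ValueError(f"rows must be (max_landmarks, {FEATURE_LEN})")
        if self.mask.shape != (self.rows.shape[0],):
            raise ValueError("mask length must match row count")

    @property
    def n_real(self) -> int:
        return int(self.mask.sum())


def assemble_sequence(
    features: list[LandmarkFeature],
    max_landmarks: int,
    image_id: str = "",
    label: str | None = None,
    saliency: np.ndarray | None = None,
) -> FeatureSequence:
    """Stack landmark features into a fixed-length padded sequence.

    When there are more landmarks than rows, the `saliency` scores (the
    detector's peak prominences) decide which to keep — the highest
    scores survive, in their original detection order.  Below
    max_landmarks, zero rows are appended and flagged off in the mask.
    An empty feature list yields an all-padding sequence (logged).
    """
    if not features:
        logger.warning("image %s produced no landmarks; emitting all-padding sequence", image_id)
        return FeatureSequence(
            image_id, np.zeros((max_landmarks, FEATURE_LEN)), np.zeros(max_landmarks, bool), label
        )
    keep = list(range(len(features)))
    if len(features) > max_landmarks:
        if saliency is not None:
            order = np.argsort(np.asarray(saliency))[::-1][:max_landmarks]
            keep = sorted(order.tolist())
        else:
            keep = keep[:max_landmarks]
    rows = np.zeros((max_landmarks, FEATURE_LEN))
    for r, idx in enumerate(keep):
        rows[r] = features[idx].flatten()
    mask = np.zeros(max_landmarks, bool)
    mask[: len(keep)] = True
    return FeatureSequence(image_id, rows, mask, label)


# --------------------------------------------------------------------------
# LSTM cell primitives


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cell_state_update(f: np.ndarray, c_prev: np.ndarray, i: np.ndarray, c_tilde: np.ndarray) -> np.ndarray:
    """The LSTM long-term memory update c_t = f ⊙ c_{t-1} + i ⊙ c~_t."""
    return f * c_prev + i * c_tilde


def lstm_cell_step(x, h_prev, c_prev, Wx, Wh, b):
    """One LSTM step. Gate order in the stacked weights: input, forget,
    candidate, output. Returns (h, c, cache-for-backprop)."""
    H = h_prev.shape[-1]
    z = x @ Wx + h_prev @ Wh + b
    i = sigmoid(z[..., :H])
    f = sigmoid(z[..., H : 2 * H])
    g = np.tanh(z[..., 2 * H : 3 * H])
    o = sigmoid(z[..., 3 * H :])
    c = cell_state_update(f, c_prev, i, g)
    tanh_c = np.tanh(c)
    h = o * tanh_c
    return h, c, (x, h_prev, c_prev, i, f, g, o, tanh_c)


# --------------------------------------------------------------------------
# model


@dataclass
class TrainConfig:
    class_names: tuple[str, ...]
    max_landmarks: int = 64
    hidden_size: int = 64
    conv_channels: tuple[int, int] = (32, 64)
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_names:
            raise ValueError("class_names must be non-empty")
        for name in ("max_landmarks", "hidden_size", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if len(self.conv_channels) != 2:
            raise ValueError("conv_channels must list two stages")


def _conv1d(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded kernel-3 1-D convolution. x: (N, C_in, L) -> (N, C_out, L)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1)))
    # stack the three shifted views: (N, C_in, 3, L)
    windows = np.stack([xp[:, :, k : k + x.shape[2]] for k in range(3)], axis=2)
    return np.einsum("nckl,ock->nol", windows, W, optimize=True) + b[None, :, None]


def _conv1d_backward(dout, x, W):
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1)))
    windows = np.stack([xp[:, :, k : k + x.shape[2]] for k in range(3)], axis=2)
    dW = np.einsum("nol,nckl->ock", dout, windows, optimize=True)
    db = dout.sum(axis=(0, 2))
    dxp_windows = np.einsum("nol,ock->nckl", dout, W, optimize=True)
    dxp = np.zeros_like(xp)
    for k in range(3):
        dxp[:, :, k : k + x.shape[2]] += dxp_windows[:, :, k, :]
    return dW, db, dxp[:, :, 1:-1]


def _maxpool2(x: np.ndarray):
    """Non-overlapping pool of 2 along the last axis (truncating odd tails)."""
    L = (x.shape[2] // 2) * 2
    xr = x[:, :, :L].reshape(x.shape[0], x.shape[1], L // 2, 2)
    arg = xr.argmax(axis=3)
    return xr.max(axis=3), (arg, x.shape[2])


def _maxpool2_backward(dout, cache):
    arg, L_in = cache
    N, C, Lp = dout.shape
    dx = np.zeros((N, C, L_in))
    n, c, l = np.meshgrid(np.arange(N), np.arange(C), np.arange(Lp), indexing="ij")
    dx[n, c, 2 * l + arg] = dout
    return dx


class SequenceClassifier:
    """CNN (per-landmark) + LSTM (over landmarks) + softmax head."""

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        C1, C2 = cfg.conv_channels
        H = cfg.hidden_size
        L_out = (FEATURE_LEN // 2) // 2  # after two pool-2 stages
        D = C2 * L_out  # LSTM input size
        n_cls = len(cfg.class_names)

        def init(*shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "W1": init(C1, 1, 3, fan_in=3),
            "b1": np.zeros(C1),
            "W2": init(C2, C1, 3, fan_in=3 * C1),
            "b2": np.zeros(C2),
            "Wx": init(D, 4 * H, fan_in=D),
            "Wh": init(H, 4 * H, fan_in=H),
            "b": np.zeros(4 * H),
            "Wo": init(H, n_cls, fan_in=H),
            "bo": np.zeros(n_cls),
        }
        # forget-gate bias 1: standard stabilization for short sequences
        self.params["b"][H : 2 * H] = 1.0
        self._lstm_in = D
        # feature standardization (fitted on training data in train())
        self.norm_mu = np.zeros(FEATURE_LEN)
        self.norm_sd = np.ones(FEATURE_LEN)
        self.n_params = int(sum(p.size for p in self.params.values()))
        logger.info("built CNN+LSTM classifier with %d parameters", self.n_params)

    def fit_normalizer(self, X: np.ndarray, mask: np.ndarray) -> None:
        """Feature-wise standardization statistics over real (unpadded) rows."""
        rows = X[mask]
        self.norm_mu = rows.mean(axis=0)
        self.norm_sd = np.maximum(rows.std(axis=0), 1e-6)

    def _normalize(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        Xn = (X - self.norm_mu) / self.norm_sd
        return Xn * mask[..., None]  # padded rows stay zero

    # ---------------- forward

    def _conv_forward(self, rows: np.ndarray):
        """rows: (N, FEATURE_LEN) -> per-timestep features (N, D) + cache."""
        p = self.params
        x0 = rows[:, None, :]  # (N, 1, 74)
        a1 = _conv1d(x0, p["W1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        p1, cache_p1 = _maxpool2(r1)
        a2 = _conv1d(p1, p["W2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        p2, cache_p2 = _maxpool2(r2)
        feats = p2.reshape(p2.shape[0], -1)
        return feats, (x0, a1, r1, p1, cache_p1, a2, r2, cache_p2, p2.shape)

    def forward(self, X: np.ndarray, mask: np.ndarray, return_cache: bool = False):
        """X: (B, T, FEATURE_LEN), mask: (B, T) -> class probabilities (B, n_cls)."""
        p = self.params
        B, T, F = X.shape
        H = self.cfg.hidden_size
        X = self._normalize(X, mask)
        feats, conv_cache = self._conv_forward(X.reshape(B * T, F))
        feats = feats.reshape(B, T, -1)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            h_new, c_new, cache = lstm_cell_step(feats[:, t], h, c, p["Wx"], p["Wh"], p["b"])
            m = mask[:, t, None].astype(float)
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
            steps.append((cache, m))
        logits = h @ p["Wo"] + p["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        probs = ez / ez.sum(axis=1, keepdims=True)
        if return_cache:
            return probs, (feats, conv_cache, steps, h)
        return probs

    # ---------------- backward

    def _backward(self, probs, y_onehot, X, mask, cache):
        p = self.params
        feats, conv_cache, steps, h_last = cache
        B, T, F = X.shape
        H = self.cfg.hidden_size
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = (probs - y_onehot) / B
        grads["Wo"] = h_last.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wo"].T
        dc = np.zeros_like(dh)
        dfeats = np.zeros_like(feats)
        for t in range(T - 1, -1, -1):
            (x_t, h_prev, c_prev, i, f, g, o, tanh_c), m = steps[t]
            dh_new = dh * m
            dc_new = dc * m
            do = dh_new * tanh_c
            dc_t = dc_new + dh_new * o * (1.0 - tanh_c**2)
            di = dc_t * g
            df = dc_t * c_prev
            dg = dc_t * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dfeats[:, t] = dz @ p["Wx"].T
            dh = dz @ p["Wh"].T + dh * (1 - m)
            dc = dc_t * f + dc * (1 - m)

        # conv backward over the flattened (B*T) axis
        x0, a1, r1, p1, cache_p1, a2, r2, cache_p2, p2_shape = conv_cache
        dp2 = dfeats.reshape(B * T, -1).reshape(p2_shape)
        dr2 = _maxpool2_backward(dp2, cache_p2)
        da2 = dr2 * (a2 > 0)
        dW2, db2, dp1 = _conv1d_backward(da2, p1, p["W2"])
        dr1 = _maxpool2_backward(dp1, cache_p1)
        da1 = dr1 * (a1 > 0)
        dW1, db1, _ = _conv1d_backward(da1, x0, p["W1"])
        grads["W1"], grads["b1"] = dW1, db1
        grads["W2"], grads["b2"] = dW2, db2
        return grads


def build_model(cfg: TrainConfig) -> SequenceClassifier:
    return SequenceClassifier(cfg)


# --------------------------------------------------------------------------
# training / inference


def _stack(dataset: list[FeatureSequence], class_names):
    X = np.stack([s.rows for s in dataset])
    mask = np.stack([s.mask for s in dataset])
    labels = [s.label for s in dataset]
    idx = {c: k for k, c in enumerate(class_names)}
    y = np.array([idx[l] for l in labels]) if all(l is not None for l in labels) else None
    return X, mask, y


def train(
    model: SequenceClassifier,
    dataset: list[FeatureSequence],
    cfg: TrainConfig | None = None,
) -> dict:
    """Adam / cross-entropy training; returns per-epoch loss and accuracy."""
    cfg = cfg or model.cfg
    X, mask, y = _stack(dataset, cfg.class_names)
    if y is None:
        raise ValueError("training requires labeled sequences")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes present")
    n_cls = len(cfg.class_names)
    onehot = np.eye(n_cls)[y]
    if mask.any():
        model.fit_normalizer(X, mask)
    rng = np.random.default_rng(cfg.rng_seed + 1)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = {"loss": [], "accuracy": []}
    n = len(dataset)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, mb, yb = X[sel], mask[sel], onehot[sel]
            probs, cache = model.forward(xb, mb, return_cache=True)
            loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
            losses.append(loss)
            correct += int((probs.argmax(1) == yb.argmax(1)).sum())
            grads = model._backward(probs, yb, xb, mb, cache)
            step += 1
            for k in model.params:
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * grads[k]
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * grads[k] ** 2
                mhat = m_state[k] / (1 - beta1**step)
                vhat = v_state[k] / (1 - beta2**step)
                model.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
    return history


def predict(model: SequenceClassifier, seq: FeatureSequence) -> tuple[np.ndarray, str]:
    """Per-class probabilities and the argmax label for one sequence."""
    probs = model.forward(seq.rows[None], seq.mask[None])[0]
    return probs, model.cfg.class_names[int(probs.argmax())]


def evaluate(model: SequenceClassifier, dataset: list[FeatureSequence]) -> dict:
    """Accuracy, per-class precision/recall/F1 and the confusion matrix
    (rows = true class, columns = predicted)."""
    if not dataset:
        raise ValueError("cannot evaluate on an empty dataset")
    X, mask, y = _stack(dataset, model.cfg.class_names)
    if y is None:
        raise ValueError("evaluation requires labeled sequences")
    probs = model.forward(X, mask)
    y_pred = probs.argmax(axis=1)
    labels = np.arange(len(model.cfg.class_names))
    prec, rec, f1, support = precision_recall_fscore_support(
        y, y_pred, labels=labels, zero_division=0
    )
    return {
        "accuracy": float(accuracy_score(y, y_pred)),
        "per_class": {
            name: {
                "precision": float(prec[k]),
                "recall": float(rec[k]),
                "f1": float(f1[k]),
                "support": int(support[k]),
            }
            for k, name in enumerate(model.cfg.class_names)
        },
        "confusion_matrix": _sk_confusion(y, y_pred, labels=labels).tolist(),
    }
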