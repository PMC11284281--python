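"""Binary tumor classifier: compact CNN, BCE loss, Adam, and Grad-CAM.

The default backbone, ``small_cnn``, is a compact convolutional network
trained end-to-end on the CPU: three 3x3 stride-2 convolution blocks
with ReLU, global average pooling, a 512-unit ReLU dense layer and a
single sigmoid output neuron.  A ``transfer_resnet50`` backbone name is
reserved for a frozen pretrained 50-layer residual backbone under the
same head; requesting it without pretrained weights on disk raises an
explicit error suggesting ``small_cnn``.

Forward, backward, the binary cross-entropy loss and the Adam optimizer
are all implemented here on NumPy arrays, which keeps every training
step inspectable and exactly reproducible from a seed.  Adam follows the
canonical bias-corrected form

    I <- g1*I + (1-g1)*g        R <- g2*R + (1-g2)*g^2
    p <- p - lr * (I/(1-g1^t)) / (sqrt(R/(1-g2^t)) + eps)

with an optional uncorrected variant (``literal_eq15``) that skips the
two bias-correction divisions, for side-by-side comparison.

``input_mode="hybrid"`` concatenates a per-image texture feature vector
(the six co-occurrence statistics) onto the pooled activation vector
before the dense head, so the classifier sees both learned spatial
features and the engineered texture summary.

Grad-CAM: the gradient of the pre-sigmoid score with respect to the last
convolutional feature maps is averaged spatially into per-channel
weights; the ReLU of the weighted sum of maps, upsampled bilinearly to
the input size and min-max normalized, is the saliency heatmap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .image_io import Image, UNIT, resize as _resize_image, PreprocessConfig
from .phantom import LabeledImage, TUMOR
from .texture import GLCMConfig, extract_features, features_to_row

__all__ = [
    "ModelConfig", "OptimizerState", "TrainedModel",
    "relu", "relu_grad", "sigmoid", "binary_cross_entropy",
    "adam_init", "adam_step",
    "build_classifier", "train", "predict", "predict_label", "gradcam",
    "stratified_split", "save_model", "load_model",
]

BCE_CLIP = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "small_cnn"
    dense_units: int = 512
    epochs: int = 30
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 32
    input_mode: str = "image"            # "image" or "hybrid"
    input_size: int = 224
    conv_channels: tuple[int, int, int] = (8, 16, 32)
    val_fraction: float = 0.3            # 70:30 train/validation split
    literal_eq15: bool = False           # Adam without bias correction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1/beta2 must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.backbone not in ("small_cnn", "transfer_resnet50"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.input_mode not in ("image", "hybrid"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")


# ---------------------------------------------------------------------------
# activations and loss
# ---------------------------------------------------------------------------

def relu(w):
    """Elementwise max(0, w)."""
    return np.maximum(0, w)


def relu_grad(w):
    """Derivative of ReLU: 1 where w > 0, else 0 (0 assigned at w = 0)."""
    return (np.asarray(w) > 0).astype(np.asarray(w).dtype)


def sigmoid(z):
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_cross_entropy(y_true, y_pred) -> float:
    """Mean negated log-likelihood  -[y ln k + (1-y) ln(1-k)].

    Predictions are clipped to [1e-7, 1 - 1e-7] so the loss stays finite
    at confident mistakes.
    """
    y = np.atleast_1d(np.asarray(y_true, dtype=np.float64))
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y_true labels must be in {0, 1}")
    k = np.clip(np.atleast_1d(np.asarray(y_pred, dtype=np.float64)),
                BCE_CLIP, 1.0 - BCE_CLIP)
    return float(-(y * np.log(k) + (1 - y) * np.log(1 - k)).mean())


# ---------------------------------------------------------------------------
# Adam optimizer
# ---------------------------------------------------------------------------

@dataclass
class OptimizerState:
    """Per-parameter first- and second-moment accumulators."""

    first_moment: dict[str, np.ndarray] = field(default_factory=dict)
    second_moment: dict[str, np.ndarray] = field(default_factory=dict)


def adam_init(params: dict[str, np.ndarray]) -> OptimizerState:
    return OptimizerState(
        {k: np.zeros_like(v) for k, v in params.items()},
        {k: np.zeros_like(v) for k, v in params.items()},
    )


def adam_step(params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
              state: OptimizerState, config: ModelConfig, t: int
              ) -> tuple[dict[str, np.ndarray], OptimizerState]:
    """One Adam update over a dict of named parameter arrays (t >= 1)."""
    if t < 1:
        raise ValueError("step count t must be >= 1")
    g1, g2, eps, lr = config.beta1, config.beta2, config.epsilon, config.learning_rate
    new_params = {}
    for name, p in params.items():
        g = grads[name]
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in parameter block {name!r}")
        I = state.first_moment[name]
        R = state.second_moment[name]
        I[...] = g1 * I + (1 - g1) * g
        R[...] = g2 * R + (1 - g2) * g * g
        if config.literal_eq15:
            i_hat, r_hat = I, R
        else:
            i_hat = I / (1 - g1 ** t)
            r_hat = R / (1 - g2 ** t)
        new_params[name] = p - lr * i_hat / (np.sqrt(r_hat) + eps)
    return new_params, state


# ---------------------------------------------------------------------------
# small CNN: parameters, forward, backward
# ---------------------------------------------------------------------------

def _conv_forward(x, W, b, stride=2, pad=1):
    """3x3 convolution via nine shifted-slice contractions.

    x: (N, Cin, H, W); W: (Cout, Cin, 3, 3); b: (Cout,).
    """
    n, cin, h, w = x.shape
    oh = (h + 2 * pad - 3) // stride + 1
    ow = (w + 2 * pad - 3) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((n, W.shape[0], oh, ow), dtype=x.dtype)
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, :, dy:dy + stride * oh:stride, dx:dx + stride * ow:stride]
            out += np.einsum("ncij,oc->noij", patch, W[:, :, dy, dx],
                             optimize=True)
    return out + b[None, :, None, None], xp


def _conv_backward(dout, xp, x_shape, W, stride=2, pad=1):
    n, cin, h, w = x_shape
    oh, ow = dout.shape[2], dout.shape[3]
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, :, dy:dy + stride * oh:stride, dx:dx + stride * ow:stride]
            dW[:, :, dy, dx] = np.einsum("noij,ncij->oc", dout, patch,
                                         optimize=True)
            dxp[:, :, dy:dy + stride * oh:stride, dx:dx + stride * ow:stride] += \
                np.einsum("noij,oc->ncij", dout, W[:, :, dy, dx], optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dx = dxp[:, :, pad:pad + h, pad:pad + w]
    return dx, dW, db


def _init_params(config: ModelConfig, n_features: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    c1, c2, c3 = config.conv_channels
    dt = np.float32

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dt)

    pooled = c3 + (n_features if config.input_mode == "hybrid" else 0)
    return {
        "conv1_w": he((c1, 1, 3, 3), 9), "conv1_b": np.zeros(c1, dt),
        "conv2_w": he((c2, c1, 3, 3), 9 * c1), "conv2_b": np.zeros(c2, dt),
        "conv3_w": he((c3, c2, 3, 3), 9 * c2), "conv3_b": np.zeros(c3, dt),
        "fc1_w": he((pooled, config.dense_units), pooled),
        "fc1_b": np.zeros(config.dense_units, dt),
        "fc2_w": he((config.dense_units, 1), config.dense_units),
        "fc2_b": np.zeros(1, dt),
    }


@dataclass
class TrainedModel:
    """Parameter store, per-epoch history, and the config that produced it."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    history: list[dict[str, float]] = field(default_factory=list)
    n_features: int = 0
    trainable: dict[str, bool] = field(default_factory=dict)


def build_classifier(config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Instantiate an untrained classifier per the config."""
    if config.backbone == "transfer_resnet50":
        raise RuntimeError(
            "transfer_resnet50 requires pretrained backbone weights, which "
            "are not available; use backbone='small_cnn' instead")
    n_features = 6 if config.input_mode == "hybrid" else 0
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, n_features, rng)
    return TrainedModel(params=params, config=config, history=[],
                        n_features=n_features,
                        trainable={k: True for k in params})


#: inputs arrive in [0, 1]; centering them at zero conditions the first
#: conv layer's gradients (the shift is part of the network definition)
INPUT_CENTER = 0.5


def _forward(model: TrainedModel, x: np.ndarray,
             feats: Optional[np.ndarray] = None, want_cache: bool = False):
    """Full forward pass; x is (N, 1, H, W) float32 in [0, 1]."""
    p = model.params
    x = x - np.asarray(INPUT_CENTER, dtype=x.dtype)
    z1, xp1 = _conv_forward(x, p["conv1_w"], p["conv1_b"])
    a1 = relu(z1)
    z2, xp2 = _conv_forward(a1, p["conv2_w"], p["conv2_b"])
    a2 = relu(z2)
    z3, xp3 = _conv_forward(a2, p["conv3_w"], p["conv3_b"])
    a3 = relu(z3)                               # last conv feature maps
    pooled = a3.mean(axis=(2, 3))               # global average pooling
    if model.config.input_mode == "hybrid":
        if feats is None:
            raise ValueError("hybrid model requires a texture feature vector")
        pooled = np.concatenate([pooled, feats.astype(pooled.dtype)], axis=1)
    z4 = pooled @ p["fc1_w"] + p["fc1_b"]
    a4 = relu(z4)
    logit = (a4 @ p["fc2_w"] + p["fc2_b"])[:, 0]
    prob = sigmoid(logit)
    if not want_cache:
        return prob, logit, a3
    cache = dict(x=x, xp1=xp1, z1=z1, a1=a1, xp2=xp2, z2=z2, a2=a2,
                 xp3=xp3, z3=z3, a3=a3, pooled=pooled, z4=z4, a4=a4,
                 logit=logit)
    return prob, logit, a3, cache


def _backward(model: TrainedModel, cache: dict, y: np.ndarray) -> dict:
    """Gradients of mean BCE w.r.t. every parameter (sigmoid folded in)."""
    p = model.params
    n = len(y)
    dt = p["fc1_w"].dtype
    prob = sigmoid(cache["logit"])
    dlogit = ((prob - y) / n).astype(dt)        # d(mean BCE)/d logit

    da4 = dlogit[:, None] @ p["fc2_w"].T
    dfc2_w = cache["a4"].T @ dlogit[:, None]
    dfc2_b = dlogit.sum(keepdims=True)
    dz4 = da4 * relu_grad(cache["z4"])
    dfc1_w = cache["pooled"].T @ dz4
    dfc1_b = dz4.sum(axis=0)
    dpooled = dz4 @ p["fc1_w"].T

    c3 = model.params["conv3_w"].shape[0]
    dpooled_conv = dpooled[:, :c3]              # hybrid features get no gradient
    oh, ow = cache["a3"].shape[2:]
    da3 = (dpooled_conv[:, :, None, None] / (oh * ow)) * np.ones_like(cache["a3"])
    dz3 = da3 * relu_grad(cache["z3"])
    da2, dconv3_w, dconv3_b = _conv_backward(dz3, cache["xp3"],
                                             cache["a2"].shape, p["conv3_w"])
    dz2 = da2 * relu_grad(cache["z2"])
    da1, dconv2_w, dconv2_b = _conv_backward(dz2, cache["xp2"],
                                             cache["a1"].shape, p["conv2_w"])
    dz1 = da1 * relu_grad(cache["z1"])
    _, dconv1_w, dconv1_b = _conv_backward(dz1, cache["xp1"],
                                           cache["x"].shape, p["conv1_w"])
    return {
        "conv1_w": dconv1_w, "conv1_b": dconv1_b,
        "conv2_w": dconv2_w, "conv2_b": dconv2_b,
        "conv3_w": dconv3_w, "conv3_b": dconv3_b,
        "fc1_w": dfc1_w, "fc1_b": dfc1_b,
        "fc2_w": dfc2_w, "fc2_b": dfc2_b,
    }


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def stratified_split(labels: np.ndarray, val_fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/validation index split."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = int(round(len(idx) * val_fraction))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def _prepare_inputs(model: TrainedModel, dataset: Sequence[LabeledImage],
                    glcm_config: GLCMConfig) -> tuple[np.ndarray, np.ndarray,
                                                      Optional[np.ndarray]]:
    size = model.config.input_size
    xs, ys, fs = [], [], []
    target = PreprocessConfig(target_height=size, target_width=size)
    for item in dataset:
        img = item.image
        if img.value_range != UNIT:
            raise ValueError("train expects unit-range images")
        if img.pixels.shape != (size, size):
            img = _resize_image(img, target)
        xs.append(img.pixels.astype(np.float32))
        ys.append(1.0 if item.label == TUMOR else 0.0)
        if model.config.input_mode == "hybrid":
            fs.append(features_to_row(extract_features(img, None, glcm_config)))
    x = np.stack(xs)[:, None, :, :]
    y = np.asarray(ys, dtype=np.float64)
    feats = np.asarray(fs, dtype=np.float32) if fs else None
    return x, y, feats


def _eval_pass(model: TrainedModel, x, y, feats, batch: int) -> tuple[float, float]:
    losses, correct = [], 0
    for s in range(0, len(y), batch):
        f = feats[s:s + batch] if feats is not None else None
        prob, _, _ = _forward(model, x[s:s + batch], f)
        losses.append(binary_cross_entropy(y[s:s + batch], prob) * len(prob))
        correct += int(((prob >= 0.5) == (y[s:s + batch] == 1)).sum())
    return sum(losses) / len(y), correct / len(y)


def train(model: TrainedModel, dataset: Sequence[LabeledImage],
          config: Optional[ModelConfig] = None,
          glcm_config: GLCMConfig = GLCMConfig()) -> TrainedModel:
    """Minibatch training with BCE loss and Adam; seeded and reproducible.

    The dataset is split stratified 70:30 into train and validation;
    per-epoch train/validation loss and accuracy are recorded in
    ``model.history``.
    """
    if config is not None and config != model.config:
        model = replace_config(model, config)
    cfg = model.config
    labels = np.asarray([it.label for it in dataset])
    if len(np.unique(labels)) < 2:
        raise ValueError("train requires both classes in the dataset")

    x, y, feats = _prepare_inputs(model, dataset, glcm_config)
    tr, va = stratified_split(y, cfg.val_fraction, cfg.seed)
    xt, yt = x[tr], y[tr]
    xv, yv = x[va], y[va]
    ft = feats[tr] if feats is not None else None
    fv = feats[va] if feats is not None else None

    state = adam_init(model.params)
    rng = np.random.default_rng(cfg.seed + 1)
    t = 0
    history = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(yt))
        ep_loss, ep_correct = 0.0, 0
        for s in range(0, len(yt), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            xb, yb = xt[idx], yt[idx]
            fb = ft[idx] if ft is not None else None
            prob, logit, _, cache = _forward(model, xb, fb, want_cache=True)
            grads = _backward(model, cache, yb)
            t += 1
            model.params, state = adam_step(model.params, grads, state, cfg, t)
            ep_loss += binary_cross_entropy(yb, prob) * len(yb)
            ep_correct += int(((prob >= 0.5) == (yb == 1)).sum())
        val_loss, val_acc = _eval_pass(model, xv, yv, fv, cfg.batch_size) \
            if len(yv) else (float("nan"), float("nan"))
        history.append({
            "epoch": _epoch + 1,
            "train_loss": ep_loss / len(yt),
            "train_acc": ep_correct / len(yt),
            "val_loss": val_loss,
            "val_acc": val_acc,
        })
    model.history = history
    return model


def replace_config(model: TrainedModel, config: ModelConfig) -> TrainedModel:
    fresh = build_classifier(config)
    return fresh


def predict(model: TrainedModel, image: Image,
            features: Optional[np.ndarray] = None) -> float:
    """Tumor probability in (0, 1) for one preprocessed image."""
    x = _as_batch(model, image)
    f = None
    if model.config.input_mode == "hybrid":
        if features is None:
            features = np.asarray(
                features_to_row(extract_features(image)), dtype=np.float32)
        f = np.asarray(features, dtype=np.float32)[None, :]
    prob, _, _ = _forward(model, x, f)
    return float(prob[0])


def predict_label(model: TrainedModel, image: Image,
                  features: Optional[np.ndarray] = None) -> int:
    """1 (tumor) when the probability is >= 0.5, else 0."""
    return int(predict(model, image, features) >= 0.5)


def _as_batch(model: TrainedModel, image: Image) -> np.ndarray:
    size = model.config.input_size
    if image.value_range != UNIT:
        raise ValueError("predict expects a unit-range image")
    if image.pixels.shape != (size, size):
        raise ValueError(
            f"image shape {image.pixels.shape} does not match the trained "
            f"input size ({size}, {size})")
    return image.pixels.astype(np.float32)[None, None, :, :]


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def gradcam(model: TrainedModel, image: Image,
            features: Optional[np.ndarray] = None) -> np.ndarray:
    """Saliency heatmap in [0, 1] at the input resolution.

    Channel weights are the spatial average of the pre-sigmoid score's
    gradient on the last conv feature maps; the heatmap is the ReLU of
    the weighted map sum, bilinearly upsampled and min-max normalized.
    An all-zero raw map is returned as all zeros.
    """
    x = _as_batch(model, image)
    f = None
    if model.config.input_mode == "hybrid":
        if features is None:
            features = np.asarray(
                features_to_row(extract_features(image)), dtype=np.float32)
        f = np.asarray(features, dtype=np.float32)[None, :]
    prob, logit, a3, cache = _forward(model, x, f, want_cache=True)
    p = model.params

    # gradient of the logit w.r.t. the pooled vector, back through the head
    da4 = p["fc2_w"].T                      # (1, dense)
    dz4 = da4 * relu_grad(cache["z4"])      # (1, dense)
    dpooled = dz4 @ p["fc1_w"].T            # (1, pooled)
    c3 = p["conv3_w"].shape[0]
    oh, ow = a3.shape[2:]
    # d logit / d a3 is spatially constant under global average pooling
    alpha = dpooled[0, :c3] / (oh * ow)     # per-channel weights

    raw = relu(np.einsum("c,cij->ij", alpha.astype(np.float64),
                         a3[0].astype(np.float64)))
    if raw.max() == 0:
        return np.zeros(image.pixels.shape)
    up = _sk_resize(raw, image.pixels.shape, order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    up = up - up.min()
    return up / up.max()


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file .npz checkpoint: parameters + config + history."""
    meta = json.dumps({"config": asdict(model.config),
                       "history": model.history,
                       "n_features": model.n_features})
    np.savez(Path(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.params)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_d = meta["config"]
    for key in ("conv_channels",):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = ModelConfig(**cfg_d)
    return TrainedModel(params=params, config=cfg, history=meta["history"],
                        n_features=meta["n_features"],
                        trainable={k: True for k in params})
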