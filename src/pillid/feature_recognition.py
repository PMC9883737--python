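"""Multitask classification of pill shape, color and form.

A shared backbone maps the composite reference image to a feature vector
``p_i`` of size ``h``; three linear heads with weight matrices of sizes
``h x 11`` (shape), ``h x 16`` (color) and ``h x 2`` (form) produce softmax
distributions ``z = softmax(w_k p_i)``.  The training loss is the weighted
sum of the three per-head cross-entropies (all weights 1 by default), and
rare classes can be oversampled with inverse-frequency weights.

The backbone here is a compact residual multilayer perceptron over a
mean-pooled image; the module interface accepts any backbone that produces
an ``h``-vector, so a deep convolutional network can be substituted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import _autograd as ag
from .synthetic_data import COLORS, FORMS, SHAPES

logger = logging.getLogger(__name__)

_HEADS = {"shape": SHAPES, "color": COLORS, "form": FORMS}
_POOL = 4  # mean-pool factor applied to the input image


@dataclass(frozen=True)
class FeaturePrediction:
    """Per-head probability vectors and their argmax labels."""

    shape_probs: np.ndarray
    color_probs: np.ndarray
    form_probs: np.ndarray
    shape_label: str
    color_label: str
    form_label: str

    def __post_init__(self):
        for probs, inventory in ((self.shape_probs, SHAPES),
                                 (self.color_probs, COLORS),
                                 (self.form_probs, FORMS)):
            if probs.shape != (len(inventory),):
                raise ValueError("probability vector has the wrong length")
            if (probs < 0).any() or abs(float(probs.sum()) - 1.0) > 1e-6:
                raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def labels(self) -> tuple[str, str, str]:
        return (self.shape_label, self.color_label, self.form_label)


@dataclass
class FeatureModelConfig:
    hidden_dim: int = 128
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    learning_rate: float = 0.02
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim < 8:
            raise ValueError("hidden_dim must be >= 8")
        if any(w <= 0 for w in self.loss_weights):
            raise ValueError("loss weights must be positive")


def multitask_loss(
    prediction: FeaturePrediction,
    truth: tuple[str, str, str],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """w_s*CE(shape) + w_c*CE(color) + w_f*CE(form) from probability vectors."""
    total = 0.0
    vectors = (prediction.shape_probs, prediction.color_probs,
               prediction.form_probs)
    for probs, label, inventory, w in zip(vectors, truth, _HEADS.values(), weights):
        if label not in inventory:
            raise ValueError(f"label {label!r} not in class inventory")
        p = float(probs[inventory.index(label)])
        total += w * -np.log(max(p, 1e-300))
    return total


def _preprocess(image: np.ndarray) -> np.ndarray:
    """Mean-pool by _POOL and center; flattens to the backbone input."""
    h, w, _ = image.shape
    x = image[:h - h % _POOL, :w - w % _POOL].astype(np.float32) / 255.0
    x = x.reshape(h // _POOL, _POOL, w // _POOL, _POOL, 3).mean(axis=(1, 3))
    return (x - 0.5).ravel()


class FeatureModel:
    """Residual MLP backbone with three linear softmax heads."""

    def __init__(self, config: FeatureModelConfig, input_dim: int,
                 image_shape: tuple[int, int], rng: np.random.Generator):
        self.config = config
        self.input_dim = input_dim
        self.image_shape = image_shape  # (height, width) expected at input
        h = config.hidden_dim
        self.W1 = ag.parameter(rng.normal(0, np.sqrt(2.0 / input_dim), (input_dim, h)))
        self.b1 = ag.parameter(np.zeros(h))
        self.W2 = ag.parameter(rng.normal(0, np.sqrt(2.0 / h), (h, h)))
        self.b2 = ag.parameter(np.zeros(h))
        self.heads = {
            name: ag.parameter(rng.normal(0, np.sqrt(1.0 / h), (h, len(inv))))
            for name, inv in _HEADS.items()
        }
        self.head_b = {name: ag.parameter(np.zeros(len(inv)))
                       for name, inv in _HEADS.items()}
        self.loss_history: list[float] = []

    @property
    def params(self) -> list[ag.Tensor]:
        return ([self.W1, self.b1, self.W2, self.b2]
                + list(self.heads.values()) + list(self.head_b.values()))

    def backbone(self, x: ag.Tensor) -> ag.Tensor:
        h1 = (x.matmul(self.W1) + self.b1).relu()
        return (h1.matmul(self.W2) + self.b2 + h1).relu()  # residual block

    def logits(self, x: np.ndarray) -> dict[str, ag.Tensor]:
        p = self.backbone(ag.tensor(x))
        return {name: p.matmul(self.heads[name]) + self.head_b[name]
                for name in _HEADS}

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {"W1": self.W1.data, "b1": self.b1.data,
                  "W2": self.W2.data, "b2": self.b2.data}
        for name in _HEADS:
            arrays[f"head_{name}"] = self.heads[name].data
            arrays[f"head_b_{name}"] = self.head_b[name].data
        np.savez(path, meta=json.dumps({
            "input_dim": self.input_dim, "image_shape": list(self.image_shape),
            "config": {**self.config.__dict__,
                       "loss_weights": list(self.config.loss_weights)}}),
            **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg = meta["config"]
        cfg["loss_weights"] = tuple(cfg["loss_weights"])
        model = cls(FeatureModelConfig(**cfg), meta["input_dim"],
                    tuple(meta["image_shape"]), np.random.default_rng(0))
        model.W1.data = data["W1"].astype(np.float32)
        model.b1.data = data["b1"].astype(np.float32)
        model.W2.data = data["W2"].astype(np.float32)
        model.b2.data = data["b2"].astype(np.float32)
        for name in _HEADS:
            model.heads[name].data = data[f"head_{name}"].astype(np.float32)
            model.head_b[name].data = data[f"head_b_{name}"].astype(np.float32)
        return model


def sampling_weights(labels: list[tuple[str, str, str]]) -> np.ndarray:
    """Inverse-frequency oversampling weights (product over the three heads),
    normalized to sum to 1.  Rare-class samples are drawn proportionally
    more often so every class's expected sampling frequency is equalized."""
    n = len(labels)
    weights = np.ones(n)
    for axis in range(3):
        values = [lab[axis] for lab in labels]
        counts: dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        freq = np.array([counts[v] / n for v in values])
        weights *= 1.0 / freq
    # cap the dynamic range: a sample rare in every head otherwise dominates
    # the epoch and starves the common classes
    weights /= weights.min()
    weights = np.minimum(weights, 100.0)
    return weights / weights.sum()


def train_features(
    images: list[np.ndarray],
    labels: list[tuple[str, str, str]],
    config: FeatureModelConfig,
    oversample: bool = False,
) -> FeatureModel:
    """Fit the multitask classifier with SGD (momentum 0.9, weight decay).

    With ``oversample=True`` each epoch draws samples with replacement using
    inverse-frequency weights.  Deterministic given config.seed.
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    for head_idx, (name, inventory) in enumerate(_HEADS.items()):
        present = {lab[head_idx] for lab in labels}
        missing = set(inventory) - present
        if missing:
            logger.warning("%s classes never observed in training: %s",
                           name, sorted(missing))

    rng = np.random.default_rng(config.seed)
    X = np.stack([_preprocess(img) for img in images])
    ys = {
        name: np.array([inv.index(lab[i]) for lab in labels])
        for i, (name, inv) in enumerate(_HEADS.items())
    }
    model = FeatureModel(config, X.shape[1], images[0].shape[:2], rng)
    opt = ag.SGD(model.params, lr=config.learning_rate, momentum=0.9,
                 weight_decay=config.weight_decay)
    n = len(images)
    probs = sampling_weights(labels) if oversample else None
    w = dict(zip(_HEADS, config.loss_weights))
    for _ in range(config.epochs):
        order = (rng.choice(n, size=n, p=probs) if oversample
                 else rng.permutation(n))
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.logits(X[idx])
            loss = ag.softmax_cross_entropy(logits["shape"], ys["shape"][idx]).scale(w["shape"])
            loss = loss + ag.softmax_cross_entropy(logits["color"], ys["color"][idx]).scale(w["color"])
            loss = loss + ag.softmax_cross_entropy(logits["form"], ys["form"][idx]).scale(w["form"])
            opt.zero_grad()
            loss.backward()
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite feature training loss")
            opt.step()
            total += float(loss.data) * len(idx)
        model.loss_history.append(total / n)
    return model


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    p = e / e.sum()
    # exact renormalization so the probability-vector invariant holds in
    # float64 regardless of the float32 compute above
    return (p / p.sum()).astype(np.float64)


def predict_features(model: FeatureModel, image: np.ndarray) -> FeaturePrediction:
    """Predict shape/color/form distributions for one composite image."""
    if image.shape[:2] != model.image_shape:
        logger.info("resizing image from %s to %s", image.shape[:2],
                    model.image_shape)
        zoom = (model.image_shape[0] / image.shape[0],
                model.image_shape[1] / image.shape[1], 1)
        image = ndimage.zoom(image, zoom, order=1)
    logits = model.logits(_preprocess(image)[None, :])
    p = {name: _softmax(logits[name].data[0]) for name in _HEADS}
    return FeaturePrediction(
        shape_probs=p["shape"], color_probs=p["color"], form_probs=p["form"],
        shape_label=SHAPES[int(p["shape"].argmax())],
        color_label=COLORS[int(p["color"].argmax())],
        form_label=FORMS[int(p["form"].argmax())],
    )
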