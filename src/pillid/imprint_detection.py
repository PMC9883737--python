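"""Character detection on pill faces.

Two responsibilities: (1) rotate a pill image so the pill's major axis is
horizontal, using the second moments of the foreground silhouette; (2) detect
imprinted characters and their 2D coordinates with a small single-shot grid
detector — the same family as YOLO (per grid cell: an objectness score, a
class distribution over the imprint vocabulary, and box offsets), trained
with SGD on annotated synthetic images.  The detector interface is
pluggable: any model exposing ``detect(image, conf_threshold)`` can stand in
for it in the pipeline.

The composite reference image holds the front face in the left half and the
back face in the right half; the detector runs per half and detections are
remapped to full-image coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import _autograd as ag
from ._vocab import TOKEN_INDEX, VOCAB_TOKENS
from .synthetic_data import BACKGROUND, CharBox

# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CharDetection:
    """One detected character with normalized center coordinates."""

    char: str
    x: float
    y: float
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise ValueError("detection coordinates must be in [0,1]")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0,1]")


@dataclass
class DetectorConfig:
    grid_size: int = 8
    conf_threshold: float = 0.5
    learning_rate: float = 1e-2
    warmup_epochs: int = 3
    batch_size: int = 16
    epochs: int = 30
    hidden_dim: int = 96
    nms_iou: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 4:
            raise ValueError("grid_size must be >= 4")
        if not 0.0 <= self.conf_threshold <= 1.0:
            raise ValueError("conf_threshold must be in [0,1]")


# --------------------------------------------------------------------------
# Orientation normalization
# --------------------------------------------------------------------------

_CIRCULAR_AXIS_RATIO_TOL = 0.05


def _foreground_mask(image: np.ndarray) -> np.ndarray:
    diff = np.abs(image.astype(np.int32) - np.array(BACKGROUND)).sum(axis=-1)
    return diff > 45


def normalize_orientation(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotate so the silhouette's principal axis is horizontal.

    Returns the rotated image and the rotation applied (degrees,
    counterclockwise in standard image display).  A near-circular silhouette
    (axis ratio within 5% of 1) is left untouched with rotation 0.
    """
    mask = _foreground_mask(image)
    if not mask.any():
        raise ValueError("no foreground silhouette found in image")
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = (x * x).mean()
    mu02 = (y * y).mean()
    mu11 = (x * y).mean()
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals = np.linalg.eigvalsh(cov)
    ratio = np.sqrt(max(evals[1], 1e-12) / max(evals[0], 1e-12))
    if abs(ratio - 1.0) < _CIRCULAR_AXIS_RATIO_TOL:
        return image, 0.0
    # angle of the major axis in screen coordinates (y down)
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    applied = float(np.rad2deg(theta))
    rotated = rotate_image(image, applied)
    return rotated, applied


def rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image center, filling with the background color."""
    if angle_deg == 0.0:
        return image
    return np.stack([
        ndimage.rotate(image[..., c], angle_deg, reshape=False, order=0,
                       mode="constant", cval=BACKGROUND[c])
        for c in range(image.shape[-1])
    ], axis=-1).astype(image.dtype)


# --------------------------------------------------------------------------
# Grid detector
# --------------------------------------------------------------------------

_N_CLASSES = len(VOCAB_TOKENS)


def _half_images(image: np.ndarray) -> list[np.ndarray]:
    s = image.shape[0]
    return [image[:, :s], image[:, s:2 * s]]


def _cell_patches(half: np.ndarray, grid: int) -> np.ndarray:
    """Per-cell normalized-contrast patches, shape (grid*grid, patch_dim).

    Each patch covers 2x2 cells centered on its cell; the feature is the
    absolute deviation from the patch median, which is invariant to ink
    polarity (dark-on-light vs light-on-dark imprints).
    """
    s = half.shape[0]
    cell = s // grid
    gray = (0.299 * half[..., 0] + 0.587 * half[..., 1]
            + 0.114 * half[..., 2]).astype(np.float32)
    pad = cell // 2
    padded = np.pad(gray, pad, mode="edge")
    patch = 2 * cell
    out = np.empty((grid * grid, patch * patch), dtype=np.float32)
    k = 0
    for i in range(grid):
        for j in range(grid):
            p = padded[i * cell:i * cell + patch, j * cell:j * cell + patch]
            dev = np.abs(p - np.median(p))
            out[k] = (dev / (dev.std() + 1e-3)).ravel()
            k += 1
    return out


class DetectorModel:
    """Shared two-layer perceptron applied per grid cell (a strided
    convolution in effect), predicting objectness, class and box geometry."""

    def __init__(self, config: DetectorConfig, image_size: int,
                 rng: np.random.Generator):
        self.config = config
        self.image_size = image_size
        cell = image_size // config.grid_size
        in_dim = (2 * cell) ** 2
        h = config.hidden_dim
        out_dim = 1 + _N_CLASSES + 4
        s1 = np.sqrt(2.0 / in_dim)
        s2 = np.sqrt(2.0 / h)
        self.W1 = ag.parameter(rng.normal(0, s1, (in_dim, h)))
        self.b1 = ag.parameter(np.zeros(h))
        self.W2 = ag.parameter(rng.normal(0, s2, (h, out_dim)))
        self.b2 = ag.parameter(np.zeros(out_dim))
        self.loss_history: list[float] = []

    @property
    def params(self) -> list[ag.Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, patches: np.ndarray) -> ag.Tensor:
        x = ag.tensor(patches)
        h = (x.matmul(self.W1) + self.b1).relu()
        return h.matmul(self.W2) + self.b2

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(path,
                 W1=self.W1.data, b1=self.b1.data,
                 W2=self.W2.data, b2=self.b2.data,
                 meta=json.dumps({"image_size": self.image_size,
                                  "config": self.config.__dict__}))

    @classmethod
    def load(cls, path: str | Path) -> "DetectorModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(DetectorConfig(**meta["config"]), meta["image_size"],
                    np.random.default_rng(0))
        for name in ("W1", "b1", "W2", "b2"):
            getattr(model, name).data = data[name].astype(np.float32)
        return model


def _targets_for_half(boxes: list[CharBox], face: str, grid: int):
    """Grid targets for one face half.  Box coordinates are normalized to
    the full composite image; the half spans x in [0,0.5) or [0.5,1)."""
    obj = np.zeros(grid * grid, dtype=np.float32)
    cls = np.zeros(grid * grid, dtype=np.int64)
    geo = np.zeros((grid * grid, 4), dtype=np.float32)
    offset = 0.0 if face == "front" else 0.5
    for b in boxes:
        if b.face != face:
            continue
        x = (b.x_center - offset) * 2.0  # half-local fraction
        y = b.y_center
        col = min(int(x * grid), grid - 1)
        row = min(int(y * grid), grid - 1)
        k = row * grid + col
        obj[k] = 1.0
        cls[k] = TOKEN_INDEX[b.char]
        geo[k] = (x * grid - col, y * grid - row, b.width * 2.0, b.height)
    return obj, cls, geo


def train_detector(
    images: list[np.ndarray],
    annotations: list[list[CharBox]],
    config: DetectorConfig,
) -> DetectorModel:
    """Fit the grid detector on annotated composite images.

    Loss per half-image: objectness binary cross-entropy over all cells,
    class cross-entropy and box regression (squared error on sigmoid
    outputs) over positive cells.  Deterministic given config.seed.
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(annotations):
        raise ValueError("images and annotations differ in length")
    grid = config.grid_size
    size = images[0].shape[0]
    rng = np.random.default_rng(config.seed)
    model = DetectorModel(config, size, rng)

    patches, objs, clss, geos = [], [], [], []
    for image, boxes in zip(images, annotations):
        for half, face in zip(_half_images(image), ("front", "back")):
            patches.append(_cell_patches(half, grid))
            o, c, g = _targets_for_half(boxes, face, grid)
            objs.append(o)
            clss.append(c)
            geos.append(g)
    patches = np.asarray(patches)
    objs = np.asarray(objs)
    clss = np.asarray(clss)
    geos = np.asarray(geos)

    n_halves = patches.shape[0]
    opt = ag.SGD(model.params, lr=config.learning_rate, momentum=0.9)
    v_slice = slice(1, 1 + _N_CLASSES)
    for epoch in range(config.epochs):
        # linear warm-up over the first warmup_epochs
        opt.lr = config.learning_rate * min(
            1.0, (epoch + 1) / max(config.warmup_epochs, 1))
        order = rng.permutation(n_halves)
        total = 0.0
        for start in range(0, n_halves, config.batch_size):
            idx = order[start:start + config.batch_size]
            X = patches[idx].reshape(-1, patches.shape[-1])
            obj_t = objs[idx].ravel()
            cls_t = clss[idx].ravel()
            geo_t = geos[idx].reshape(-1, 4)
            out = model.forward(X)
            obj_logits = out[:, 0]
            loss = ag.bce_with_logits(obj_logits, obj_t).scale(2.0)
            pos = obj_t > 0.5
            if pos.any():
                w = pos.astype(np.float32)
                loss = loss + ag.softmax_cross_entropy(out[:, v_slice], cls_t, w)
                geo_pred = out[:, 1 + _N_CLASSES:].sigmoid()
                diff = geo_pred - ag.tensor(geo_t)
                mask = ag.tensor((w / w.sum())[:, None])
                loss = loss + (diff * diff * mask).sum().scale(5.0)
            opt.zero_grad()
            loss.backward()
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite detector training loss")
            opt.step()
            total += float(loss.data) * len(idx)
        model.loss_history.append(total / n_halves)
    return model


def _iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    ix = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    iy = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = ix * iy
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def detect_characters(
    model: DetectorModel,
    image: np.ndarray,
    conf_threshold: float | None = None,
) -> list[CharDetection]:
    """Detect characters on a composite image.

    Returns detections with confidence >= conf_threshold, after greedy
    non-maximum suppression (IoU 0.45, ties by lower cell index), sorted by
    face (left half first), then y, then x.
    """
    if conf_threshold is None:
        conf_threshold = model.config.conf_threshold
    grid = model.config.grid_size
    results: list[tuple[float, float, float, CharDetection, tuple]] = []
    for half_idx, half in enumerate(_half_images(image)):
        out = model.forward(_cell_patches(half, grid)).data
        conf = 1.0 / (1.0 + np.exp(-out[:, 0]))
        cls = out[:, 1:1 + _N_CLASSES].argmax(axis=1)
        geo = 1.0 / (1.0 + np.exp(-out[:, 1 + _N_CLASSES:]))
        kept: list[tuple[int, float, tuple, str]] = []
        order = sorted(range(grid * grid), key=lambda k: (-conf[k], k))
        for k in order:
            if conf[k] < conf_threshold:
                continue
            row, col = divmod(k, grid)
            x = (col + geo[k, 0]) / grid
            y = (row + geo[k, 1]) / grid
            w, h = geo[k, 2], geo[k, 3]
            box = (x - w / 2, y - h / 2, x + w / 2, y + h / 2)
            if any(_iou(box, kb) > model.config.nms_iou for _, _, kb, _ in kept):
                continue
            kept.append((k, float(conf[k]), box, VOCAB_TOKENS[cls[k]]))
            det = CharDetection(
                char=VOCAB_TOKENS[cls[k]],
                x=float(np.clip(half_idx * 0.5 + x / 2, 0, 1)),
                y=float(np.clip(y, 0, 1)),
                confidence=float(conf[k]))
            results.append((half_idx, det.y, det.x, det, box))
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    return [r[3] for r in results]
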