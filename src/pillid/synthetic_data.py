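"""Synthetic pill databases, rendered reference images and detector noise.

Every downstream stage (character detection, feature classification, imprint
correction, retrieval) trains and evaluates on data from this module, so it
emulates the structure of real regulatory pill databases:

* one record per pill with shape (11 classes), color (16 classes), form
  (tablet/capsule) and a canonical imprint string whose "_" separates the
  front and back faces;
* one reference image per pill showing the front face on the left half and
  the back face on the right half, with exact per-character ground-truth
  boxes derived from the glyph metrics of the built-in bitmap font;
* detector-style corruptions of the ground truth (character confusions such
  as O<->0 and I<->1, coordinate jitter, drops, order scrambling) so the
  correction model can be trained in isolation from the detector.

Default class frequencies follow the marginals of the NLM pill database
(round 46.18%, oval 35.01%, oblong 15.46%; white 42.27%, yellow 12.68%, ...;
15% capsules).  All operations are pure functions of their arguments
including the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from scipy import ndimage

from ._font import GLYPH_H, GLYPH_W, token_bitmap
from ._vocab import SEPARATOR, TOKEN_INDEX, VOCAB_TOKENS, split_faces, tokenize

# --------------------------------------------------------------------------
# Class inventories
# --------------------------------------------------------------------------

# 11 shape classes: the 10 regulatory types plus "rectangle"; sampled
# rectangles are mapped to "square" at generation time, as done when
# fine-tuning on the NLM inventory, so the class stays in the head but is
# rare in the data.
SHAPES: tuple[str, ...] = (
    "round", "oblong", "oval", "triangle", "square", "diamond",
    "pentagon", "hexagon", "octagon", "rectangle", "others",
)
COLORS: tuple[str, ...] = (
    "white", "yellow", "orange", "pink", "red", "brown", "light green",
    "green", "cyan", "blue", "navy", "purple", "gray", "black", "violet",
    "transparent",
)
FORMS: tuple[str, ...] = ("tablet", "capsule")

_RGB: dict[str, tuple[int, int, int]] = {
    "white": (245, 245, 245), "yellow": (235, 214, 64), "orange": (235, 140, 52),
    "pink": (238, 162, 173), "red": (200, 48, 48), "brown": (139, 94, 60),
    "light green": (168, 224, 150), "green": (70, 160, 73), "cyan": (92, 200, 214),
    "blue": (66, 110, 200), "navy": (36, 48, 112), "purple": (128, 66, 160),
    "gray": (150, 150, 150), "black": (35, 35, 35), "violet": (186, 134, 216),
    "transparent": (225, 228, 230),
}
BACKGROUND = (204, 204, 204)


def _nlm_shape_freqs() -> dict[str, float]:
    major = {"round": 0.4618, "oval": 0.3501, "oblong": 0.1546}
    rest = [s for s in SHAPES if s not in major]
    residual = 1.0 - sum(major.values())
    table = dict(major)
    table.update({s: residual / len(rest) for s in rest})
    return table


def _nlm_color_freqs() -> dict[str, float]:
    major = {
        "white": 0.4227, "yellow": 0.1268, "pink": 0.0893, "orange": 0.0864,
        "blue": 0.0844, "brown": 0.0576, "green": 0.0553,
    }
    rest = [c for c in COLORS if c not in major]
    residual = 1.0 - sum(major.values())
    table = dict(major)
    table.update({c: residual / len(rest) for c in rest})
    return table


NLM_FREQUENCIES: dict[str, dict[str, float]] = {
    "shape": _nlm_shape_freqs(),
    "color": _nlm_color_freqs(),
    "form": {"tablet": 0.85, "capsule": 0.15},
}

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PillRecord:
    """One database entry: the retrieval target."""

    pill_id: str
    shape: str
    color: str
    form: str
    imprint: str

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.imprint.count(SEPARATOR) > 1:
            raise ValueError("imprint contains more than one '_' separator")
        # Database imprints are permissive (real databases contain symbols
        # outside the generation vocabulary); the generator itself only
        # emits vocabulary tokens.
        tokenize(self.imprint, strict=False)

    @property
    def features(self) -> tuple[str, str, str]:
        return (self.shape, self.color, self.form)


@dataclass(frozen=True)
class CharBox:
    """Ground-truth character box; coordinates are fractions of the full
    (front|back composite) image, origin top-left, y down-positive."""

    char: str
    x_center: float
    y_center: float
    width: float
    height: float
    face: str  # "front" | "back"

    def __post_init__(self):
        if not (0 <= self.x_center <= 1 and 0 <= self.y_center <= 1):
            raise ValueError("box center outside the unit square")
        if not (0 < self.width <= 1 and 0 < self.height <= 1):
            raise ValueError("box size outside (0,1]")
        if (self.x_center - self.width / 2 < -1e-9
                or self.x_center + self.width / 2 > 1 + 1e-9
                or self.y_center - self.height / 2 < -1e-9
                or self.y_center + self.height / 2 > 1 + 1e-9):
            raise ValueError("box extends outside the unit square")


DEFAULT_CONFUSION_PAIRS: tuple[tuple[str, str], ...] = (
    ("O", "0"), ("I", "1"), ("B", "8"), ("S", "5"), ("Z", "2"),
)


@dataclass(frozen=True)
class NoiseConfig:
    """Detector-noise model: confusions, drops, coordinate jitter, scrambling."""

    confusion_rate: float = 0.0
    confusion_pairs: tuple[tuple[str, str], ...] = DEFAULT_CONFUSION_PAIRS
    drop_rate: float = 0.0
    coord_jitter_sd: float = 0.0
    shuffle: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("confusion_rate", "drop_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.coord_jitter_sd < 0:
            raise ValueError("coord_jitter_sd must be non-negative")

    @property
    def confusion_map(self) -> dict[str, str]:
        m: dict[str, str] = {}
        for a, b in self.confusion_pairs:
            m[a] = b
            m[b] = a
        return m


class ImprintOverflowError(ValueError):
    """Raised when an imprint cannot be laid out inside the pill silhouette."""


# --------------------------------------------------------------------------
# Database generation
# --------------------------------------------------------------------------

_INVENTORIES = {"shape": SHAPES, "color": COLORS, "form": FORMS}


def _validate_frequencies(freqs: dict[str, dict[str, float]]) -> None:
    for feature, inventory in _INVENTORIES.items():
        table = freqs.get(feature)
        if table is None:
            raise ValueError(f"missing frequency table for feature '{feature}'")
        unknown = set(table) - set(inventory)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)} for feature '{feature}'")
        vals = np.array([table.get(c, 0.0) for c in inventory], dtype=float)
        if (vals < 0).any():
            raise ValueError(f"negative frequency for feature '{feature}'")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"frequencies for feature '{feature}' sum to {vals.sum()!r}, not 1")


def _sample_imprint(rng: np.random.Generator,
                    length_range: tuple[int, int]) -> str:
    lo, hi = length_range

    def face() -> str:
        n = int(rng.integers(lo, hi + 1))
        toks = []
        for _ in range(n):
            u = rng.random()
            if u < 0.06:
                toks.append("mg")
            elif u < 0.50:
                toks.append(str(rng.integers(0, 10)))
            else:
                toks.append(chr(ord("A") + int(rng.integers(0, 26))))
        return "".join(toks)

    return face() + SEPARATOR + face()


def generate_database(
    n: int,
    class_frequencies: dict[str, dict[str, float]] | None = None,
    imprint_length_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    min_feature_duplicate_fraction: float = 0.10,
) -> list[PillRecord]:
    """Sample `n` pill records with NLM-like class marginals.

    At least ``min_feature_duplicate_fraction`` of the records share their
    (shape, color, form) triple with another record while having a different
    imprint, so that retrieval cannot succeed on appearance features alone.
    Imprints are unique within the database.  Deterministic given `seed`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = class_frequencies if class_frequencies is not None else NLM_FREQUENCIES
    _validate_frequencies(freqs)
    rng = np.random.default_rng(seed)

    tables = {}
    for feature, inventory in _INVENTORIES.items():
        tables[feature] = np.array([freqs[feature].get(c, 0.0) for c in inventory])

    # Capsules are lozenge-shaped, so shape is sampled conditionally on form
    # (capsule -> oval/oblong only) with the tablet-conditional adjusted so
    # the configured shape *marginals* are preserved.
    p_shape, p_form = tables["shape"], tables["form"]
    p_capsule = p_form[FORMS.index("capsule")]
    caps_idx = [SHAPES.index("oval"), SHAPES.index("oblong")]
    caps_mass = sum(p_shape[i] for i in caps_idx)
    p_caps_shape = np.zeros(len(SHAPES))
    if caps_mass > 0:
        for i in caps_idx:
            p_caps_shape[i] = p_shape[i] / caps_mass
    else:
        for i in caps_idx:
            p_caps_shape[i] = 0.5
    p_tablet_mass = 1.0 - p_capsule
    if p_tablet_mass > 0:
        p_tab_shape = np.clip(p_shape - p_capsule * p_caps_shape, 0.0, None)
        p_tab_shape /= p_tab_shape.sum()
    else:
        p_tab_shape = p_caps_shape

    colors = rng.choice(len(COLORS), size=n, p=tables["color"])
    forms = rng.choice(len(FORMS), size=n, p=p_form)

    feats: list[tuple[str, str, str]] = []
    for i in range(n):
        form = FORMS[forms[i]]
        p = p_caps_shape if form == "capsule" else p_tab_shape
        shape = SHAPES[rng.choice(len(SHAPES), p=p)]
        if shape == "rectangle":  # regulatory fine-tuning convention
            shape = "square"
        feats.append((shape, COLORS[colors[i]], form))

    # Force a floor on feature-duplicate pills (same features, different
    # imprint): white round tablets and their kin are the hard case.
    counts: dict[tuple[str, str, str], int] = {}
    for f in feats:
        counts[f] = counts.get(f, 0) + 1
    dup_frac = sum(c for c in counts.values() if c > 1) / n
    if n > 1 and dup_frac < min_feature_duplicate_fraction:
        need = int(np.ceil(min_feature_duplicate_fraction * n))
        idx = rng.permutation(n)
        forced, j = 0, 0
        while forced < need and j + 1 < n:
            feats[idx[j]] = feats[idx[j + 1]]
            forced += 2
            j += 2

    seen: set[str] = set()
    records: list[PillRecord] = []
    mask_cache: dict[str, np.ndarray] = {}
    fit_rng = np.random.default_rng(seed + 1)
    for i in range(n):
        shape, color, form = feats[i]
        for _ in range(200):
            imprint = _sample_imprint(rng, imprint_length_range)
            if imprint not in seen and _imprint_fits(imprint, shape,
                                                     mask_cache, fit_rng):
                break
        else:  # pragma: no cover - would need astronomically many rejections
            raise RuntimeError("could not sample a unique, renderable imprint")
        seen.add(imprint)
        records.append(PillRecord(
            pill_id=f"P{i:05d}", shape=shape, color=color, form=form,
            imprint=imprint))
    return records


_FIT_CHECK_SIZE = 96


def _imprint_fits(imprint: str, shape: str, mask_cache: dict[str, np.ndarray],
                  rng: np.random.Generator) -> bool:
    """True if both faces lay out inside the silhouette at reference size.

    Fitting is a precondition of render_pill, so the generator only emits
    imprints that render.
    """
    if shape not in mask_cache:
        mask_cache[shape] = _silhouette(shape, _FIT_CHECK_SIZE)
    mask = mask_cache[shape]
    scale = max(1, _FIT_CHECK_SIZE // 48)
    try:
        for tokens in split_faces(imprint):
            _layout_face(tokens, mask, scale, rng)
    except ImprintOverflowError:
        return False
    return True


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def _silhouette(shape: str, size: int) -> np.ndarray:
    """Boolean mask of the pill silhouette on a size x size face canvas."""
    img = Image.new("L", (size, size), 0)
    draw = ImageDraw.Draw(img)
    c = size / 2.0
    r = 0.46 * size

    def polygon(k: int, phase: float) -> None:
        pts = [(c + r * np.cos(2 * np.pi * i / k + phase),
                c + r * np.sin(2 * np.pi * i / k + phase)) for i in range(k)]
        draw.polygon(pts, fill=255)

    if shape == "round":
        draw.ellipse([c - r, c - r, c + r, c + r], fill=255)
    elif shape == "oval":
        draw.ellipse([c - 0.48 * size, c - 0.32 * size,
                      c + 0.48 * size, c + 0.32 * size], fill=255)
    elif shape == "oblong":
        ry = 0.26 * size
        draw.rounded_rectangle([c - 0.48 * size, c - ry, c + 0.48 * size, c + ry],
                               radius=ry, fill=255)
    elif shape == "triangle":
        polygon(3, -np.pi / 2)
    elif shape == "square":
        half = 0.40 * size
        draw.rectangle([c - half, c - half, c + half, c + half], fill=255)
    elif shape == "rectangle":
        draw.rectangle([c - 0.48 * size, c - 0.30 * size,
                        c + 0.48 * size, c + 0.30 * size], fill=255)
    elif shape == "diamond":
        polygon(4, -np.pi / 2)
    elif shape == "pentagon":
        polygon(5, -np.pi / 2)
    elif shape == "hexagon":
        polygon(6, 0.0)
    elif shape == "octagon":
        polygon(8, np.pi / 8)
    elif shape == "others":  # semicircle, flat side down
        draw.pieslice([c - r, c - r + 0.18 * size, c + r, c + r + 0.72 * size],
                      180, 360, fill=255)
    else:  # pragma: no cover
        raise ValueError(f"unknown shape {shape!r}")
    return np.asarray(img) > 127


def _row_extent(mask: np.ndarray, y_top: int, y_bot: int) -> tuple[int, int]:
    """Columns whose full [y_top, y_bot) band lies inside the mask."""
    band = mask[max(y_top, 0):min(y_bot, mask.shape[0])]
    if band.size == 0:
        return (0, 0)
    inside = band.all(axis=0)
    cols = np.flatnonzero(inside)
    if cols.size == 0:
        return (0, 0)
    return int(cols[0]), int(cols[-1]) + 1


def _layout_face(tokens: list[str], mask: np.ndarray, scale: int,
                 rng: np.random.Generator) -> list[tuple[str, int, int, int, int]]:
    """Place tokens in centered rows inside the silhouette.

    Returns (token, x_left, y_top, w, h) in face-pixel units.  Raises
    ImprintOverflowError when no row arrangement fits.
    """
    if not tokens:
        return []
    size = mask.shape[0]
    gh = GLYPH_H * scale
    gap = 3 * scale
    pitch_y = gh + 5 * scale
    widths = [token_bitmap(t).shape[1] * scale for t in tokens]

    for n_rows in range(int(np.ceil(len(tokens) / 4)), 5):
        per_row = int(np.ceil(len(tokens) / n_rows))
        rows = [list(range(i, min(i + per_row, len(tokens))))
                for i in range(0, len(tokens), per_row)]
        y_centers = [size / 2 + (r - (len(rows) - 1) / 2) * pitch_y
                     for r in range(len(rows))]
        placement: list[tuple[str, int, int, int, int]] = []
        ok = True
        for row, y_c in zip(rows, y_centers):
            y_top = int(round(y_c - gh / 2))
            x_lo, x_hi = _row_extent(mask, y_top - 1, y_top + gh + 1)
            need = sum(widths[i] for i in row) + gap * (len(row) - 1)
            avail = x_hi - x_lo
            if need > avail or y_top < 0 or y_top + gh > size:
                ok = False
                break
            x = x_lo + (avail - need) // 2
            for i in row:
                jitter = int(rng.integers(-1, 2))
                y_pos = int(np.clip(y_top + jitter, 0, size - gh))
                placement.append((tokens[i], x, y_pos, widths[i], gh))
                x += widths[i] + gap
        if ok:
            return placement
    raise ImprintOverflowError(
        f"imprint {''.join(tokens)!r} does not fit inside the pill silhouette")


def _render_face(tokens: list[str], record: PillRecord, size: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, list[tuple[str, float, float, float, float]]]:
    """Render one face; boxes returned as (char, cx, cy, w, h) face fractions."""
    mask = _silhouette(record.shape, size)
    canvas = np.empty((size, size, 3), dtype=np.uint8)
    canvas[:] = BACKGROUND
    base = np.array(_RGB[record.color], dtype=np.uint8)
    canvas[mask] = base
    if record.form == "capsule":
        # two-tone lozenge; the record's color is the dominant (left) part
        others = [c for c in COLORS if c != record.color]
        second = np.array(_RGB[others[int(rng.integers(len(others)))]],
                          dtype=np.uint8)
        split = int(0.62 * size)
        right = mask.copy()
        right[:, :split] = False
        canvas[right] = second
    lum = 0.299 * base[0] + 0.587 * base[1] + 0.114 * base[2]
    ink = np.array((40, 40, 40) if lum > 135 else (248, 248, 248), dtype=np.uint8)

    scale = max(1, size // 48)
    boxes: list[tuple[str, float, float, float, float]] = []
    for token, x, y, w, h in _layout_face(tokens, mask, scale, rng):
        bmp = np.kron(token_bitmap(token), np.ones((scale, scale), dtype=bool))
        region = canvas[y:y + h, x:x + w]
        region[bmp] = ink
        boxes.append((token, (x + w / 2) / size, (y + h / 2) / size,
                      w / size, h / size))
    return canvas, boxes


def _rotate_face(canvas: np.ndarray, boxes, angle_deg: float, size: int):
    """Rotate a face canvas and its boxes about the face center."""
    if angle_deg == 0.0:
        return canvas, boxes
    rotated = np.stack([
        ndimage.rotate(canvas[..., ch], angle_deg, reshape=False, order=0,
                       mode="constant", cval=BACKGROUND[ch])
        for ch in range(3)
    ], axis=-1).astype(np.uint8)
    # image rotation by +angle moves content counterclockwise in screen
    # coordinates (y down); transform the box centers accordingly
    th = np.deg2rad(angle_deg)
    cos, sin = np.cos(th), np.sin(th)
    out = []
    for char, cx, cy, w, h in boxes:
        dx, dy = cx - 0.5, cy - 0.5
        nx = 0.5 + cos * dx + sin * dy
        ny = 0.5 - sin * dx + cos * dy
        nw = abs(cos) * w + abs(sin) * h
        nh = abs(sin) * w + abs(cos) * h
        out.append((char, float(nx), float(ny), float(nw), float(nh)))
    return rotated, out


def render_pill(
    record: PillRecord,
    image_size: int = 96,
    rotation_deg: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[CharBox]]:
    """Render the reference image: front face left, back face right.

    Returns an (image_size, 2*image_size, 3) uint8 RGB array and one CharBox
    per imprint token, normalized to the full composite image.  Raises
    :class:`ImprintOverflowError` if the imprint cannot fit.
    """
    if image_size < 64:
        raise ValueError("image_size must be >= 64")
    rng = np.random.default_rng(seed)
    front, back = split_faces(record.imprint)
    halves = []
    all_boxes: list[CharBox] = []
    for face_name, tokens, offset in (("front", front, 0.0), ("back", back, 0.5)):
        canvas, boxes = _render_face(tokens, record, image_size, rng)
        canvas, boxes = _rotate_face(canvas, boxes, rotation_deg, image_size)
        halves.append(canvas)
        for char, cx, cy, w, h in boxes:
            all_boxes.append(CharBox(
                char=char, x_center=offset + cx / 2, y_center=cy,
                width=w / 2, height=h, face=face_name))
    image = np.hstack(halves)
    return image, all_boxes


# --------------------------------------------------------------------------
# Detector-noise corruption
# --------------------------------------------------------------------------


def corrupt_detections(boxes: list[CharBox], noise: NoiseConfig):
    """Simulate detector output from ground truth: drops, confusions,
    coordinate jitter and order scrambling.  Deterministic given noise.seed.

    Returns a list of :class:`pillid.imprint_detection.CharDetection`.
    """
    from .imprint_detection import CharDetection  # local: avoids module cycle

    rng = np.random.default_rng(noise.seed)
    cmap = noise.confusion_map
    out = []
    for box in boxes:
        u_drop = rng.random()
        u_conf = rng.random()
        jx, jy = rng.normal(0.0, 1.0, size=2)
        confidence = float(rng.uniform(0.5, 1.0))
        if u_drop < noise.drop_rate:
            continue
        char = box.char
        if char in cmap and u_conf < noise.confusion_rate:
            char = cmap[char]
        x = float(np.clip(box.x_center + jx * noise.coord_jitter_sd, 0.0, 1.0))
        y = float(np.clip(box.y_center + jy * noise.coord_jitter_sd, 0.0, 1.0))
        out.append(CharDetection(char=char, x=x, y=y, confidence=confidence))
    if noise.shuffle and out:
        order = rng.permutation(len(out))
        out = [out[i] for i in order]
    return out


# --------------------------------------------------------------------------
# File I/O (CSV database, PNG images, JSON annotations)
# --------------------------------------------------------------------------


def save_database(records: list[PillRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def load_database(path: str | Path) -> list[PillRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [PillRecord(**row) for row in df.to_dict(orient="records")]


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image).save(path, format="PNG")


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_annotations(boxes: list[CharBox], path: str | Path) -> None:
    Path(path).write_text(json.dumps([dataclasses.asdict(b) for b in boxes]))


def load_annotations(path: str | Path) -> list[CharBox]:
    return [CharBox(**d) for d in json.loads(Path(path).read_text())]
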