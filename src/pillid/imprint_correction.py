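"""Character-level imprint correction with coordinate encoding.

The character detector emits an unordered, confusion-prone bag of characters
with 2D coordinates.  This module turns that bag into the canonical imprint
string (front face, "_", back face) with an attention-based bidirectional
sequence-to-sequence model:

* each detected character is encoded as one-hot(char) concatenated with its
  normalized (x, y) center — the coordinate encoding;
* a bidirectional GRU encoder reads the (face, y, x)-sorted detections;
* a GRU decoder with additive attention emits one target token per step,
  trained by teacher forcing to maximize the per-position conditional
  likelihood of the canonical imprint given the noisy source;
* optionally the pill's predicted (shape, color, form) labels are embedded
  and added to the recurrent initial states, letting appearance features act
  as context for the imprint.

Decoding is greedy.  "_" is an ordinary vocabulary token during training and
decoding; outputs with more than one "_" keep only the first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _autograd as ag
from ._vocab import SEPARATOR, TOKEN_INDEX, VOCAB_TOKENS, tokenize
from .imprint_detection import CharDetection
from .synthetic_data import COLORS, FORMS, SHAPES

# --------------------------------------------------------------------------
# Vocabulary and encoding
# --------------------------------------------------------------------------

_INPUT_DIM = len(VOCAB_TOKENS) + 2  # one-hot + (x, y)

# decoder vocabulary: specials, imprint tokens, and the face separator
PAD, BOS, EOS = 0, 1, 2
_TGT_TOKENS: tuple[str, ...] = ("<pad>", "<bos>", "<eos>") + VOCAB_TOKENS + (SEPARATOR,)
_TGT_INDEX = {t: i for i, t in enumerate(_TGT_TOKENS)}


@dataclass(frozen=True)
class EncodedChar:
    """one-hot(char) ++ (x, y); dimension |V| + 2."""

    vector: np.ndarray

    def __post_init__(self):
        if self.vector.shape != (_INPUT_DIM,):
            raise ValueError("encoded character has the wrong dimension")


def encode_sequence(detections: Sequence[CharDetection]) -> list[EncodedChar]:
    """Coordinate-encode detections, order preserved."""
    out = []
    for det in detections:
        if det.char not in TOKEN_INDEX:
            raise ValueError(f"character {det.char!r} is not in the vocabulary")
        v = np.zeros(_INPUT_DIM, dtype=np.float32)
        v[TOKEN_INDEX[det.char]] = 1.0
        v[-2] = det.x
        v[-1] = det.y
        out.append(EncodedChar(vector=v))
    return out


def sort_detections(detections: Sequence[CharDetection]) -> list[CharDetection]:
    """Reading-order convention: face (left half first), row band, then x.

    y is quantized to 1/8 bands so small vertical jitter cannot scramble a
    text row; robustness to genuinely wrong order is the model's job.
    """
    return sorted(detections,
                  key=lambda d: (d.x >= 0.5, int(d.y * 8 + 0.5), d.x))


@dataclass(frozen=True)
class CorrectionPair:
    """Noisy source detections and the canonical target imprint."""

    source: tuple[CharDetection, ...]
    target: str

    def __post_init__(self):
        if self.target.count(SEPARATOR) > 1:
            raise ValueError("target contains more than one '_' separator")


@dataclass
class CorrectorConfig:
    embedding_size: int = 45
    hidden_size: int = 256
    context_mode: str = "none"  # "none" | "features"
    learning_rate: float = 1e-3
    batch_size: int = 50
    epochs: int = 30
    max_target_len: int = 24
    seed: int = 0

    def __post_init__(self):
        if self.embedding_size < 1 or self.hidden_size < 1:
            raise ValueError("embedding_size and hidden_size must be positive")
        if self.context_mode not in ("none", "features"):
            raise ValueError("context_mode must be 'none' or 'features'")


def _target_ids(text: str, max_len: int) -> list[int]:
    toks = tokenize(text, strict=False)
    if len(toks) > max_len:
        raise ValueError(
            f"target imprint {text!r} longer than max_target_len={max_len}")
    return [_TGT_INDEX[t] for t in toks]


def _feature_ids(features: tuple[str, str, str]) -> tuple[int, int, int]:
    return (SHAPES.index(features[0]), COLORS.index(features[1]),
            FORMS.index(features[2]))


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------


class _GRUCell:
    """Gated recurrent unit; parameters owned by the cell."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        s = np.sqrt(1.0 / hidden)
        si = np.sqrt(1.0 / in_dim)
        self.Wx = ag.parameter(rng.uniform(-si, si, (in_dim, 3 * hidden)))
        self.Wh = ag.parameter(rng.uniform(-s, s, (hidden, 3 * hidden)))
        self.b = ag.parameter(np.zeros(3 * hidden))
        self.hidden = hidden

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def __call__(self, x: ag.Tensor, h: ag.Tensor) -> ag.Tensor:
        H = self.hidden
        gx = x.matmul(self.Wx) + self.b
        gh = h.matmul(self.Wh)
        z = (gx[:, 0:H] + gh[:, 0:H]).sigmoid()
        r = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
        n = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
        one = ag.tensor(np.ones_like(z.data))
        return (one - z) * n + z * h


class CorrectorModel:
    """Bidirectional GRU encoder, additive-attention GRU decoder."""

    def __init__(self, config: CorrectorConfig, rng: np.random.Generator):
        self.config = config
        E, H = config.embedding_size, config.hidden_size
        si = np.sqrt(1.0 / _INPUT_DIM)
        self.W_in = ag.parameter(rng.uniform(-si, si, (_INPUT_DIM, E)))
        self.enc_fwd = _GRUCell(E, H, rng)
        self.enc_bwd = _GRUCell(E, H, rng)
        self.emb_tgt = ag.parameter(rng.normal(0, 0.1, (len(_TGT_TOKENS), E)))
        self.dec = _GRUCell(E + 2 * H, H, rng)
        sb = np.sqrt(1.0 / (2 * H))
        self.W_bridge = ag.parameter(rng.uniform(-sb, sb, (2 * H, H)))
        self.b_bridge = ag.parameter(np.zeros(H))
        # additive attention
        self.W_att_e = ag.parameter(rng.uniform(-sb, sb, (2 * H, H)))
        self.W_att_d = ag.parameter(rng.uniform(-np.sqrt(1 / H), np.sqrt(1 / H), (H, H)))
        self.b_att = ag.parameter(np.zeros(H))
        self.v_att = ag.parameter(rng.uniform(-np.sqrt(1 / H), np.sqrt(1 / H), (H, 1)))
        so = np.sqrt(1.0 / (3 * H))
        self.W_out = ag.parameter(rng.uniform(-so, so, (3 * H, len(_TGT_TOKENS))))
        self.b_out = ag.parameter(np.zeros(len(_TGT_TOKENS)))
        # feature-context embeddings (used when context_mode == "features")
        self.emb_shape = ag.parameter(rng.normal(0, 0.1, (len(SHAPES), H)))
        self.emb_color = ag.parameter(rng.normal(0, 0.1, (len(COLORS), H)))
        self.emb_form = ag.parameter(rng.normal(0, 0.1, (len(FORMS), H)))
        self.loss_history: list[float] = []

    @property
    def params(self) -> list[ag.Tensor]:
        ps = [self.W_in, self.emb_tgt, self.W_bridge, self.b_bridge,
              self.W_att_e, self.W_att_d, self.b_att, self.v_att,
              self.W_out, self.b_out,
              self.emb_shape, self.emb_color, self.emb_form]
        for cell in (self.enc_fwd, self.enc_bwd, self.dec):
            ps.extend(cell.params)
        return ps

    # -- forward pieces ----------------------------------------------------

    def _context_state(self, feat_ids: np.ndarray | None, batch: int) -> ag.Tensor | None:
        if self.config.context_mode != "features" or feat_ids is None:
            return None
        s = ag.embedding(self.emb_shape, feat_ids[:, 0])
        c = ag.embedding(self.emb_color, feat_ids[:, 1])
        f = ag.embedding(self.emb_form, feat_ids[:, 2])
        return (s + c + f).tanh()

    def _encode(self, src: np.ndarray, src_mask: np.ndarray,
                ctx: ag.Tensor | None):
        """src: (B, T, in_dim); returns (T bidirectional states (B, 2H),
        summary (B, 2H) = [forward final; backward first])."""
        B, T, _ = src.shape
        H = self.config.hidden_size
        zeros = np.zeros((B, H), dtype=np.float32)
        h_f = ctx if ctx is not None else ag.tensor(zeros)
        h_b = ctx if ctx is not None else ag.tensor(zeros)
        xs = [ag.tensor(src[:, t]).matmul(self.W_in).tanh() for t in range(T)]
        fwd, bwd = [], [None] * T
        for t in range(T):
            h_new = self.enc_fwd(xs[t], h_f)
            m = ag.tensor(src_mask[:, t:t + 1])
            h_f = m * h_new + (ag.tensor(1.0 - src_mask[:, t:t + 1])) * h_f
            fwd.append(h_f)
        for t in reversed(range(T)):
            h_new = self.enc_bwd(xs[t], h_b)
            m = ag.tensor(src_mask[:, t:t + 1])
            h_b = m * h_new + (ag.tensor(1.0 - src_mask[:, t:t + 1])) * h_b
            bwd[t] = h_b
        states = [ag.concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
        summary = ag.concat([fwd[-1], bwd[0]], axis=1)
        return states, summary

    def _attend(self, enc_proj: list[ag.Tensor], enc_states: list[ag.Tensor],
                src_mask: np.ndarray, h_dec: ag.Tensor) -> ag.Tensor:
        dproj = h_dec.matmul(self.W_att_d)
        scores = []
        for t, ep in enumerate(enc_proj):
            e = (ep + dproj + self.b_att).tanh().matmul(self.v_att)  # (B,1)
            scores.append(e)
        s = ag.concat(scores, axis=1)  # (B,T)
        # mask out padding positions before the softmax
        neg = ag.tensor((1.0 - src_mask) * -1e9)
        w = ag.softmax(s + neg, axis=1)
        ctx = None
        for t, hs in enumerate(enc_states):
            term = w[:, t:t + 1] * hs
            ctx = term if ctx is None else ctx + term
        return ctx

    # -- training ----------------------------------------------------------

    def _batch_loss(self, src, src_mask, tgt_in, tgt_out, tgt_mask, feat_ids):
        B, T_t = tgt_in.shape
        ctx_state = self._context_state(feat_ids, B)
        enc_states, summary = self._encode(src, src_mask, ctx_state)
        enc_proj = [h.matmul(self.W_att_e) for h in enc_states]
        h0 = summary.matmul(self.W_bridge) + self.b_bridge
        h = h0.tanh() if ctx_state is None else (h0 + ctx_state).tanh()
        step_logits = []
        for t in range(T_t):
            ctx = self._attend(enc_proj, enc_states, src_mask, h)
            x = ag.concat([ag.embedding(self.emb_tgt, tgt_in[:, t]), ctx], axis=1)
            h = self.dec(x, h)
            logits = ag.concat([h, ctx], axis=1).matmul(self.W_out) + self.b_out
            step_logits.append(logits)
        all_logits = ag.concat(step_logits, axis=0)  # (T_t*B, V) time-major
        flat_tgt = tgt_out.T.reshape(-1)
        flat_w = tgt_mask.T.reshape(-1).astype(np.float32)
        return ag.softmax_cross_entropy(all_logits, flat_tgt, flat_w)

    # -- persistence -------------------------------------------------------

    _ARRAYS = ("W_in", "emb_tgt", "W_bridge", "b_bridge", "W_att_e",
               "W_att_d", "b_att", "v_att", "W_out", "b_out",
               "emb_shape", "emb_color", "emb_form")

    def save(self, path: str | Path) -> None:
        arrays = {n: getattr(self, n).data for n in self._ARRAYS}
        for cname, cell in (("enc_fwd", self.enc_fwd), ("enc_bwd", self.enc_bwd),
                            ("dec", self.dec)):
            arrays[f"{cname}_Wx"] = cell.Wx.data
            arrays[f"{cname}_Wh"] = cell.Wh.data
            arrays[f"{cname}_b"] = cell.b.data
        np.savez(path, meta=json.dumps({"config": self.config.__dict__}), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CorrectorModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(CorrectorConfig(**meta["config"]), np.random.default_rng(0))
        for n in cls._ARRAYS:
            getattr(model, n).data = data[n].astype(np.float32)
        for cname, cell in (("enc_fwd", model.enc_fwd), ("enc_bwd", model.enc_bwd),
                            ("dec", model.dec)):
            cell.Wx.data = data[f"{cname}_Wx"].astype(np.float32)
            cell.Wh.data = data[f"{cname}_Wh"].astype(np.float32)
            cell.b.data = data[f"{cname}_b"].astype(np.float32)
        return model


# --------------------------------------------------------------------------
# Training and decoding
# --------------------------------------------------------------------------


def _prepare_batch(pairs: Sequence[CorrectionPair], idx: np.ndarray,
                   max_len: int, zero_coords: bool):
    """Pad a batch of pairs into dense arrays."""
    srcs, tgts = [], []
    for i in idx:
        # the coordinate ablation removes *all* positional information:
        # no coordinates in the encoding and no coordinate-based pre-sort
        dets = (list(pairs[i].source) if zero_coords
                else sort_detections(pairs[i].source))
        enc = encode_sequence(dets)
        vec = (np.stack([e.vector for e in enc])
               if enc else np.zeros((0, _INPUT_DIM), dtype=np.float32))
        if zero_coords:
            vec = vec.copy()
            vec[:, -2:] = 0.0
        srcs.append(vec)
        tgts.append(_target_ids(pairs[i].target, max_len))
    T_s = max(1, max(len(s) for s in srcs))
    T_t = max(len(t) for t in tgts) + 1  # room for EOS
    B = len(idx)
    src = np.zeros((B, T_s, _INPUT_DIM), dtype=np.float32)
    src_mask = np.zeros((B, T_s), dtype=np.float32)
    tgt_in = np.full((B, T_t), PAD, dtype=np.int64)
    tgt_out = np.full((B, T_t), PAD, dtype=np.int64)
    tgt_mask = np.zeros((B, T_t), dtype=np.float32)
    for b, (s, t) in enumerate(zip(srcs, tgts)):
        if len(s):
            src[b, :len(s)] = s
            src_mask[b, :len(s)] = 1.0
        seq_in = [BOS] + t
        seq_out = t + [EOS]
        tgt_in[b, :len(seq_in)] = seq_in
        tgt_out[b, :len(seq_out)] = seq_out
        tgt_mask[b, :len(seq_out)] = 1.0
    return src, src_mask, tgt_in, tgt_out, tgt_mask


def train_corrector(
    pairs: Sequence[CorrectionPair],
    feature_context: Sequence[tuple[str, str, str]] | None = None,
    config: CorrectorConfig | None = None,
    zero_coords: bool = False,
) -> CorrectorModel:
    """Fit the seq2seq corrector by teacher forcing with Adam.

    ``feature_context`` must be supplied per pair when
    ``config.context_mode == "features"``.  ``zero_coords=True`` ablates the
    coordinate encoding (zeroing x, y before the reading-order sort), for
    measuring the value of coordinates.  Deterministic given config.seed.
    """
    config = config or CorrectorConfig()
    if len(pairs) == 0:
        raise ValueError("no training pairs")
    if config.context_mode == "features":
        if feature_context is None or len(feature_context) != len(pairs):
            raise ValueError("context_mode='features' requires one feature "
                             "triple per pair")
    for p in pairs:  # fail at data load, not mid-training
        _target_ids(p.target, config.max_target_len)
    feats = (np.array([_feature_ids(f) for f in feature_context])
             if feature_context is not None else None)

    rng = np.random.default_rng(config.seed)
    model = CorrectorModel(config, rng)
    opt = ag.Adam(model.params, lr=config.learning_rate)
    n = len(pairs)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            src, sm, ti, to, tm = _prepare_batch(pairs, idx,
                                                 config.max_target_len,
                                                 zero_coords)
            fb = feats[idx] if feats is not None else None
            loss = model._batch_loss(src, sm, ti, to, tm, fb)
            opt.zero_grad()
            loss.backward()
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite corrector training loss")
            opt.step()
            total += float(loss.data) * len(idx)
        model.loss_history.append(total / n)
    return model


def _postfilter(tokens: list[str]) -> str:
    """Keep at most one face separator (the first)."""
    out, seen = [], False
    for t in tokens:
        if t == SEPARATOR:
            if seen:
                continue
            seen = True
        out.append(t)
    return "".join(out)


def correct_imprint(
    model: CorrectorModel,
    detections: Sequence[CharDetection],
    features: tuple[str, str, str] | None = None,
    zero_coords: bool = False,
) -> str:
    """Greedy-decode the canonical imprint for one detection set.

    Empty input decodes to the empty imprint.  The output has at most one
    "_" and at most ``max_target_len`` tokens.
    """
    if len(detections) == 0:
        return ""
    cfg = model.config
    dets = list(detections) if zero_coords else sort_detections(detections)
    enc_chars = encode_sequence(dets)
    src = np.stack([e.vector for e in enc_chars])[None, :, :]
    if zero_coords:
        src = src.copy()
        src[:, :, -2:] = 0.0
    src_mask = np.ones((1, src.shape[1]), dtype=np.float32)
    feat_ids = (np.array([_feature_ids(features)])
                if features is not None and cfg.context_mode == "features"
                else None)
    ctx_state = model._context_state(feat_ids, 1)
    enc_states, summary = model._encode(src, src_mask, ctx_state)
    enc_proj = [h.matmul(model.W_att_e) for h in enc_states]
    h0 = summary.matmul(model.W_bridge) + model.b_bridge
    h = h0.tanh() if ctx_state is None else (h0 + ctx_state).tanh()
    token = np.array([BOS])
    out_tokens: list[str] = []
    for _ in range(cfg.max_target_len):
        ctx = model._attend(enc_proj, enc_states, src_mask, h)
        x = ag.concat([ag.embedding(model.emb_tgt, token), ctx], axis=1)
        h = model.dec(x, h)
        logits = (ag.concat([h, ctx], axis=1).matmul(model.W_out)
                  + model.b_out).data[0]
        logits[PAD] = logits[BOS] = -np.inf
        nxt = int(logits.argmax())
        if nxt == EOS:
            break
        out_tokens.append(_TGT_TOKENS[nxt])
        token = np.array([nxt])
    return _postfilter(out_tokens)
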