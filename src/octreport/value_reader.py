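"""Value Reader: turn cropped numeric-region images into typed measurements.

Two recognizer backends share one interface:

* :class:`OcrModel` — a trainable three-stage scene-text recognizer:
  a residual convolutional feature extractor that maps the normalized crop to
  a left-to-right feature sequence, a bidirectional LSTM that contextualizes
  it, and an attention decoder that emits characters recurrently (greedy,
  deterministic) up to 50 characters.  Trained with AdaDelta
  (learning rate 1, decay 0.95), batch size 32, on synthetic corpora.
* :class:`ReferenceRecognizer` — a deterministic, training-free per-glyph
  template matcher sharing glyph shapes with the synthetic renderer.  It is
  exact on clean renders and raises on anything it cannot match, which makes
  it the plumbing oracle for the rest of the pipeline.

`parse_value` converts recognized strings into unit-bearing measurements,
treating the dash placeholder as an explicit missing value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from PIL import Image

from . import _nn
from ._nn import Parameter, Tensor, concat, softmax_cross_entropy
from .layout_config import DEFAULT_CHARSET, FieldKind, FieldSpec

__all__ = [
    "Recognition",
    "Measurement",
    "TrainConfig",
    "OcrModel",
    "ReferenceRecognizer",
    "RecognitionFailure",
    "ParseError",
    "train",
    "recognize",
    "reference_recognize",
    "parse_value",
    "allowed_chars_from_pattern",
    "normalize_crop",
    "save_model",
    "load_model",
    "MAX_DECODE_LEN",
    "REJECT_THRESHOLD",
    "MISSING_MARKERS",
]

MAX_DECODE_LEN = 50
#: Recognitions with confidence below this are treated as unreliable/empty.
REJECT_THRESHOLD = 0.5
MISSING_MARKERS = ("--", "-")

INPUT_HEIGHT = 32
_MAX_WIDTH = 512


class RecognitionFailure(RuntimeError):
    """The reference recognizer could not match a glyph above tolerance."""


class ParseError(ValueError):
    def __init__(self, message: str, raw_text: str):
        super().__init__(message)
        self.raw_text = raw_text


@dataclass(frozen=True)
class Recognition:
    text: str
    confidence: float  # geometric mean of per-character probabilities


@dataclass(frozen=True)
class Measurement:
    name: str
    value: float | None  # None = explicit missing (dash placeholder)
    unit: str
    raw_text: str

    @property
    def is_missing(self) -> bool:
        return self.value is None


# ---------------------------------------------------------------------------
# crop normalization (shared by training and inference)

def normalize_crop(crop: np.ndarray) -> np.ndarray | None:
    """Tight-crop to ink, resize to height 32 (aspect preserved), grayscale.

    Returns a uint8 array, or None when the crop contains no ink.  Cropping
    to the ink bounding box first makes recognition invariant to background
    padding around the region.
    """
    arr = np.asarray(crop)
    if arr.size == 0:
        raise ValueError("empty crop")
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    arr = arr.astype(np.float32)
    if float(arr.max() - arr.min()) < 25.0:
        return None
    thr = _otsu(arr)
    ink = arr < thr
    if ink.sum() < 4:
        return None
    ys, xs = np.nonzero(ink)
    y0, y1 = max(ys.min() - 2, 0), min(ys.max() + 3, arr.shape[0])
    x0, x1 = max(xs.min() - 2, 0), min(xs.max() + 3, arr.shape[1])
    tight = arr[y0:y1, x0:x1]
    h, w = tight.shape
    new_w = int(np.clip(round(w * INPUT_HEIGHT / h), 8, _MAX_WIDTH))
    img = Image.fromarray(np.clip(tight, 0, 255).astype(np.uint8))
    img = img.resize((new_w, INPUT_HEIGHT), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def _otsu(arr: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(arr.astype(np.uint8)))


def _standardize_batch(images: list[np.ndarray], pad_to: int) -> np.ndarray:
    """Pad normalized crops to a common width with background, standardize."""
    B = len(images)
    out = np.full((B, 1, INPUT_HEIGHT, pad_to), 255.0, dtype=np.float32)
    for i, im in enumerate(images):
        out[i, 0, :, : im.shape[1]] = im
    mean = out.mean(axis=(2, 3), keepdims=True)
    std = out.std(axis=(2, 3), keepdims=True) + 1e-3
    return (out - mean) / std


# ---------------------------------------------------------------------------
# trainable recognizer

@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults are desk-scale (CPU, minutes); ``iterations`` and the corpus
    size scale up to full-scale runs unchanged.  AdaDelta with learning rate
    1 and decay 0.95, batch size 32.
    """

    batch_size: int = 32
    iterations: int = 3000
    lr: float = 1.0
    decay: float = 0.95
    seed: int = 0
    eval_every: int = 250
    val_subset: int = 400
    hidden: int = 64
    attn_dim: int = 64
    embed_dim: int = 32
    grad_clip: float = 5.0
    ema_decay: float = 0.999  # 0 disables Polyak weight averaging

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


class OcrModel:
    """Conv feature extractor + BiLSTM + attention decoder over a charset."""

    def __init__(self, charset: str = DEFAULT_CHARSET, hidden: int = 64,
                 attn_dim: int = 64, embed_dim: int = 32, seed: int = 0,
                 channels: tuple[int, int, int] = (8, 8, 16)):
        self.charset = charset
        self.hidden = hidden
        self.attn_dim = attn_dim
        self.embed_dim = embed_dim
        self.channels = tuple(channels)
        self.max_len = MAX_DECODE_LEN
        V = len(charset)
        self.eos = V            # end-of-sequence class
        self.go = V + 1         # decoder start token (input side only)
        self.n_classes = V + 1  # charset + EOS
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)

    # -- parameter init ----------------------------------------------------
    def _p(self, name: str, shape, scale=None, rng=None):
        if scale is None:
            fan_in = shape[0] if len(shape) > 1 else shape[0]
            scale = np.sqrt(2.0 / fan_in)
        self.params[name] = Parameter(rng.normal(0.0, scale, shape))

    def _init_params(self, rng):
        h, a, e = self.hidden, self.attn_dim, self.embed_dim
        c1, c2, c3 = self.channels
        feat = c3 * 4  # 32 input rows pooled 3x -> 4 rows
        self._p("conv1_w", (c1, 1 * 9), rng=rng)
        self.params["conv1_b"] = Parameter(np.zeros(c1))
        self._p("conv2a_w", (c2, c1 * 9), rng=rng)
        self.params["conv2a_b"] = Parameter(np.zeros(c2))
        self._p("conv2b_w", (c2, c2 * 9), rng=rng)
        self.params["conv2b_b"] = Parameter(np.zeros(c2))
        self._p("conv3_w", (c3, c2 * 9), rng=rng)
        self.params["conv3_b"] = Parameter(np.zeros(c3))
        for d in ("f", "b"):  # encoder directions (input / recurrent parts)
            self._p(f"enc_{d}_wx", (feat, 4 * h), scale=np.sqrt(1.0 / feat), rng=rng)
            self._p(f"enc_{d}_wh", (h, 4 * h), scale=np.sqrt(1.0 / h), rng=rng)
            self.params[f"enc_{d}_b"] = Parameter(np.zeros(4 * h))
        ctx = 2 * h
        self._p("emb", (self.go + 1, e), scale=0.1, rng=rng)
        self._p("dec_w", (e + ctx + h, 4 * h), scale=np.sqrt(1.0 / (e + ctx + h)), rng=rng)
        self.params["dec_b"] = Parameter(np.zeros(4 * h))
        self._p("attn_wh", (ctx, a), scale=np.sqrt(1.0 / ctx), rng=rng)
        self._p("attn_ws", (h, a), scale=np.sqrt(1.0 / h), rng=rng)
        self._p("attn_wl", (2, a), scale=0.5, rng=rng)
        self._p("attn_v", (a, 1), scale=np.sqrt(1.0 / a), rng=rng)
        self._p("out_w", (h + ctx, self.n_classes), scale=np.sqrt(1.0 / (h + ctx)), rng=rng)
        self.params["out_b"] = Parameter(np.zeros(self.n_classes))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- encoding ----------------------------------------------------------
    @staticmethod
    def _lstm_step(x: Tensor, h: Tensor, c: Tensor, w: Tensor, b: Tensor,
                   nh: int) -> tuple[Tensor, Tensor]:
        z = concat([x, h], axis=1) @ w + b
        return OcrModel._lstm_gates(z, c, nh)

    @staticmethod
    def _lstm_gates(z: Tensor, c: Tensor, nh: int) -> tuple[Tensor, Tensor]:
        i = z[:, 0 * nh:1 * nh].sigmoid()
        f = z[:, 1 * nh:2 * nh].sigmoid()
        g = z[:, 2 * nh:3 * nh].tanh()
        o = z[:, 3 * nh:4 * nh].sigmoid()
        c2 = f * c + i * g
        return o * c2.tanh(), c2

    def _encode(self, x: np.ndarray) -> Tensor:
        """x: standardized (B,1,32,W) -> encoder contexts (B,T,2h), T=W/8."""
        p = self.params
        t = Tensor(x)
        t = t.conv2d(p["conv1_w"], p["conv1_b"]).relu().maxpool2()
        r = t.conv2d(p["conv2a_w"], p["conv2a_b"]).relu()
        r = r.conv2d(p["conv2b_w"], p["conv2b_b"])
        t = (t + r).relu().maxpool2()
        # final stage pools height only, preserving horizontal resolution
        # (roughly 4 encoder steps per glyph) for the attention decoder
        t = t.conv2d(p["conv3_w"], p["conv3_b"]).relu().maxpool(2, 1)
        B, C, H, W = t.shape
        seq = t.transpose(0, 3, 1, 2).reshape(B * W, C * H)  # (B*T, feat)
        T = W
        h = self.hidden
        # input-side gate contributions for every timestep in one matmul
        zx_f = (seq @ p["enc_f_wx"] + p["enc_f_b"]).reshape(B, T, 4 * h)
        zx_b = (seq @ p["enc_b_wx"] + p["enc_b_b"]).reshape(B, T, 4 * h)
        zeros = Tensor(np.zeros((B, h), dtype=np.float32))
        outs_f: list[Tensor] = []
        hf, cf = zeros, zeros
        for i in range(T):
            hf, cf = self._lstm_gates(zx_f[:, i, :] + hf @ p["enc_f_wh"], cf, h)
            outs_f.append(hf)
        outs_b: list[Tensor] = [None] * T
        hb, cb = zeros, zeros
        for i in reversed(range(T)):
            hb, cb = self._lstm_gates(zx_b[:, i, :] + hb @ p["enc_b_wh"], cb, h)
            outs_b[i] = hb
        steps = [concat([f_, b_], axis=1).reshape(B, 1, 2 * h)
                 for f_, b_ in zip(outs_f, outs_b)]
        return concat(steps, axis=1)  # (B,T,2h)

    def _attend(self, H: Tensor, WhH: Tensor, s: Tensor, alpha_prev: Tensor,
                coverage: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """One location-aware attention read.

        H (B,T,2h), WhH (B,T,a), s (B,h); alpha_prev/coverage (B,T,1) carry
        the previous attention and its running sum, which keeps alignment
        monotonic on long runs of visually identical glyphs (digit strings).
        Returns (context (B,2h), alpha, coverage).
        """
        p = self.params
        B, T, _ = H.shape
        q = (s @ p["attn_ws"]).reshape(B, 1, self.attn_dim)
        loc = (concat([alpha_prev, coverage], axis=2).reshape(B * T, 2)
               @ p["attn_wl"]).reshape(B, T, self.attn_dim)
        scores = ((WhH + q + loc).tanh().reshape(B * T, self.attn_dim)
                  @ p["attn_v"]).reshape(B, T)
        alpha = scores.softmax(axis=1).reshape(B, T, 1)
        ctx = (alpha * H).sum(axis=1)
        return ctx, alpha, coverage + alpha

    def _attn_state(self, B: int, T: int) -> tuple[Tensor, Tensor]:
        zeros = np.zeros((B, T, 1), dtype=np.float32)
        return Tensor(zeros), Tensor(zeros.copy())

    def _embed(self, ids: np.ndarray) -> Tensor:
        onehot = np.zeros((ids.shape[0], self.go + 1), dtype=np.float32)
        onehot[np.arange(ids.shape[0]), ids] = 1.0
        return Tensor(onehot) @ self.params["emb"]

    # -- training forward --------------------------------------------------
    def loss(self, x: np.ndarray, targets: np.ndarray, weights: np.ndarray) -> Tensor:
        """Teacher-forced cross-entropy.

        targets: (B,L) int ids where each row is label chars followed by EOS
        padding; weights: (B,L) with 1.0 through the first EOS, 0 after.
        """
        p = self.params
        H = self._encode(x)
        B, T, _ = H.shape
        WhH = (H.reshape(B * T, 2 * self.hidden) @ p["attn_wh"]).reshape(B, T, self.attn_dim)
        h = self.hidden
        s = Tensor(np.zeros((B, h), dtype=np.float32))
        c = Tensor(np.zeros((B, h), dtype=np.float32))
        L = targets.shape[1]
        prev = np.full(B, self.go, dtype=np.int64)
        alpha, cov = self._attn_state(B, T)
        losses = []
        for t_step in range(L):
            ctx, alpha, cov = self._attend(H, WhH, s, alpha, cov)
            inp = concat([self._embed(prev), ctx], axis=1)
            s, c = self._lstm_step(inp, s, c, p["dec_w"], p["dec_b"], h)
            logits = concat([s, ctx], axis=1) @ p["out_w"] + p["out_b"]
            losses.append(softmax_cross_entropy(logits, targets[:, t_step],
                                                weights[:, t_step]))
            prev = targets[:, t_step]
        total = losses[0]
        for l in losses[1:]:
            total = total + l
        return total * (1.0 / L)

    # -- greedy inference --------------------------------------------------
    def decode(self, x: np.ndarray,
               allowed: str | None = None) -> list[Recognition]:
        """Greedy attention decoding of a standardized batch (B,1,32,W).

        ``allowed`` restricts the output alphabet (constrained decoding for
        fields whose catalog pattern declares their character class); the
        end-of-sequence symbol always stays available.
        """
        p = self.params
        mask = None
        if allowed is not None:
            allowed_set = set(allowed)
            mask = np.array([ch not in allowed_set for ch in self.charset]
                            + [False], dtype=bool)  # EOS never masked
        H = self._encode(x)
        B, T, _ = H.shape
        WhH = (H.reshape(B * T, 2 * self.hidden) @ p["attn_wh"]).reshape(B, T, self.attn_dim)
        h = self.hidden
        s = Tensor(np.zeros((B, h), dtype=np.float32))
        c = Tensor(np.zeros((B, h), dtype=np.float32))
        prev = np.full(B, self.go, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        texts = [[] for _ in range(B)]
        logps = [[] for _ in range(B)]
        alpha, cov = self._attn_state(B, T)
        for _ in range(self.max_len):
            ctx, alpha, cov = self._attend(H, WhH, s, alpha, cov)
            inp = concat([self._embed(prev), ctx], axis=1)
            s, c = self._lstm_step(inp, s, c, p["dec_w"], p["dec_b"], h)
            logits = (concat([s, ctx], axis=1) @ p["out_w"] + p["out_b"]).data
            if mask is not None:
                logits[:, mask] = -np.inf
            z = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(z)
            probs /= probs.sum(axis=1, keepdims=True)
            ids = probs.argmax(axis=1)
            for b in range(B):
                if done[b]:
                    continue
                if ids[b] == self.eos:
                    done[b] = True
                else:
                    texts[b].append(self.charset[ids[b]])
                    logps[b].append(np.log(max(probs[b, ids[b]], 1e-12)))
            if done.all():
                break
            prev = ids
        out = []
        for b in range(B):
            text = "".join(texts[b])
            conf = float(np.exp(np.mean(logps[b]))) if logps[b] else 0.0
            out.append(Recognition(text=text, confidence=conf))
        return out

    # -- checkpointing -----------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.astype(np.float32).copy()

    def recognize_crops(self, crops: list[np.ndarray],
                        allowed: list[str | None] | None = None) -> list[Recognition]:
        """Recognize raw crops, batching same-width normalizations.

        ``allowed`` optionally gives a per-crop permitted alphabet (None =
        unconstrained); crops are grouped by (padded width, alphabet).
        """
        norm = [normalize_crop(c) for c in crops]
        if allowed is None:
            allowed = [None] * len(crops)
        out: list[Recognition | None] = [None] * len(crops)
        groups: dict[tuple, list[int]] = {}
        for i, im in enumerate(norm):
            if im is None:
                out[i] = Recognition("", 0.0)
            else:
                # pad to the same width grid the training buckets use
                wpad = int(np.ceil(max(im.shape[1], 32) / 32) * 32)
                groups.setdefault((wpad, allowed[i]), []).append(i)
        for (wpad, chars), idxs in groups.items():
            x = _standardize_batch([norm[i] for i in idxs], wpad)
            for i, rec in zip(idxs, self.decode(x, allowed=chars)):
                out[i] = rec
        return out  # type: ignore[return-value]

    def recognize(self, crop: np.ndarray,
                  allowed: str | None = None) -> Recognition:
        return self.recognize_crops([crop], [allowed])[0]


def recognize(model: OcrModel, crop: np.ndarray) -> Recognition:
    """Greedy attention decoding of one crop (at most 50 characters)."""
    if np.asarray(crop).size == 0:
        raise ValueError("empty crop")
    return model.recognize(crop)


def allowed_chars_from_pattern(pattern: str | None, charset: str) -> str | None:
    """Character alphabet implied by a field's regular-expression pattern.

    Supports the restricted regex dialect catalog patterns use: literals,
    ``\\d``, escaped characters, character classes with ranges, alternation
    and repetition.  Returns None (unconstrained) when the pattern is absent
    or uses constructs this analysis does not cover.
    """
    if not pattern:
        return None
    out: set[str] = set()
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "\\":
            if i + 1 >= len(pattern):
                return None
            nxt = pattern[i + 1]
            if nxt == "d":
                out.update("0123456789")
            elif nxt in "wWsSbBDAZ":
                return None  # too broad to constrain safely
            else:
                out.add(nxt)
            i += 2
        elif ch == "{":  # repetition count, not content
            j = pattern.find("}", i)
            if j < 0:
                return None
            i = j + 1
        elif ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                return None
            body = pattern[i + 1:j]
            if body.startswith("^"):
                return None
            k = 0
            while k < len(body):
                if k + 2 < len(body) and body[k + 1] == "-":
                    out.update(chr(c) for c in range(ord(body[k]),
                                                     ord(body[k + 2]) + 1))
                    k += 3
                else:
                    out.add(body[k].lstrip("\\") or "\\")
                    k += 1
            i = j + 1
        elif ch in "()|+*?^$":
            i += 1
        elif ch == ".":
            return None  # wildcard: unconstrained
        else:
            out.add(ch)
            i += 1
    chars = "".join(c for c in charset if c in out)
    return chars or None


# ---------------------------------------------------------------------------
# training loop

def _encode_labels(labels: list[str], charset: str, eos: int) -> tuple[np.ndarray, np.ndarray]:
    idx = {ch: i for i, ch in enumerate(charset)}
    L = max(len(s) for s in labels) + 1
    targets = np.full((len(labels), L), eos, dtype=np.int64)
    weights = np.zeros((len(labels), L), dtype=np.float32)
    for r, s in enumerate(labels):
        for j, ch in enumerate(s):
            targets[r, j] = idx[ch]
        weights[r, : len(s) + 1] = 1.0
    return targets, weights


def train(train_set, val_set, config: TrainConfig = TrainConfig(),
          charset: str = DEFAULT_CHARSET,
          progress: bool = False) -> tuple[OcrModel, list[dict]]:
    """Train the recognizer; returns (best-validation checkpoint, curves).

    Curves are a list of dicts (iteration, loss, val_accuracy); the returned
    model carries the weights of the checkpoint with the best validation
    sequence accuracy.  Fully reproducible given ``config.seed``.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    for s in list(train_set)[:64] + list(val_set)[:64]:
        bad = set(s.label) - set(charset)
        if bad:
            raise ValueError(f"label {s.label!r} outside charset: {sorted(bad)}")

    rng = np.random.default_rng(config.seed)
    model = OcrModel(charset, config.hidden, config.attn_dim, config.embed_dim,
                     seed=int(rng.integers(0, 2**31 - 1)))
    opt = _nn.AdaDelta(model.parameters(), lr=config.lr, rho=config.decay)

    # pre-normalize once; bucket by padded width so batches stay rectangular
    norm_train, labels_train = [], []
    for s in train_set:
        im = normalize_crop(s.image)
        if im is None:
            continue
        norm_train.append(im)
        labels_train.append(s.label)
    buckets: dict[int, list[int]] = {}
    for i, im in enumerate(norm_train):
        wpad = int(np.ceil(im.shape[1] / 32) * 32)
        buckets.setdefault(wpad, []).append(i)
    bucket_keys = sorted(buckets)
    bucket_p = np.array([len(buckets[k]) for k in bucket_keys], dtype=float)
    bucket_p /= bucket_p.sum()

    val_idx = rng.permutation(len(val_set))[: config.val_subset]
    val_samples = [val_set[i] for i in val_idx]

    def _evaluate() -> float:
        preds = model.recognize_crops([s.image for s in val_samples])
        return float(np.mean([p.text == s.label
                              for p, s in zip(preds, val_samples)]))

    curves: list[dict] = []
    best_acc, best_state = -1.0, model.state()
    # Polyak-averaged shadow weights smooth out late-training fluctuation;
    # the returned checkpoint is whichever (raw or averaged) validates best
    ema_state: dict[str, np.ndarray] | None = None
    ema_decay = config.ema_decay
    loss_accum, loss_n = 0.0, 0
    for it in range(1, config.iterations + 1):
        k = bucket_keys[int(rng.choice(len(bucket_keys), p=bucket_p))]
        pool = buckets[k]
        take = [pool[j] for j in rng.integers(0, len(pool), size=config.batch_size)]
        x = _standardize_batch([norm_train[i] for i in take], k)
        targets, weights = _encode_labels([labels_train[i] for i in take],
                                          charset, model.eos)
        opt.zero_grad()
        loss = model.loss(x, targets, weights)
        loss.backward()
        _nn.clip_global_norm(model.parameters(), config.grad_clip)
        opt.step()
        if ema_decay:
            if ema_state is None:
                ema_state = model.state()
            else:
                for name, p in model.params.items():
                    ema_state[name] *= ema_decay
                    ema_state[name] += (1.0 - ema_decay) * p.data
        loss_accum += float(loss.data)
        loss_n += 1
        if it % config.eval_every == 0 or it == config.iterations:
            acc = _evaluate()
            if acc >= best_acc:
                best_acc, best_state = acc, model.state()
            if ema_state is not None:
                raw_state = model.state()
                model.load_state(ema_state)
                ema_acc = _evaluate()
                model.load_state(raw_state)
                if ema_acc >= best_acc:
                    best_acc = ema_acc
                    best_state = {k2: v.copy() for k2, v in ema_state.items()}
                acc = max(acc, ema_acc)
            curves.append({"iteration": it, "loss": loss_accum / max(loss_n, 1),
                           "val_accuracy": acc})
            if progress:
                print(f"iter {it:6d}  loss {loss_accum / max(loss_n, 1):.4f}  "
                      f"val acc {acc:.4f}", flush=True)
            loss_accum, loss_n = 0.0, 0
    model.load_state(best_state)
    return model, curves


def save_model(model: OcrModel, path) -> None:
    meta = {"charset": model.charset, "hidden": model.hidden,
            "attn_dim": model.attn_dim, "embed_dim": model.embed_dim,
            "channels": list(model.channels)}
    _nn.save_params(path, model.params, meta)


def load_model(path) -> OcrModel:
    arrays, meta = _nn.load_params(path)
    model = OcrModel(meta["charset"], meta["hidden"], meta["attn_dim"],
                     meta["embed_dim"], channels=tuple(meta["channels"]))
    model.load_state(arrays)
    return model


# ---------------------------------------------------------------------------
# deterministic reference recognizer (template matching)

_TPL_HEIGHT = 24
_SIZE_RANGE = range(8, 41)


@lru_cache(maxsize=4)
def _template_bank(charset: str) -> list[tuple[str, np.ndarray, float]]:
    """(char, normalized binary template, aspect w/h) for every bundled font."""
    from .synthetic import FONT_IDS, TextStyle, render_text

    bank = []
    for font_id in FONT_IDS:
        for ch in charset:
            if ch == " ":
                continue
            bmp = render_text(ch, TextStyle(font=font_id, size=32), pad=4)
            mask = bmp < 128
            tpl, aspect = _norm_glyph(mask)
            bank.append((ch, tpl, aspect))
    return bank


def _tight(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]


@lru_cache(maxsize=512)
def _size_templates(font_id: str, size: int, charset: str) -> dict[str, np.ndarray]:
    """Tight binary glyph masks rendered at a specific font size."""
    from .synthetic import TextStyle, render_text

    out = {}
    for ch in charset:
        if ch == " ":
            continue
        bmp = render_text(ch, TextStyle(font=font_id, size=size), pad=4)
        out[ch] = _tight(bmp < 128)
    return out


@lru_cache(maxsize=16)
def _glyph_heights(font_id: str, charset: str) -> dict[int, tuple[int, ...]]:
    """Distinct rendered ink heights per font size (for size estimation)."""
    heights = {}
    for size in _SIZE_RANGE:
        tpls = _size_templates(font_id, size, charset)
        heights[size] = tuple(sorted({t.shape[0] for t in tpls.values()}))
    return heights


def _ncc_masks(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean correlation of two binary masks on one canvas.

    Maximized over +-1 px shifts: centering two tight boxes of different
    width parity misaligns thin strokes by a pixel, which would crater the
    correlation of otherwise identical glyphs.
    """
    h = max(a.shape[0], b.shape[0]) + 2
    w = max(a.shape[1], b.shape[1]) + 2
    pa = np.zeros((h, w), dtype=np.float32)
    pa[(h - a.shape[0]) // 2:(h - a.shape[0]) // 2 + a.shape[0],
       (w - a.shape[1]) // 2:(w - a.shape[1]) // 2 + a.shape[1]] = a
    am = pa.mean()
    na = float(((pa - am) ** 2).sum())
    if na < 1e-9:
        return 0.0
    oy = (h - b.shape[0]) // 2
    ox = (w - b.shape[1]) // 2
    bf = b.astype(np.float32)
    bm = bf.sum() / (h * w)
    nb = float((bf * bf).sum()) - (h * w) * bm * bm
    denom = np.sqrt(na * nb)
    if denom < 1e-9:
        return 0.0
    dys = (0, 1) if (a.shape[0] - b.shape[0]) % 2 else (0,)
    dxs = (0, 1) if (a.shape[1] - b.shape[1]) % 2 else (0,)
    best = 0.0
    for dy in dys:
        for dx in dxs:
            window = pa[oy + dy:oy + dy + b.shape[0], ox + dx:ox + dx + b.shape[1]]
            # zero-mean cross term without materializing the shifted canvas
            cross = float((window * bf).sum()) - am * float(bf.sum()) \
                - bm * float(pa.sum()) + (h * w) * am * bm
            best = max(best, cross / denom)
    return best


def _norm_glyph(mask: np.ndarray) -> tuple[np.ndarray, float]:
    ys, xs = np.nonzero(mask)
    tight = mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1].astype(np.float32)
    h, w = tight.shape
    aspect = w / h
    # background margin keeps solid glyphs (e.g. '.') from zero-variance NCC
    m = max(1, int(round(0.15 * max(h, w))))
    tight = np.pad(tight, m)
    h, w = tight.shape
    new_w = max(int(round(w * _TPL_HEIGHT / h)), 2)
    img = Image.fromarray((tight * 255).astype(np.uint8))
    img = img.resize((new_w, _TPL_HEIGHT), Image.BILINEAR)
    return np.asarray(img, dtype=np.float32) / 255.0, aspect


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean correlation of two glyph images on a common canvas."""
    w = max(a.shape[1], b.shape[1])
    pa = np.zeros((_TPL_HEIGHT, w), dtype=np.float32)
    pb = np.zeros((_TPL_HEIGHT, w), dtype=np.float32)
    oa = (w - a.shape[1]) // 2
    ob = (w - b.shape[1]) // 2
    pa[:, oa:oa + a.shape[1]] = a
    pb[:, ob:ob + b.shape[1]] = b
    pa -= pa.mean()
    pb -= pb.mean()
    denom = np.sqrt((pa * pa).sum() * (pb * pb).sum())
    if denom < 1e-9:
        return 0.0
    return float((pa * pb).sum() / denom)


class ReferenceRecognizer:
    """Deterministic left-to-right glyph matcher (no training).

    Segments the binarized crop into glyph runs by column gaps.  The text's
    rendering size is estimated from the tallest glyph's ink height, and each
    run is matched against glyph templates rendered at that native size
    (zero-mean correlation of center-aligned binary masks), which keeps
    near-twin glyph pairs (0/O, B/8) apart.  When no size candidate fits —
    e.g. rescaled input — matching falls back to height-normalized templates
    with an aspect-ratio penalty.  Raises :class:`RecognitionFailure` when
    the best match falls below tolerance (e.g., heavy noise).
    """

    def __init__(self, charset: str = DEFAULT_CHARSET, tolerance: float = 0.55,
                 aspect_lambda: float = 0.35):
        self.charset = charset
        self.tolerance = tolerance
        self.aspect_lambda = aspect_lambda
        self._bank = _template_bank(charset)

    def _size_candidates(self, cap_h: int) -> list[tuple[str, int]]:
        """(font, size) pairs where some glyph's ink height matches the
        tallest segment's height — the true rendering size is always among
        them for native-resolution crops."""
        from .synthetic import FONT_IDS

        out = []
        for font_id in FONT_IDS:
            for size, hs in _glyph_heights(font_id, self.charset).items():
                if any(abs(h - cap_h) <= 1 for h in hs):
                    out.append((font_id, size))
        return out

    def _match_one(self, tight: np.ndarray, tpls: dict[str, np.ndarray],
                   allowed: str | None = None) -> tuple[str, float]:
        """Best template for one glyph; near-ties resolve by charset order
        (digits first), since report content is predominantly numeric."""
        th, tw = tight.shape
        scored: list[tuple[float, int, str]] = []
        for idx, ch in enumerate(self.charset):
            tpl = tpls.get(ch)
            if tpl is None or (allowed is not None and ch not in allowed):
                continue
            h, w = tpl.shape
            if abs(h - th) > max(2, 0.3 * th) or abs(w - tw) > max(2, 0.3 * tw):
                continue  # cheap shape pre-filter
            scored.append((_ncc_masks(tight, tpl), idx, ch))
        if not scored:
            return "", -1.0
        top = max(s for s, _, _ in scored)
        near = [(idx, ch, s) for s, idx, ch in scored if top - s < 0.02]
        idx, ch, s = min(near)
        return ch, s

    def _match_segments(self, segments: list[np.ndarray],
                        candidates: list[tuple[str, int]],
                        allowed: str | None = None) -> tuple[list[str], list[float]]:
        """Jointly pick the (font, size) that best explains every glyph."""
        tights = [_tight(s) for s in segments]
        est = max(1.0, max(t.shape[0] for t in tights) / 0.72)
        candidates = sorted(candidates, key=lambda fs: abs(fs[1] - est))
        best: tuple[float, list[str], list[float]] | None = None
        for font_id, size in candidates:
            tpls = _size_templates(font_id, size, self.charset)
            chars, scores = [], []
            for i, tight in enumerate(tights):
                # branch & bound: drop this size once it cannot win
                if best is not None and \
                        sum(scores) + (len(tights) - i) <= best[0]:
                    break
                ch, s = self._match_one(tight, tpls, allowed)
                chars.append(ch)
                scores.append(s)
            if len(scores) < len(tights):
                continue
            total = float(np.sum(scores))
            if best is None or total > best[0]:
                best = (total, chars, scores)
        if best is not None and min(best[2]) >= self.tolerance:
            return best[1], best[2]
        # fallback: scale-normalized matching (handles rescaled input)
        chars, scores = [], []
        for seg in segments:
            glyph, aspect = _norm_glyph(seg)
            best_ch, best_score = "", -1.0
            for ch, tpl, tpl_aspect in self._bank:
                if allowed is not None and ch not in allowed:
                    continue
                penalty = self.aspect_lambda * abs(np.log(aspect / tpl_aspect))
                score = _ncc(glyph, tpl) - penalty
                if score > best_score:
                    best_ch, best_score = ch, score
            chars.append(best_ch)
            scores.append(best_score)
        if best is not None and float(np.sum(best[2])) >= float(np.sum(scores)):
            return best[1], best[2]
        return chars, scores

    def recognize(self, crop: np.ndarray,
                  allowed: str | None = None) -> Recognition:
        arr = np.asarray(crop)
        if arr.size == 0:
            raise ValueError("empty crop")
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        arr = arr.astype(np.float32)
        if float(arr.max() - arr.min()) < 25.0:
            return Recognition("", 0.0)
        # midpoint threshold: matches the templates' binarization exactly on
        # clean renders and is invariant to linear contrast scaling
        mask = arr < (float(arr.min()) + float(arr.max())) / 2.0
        cols = mask.any(axis=0)
        if not cols.any():
            return Recognition("", 0.0)
        runs = _column_runs(cols)
        # spaces: a gap must be large both on the glyph-height scale and
        # relative to the typical inter-glyph gap in this crop
        ys, _ = np.nonzero(mask)
        glyph_h = float(ys.max() - ys.min() + 1)
        gaps = [runs[i + 1][0] - runs[i][1] for i in range(len(runs) - 1)]
        median_gap = float(np.median(gaps)) if gaps else 0.0
        space_gap = max(0.6 * glyph_h, 1.8 * median_gap, median_gap + 4.0)
        segments, seg_runs = [], []
        for lo, hi in runs:
            seg = mask[:, lo:hi]
            if seg.any():
                segments.append(seg)
                seg_runs.append((lo, hi))
        if not segments:
            return Recognition("", 0.0)
        cap_h = max(int(np.ptp(np.nonzero(s.any(axis=1))[0])) + 1 for s in segments)
        candidates = self._size_candidates(cap_h)
        glyphs, scores = self._match_segments(segments, candidates, allowed)
        chars: list[str] = []
        prev_end = None
        for (lo, hi), ch, score in zip(seg_runs, glyphs, scores):
            if score < self.tolerance:
                raise RecognitionFailure(
                    f"glyph at columns {lo}:{hi} matched {ch!r} "
                    f"with score {score:.3f} < tolerance {self.tolerance}")
            if prev_end is not None and " " in self.charset and \
                    (allowed is None or " " in allowed) and \
                    (lo - prev_end) > space_gap:
                chars.append(" ")
            prev_end = hi
            chars.append(ch)
        text = "".join(chars)
        conf = float(np.exp(np.mean(np.log(np.clip(scores, 1e-6, 1.0))))) if scores else 0.0
        return Recognition(text=text, confidence=conf)


def _column_runs(cols: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [lo, hi) runs of True columns."""
    padded = np.concatenate([[False], cols, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return list(zip(starts, ends))


def reference_recognize(crop: np.ndarray, charset: str = DEFAULT_CHARSET) -> Recognition:
    return ReferenceRecognizer(charset).recognize(crop)


# ---------------------------------------------------------------------------
# parsing

_DEFAULT_NUMERIC = r"-?\d+(?:\.\d+)?"


def parse_value(recognition: Recognition, field: FieldSpec) -> Measurement:
    """Convert a recognized string into a typed, unit-bearing measurement.

    The dash placeholder denotes a missing value (never zero).  Anything else
    must match the field pattern and parse as a decimal number.
    """
    if field.kind != FieldKind.NUMERIC:
        raise ValueError(f"parse_value requires a numeric field, got {field.kind}")
    text = recognition.text.strip()
    if text in MISSING_MARKERS:
        return Measurement(field.name, None, field.unit, recognition.text)
    pattern = field.pattern or _DEFAULT_NUMERIC
    if re.fullmatch(pattern, text) is None or \
            re.fullmatch(_DEFAULT_NUMERIC, text) is None:
        raise ParseError(
            f"field {field.name!r}: text {text!r} does not match pattern "
            f"{pattern!r}", raw_text=recognition.text)
    return Measurement(field.name, float(text), field.unit, recognition.text)
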