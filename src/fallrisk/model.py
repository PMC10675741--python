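"""Convolutional self-attention encoder and Berg-score regression head.

The encoder maps a 20 x 20 x 6 window matrix to an ``embed_dim`` vector:

    input -> stem convolution + ReLU -> spatial self-attention block
          -> global average pooling -> embedding

The self-attention block computes key, query, and value with three
convolution layers.  The softmax of the dot product between the query at
each spatial position and the keys at all 400 positions yields a
400 x 400 row-stochastic attention map; values aggregated by those
scores form the attention output ``o``, and a learnable scalar gate
gamma combines it with the block input:

    y = gamma * o + x

Gamma is initialized to 0, so an untrained block is exactly the
identity, and its learned magnitude expresses how much the model relies
on attention.  The regression head is a single linear map from the
concatenation of five view embeddings to one Berg score.

Everything is plain numpy (see ``_nn``); gradients are computed by
hand-written backpropagation in :mod:`fallrisk.train`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ConfigurationError, SizeError, StateError
from .preprocess import MATRIX_SIDE, ModelInput

VALID_KERNEL_SIZES = (1, 2, 4, 6, 8)
N_VIEWS = 5  # original + noise/quantize/drift/reverse


@dataclass
class ModelConfig:
    in_channels: int = 6
    kernel_size: int = 1
    embed_dim: int = 64
    kq_channels: int | None = None  # default: max(1, embed_dim // 8)
    gamma_init: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size not in VALID_KERNEL_SIZES:
            raise ConfigurationError(
                f"kernel_size must be one of {VALID_KERNEL_SIZES}, "
                f"got {self.kernel_size}")
        if self.embed_dim < 1:
            raise ConfigurationError("embed_dim must be >= 1")
        if self.kq_channels is None:
            self.kq_channels = max(1, self.embed_dim // 8)


@dataclass
class AttentionRecord:
    """A row-stochastic spatial attention map plus the gamma gate."""

    attention: np.ndarray  # (S, S): rows index queries, columns keys
    gamma: float

    def validate(self, tol: float = 1e-5) -> None:
        if (self.attention < -tol).any():
            raise SizeError("attention entries must be non-negative")
        rows = self.attention.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=tol):
            raise SizeError("attention rows must sum to 1")


@dataclass
class Embedding:
    vector: np.ndarray
    window_ref: object = None


def _init_conv(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (cin * k * k))
    return rng.normal(0.0, scale, size=(cout, cin, k, k))


class AttentionModel:
    """Encoder + regression head with a flat parameter dictionary."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        kq = config.kq_channels
        k = config.kernel_size
        self.params: dict[str, np.ndarray] = {
            "stem_W": _init_conv(rng, d, config.in_channels, 1),
            "stem_b": np.zeros(d),
            "q_W": _init_conv(rng, kq, d, k),
            "q_b": np.zeros(kq),
            "k_W": _init_conv(rng, kq, d, k),
            "k_b": np.zeros(kq),
            "v_W": _init_conv(rng, d, d, k),
            "v_b": np.zeros(d),
            "gamma": np.array([config.gamma_init]),
            "head_W": rng.normal(0.0, 1.0 / np.sqrt(N_VIEWS * d),
                                 size=(N_VIEWS * d,)),
            "head_b": np.zeros(1),
        }
        # Berg targets are z-scored during training; predictions are
        # mapped back through these statistics.
        self.target_mean = 0.0
        self.target_sd = 1.0
        self.trained = False

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray):
        """Encode a batch ``(N, 6, H, W)``; returns (emb, attn, cache)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise SizeError(f"expected (N, {self.config.in_channels}, H, W) "
                            f"input, got shape {x.shape}")
        p = self.params
        h0, stem_cache = _nn.conv2d_forward(x, p["stem_W"], p["stem_b"])
        h = np.maximum(h0, 0.0)
        y, attn, att_cache = self._attention_forward(h)
        emb = y.mean(axis=(2, 3))
        cache = (x, h0, h, att_cache, y.shape)
        return emb, attn, cache

    def _attention_forward(self, h: np.ndarray):
        p = self.params
        n, c, hh, ww = h.shape
        s = hh * ww
        q, q_cache = _nn.conv2d_forward(h, p["q_W"], p["q_b"])
        k, k_cache = _nn.conv2d_forward(h, p["k_W"], p["k_b"])
        v, v_cache = _nn.conv2d_forward(h, p["v_W"], p["v_b"])
        qf = q.reshape(n, -1, s)
        kf = k.reshape(n, -1, s)
        vf = v.reshape(n, c, s)
        logits = np.einsum("ncq,nck->nqk", qf, kf, optimize=True)
        attn = _nn.softmax_lastaxis(logits)
        of = np.einsum("nqk,nck->ncq", attn, vf, optimize=True)
        o = of.reshape(h.shape)
        gamma = float(p["gamma"][0])
        y = gamma * o + h
        cache = (q_cache, k_cache, v_cache, qf, kf, vf, attn, of, o)
        return y, attn, cache

    def backward(self, demb: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt all encoder params given d(emb)."""
        x, h0, h, att_cache, y_shape = cache
        p = self.params
        n, c, hh, ww = y_shape
        s = hh * ww
        dy = np.broadcast_to(demb[:, :, None, None] / s, y_shape).copy()

        q_cache, k_cache, v_cache, qf, kf, vf, attn, of, o = att_cache
        gamma = float(p["gamma"][0])
        dgamma = float((dy * o).sum())
        do = gamma * dy
        dh = dy.copy()

        dof = do.reshape(n, c, s)
        dattn = np.einsum("ncq,nck->nqk", dof, vf, optimize=True)
        dvf = np.einsum("nqk,ncq->nck", attn, dof, optimize=True)
        dlogits = _nn.softmax_backward(attn, dattn)
        dqf = np.einsum("nqk,nck->ncq", dlogits, kf, optimize=True)
        dkf = np.einsum("nqk,ncq->nck", dlogits, qf, optimize=True)

        grads: dict[str, np.ndarray] = {"gamma": np.array([dgamma])}
        for name, dflat, cache_c, shape in (
            ("q", dqf, q_cache, qf.shape),
            ("k", dkf, k_cache, kf.shape),
            ("v", dvf, v_cache, vf.shape),
        ):
            dyc = dflat.reshape(dflat.shape[0], dflat.shape[1], hh, ww)
            dx_c, dW, db = _nn.conv2d_backward(dyc, p[f"{name}_W"], cache_c)
            grads[f"{name}_W"] = dW
            grads[f"{name}_b"] = db
            dh += dx_c

        dh0 = dh * (h0 > 0)
        _, dW, db = _nn.conv2d_backward(dh0, p["stem_W"], (x, None, 1))
        grads["stem_W"] = dW
        grads["stem_b"] = db
        return grads

    # ---- head ---------------------------------------------------------------

    def head_forward(self, concat_emb: np.ndarray) -> np.ndarray:
        """Linear head on (N, 5*embed_dim) concatenated view embeddings.

        Output is in z-scored target units; use :meth:`predict_berg` for
        Berg points.
        """
        return concat_emb @ self.params["head_W"] + self.params["head_b"][0]

    def head_backward(self, concat_emb: np.ndarray, dpred: np.ndarray):
        dW = dpred @ concat_emb
        db = np.array([dpred.sum()])
        dconcat = np.outer(dpred, self.params["head_W"])
        return dconcat, {"head_W": dW, "head_b": db}

    # ---- persistence --------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "config": {
                "in_channels": self.config.in_channels,
                "kernel_size": self.config.kernel_size,
                "embed_dim": self.config.embed_dim,
                "kq_channels": self.config.kq_channels,
                "gamma_init": self.config.gamma_init,
                "seed": self.config.seed,
            },
            "target_mean": self.target_mean,
            "target_sd": self.target_sd,
            "trained": self.trained,
        }
        np.savez(path, _meta=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "AttentionModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))
            model = cls(ModelConfig(**meta["config"]))
            for key in model.params:
                model.params[key] = data[key]
        model.target_mean = meta["target_mean"]
        model.target_sd = meta["target_sd"]
        model.trained = meta["trained"]
        return model


def init_model(config: ModelConfig) -> AttentionModel:
    """Build a freshly initialized model; gamma starts at ``gamma_init``."""
    return AttentionModel(config)


def self_attention_forward(x: np.ndarray, model: AttentionModel):
    """Apply the self-attention block alone to a feature map.

    ``x`` is ``(C, H, W)`` with ``C == embed_dim``; any spatial size is
    accepted (the attention map is ``(H*W, H*W)``).  Returns
    ``(y, AttentionRecord)`` with ``y = gamma * o + x``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or x.shape[0] != self_attention_channels(model):
        raise SizeError(
            f"expected ({self_attention_channels(model)}, H, W), got {x.shape}")
    y, attn, _ = model._attention_forward(x[None])
    return y[0], AttentionRecord(attention=attn[0],
                                 gamma=float(model.params["gamma"][0]))


def self_attention_channels(model: AttentionModel) -> int:
    return model.config.embed_dim


def encode(mi: ModelInput, model: AttentionModel):
    """Encode one model input; returns (Embedding, AttentionRecord)."""
    if model is None:
        raise StateError("model is not initialized")
    data = np.asarray(mi.data, dtype=float)
    if data.shape != (model.config.in_channels, MATRIX_SIDE, MATRIX_SIDE):
        raise SizeError(f"expected ({model.config.in_channels}, {MATRIX_SIDE}, "
                        f"{MATRIX_SIDE}) input, got {data.shape}")
    emb, attn, _ = model.forward(data[None])
    return (Embedding(vector=emb[0], window_ref=mi.window_ref),
            AttentionRecord(attention=attn[0],
                            gamma=float(model.params["gamma"][0])))


def encode_batch(x: np.ndarray, model: AttentionModel):
    """Encode a batch ``(N, 6, 20, 20)``; returns (embeddings, attentions)."""
    emb, attn, _ = model.forward(x)
    return emb, attn


def predict_berg(embeddings, model: AttentionModel) -> float:
    """Predict the Berg score from exactly five view embeddings.

    At inference on a bare window (no augmentation) pass the same
    embedding five times; the head was trained on five concatenated
    views.
    """
    vecs = [e.vector if isinstance(e, Embedding) else np.asarray(e, float)
            for e in embeddings]
    if len(vecs) != N_VIEWS:
        raise SizeError(f"need exactly {N_VIEWS} embeddings, got {len(vecs)}")
    concat = np.concatenate(vecs)
    if concat.shape[0] != model.params["head_W"].shape[0]:
        raise SizeError("embedding dimension does not match the head")
    raw = float(concat @ model.params["head_W"] + model.params["head_b"][0])
    return raw * model.target_sd + model.target_mean


def predict_window(mi: ModelInput, model: AttentionModel) -> float:
    """Berg prediction for a bare window: original embedding replicated 5x."""
    emb, _ = encode(mi, model)
    return predict_berg([emb] * N_VIEWS, model)
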