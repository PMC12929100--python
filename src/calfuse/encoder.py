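"""Cross-modal transformer encoder for multimodal tabular classification.

Each modality's feature vector is embedded by a modality-specific affine map
with a tanh nonlinearity into one token of shared width h, so a sample is a
short sequence of M tokens. A learnable positional encoding identifies the
modality slots, L standard transformer layers (multi-head self-attention and
a position-wise feed-forward block, each wrapped as LayerNorm(x + sublayer(x)))
contextualise the tokens, explicit pairwise cross-modality attention
C(i→j) = softmax(H_i W_Q (H_j W_K)^T / sqrt(d_k)) H_j W_V
is added to the receiving modality's row, and the mean-pooled fused
representation feeds a linear classification head.

Dropout (inverted scaling) is active only in training mode — or during
Monte-Carlo-dropout inference, which simply reuses training mode with a
dedicated mask stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, layer_norm, log_softmax, softmax

__all__ = [
    "EncoderConfig",
    "CrossModalEncoder",
    "FusedRepresentation",
    "cross_modal_attention",
    "softmax_probs",
    "predict",
]


@dataclass(frozen=True)
class EncoderConfig:
    modality_dims: tuple
    n_classes: int
    embed_dim: int = 16
    n_layers: int = 1
    n_heads: int = 2
    key_dim: int | None = None  # default embed_dim // n_heads
    ffn_dim: int | None = None  # default 2 * embed_dim
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "modality_dims", tuple(int(d) for d in self.modality_dims))
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_layers < 1:
            raise ValueError("need at least one encoder layer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.key_dim is None:
            object.__setattr__(self, "key_dim", self.embed_dim // self.n_heads)
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 2 * self.embed_dim)

    @property
    def n_modalities(self) -> int:
        return len(self.modality_dims)


@dataclass
class FusedRepresentation:
    """Fused token matrix (M x h per sample) and its mean-pooled readout."""

    H_fused: np.ndarray  # (n, M, h)
    pooled: np.ndarray   # (n, h)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def init_params(config: EncoderConfig) -> dict:
    """Glorot-uniform weights, zero biases, unit LayerNorm gains."""
    rng = np.random.default_rng(config.seed)
    h, M, K = config.embed_dim, config.n_modalities, config.n_classes
    p: dict[str, Tensor] = {}
    for m, d in enumerate(config.modality_dims):
        p[f"emb{m}_W"] = Tensor(_glorot(rng, d, h), requires_grad=True)
        p[f"emb{m}_b"] = Tensor(np.zeros(h), requires_grad=True)
    p["pos"] = Tensor(rng.normal(0.0, 0.02, size=(M, h)), requires_grad=True)
    for l in range(config.n_layers):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"layer{l}_{name}"] = Tensor(_glorot(rng, h, h), requires_grad=True)
        p[f"layer{l}_ff_W1"] = Tensor(_glorot(rng, h, config.ffn_dim), requires_grad=True)
        p[f"layer{l}_ff_b1"] = Tensor(np.zeros(config.ffn_dim), requires_grad=True)
        p[f"layer{l}_ff_W2"] = Tensor(_glorot(rng, config.ffn_dim, h), requires_grad=True)
        p[f"layer{l}_ff_b2"] = Tensor(np.zeros(h), requires_grad=True)
        for sub in ("a", "b"):
            p[f"layer{l}_ln{sub}_g"] = Tensor(np.ones(h), requires_grad=True)
            p[f"layer{l}_ln{sub}_b"] = Tensor(np.zeros(h), requires_grad=True)
    # one shared projection set for all ordered cross-modality pairs
    for name in ("Wq", "Wk", "Wv"):
        p[f"cross_{name}"] = Tensor(_glorot(rng, h, h), requires_grad=True)
    p["head_W"] = Tensor(_glorot(rng, h, K), requires_grad=True)
    p["head_b"] = Tensor(np.zeros(K), requires_grad=True)
    return p


def _dropout(x: Tensor, rate: float, training: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not training or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout needs an explicit rng")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)  # inverted scaling
    return x * Tensor(mask)


def cross_modal_attention(H_i, H_j, W_Q, W_K, W_V, d_k: int,
                          return_weights: bool = False):
    """C(i→j): queries from modality i, keys/values from modality j.

    Accepts (.., t_i, h) and (.., t_j, h) arrays or Tensors; generic in the
    number of tokens per modality (one, in the full pipeline).
    """
    H_i, H_j = Tensor.as_tensor(H_i), Tensor.as_tensor(H_j)
    W_Q, W_K, W_V = (Tensor.as_tensor(w) for w in (W_Q, W_K, W_V))
    q = H_i @ W_Q
    k = H_j @ W_K
    v = H_j @ W_V
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    weights = softmax(scores, axis=-1)
    out = weights @ v
    if return_weights:
        return out, weights
    return out


class CrossModalEncoder:
    """Forward model over a list of per-modality feature matrices."""

    def __init__(self, config: EncoderConfig, params: dict | None = None):
        self.config = config
        self.params = params if params is not None else init_params(config)

    # -- stages ---------------------------------------------------------------
    def embed_modalities(self, features: list) -> Tensor:
        """Per-modality affine + tanh into an (n, M, h) token stack."""
        cfg = self.config
        if len(features) != cfg.n_modalities:
            raise ValueError("modality count does not match the manifest")
        toks = []
        for m, x in enumerate(features):
            x = np.asarray(x, dtype=float)
            if x.ndim == 1:
                x = x[None, :]
            if x.shape[1] != cfg.modality_dims[m]:
                raise ValueError(
                    f"modality {m}: got {x.shape[1]} features, manifest says "
                    f"{cfg.modality_dims[m]}")
            if np.isnan(x).any():
                raise ValueError("missing entries must be imputed before encoding")
            t = (Tensor(x) @ self.params[f"emb{m}_W"] + self.params[f"emb{m}_b"]).tanh()
            toks.append(t.reshape(x.shape[0], 1, cfg.embed_dim))
        # concatenate along the token axis in manifest order
        n = toks[0].shape[0]
        out = toks[0]
        for t in toks[1:]:
            out = _concat_tokens(out, t)
        return out

    def add_positional_encoding(self, H: Tensor) -> Tensor:
        return H + self.params["pos"]

    def _self_attention(self, H: Tensor, layer: int, fusion: bool,
                        record: dict | None) -> Tensor:
        cfg = self.config
        n, M, h = H.shape
        nh, dk = cfg.n_heads, cfg.embed_dim // cfg.n_heads
        p = self.params

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(n, M, nh, dk).swapaxes(1, 2)  # (n, nh, M, dk)

        q = split_heads(H @ p[f"layer{layer}_Wq"])
        k = split_heads(H @ p[f"layer{layer}_Wk"])
        v = split_heads(H @ p[f"layer{layer}_Wv"])
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
        if not fusion:
            # diagonal attention only: no cross-modality information flow
            scores = scores + Tensor(np.where(np.eye(M, dtype=bool), 0.0, -1e9))
        weights = softmax(scores, axis=-1)
        if record is not None:
            record.setdefault("self_attention", []).append(weights.data)
        out = (weights @ v).swapaxes(1, 2).reshape(n, M, h)
        return out @ p[f"layer{layer}_Wo"]

    def transformer_encode(self, H_pos: Tensor, training: bool = False,
                           rng: np.random.Generator | None = None,
                           fusion: bool = True,
                           record: dict | None = None) -> Tensor:
        cfg, p = self.config, self.params
        H = H_pos
        for l in range(cfg.n_layers):
            att = self._self_attention(H, l, fusion, record)
            att = _dropout(att, cfg.dropout_rate, training, rng)
            H = layer_norm(H + att, p[f"layer{l}_lna_g"], p[f"layer{l}_lna_b"])
            ff = ((H @ p[f"layer{l}_ff_W1"] + p[f"layer{l}_ff_b1"]).relu()
                  @ p[f"layer{l}_ff_W2"] + p[f"layer{l}_ff_b2"])
            ff = _dropout(ff, cfg.dropout_rate, training, rng)
            H = layer_norm(H + ff, p[f"layer{l}_lnb_g"], p[f"layer{l}_lnb_b"])
            if not np.all(np.isfinite(H.data)):
                raise FloatingPointError(f"non-finite activations in layer {l}")
        return H

    def fuse(self, H_L: Tensor, training: bool = False,
             rng: np.random.Generator | None = None, fusion: bool = True,
             record: dict | None = None) -> Tensor:
        """H_fused = H^L + sum over ordered pairs of C(i→j) at receiving row i."""
        cfg, p = self.config, self.params
        M = cfg.n_modalities
        if not fusion or M == 1:
            return H_L
        n, _, h = H_L.shape
        rows = []
        for i in range(M):
            H_i = _slice_token(H_L, i)  # (n, 1, h)
            acc = H_i
            for j in range(M):
                if j == i:
                    continue
                H_j = _slice_token(H_L, j)
                c, w = cross_modal_attention(
                    H_i, H_j, p["cross_Wq"], p["cross_Wk"], p["cross_Wv"],
                    cfg.key_dim, return_weights=True)
                if record is not None:
                    record.setdefault("cross_attention", {})[(i, j)] = w.data
                acc = acc + c
            rows.append(acc)
        out = rows[0]
        for r in rows[1:]:
            out = _concat_tokens(out, r)
        return _dropout(out, cfg.dropout_rate, training, rng)

    def classify(self, H_fused: Tensor) -> tuple:
        """Mean-pool tokens, apply the linear head; returns (logits, pooled)."""
        pooled = H_fused.mean(axis=1)
        logits = pooled @ self.params["head_W"] + self.params["head_b"]
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite logits")
        return logits, pooled

    # -- whole forward pass ---------------------------------------------------
    def forward(self, features: list, training: bool = False,
                rng: np.random.Generator | None = None, fusion: bool = True,
                record: dict | None = None) -> tuple:
        H = self.embed_modalities(features)
        H = self.add_positional_encoding(H)
        H = self.transformer_encode(H, training=training, rng=rng,
                                    fusion=fusion, record=record)
        H = self.fuse(H, training=training, rng=rng, fusion=fusion, record=record)
        return self.classify(H)

    def logits(self, features: list, **kw) -> np.ndarray:
        return self.forward(features, **kw)[0].data

    def predict_proba(self, features: list, **kw) -> np.ndarray:
        return softmax_probs(self.logits(features, **kw))

    def fused_representation(self, features: list, **kw) -> FusedRepresentation:
        H = self.embed_modalities(features)
        H = self.add_positional_encoding(H)
        H = self.transformer_encode(H, **kw)
        H = self.fuse(H, **kw)
        return FusedRepresentation(H_fused=H.data, pooled=H.data.mean(axis=1))


def _slice_token(H: Tensor, i: int) -> Tensor:
    """Extract token i as (n, 1, h), differentiably (selection matmul)."""
    n, M, h = H.shape
    sel = np.zeros((1, M))
    sel[0, i] = 1.0
    return Tensor(sel) @ H  # (1, M) @ (n, M, h) broadcasts to (n, 1, h)


def _concat_tokens(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the token axis via block placement matrices."""
    ta, tb = a.shape[1], b.shape[1]
    Ea = np.zeros((ta + tb, ta))
    Ea[np.arange(ta), np.arange(ta)] = 1.0
    Eb = np.zeros((ta + tb, tb))
    Eb[ta + np.arange(tb), np.arange(tb)] = 1.0
    return Tensor(Ea) @ a + Tensor(Eb) @ b


# ---------------------------------------------------------------------------
# prediction utilities (plain numpy; used on detached logits)
# ---------------------------------------------------------------------------

def softmax_probs(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite logits")
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def predict(z: np.ndarray) -> tuple:
    """(probabilities, hard labels); argmax ties break toward the lowest class."""
    p = softmax_probs(z)
    return p, np.argmax(p, axis=-1)
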