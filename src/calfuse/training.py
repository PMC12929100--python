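"""Imbalance-aware supervised training of the cross-modal encoder.

The objective is weighted cross-entropy with inverse-frequency class weights
w_k = N / (K · N_k) (all-ones on balanced data), optionally augmented with a
squared-norm penalty on the pooled fused representation. Optimisation is Adam
with L2 weight decay, mini-batches reshuffled per epoch from a dedicated
generator, and early stopping on validation loss with a patience window; the
parameters of the best validation epoch are returned. With fixed seeds the
loss curves are reproducible to machine precision on one device.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, log_softmax
from .encoder import CrossModalEncoder, EncoderConfig, init_params
from .synthetic import DatasetBundle

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "class_weights",
    "weighted_cross_entropy",
    "scale_regularizer",
    "fit",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    max_epochs: int = 30
    batch_size: int = 32
    patience: int = 10
    lambda_scale: float = 0.0   # pooled-representation norm penalty; 0 = off
    use_scale_reg: bool = False
    gamma_imb: float = 0.0      # reserved imbalance-loss coefficient (inactive)
    beta_unc: float = 0.0       # reserved uncertainty-loss coefficient (inactive)
    seed: int = 0

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        for name in ("lambda_scale", "gamma_imb", "beta_unc", "weight_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class TrainedModel:
    encoder: CrossModalEncoder
    class_weights: np.ndarray
    train_curve: list
    val_curve: list
    best_epoch: int
    encoder_config: EncoderConfig
    train_config: TrainConfig
    fusion: bool = True
    train_class_counts: np.ndarray | None = None

    def predict_proba(self, features: list, **kw) -> np.ndarray:
        return self.encoder.predict_proba(features, fusion=self.fusion, **kw)

    def logits(self, features: list, **kw) -> np.ndarray:
        return self.encoder.logits(features, fusion=self.fusion, **kw)


def class_weights(class_counts) -> np.ndarray:
    """Inverse-frequency weights w_k = N / (K · N_k); all-ones when balanced."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("cannot weight a class with zero samples")
    return counts.sum() / (len(counts) * counts)


def weighted_cross_entropy(probs, labels, weights=None) -> float:
    """Mean over the batch of −w_y · log p_y (plain CE when weights are 1)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true <= _PROB_FLOOR):
        logger.warning("probability at true class clamped to %.0e for %d samples",
                       _PROB_FLOOR, int((p_true <= _PROB_FLOOR).sum()))
        p_true = np.clip(p_true, _PROB_FLOOR, None)
    w = np.ones(probs.shape[1]) if weights is None else np.asarray(weights, float)
    return float(np.mean(-w[labels] * np.log(p_true)))


def scale_regularizer(pooled, lambda_scale: float) -> float:
    """λ · mean over the batch of the squared norm of the pooled representation."""
    if lambda_scale < 0:
        raise ValueError("lambda_scale must be nonnegative")
    pooled = np.atleast_2d(np.asarray(pooled, dtype=float))
    return float(lambda_scale * np.mean(np.sum(pooled ** 2, axis=1)))


class _Adam:
    def __init__(self, params: dict, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def _batch_loss(model: CrossModalEncoder, X: list, y: np.ndarray,
                w: np.ndarray, cfg: TrainConfig, training: bool,
                rng: np.random.Generator | None) -> Tensor:
    """Differentiable weighted CE (log-softmax form) + optional norm penalty."""
    H = model.embed_modalities(X)
    H = model.add_positional_encoding(H)
    H = model.transformer_encode(H, training=training, rng=rng,
                                 fusion=getattr(model, "_fusion", True))
    H = model.fuse(H, training=training, rng=rng,
                   fusion=getattr(model, "_fusion", True))
    logits, pooled = model.classify(H)
    logp = log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(y)), y] = 1.0
    weight_col = Tensor(w[y][:, None])
    loss = -(logp * Tensor(onehot) * weight_col).sum(axis=-1).mean()
    if cfg.use_scale_reg and cfg.lambda_scale > 0:
        loss = loss + cfg.lambda_scale * (pooled ** 2).sum(axis=-1).mean()
    return loss


def fit(bundle: DatasetBundle, encoder_config: EncoderConfig,
        train_config: TrainConfig, fusion: bool = True,
        use_class_weights: bool = True) -> TrainedModel:
    """Train on the bundle's train split, early-stop on its validation split."""
    if bundle.has_missing():
        raise ValueError("bundle contains missing entries; impute() first")
    X_train, y_train = bundle.split_arrays("train")
    X_val, y_val = bundle.split_arrays("val")
    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("train and validation splits must both be non-empty")

    counts = np.bincount(y_train, minlength=encoder_config.n_classes)
    w = class_weights(np.maximum(counts, 1)) if use_class_weights \
        else np.ones(encoder_config.n_classes)

    model = CrossModalEncoder(encoder_config)
    model._fusion = fusion
    opt = _Adam(model.params, train_config.learning_rate, train_config.weight_decay)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([train_config.seed, 101]))
    drop_rng = np.random.default_rng(
        np.random.SeedSequence([train_config.seed, 202]))

    n = len(y_train)
    train_curve, val_curve = [], []
    best_val, best_epoch, best_params = np.inf, -1, None
    stale = 0
    for epoch in range(train_config.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            opt.zero_grad()
            loss = _batch_loss(model, [x[idx] for x in X_train], y_train[idx],
                               w, train_config, True, drop_rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_curve.append(epoch_loss / n_batches)

        val_loss = float(_batch_loss(model, X_val, y_val, w, train_config,
                                     False, None).data)
        val_curve.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val, best_epoch = val_loss, epoch
            best_params = {k: Tensor(v.data.copy(), requires_grad=True)
                           for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= train_config.patience:
                break

    model.params = best_params if best_params is not None else model.params
    return TrainedModel(
        encoder=model,
        class_weights=w,
        train_curve=train_curve,
        val_curve=val_curve,
        best_epoch=best_epoch,
        encoder_config=encoder_config,
        train_config=train_config,
        fusion=fusion,
        train_class_counts=counts,
    )
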