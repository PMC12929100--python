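"""Epistemic uncertainty via Monte-Carlo dropout.

Dropout stays active at inference and each stochastic forward pass samples
fresh inverted-dropout Bernoulli masks, so the expectation over passes matches
the deterministic forward pass. The predictive mean is the average of the
per-pass softmax outputs; the scalar uncertainty u is the mean over classes of
the per-class variance of the per-pass probabilities — bounded, in probability
space, and comparable across models.

Each sample's mask stream is derived from (seed, sample_id), so per-sample
results do not depend on batch composition or ordering.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .encoder import softmax_probs
from .synthetic import DatasetBundle
from .training import TrainedModel

__all__ = ["UncertaintyEstimate", "mc_dropout_predict", "batch_uncertainty",
           "inverted_dropout"]


@dataclass
class UncertaintyEstimate:
    sample_id: str
    mean_probs: np.ndarray     # length K, mean of per-pass softmax outputs
    class_variance: np.ndarray  # length K, per-class variance over passes
    u: float                   # mean of class_variance
    n_passes: int
    seed: int


def inverted_dropout(x: np.ndarray, p_drop: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Bernoulli mask then rescale by 1/(1−p): expectation equals the input."""
    if not 0.0 <= p_drop < 1.0:
        raise ValueError("p_drop must be in [0, 1)")
    if p_drop == 0.0:
        return np.asarray(x, dtype=float)
    mask = rng.random(np.shape(x)) >= p_drop
    return np.asarray(x, dtype=float) * mask / (1.0 - p_drop)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # stable per-sample stream, independent of batch position
    key = zlib.crc32(str(sample_id).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def mc_dropout_predict(model: TrainedModel, features: list, n_passes: int,
                       seed: int, sample_id: str = "S0") -> UncertaintyEstimate:
    """Uncertainty estimate for one sample (list of M per-modality vectors)."""
    if n_passes < 2:
        raise ValueError("n_passes must be >= 2 (variance undefined otherwise)")
    # tile the sample across the batch axis: each row draws its own masks
    tiled = [np.tile(np.asarray(x, dtype=float)[None, :], (n_passes, 1))
             for x in features]
    rng = _sample_rng(seed, sample_id)
    logits = model.logits(tiled, training=True, rng=rng)
    probs = softmax_probs(logits)  # (n_passes, K)
    mean_probs = probs.mean(axis=0)
    class_var = probs.var(axis=0)  # population variance over passes
    return UncertaintyEstimate(
        sample_id=str(sample_id),
        mean_probs=mean_probs,
        class_variance=class_var,
        u=float(class_var.mean()),
        n_passes=n_passes,
        seed=seed,
    )


def batch_uncertainty(model: TrainedModel, features: list, n_passes: int,
                      seed: int, sample_ids: list | None = None) -> list:
    """Per-sample estimates for a batch (list of M (n, d_m) matrices)."""
    n = np.asarray(features[0]).shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i:06d}" for i in range(n)]
    return [
        mc_dropout_predict(model, [np.asarray(x)[i] for x in features],
                           n_passes, seed, sample_ids[i])
        for i in range(n)
    ]


def bundle_uncertainty(model: TrainedModel, bundle: DatasetBundle,
                       split: str, n_passes: int, seed: int) -> list:
    mask = bundle.mask(split)
    ids = [sid for sid, m in zip(bundle.sample_ids, mask) if m]
    X = [x[mask] for x in bundle.features]
    return batch_uncertainty(model, X, n_passes, seed, ids)


def uncertainty_vector(estimates: list) -> np.ndarray:
    return np.array([e.u for e in estimates])


def mean_probs_matrix(estimates: list) -> np.ndarray:
    return np.vstack([e.mean_probs for e in estimates])
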