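"""Domain-aware post-hoc calibration of classifier logits.

Three stages are applied in a fixed order, each fitted on the validation
split only and then applied to held-out logits:

1. class-conditioned temperature scaling — each logit is divided by its own
   class temperature T_k (a global scalar temperature is the special case of
   equal entries); temperatures minimise validation NLL.
2. uncertainty modulation — the scaled logits are shrunk by 1/(1 + γ_u·u)
   where u is the per-sample Monte-Carlo-dropout uncertainty, flattening the
   softmax for uncertain samples while preserving the argmax; γ_u is chosen on
   a logarithmic validation-NLL grid.
3. prior injection — expert per-class prior probabilities π are smoothed
   against the empirical training frequencies π̂ (convex combination with
   coefficient β), converted to log-odds δ_k = log(π̃_k/(1−π̃_k)), and added to
   the logits with weight λ_prior, also chosen by validation NLL.

The final probabilities are the softmax of the adjusted logits. Each π_k is
treated as a marginal per-class prevalence; no sum-to-one constraint is
imposed on the expert prior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .encoder import softmax_probs

__all__ = [
    "CalibrationParams",
    "CalibratedOutput",
    "T_MIN",
    "T_MAX",
    "temperature_scale",
    "fit_temperatures",
    "uncertainty_adjust",
    "log_odds",
    "smooth_prior",
    "empirical_prior",
    "adjust_logits",
    "calibrated_probs",
    "fit_calibration",
    "calibrate_pipeline",
    "nll",
]

T_MIN, T_MAX = 0.05, 20.0
GAMMA_U_GRID = (0.0, 0.1, 1.0, 10.0, 100.0)
LAMBDA_PRIOR_GRID = (0.0, 0.25, 0.5, 1.0, 2.0)


@dataclass
class CalibrationParams:
    T: np.ndarray                  # per-class temperatures in [T_MIN, T_MAX]
    gamma_u: float = 0.0           # uncertainty modulation weight
    lambda_prior: float = 0.0      # prior injection weight
    beta: float = 0.5              # prior smoothing coefficient
    pi: np.ndarray | None = None       # expert prior, entries in (0,1)
    pi_hat: np.ndarray | None = None   # empirical train frequencies (smoothed)
    pi_tilde: np.ndarray | None = None
    delta: np.ndarray | None = None    # log-odds of pi_tilde
    fitted: bool = False
    fit_split: str = "val"

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        if np.any(self.T < T_MIN - 1e-12) or np.any(self.T > T_MAX + 1e-12):
            raise ValueError(f"temperatures must lie in [{T_MIN}, {T_MAX}]")
        if self.gamma_u < 0 or self.lambda_prior < 0:
            raise ValueError("gamma_u and lambda_prior must be nonnegative")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")

    def to_json(self, path) -> None:
        d = {
            "version": 1,
            "T": self.T.tolist(),
            "gamma_u": self.gamma_u,
            "lambda_prior": self.lambda_prior,
            "beta": self.beta,
            "pi": None if self.pi is None else np.asarray(self.pi).tolist(),
            "pi_hat": None if self.pi_hat is None else np.asarray(self.pi_hat).tolist(),
            "pi_tilde": None if self.pi_tilde is None else np.asarray(self.pi_tilde).tolist(),
            "delta": None if self.delta is None else np.asarray(self.delta).tolist(),
            "fitted": self.fitted,
            "fit_split": self.fit_split,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "CalibrationParams":
        d = json.loads(Path(path).read_text())
        arr = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(T=arr(d["T"]), gamma_u=d["gamma_u"],
                   lambda_prior=d["lambda_prior"], beta=d["beta"],
                   pi=arr(d["pi"]), pi_hat=arr(d["pi_hat"]),
                   pi_tilde=arr(d["pi_tilde"]), delta=arr(d["delta"]),
                   fitted=d["fitted"], fit_split=d["fit_split"])


@dataclass
class CalibratedOutput:
    probs: np.ndarray            # final p̂, rows sum to 1
    raw_logits: np.ndarray
    temperature_scaled: np.ndarray
    uncertainty_adjusted: np.ndarray
    prior_adjusted: np.ndarray
    stages: tuple = ("raw", "temperature", "uncertainty", "prior", "softmax")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def temperature_scale(logits, T):
    """Divide each class logit by its own temperature; returns (logits, probs)."""
    T = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    scaled = np.asarray(logits, dtype=float) / T
    return scaled, softmax_probs(scaled)


def nll(logits, labels) -> float:
    """Mean negative log-likelihood of labels under softmax(logits)."""
    logits = np.asarray(logits, dtype=float)
    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1))
    return float(np.mean(logz - shifted[np.arange(len(labels)), labels]))


def _fit_global_T(logits, labels) -> float:
    res = minimize_scalar(lambda t: nll(logits / t, labels),
                          bounds=(T_MIN, T_MAX), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def _coordinate_descent(logits, labels, T0, tol=1e-4, max_sweeps=50):
    """Per-class coordinate descent on validation NLL, accept-if-improves."""
    K = logits.shape[1]
    T = np.asarray(T0, dtype=float).copy()
    best = nll(logits / T, labels)
    for _ in range(max_sweeps):
        max_change = 0.0
        for k in range(K):
            def obj(t, k=k):
                Tk = T.copy()
                Tk[k] = t
                return nll(logits / Tk, labels)
            res = minimize_scalar(obj, bounds=(T_MIN, T_MAX), method="bounded",
                                  options={"xatol": 1e-5})
            if res.fun < best - 1e-12:
                max_change = max(max_change, abs(float(res.x) - T[k]))
                T[k] = float(res.x)
                best = float(res.fun)
        if max_change < tol:
            break
    return T, best


def fit_temperatures(val_logits, val_labels, mode: str = "global") -> np.ndarray:
    """NLL-minimising temperatures on the validation split.

    global: one bounded scalar fit, broadcast to all classes. per_class:
    coordinate descent started from both all-ones and the global solution,
    keeping the better endpoint — this guarantees the per-class fit never does
    worse than the global one on the fitting split.
    """
    logits = np.asarray(val_logits, dtype=float)
    labels = np.asarray(val_labels)
    K = logits.shape[1]
    if mode == "global":
        return np.full(K, _fit_global_T(logits, labels))
    if mode != "per_class":
        raise ValueError("mode must be 'global' or 'per_class'")
    present = np.unique(labels)
    if len(present) < K:
        raise ValueError("per-class fitting requires every class in validation")
    t_global = _fit_global_T(logits, labels)
    cand = [
        _coordinate_descent(logits, labels, np.ones(K)),
        _coordinate_descent(logits, labels, np.full(K, t_global)),
    ]
    cand.append((np.full(K, t_global), nll(logits / t_global, labels)))
    return min(cand, key=lambda c: c[1])[0]


def uncertainty_adjust(scaled_logits, u, gamma_u: float) -> np.ndarray:
    """Shrink logits by 1/(1+γ_u·u): flattens with uncertainty, keeps argmax."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("uncertainty must be nonnegative")
    if gamma_u < 0:
        raise ValueError("gamma_u must be nonnegative")
    scaled = np.asarray(scaled_logits, dtype=float)
    denom = 1.0 + gamma_u * u
    return scaled / (denom[:, None] if denom.ndim == 1 and scaled.ndim == 2 else denom)


def log_odds(pi_tilde) -> np.ndarray:
    """δ_k = log(π̃_k / (1 − π̃_k)); requires entries strictly inside (0,1)."""
    p = np.asarray(pi_tilde, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("prior entries must lie strictly in (0, 1)")
    return np.log(p / (1.0 - p))


def smooth_prior(pi, pi_hat, beta: float) -> np.ndarray:
    """Convex combination β·π + (1−β)·π̂."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    return beta * np.asarray(pi, dtype=float) + (1.0 - beta) * np.asarray(pi_hat, dtype=float)


def empirical_prior(train_class_counts) -> np.ndarray:
    """Add-one-smoothed class frequencies; entries strictly inside (0,1)."""
    counts = np.asarray(train_class_counts, dtype=float)
    return (counts + 1.0) / (counts.sum() + len(counts))


def adjust_logits(z_tilde, delta, lambda_prior: float) -> np.ndarray:
    """ẑ_k = z̃_k + λ_prior · δ_k."""
    if lambda_prior < 0:
        raise ValueError("lambda_prior must be nonnegative")
    return np.asarray(z_tilde, dtype=float) + lambda_prior * np.asarray(delta, dtype=float)


def calibrated_probs(z_hat) -> np.ndarray:
    return softmax_probs(z_hat)


# ---------------------------------------------------------------------------
# fitting and full pipeline
# ---------------------------------------------------------------------------

def fit_calibration(val_logits, val_labels, u_val=None, expert_prior=None,
                    train_class_counts=None, beta: float = 0.5,
                    temperature_mode: str = "per_class",
                    gamma_grid=GAMMA_U_GRID,
                    lambda_grid=LAMBDA_PRIOR_GRID) -> CalibrationParams:
    """Fit all three stages sequentially on the validation split.

    Temperatures first; then γ_u over its grid (needs u_val); then λ_prior
    over its grid (needs expert_prior and train_class_counts). Stages whose
    inputs are absent stay at their identity settings.
    """
    val_logits = np.asarray(val_logits, dtype=float)
    val_labels = np.asarray(val_labels)
    if len(val_labels) == 0:
        raise ValueError("calibration fitting requires a non-empty validation split")

    T = fit_temperatures(val_logits, val_labels, mode=temperature_mode)
    scaled, _ = temperature_scale(val_logits, T)

    gamma_u = 0.0
    if u_val is not None:
        u_val = np.asarray(u_val, dtype=float)
        gamma_u = min(gamma_grid,
                      key=lambda g: nll(uncertainty_adjust(scaled, u_val, g),
                                        val_labels))
    z_tilde = uncertainty_adjust(scaled, u_val, gamma_u) if u_val is not None else scaled

    lambda_prior, pi, pi_hat, pi_tilde, delta = 0.0, None, None, None, None
    if expert_prior is not None:
        if train_class_counts is None:
            raise ValueError("prior injection needs the training class counts")
        pi = np.asarray(expert_prior, dtype=float)
        pi_hat = empirical_prior(train_class_counts)
        pi_tilde = smooth_prior(pi, pi_hat, beta)
        delta = log_odds(pi_tilde)
        lambda_prior = min(lambda_grid,
                           key=lambda lam: nll(adjust_logits(z_tilde, delta, lam),
                                               val_labels))
    return CalibrationParams(T=T, gamma_u=gamma_u, lambda_prior=lambda_prior,
                             beta=beta, pi=pi, pi_hat=pi_hat,
                             pi_tilde=pi_tilde, delta=delta, fitted=True)


def calibrate_pipeline(logits, u, params: CalibrationParams) -> CalibratedOutput:
    """Apply raw → temperature → uncertainty → prior → softmax, keeping stages."""
    if not params.fitted:
        raise ValueError("calibration parameters have not been fitted")
    logits = np.asarray(logits, dtype=float)
    scaled, _ = temperature_scale(logits, params.T)
    if u is None:
        u = np.zeros(len(logits))
    z_tilde = uncertainty_adjust(scaled, u, params.gamma_u)
    delta = params.delta if params.delta is not None else np.zeros(logits.shape[1])
    z_hat = adjust_logits(z_tilde, delta, params.lambda_prior)
    return CalibratedOutput(
        probs=calibrated_probs(z_hat),
        raw_logits=logits,
        temperature_scaled=scaled,
        uncertainty_adjusted=z_tilde,
        prior_adjusted=z_hat,
    )
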