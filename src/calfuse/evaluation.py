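"""Discrimination and calibration metrics, paired significance tests, and the
component ablation harness.

Discrimination metrics are macro-averaged over classes (one-vs-rest for AUC);
calibration is summarised by expected/maximum calibration error over 15
equal-width confidence bins, with NLL and the multiclass Brier score reported
alongside. Paired comparisons use the two-sided paired t-test and the Wilcoxon
signed-rank test (exact null distribution for n ≤ 25); identical runs — zero
variance of the differences — return p = 1.0 for both by convention so ablation
tables never crash on degenerate pairings.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (confusion_matrix, f1_score, precision_score,
                             recall_score, roc_auc_score)

from . import calibration, synthetic, training, uncertainty
from .encoder import EncoderConfig

__all__ = [
    "EvalReport",
    "ComparisonResult",
    "AblationFlags",
    "classification_metrics",
    "expected_calibration_error",
    "maximum_calibration_error",
    "brier_score",
    "reliability_table",
    "paired_tests",
    "ablation_run",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    accuracy: float
    macro_recall: float
    macro_f1: float
    macro_auc: float
    nll: float
    brier: float
    ece: float
    mce: float
    confusion: np.ndarray
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    n_samples: int

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("accuracy", "macro_recall", "macro_f1", "macro_auc",
              "nll", "brier", "ece", "mce", "n_samples")}
        d["confusion"] = self.confusion.tolist()
        d["per_class_precision"] = self.per_class_precision.tolist()
        d["per_class_recall"] = self.per_class_recall.tolist()
        d["per_class_f1"] = self.per_class_f1.tolist()
        return d


@dataclass
class ComparisonResult:
    values_a: np.ndarray
    values_b: np.ndarray
    mean_difference: float
    t_pvalue: float
    wilcoxon_pvalue: float


def classification_metrics(probs, labels) -> EvalReport:
    """Full report from normalised probabilities and integer labels."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    K = probs.shape[1]
    hard = np.argmax(probs, axis=1)  # ties break toward the lowest class index
    class_range = np.arange(K)

    aucs = []
    for k in class_range:
        mask = labels == k
        if mask.all() or not mask.any():
            logger.warning("class %d absent from labels; excluded from macro AUC", k)
            continue
        aucs.append(roc_auc_score(mask.astype(int), probs[:, k]))

    labels_onehot = np.zeros_like(probs)
    labels_onehot[np.arange(len(labels)), labels] = 1.0
    return EvalReport(
        accuracy=float(np.mean(hard == labels)),
        macro_recall=float(recall_score(labels, hard, labels=class_range,
                                        average="macro", zero_division=0)),
        macro_f1=float(f1_score(labels, hard, labels=class_range,
                                average="macro", zero_division=0)),
        macro_auc=float(np.mean(aucs)) if aucs else float("nan"),
        nll=calibration.nll(np.log(np.clip(probs, 1e-300, None)), labels),
        brier=brier_score(probs, labels),
        ece=expected_calibration_error(probs, labels),
        mce=maximum_calibration_error(probs, labels),
        confusion=confusion_matrix(labels, hard, labels=class_range),
        per_class_precision=precision_score(labels, hard, labels=class_range,
                                            average=None, zero_division=0),
        per_class_recall=recall_score(labels, hard, labels=class_range,
                                      average=None, zero_division=0),
        per_class_f1=f1_score(labels, hard, labels=class_range,
                              average=None, zero_division=0),
        n_samples=len(labels),
    )


def _bin_stats(probs, labels, n_bins):
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    conf = probs.max(axis=1)
    correct = probs.argmax(axis=1) == labels
    # equal-width bins on [0, 1]; right-closed so confidence 1.0 lands in the top bin
    idx = np.minimum((conf * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    conf_sum = np.bincount(idx, weights=conf, minlength=n_bins)
    acc_sum = np.bincount(idx, weights=correct.astype(float), minlength=n_bins)
    return counts, conf_sum, acc_sum


def expected_calibration_error(probs, labels, n_bins: int = 15) -> float:
    """Σ_b (n_b/n)·|acc_b − conf_b| over equal-width confidence bins."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, conf_sum, acc_sum = _bin_stats(probs, labels, n_bins)
    n = counts.sum()
    nz = counts > 0
    gaps = np.abs(acc_sum[nz] / counts[nz] - conf_sum[nz] / counts[nz])
    return float(np.sum(counts[nz] / n * gaps))


def maximum_calibration_error(probs, labels, n_bins: int = 15) -> float:
    counts, conf_sum, acc_sum = _bin_stats(probs, labels, n_bins)
    nz = counts > 0
    if not nz.any():
        return 0.0
    return float(np.max(np.abs(acc_sum[nz] / counts[nz] - conf_sum[nz] / counts[nz])))


def brier_score(probs, labels) -> float:
    """Multiclass Brier score: mean squared distance to the one-hot label."""
    probs = np.asarray(probs, dtype=float)
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(labels)), np.asarray(labels)] = 1.0
    return float(np.mean(np.sum((probs - onehot) ** 2, axis=1)))


def reliability_table(probs, labels, n_bins: int = 15) -> pd.DataFrame:
    counts, conf_sum, acc_sum = _bin_stats(probs, labels, n_bins)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    with np.errstate(invalid="ignore"):
        return pd.DataFrame({
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "mean_confidence": np.where(counts > 0, conf_sum / np.maximum(counts, 1), np.nan),
            "accuracy": np.where(counts > 0, acc_sum / np.maximum(counts, 1), np.nan),
        })


def paired_tests(metric_runs_a, metric_runs_b) -> ComparisonResult:
    """Two-sided paired t-test and Wilcoxon signed-rank on aligned run vectors."""
    a = np.asarray(metric_runs_a, dtype=float)
    b = np.asarray(metric_runs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired runs must be equal-length 1-D vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 paired runs")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        # degenerate zero-variance pairing: no evidence of a difference
        return ComparisonResult(a, b, 0.0, 1.0, 1.0)
    t_p = float(stats.ttest_rel(a, b).pvalue)
    nonzero = diffs[diffs != 0]
    method = "exact" if len(nonzero) <= 25 else "auto"
    w_p = float(stats.wilcoxon(nonzero, method=method,
                               alternative="two-sided").pvalue)
    return ComparisonResult(a, b, float(diffs.mean()), t_p, w_p)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AblationFlags:
    fusion: bool = True              # cross-modal information flow
    uncertainty_adjust: bool = True  # DACS stage 2
    prior_injection: bool = True     # DACS stage 3
    class_weighting: bool = True     # inverse-frequency CE weights


def run_pipeline(bundle: synthetic.DatasetBundle,
                 encoder_config: EncoderConfig,
                 train_config: training.TrainConfig,
                 flags: AblationFlags = AblationFlags(),
                 expert_prior=None, beta: float = 0.5,
                 n_passes: int = 30,
                 temperature_mode: str = "per_class") -> tuple:
    """One full train → uncertainty → calibrate → evaluate cycle.

    Returns (EvalReport on the test split, TrainedModel, CalibrationParams).
    """
    if bundle.has_missing():
        bundle = synthetic.impute(bundle)
    model = training.fit(bundle, encoder_config, train_config,
                         fusion=flags.fusion,
                         use_class_weights=flags.class_weighting)
    X_val, y_val = bundle.split_arrays("val")
    X_test, y_test = bundle.split_arrays("test")
    val_logits = model.logits(X_val)
    test_logits = model.logits(X_test)

    u_val = u_test = None
    if flags.uncertainty_adjust:
        seed = train_config.seed
        u_val = uncertainty.uncertainty_vector(
            uncertainty.bundle_uncertainty(model, bundle, "val", n_passes, seed))
        u_test = uncertainty.uncertainty_vector(
            uncertainty.bundle_uncertainty(model, bundle, "test", n_passes, seed))

    prior = np.asarray(expert_prior, dtype=float) if (
        flags.prior_injection and expert_prior is not None) else None
    params = calibration.fit_calibration(
        val_logits, y_val, u_val=u_val, expert_prior=prior,
        train_class_counts=model.train_class_counts, beta=beta,
        temperature_mode=temperature_mode)
    out = calibration.calibrate_pipeline(test_logits, u_test, params)
    return classification_metrics(out.probs, y_test), model, params


def ablation_run(bundle: synthetic.DatasetBundle,
                 encoder_config: EncoderConfig,
                 train_config: training.TrainConfig,
                 flag_configs: list,
                 seeds: list,
                 expert_prior=None, n_passes: int = 30) -> pd.DataFrame:
    """One train+calibrate+evaluate cycle per flag configuration per seed."""
    rows = []
    for flags, seed in itertools.product(flag_configs, seeds):
        cfg = training.TrainConfig(**{**train_config.__dict__, "seed": seed})
        report, _, _ = run_pipeline(bundle, encoder_config, cfg, flags,
                                    expert_prior=expert_prior, n_passes=n_passes)
        row = {"seed": seed, **flags.__dict__, **{
            k: v for k, v in report.to_dict().items()
            if not isinstance(v, list)}}
        rows.append(row)
    return pd.DataFrame(rows)
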