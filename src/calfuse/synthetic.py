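"""Synthetic multimodal classification data with known ground truth.

The generator realises the data-quality pathologies that motivate the rest of
the package: class imbalance (controlled through exact class proportions),
label noise (a row-stochastic transition matrix acting on true labels),
missing-completely-at-random feature entries, and cross-modal structure — a
shared latent factor coupling the modalities, or an interaction labelling mode
in which the class is a sign-product of two modalities' leading coordinates so
that no single modality carries any marginal signal.

Class-conditional features are Gaussian with unit within-class scale; the
separation parameter is the Euclidean distance between class means measured in
within-class standard deviations. All randomness flows from one integer seed
through named per-stage generators (labels, features, coupling, noise,
missingness, split) so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "MultimodalSample",
    "DatasetBundle",
    "generate_dataset",
    "imbalance_ratio",
    "apply_label_noise",
    "apply_missingness",
    "impute",
    "largest_remainder_counts",
    "binary_gaussian_logits",
    "write_bundle",
    "read_bundle",
]

# fixed sub-stream codes so every stage has its own reproducible generator
_STAGES = {"labels": 0, "features": 1, "coupling": 2, "noise": 3,
           "missing": 4, "split": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative description of one synthetic dataset."""

    n_samples: int
    n_classes: int
    class_proportions: tuple = ()
    modality_dims: tuple = (8, 8)
    class_separation: float = 2.0
    cross_modal_coupling: float = 0.0
    interaction_label_mode: bool = False
    label_noise_matrix: tuple | None = None  # K x K row-stochastic, or None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        props = self.class_proportions or tuple([1.0 / self.n_classes] * self.n_classes)
        object.__setattr__(self, "class_proportions", tuple(float(p) for p in props))
        object.__setattr__(self, "modality_dims", tuple(int(d) for d in self.modality_dims))
        if len(self.class_proportions) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if any(d < 1 for d in self.modality_dims):
            raise ValueError("modality dims must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")
        if not 0.0 <= self.cross_modal_coupling <= 1.0:
            raise ValueError("cross_modal_coupling must be in [0, 1]")
        if self.n_samples < self.n_classes:
            raise ValueError("fewer samples than classes")
        if self.interaction_label_mode:
            if self.n_classes != 2 or len(self.modality_dims) < 2:
                raise ValueError("interaction labelling needs K=2 and >=2 modalities")
        if self.label_noise_matrix is not None:
            eta = np.asarray(self.label_noise_matrix, dtype=float)
            if eta.shape != (self.n_classes, self.n_classes):
                raise ValueError("label noise matrix must be K x K")
            _check_row_stochastic(eta)
            object.__setattr__(self, "label_noise_matrix",
                               tuple(tuple(row) for row in eta))

    @property
    def n_modalities(self) -> int:
        return len(self.modality_dims)


def _check_row_stochastic(eta: np.ndarray) -> None:
    if np.any(eta < 0):
        raise ValueError("transition matrix entries must be nonnegative")
    if np.max(np.abs(eta.sum(axis=1) - 1.0)) > 1e-9:
        raise ValueError("transition matrix rows must sum to 1")


@dataclass
class MultimodalSample:
    sample_id: str
    features: list  # list of M float vectors
    missing_flags: list  # list of M bool vectors
    observed_label: int
    true_label: int


@dataclass
class DatasetBundle:
    """Column-major container: one (n, d_m) matrix per modality.

    Missing entries are stored as NaN with an aligned boolean flag so that any
    accidental use before imputation propagates loudly.
    """

    features: list  # M arrays, each (n, d_m)
    missing_flags: list  # M bool arrays, each (n, d_m)
    true_labels: np.ndarray
    observed_labels: np.ndarray
    split: np.ndarray  # per-sample tag in {train, val, test}
    sample_ids: list
    manifest: dict

    @property
    def n_samples(self) -> int:
        return len(self.observed_labels)

    @property
    def n_classes(self) -> int:
        return int(self.manifest["n_classes"])

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.observed_labels, minlength=self.n_classes)

    def mask(self, split: str) -> np.ndarray:
        return self.split == split

    def split_arrays(self, split: str):
        """(list of per-modality matrices, observed labels) for one split."""
        m = self.mask(split)
        return [x[m] for x in self.features], self.observed_labels[m]

    @property
    def samples(self) -> list:
        return [
            MultimodalSample(
                sample_id=self.sample_ids[i],
                features=[x[i] for x in self.features],
                missing_flags=[f[i] for f in self.missing_flags],
                observed_label=int(self.observed_labels[i]),
                true_label=int(self.true_labels[i]),
            )
            for i in range(self.n_samples)
        ]

    def has_missing(self) -> bool:
        return any(f.any() for f in self.missing_flags)

    def copy(self) -> "DatasetBundle":
        return DatasetBundle(
            features=[x.copy() for x in self.features],
            missing_flags=[f.copy() for f in self.missing_flags],
            true_labels=self.true_labels.copy(),
            observed_labels=self.observed_labels.copy(),
            split=self.split.copy(),
            sample_ids=list(self.sample_ids),
            manifest=json.loads(json.dumps(self.manifest)),
        )


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def largest_remainder_counts(n: int, proportions) -> np.ndarray:
    """Deterministic apportionment of n by proportions; sums to n exactly.

    Remainder ties go to the lower class index.
    """
    props = np.asarray(proportions, dtype=float)
    quotas = props * n
    counts = np.floor(quotas).astype(int)
    remainder = quotas - counts
    short = n - counts.sum()
    # stable sort: descending remainder, ties broken toward lower index
    order = np.lexsort((np.arange(len(props)), -remainder))
    counts[order[:short]] += 1
    return counts


def imbalance_ratio(class_counts) -> float:
    """max_k N_k / min_k N_k; undefined when any class is empty."""
    counts = np.asarray(class_counts)
    if np.any(counts < 1):
        raise ValueError("degenerate class with zero samples: imbalance ratio undefined")
    return float(counts.max() / counts.min())


def apply_label_noise(labels: np.ndarray, eta, seed_or_rng) -> np.ndarray:
    """Draw each observed label from eta's row indexed by the true label."""
    eta = np.asarray(eta, dtype=float)
    _check_row_stochastic(eta)
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    labels = np.asarray(labels)
    cdf = np.cumsum(eta, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(labels.shape[0])
    return (u[:, None] > cdf[labels]).sum(axis=1).astype(labels.dtype)


def _class_means(K: int, d: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """Class-mean layout with pairwise distance = separation (exact for K=2 or d>=K)."""
    if K == 2:
        mu = np.zeros((2, d))
        mu[0, 0] = -separation / 2.0
        mu[1, 0] = +separation / 2.0
        return mu
    if d >= K:
        return np.eye(K, d) * (separation / np.sqrt(2.0))
    # fallback: random unit directions; distances approximate
    dirs = rng.standard_normal((K, d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs * (separation / np.sqrt(2.0))


def generate_dataset(spec: SyntheticSpec,
                     split_fractions=(0.6, 0.2, 0.2)) -> DatasetBundle:
    """Generate a full bundle; identical spec reproduces it bit-identically."""
    n, K, M = spec.n_samples, spec.n_classes, spec.n_modalities
    feat_rng = _rng(spec.seed, "features")

    if spec.interaction_label_mode:
        features = [feat_rng.standard_normal((n, d)) for d in spec.modality_dims]
        if spec.cross_modal_coupling > 0:
            z = _rng(spec.seed, "coupling").standard_normal(n)
            features = [x + spec.cross_modal_coupling * z[:, None] for x in features]
        true = (features[0][:, 0] * features[1][:, 0] > 0).astype(np.int64)
    else:
        counts = largest_remainder_counts(n, spec.class_proportions)
        true = np.repeat(np.arange(K), counts)
        _rng(spec.seed, "labels").shuffle(true)
        features = []
        for d in spec.modality_dims:
            mu = _class_means(K, d, spec.class_separation, feat_rng)
            features.append(mu[true] + feat_rng.standard_normal((n, d)))
        if spec.cross_modal_coupling > 0:
            z = _rng(spec.seed, "coupling").standard_normal(n)
            features = [x + spec.cross_modal_coupling * z[:, None] for x in features]

    if spec.label_noise_matrix is not None:
        observed = apply_label_noise(true, spec.label_noise_matrix,
                                     _rng(spec.seed, "noise"))
    else:
        observed = true.copy()

    flags = []
    miss_rng = _rng(spec.seed, "missing")
    for m, d in enumerate(spec.modality_dims):
        f = (miss_rng.random((n, d)) < spec.missing_rate
             if spec.missing_rate > 0 else np.zeros((n, d), dtype=bool))
        features[m] = features[m].copy()
        features[m][f] = np.nan
        flags.append(f)

    split = _stratified_split(observed, split_fractions, _rng(spec.seed, "split"))

    manifest = {
        "n_samples": n,
        "n_classes": K,
        "modality_names": [f"modality_{m + 1}" for m in range(M)],
        "modality_dims": list(spec.modality_dims),
        "seed": spec.seed,
        "spec": _spec_to_jsonable(spec),
    }
    return DatasetBundle(
        features=features,
        missing_flags=flags,
        true_labels=true,
        observed_labels=observed,
        split=split,
        sample_ids=[f"S{i:06d}" for i in range(n)],
        manifest=manifest,
    )


def _stratified_split(labels, fractions, rng) -> np.ndarray:
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must be three values summing to 1")
    n = len(labels)
    split = np.empty(n, dtype=object)
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        rng.shuffle(idx)
        n_k = len(idx)
        n_train = int(round(fractions[0] * n_k))
        n_val = int(round(fractions[1] * n_k))
        n_train = min(n_train, n_k)
        n_val = min(n_val, n_k - n_train)
        split[idx[:n_train]] = "train"
        split[idx[n_train:n_train + n_val]] = "val"
        split[idx[n_train + n_val:]] = "test"
    return split.astype(str)


def apply_missingness(bundle: DatasetBundle, missing_rate: float,
                      seed: int) -> DatasetBundle:
    """Set i.i.d. missing flags at `missing_rate` on a copy of the bundle."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    out = bundle.copy()
    rng = np.random.default_rng(seed)
    for m in range(len(out.features)):
        f = rng.random(out.features[m].shape) < missing_rate
        out.features[m][f] = np.nan
        out.missing_flags[m] |= f
    return out


def impute(bundle: DatasetBundle, strategy: str = "mean") -> DatasetBundle:
    """Fill flagged entries using train-split statistics only.

    mean: column mean of observed train entries (continuous features);
    mode: column mode of observed train entries (categorical codes).
    """
    if not set(np.unique(bundle.split)) <= {"train", "val", "test"}:
        raise ValueError("bundle has no valid split assignment")
    if "train" not in bundle.split:
        raise ValueError("imputation requires a non-empty train split")
    out = bundle.copy()
    train = out.mask("train")
    for m, x in enumerate(out.features):
        flags = out.missing_flags[m]
        if not flags.any():
            continue
        for j in range(x.shape[1]):
            col_train = x[train, j]
            observed = col_train[~np.isnan(col_train)]
            if strategy == "mean":
                fill = float(observed.mean()) if observed.size else 0.0
            elif strategy == "mode":
                if observed.size:
                    vals, cnt = np.unique(observed, return_counts=True)
                    fill = float(vals[np.argmax(cnt)])
                else:
                    fill = 0.0
            else:
                raise ValueError(f"unknown imputation strategy: {strategy}")
            x[flags[:, j], j] = fill
        out.missing_flags[m] = np.zeros_like(flags)
    return out


# ---------------------------------------------------------------------------
# calibration test-bed: binary Gaussian scores with known posterior
# ---------------------------------------------------------------------------

def binary_gaussian_logits(n: int, separation: float = 2.0,
                           miscalibration: float = 2.0, seed: int = 0):
    """Univariate two-class Gaussian scores with analytically known posterior.

    x | y=k ~ N(±separation/2, 1) with equal priors. Returns miscalibrated
    logits (`miscalibration` × the true log-posterior, so the NLL-optimal
    global temperature equals `miscalibration`), the labels, and the true
    log-posterior logits.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    x = rng.standard_normal(n) + (y - 0.5) * separation
    # log p(y=1|x) - log p(y=0|x) = separation * x ; symmetric 2-logit form
    half = separation * x / 2.0
    true_logits = np.column_stack([-half, half])
    return miscalibration * true_logits, y, true_logits


# ---------------------------------------------------------------------------
# delimited-text round trip
# ---------------------------------------------------------------------------

def write_bundle(bundle: DatasetBundle, outdir) -> None:
    """One CSV per modality (NA for missing), a labels CSV, a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, x in zip(bundle.manifest["modality_names"], bundle.features):
        cols = [f"{name}_f{j}" for j in range(x.shape[1])]
        df = pd.DataFrame(x, columns=cols)
        df.insert(0, "sample_id", bundle.sample_ids)
        df.to_csv(outdir / f"{name}.csv", index=False, na_rep="NA")
    labels = pd.DataFrame({
        "sample_id": bundle.sample_ids,
        "observed_label": bundle.observed_labels,
        "true_label": bundle.true_labels,
        "split": bundle.split,
    })
    labels.to_csv(outdir / "labels.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))


def read_bundle(indir) -> DatasetBundle:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    labels = pd.read_csv(indir / "labels.csv")
    features, flags = [], []
    for name in manifest["modality_names"]:
        df = pd.read_csv(indir / f"{name}.csv", na_values=["NA"])
        x = df.drop(columns=["sample_id"]).to_numpy(dtype=float)
        features.append(x)
        flags.append(np.isnan(x))
    return DatasetBundle(
        features=features,
        missing_flags=flags,
        true_labels=labels["true_label"].to_numpy(),
        observed_labels=labels["observed_label"].to_numpy(),
        split=labels["split"].to_numpy().astype(str),
        sample_ids=labels["sample_id"].tolist(),
        manifest=manifest,
    )


def _spec_to_jsonable(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    if d["label_noise_matrix"] is not None:
        d["label_noise_matrix"] = [list(r) for r in d["label_noise_matrix"]]
    return d
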