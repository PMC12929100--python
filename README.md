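# calfuse

Cross-modal attention **fusion** classification with domain-aware post-hoc
probability **cal**ibration, for multimodal diagnostic tabular data that is
imbalanced, label-noisy and partially missing.

## The problem

Clinical risk models increasingly combine heterogeneous per-patient feature
blocks — e.g. radiomic descriptors extracted from imaging alongside molecular
or demographic variables. Three pathologies dominate such data: severe class
imbalance (high-risk cases are rare), annotation noise, and missing entries.
A classifier that merely concatenates modalities misses cross-modal
interactions, and even an accurate one is typically *miscalibrated*: its
confidence does not match its empirical accuracy, which matters when a
probability is compared against a clinical decision threshold.

`calfuse` provides, as a library and a CLI:

- a **synthetic multimodal generator** with exact class apportionment,
  a row-stochastic label-noise channel, missing-completely-at-random entries,
  cross-modal latent coupling, and an interaction labelling mode in which no
  single modality carries any marginal signal;
- a **cross-modal transformer encoder**: per-modality embeddings (one token of
  width *h* per modality), learnable positional encoding, *L* self-attention
  layers, explicit pairwise cross-modality attention
  `C(i→j) = softmax(H_i W_Q (H_j W_K)ᵀ / √d_k) H_j W_V`
  added to the receiving modality row, mean pooling and a linear head;
- **imbalance-aware training**: weighted cross-entropy with inverse-frequency
  weights `w_k = N/(K·N_k)`, Adam, early stopping on validation loss;
- **Monte-Carlo-dropout uncertainty**: dropout kept active at inference,
  predictive mean over passes, and a scalar uncertainty
  `u = mean_k Var_passes(p_k)`;
- a three-stage **calibration pipeline** fitted on the validation split:
  class-conditioned temperature scaling `z_k / T_k`, uncertainty modulation
  `z̃ = z / (1 + γ_u·u)`, and prior injection
  `ẑ_k = z̃_k + λ·log(π̃_k/(1−π̃_k))` with smoothed priors
  `π̃ = β·π + (1−β)·π̂`;
- **evaluation and ablation**: macro discrimination metrics, expected/maximum
  calibration error, Brier score, reliability tables, paired t and exact
  Wilcoxon signed-rank comparisons, and a factorial component-ablation harness.

The package is pure numpy/scipy: the encoder is trained through a small,
finite-difference-verified reverse-mode autodiff core (`calfuse._autodiff`).

## Worked example

```python
import numpy as np
import calfuse as cf
from calfuse.calibration import fit_calibration, calibrate_pipeline
from calfuse.encoder import softmax_probs
from calfuse.evaluation import classification_metrics, expected_calibration_error
from calfuse.uncertainty import bundle_uncertainty, uncertainty_vector

spec = cf.SyntheticSpec(
    n_samples=1200, n_classes=2, class_proportions=(0.85, 0.15),
    modality_dims=(8, 6), class_separation=1.8,
    label_noise_matrix=((0.95, 0.05), (0.10, 0.90)),
    missing_rate=0.05, seed=42)
bundle = cf.impute(cf.generate_dataset(spec))
print("imbalance ratio:", cf.imbalance_ratio(bundle.class_counts))

enc = cf.EncoderConfig(modality_dims=(8, 6), n_classes=2, embed_dim=16,
                       n_layers=1, n_heads=2, dropout_rate=0.1, seed=0)
model = cf.fit(bundle, enc, cf.TrainConfig(learning_rate=5e-3,
                                           max_epochs=30, seed=0))
print("class weights:", np.round(model.class_weights, 3))

X_val, y_val = bundle.split_arrays("val")
X_test, y_test = bundle.split_arrays("test")
u_val = uncertainty_vector(bundle_uncertainty(model, bundle, "val", 30, seed=0))
u_test = uncertainty_vector(bundle_uncertainty(model, bundle, "test", 30, seed=0))

params = fit_calibration(model.logits(X_val), y_val, u_val=u_val,
                         expert_prior=[0.85, 0.15],
                         train_class_counts=model.train_class_counts)
print("fitted temperatures:", np.round(params.T, 3))

raw = softmax_probs(model.logits(X_test))
cal = calibrate_pipeline(model.logits(X_test), u_test, params).probs
report = classification_metrics(cal, y_test)
print(f"test accuracy {report.accuracy:.3f}, minority recall "
      f"{report.per_class_recall[1]:.3f}, macro AUC {report.macro_auc:.3f}")
print(f"ECE raw {expected_calibration_error(raw, y_test):.4f} -> "
      f"calibrated {report.ece:.4f}")
```

Output:

```
imbalance ratio: 4.797101449275362
class weights: [0.604 2.903]
fitted temperatures: [1.256 1.047]
test accuracy 0.858, minority recall 0.405, macro AUC 0.791
ECE raw 0.0993 -> calibrated 0.0386
```

Reading the numbers: the generator draws an 85/15 split of *true* labels, but
the imbalance ratio (4.8 rather than 5.67) is computed from *observed* labels
after the asymmetric noise channel has flipped some of them — exactly what a
real registry exhibits. Inverse-frequency weights up-weight the minority class
by ≈2.9. The fitted temperatures exceed 1, i.e. the network was overconfident;
applying the calibration pipeline on the held-out split cuts the expected
calibration error from 0.099 to 0.039 without touching the hard predictions.

The same pipeline is available from the shell:

```bash
calfuse simulate  --config config.json --out run/data
calfuse train     --config config.json --data run/data --out run/model
calfuse predict   --model run/model --data run/data --split val \
                  --out run/preds --mc-passes 30
calfuse predict   --model run/model --data run/data --split test \
                  --out run/preds --mc-passes 30
calfuse calibrate --val run/preds/predictions_val.csv \
                  --apply run/preds/predictions_test.csv --out run/calib
calfuse evaluate  --probs run/calib/calibrated_probs.csv --out run/report
calfuse ablate    --config config.json --data run/data --out run/ablation
```

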