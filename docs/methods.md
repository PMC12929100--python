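# Methods

## Model

A sample is a tuple of M feature vectors x⁽¹⁾…x⁽ᴹ⁾, one per modality (e.g. an
imaging-derived block and a molecular/clinical block), with a label in
{1,…,K}. Each modality is embedded by its own affine map followed by tanh into
a single token of shared width h; a sample is therefore a length-M token
sequence. Tokens carry a learnable positional encoding P ∈ ℝ^{M×h} that
identifies the modality slots (the sequence is unordered, so P is the only
slot identity). L transformer layers follow, each a multi-head self-attention
sub-block and a position-wise feed-forward sub-block (ReLU, inner width 2h),
both wrapped as LayerNorm(x + Dropout(sublayer(x))). Self-attention over M
tokens already mixes modalities coarsely; fine-grained fusion is made explicit
by pairwise cross-modality attention

    C(i→j) = softmax(H_i W_Q (H_j W_K)ᵀ / √d_k) · H_j W_V,   i ≠ j,

with one shared (W_Q, W_K, W_V) triple across ordered pairs, added to the
*receiving* row i of the final token matrix: H_fused = H^L + Σ_{i≠j} C(i→j).
With one token per modality each pairwise softmax is over a single key, so
C(i→j) reduces to a learned value projection of the sending token; the
mechanism is implemented generically over token counts and tested on
multi-token inputs. The fused tokens are mean-pooled and a linear head
produces logits; probabilities are softmax with argmax ties broken toward the
lowest class index.

Token granularity was a genuinely open choice: one token per modality makes
pairwise cross-attention well-typed, keeps cost at desk scale, and leaves the
feature-level mixing to the embedding and feed-forward blocks. The row
alignment of the fusion sum (add C(i→j) at row i, whose queries produced it)
is likewise a design decision.

### Training

The loss is weighted cross-entropy with inverse-frequency weights
w_k = N/(K·N_k) (all ones when balanced), computed from the training split.
An optional penalty λ_scale·‖pooled‖² (off by default) constrains the fused
representation norm; imbalance weighting subsumed a fuller difficulty-aware
feature scaling in practice, so weighted CE is the default objective.
Optimisation is Adam (lr 1e-4, L2 weight decay 1e-5 applied to the gradient)
with per-epoch reshuffled mini-batches and early stopping: training halts
after `patience` epochs without validation-loss improvement and the
best-validation-epoch parameters are returned. Config defaults are desk-scale
(30 epochs, batch 32); the worked examples use lr 5e-3 because the problems
are tiny. Reserved coefficients for additional imbalance/uncertainty loss
terms exist in the config but contribute zero — no functional form is defined
for them.

Because no GPU autodiff framework is a dependency, gradients come from a
compact reverse-mode autodiff over float64 numpy arrays
(`calfuse._autodiff`), whose every primitive is checked against central
finite differences in the test suite (worst relative error ~1e-7 on the full
model loss). This also makes training bit-reproducible for a fixed seed on
one device.

### Monte-Carlo-dropout uncertainty

Dropout is inverted (mask, then rescale by 1/(1−p)), so the expected
stochastic pass equals the deterministic one. At inference, n_passes ≥ 2
(default 30) stochastic passes per sample yield a predictive mean and a
per-class variance; the scalar uncertainty is u = mean_k Var(p_k), chosen in
probability space because it is bounded, comparable across models, and
invariant to relabelling of the readout. Each sample's mask stream is seeded
by (seed, crc32(sample_id)), so results are independent of batch composition
and ordering. Two consequences are tested: u = 0 exactly when p_drop = 0, and
the Monte-Carlo error of the predictive mean contracts like 1/n_passes.

### Calibration

Fitted on the validation split only, applied to held-out logits, in the fixed
order raw → temperature → uncertainty → prior → softmax:

1. **Class-conditioned temperature scaling.** Scaled logit k is z_k/T_k with
   T ∈ [0.05, 20]^K. Each class's logit is divided by its *own* temperature,
   which is the only form under which the scaled softmax is a probability
   distribution. A global temperature is the equal-entries special case and
   is fitted by bounded scalar minimisation of validation NLL; the per-class
   fit runs coordinate descent (bounded 1-D minimisation per coordinate,
   updates accepted only when NLL decreases, sweep tolerance 1e-4, max 50
   sweeps) from two starts — all-ones and the fitted global broadcast —
   keeping the better endpoint. The second start guarantees the nesting
   property (per-class NLL ≤ global NLL on the fitting split) that a single
   all-ones start cannot in principle.
2. **Uncertainty modulation.** z̃ = scaled/(1 + γ_u·u): identity at u = 0,
   uniform softmax in the large-u limit, argmax-preserving at any finite u.
   γ_u is selected on the grid {0, 0.1, 1, 10, 100} by validation NLL, after
   temperatures; ties prefer the identity.
3. **Prior injection.** Expert per-class prevalences π (treated marginally —
   no sum-to-one constraint) are smoothed against add-one-smoothed empirical
   training frequencies π̂, π̃ = β·π + (1−β)·π̂ with user β (default 0.5), then
   δ_k = log(π̃_k/(1−π̃_k)) is added with weight λ_prior selected on
   {0, 0.25, 0.5, 1, 2} by validation NLL. Add-one smoothing keeps π̂ strictly
   inside (0,1), so the log-odds are always finite.

## Synthetic data generator

The generator emulates the data-quality regime the method targets, with known
ground truth so every stage is testable without external data:

- **Class counts** are the deterministic largest-remainder apportionment of
  n by the class proportions (remainder ties to the lower index), making the
  imbalance ratio max_k N_k / min_k N_k exact.
- **Features** are class-conditional Gaussians with unit within-class scale;
  class means are separated by `class_separation` in within-class standard
  deviations (exactly, for K = 2 or when the modality dimension ≥ K;
  approximately via random unit directions otherwise).
- **Coupling**: a shared per-sample standard-normal latent, scaled by the
  coupling coefficient, is added to every coordinate of every modality.
- **Interaction labelling mode** (K = 2): features are unconditional
  Gaussians and the label is the sign product of the first coordinates of
  modalities 1 and 2, so each modality is marginally uninformative — a
  logistic model on either modality alone stays at chance — and cross-modal
  fusion is necessary, not merely helpful.
- **Label noise**: observed labels are drawn from the row of a K×K
  row-stochastic transition matrix indexed by the true label.
- **Missingness** is completely at random at a fixed entry rate; missing
  entries are stored as NaN and flagged, and the encoder refuses un-imputed
  input. Imputation fills flagged entries with training-split column means
  (or modes, for categorical codes) — never statistics of validation or test
  rows.
- **Splits** are stratified 60/20/20 on observed labels.

All randomness flows from one integer seed through named per-stage generators
(labels, features, coupling, noise, missingness, split), so identical
specifications reproduce bundles bit-identically and sub-steps can be
re-verified independently.

What the generator does *not* emulate: raw images or their backbones,
longitudinal follow-up, survival endpoints, feature-dependent (informative)
missingness, or instance-dependent label noise. Passing tests therefore
demonstrate correctness of the mechanisms under the stated generative
assumptions, not clinical performance on real registries.

A second test-bed, `binary_gaussian_logits`, draws univariate two-class
Gaussian scores whose posterior is known in closed form; scaling the true
log-posterior by a factor c produces logits whose NLL-optimal global
temperature is exactly c, giving an analytic target for temperature recovery
and held-out calibration-error reduction.

## Evaluation choices

Recall, F1 and one-vs-rest AUC are macro-averaged; a class absent from the
labels is excluded from the macro AUC with a warning. Calibration is
summarised by ECE over 15 equal-width confidence bins (right-closed top bin;
empty bins contribute zero), with MCE, NLL and the multiclass Brier score
alongside. Paired comparisons report the two-sided paired t-test and the
Wilcoxon signed-rank test (exact null for ≤ 25 non-zero differences); a
zero-variance set of differences returns p = 1.0 for both by convention so
factorial ablation tables never crash. The ablation harness toggles four
components — cross-modal information flow (fusion off also restricts
self-attention to the diagonal, so no cross-modality information leaks
through the encoder), uncertainty modulation, prior injection, and class
weighting — and runs one full train/calibrate/evaluate cycle per flag set per
seed.

## Numerical notes

- float64 throughout; softmax and log-softmax use detached max-shifts.
- LayerNorm ε = 1e-5; probabilities are clamped at 1e-12 inside the
  cross-entropy with a logged warning; non-finite activations or logits abort
  with a diagnostic rather than propagate.
- Temperatures are clipped to [0.05, 20]; grid ties in γ_u/λ_prior selection
  resolve to the smallest (identity-favouring) value.
- Problem sizes in the tests and acceptance script (n = 300–5000 samples,
  h = 8–16, L = 1–2, 5 seeds per comparison) are chosen so every claimed
  effect is detectable with comfortable margins at desk scale.

## Known limitations

- One token per modality bounds the attention's expressiveness over very
  high-dimensional modalities; feature-level tokenisation is out of scope.
- The uncertainty modulation never changes the predicted label, by design; it
  only tempers confidence.
- λ_prior and γ_u are grid-searched, not learned by gradient descent; the
  grids are coarse by intent (the NLL surface over them is shallow).
- Expert priors enter marginally per class; if they encode a full prevalence
  simplex the user must normalise upstream.
- The coordinate-descent per-class temperature fit finds a local optimum of a
  generally non-convex objective; the two-start strategy guarantees it never
  underperforms the global fit but not global optimality.
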