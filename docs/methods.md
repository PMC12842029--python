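# Methods

## Problem and model

`scafkan` predicts subclinical atrial fibrillation (SCAF) — asymptomatic,
device-detected atrial high-rate episodes with irregular A–A intervals
lasting over 30 s — in patients carrying a cardiac implantable electronic
device, from 27 routinely collected clinical parameters: demographics,
comorbidity flags, biochemical markers, and echocardiographic /
tissue-Doppler measures.

The core classifier is a dual-path network over the preprocessed feature
vector `x ∈ ℝ²⁷`:

* **ResKAN pathway.** Stacked residual Kolmogorov–Arnold (KAN) blocks. A
  KAN layer places a learnable univariate activation on every directed
  edge i→j,

      φ_ij(x) = w_b[i,j]·silu(x) + w_s[i,j]·Σ_b c[i,j,b]·B_b(x),

  where the `B_b` are degree-`k` B-spline basis functions on a uniform
  grid shared across edges, and each output unit sums its incoming edge
  activations. Blocks are pre-norm residual: `y = skip(x) + KAN(LN(x))`,
  with a linear projection on the skip when dimensions change.
* **MLP pathway.** A linear stem to the token dimension followed by
  pre-norm residual dense blocks with ReLU and dropout.
* **Cross-attention fusion.** Each pathway's final hidden vector is one
  `d`-dimensional token per patient (optionally expanded to several
  pseudo-tokens). Multi-head scaled dot-product cross-attention lets each
  pathway attend to the other (bidirectional by default; single-direction
  modes exist for ablation). Attended outputs are residual-added to the
  query source, mean-pooled over tokens, concatenated, and mapped by a
  dense head to one logit; the sigmoid of that logit is the SCAF
  probability.

The networks are built on a small in-package reverse-mode autodiff engine
over NumPy arrays (`scafkan.nn`); the B-spline design matrix is a custom
primitive whose input gradient uses the analytic B-spline derivative
recurrence. Training uses AdamW (decoupled weight decay) with mini-batches
and early stopping on validation AUC, restoring the best-epoch weights.

### Defaults that matter

| parameter | default | notes |
| --- | --- | --- |
| spline degree k | 3 (cubic) | grid G=5 intervals on [−3, 3], matching z-scored inputs; out-of-range values are evaluated on the k-extended knots, not clamped |
| token dimension d / heads H | 64 / 4 | d must divide by H |
| pathway depth | 2 blocks each | 1 is used in the test-scale configurations |
| dropout | 0.1 | evaluation mode is exactly deterministic |
| learning rate / weight decay | 1e−3 / 1e−2 | AdamW |
| batch size / patience | 32 / 20 epochs | early stopping monitors validation AUC (strict improvement) |
| spline coefficient init | N(0, 0.1²) | base weights use Glorot-style scaling; spline mixing weights start at 1 |

The spline grid is fixed at construction (no refinement during training).

## Evaluation protocol

Stratified K-fold (default 5) cross-validation. Within each fold, and on
the training rows only: chained-equations imputation (per-feature ridge
regressions, ≤10 sweeps, 1e−3 convergence tolerance on imputed values),
`log1p` of the right-skewed markers NT-proBNP and CRP, z-standardisation
of continuous features, and SMOTE-style minority oversampling (k=5
neighbours, synthetic rows interpolated on segments between minority
neighbours, originals preserved). Binary features are imputed on the
continuous scale, rounded back to {0,1}, and by default not z-scored so
attribution signs stay interpretable (a `standardize_binary` flag flips
this). The fitted preprocessing state carries a SHA-256 fingerprint of the
training rows; `cross_validate` recomputes the expected fingerprint and
aborts on any mismatch, so held-out rows cannot leak into the fit. The
held-out fold also serves as the early-stopping monitor, mirroring the
evaluation protocol the score metrics are reported under.

AUC is the Mann–Whitney rank statistic (ties count ½); secondary metrics
come from the confusion matrix at threshold 0.5 (undefined precision is
reported as 0 with a flag). Fold-wise model comparison uses paired
t-tests and paired Cohen's d = mean(ΔAUC)/SD(ΔAUC); constant nonzero
differences return a ±∞ sentinel with a warning. Raw p-values are primary;
a Holm-adjusted column is available as a labelled extension.

The baseline roster (logistic regression, random forest, k-NN, Gaussian
naive Bayes, SVM, sklearn MLP, XGBoost, LightGBM where installed, plus
in-package residual MLP, feature-tokenizing transformer, and plain KAN
references) runs through the identical fold pipeline; entries whose
dependency is absent are skipped with a logged warning.

## Interpretation

Global attribution follows the kernel-weighted coalition view of Shapley
values: coalition value v(S) replaces out-of-coalition features with
background rows (training fold, capped at 100 rows) and averages the
model output; coalitions are sampled from the Shapley-kernel size
distribution with antithetic complements (default budget 2¹¹ per
patient), and a sum-constrained least-squares solve returns attributions,
so local accuracy (Σφ = f(x) − E_bg f) holds exactly by construction.
`exact_shapley` enumerates all 2^m coalitions for small m and is the
independent cross-check. Global importance is the mean absolute
attribution; ties in the ranking break by canonical schema order.

Local explanations fit an exponential-distance-kernel-weighted sparse
linear surrogate (default 1000 Gaussian perturbations, 10 nonzero
weights: full weighted ridge for ranking, weighted refit on the kept
features). Activation reports sample the learned input-layer KAN edge
activations over each feature's observed range.

## Distillation and the clinical risk score

A logistic student on 10 raw-unit features (LDH entering as ln(LDH+1)) is
trained against α·T²·CE(teacher softened at temperature T) +
(1−α)·CE(true labels), defaults T=2, α=0.7, via L-BFGS with analytic
gradients on an internally standardised design (mapped back exactly to
raw-unit coefficients). α=0 reduces to a plain label fit; with α=1, T=1 a
logistic teacher is recovered to optimisation tolerance. Fidelity is
reported as Pearson correlation and MAE of the probability vectors plus
the student/teacher AUC ratio. The published 10-feature score ships as a
frozen, versioned JSON fixture; scoring validates raw units, rejects
missing fields, non-binary indicators, and LDH ≤ −1 by name, and
serialisation round-trips bit-identically.

## Synthetic cohorts

The generator reproduces the development cohort's *marginal* arm
statistics: labels i.i.d. at the configured prevalence (default 39/124);
per-arm Gaussians for continuous features, clipped to maintainer-chosen
physiologic bounds recorded in the schema; log-normals for NT-proBNP and
CRP parameterised so the back-transformed mean/SD match the configured
values; per-arm Bernoulli flags. Missingness is injected completely at
random (labels never masked). Features are independent given the label by
default; a latent-Gaussian correlation hook exists for sensitivity work.

What it does **not** emulate: inter-feature correlation structure (the
source summaries are marginal), the true shapes of heavy-tailed markers —
hsTnI's published SD (1465) dwarfs its mean (183), so a zero-truncated
Gaussian cannot match that mean and its empirical shape is unknowable
from summary statistics — informative missingness, longitudinal follow-up
structure, or site effects. Passing tests therefore certify the
machinery (leakage safety, optimisation, attribution correctness,
distillation fidelity), not clinical performance on real cohorts.

The planted-signal variant pools both arms to a common marginal (so
features carry no intrinsic label signal) and draws labels from
`logit(risk) = b0 + 2.2·z_LAD + 1.5·max(z_LAD − 0.5, 0) + 1.0·z_LAD·z_E/e'`
— a dominant left-atrial-diameter effect with a threshold kink and a
diastolic-function interaction — with b0 bisected so the realised
prevalence hits the target. It drives the capacity comparison (fused
model vs logistic), the pathway-ablation check, and planted-feature
attribution recovery.

## Problem sizes and numerical choices

Test-scale runs use 124-patient cohorts (the development cohort size),
K=5, compact architectures (d=32, one block per pathway), ≤120 epochs,
Shapley budgets of 128–512 on 10–20 patients, and 5 seeded replicates for
the stochastic recovery checks; convergence checks for generator moments
use 10⁵–2·10⁵ draws. Degenerate inputs are refused loudly: cohorts under
10 patients or with expected positives < 2, missing rates ≥ 1, K=1 folds,
single-class oversampling, fully missing features (named), non-finite
losses, zero-variance perturbation designs. Cohen's d with zero-variance
differences returns a signed infinity sentinel rather than NaN.

## Known limitations

* Architecture hyperparameters (depths, grid size, fusion wiring,
  distillation temperature) could not be taken from a reference
  configuration and are package defaults, exposed in config and swept only
  lightly in tests.
* The reported cross-validation AUCs on synthetic cohorts characterise
  the pipeline under the generator's assumptions; they are not estimates
  of performance on any clinical population.
* Sampled Shapley attributions inherit Monte-Carlo error from the
  coalition budget; the exact enumerator is exponential and limited to
  ≤16 features.
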