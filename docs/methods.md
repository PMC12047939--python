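# Methods

This document describes the models, generators, training procedure, and
numerical choices implemented in `attnmap`, together with the package's
default problem sizes and known limitations.

## Notation

A panel of `n` haploid individuals is genotyped at `L` biallelic loci.
Individual `g` is the vector `x(g) ∈ {−1, +1}^L`; its trait value is
`y(g) ∈ ℝ`.  `d` denotes the embedding dimension and `NL` the number of
attention layers (default 3).

## Single-environment attention model

### Architecture

1. **Signed embedding.** Each locus has a learned row in the embedding
   matrix `W_embed ∈ ℝ^{L×d}`; the token for locus `l` is
   `z_l = x_l · W_embed[l]`.  This equals multiplying the signed one-hot
   genotype matrix by `W_embed`, computed without materializing it.
   An allele flip at locus `l` negates exactly row `l` of the token
   matrix `Z ∈ ℝ^{L×d}`.
2. **Attention stack.** `NL` single-head, *unscaled* attention layers:
   `Z ← softmax(Z W_Q (Z W_K)ᵀ) Z W_V`, with per-layer projections
   `W_Q, W_K, W_V ∈ ℝ^{d×d}`.  There is no `1/√d` score scaling, no
   biases, no residual connections, no layer normalization, and no
   feed-forward sublayers.  The row-wise softmax subtracts the row
   maximum before exponentiating, so attention rows sum to one even for
   scores of magnitude 10⁶.
3. **Regression head.** `y_pred = β0 + Σ_l ⟨B_l, Z‴_l⟩` with per-locus
   weights `B ∈ ℝ^{L×d}` and scalar intercept `β0`.

The trainable-parameter count is `2Ld + 3d²NL + 1` (embedding `Ld`, head
`Ld + 1`, projections `3d²` per layer); at `L=1000, d=12, NL=3` this is
25,297.  The linear+pairwise baseline over the same loci has
`L(L+1)/2 + 1` parameters (500,501 at `L=1000`).

### Gradients and optimization

The environment provides no automatic-differentiation framework, so the
backward pass is hand-derived and implemented in NumPy:

- softmax backward: `dS = A ⊙ (dA − rowsum(dA ⊙ A))` for `A = softmax(S)`;
- attention backward: `dA = dZ' Vᵀ`, `dV = Aᵀ dZ'`, `dQ = dS K`,
  `dK = dSᵀ Q`, with projection gradients accumulated over the batch by
  `einsum("nld,nle->de", ·, ·)`;
- embedding backward: `dW_embed[l] = Σ_g x_l(g) · dZ0[g, l]`.

Analytic gradients are checked against central finite differences in the
test suite for both architectures.  Optimizers (Adam with the standard
bias correction, and plain SGD) are implemented in-package and operate on
the model's parameter dictionary.  Training minimizes mean-squared error
over shuffled mini-batches with early stopping on validation MSE; the
best-validation parameter snapshot is restored.  A non-finite training
loss aborts with a diagnostic.

Defaults used by the experiment drivers: Adam, learning rate 3·10⁻³,
batch size 256, patience 15–20 epochs, float32 parameters and data, and
target standardization — the trait is centered and scaled by training-set
statistics before training and predictions are mapped back to original
units before any metric is computed.  Initialization follows a scaled
Gaussian (sd `1/√d`) for the embedding and projections and zeros for the
regression head.

### The parity constraint (important limitation)

The architecture above is an *odd function of the genotype plus a
constant*: a global allele flip `x → −x` negates every token, attention
scores are quadratic in the tokens and hence invariant, so each layer's
output negates, and the linear head preserves the sign; therefore
`y_pred(−x) = 2β0 − y_pred(x)` identically, for every parameter setting.
Consequently the model can represent odd-order interaction terms
(linear, cubic, …) but **no even-order terms**.  Under a sign-symmetric
genotype distribution (such as an F1 cross, where both alleles segregate
1:1) a purely fourth-order map has zero correlation with every function
in this model class, so the best achievable out-of-sample R² is 0.  This
is verified executably in the test suite
(`test_single_env_model_is_odd_around_intercept`) and observed in
benchmarks: at mixing weight ε=0 the attention model and the linear
baseline both sit at R² ≈ 0, and at intermediate ε the attention model
recovers exactly the additive (odd) share of the variance.  The
multi-environment model below does not have this constraint: its
appended ones column breaks the sign symmetry.

## Multi-environment attention model

For `E` environments, tokens are widened to `D = d + E + 1`:

- locus rows: `[x_l · W_embed[l] | 0_E | 1]`;
- one environment row: `[0_d | e_α | 1]`, where `e_α` is the one-hot
  code of the environment;
- the final column of ones is appended to every token.

The `L+1` tokens pass through `NL` shared attention layers with `D×D`
projections; the head reads all `L+1` output tokens:
`y_pred = β0 + Σ_t ⟨B_t, Z‴_t⟩` with `B ∈ ℝ^{(L+1)×D}` (a
`head_locus_only` flag restricts the head to locus tokens for
ablations).  Parameter count: `Ld + 3D²NL + (L+1)D + 1`.  One jointly
trained model serves all environments; records from different
environments are pooled into a single training set.

## Synthetic data generators

### Genotypes: F1 cross with linkage

Chromosomes are simulated as two-state Markov chains: the first allele
of each chromosome is ±1 with probability ½, and each subsequent locus
flips parental origin with recombination probability `r ∈ [0, 0.5]`,
giving adjacent-locus correlation `1 − 2r`.  `r = 0.5` yields
independent loci (one locus per chromosome is equivalent).  The marginal
allele distribution is symmetric (frequency ½ at every locus).

### Phenotypes: linear plus fourth-order epistasis

Given a set of `L_causal` causal loci,

```
y = β0 + ε Σ_l β_l x_l + (1 − ε) Σ_q β_q x_i x_j x_k x_l + η
```

with `L_causal` distinct quadruplets drawn uniformly from the causal
loci, coefficients i.i.d. Gaussian (or exponential with random sign),
and Gaussian noise `η` with standard deviation equal to `noise_frac`
(default 0.2) times the noise-free signal's standard deviation.  With
`noise_frac = 0.2` the explainable variance fraction — the noise ceiling
for any model — is `1/1.04 ≈ 0.962`.  The mixing weight `ε` interpolates
from purely fourth-order (`ε=0`) to purely additive (`ε=1`).

Multi-environment maps share causal loci and quadruplets across
environments; each coefficient is drawn from a multivariate normal over
environments with unit marginal variance and a supplied correlation
matrix, realized exactly through an eigendecomposition factor.  The
built-in temperature kernel is `corr(a, b) = exp(−|T_a − T_b|/τ)`.

## Baselines

Additive (`linear`) and additive-plus-pairwise (`pairwise`) penalized
regressions use scikit-learn's Ridge/Lasso with the intercept
unpenalized.  `λ` may be a scalar or a grid (default
`{10⁻⁴ … 10²}`), selected by validation MSE.  Pairwise features are the
products `x_j x_k` for `j < k`; fits are refused beyond 10⁷ features, so
genome-scale pairwise fits must be restricted to a causal-locus subset.
On the ±1 hypercube, degree-4 interaction characters are orthogonal to
all degree-≤2 features, so the pairwise baseline gains nothing on purely
fourth-order maps — a property the test suite checks.

## Evaluation

- **Splits:** 85% train+validation / 15% test, then 85/15 within the
  retained block (`n=100 → 72/13/15`), by seeded permutation.
- **Metrics:** out-of-sample `R² = 1 − SS_res/SS_tot` and Pearson
  correlation, both raising on degenerate (constant-truth) inputs.
- **Effect sizes:** `Δf_l(g) = ŷ(x_l = +1; g) − ŷ(x_l = −1; g)` by
  in-silico allele flipping with all other loci fixed; `Δf_l` averages
  over backgrounds.  For an additive map the true effect is `2εβ_l`,
  and a fitted linear model satisfies `Δf_l(g) = 2β̂_l` in every
  background exactly.
- **Embedding-dimension selection:** candidate `d` values are trained
  on the training split and compared by validation R² (ties favor the
  smaller `d`).

## Default problem sizes

All benchmark sizes are package choices ("desk scale", minutes on one
CPU), not claims about the source experiments:

- epsilon sweep / additive benchmark: `L_causal = 20`, `n = 20,000`,
  `d = 12`, `NL = 3`;
- noise-ceiling check: `L_causal = 100`, `n = 10,000`, ridge with the
  default λ grid;
- transfer: 7 temperature-labelled environments (23–37 °C, τ = 20),
  `n = 3,000` per environment, `ε = 1`, joint model trained on six full
  environments plus {100, full} records of the held environment, with
  an identity-correlation control.

Observed reference numbers (one CPU): the additive benchmark reaches the
noise ceiling (linear 0.962, attention 0.962); the transfer benchmark
reaches R² 0.854 in the held environment with 100 records versus 0.958
with full data, while the identity control reaches only 0.482 with 100
records (versus 0.947 with full data).

## Limitations

- The single-environment model cannot represent even-order interaction
  terms (see the parity constraint above); with symmetric genotypes its
  advantage over the linear baseline is limited to odd-order epistasis.
- No GPU or autodiff backend: training is NumPy on CPU; desk-scale
  problems train in minutes, but the ~10⁵-individual, ~10³-locus regime
  is out of scope for the test suite.
- The pairwise baseline materializes its feature matrix; memory grows
  as `n·L²/2`.
- Multi-head attention, dropout, residual connections, positional
  encodings, masking-based pretraining, and the no-embedding `d=L+1`
  variant are not implemented.
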