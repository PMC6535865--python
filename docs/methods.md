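# Methods

## Model

The pipeline maps a nonnegative expression matrix `V (m x n)` and a
clinical matrix `C (m x d)` with entries in `[0, 1]` to per-sample 5-year
survival probabilities in four stages.

1. **Normalization.** Expression columns (genes) are min–max scaled to
   `[0, 1]`; constant columns map to 0. Clinical entries are validated to
   lie in `[0, 1]` already (categorical covariates are assumed one-hot or
   ordinal-scaled upstream). Normalization statistics can be computed
   globally (`mode="global"`) or on the training rows only
   (`mode="train_only"`), in which case held-out rows are clipped to
   `[0, 1]` after applying the training statistics and their features are
   obtained by projecting onto the trained basis `H` with NNLS
   (`project_new_samples`), keeping the evaluation leakage-free.

2. **Feature extraction.** Five NMF solvers factorize the same `V` at rank
   `r`, all starting from the same deterministic NNDSVD initialization, so
   solver differences reflect the update rules rather than random starts.
   Rows of each `W_j` are the per-sample features.

3. **Attention fusion.** Sample-specific solver weights come from a
   bilinear form between each solver's feature vector and the sample's
   clinical vector, `w_ij = F_j(x_i)^T X C(x_i)`, normalized with a
   max-subtracted softmax over the five solvers. The fused feature vector
   is the resulting convex combination, concatenated with the clinical
   vector.

4. **Classification.** A feed-forward network with ReLU hidden layers,
   inverted dropout, and a single logit output is trained with
   binary-cross-entropy-with-logits loss and Adam, *jointly* with the
   attention matrix `X` — gradients flow through the softmax into `X`.
   Early stopping tracks validation AUC and restores the best parameters.

Splits are stratified 80/10/10: per class, validation and test each get
`round_half_up(0.1 * m_c)` samples and training the remainder. A cohort
with class sizes 1489/491 therefore yields 1584/198/198 overall.

## Assumptions

- Expression is nonnegative and approximately low-rank plus noise; the
  factorization rank `r` is a modeling choice, typically above the
  (unknown) true latent dimension.
- Clinical covariates are informative about survival both directly and as
  conditioning information for the attention weights.
- The 5-year label is a deterministic threshold of survival time
  (`time >= 5 -> 1`), i.e. censoring is not modeled.

## Parameters and defaults

### Solvers (`SolverConfig`)

| parameter | default | rationale |
|---|---|---|
| `max_outer_iter` | 200 | enough for the ALS family to converge on desk-scale problems; the multiplicative solvers converge more slowly by design |
| `rel_tol` | 1e-4 | stop when the relative objective decrease falls below this; 0 disables |
| `epsilon_guard` | 1e-12 | added to multiplicative-update denominators to avoid division by zero |
| `cost` | euclidean | Frobenius objective `0.5 * ||V - WH||_F^2`; KL divergence available for `mu` |
| `pg_beta`, `pg_sigma` | 0.1, 0.01 | Armijo backtracking ratio and sufficient-decrease constant, the standard choices for projected-gradient NMF |
| `pg_eps` | 1e-4 | subproblem stops when the projected-gradient norm falls below `pg_eps` times the initial gradient norm |
| `pnmf_alpha`, `pnmf_beta` | 0.1 | ridge penalties on `W` and `H`; at 0 the update is exactly the plain multiplicative rule (tested elementwise) |
| `ridge` | 1e-10 | stabilizes Gram-matrix solves in the ALS/OBS path |

### Network (`ModelConfig`)

| parameter | default | rationale |
|---|---|---|
| `hidden_layers` | (128, 32) | two ReLU layers; enough capacity for fused-plus-clinical inputs at desk scale |
| `dropout` | 0.2 | inverted dropout on hidden activations |
| `learning_rate` | 1e-3 | Adam default scale |
| `batch_size` | 32 | mini-batch SGD; batches are reshuffled each epoch from a run-specific generator |
| `max_epochs`, `patience` | 200, 20 | early stopping on validation AUC with best-parameter restore |

The attention matrix is initialized uniformly in `[-s, s]` with
`s = 1 / sqrt(r * d)`, so initial raw scores are near zero and the initial
weights are near-uniform (0.2 per solver): the model starts as the
fixed-weight fusion baseline and departs from it only if the data warrant.

### Synthetic cohort (`SyntheticCohortConfig`)

Defaults: `m=400`, `n=500`, `r0=6`, `d_c=25`, `noise_sd=1.0`,
`class_balance=491/1980`, `clinical_signal=0.5`. These sizes are the
package's own desk-scale choice: large enough that stratified splitting,
rank-20 factorization, and repeated retraining are meaningful, small
enough that the full pipeline runs in seconds to minutes on one CPU.

## What the generator emulates — and what it does not

Emulated:

- nonnegative, approximately low-rank expression (gamma-distributed
  planted factors, additive noise, clipped at zero);
- clinical covariates that mix nonlinear transforms of the same latent
  factors (shared signal) with an independent clinical-only factor and
  noise, squashed to `[0, 1]`;
- class imbalance: the logistic intercept is calibrated by root finding so
  the expected long-term fraction matches `1 - class_balance`;
- survival times consistent with the labels (time ≥ 5 years iff label 1).

Not emulated: censoring, batch effects, gene–gene correlation structure
beyond low rank, missing data, multi-modal platforms, or any real cohort's
marginal distributions. Numbers obtained on synthetic cohorts demonstrate
the pipeline's mechanics, not clinical performance.

## Numerical choices

- **Epsilon guards.** Multiplicative updates add `epsilon_guard` (1e-12)
  to denominators; ALS/OBS Gram solves add `ridge` (1e-10) to the
  diagonal. Both are absolute constants, so factorizing `c * V` is
  scale-covariant only up to these guards; the test suite asserts
  relative-error agreement at 1e-4 rather than machine precision.
- **Zero handling in NNDSVD.** For the multiplicative solvers, zeros in
  the initialization are lifted to `1e-6 * mean(V)` (they would otherwise
  be absorbing states of the update); the additive solvers keep exact
  zeros.
- **OBS safeguard.** The saliency-pruning NNLS step (delete the
  minimum-saliency coefficient `L_i = ω_i^2 / (2 [G^-1]_ii)`, correct the
  survivors with `Δω = -(ω_i/[G^-1]_ii) G^-1 e_i`) is greedy and does not
  by itself guarantee the column objective improves. A per-column
  keep-better fallback retains the previous iterate when pruning made the
  residual worse, which restores a provably nonincreasing objective trace.
- **Projected gradient.** The subproblem works on the Gram form
  (`W^T W`, `V^T W`), so each Armijo trial costs `O(n r^2)` instead of
  `O(mnr)`; step sizes are `beta^t` with the sufficient-decrease test
  evaluated through the quadratic expansion.
- **Softmax stability.** Attention softmax subtracts the row maximum;
  BCE-with-logits uses the log-sum-exp form.
- **Determinism.** NNDSVD is deterministic; all stochastic components
  (generator, splits, dropout, batch order, initialization) draw from
  explicit seeds, so every experiment is bit-reproducible. Derived seeds
  stay below 2^31.

## Design decisions

- The five solvers share one NNDSVD starting point so the downstream
  fusion sees genuinely comparable feature coordinate systems; with random
  per-solver starts, factor columns would be arbitrarily permuted across
  solvers and elementwise fusion would be meaningless.
- Exact NNLS (active-set) is used for ALS subproblems rather than
  clamped least squares; clamping negative entries to zero does not solve
  the constrained problem and breaks the monotonicity of the trace.
- Ablation variants are implemented inside one network module with shared
  code paths, so comparisons between `amnd` and its ablations differ only
  in their input construction, never in training mechanics.
- Repeated-split evaluation uses the same derived seed for every variant
  at a given repeat, making variant comparisons paired.
- Evaluation metrics are delegated to scikit-learn; the test suite checks
  them against an independent brute-force pairwise-concordance oracle.

## Limitations

- The NumPy network trains on CPU mini-batches; it is intended for
  desk-scale cohorts (hundreds to a few thousand samples), not
  genome-scale deep learning.
- Attention fusion can only help when the solver branches genuinely
  differ and the validation set is large enough to steer early stopping;
  on small cohorts the attention model and the fixed-weight baseline are
  often statistically indistinguishable.
- No censoring model: samples must have observed 5-year status.
- KL-divergence cost is available only for the multiplicative solver.
- `class_balance` calibration fixes the *expected* positive fraction; the
  realized fraction varies binomially.
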