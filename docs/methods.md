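# Methods

This note documents the model, the numerical procedures, the synthetic-data
generator and the design choices behind `spcovr`, in enough detail to judge
what the test suite does — and does not — establish.

## Model and objective

Both data blocks are centered and scaled to per-column sum of squares one
(`center_scale`); under that convention `‖X‖²F = Jx` and `‖Y‖²F = Jy`, so the
two residual terms of the loss are normalized fractions in [0, 1]. The
scaling divisor is the root sum of squares of the centered column — not the
standard deviation — and is stored together with the column mean so the raw
data can be recovered exactly.

The objective is the convex combination, weighted by `α`, of the normalized
predictor-reconstruction and outcome-prediction errors, plus an elastic-net
penalty on the component weights `W` only (neither the loadings `Px` nor the
regression weights `Py` are penalized — the ridge included). It is
equivalently a single least-squares problem on the weighted concatenation
`Z = [w1·Y, w2·X]` with `w1 = sqrt(1−α)/‖Y‖`, `w2 = sqrt(α)/‖X‖` and the
stacked loading matrix `P = [w1·Pyᵀ, w2·Pxᵀ]ᵀ`; the equality of the two
algebraic forms is asserted in the tests to 1e-10.

## Exact solution of the unpenalized problem

For `λ1 = λ2 = 0` under `TᵀT = I` the global minimizer is closed-form: the
scores are the top-R eigenvectors of `H_X Z Zᵀ H_X`, with `H_X` the projector
onto the column space of X. The implementation computes a thin SVD of X
through the smaller of the two Gram matrices (`X Xᵀ` when observations are
fewer, `Xᵀ X` otherwise), reduces the eigenproblem to rank(X) × rank(X), and
recovers `W` as the least-squares solution of `X W = T` and `P = Zᵀ T`. This
solution is validated against a 1000-candidate random search and serves as
the *rational start* of the penalized fits.

## Alternating estimation

The penalized loss is minimized by alternating two conditional problems:

* **Weights given loadings.** A coordinate-descent sweep over all `J×R`
  coefficients. Isolating `w[j, r]` leaves a univariate elastic-net problem
  whose unique minimizer is `w⁺ = sign(s)·max(|s| − λ1/2, 0) / d` with
  `s = x_jᵀ R p_r + w[j,r]·‖x_j‖²·‖p_r‖²` (R the current full residual) and
  `d = λ2 + ‖x_j‖²·‖p_r‖²`. The denominator includes the loading-norm factor
  `‖p_r‖²`; it reduces to `λ2 + ‖x_j‖²` exactly when the concatenated loading
  column has unit norm. The update is verified coefficient-by-coefficient
  against a dense 1-D grid search of the full objective. The residual matrix
  is maintained incrementally (each update costs O(I)) and recomputed from
  scratch every 10 sweeps to bound floating-point drift; tests check the
  incremental and from-scratch residuals agree to 1e-8. The sweep kernel is
  compiled with numba when available; a pure-Python reference implementation
  of the same loop is used otherwise.
* **Loadings given weights.** With the *unit-length* constraint
  (`diag(PᵀP) = 1`, the default; allows correlated loadings) each column is
  the normalized cross-product `p_r = Q_rᵀ t_r / ‖Q_rᵀ t_r‖` of the deflated
  target with the component's score, cycled until stable. The normalization
  to unit length is what the constraint demands; a vanishing cross-product
  leaves the column unchanged with a logged warning. With the *orthogonal*
  constraint the update is the orthogonal Procrustes solution `P = V Uᵀ` from
  the SVD of `TᵀZ`, with an equivalent R × R eigendecomposition path used
  when the concatenated variable count is large (both paths are compared to
  1e-10 in tests). The unit-length constraint is applied to the
  *concatenated* loading column — the form the conditional algebra assumes.

Both steps are exact conditional minimizers, so the penalized loss is
non-increasing; the alternation asserts this at every conditional step and
raises if a step increases the loss by more than 1e-8 (an implementation
fault, not a data condition). Convergence is declared when the relative loss
change over one alternation falls below `tol = 1e-6` (default), capped at
`max_iter = 500` alternations. Multistart: the rational start, an optional
warm start (the previous solution on a penalty path), and 5 random starts by
default (standard-normal weights scaled to unit score variance). Sparse fits
do not enforce `TᵀT = I` — the penalty breaks score orthogonality, and
identification is carried by the loading constraint.

Fixed-support refits (`refit_fixed_support`) rerun the same alternation with
`λ1 = λ2 = 0` and all coordinates outside a given zero-pattern mask skipped;
this debiases the elastic-net shrinkage of selected coefficients and is also
a building block of the data generator.

## Meta-parameter tuning

* **α** — the maximum-likelihood rule `α = Jx / (Jx + Jy σ²εx/σ²εy)`. The
  error variances are plug-in moment estimates: `σ²εx` is the residual mean
  square of the r-component PCA of X, `σ²εy` the residual mean square of the
  least-squares regression of Y on those r PCA scores. For wide predictor
  blocks the raw value approaches 1; it is capped at 0.99 so the outcome
  always keeps strictly positive weight (what distinguishes the method from
  plain principal components regression).
* **R** — a scree test on the exact loss for r = 1..Rmax. The visual test
  (pick the r before the curve levels off) is automated as the r maximizing
  the drop ratio `(loss[r−1] − loss[r]) / (loss[r] − loss[r+1])`, with the
  zero-component loss equal to one; a maximal ratio below 2 (a near-linear
  decrease, as for pure noise) is flagged low-confidence. The loss table and
  plot are still emitted for visual inspection.
* **λ2** — rides at 5% of λ1 along the path (`ridge_fraction`), enough to
  stabilize the estimates and encourage grouping without blunting selection.
* **λ1** — stability selection, below.

## Stability selection

The path starts at `λmax = 2·max_{j,r} |x_jᵀ Z p_r|` (the smallest penalty at
which every coordinate update from W = 0 stays zero, computed with the
rational-start loadings), ends at `λmin = 1e-4·λmax`, and is equally spaced
in log2 (50 values by default). At each λ, in decreasing order:

1. the full data are refit (warm-started from the previous λ, multistart) as
   the alignment reference;
2. the running candidate count `q_Λ` — distinct coefficients nonzero in any
   reference fit so far, components aligned across λ to the non-sparse
   solution's scores — is updated; if it would exceed the bound
   `q_R = floor(R·sqrt(J(2π_thr − 1)E(V)))` (or an explicit override), the
   procedure stops *without* including that λ, keeping the premise of the
   expected-false-positive bound (the candidate set over the range stays
   within `q_R`) intact;
3. otherwise N resamples of `round(f·I)` observations are drawn with
   replacement (`f = 0.5`, `N = 500` by default), re-scaled and refit from
   the reference solution (rational-start warm start only — the full
   multistart is reserved for reference fits, for cost), each solution is
   aligned to the reference by maximal Tucker congruence of the scores at the
   resampled rows (exhaustive over permutations and signs for R ≤ 6), and
   the per-coefficient selection frequency is recorded in `Π^(λ)`. A
   coefficient counts as selected by its zero/non-zero status, regardless of
   sign.

`Π^(Stable)` is the elementwise maximum over the λ range used; the stable set
is `π ≥ π_thr` (default 0.90 with `E(V) = 1`), and the final model is an
unpenalized fixed-support refit on it.

## Synthetic-data generator

The generator emulates a two-component sparse covariates regression design:

1. `X⁰` is I × J standard normal (defaults I = 100, J = 200);
2. initial weights are the first two right singular vectors of `X⁰`, with
   `round(0.80·J·R)` randomly chosen entries set to zero (320 of 400 at the
   defaults);
3. weight columns are rescaled so `‖X⁰ w_r‖²` equals the component's share
   of the covariate-block signal (relative strengths, e.g. 0.10/0.90);
4. a fixed-zero-pattern covariates regression of `X⁰` with orthogonal
   loadings (the α = 1 fixed-support refit) yields a model-consistent pair
   (W, P): the generating model needs only the weights and orthonormal
   covariate loadings — the outcome is constructed from fixed regression
   weights — and at α = 1 the orthogonality constraint on the concatenated
   loadings coincides exactly with orthonormal `Px`;
5. after a second relative-strength rescale, `X_TRUE = X⁰ W Pᵀ` and
   `y_TRUE = X_TRUE W b` with `b = (1, −0.02)` (the first component drives
   the outcome);
6. normal noise is added with one variance per block (not per variable),
   calibrated so the expected signal fraction equals the nominal VAF:
   `σ² = SS(signal)·(1 − VAF) / (VAF · #entries)`.

Two score matrices are recorded: `t_true = X_TRUE W` (the component-recovery
target for Tucker congruence) and `t_construction = X⁰ W` (the scores the
block was built from, which reconstruct `X_TRUE` exactly with the orthonormal
loadings and whose rank-one terms define the per-component variance shares).
The two are distinct because `PᵀW ≠ I`, though it is near-diagonal; their
columns correlate above 0.99 in practice.

Test data for prediction metrics are fresh draws under the same model —
same design parameters, new signal and noise. Metrics: Tucker congruence
`φ = vec(T)ᵀvec(T̂) / sqrt(…)` after permutation/sign alignment (≥ 0.95 read
as "equal", 0.85–0.94 as fair similarity), computed with back-transformed
estimated scores (weights divided by the training column norms, so both score
sets live on the centered raw scale); and `PRESS = Σ(y − ŷ)² / Σy²` on the
test outcome, both observed and predicted mapped through the training
scaling.

The study harness ships sparse PCovR at α ∈ {0.01, 0.50, 0.99} as built-in
methods. Each walks the λ1 path (warm-started, ridge at 5%) until at least
`q = 80` weights are active — mirroring a tuning matched to the true
sparseness — then debiases on the selected support. Competing-method
providers can be supplied by the caller through the same `fit`/`predict`
protocol; failures are recorded per row, not fatal.

## What the generator does and does not establish

The planted loadings `P` are **dense**: every covariate column carries
component signal, so the component *scores* are identified but the sparse
*weights* are not — the scores admit many sparse representations, and on
exactly noise-free (rank-R) data the penalized fit reaches zero loss with a
sparser weight set than the planted one. Passing recovery tests therefore
certify score congruence, not support recovery; selection stability under
this design measures the reproducibility of the compact representation the
penalty prefers. Real data with approximately sparse loadings may behave
differently in this respect. The generator also uses one noise variance per
block, so it does not emulate per-gene heteroscedasticity, batch structure,
or heavy-tailed expression noise.

## Vaccine-study recipe

The application module reproduces the preprocessing of the flu-vaccination
analysis: predictor block = day-3 minus baseline expression per probeset,
centered and scaled (probesets with constant differences must be filtered
first — they raise); outcome = the per-subject maximum over three HAI assay
types of the log titer change from baseline to day 28, centered but *not*
rescaled (the maximum dampens subjects starting high from prior infections;
natural logarithms are used). The full recipe — R = 2, α = 0.99,
λ2 = 0.05·λ1, stability selection with N = 500, π_thr = 0.90, E(V) = 1 — is
one function call (`run_flu_recipe`) or one config file via the CLI. Public
accession identifiers are carried as provenance strings only; nothing is
downloaded, and tests exercise the recipe on a synthetic fixture of the
study's shape (26 subjects × 2000 probesets).

## Problem sizes and numerical choices

The simulation-backed tests run at the design's native I = 100, J = 200 with
replicate counts scaled to desk size: 5 replicates per condition for the
PRESS and recovery checks, 20 seeds for generator calibration, N = 100
resamples (half the recommended 500) for the stability-selection check.
Stochastic assertions use a 10% tolerance; exact algebraic identities use
1e-8–1e-12; estimator-vs-oracle comparisons use 1e-6 (or the oracle's grid
step). Ties in the soft threshold resolve to zero (`|s| = λ1/2` gives
`w⁺ = 0`); degenerate inputs (constant columns, empty supports, zero score
columns, rank-deficient Procrustes) are either rejected with a named error or
handled with a logged warning, as documented per function.
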