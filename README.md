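# spcovr — sparse principal covariates regression

`spcovr` fits **sparse principal covariates regression (SPCovR)** models:
penalized component models for settings where a high-dimensional predictor
block (for example genomewide expression responses) must be *reduced to a few
interpretable components* and those components must *predict an outcome* (for
example antibody titers after vaccination) — both at once. Pure prediction
methods (lasso/elastic net) ignore the structural variation in the
predictors; pure exploration methods (PCA) ignore the outcome. SPCovR weighs
both goals and selects the variables that carry the components.

## Model

Predictors `X` (I × Jx) and outcomes `Y` (I × Jy) are centered and scaled to
per-column sum of squares one. With component weights `W` (Jx × R), scores
`T = X W`, predictor loadings `Px` and regression weights `Py`, the model is

```
X = X W Pxᵀ + Ex        Y = X W Pyᵀ + Ey
```

and the penalized objective, for a weighting parameter `α ∈ [0, 1]`,

```
L(W, Px, Py) = (1 − α) ‖Y − X W Pyᵀ‖² / ‖Y‖²
             + α      ‖X − X W Pxᵀ‖² / ‖X‖²
             + λ₁ |W|₁ + λ₂ |W|₂²
```

`α = 1` is (sparse) principal components analysis/regression; `α = 0, R = 1`
is elastic-net regression. The loss is minimized by alternating coordinate
descent on `W` (soft thresholding) with constrained least-squares updates of
the loadings (unit-length columns, or orthonormal via Procrustes), from a
rational start (the exact unpenalized solution, computed in closed form from
an SVD of `X`) plus random restarts.

Meta-parameters follow a stepwise strategy: `α` from a maximum-likelihood
rule (`α = Jx / (Jx + Jy σ²εx/σ²εy)`, capped at 0.99), `R` from a scree test,
`λ₂ = 0.05 λ₁`, and `λ₁` by **stability selection**: refitting on resamples
along a decreasing λ₁ path and keeping the coefficients whose selection
probability exceeds `π_thr = 0.90`, with the path length limited by the bound
`q_R = R·sqrt(J (2π_thr − 1) E(V))` on the expected number `E(V)` of false
selections.

## Worked example

```python
import numpy as np
from spcovr import (PenaltySettings, SimulationDesign, StabilitySettings,
                    FitOptions, center_scale, generate_dataset,
                    run_stability_selection)

data = generate_dataset(SimulationDesign(vaf_x=0.70, vaf_y=0.80), seed=1)
x, y = center_scale(data.x_observed), center_scale(data.y_observed)
result, model = run_stability_selection(
    x, y,
    PenaltySettings(alpha=0.99, n_components=2),
    StabilitySettings(n_resamples=100, q_override=80, seed=2),
    FitOptions(n_random_starts=1, seed=3),
)
print("lambda values in range:", len(result.lambdas_used))
print("candidate coefficients q_Lambda:", result.q_lambda, "bound:", result.q_bound)
print("stable coefficients:", int(result.stable_set.sum()))
print("nonzero weights in final model:", int((model.weights != 0).sum()))
```

prints

```
lambda values in range: 19
candidate coefficients q_Lambda: 73 bound: 80
stable coefficients: 10
nonzero weights in final model: 10
```

Of the 200 simulated predictors (2 planted components, 80% sparse weights,
70% covariate and 80% outcome variance accounted for), the λ₁ path was
extended over 19 values, accumulating 73 candidate coefficients before the
next value would have exceeded the sparseness bound of 80; 10 coefficients
were selected in ≥ 90% of 100 resamples, and the final model is an
unpenalized refit on exactly that stable set. (Only the *component scores*
are identified in this design — many sparse weight sets represent the same
components, so the stable set is a compact representation rather than the
planted support; see `docs/methods.md`.)

The same pipeline is available from the shell (`spcovr fit`,
`spcovr stability`, `spcovr scree`, `spcovr simulate`, `spcovr flu-recipe`);
every run writes a `manifest.json` with all settings and the seed.

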