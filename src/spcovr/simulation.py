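"""Synthetic data under a sparse covariates regression model, and study metrics.

The generator emulates a two-component design: sparse component weights are
derived from the leading right singular vectors of a standard-normal matrix,
80% of their entries are zeroed at random, and the columns are rescaled so the
components account for chosen relative shares of the covariate-block
variation.  A fixed-zero-pattern covariates regression refit then produces a
model-consistent weight/orthogonal-loading pair from which a noise-free
covariate block ``X_TRUE = X0 W P'`` and outcome ``y_TRUE = X_TRUE W b`` are
built (regression weights ``b = (1, -0.02)``, so the first component drives
the outcome).  Normal noise is added with one variance per block, calibrated
so the expected signal fraction equals the nominal variance-accounted-for
(VAFX for the covariates, VAFY for the outcome).

The evaluation metrics are Tucker's congruence coefficient between true and
recovered component scores (>= 0.95 read as "equal", 0.85-0.94 as fair
similarity) and the normalized squared prediction error PRESS on independent
test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    PenaltySettings,
    ScaledBlock,
    apply_scaling,
    center_scale,
)
from .sparse import FitOptions, _alternate, fit_spcovr, refit_fixed_support
from .stability import (
    StabilitySettings,
    align_components,
    build_lambda_path,
    compute_lambda_max,
    run_stability_selection,
)

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "generate_dataset",
    "tucker_congruence",
    "press",
    "run_study",
    "SPCovRProvider",
    "default_study_methods",
    "CONGRUENCE_EQUAL",
    "CONGRUENCE_FAIR",
]

#: Congruence at or above which components are considered equal.
CONGRUENCE_EQUAL = 0.95
#: Lower edge of the "fair similarity" congruence band.
CONGRUENCE_FAIR = 0.85


@dataclass(frozen=True)
class SimulationDesign:
    """Factors of the simulation design.

    ``vaf_x``/``vaf_y`` are the total proportions of variation accounted for
    by the components in the covariate block and the outcome; ``rel_strength``
    is the first component's share of the component variation in the covariate
    block (the second gets the complement); ``sparsity`` is the fraction of
    true component weights set to zero; ``b`` are the fixed regression weights
    of the two components.
    """

    n_obs: int = 100
    n_vars: int = 200
    n_components: int = 2
    vaf_x: float = 0.40
    vaf_y: float = 0.50
    rel_strength: float = 0.50
    sparsity: float = 0.80
    b: tuple[float, ...] = (1.0, -0.02)
    n_replicates: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.vaf_x < 1 and 0 < self.vaf_y < 1):
            raise ValueError("vaf_x and vaf_y must lie strictly between 0 and 1")
        if not 0 < self.rel_strength < 1:
            raise ValueError("rel_strength must lie strictly between 0 and 1")
        if len(self.b) != self.n_components:
            raise ValueError("b must have one weight per component")

    @property
    def strength_shares(self) -> tuple[float, ...]:
        if self.n_components != 2:
            raise ValueError("relative strengths are defined for two components")
        return (self.rel_strength, 1.0 - self.rel_strength)

    @property
    def n_zero_weights(self) -> int:
        return round(self.sparsity * self.n_vars * self.n_components)


@dataclass(frozen=True)
class SimulatedDataset:
    """One generated replicate: noisy and noise-free blocks plus the truth.

    ``t_true = X_TRUE @ w_true`` is the component-recovery target (scores of
    the noise-free data under the true weights).  ``t_construction = X0 @
    w_true`` holds the scores the block was built from; with the orthonormal
    true loadings they satisfy ``X_TRUE = t_construction @ p_true'`` exactly,
    and their rank-one terms tile the noise-free block, so per-component
    variance shares are computed from them.
    """

    x_observed: np.ndarray
    y_observed: np.ndarray
    x_true: np.ndarray
    y_true: np.ndarray
    w_true: np.ndarray
    p_true: np.ndarray
    t_true: np.ndarray
    t_construction: np.ndarray

    def component_share(self, r: int, of_observed: bool = True) -> float:
        """Share of the covariate-block sum of squares from component ``r``'s
        rank-one reconstruction."""
        rank_one = np.outer(self.t_construction[:, r], self.p_true[:, r])
        denom = self.x_observed if of_observed else self.x_true
        return float((rank_one**2).sum()) / float((denom**2).sum())


def _rescale_to_shares(
    w: np.ndarray, x0: np.ndarray, shares: tuple[float, ...]
) -> np.ndarray:
    """Scale each weight column so ||X0 w_r||^2 equals its strength share."""
    w = w.copy()
    for r, share in enumerate(shares):
        norm = np.linalg.norm(x0 @ w[:, r])
        if norm <= 1e-14:
            raise RuntimeError(f"component {r} vanished after sparsification")
        w[:, r] *= np.sqrt(share) / norm
    return w


def generate_dataset(design: SimulationDesign, seed: int) -> SimulatedDataset:
    """Generate one replicate under the sparse covariates regression model.

    Steps: standard-normal ``X0``; initial weights = leading right singular
    vectors; random zeroing of the designed number of entries; rescale to the
    relative strength shares; fixed-support covariates regression refit of
    ``X0`` with orthogonal loadings to obtain a model-consistent (W, P); a
    second rescale; then ``X_TRUE = X0 W P'``, ``y_TRUE = X_TRUE W b`` and
    per-block normal noise calibrated to the nominal VAF levels.
    """
    rng = np.random.default_rng(seed)
    i_obs, j_vars, n_comp = design.n_obs, design.n_vars, design.n_components
    x0 = rng.standard_normal((i_obs, j_vars))
    _, _, vt = np.linalg.svd(x0, full_matrices=False)
    w0 = vt[:n_comp].T
    flat = rng.choice(j_vars * n_comp, size=design.n_zero_weights, replace=False)
    w0 = w0.copy()
    w0.flat[flat] = 0.0
    shares = design.strength_shares
    w0 = _rescale_to_shares(w0, x0, shares)
    b = np.asarray(design.b)
    support = w0 != 0
    # Fixed-zero-pattern covariates regression of X0 with orthogonal loadings.
    refit_settings = PenaltySettings(
        alpha=1.0, n_components=n_comp, loading_constraint="orthogonal"
    )
    w_fit, p_fit, _ = _alternate(
        w0, x0, x0, refit_settings, FitOptions(max_iter=200, tol=1e-10),
        support=support, lambda1=0.0, lambda2=0.0,
    )
    w_true = _rescale_to_shares(w_fit, x0, shares)
    t_construction = x0 @ w_true
    x_true = t_construction @ p_fit.T
    y_true = x_true @ w_true @ b
    t_true = x_true @ w_true
    ss_x = float((x_true**2).sum())
    ss_y = float((y_true**2).sum())
    sigma_x = np.sqrt(ss_x * (1.0 - design.vaf_x) / (design.vaf_x * i_obs * j_vars))
    sigma_y = np.sqrt(ss_y * (1.0 - design.vaf_y) / (design.vaf_y * i_obs))
    x_obs = x_true + rng.normal(0.0, sigma_x, size=x_true.shape)
    y_obs = y_true + rng.normal(0.0, sigma_y, size=y_true.shape)
    return SimulatedDataset(
        x_observed=x_obs,
        y_observed=y_obs,
        x_true=x_true,
        y_true=y_true,
        w_true=w_true,
        p_true=p_fit,
        t_true=t_true,
        t_construction=t_construction,
    )


def tucker_congruence(t_true: np.ndarray, t_est: np.ndarray) -> float:
    """Cosine between the vectorized score matrices.

    Callers are expected to permute/sign-match the estimated columns first
    (see :func:`spcovr.stability.align_components`).
    """
    a = np.asarray(t_true, dtype=float).ravel()
    b = np.asarray(t_est, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("score matrices must share a shape")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("congruence undefined for an all-zero score matrix")
    return float(a @ b) / (na * nb)


def press(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared prediction error normalized by the total variation of y:
    ``sum((y - yhat)^2) / sum(y^2)``."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape:
        raise ValueError("observed and predicted outcomes must share a length")
    denom = float((y_obs**2).sum())
    if denom == 0:
        raise ValueError("PRESS undefined: observed outcome has zero sum of squares")
    return float(((y_obs - y_pred) ** 2).sum()) / denom


class SPCovRProvider:
    """Fitted-model provider for the study harness.

    Fits sparse PCovR at a given ``alpha``: walks the lasso path from
    ``lambda_max`` down (warm-started, ridge riding at ``ridge_fraction`` of
    the lasso) until at least ``q_nonzero`` component weights are active —
    mirroring a tuning that matches the true sparseness — then debiases by an
    unpenalized fixed-support refit.
    """

    def __init__(
        self,
        alpha: float,
        n_components: int = 2,
        q_nonzero: int = 80,
        grid_size: int = 20,
        ridge_fraction: float = 0.05,
        loading_constraint: str = "unit_length",
        n_random_starts: int = 1,
        use_stability: bool = False,
        stability: StabilitySettings | None = None,
    ) -> None:
        self.alpha = alpha
        self.n_components = n_components
        self.q_nonzero = q_nonzero
        self.grid_size = grid_size
        self.ridge_fraction = ridge_fraction
        self.loading_constraint = loading_constraint
        self.n_random_starts = n_random_starts
        self.use_stability = use_stability
        self.stability = stability
        self._x_block: ScaledBlock | None = None
        self._y_block: ScaledBlock | None = None
        self.model = None

    def fit(self, x_raw: np.ndarray, y_raw: np.ndarray, seed: int = 0) -> "SPCovRProvider":
        xb = center_scale(x_raw)
        yb = center_scale(y_raw)
        self._x_block, self._y_block = xb, yb
        options = FitOptions(n_random_starts=self.n_random_starts, seed=seed)
        base = PenaltySettings(
            alpha=self.alpha,
            n_components=self.n_components,
            loading_constraint=self.loading_constraint,
        )
        if self.use_stability:
            stab = self.stability or StabilitySettings(
                q_override=self.q_nonzero, seed=seed
            )
            _, self.model = run_stability_selection(xb, yb, base, stab, options)
            return self
        lam_max = compute_lambda_max(xb, yb, base)
        path = build_lambda_path(lam_max, self.grid_size)
        w_warm = None
        model = None
        for lam in path.values:
            lam_settings = PenaltySettings(
                alpha=self.alpha,
                lambda1=float(lam),
                lambda2=self.ridge_fraction * float(lam),
                n_components=self.n_components,
                loading_constraint=self.loading_constraint,
            )
            model, _, _ = fit_spcovr(xb, yb, lam_settings, options, w_init=w_warm)
            w_warm = model.weights
            if int((model.weights != 0).sum()) >= self.q_nonzero:
                break
        support = model.weights != 0
        if support.any():
            model = refit_fixed_support(xb, yb, support, base, options)
        self.model = model
        return self

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights

    def scores_raw(self, x_raw: np.ndarray) -> np.ndarray:
        """Component scores on the centered raw scale (back-transformed weights)."""
        xs = apply_scaling(x_raw, self._x_block)
        return xs @ self.model.weights

    def predict_scaled(self, x_raw: np.ndarray) -> np.ndarray:
        """Predicted outcome on the training-scaled outcome scale."""
        xs = apply_scaling(x_raw, self._x_block)
        return self.model.predict(xs)

    def scale_outcome(self, y_raw: np.ndarray) -> np.ndarray:
        return apply_scaling(y_raw, self._y_block)


def default_study_methods(**kwargs) -> dict:
    """The built-in method set: sparse PCovR at alpha in {0.01, 0.50, 0.99}."""
    return {
        f"spcovr_alpha{a:.2f}": SPCovRProvider(alpha=a, **kwargs)
        for a in (0.01, 0.50, 0.99)
    }


def run_study(
    conditions: list[SimulationDesign],
    n_replicates: int,
    methods: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the simulation study over ``conditions`` and return a tidy table.

    Per replicate: a training and an independent test dataset are generated
    under the same model parameters (fresh signal and noise), each method is
    fit on the training data, and two metrics are recorded — the aligned
    Tucker congruence between the true scores ``X_TRUE W_true`` and the
    recovered ones, and PRESS on the test outcome.  Method failures are
    recorded as rows with null metrics rather than aborting the study.
    """
    methods = methods if methods is not None else default_study_methods()
    rows = []
    rng = np.random.default_rng(seed)
    for cond_idx, design in enumerate(conditions):
        for rep in range(n_replicates):
            train_seed = int(rng.integers(0, 2**31 - 1))
            test_seed = int(rng.integers(0, 2**31 - 1))
            train = generate_dataset(design, train_seed)
            test = generate_dataset(design, test_seed)
            for name, provider in methods.items():
                base = {
                    "condition": cond_idx,
                    "vaf_x": design.vaf_x,
                    "vaf_y": design.vaf_y,
                    "rel_strength": design.rel_strength,
                    "method": name,
                    "replicate": rep,
                }
                try:
                    fitted = provider.fit(
                        train.x_observed, train.y_observed, seed=train_seed
                    )
                    t_hat = fitted.scores_raw(train.x_observed)
                    perm, signs = align_components(t_hat, train.t_true)
                    phi = tucker_congruence(train.t_true, t_hat[:, perm] * signs)
                    y_pred = fitted.predict_scaled(test.x_observed)
                    y_test = fitted.scale_outcome(test.y_observed)
                    prs = press(y_test, y_pred)
                except Exception as exc:  # failures are data, not fatal
                    rows.append({**base, "phi": np.nan, "press": np.nan,
                                 "error": str(exc)})
                    continue
                rows.append({**base, "phi": phi, "press": prs, "error": ""})
    return pd.DataFrame(rows)
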