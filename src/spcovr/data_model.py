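"""Core data containers and the weighted least-squares loss of principal covariates
regression.

Principal covariates regression (PCovR) summarizes a predictor block ``X`` (I
observations x Jx variables) by R component scores ``T = X W`` and uses those
scores both to reconstruct ``X`` (through loadings ``Px``) and to predict an
outcome block ``Y`` (through regression weights ``Py``).  The loss is a convex
combination, weighted by ``alpha``, of the two normalized residual fractions::

    L = (1 - alpha) * ||Y - X W Py'||^2 / ||Y||^2
        + alpha * ||X - X W Px'||^2 / ||X||^2

which can be rewritten as a single least-squares problem ``||Z - X W P'||^2``
on the weighted concatenation ``Z = [w1*Y, w2*X]`` with ``w1 = sqrt(1-alpha)/||Y||``
and ``w2 = sqrt(alpha)/||X||``.  The sparse extension adds an elastic-net
penalty on the component weights ``W`` only.

All blocks are centered and scaled so every column has sum of squares one;
under that convention ``||X||_F^2 = Jx`` and ``||Y||_F^2 = Jy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaledBlock",
    "PenaltySettings",
    "ConcatenatedTarget",
    "ComponentModel",
    "FitSummary",
    "center_scale",
    "apply_scaling",
    "build_concatenated_target",
    "evaluate_fit",
]


@dataclass(frozen=True)
class ScaledBlock:
    """A centered data block whose columns each have sum of squares one.

    ``column_means`` and ``column_norms`` hold the original per-column mean and
    the root sum of squares of the centered column, so the raw data can be
    recovered exactly as ``values * column_norms + column_means``.
    """

    values: np.ndarray
    column_means: np.ndarray
    column_norms: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def unscale(self) -> np.ndarray:
        """Back-transform to the raw data."""
        return self.values * self.column_norms + self.column_means


@dataclass(frozen=True)
class PenaltySettings:
    """Meta-parameters of a (sparse) PCovR fit.

    Parameters
    ----------
    alpha : float in [0, 1]
        Weight of the predictor-reconstruction term; ``alpha=1`` gives
        principal components regression, ``alpha=0`` ordinary (penalized)
        regression.
    lambda1, lambda2 : float >= 0
        Lasso and ridge penalty strengths on the component weights W.
    n_components : int >= 1
        Number of components R.
    loading_constraint : {"unit_length", "orthogonal"}
        Identification constraint on the concatenated loading matrix P:
        unit-length columns (oblique, allows correlated loadings) or
        orthonormal columns.
    """

    alpha: float
    lambda1: float = 0.0
    lambda2: float = 0.0
    n_components: int = 2
    loading_constraint: str = "unit_length"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be non-negative")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.loading_constraint not in ("unit_length", "orthogonal"):
            raise ValueError(
                "loading_constraint must be 'unit_length' or 'orthogonal', "
                f"got {self.loading_constraint!r}"
            )


@dataclass(frozen=True)
class ConcatenatedTarget:
    """The weighted concatenation ``Z = [w1*Y, w2*X]`` of outcome and predictors.

    The first ``n_outcomes`` columns are the outcome block.  ``w1`` and ``w2``
    are the concatenation weights sqrt(1-alpha)/||Y|| and sqrt(alpha)/||X||.
    """

    z: np.ndarray
    w1: float
    w2: float
    n_outcomes: int

    @property
    def n_predictors(self) -> int:
        return self.z.shape[1] - self.n_outcomes


@dataclass
class ComponentModel:
    """Fitted (sparse) PCovR parameters.

    ``weights`` (Jx x R) map predictors to scores, ``loadings_x`` (Jx x R)
    reconstruct the predictors from the scores and ``loadings_y`` (Jy x R)
    predict the outcomes.  ``scores`` is always ``X @ weights``.
    """

    weights: np.ndarray
    loadings_x: np.ndarray
    loadings_y: np.ndarray
    scores: np.ndarray
    constraint_mode: str = "unit_length"

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def predict(self, x_scaled: np.ndarray) -> np.ndarray:
        """Predict the (scaled) outcome block for new scaled predictors."""
        return x_scaled @ self.weights @ self.loadings_y.T

    def reconstruct(self, x_scaled: np.ndarray) -> np.ndarray:
        """Reconstruct the (scaled) predictor block."""
        return x_scaled @ self.weights @ self.loadings_x.T


@dataclass(frozen=True)
class FitSummary:
    """Loss and variance-accounted-for summary of a fitted model."""

    loss_unpenalized: float
    loss_penalized: float
    r2_x: float
    r2_y: float
    vaf_per_component_x: np.ndarray
    r2_y_per_component: np.ndarray


def center_scale(raw: np.ndarray) -> ScaledBlock:
    """Center each column and scale it to sum of squares one.

    Raises ``ValueError`` on non-finite entries or constant columns (the
    offending column index is named so callers can filter).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    if raw.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite entries in input matrix")
    means = raw.mean(axis=0)
    centered = raw - means
    norms = np.sqrt((centered**2).sum(axis=0))
    bad = np.flatnonzero(norms <= 1e-12 * max(1.0, np.abs(means).max()))
    if bad.size:
        raise ValueError(f"constant column at index {bad[0]}: cannot scale")
    return ScaledBlock(values=centered / norms, column_means=means, column_norms=norms)


def apply_scaling(raw: np.ndarray, block: ScaledBlock) -> np.ndarray:
    """Apply a previously fitted centering/scaling (e.g. to test data)."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    if raw.shape[1] != block.n_vars:
        raise ValueError("column count does not match the fitted block")
    return (raw - block.column_means) / block.column_norms


def build_concatenated_target(
    x: ScaledBlock, y: ScaledBlock, settings: PenaltySettings
) -> ConcatenatedTarget:
    """Form ``Z = [w1*Y, w2*X]`` with the alpha-dependent concatenation weights."""
    if x.n_obs != y.n_obs:
        raise ValueError(
            f"row-count mismatch: X has {x.n_obs} observations, Y has {y.n_obs}"
        )
    norm_y = np.linalg.norm(y.values)  # = sqrt(Jy) under the scaling convention
    norm_x = np.linalg.norm(x.values)  # = sqrt(Jx)
    w1 = np.sqrt(1.0 - settings.alpha) / norm_y
    w2 = np.sqrt(settings.alpha) / norm_x
    z = np.hstack([w1 * y.values, w2 * x.values])
    return ConcatenatedTarget(z=z, w1=w1, w2=w2, n_outcomes=y.n_vars)


def concatenated_loadings(model: ComponentModel, target: ConcatenatedTarget) -> np.ndarray:
    """Stack the loading blocks into the concatenated ``P = [w1*Py; w2*Px]``."""
    return np.vstack([target.w1 * model.loadings_y, target.w2 * model.loadings_x])


def split_loadings(
    p: np.ndarray, target: ConcatenatedTarget
) -> tuple[np.ndarray, np.ndarray]:
    """Split a concatenated loading matrix back into (Py, Px).

    Degenerate weights (``w1 = 0`` at ``alpha = 1`` or ``w2 = 0`` at
    ``alpha = 0``) map the corresponding block to zero: those loadings do not
    enter the loss and are reported as zero rather than as an ill-defined
    division.
    """
    jy = target.n_outcomes
    py = p[:jy] / target.w1 if target.w1 > 0 else np.zeros_like(p[:jy])
    px = p[jy:] / target.w2 if target.w2 > 0 else np.zeros_like(p[jy:])
    return py, px


def evaluate_fit(
    model: ComponentModel,
    x: ScaledBlock,
    y: ScaledBlock,
    settings: PenaltySettings,
) -> FitSummary:
    """Evaluate the PCovR loss and variance-accounted-for measures.

    ``loss_unpenalized`` is the convex combination of the normalized residual
    fractions of the two blocks; ``loss_penalized`` adds the elastic-net
    penalty on W.  Per-component VAF in X uses the rank-one reconstruction
    ``t_r px_r'`` sum of squares over the total sum of squares of X; the
    per-component outcome measure is analogous on Y.
    """
    w, px, py = model.weights, model.loadings_x, model.loadings_y
    t = x.values @ w
    ss_x = float((x.values**2).sum())
    ss_y = float((y.values**2).sum())
    res_x = x.values - t @ px.T
    res_y = y.values - t @ py.T
    frac_x = float((res_x**2).sum()) / ss_x
    frac_y = float((res_y**2).sum()) / ss_y
    loss = (1.0 - settings.alpha) * frac_y + settings.alpha * frac_x
    penalty = settings.lambda1 * np.abs(w).sum() + settings.lambda2 * (w**2).sum()
    vaf_x = np.array(
        [float((np.outer(t[:, r], px[:, r]) ** 2).sum()) / ss_x for r in range(w.shape[1])]
    )
    r2y_comp = np.array(
        [float((np.outer(t[:, r], py[:, r]) ** 2).sum()) / ss_y for r in range(w.shape[1])]
    )
    return FitSummary(
        loss_unpenalized=loss,
        loss_penalized=loss + float(penalty),
        r2_x=1.0 - frac_x,
        r2_y=1.0 - frac_y,
        vaf_per_component_x=vaf_x,
        r2_y_per_component=r2y_comp,
    )
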