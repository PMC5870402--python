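"""Exact (non-sparse) principal covariates regression and meta-parameter tuning.

The unpenalized PCovR problem ``min ||Z - X W P'||^2`` subject to
``T = X W``, ``T'T = I`` has a closed-form solution: the optimal scores are
the leading eigenvectors of ``H_X Z Z' H_X`` where ``H_X`` projects onto the
column space of X.  This module computes that solution through an SVD of X
(working with the smaller Gram matrix when either dimension is large), and
implements the two stepwise tuning steps that precede the sparse fit: the
maximum-likelihood choice of the weighting parameter alpha and a scree test
over the number of components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    ComponentModel,
    PenaltySettings,
    ScaledBlock,
    build_concatenated_target,
    split_loadings,
)

__all__ = [
    "AlphaEstimate",
    "ScreeResult",
    "solve_pcovr",
    "alpha_from_variances",
    "maximum_likelihood_alpha",
    "scree",
]

#: alpha is capped strictly below one so the outcome keeps nonzero weight.
ALPHA_CAP = 0.99

#: Drop-ratio below which a scree elbow suggestion is flagged low-confidence.
SCREE_CONFIDENCE_RATIO = 2.0


@dataclass(frozen=True)
class AlphaEstimate:
    """Maximum-likelihood estimate of the weighting parameter alpha.

    ``alpha = Jx / (Jx + Jy * sigma2_ex / sigma2_ey)`` with plug-in error
    variances; ``clamped`` marks that the cap at :data:`ALPHA_CAP` was applied.
    """

    alpha: float
    sigma2_ex: float
    sigma2_ey: float
    clamped: bool


@dataclass(frozen=True)
class ScreeResult:
    """Loss per number of components and the automated elbow suggestion."""

    losses: np.ndarray
    suggested_r: int
    confident: bool


def _thin_svd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD of x via the smaller Gram matrix; returns only rank(x) triplets."""
    i, j = x.shape
    if i <= j:
        g = x @ x.T
        evals, u = np.linalg.eigh(g)
        order = np.argsort(evals)[::-1]
        evals, u = evals[order], u[:, order]
        keep = evals > max(evals[0], 0.0) * 1e-12
        s = np.sqrt(evals[keep])
        u = u[:, keep]
        v = x.T @ u / s
    else:
        g = x.T @ x
        evals, v = np.linalg.eigh(g)
        order = np.argsort(evals)[::-1]
        evals, v = evals[order], v[:, order]
        keep = evals > max(evals[0], 0.0) * 1e-12
        s = np.sqrt(evals[keep])
        v = v[:, keep]
        u = x @ v / s
    return u, s, v


def solve_pcovr(
    x: ScaledBlock, y: ScaledBlock, settings: PenaltySettings
) -> ComponentModel:
    """Solve unpenalized PCovR exactly.

    Requires ``lambda1 = lambda2 = 0`` and ``R <= rank(X)``.  The returned
    scores are orthonormal, ``W`` is the least-squares solution of
    ``X W = T`` and the loadings are ``P = Z' T`` split into outcome and
    predictor blocks.
    """
    if settings.lambda1 != 0 or settings.lambda2 != 0:
        raise ValueError("closed-form PCovR requires lambda1 = lambda2 = 0")
    r = settings.n_components
    target = build_concatenated_target(x, y, settings)
    u, s, v = _thin_svd(x.values)
    if r > s.size:
        raise ValueError(f"R = {r} exceeds rank(X) = {s.size}")
    # Project Z onto col(X): H_X Z = U (U'Z). Eigenvectors of H_X Z Z' H_X are
    # U A with A the top eigenvectors of the rank x rank matrix (U'Z)(U'Z)'.
    g = u.T @ target.z
    evals, vecs = np.linalg.eigh(g @ g.T)
    order = np.argsort(evals)[::-1][:r]
    a = vecs[:, order]
    t = u @ a
    w = v @ (a / s[:, None])
    p = target.z.T @ t
    py, px = split_loadings(p, target)
    return ComponentModel(
        weights=w,
        loadings_x=px,
        loadings_y=py,
        scores=x.values @ w,
        constraint_mode=settings.loading_constraint,
    )


def alpha_from_variances(
    jx: int, jy: int, sigma2_ex: float, sigma2_ey: float
) -> AlphaEstimate:
    """The maximum-likelihood weighting rule for given error variances:
    ``alpha = Jx / (Jx + Jy * sigma2_ex / sigma2_ey)``, capped at
    :data:`ALPHA_CAP`."""
    if sigma2_ey <= 0 or sigma2_ex < 0:
        return AlphaEstimate(ALPHA_CAP, max(sigma2_ex, 0.0), max(sigma2_ey, 0.0), True)
    alpha = jx / (jx + jy * sigma2_ex / sigma2_ey)
    if alpha > ALPHA_CAP:
        return AlphaEstimate(ALPHA_CAP, sigma2_ex, sigma2_ey, True)
    return AlphaEstimate(alpha, sigma2_ex, sigma2_ey, False)


def maximum_likelihood_alpha(x: ScaledBlock, y: ScaledBlock, r: int) -> AlphaEstimate:
    """Choose alpha by the maximum-likelihood rule with plug-in error variances.

    ``sigma2_ex`` is the residual mean square of the r-component PCA of X and
    ``sigma2_ey`` the residual mean square of the least-squares regression of Y
    on those r PCA scores.  The returned alpha is capped at :data:`ALPHA_CAP`
    (for wide predictor blocks the raw ratio approaches one, and keeping the
    outcome weighted strictly positive is what distinguishes PCovR from plain
    principal components regression).
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    jx, jy = x.n_vars, y.n_vars
    u, s, _ = _thin_svd(x.values)
    r_eff = min(r, s.size)
    ss_x = float((x.values**2).sum())
    sigma2_ex = (ss_x - float((s[:r_eff] ** 2).sum())) / (x.n_obs * jx)
    scores = u[:, :r_eff] * s[:r_eff]
    coef, *_ = np.linalg.lstsq(scores, y.values, rcond=None)
    resid = y.values - scores @ coef
    sigma2_ey = float((resid**2).sum()) / (y.n_obs * jy)
    return alpha_from_variances(jx, jy, sigma2_ex, sigma2_ey)


def scree(
    x: ScaledBlock, y: ScaledBlock, alpha: float, r_max: int
) -> ScreeResult:
    """Loss of the exact PCovR solution for r = 1..r_max plus an elbow suggestion.

    The visual scree test looks for the point where the loss-versus-r curve
    levels off; the automated stand-in picks the r maximizing the drop ratio
    ``(loss[r-1] - loss[r]) / (loss[r] - loss[r+1])`` with the zero-component
    loss equal to one.  A maximal ratio below :data:`SCREE_CONFIDENCE_RATIO`
    (near-linear decrease, as for pure noise) is flagged low-confidence.
    """
    from .data_model import evaluate_fit

    losses = []
    for r in range(1, r_max + 1):
        settings = PenaltySettings(alpha=alpha, n_components=r)
        model = solve_pcovr(x, y, settings)
        losses.append(evaluate_fit(model, x, y, settings).loss_unpenalized)
    losses = np.asarray(losses)
    if r_max == 1:
        return ScreeResult(losses=losses, suggested_r=1, confident=False)
    padded = np.concatenate([[1.0], losses])  # padded[r] = loss with r components
    eps = 1e-12
    ratios = np.full(r_max, -np.inf)
    for r in range(1, r_max):
        drop_here = padded[r - 1] - padded[r]
        drop_next = padded[r] - padded[r + 1]
        ratios[r - 1] = drop_here / max(drop_next, eps)
    best = int(np.argmax(ratios[: r_max - 1]))
    return ScreeResult(
        losses=losses,
        suggested_r=best + 1,
        confident=bool(ratios[best] >= SCREE_CONFIDENCE_RATIO),
    )
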