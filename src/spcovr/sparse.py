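"""The alternating sparse PCovR estimator.

The penalized loss ``||Z - X W P'||^2 + lambda1*|W|_1 + lambda2*|W|_2^2`` is
minimized by alternating two conditional steps:

* **Weights given loadings** — an elastic-net regression on RJ coefficients,
  solved by coordinate descent: isolating one coefficient ``w[j, r]`` leaves a
  univariate elastic-net problem whose minimizer is the soft-thresholding
  update ``w+ = sign(s) * max(|s| - lambda1/2, 0) / d`` with
  ``s = x_j' R p_r + w[j, r] * ||x_j||^2 * ||p_r||^2`` (R the full residual)
  and ``d = lambda2 + ||x_j||^2 * ||p_r||^2``.
* **Loadings given weights** — a restricted least-squares problem: with
  orthonormality on P it is an orthogonal Procrustes problem solved from the
  SVD of ``T'Z``; with unit-length columns each ``p_r`` is the normalized
  cross-product ``Q_r' t_r / ||Q_r' t_r||`` of the component's deflated target
  with its score, cycled until stable.

Both steps decrease the penalized loss, so the alternation converges to a
stationary point; a multistart scheme (rational start from the exact
non-sparse solution plus random starts) guards against local minima.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    ComponentModel,
    ConcatenatedTarget,
    FitSummary,
    PenaltySettings,
    ScaledBlock,
    build_concatenated_target,
    evaluate_fit,
    split_loadings,
)
from .pcovr import solve_pcovr

__all__ = [
    "FitOptions",
    "fit_spcovr",
    "refit_fixed_support",
    "update_weights_coordinate_descent",
    "update_loadings",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Recompute the residual matrix from scratch every this many sweeps to bound
#: floating-point drift of the incremental updates.
RESIDUAL_REFRESH_EVERY = 10

#: A conditional step increasing the penalized loss by more than this signals
#: an implementation fault and raises.
MONOTONICITY_SLACK = 1e-8


def _cd_component_py(xt, u, w_r, col_ss, c_r, lam1, lam2, support_r, order, delta):
    """Sequential coordinate updates for one component (reference kernel).

    ``xt`` is the transposed predictor block (J x I, so each variable is a
    contiguous row), ``u = residual @ p_r`` is maintained incrementally and
    ``delta`` collects the per-variable weight changes for the caller's
    residual update.  Returns (max |change|, all-finite flag).
    """
    half = lam1 / 2.0
    max_change = 0.0
    n_obs = xt.shape[1]
    for oi in range(order.shape[0]):
        j = order[oi]
        if not support_r[j]:
            continue
        s = 0.0
        for i in range(n_obs):
            s += xt[j, i] * u[i]
        s += w_r[j] * col_ss[j] * c_r
        if not np.isfinite(s):
            return max_change, False
        d = lam2 + col_ss[j] * c_r
        if s > half:
            w_new = (s - half) / d
        elif s < -half:
            w_new = (s + half) / d
        else:
            w_new = 0.0
        diff = w_new - w_r[j]
        if diff != 0.0:
            step = diff * c_r
            for i in range(n_obs):
                u[i] -= step * xt[j, i]
            w_r[j] = w_new
            delta[j] = diff
            if abs(diff) > max_change:
                max_change = abs(diff)
    return max_change, True


try:  # the jitted kernel is a drop-in replacement for the reference loop
    from numba import njit

    _cd_component = njit(cache=False, fastmath=False)(_cd_component_py)
except ImportError:  # pragma: no cover
    _cd_component = _cd_component_py


@dataclass(frozen=True)
class FitOptions:
    """Convergence and multistart control for :func:`fit_spcovr`.

    ``tol`` is the relative penalized-loss change below which the alternation
    stops; ``n_random_starts`` random starts are run in addition to the
    rational (exact non-sparse) start; ``debias`` re-estimates the nonzero
    weights without penalties after convergence.
    """

    max_iter: int = 500
    tol: float = 1e-6
    n_random_starts: int = 5
    seed: int = 0
    debias: bool = False

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _penalized_loss(
    z: np.ndarray, x: np.ndarray, w: np.ndarray, p: np.ndarray,
    lambda1: float, lambda2: float,
) -> float:
    resid = z - (x @ w) @ p.T
    return float((resid**2).sum() + lambda1 * np.abs(w).sum() + lambda2 * (w**2).sum())


def update_weights_coordinate_descent(
    w: np.ndarray,
    p: np.ndarray,
    x: np.ndarray,
    residual: np.ndarray,
    lambda1: float,
    lambda2: float,
    support: np.ndarray | None = None,
    order: np.ndarray | None = None,
) -> float:
    """One full coordinate-descent sweep over all weight coefficients.

    ``w`` and ``residual`` (the full residual ``Z - X W P'``) are updated in
    place; the incremental residual bookkeeping keeps each coordinate update
    O(I).  ``support`` restricts updates to a boolean mask (coefficients
    outside it stay at their current value, used with an all-zero ``w`` for
    fixed-support refits); ``order`` permutes the variable order within each
    component sweep.  Returns the largest absolute coefficient change.
    """
    n_comp = w.shape[1]
    n_vars = w.shape[0]
    xt = np.ascontiguousarray(x.T)
    col_ss = (x**2).sum(axis=0)
    j_order = (
        np.arange(n_vars, dtype=np.int64)
        if order is None
        else np.asarray(order, dtype=np.int64)
    )
    all_true = np.ones(n_vars, dtype=bool)
    max_change = 0.0
    for r in range(n_comp):
        p_r = p[:, r]
        c_r = float(p_r @ p_r)
        if c_r == 0.0:
            continue
        u = residual @ p_r  # I-vector, maintained incrementally
        delta = np.zeros(n_vars)
        w_r = np.ascontiguousarray(w[:, r])
        support_r = all_true if support is None else np.ascontiguousarray(support[:, r])
        change, finite = _cd_component(
            xt, u, w_r, col_ss, c_r, lambda1, lambda2, support_r, j_order, delta
        )
        if not finite:
            raise ValueError(
                "non-finite value in coordinate update; input is likely "
                "unscaled or contains non-finite entries"
            )
        w[:, r] = w_r
        max_change = max(max_change, change)
        if np.any(delta):
            residual -= np.outer(x @ delta, p_r)
    return max_change


def _procrustes_loadings(t: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Orthonormal P maximizing tr(P' Z' T): P = V U' from the SVD of T'Z."""
    m = t.T @ z
    u, _, vt = np.linalg.svd(m, full_matrices=False)
    return vt.T @ u.T


def _procrustes_loadings_gram(t: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Same Procrustes solution via the R x R eigendecomposition of T'ZZ'T.

    Cheaper than the direct SVD when the concatenated variable count is much
    larger than R.
    """
    m = t.T @ z
    evals, u = np.linalg.eigh(m @ m.T)
    order = np.argsort(evals)[::-1]
    evals, u = evals[order], u[:, order]
    s = np.sqrt(np.maximum(evals, 0.0))
    if np.any(s <= s[0] * 1e-12):
        return _procrustes_loadings(t, z)  # rank-deficient: fall back
    v = m.T @ (u / s)
    return v @ u.T


def update_loadings(
    t: np.ndarray,
    z: np.ndarray,
    p: np.ndarray,
    mode: str,
    max_cycles: int = 20,
    tol: float = 1e-10,
) -> np.ndarray:
    """Conditional update of the concatenated loadings given fixed scores.

    ``mode='orthogonal'`` solves the Procrustes problem in one shot;
    ``mode='unit_length'`` cycles the per-component normalized cross-product
    update until the loadings stabilize.  A component whose cross-product
    vanishes is left unchanged with a warning.
    """
    if mode == "orthogonal":
        if z.shape[1] > 4 * t.shape[1]:
            return _procrustes_loadings_gram(t, z)
        return _procrustes_loadings(t, z)
    if mode != "unit_length":
        raise ValueError(f"unknown loading constraint {mode!r}")
    p = p.copy()
    n_comp = t.shape[1]
    zt = z.T @ t  # (Jy+Jx) x R
    gram_t = t.T @ t
    degenerate: set[int] = set()
    for _ in range(max_cycles):
        max_shift = 0.0
        for r in range(n_comp):
            # Q_r' t_r = Z' t_r - sum_{r' != r} p_r' (t_r'' t_r)
            cross = zt[:, r] - p @ gram_t[:, r] + p[:, r] * gram_t[r, r]
            norm = np.linalg.norm(cross)
            if norm <= 1e-14:
                degenerate.add(r)
                continue
            new_p = cross / norm
            max_shift = max(max_shift, float(np.abs(new_p - p[:, r]).max()))
            p[:, r] = new_p
        if max_shift < tol:
            break
    if degenerate:
        logger.warning(
            "zero cross-product for component(s) %s; loading column(s) kept",
            sorted(degenerate),
        )
    return p


def _rational_start(
    x: ScaledBlock, y: ScaledBlock, settings: PenaltySettings
) -> np.ndarray:
    base = PenaltySettings(
        alpha=settings.alpha,
        n_components=settings.n_components,
        loading_constraint=settings.loading_constraint,
    )
    return solve_pcovr(x, y, base).weights


def _random_start(
    rng: np.random.Generator, x: np.ndarray, n_comp: int
) -> np.ndarray:
    w = rng.standard_normal((x.shape[1], n_comp))
    scores = x @ w
    scale = np.sqrt((scores**2).mean(axis=0))
    scale[scale == 0] = 1.0
    return w / scale


def _alternate(
    w0: np.ndarray,
    x: np.ndarray,
    z: np.ndarray,
    settings: PenaltySettings,
    options: FitOptions,
    support: np.ndarray | None = None,
    lambda1: float | None = None,
    lambda2: float | None = None,
    log: list | None = None,
    start_label: str = "start",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Run the alternating algorithm from one start; returns (W, P, loss)."""
    l1 = settings.lambda1 if lambda1 is None else lambda1
    l2 = settings.lambda2 if lambda2 is None else lambda2
    w = w0.copy()
    if support is not None:
        w[~support] = 0.0
    t = x @ w
    if not np.any(t):
        # degenerate start (e.g. empty support): loadings are arbitrary
        p = np.zeros((z.shape[1], w.shape[1]))
        p[: w.shape[1], :] = np.eye(w.shape[1])
    else:
        p = update_loadings(t, z, np.zeros((z.shape[1], w.shape[1])), settings.loading_constraint)
    residual = z - t @ p.T
    loss = _penalized_loss(z, x, w, p, l1, l2)
    if log is not None:
        log.append({"start": start_label, "step": "init", "loss": loss})
    for it in range(options.max_iter):
        prev = loss
        update_weights_coordinate_descent(w, p, x, residual, l1, l2, support=support)
        if (it + 1) % RESIDUAL_REFRESH_EVERY == 0:
            residual = z - (x @ w) @ p.T
        loss_w = _penalized_loss(z, x, w, p, l1, l2)
        if loss_w > loss + MONOTONICITY_SLACK:
            raise RuntimeError(
                f"penalized loss increased in weight step ({loss} -> {loss_w})"
            )
        if log is not None:
            log.append({"start": start_label, "step": f"iter{it + 1}:W", "loss": loss_w})
        t = x @ w
        if np.any(t):
            p = update_loadings(t, z, p, settings.loading_constraint)
        residual = z - t @ p.T
        loss = _penalized_loss(z, x, w, p, l1, l2)
        if loss > loss_w + MONOTONICITY_SLACK:
            raise RuntimeError(
                f"penalized loss increased in loading step ({loss_w} -> {loss})"
            )
        if log is not None:
            log.append({"start": start_label, "step": f"iter{it + 1}:P", "loss": loss})
        if prev - loss < options.tol * max(prev, 1e-12):
            break
    return w, p, loss


def _to_model(
    w: np.ndarray,
    p: np.ndarray,
    x: ScaledBlock,
    target: ConcatenatedTarget,
    settings: PenaltySettings,
) -> ComponentModel:
    py, px = split_loadings(p, target)
    return ComponentModel(
        weights=w,
        loadings_x=px,
        loadings_y=py,
        scores=x.values @ w,
        constraint_mode=settings.loading_constraint,
    )


def fit_spcovr(
    x: ScaledBlock,
    y: ScaledBlock,
    settings: PenaltySettings,
    options: FitOptions | None = None,
    w_init: np.ndarray | None = None,
) -> tuple[ComponentModel, FitSummary, list[dict]]:
    """Fit sparse PCovR by multistart alternating least squares.

    Runs the rational start (exact non-sparse PCovR weights), optionally a
    warm start ``w_init`` (e.g. the solution at the previous penalty on a
    path), and ``options.n_random_starts`` random starts, and returns the
    lowest penalized-loss solution together with its fit summary and the
    per-conditional-step convergence log.
    """
    options = options or FitOptions()
    target = build_concatenated_target(x, y, settings)
    starts: list[tuple[str, np.ndarray]] = [("rational", _rational_start(x, y, settings))]
    if w_init is not None:
        starts.append(("warm", np.asarray(w_init, dtype=float)))
    rng = np.random.default_rng(options.seed)
    for k in range(options.n_random_starts):
        starts.append((f"random{k}", _random_start(rng, x.values, settings.n_components)))
    log: list[dict] = []
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for label, w0 in starts:
        w, p, loss = _alternate(
            w0, x.values, target.z, settings, options, log=log, start_label=label
        )
        if best is None or loss < best[0]:
            best = (loss, w, p)
    assert best is not None
    _, w, p = best
    model = _to_model(w, p, x, target, settings)
    if options.debias:
        model = refit_fixed_support(x, y, model.weights != 0, settings, options)
    summary = evaluate_fit(model, x, y, settings)
    return model, summary, log


def refit_fixed_support(
    x: ScaledBlock,
    y: ScaledBlock,
    support: np.ndarray,
    settings: PenaltySettings,
    options: FitOptions | None = None,
) -> ComponentModel:
    """Unpenalized alternating refit with weights outside ``support`` fixed at zero.

    This undoes the elastic-net shrinkage of the selected coefficients
    (debiasing) and is also the generating step of the simulation design.
    """
    options = options or FitOptions()
    support = np.asarray(support, dtype=bool)
    target = build_concatenated_target(x, y, settings)
    expected = (x.n_vars, settings.n_components)
    if support.shape != expected:
        raise ValueError(f"support must have shape {expected}, got {support.shape}")
    if not support.any():
        warnings.warn("empty support: returning the all-zero model")
        w = np.zeros(expected)
        p = np.zeros((target.z.shape[1], settings.n_components))
        return _to_model(w, p, x, target, settings)
    try:
        w0 = _rational_start(x, y, settings)
        w0 = np.where(support, w0, 0.0)
    except ValueError:  # R > rank(X): start from scaled noise on the support
        w0 = np.where(support, 1.0 / np.sqrt(x.n_vars), 0.0)
    w, p, _ = _alternate(
        w0, x.values, target.z, settings, options,
        support=support, lambda1=0.0, lambda2=0.0,
    )
    return _to_model(w, p, x, target, settings)


def save_model(
    model: ComponentModel,
    settings: PenaltySettings,
    out_dir: str | Path,
    convergence_log: list[dict] | None = None,
) -> Path:
    """Serialize a fitted model as a JSON + CSV bundle under ``out_dir``."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.weights).to_csv(out / "weights.csv", index=False)
    pd.DataFrame(model.loadings_x).to_csv(out / "loadings_x.csv", index=False)
    pd.DataFrame(model.loadings_y).to_csv(out / "loadings_y.csv", index=False)
    meta = {
        "alpha": settings.alpha,
        "lambda1": settings.lambda1,
        "lambda2": settings.lambda2,
        "n_components": settings.n_components,
        "loading_constraint": settings.loading_constraint,
        "constraint_mode": model.constraint_mode,
    }
    (out / "settings.json").write_text(json.dumps(meta, indent=2))
    if convergence_log is not None:
        pd.DataFrame(convergence_log).to_csv(out / "convergence.csv", index=False)
    return out


def load_model(in_dir: str | Path, x: ScaledBlock) -> tuple[ComponentModel, PenaltySettings]:
    """Load a model bundle written by :func:`save_model`."""
    import pandas as pd

    src = Path(in_dir)
    meta = json.loads((src / "settings.json").read_text())
    settings = PenaltySettings(
        alpha=meta["alpha"],
        lambda1=meta["lambda1"],
        lambda2=meta["lambda2"],
        n_components=meta["n_components"],
        loading_constraint=meta["loading_constraint"],
    )
    w = pd.read_csv(src / "weights.csv").to_numpy()
    px = pd.read_csv(src / "loadings_x.csv").to_numpy()
    py = pd.read_csv(src / "loadings_y.csv").to_numpy()
    model = ComponentModel(
        weights=w, loadings_x=px, loadings_y=py,
        scores=x.values @ w, constraint_mode=meta["constraint_mode"],
    )
    return model, settings
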