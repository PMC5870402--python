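"""Stability selection for the lasso penalty with false-positive control.

The lasso strength ``lambda1`` is tuned by resampling: at each value on a
decreasing log2-spaced path, N resamples (a fraction f of the observations,
drawn with replacement) are each refit and the per-coefficient selection
frequency is recorded in a probability matrix ``Pi``.  Thresholding the
elementwise maximum of these matrices at ``pi_thr`` yields the stable set,
and the path is only extended while the number of candidate coefficients
``q_Lambda`` stays within the bound ``q_R = R * sqrt(J * (2*pi_thr - 1) * E(V))``
implied by controlling the expected number of falsely selected coefficients
``E(V)``.

Because the components of a sparse PCovR solution are identified only up to
permutation and sign, every resample solution is aligned to the full-data
reference solution (maximal Tucker congruence of the component scores) before
its zero pattern is recorded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    ComponentModel,
    PenaltySettings,
    ScaledBlock,
    build_concatenated_target,
    center_scale,
)
from .pcovr import solve_pcovr
from .sparse import FitOptions, _alternate, fit_spcovr, refit_fixed_support, update_loadings

__all__ = [
    "StabilitySettings",
    "LambdaPath",
    "StabilityResult",
    "compute_lambda_max",
    "build_lambda_path",
    "q_bound",
    "align_components",
    "apply_alignment",
    "run_stability_selection",
]


@dataclass(frozen=True)
class StabilitySettings:
    """Control parameters of the resampling procedure.

    Defaults follow the recommended practice: ``pi_threshold = 0.90``,
    ``expected_false = 1`` false selection, resamples of half the sample,
    and a ridge penalty riding at 5% of the lasso along the path.
    ``q_override`` replaces the theoretical bound in the stopping rule (used
    e.g. to request a fixed number of non-zero coefficients).
    """

    n_resamples: int = 500
    resample_fraction: float = 0.5
    pi_threshold: float = 0.90
    expected_false: float = 1.0
    q_override: int | None = None
    grid_size: int = 50
    seed: int = 0
    ridge_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.5 <= self.resample_fraction < 1.0:
            raise ValueError("resample_fraction must satisfy 0.5 <= f < 1")
        if not 0.5 < self.pi_threshold <= 1.0:
            raise ValueError("pi_threshold must be in (0.5, 1]")
        if self.expected_false < 0:
            raise ValueError("expected_false must be >= 0")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")


@dataclass(frozen=True)
class LambdaPath:
    """Decreasing lasso path, log2-equispaced from lambda_max to 1e-4*lambda_max."""

    values: np.ndarray


@dataclass
class StabilityResult:
    """Selection probabilities, the stable set and the stopping diagnostics."""

    pi_per_lambda: list[np.ndarray]
    pi_stable: np.ndarray
    stable_set: np.ndarray
    q_lambda: int
    q_bound: int
    lambdas_used: np.ndarray
    q_per_lambda: list[int]
    path_exhausted: bool


def compute_lambda_max(
    x: ScaledBlock, y: ScaledBlock, settings: PenaltySettings
) -> float:
    """Smallest lambda1 at which every coordinate update from W = 0 stays zero.

    Uses the rational-start loadings (the constraint-projected loadings of the
    exact non-sparse solution): a coordinate stays at zero iff
    ``|x_j' Z p_r| <= lambda1 / 2``, so ``lambda_max = 2 * max |X' Z P|``.
    """
    base = PenaltySettings(
        alpha=settings.alpha,
        n_components=settings.n_components,
        loading_constraint=settings.loading_constraint,
    )
    model = solve_pcovr(x, y, base)
    target = build_concatenated_target(x, y, settings)
    t = x.values @ model.weights
    p = update_loadings(
        t, target.z, np.zeros((target.z.shape[1], t.shape[1])),
        settings.loading_constraint,
    )
    return 2.0 * float(np.abs(x.values.T @ target.z @ p).max())


def build_lambda_path(lambda_max: float, grid_size: int) -> LambdaPath:
    """Equally log2-spaced decreasing path from lambda_max to 1e-4*lambda_max."""
    if lambda_max <= 0:
        raise ValueError("lambda_max must be > 0")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    exponents = np.linspace(
        np.log2(lambda_max), np.log2(1e-4 * lambda_max), grid_size
    )
    values = 2.0**exponents
    values[0] = lambda_max
    values[-1] = 1e-4 * lambda_max
    return LambdaPath(values=values)


def q_bound(j_vars: int, r: int, pi_threshold: float, expected_false: float) -> int:
    """Upper bound on the number of non-zero coefficients for R components:
    ``floor(R * sqrt(J * (2*pi_thr - 1) * E(V)))``."""
    if pi_threshold <= 0.5:
        raise ValueError("pi_threshold must exceed 0.5 for the bound to be defined")
    return math.floor(r * math.sqrt(j_vars * (2 * pi_threshold - 1) * expected_false))


def _column_congruence(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b) / (na * nb)


def align_components(
    candidate_scores: np.ndarray, reference_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation and signs matching candidate components to a reference.

    Returns ``(perm, signs)`` such that candidate column ``perm[l]`` flipped
    by ``signs[l]`` corresponds to reference column ``l``, maximizing the
    summed absolute Tucker congruence of the score columns.  Exhaustive over
    permutations for R <= 6, greedy beyond.
    """
    if candidate_scores.shape != reference_scores.shape:
        raise ValueError("candidate and reference scores must share a shape")
    n_comp = candidate_scores.shape[1]
    cong = np.array(
        [
            [
                _column_congruence(candidate_scores[:, k], reference_scores[:, l])
                for l in range(n_comp)
            ]
            for k in range(n_comp)
        ]
    )
    abs_cong = np.abs(cong)
    if n_comp <= 6:
        best_perm, best_val = None, -np.inf
        for perm in itertools.permutations(range(n_comp)):
            val = sum(abs_cong[perm[l], l] for l in range(n_comp))
            if val > best_val:
                best_val, best_perm = val, perm
        perm = np.array(best_perm)
    else:  # greedy: repeatedly take the best remaining pair
        perm = np.full(n_comp, -1)
        remaining = abs_cong.copy()
        for _ in range(n_comp):
            k, l = np.unravel_index(np.argmax(remaining), remaining.shape)
            perm[l] = k
            remaining[k, :] = -np.inf
            remaining[:, l] = -np.inf
    signs = np.array(
        [1.0 if cong[perm[l], l] >= 0 else -1.0 for l in range(n_comp)]
    )
    return perm, signs


def apply_alignment(
    model: ComponentModel, perm: np.ndarray, signs: np.ndarray
) -> ComponentModel:
    """Return a copy of ``model`` with columns permuted and sign-flipped."""
    return ComponentModel(
        weights=model.weights[:, perm] * signs,
        loadings_x=model.loadings_x[:, perm] * signs,
        loadings_y=model.loadings_y[:, perm] * signs,
        scores=model.scores[:, perm] * signs,
        constraint_mode=model.constraint_mode,
    )


def run_stability_selection(
    x: ScaledBlock,
    y: ScaledBlock,
    settings: PenaltySettings,
    stab: StabilitySettings | None = None,
    options: FitOptions | None = None,
) -> tuple[StabilityResult, ComponentModel]:
    """Tune lambda1 by stability selection and return the debiased final model.

    Walks the lambda path from ``lambda_max`` downward.  At each value the
    full data are refit (warm-started, multistart) as the alignment reference;
    the running candidate count ``q_Lambda`` — distinct coefficients non-zero
    in any reference fit so far, with components aligned across lambda to the
    non-sparse solution — must stay within ``q_R`` for the value to join the
    range.  Only values inside the range are resampled.  The final model is an
    unpenalized refit on the stable set.
    """
    stab = stab or StabilitySettings()
    options = options or FitOptions()
    n_obs, j_vars = x.n_obs, x.n_vars
    n_comp = settings.n_components
    q_r = (
        stab.q_override
        if stab.q_override is not None
        else q_bound(j_vars, n_comp, stab.pi_threshold, stab.expected_false)
    )
    lam_max = compute_lambda_max(x, y, settings)
    path = build_lambda_path(lam_max, stab.grid_size)
    anchor = solve_pcovr(
        x, y, PenaltySettings(alpha=settings.alpha, n_components=n_comp,
                              loading_constraint=settings.loading_constraint),
    ).scores
    rng = np.random.default_rng(stab.seed)
    m = round(stab.resample_fraction * n_obs)
    union = np.zeros((j_vars, n_comp), dtype=bool)
    pis: list[np.ndarray] = []
    q_per_lambda: list[int] = []
    lambdas_used: list[float] = []
    w_warm: np.ndarray | None = None
    exhausted = True
    for lam in path.values:
        lam_settings = PenaltySettings(
            alpha=settings.alpha,
            lambda1=float(lam),
            lambda2=stab.ridge_fraction * float(lam),
            n_components=n_comp,
            loading_constraint=settings.loading_constraint,
        )
        ref_model, _, _ = fit_spcovr(x, y, lam_settings, options, w_init=w_warm)
        w_warm = ref_model.weights
        perm, signs = align_components(ref_model.scores, anchor)
        ref_aligned = apply_alignment(ref_model, perm, signs)
        candidate_union = union | (ref_aligned.weights != 0)
        if int(candidate_union.sum()) > q_r:
            exhausted = False
            break  # this lambda would overshoot the bound: not part of the range
        union = candidate_union
        q_per_lambda.append(int(union.sum()))
        lambdas_used.append(float(lam))
        counts = np.zeros((j_vars, n_comp))
        target = build_concatenated_target(x, y, lam_settings)
        for _ in range(stab.n_resamples):
            idx = rng.integers(0, n_obs, size=m)
            try:
                xb = center_scale(x.values[idx])
                yb = center_scale(y.values[idx])
            except ValueError:  # a column constant within the resample
                continue
            sub_target = build_concatenated_target(xb, yb, lam_settings)
            w_fit, _, _ = _alternate(
                ref_model.weights, xb.values, sub_target.z, lam_settings, options
            )
            sub_scores = xb.values @ w_fit
            perm_b, signs_b = align_components(sub_scores, ref_aligned.scores[idx])
            counts += (w_fit[:, perm_b] != 0)
        pis.append(counts / stab.n_resamples)
    if pis:
        pi_stable = np.maximum.reduce(pis)
    else:
        pi_stable = np.zeros((j_vars, n_comp))
    stable_set = pi_stable >= stab.pi_threshold
    final = refit_fixed_support(x, y, stable_set, settings, options)
    result = StabilityResult(
        pi_per_lambda=pis,
        pi_stable=pi_stable,
        stable_set=stable_set,
        q_lambda=int(union.sum()),
        q_bound=q_r,
        lambdas_used=np.asarray(lambdas_used),
        q_per_lambda=q_per_lambda,
        path_exhausted=exhausted,
    )
    return result, final
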