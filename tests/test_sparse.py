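import numpy as np
import pytest
from sklearn.linear_model import ElasticNet

from spcovr import (
    FitOptions,
    PenaltySettings,
    center_scale,
    evaluate_fit,
    fit_spcovr,
    refit_fixed_support,
    solve_pcovr,
    update_loadings,
    update_weights_coordinate_descent,
)
from spcovr.data_model import build_concatenated_target
from spcovr.sparse import (
    _penalized_loss,
    _procrustes_loadings,
    _procrustes_loadings_gram,
    load_model,
    save_model,
)

from conftest import make_settings


def _setup_state(rng, i=20, jx=10, jy=1, r=2, alpha=0.5, lambda1=0.1, lambda2=0.05):
    x = center_scale(rng.standard_normal((i, jx)))
    y = center_scale(rng.standard_normal((i, jy)))
    settings = make_settings(alpha=alpha, lambda1=lambda1, lambda2=lambda2, r=r)
    target = build_concatenated_target(x, y, settings)
    w = rng.standard_normal((jx, r)) * 0.2
    t = x.values @ w
    p = update_loadings(t, target.z, np.zeros((target.z.shape[1], r)), "unit_length")
    residual = target.z - t @ p.T
    return x, y, settings, target, w, p, residual


class TestCoordinateDescent:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_update_matches_grid_search(self, seed):
        """Each coordinate update is the 1-D minimizer of the isolated
        elastic-net problem, checked by dense grid search."""
        rng = np.random.default_rng(seed)
        x, y, settings, target, w, p, residual = _setup_state(rng)
        grid = np.arange(-3.0, 3.0 + 1e-9, 1e-4)
        for j, r in [(0, 0), (3, 1), (7, 0)]:
            w_work = w.copy()
            res_work = target.z - (x.values @ w_work) @ p.T
            support = np.zeros_like(w, dtype=bool)
            support[j, r] = True
            update_weights_coordinate_descent(
                w_work, p, x.values, res_work,
                settings.lambda1, settings.lambda2, support=support,
            )
            # independent oracle: evaluate the full penalized loss on a grid
            w_rest = w.copy()
            w_rest[j, r] = 0.0
            a = target.z - (x.values @ w_rest) @ p.T
            b = np.outer(x.values[:, j], p[:, r])
            quad = (
                (a**2).sum()
                - 2 * grid * (a * b).sum()
                + grid**2 * (b**2).sum()
                + settings.lambda1 * np.abs(grid)
                + settings.lambda2 * grid**2
            )
            w_star = grid[np.argmin(quad)]
            assert abs(w_work[j, r] - w_star) <= 1e-4

    def test_full_shrinkage_keeps_zero_weights(self, rng):
        x, y, settings, target, w, p, residual = _setup_state(rng)
        w0 = np.zeros_like(w)
        res0 = target.z.copy()
        s_max = np.abs(x.values.T @ target.z @ p).max()
        update_weights_coordinate_descent(
            w0, p, x.values, res0, 2.0 * s_max + 1e-9, 0.0
        )
        assert np.all(w0 == 0)

    def test_reduces_to_ols_single_predictor(self, rng):
        """One predictor, one component, no penalty and unit loading: the
        update is the simple least-squares coefficient."""
        x = center_scale(rng.standard_normal((15, 1)))
        z = rng.standard_normal((15, 1))
        z -= z.mean()
        w = np.zeros((1, 1))
        p = np.ones((1, 1))
        residual = z - (x.values @ w) @ p.T
        update_weights_coordinate_descent(w, p, x.values, residual, 0.0, 0.0)
        beta = float(x.values[:, 0] @ z[:, 0]) / float(x.values[:, 0] @ x.values[:, 0])
        assert w[0, 0] == pytest.approx(beta, rel=1e-12)

    def test_sweep_never_increases_penalized_loss(self, rng):
        x, y, settings, target, w, p, residual = _setup_state(rng)
        loss = _penalized_loss(
            target.z, x.values, w, p, settings.lambda1, settings.lambda2
        )
        for _ in range(5):
            update_weights_coordinate_descent(
                w, p, x.values, residual, settings.lambda1, settings.lambda2
            )
            new = _penalized_loss(
                target.z, x.values, w, p, settings.lambda1, settings.lambda2
            )
            assert new <= loss + 1e-10
            loss = new

    def test_incremental_residual_matches_recomputation(self, rng):
        x, y, settings, target, w, p, residual = _setup_state(rng)
        for _ in range(4):
            update_weights_coordinate_descent(
                w, p, x.values, residual, settings.lambda1, settings.lambda2
            )
            fresh = target.z - (x.values @ w) @ p.T
            np.testing.assert_allclose(residual, fresh, atol=1e-8)

    def test_non_finite_input_raises(self, rng):
        x, y, settings, target, w, p, residual = _setup_state(rng)
        residual[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            update_weights_coordinate_descent(w, p, x.values, residual, 0.1, 0.0)


class TestLoadingUpdates:
    def test_orthogonal_recovers_planted_loadings(self, rng):
        t = np.linalg.qr(rng.standard_normal((25, 3)))[0]
        p0 = np.linalg.qr(rng.standard_normal((9, 3)))[0]
        z = t @ p0.T
        p = update_loadings(t, z, np.zeros((9, 3)), "orthogonal")
        np.testing.assert_allclose(p, p0, atol=1e-10)

    def test_orthogonal_beats_random_candidates(self, rng):
        t = rng.standard_normal((20, 2))
        z = rng.standard_normal((20, 15))
        p = update_loadings(t, z, np.zeros((15, 2)), "orthogonal")
        crit = np.trace(p.T @ z.T @ t)
        for _ in range(1000):
            cand = np.linalg.qr(rng.standard_normal((15, 2)))[0]
            assert crit >= np.trace(cand.T @ z.T @ t) - 1e-10

    def test_gram_path_equals_svd_path(self, rng):
        for _ in range(5):
            t = rng.standard_normal((20, 3))
            z = rng.standard_normal((20, 50))
            np.testing.assert_allclose(
                _procrustes_loadings(t, z),
                _procrustes_loadings_gram(t, z),
                atol=1e-10,
            )

    def test_unit_length_columns(self, rng):
        t = rng.standard_normal((20, 2))
        z = rng.standard_normal((20, 8))
        p = update_loadings(t, z, np.zeros((8, 2)), "unit_length")
        np.testing.assert_allclose(np.linalg.norm(p, axis=0), 1.0, atol=1e-8)

    def test_unit_length_decreases_loss(self, rng):
        t = rng.standard_normal((20, 2))
        z = rng.standard_normal((20, 8))
        p0 = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        before = ((z - t @ p0.T) ** 2).sum()
        p = update_loadings(t, z, p0, "unit_length")
        after = ((z - t @ p.T) ** 2).sum()
        assert after <= before + 1e-10


class TestFitSpcovr:
    def test_unpenalized_matches_closed_form(self, small_blocks):
        x, y = small_blocks
        for constraint in ("unit_length", "orthogonal"):
            settings = make_settings(alpha=0.5, r=2, constraint=constraint)
            exact = evaluate_fit(solve_pcovr(x, y, settings), x, y, settings)
            _, fs, _ = fit_spcovr(
                x, y, settings, FitOptions(n_random_starts=2, tol=1e-12, seed=0)
            )
            assert fs.loss_unpenalized == pytest.approx(
                exact.loss_unpenalized, abs=1e-6
            )

    def test_alpha_zero_rank_one_is_elastic_net(self, rng):
        """With alpha=0, R=1 and the outcome loading fixed at one, coordinate
        descent solves the elastic-net regression of y on X; cross-checked
        against an independent solver."""
        i, j = 40, 12
        x = center_scale(rng.standard_normal((i, j)))
        y = center_scale(rng.standard_normal((i, 1)))
        lam1, lam2 = 0.08, 0.04
        settings = make_settings(alpha=0.0, lambda1=lam1, lambda2=lam2, r=1)
        target = build_concatenated_target(x, y, settings)
        p = np.zeros((target.z.shape[1], 1))
        p[0, 0] = target.w1  # fixed outcome loading of one
        w = np.zeros((j, 1))
        residual = target.z - (x.values @ w) @ p.T
        for _ in range(2000):
            change = update_weights_coordinate_descent(
                w, p, x.values, residual, lam1, lam2
            )
            if change < 1e-13:
                break
        # ||y||=1, so the objective is ||y-Xw||^2 + lam1|w| + lam2 w^2;
        # sklearn's scaling: 2n*a*l1r = lam1, n*a*(1-l1r) = lam2
        a = lam1 / (2 * i) + lam2 / i
        l1r = (lam1 / 2) / (lam1 / 2 + lam2)
        enet = ElasticNet(
            alpha=a, l1_ratio=l1r, fit_intercept=False, tol=1e-12, max_iter=100000
        ).fit(x.values, y.values.ravel())
        np.testing.assert_allclose(w.ravel(), enet.coef_, atol=1e-6)
        assert set(np.flatnonzero(w.ravel())) == set(np.flatnonzero(enet.coef_))

    def test_alpha_one_matches_sparse_pca_oracle(self, rng):
        """With alpha=1 the criterion is sparse PCA; an independent alternating
        oracle (per-component elastic net + Procrustes) reaches the same loss."""
        i, j, r = 20, 10, 2
        x = center_scale(rng.standard_normal((i, j)))
        y = center_scale(rng.standard_normal((i, 1)))
        lam1, lam2 = 0.02, 0.01
        settings = make_settings(
            alpha=1.0, lambda1=lam1, lambda2=lam2, r=r, constraint="orthogonal"
        )
        _, fs, _ = fit_spcovr(
            x, y, settings, FitOptions(n_random_starts=3, tol=1e-12, seed=1)
        )
        target = build_concatenated_target(x, y, settings)
        z = target.z
        # oracle: with orthonormal P the weight problem decouples per component
        w = solve_pcovr(x, y, make_settings(alpha=1.0, r=r)).weights
        a = lam1 / (2 * i) + lam2 / i
        l1r = (lam1 / 2) / (lam1 / 2 + lam2)
        loss_prev = np.inf
        for _ in range(500):
            u, _, vt = np.linalg.svd((x.values @ w).T @ z, full_matrices=False)
            p = vt.T @ u.T
            zp = z @ p
            for k in range(r):
                enet = ElasticNet(
                    alpha=a, l1_ratio=l1r, fit_intercept=False,
                    tol=1e-12, max_iter=100000,
                ).fit(x.values, zp[:, k])
                w[:, k] = enet.coef_
            loss = _penalized_loss(z, x.values, w, p, lam1, lam2)
            if loss_prev - loss < 1e-14:
                break
            loss_prev = loss
        assert fs.loss_penalized == pytest.approx(loss, abs=1e-6)

    def test_deterministic_given_seed(self, small_blocks):
        x, y = small_blocks
        settings = make_settings(alpha=0.7, lambda1=0.05, lambda2=0.01)
        opts = FitOptions(n_random_starts=3, seed=42)
        m1, _, _ = fit_spcovr(x, y, settings, opts)
        m2, _, _ = fit_spcovr(x, y, settings, opts)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_convergence_log_non_increasing(self, small_blocks):
        x, y = small_blocks
        settings = make_settings(alpha=0.5, lambda1=0.05, lambda2=0.02)
        _, _, log = fit_spcovr(x, y, settings, FitOptions(n_random_starts=1, seed=0))
        per_start: dict = {}
        for entry in log:
            per_start.setdefault(entry["start"], []).append(entry["loss"])
        for losses in per_start.values():
            assert all(a >= b - 1e-8 for a, b in zip(losses, losses[1:]))

    def test_sweep_order_robustness(self, rng):
        """Two different fixed coordinate orders reach nearly the same loss."""
        x, y, settings, target, w, p, residual = _setup_state(
            rng, i=30, jx=8, lambda1=0.05, lambda2=0.02
        )
        results = []
        for order in (np.arange(8), np.arange(8)[::-1].copy()):
            w_o = np.zeros_like(w)
            p_o = p.copy()
            res_o = target.z - (x.values @ w_o) @ p_o.T
            for _ in range(300):
                update_weights_coordinate_descent(
                    w_o, p_o, x.values, res_o,
                    settings.lambda1, settings.lambda2, order=order,
                )
                p_o = update_loadings(x.values @ w_o, target.z, p_o, "unit_length")
                res_o = target.z - (x.values @ w_o) @ p_o.T
            results.append(
                _penalized_loss(
                    target.z, x.values, w_o, p_o, settings.lambda1, settings.lambda2
                )
            )
        assert abs(results[0] - results[1]) < 1e-4


class TestRefitFixedSupport:
    def test_full_support_equals_unpenalized_fit(self, small_blocks):
        x, y = small_blocks
        settings = make_settings(alpha=0.5, r=2)
        opts = FitOptions(n_random_starts=2, tol=1e-12, seed=0)
        _, fs_free, _ = fit_spcovr(x, y, settings, opts)
        model = refit_fixed_support(
            x, y, np.ones((x.n_vars, 2), dtype=bool), settings, opts
        )
        fs_refit = evaluate_fit(model, x, y, settings)
        assert fs_refit.loss_unpenalized == pytest.approx(
            fs_free.loss_unpenalized, abs=1e-6
        )

    def test_empty_support_returns_null_model(self, small_blocks):
        x, y = small_blocks
        settings = make_settings(alpha=0.5, r=2)
        with pytest.warns(UserWarning, match="empty support"):
            model = refit_fixed_support(
                x, y, np.zeros((x.n_vars, 2), dtype=bool), settings
            )
        assert np.all(model.weights == 0)
        fs = evaluate_fit(model, x, y, settings)
        assert fs.loss_unpenalized == pytest.approx(1.0)

    def test_debiasing_improves_data_fit(self, small_blocks):
        x, y = small_blocks
        settings = make_settings(alpha=0.5, lambda1=0.2, lambda2=0.05, r=2)
        opts = FitOptions(n_random_starts=2, seed=0)
        model, fs_pen, _ = fit_spcovr(x, y, settings, opts)
        support = model.weights != 0
        if not support.any():
            pytest.skip("penalty shrank everything in this instance")
        refit = refit_fixed_support(x, y, support, settings, opts)
        fs_refit = evaluate_fit(refit, x, y, settings)
        assert fs_refit.loss_unpenalized <= fs_pen.loss_unpenalized + 1e-10


def test_model_bundle_round_trip(tmp_path, small_blocks):
    x, y = small_blocks
    settings = make_settings(alpha=0.5, lambda1=0.05, lambda2=0.01)
    model, _, log = fit_spcovr(x, y, settings, FitOptions(n_random_starts=1, seed=0))
    out = save_model(model, settings, tmp_path / "bundle", convergence_log=log)
    loaded, loaded_settings = load_model(out, x)
    np.testing.assert_allclose(loaded.weights, model.weights)
    np.testing.assert_allclose(loaded.loadings_y, model.loadings_y)
    assert loaded_settings == settings
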