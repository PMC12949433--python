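"""Partially penalised adaptive lasso: partition, weights, solver, CV."""

import numpy as np
import pytest

from hublasso import (
    ConvergenceError,
    ExpressionMatrix,
    HubPartition,
    adaptive_weights,
    build_partition,
    cv_select,
    fit_ng,
    initial_estimator,
    predict,
)
from hublasso.regression import lambda_max

from conftest import exact_partial_lasso


def _toy(rng, n=40, p=8, h=2, c=2, beta=None):
    x = ExpressionMatrix(
        rng.standard_normal((n, p)),
        [f"P{j}" for j in range(p)],
        [f"s{i}" for i in range(n)],
    )
    z = rng.standard_normal((n, c))
    hubs = HubPartition(
        hub_indices=list(range(h)),
        nonhub_indices=list(range(h, p)),
        h=h,
        delta=0.1,
        tau=5,
    )
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [2.0, -1.0, 0.5][: min(3, p)]
    y = 1.0 + z @ np.full(c, 0.7) + x.values @ beta + 0.3 * rng.standard_normal(n)
    return x, z, y, hubs


class TestBuildPartition:
    def test_dimensions_and_column_map(self, rng):
        x, z, y, hubs = _toy(rng, p=8, h=3, c=3)
        part = build_partition(x, z, y, hubs)
        assert part.t == 3 + 3 + 1
        assert part.q == 5
        blocks = [b for b, _ in part.column_map]
        assert blocks[0] == "intercept"
        assert blocks.count("confounder") == 3
        assert blocks.count("hub") == 3
        assert blocks.count("nonhub") == 5

    def test_no_hubs_no_confounders_leaves_intercept_only(self, rng):
        x, _, y, _ = _toy(rng, p=5, h=0, c=0)
        hubs = HubPartition([], list(range(5)), 0, 0.01, 5)
        part = build_partition(x, None, y, hubs)
        assert part.t == 1
        assert part.q == 5

    def test_column_map_round_trips_names(self, rng):
        x, z, y, hubs = _toy(rng)
        part = build_partition(x, z, y, hubs)
        names = [nm for _, nm in part.column_map[1:]]
        assert sorted(names) == sorted(
            [f"Z{k+1}" for k in range(z.shape[1])] + x.feature_names
        )

    def test_row_mismatch_rejected(self, rng):
        x, z, y, hubs = _toy(rng)
        with pytest.raises(ValueError, match="outcome length"):
            build_partition(x, z, y[:-1], hubs)


class TestInitialEstimator:
    def test_single_predictor_matches_ols_magnitude(self, rng):
        # one non-hub with strong signal and no real penalty needed: the
        # perturbed magnitude approaches |OLS| + 1/n
        n = 200
        u = np.ones((n, 1))
        nh = rng.standard_normal((n, 1))
        y = 3.0 * nh[:, 0] + 0.1 * rng.standard_normal(n)
        from hublasso.regression import DesignPartition

        part = DesignPartition(
            u=u, n_mat=nh, y=y,
            column_map=[("intercept", "(Intercept)"), ("nonhub", "P0")],
        )
        ols = float(np.linalg.lstsq(np.column_stack([u, nh]), y, rcond=None)[0][1])
        mags = initial_estimator(part, seed=0)
        assert mags[0] == pytest.approx(abs(ols) + 1.0 / n, rel=0.05)

    def test_magnitudes_strictly_positive_even_for_noise(self, rng):
        x, z, _, hubs = _toy(rng)
        y = rng.standard_normal(40)  # pure noise outcome
        part = build_partition(x, z, y, hubs)
        mags = initial_estimator(part, seed=1)
        assert np.all(mags > 0)

    def test_zero_variance_column_floored_with_warning(self, rng):
        x, z, y, hubs = _toy(rng)
        x.values[:, 5] = 2.0  # constant non-hub column
        part = build_partition(x, z, y, hubs)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            mags = initial_estimator(part, seed=1)
        j = part.column_map.index(("nonhub", "P5")) - part.t
        assert mags[j] == pytest.approx(1.0 / part.n)


class TestAdaptiveWeights:
    def test_reciprocal_at_nu_one(self):
        np.testing.assert_allclose(
            adaptive_weights(np.array([2.0, 0.5]), 1.0), [0.5, 2.0]
        )

    def test_small_nu_approaches_plain_lasso(self):
        w = adaptive_weights(np.array([4.0, 0.25]), 1e-9)
        np.testing.assert_allclose(w, 1.0, rtol=1e-6)

    def test_power_arithmetic(self):
        assert adaptive_weights(np.array([4.0]), 0.5)[0] == pytest.approx(0.5)

    def test_zero_magnitude_rejected(self):
        with pytest.raises(ValueError):
            adaptive_weights(np.array([0.0, 1.0]), 1.0)


class TestFitNG:
    def test_unpenalised_limit_is_joint_ols(self, rng):
        x, z, y, hubs = _toy(rng)
        part = build_partition(x, z, y, hubs)
        fit = fit_ng(part, 0.0, np.ones(part.q), tol=1e-14, max_iter=5000)
        design = np.column_stack([part.u, part.n_mat])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(
            np.concatenate([fit.alpha, fit.beta]), ols, atol=1e-6
        )

    def test_full_shrinkage_limit_zeroes_penalised_block(self, rng):
        x, z, y, hubs = _toy(rng)
        part = build_partition(x, z, y, hubs)
        w = np.ones(part.q)
        lam = 10 * lambda_max(part, w)
        fit = fit_ng(part, lam, w)
        np.testing.assert_array_equal(fit.beta, 0.0)
        ols_u = np.linalg.lstsq(part.u, y, rcond=None)[0]
        np.testing.assert_allclose(fit.alpha, ols_u, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_enumeration_oracle_on_tiny_instances(self, seed):
        # n=30, p=8, h=2 random instances against the exact support-
        # enumeration solver of the same objective
        g = np.random.default_rng(seed)
        x, z, y, hubs = _toy(g, n=30, p=8, h=2, c=1)
        part = build_partition(x, z, y, hubs)
        w = g.uniform(0.5, 2.0, part.q)
        lam = 0.4 * lambda_max(part, w)
        fit = fit_ng(part, lam, w, tol=1e-14, max_iter=20000)
        obj_oracle, alpha_o, beta_o = exact_partial_lasso(
            part.u, part.n_mat, part.y, lam, w
        )
        assert fit.objective_value == pytest.approx(obj_oracle, abs=1e-6)
        np.testing.assert_allclose(fit.beta, beta_o, atol=1e-5)
        np.testing.assert_allclose(fit.alpha, alpha_o, atol=1e-5)
        # oracle predictions coincide as well
        np.testing.assert_allclose(
            predict(fit, part.u, part.n_mat),
            part.u @ alpha_o + part.n_mat @ beta_o,
            atol=1e-4,
        )

    def test_kkt_conditions_at_convergence(self, rng):
        x, z, y, hubs = _toy(rng)
        part = build_partition(x, z, y, hubs)
        w = np.ones(part.q)
        lam = 0.3 * lambda_max(part, w)
        fit = fit_ng(part, lam, w, tol=1e-14, max_iter=20000)
        r = part.y - part.u @ fit.alpha - part.n_mat @ fit.beta
        # unpenalised block stationarity
        np.testing.assert_allclose(part.u.T @ r, 0.0, atol=1e-7)
        grad = 2.0 * part.n_mat.T @ r
        tol = 1e-6
        for j in range(part.q):
            if fit.beta[j] == 0:
                assert abs(grad[j]) <= lam * w[j] + tol
            else:
                assert grad[j] == pytest.approx(
                    lam * w[j] * np.sign(fit.beta[j]), abs=tol
                )

    def test_objective_value_recomputes(self, rng):
        x, z, y, hubs = _toy(rng)
        part = build_partition(x, z, y, hubs)
        w = np.ones(part.q)
        lam = 0.2 * lambda_max(part, w)
        fit = fit_ng(part, lam, w)
        r = part.y - part.u @ fit.alpha - part.n_mat @ fit.beta
        recomputed = float(r @ r + lam * np.sum(w * np.abs(fit.beta)))
        assert fit.objective_value == pytest.approx(recomputed, rel=1e-9)

    def test_nonconvergence_raises(self, rng):
        x, z, y, hubs = _toy(rng)
        part = build_partition(x, z, y, hubs)
        with pytest.raises(ConvergenceError):
            fit_ng(part, 0.01, np.ones(part.q), tol=1e-16, max_iter=1)

    def test_predictions_with_zero_inputs_return_intercept(self, rng):
        x, z, y, hubs = _toy(rng)
        part = build_partition(x, z, y, hubs)
        fit = fit_ng(part, 1.0, np.ones(part.q))
        u0 = np.zeros((3, part.t))
        u0[:, 0] = 1.0
        np.testing.assert_allclose(
            predict(fit, u0, np.zeros((3, part.q))), fit.alpha[0]
        )


class TestCVSelect:
    def test_same_seed_reproduces_choice_and_fit(self, rng):
        x, z, y, hubs = _toy(rng, n=60)
        part = build_partition(x, z, y, hubs)
        c1, f1 = cv_select(part, seed=7)
        c2, f2 = cv_select(part, seed=7)
        assert c1.chosen == c2.chosen
        np.testing.assert_array_equal(f1.beta, f2.beta)
        np.testing.assert_array_equal(f1.alpha, f2.alpha)

    def test_single_point_grids_degenerate_cv(self, rng):
        x, z, y, hubs = _toy(rng, n=60)
        part = build_partition(x, z, y, hubs)
        choice, fit = cv_select(part, nu_grid=(1.0,), n_lambda=1, seed=3)
        assert choice.chosen[0] == 1.0
        assert fit.lambda_n == pytest.approx(choice.lambda_path[1.0][0])

    def test_empty_penalised_block_runs_as_ols(self, rng):
        x, z, y, _ = _toy(rng, n=60, p=5)
        hubs = HubPartition(list(range(5)), [], 5, 0.5, 5)
        part = build_partition(x, z, y, hubs)
        choice, fit = cv_select(part, seed=0)
        assert fit.beta.size == 0
        design = part.u
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(fit.alpha, ols, atol=1e-6)

    def test_hub_and_confounder_coefficients_never_zeroed(self, rng):
        x, z, y, hubs = _toy(rng, n=60)
        part = build_partition(x, z, y, hubs)
        _, fit = cv_select(part, seed=5)
        assert np.all(fit.alpha != 0.0)

    def test_reported_fit_is_on_original_scale(self, rng):
        x, z, y, hubs = _toy(rng, n=80)
        part = build_partition(x, z, y, hubs)
        _, fit = cv_select(part, seed=2)
        # refitting OLS on the selected support must roughly agree in scale
        sel = fit.selected_nonhubs
        design = np.column_stack([part.u, part.n_mat[:, sel]])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        # lasso shrinks toward zero: same sign, not wildly different size
        for pos, j in enumerate(sel):
            assert np.sign(fit.beta[j]) == np.sign(ols[part.t + pos])
            assert abs(fit.beta[j]) <= abs(ols[part.t + pos]) * 1.5 + 0.2


def test_solver_objective_monotone_within_sweeps(rng):
    # the block-coordinate kernel reports a monotonicity flag; exercise it on
    # a moderately hard correlated problem
    from hublasso import _solvers

    n, t, q = 50, 3, 12
    u = np.column_stack([np.ones(n), rng.standard_normal((n, t - 1))])
    base = rng.standard_normal((n, q))
    nm = base + 0.8 * base[:, :1]  # correlated columns
    y = nm[:, 0] - nm[:, 3] + rng.standard_normal(n)
    P = np.linalg.pinv(u)
    w = np.ones(q)
    lams = np.geomspace(10.0, 0.01, 25)
    *_, mono, conv = _solvers.cd_path(u, P, nm, y, w, lams, 1e-12, 5000)
    assert mono.all()
    assert conv.all()
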