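"""Training-mode components: UI extension, loss pieces, alternating updates."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from harp.harmonize import (
    RegularizationConfig,
    extend_composition,
    extend_reference,
    harmonize,
    normalize_columns,
    regularizer,
    regularizer_gradient,
    select_lambda,
    training_loss,
    update_alpha,
    update_reference,
)
from harp.matrixio import CompositionMatrix, ExpressionMatrix

from conftest import make_consistent_instance


def comp(values, types=None, samples=None):
    values = np.asarray(values, float)
    types = types or [f"ct{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CompositionMatrix(values, types, samples)


class TestExtendComposition:
    def test_residual_to_one(self):
        c = extend_composition(comp([[0.6], [0.3]]))
        np.testing.assert_allclose(c.values[:, 0], [0.6, 0.3, 0.1])
        assert c.is_extended and c.celltype_ids[-1] == "UI"

    def test_complete_measurement_zero_residual(self):
        c = extend_composition(comp([[0.5], [0.5]]))
        assert c.values[-1, 0] == 0.0
        np.testing.assert_allclose(c.values.sum(axis=0), 1.0)

    def test_oversum_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            c = extend_composition(comp([[0.8], [0.4]]))
        np.testing.assert_allclose(c.values[:, 0], [0.8, 0.4, 0.0])

    def test_already_extended_rejected(self):
        c = extend_composition(comp([[0.6], [0.3]]))
        with pytest.raises(ValueError, match="already extended"):
            extend_composition(c)


class TestExtendReference:
    def _x(self):
        return ExpressionMatrix(
            np.array([[1.0, 2.0, 4.0], [3.0, 4.0, 8.0]]),
            ["g1", "g2"], ["B", "NK", "T"])

    def test_ui_is_mean_of_leftover(self):
        x = ExpressionMatrix(np.array([[1.0, 2.0, 4.0], [1.0, 4.0, 8.0]]),
                             ["g1", "g2"], ["B", "NK", "T"])
        xs = extend_reference(x, ["B"])
        assert xs.column_ids == ["B", "UI"]
        np.testing.assert_allclose(xs.values[:, 1], [3.0, 6.0])

    def test_no_leftover_falls_back_to_identified_mean(self):
        x = self._x()
        with pytest.warns(UserWarning, match="no leftover"):
            xs = extend_reference(x, ["B", "NK", "T"])
        np.testing.assert_allclose(xs.values[:, -1], x.values.mean(axis=1))

    def test_identified_order_is_preserved(self):
        xs = extend_reference(self._x(), ["T", "B"])
        assert xs.column_ids == ["T", "B", "UI"]
        np.testing.assert_allclose(xs.values[:, 0], [4.0, 8.0])

    def test_empty_identified_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            extend_reference(self._x(), [])


class TestRegularizer:
    def test_value_at_anchor(self):
        x = np.full((2, 2), 1.7)
        assert regularizer(x, x) == pytest.approx(4 * 2 * np.log(2), abs=1e-12)

    def test_single_entry_offset_three(self):
        # softplus(3) + softplus(-3) = 3 + 2*log1p(exp(-3))
        expected = 3.0 + 2.0 * np.log1p(np.exp(-3.0))
        assert regularizer(np.zeros((1, 1)), np.full((1, 1), 3.0)) == \
            pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(3.0971747, abs=1e-6)

    def test_symmetry(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        assert regularizer(a, b) == pytest.approx(regularizer(b, a), rel=1e-14)

    def test_numerically_stable_at_huge_offsets(self):
        r = regularizer(np.zeros((1, 1)), np.full((1, 1), 1e4))
        assert np.isfinite(r) and r == pytest.approx(1e4, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.normal(size=(4, 3))
        phi = x + rng.normal(scale=0.5, size=(4, 3))
        grad = regularizer_gradient(x, phi)
        eps = 1e-6
        for idx in np.ndindex(phi.shape):
            p1, p2 = phi.copy(), phi.copy()
            p1[idx] += eps
            p2[idx] -= eps
            fd = (regularizer(x, p1) - regularizer(x, p2)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, abs=1e-8)
        np.testing.assert_allclose(grad, np.tanh((phi - x) / 2), atol=1e-14)


class TestTrainingLoss:
    def test_perfect_fit_zero(self, consistent_instance):
        y, x, c = consistent_instance
        alpha = np.ones(3)
        assert training_loss(y, x, alpha, c, 0.0, x) == pytest.approx(0.0, abs=1e-18)

    def test_frobenius_of_ones(self):
        y = np.zeros((2, 1))
        phi = np.ones((2, 1))
        c = np.ones((1, 1))
        assert training_loss(y, phi, np.ones(1), c, 0.0, phi) == pytest.approx(2.0)

    def test_regularizer_term_only(self):
        x = np.full((2, 2), 0.5)
        c = np.eye(2)
        y = x @ c
        val = training_loss(y, x, np.ones(2), c, 1.0, x)
        assert val == pytest.approx(8 * np.log(2), abs=1e-12)
        assert val == pytest.approx(5.545177, abs=1e-6)

    def test_negative_lambda_rejected(self):
        x = np.ones((1, 1))
        with pytest.raises(ValueError, match="non-negative"):
            training_loss(x, x, np.ones(1), np.ones((1, 1)), -1.0, x)


class TestUpdateReference:
    def test_identity_design_returns_y(self, rng):
        # with C* = I and alpha = 1, the unregularized minimizer is Y itself
        g, k = 6, 4
        y = rng.uniform(0.1, 2.0, (g, k))
        x = rng.uniform(0.1, 2.0, (g, k))
        phi = update_reference(y, np.ones(k), np.eye(k), x, 0.0)
        np.testing.assert_allclose(phi, y, atol=1e-6)

    def test_scalar_case_against_bisection_oracle(self):
        # 1 gene/type/sample: minimize (phi-2)^2 + pair_softplus(phi-1);
        # stationarity: 2(phi-2) + tanh((phi-1)/2) = 0, solved by bisection
        def grad(p):
            return 2 * (p - 2.0) + np.tanh((p - 1.0) / 2.0)
        lo, hi = 1.0, 2.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if grad(mid) > 0:
                hi = mid
            else:
                lo = mid
        oracle = (lo + hi) / 2
        phi = update_reference(np.array([[2.0]]), np.ones(1), np.ones((1, 1)),
                               np.array([[1.0]]), 1.0)
        assert phi[0, 0] == pytest.approx(oracle, abs=1e-6)
        assert oracle == pytest.approx(1.808, abs=1e-3)

    def test_huge_lambda_pins_to_anchor(self, rng):
        g, q, n = 5, 2, 4
        x = rng.uniform(0.5, 1.5, (g, q))
        c = rng.dirichlet(np.ones(q), n).T
        y = rng.uniform(0.5, 1.5, (g, n))
        phi = update_reference(y, np.ones(q), c, x, 1e8)
        assert np.max(np.abs(phi - x)) < 1e-3

    def test_objective_not_worse_than_warm_start(self, rng):
        y, x, c = make_consistent_instance(rng, g=8, q=3, n=5, noise=0.3)
        alpha = rng.uniform(0.5, 1.5, 3)
        phi = update_reference(y.values, alpha, c.values, x.values, 2.0)
        f_phi = training_loss(y.values, phi, alpha, c.values, 2.0, x.values)
        f_x = training_loss(y.values, x.values, alpha, c.values, 2.0, x.values)
        assert f_phi <= f_x + 1e-9


class TestNormalizeColumns:
    def test_already_normalized(self):
        x = np.ones((2, 1))
        np.testing.assert_allclose(normalize_columns(x), x)

    def test_rescaling(self):
        out = normalize_columns(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [0.5, 1.5])

    def test_zero_column_fatal_names_column(self):
        x = ExpressionMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]),
                             ["g1", "g2"], ["B", "T"])
        with pytest.raises(ValueError, match="T"):
            normalize_columns(x)


class TestUpdateAlpha:
    def test_uniform_halving(self):
        a = update_alpha(np.array([[0.5, 0.5]]), np.array([[0.25, 0.25]]))
        assert a[0] == pytest.approx(0.5)

    def test_closed_form_matches_quadratic(self):
        a = update_alpha(np.array([[0.2, 0.4]]), np.array([[0.3, 0.6]]))
        assert a[0] == pytest.approx(1.5)

    def test_zero_estimate_clamps_to_zero(self):
        a = update_alpha(np.array([[0.2, 0.4]]), np.zeros((1, 2)))
        assert a[0] == 0.0

    def test_zero_row_gets_one_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            a = update_alpha(np.zeros((1, 3)), np.ones((1, 3)))
        assert a[0] == 1.0

    def test_matches_scalar_minimizer_on_random_rows(self, rng):
        cs = rng.uniform(0.01, 1.0, (20, 6))
        ch = rng.uniform(0.0, 1.5, (20, 6))
        a = update_alpha(cs, ch)
        for i in range(20):
            res = minimize_scalar(
                lambda t: ((t * cs[i] - ch[i]) ** 2).sum(),
                bounds=(0.0, 50.0), method="bounded",
                options={"xatol": 1e-13})
            assert a[i] == pytest.approx(res.x, abs=1e-8)


class TestHarmonize:
    def test_self_consistent_inputs_are_a_fixed_point(self, rng):
        y, x, c = make_consistent_instance(rng, g=40, q=3, n=10)
        res = harmonize(y, x, c, RegularizationConfig(fixed_lambda=1e4),
                        complete_reference=True, seed=0)
        np.testing.assert_allclose(res.alpha.alpha, 1.0, atol=1e-2)
        np.testing.assert_allclose(res.x_prime.values,
                                   normalize_columns(x).values, rtol=1e-2)
        assert res.converged

    def test_recovers_inverse_distortion(self, rng):
        # measured compositions are delta-distorted; alpha should invert delta
        y, x, c = make_consistent_instance(rng, g=60, q=3, n=12)
        delta = np.array([0.5, 1.0, 2.0])
        c_meas = CompositionMatrix(c.values * delta[:, None],
                                   list(c.celltype_ids), list(c.sample_ids))
        res = harmonize(y, x, c_meas, RegularizationConfig(fixed_lambda=32.0),
                        complete_reference=True, seed=0)
        np.testing.assert_allclose(res.alpha.alpha, 1.0 / delta, rtol=0.10)

    def test_extends_when_reference_incomplete(self, rng):
        y, x, c = make_consistent_instance(rng, g=30, q=3, n=8)
        c_partial = CompositionMatrix(c.values[:2] * 0.9,
                                      c.celltype_ids[:2], list(c.sample_ids))
        res = harmonize(y, x, c_partial,
                        RegularizationConfig(fixed_lambda=64.0), seed=0)
        assert res.x_prime.column_ids[-1] == "UI"
        assert res.c_prime.is_extended
        assert len(res.alpha) == 3

    def test_loss_trace_monotone_on_consistent_data(self, rng):
        y, x, c = make_consistent_instance(rng, g=30, q=3, n=8, noise=0.1)
        res = harmonize(y, x, c, RegularizationConfig(fixed_lambda=4.0),
                        complete_reference=True, seed=0)
        trace = np.array(res.loss_trace)
        assert np.all(np.diff(trace) <= 1e-6 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_x_prime_columns_always_sum_to_gene_count(self, rng):
        y, x, c = make_consistent_instance(rng, g=25, q=3, n=7, noise=0.3)
        res = harmonize(y, x, c, RegularizationConfig(fixed_lambda=2.0),
                        complete_reference=True, seed=0)
        g = res.x_prime.n_genes
        np.testing.assert_allclose(res.x_prime.values.sum(axis=0), g,
                                   rtol=1e-6)


class TestSelectLambda:
    def test_single_lambda_returned_without_cv(self, rng):
        y, x, c = make_consistent_instance(rng, g=10, q=2, n=6)
        config = RegularizationConfig(lambda_grid=np.array([7.0]),
                                      fixed_lambda=None)
        lam, scores = select_lambda(y.values, normalize_columns(x), c, config)
        assert lam == 7.0

    def test_tiebreak_toward_larger_lambda_on_consistent_data(self, rng):
        y, x, c = make_consistent_instance(rng, g=20, q=3, n=10)
        config = RegularizationConfig(lambda_grid=np.array([0.0, 2.0**15]),
                                      cv_folds=5)
        lam, scores = select_lambda(y.values, normalize_columns(x), c,
                                    config, seed=3)
        assert lam == 2.0**15

    def test_deterministic_given_seed(self, rng):
        y, x, c = make_consistent_instance(rng, g=15, q=3, n=10, noise=0.2)
        config = RegularizationConfig(lambda_grid=np.array([0.0, 1.0, 64.0]),
                                      cv_folds=3)
        out1 = select_lambda(y.values, normalize_columns(x), c, config, seed=9)
        out2 = select_lambda(y.values, normalize_columns(x), c, config, seed=9)
        assert out1 == out2

    def test_fewer_samples_than_folds_fatal(self, rng):
        y, x, c = make_consistent_instance(rng, g=10, q=2, n=3)
        config = RegularizationConfig(cv_folds=5)
        with pytest.raises(ValueError, match="folds"):
            select_lambda(y.values, normalize_columns(x), c, config)
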