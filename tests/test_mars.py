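"""The MARS engine: basis evaluation, GCV arithmetic, forward knot search,
GCV backward pruning, and the published-model evaluator fixture."""

import numpy as np
import pytest

from pcamars import (
    BasisFunction,
    HingeTerm,
    MarsConfig,
    backward_pass,
    eval_basis,
    eval_model,
    fit_mars,
    forward_pass,
    gcv,
    reference_no2_model,
)
from pcamars.mars import (
    MarsModel,
    _basis_column,
    load_model,
    model_from_dict,
    model_to_dict,
    predict,
    save_model,
)


def normal_equations_coefficients(model, X, y):
    """Independent oracle: solve B'B c = B'y on the model's basis matrix."""
    B = np.column_stack(
        [np.ones(len(X))] + [_basis_column(b, X) for b in model.basis]
    )
    return np.linalg.solve(B.T @ B, B.T @ y)


class TestEvalBasis:
    def test_hinge_vanishes_at_knot(self):
        bf = BasisFunction((HingeTerm(0, 1, -2.3324),))
        assert eval_basis(bf, [-2.3324, 0.0]) == 0.0

    def test_interaction_product_hand_case(self):
        # max(0, 0.55517 - x2) * max(0, 2.8871 - x1) at the origin
        bf = BasisFunction(
            (HingeTerm(1, -1, 0.55517), HingeTerm(0, -1, 2.8871))
        )
        assert eval_basis(bf, [0.0, 0.0]) == pytest.approx(1.60283, abs=1e-5)

    def test_constant_basis(self, rng):
        assert eval_basis(BasisFunction(), rng.normal(size=3)) == 1.0

    def test_out_of_range_variable(self):
        bf = BasisFunction((HingeTerm(5, 1, 0.0),))
        with pytest.raises(IndexError):
            eval_basis(bf, [1.0, 2.0])


class TestReferenceModel:
    def test_intercept_at_vanishing_point(self):
        model = reference_no2_model()
        assert eval_model(model, [-2.3324, 0.55517]) == 76.358

    def test_value_at_origin_hand_arithmetic(self):
        model = reference_no2_model()
        expected = 76.358 - 16.112 * 2.3324 + 32.65 * 0.55517 - 8.6937 * 1.60283
        assert eval_model(model, [0.0, 0.0]) == pytest.approx(expected, abs=1e-3)

    def test_vectorized_predict_agrees_with_pointwise(self, rng):
        model = reference_no2_model()
        X = rng.normal(0, 2, size=(50, 2))
        np.testing.assert_allclose(
            predict(model, X), [eval_model(model, x) for x in X], atol=1e-10
        )


class TestGcv:
    def test_perfect_fit_is_zero(self):
        assert gcv(0.0, 21, 5, 3.0) == 0.0

    def test_hand_arithmetic(self):
        # SSE/n = 100, C = 5 + 3*4/2 = 11, (1 - 11/21)^2 = 100/441
        assert gcv(2100.0, 21, 5, 3.0) == pytest.approx(441.0)

    def test_intercept_only_independent_of_penalty(self):
        vals = {gcv(50.0, 20, 1, d) for d in (0.0, 1.0, 3.0, 10.0)}
        assert len(vals) == 1
        assert vals.pop() == pytest.approx((50.0 / 20) / (1 - 1 / 20) ** 2)

    def test_saturated_model_is_infinite(self):
        assert gcv(1.0, 10, 10, 3.0) == np.inf


class TestForwardPass:
    def test_noiseless_hinge_recovery(self, rng):
        x = rng.uniform(0, 1, 50)
        y = np.maximum(0.0, x - 0.5)
        model = forward_pass(x[:, None], y)
        assert model.sse < 1e-10
        knots = [t.knot for b in model.basis for t in b.terms]
        assert min(abs(k - 0.5) for k in knots) < 0.05

    def test_constant_response_gives_intercept_only(self):
        X = np.linspace(0, 1, 30)[:, None]
        model = forward_pass(X, np.full(30, 7.0))
        assert model.basis == []
        assert model.intercept == pytest.approx(7.0)

    def test_pure_linear_fit(self, rng):
        x = rng.uniform(0, 1, 60)
        y = 3.0 * x - 1.0
        model = forward_pass(x[:, None], y)
        r2 = 1 - model.sse / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.999

    def test_monotone_sse_descent_and_oracle_coefficients(self, rng):
        X = rng.uniform(0, 1, (60, 3))
        y = 5 * np.maximum(0, X[:, 0] - 0.4) - 3 * X[:, 1] + rng.normal(0, 0.2, 60)
        model = forward_pass(X, y, MarsConfig(max_terms=9))
        # refit-from-scratch SSE of each prefix of the basis list never rises
        sses = []
        for k in range(len(model.basis) + 1):
            B = np.column_stack(
                [np.ones(60)] + [_basis_column(b, X) for b in model.basis[:k]]
            )
            coef, *_ = np.linalg.lstsq(B, y, rcond=None)
            sses.append(float(np.sum((y - B @ coef) ** 2)))
        assert all(b <= a + 1e-9 for a, b in zip(sses, sses[1:]))
        oracle = normal_equations_coefficients(model, X, y)
        np.testing.assert_allclose(
            np.concatenate([[model.intercept], model.coefficients]), oracle, atol=1e-6
        )

    def test_max_terms_respected(self, rng):
        X = rng.uniform(0, 1, (40, 2))
        y = rng.normal(size=40)
        model = forward_pass(X, y, MarsConfig(max_terms=5, endspan=1))
        assert model.n_basis <= 5


class TestBackwardPass:
    def test_noise_pruned_to_few_terms(self):
        survivors = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.uniform(0, 1, (50, 3))
            y = rng.standard_normal(50)
            model = fit_mars(X, y)
            survivors.append(len(model.basis))
        assert np.median(survivors) <= 2

    def test_gcv_optimal_model_is_fixed_point(self, rng):
        x = rng.uniform(0, 1, 50)
        y = np.maximum(0, x - 0.5) + rng.normal(0, 0.05, 50)
        pruned = fit_mars(x[:, None], y)
        again = backward_pass(pruned, x[:, None], y)
        assert model_to_dict(again) == model_to_dict(pruned)

    def test_noisy_hinge_knot_retained(self):
        knot_errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 50)
            y = np.maximum(0, x - 0.5) + rng.normal(0, 0.1, 50)
            model = fit_mars(x[:, None], y)
            knots = [t.knot for b in model.basis for t in b.terms]
            knot_errors.append(
                min(abs(k - 0.5) for k in knots) if knots else np.inf
            )
        assert np.median(knot_errors) < 0.1

    def test_backward_sequence_nested(self, rng):
        # pruned model's basis is a subset of the forward model's
        X = rng.uniform(0, 1, (60, 3))
        y = 5 * np.maximum(0, X[:, 0] - 0.4) + rng.normal(0, 0.3, 60)
        fwd = forward_pass(X, y)
        pruned = backward_pass(fwd, X, y)
        fwd_set = {tuple(b.terms) for b in fwd.basis}
        assert {tuple(b.terms) for b in pruned.basis} <= fwd_set
        oracle = normal_equations_coefficients(pruned, X, y)
        np.testing.assert_allclose(
            np.concatenate([[pruned.intercept], pruned.coefficients]), oracle,
            atol=1e-6,
        )


class TestFitMars:
    def test_benchmark_out_of_sample_r2(self):
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            X = rng.uniform(0, 1, (200, 3))
            Xt = rng.uniform(0, 1, (200, 3))
            f = lambda A: 10 * np.maximum(0, A[:, 0] - 0.5) + 5 * A[:, 1]
            y = f(X) + rng.normal(0, 0.5, 200)
            model = fit_mars(X, y)
            yt = f(Xt)
            pred = predict(model, Xt)
            r2s.append(1 - np.sum((yt - pred) ** 2) / np.sum((yt - yt.mean()) ** 2))
        assert np.median(r2s) > 0.8

    def test_station_scale_sanity(self, rng):
        X = rng.normal(size=(21, 3))
        y = rng.normal(60, 15, 21)
        model = fit_mars(X, y)
        assert model.n_basis < 21
        assert np.isfinite(model.gcv)

    def test_deterministic(self, rng):
        X = rng.uniform(0, 1, (40, 2))
        y = np.sin(3 * X[:, 0]) + rng.normal(0, 0.1, 40)
        a = fit_mars(X, y)
        b = fit_mars(X, y)
        assert model_to_dict(a) == model_to_dict(b)


def test_serialization_round_trip(tmp_path):
    model = reference_no2_model()
    save_model(model, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    assert model_to_dict(back) == model_to_dict(model)
    assert eval_model(back, [-2.3324, 0.55517]) == 76.358


def test_model_validation():
    with pytest.raises(ValueError):
        MarsModel(0.0, [1.0], [], 0.0, 0.0, 3.0, 10)
    with pytest.raises(ValueError):
        HingeTerm(0, 2, 0.0)
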