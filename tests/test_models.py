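"""Ratio models and envelope inversion: normal-equations oracle, nu-SVR
properties, geometric inversion checks."""

import numpy as np
import pytest

from oscibp.features import RatioPair
from oscibp.models import (
    EnvelopeCrossingError,
    FixedRatio,
    RankDeficientError,
    RatioMLR,
    RatioNuSVR,
    clip_ratio,
    estimate_bp_from_ratios,
    fit_mlr,
    fit_nusvr,
    maa_fixed_ratios,
    predict_linear,
)


class TestFixedRatios:
    def test_single_pair_is_its_own_mean(self):
        assert maa_fixed_ratios([RatioPair(0.6, 0.8)]) == RatioPair(0.6, 0.8)

    def test_two_pair_arithmetic(self):
        got = maa_fixed_ratios([RatioPair(0.5, 0.7), RatioPair(0.7, 0.9)])
        assert got.sbpr == pytest.approx(0.6)
        assert got.dbpr == pytest.approx(0.8)

    def test_matches_fold_left_accumulator(self):
        rng = np.random.default_rng(2)
        pairs = [RatioPair(float(s), float(d))
                 for s, d in zip(rng.uniform(0.3, 0.9, 100), rng.uniform(0.4, 0.95, 100))]
        acc_s = acc_d = 0.0
        for p in pairs:
            acc_s += p.sbpr
            acc_d += p.dbpr
        got = maa_fixed_ratios(pairs)
        assert got.sbpr == pytest.approx(acc_s / 100, abs=1e-12)
        assert got.dbpr == pytest.approx(acc_d / 100, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            maa_fixed_ratios([])

    def test_estimator_predicts_training_mean(self):
        est = FixedRatio().fit(np.zeros((4, 2)), [0.5, 0.6, 0.7, 0.8])
        np.testing.assert_allclose(est.predict(np.zeros((3, 2))), 0.65)


class TestMLR:
    def test_noiseless_line_recovered(self):
        x = np.linspace(0, 1, 20)
        model = RatioMLR().fit(x[:, None], 2.0 * x + 1.0)
        assert model.intercept_ == pytest.approx(1.0, abs=1e-10)
        assert model.coef_[0] == pytest.approx(2.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            X = rng.normal(size=(50, 3))
            y = X @ [0.3, -0.2, 0.1] + 0.5 + rng.normal(0, 0.05, 50)
            A = np.column_stack([np.ones(50), X])
            beta = np.linalg.inv(A.T @ A) @ A.T @ y
            model = fit_mlr(A, y, feature_names=("a", "b", "c"))
            assert model.intercept == pytest.approx(beta[0], abs=1e-8)
            np.testing.assert_allclose(model.weights, beta[1:], atol=1e-8)

    def test_duplicated_column_raises_rank_error(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        X = np.column_stack([x, x])
        with pytest.raises(RankDeficientError):
            RatioMLR().fit(X, x)

    def test_leading_ones_required_by_wrapper(self):
        with pytest.raises(ValueError, match="ones"):
            fit_mlr(np.random.default_rng(0).normal(size=(10, 2)), np.zeros(10))


class TestNuSVR:
    def test_noiseless_linear_agrees_with_mlr(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(-1, 1, 40)
        y = 0.5 * x
        svr = RatioNuSVR(C=100.0, nu=0.5).fit(x[:, None], y)
        mlr = RatioMLR().fit(x[:, None], y)
        np.testing.assert_allclose(svr.predict(x[:, None]), mlr.predict(x[:, None]), atol=0.02)

    @pytest.mark.parametrize("bad", [{"nu": -1.89}, {"nu": 0.0}, {"nu": 1.5}, {"C": -1.0}])
    def test_invalid_hyperparameters_rejected(self, bad):
        with pytest.raises(ValueError):
            RatioNuSVR(**bad).fit(np.zeros((5, 1)), np.zeros(5))

    def test_support_vector_fraction_respects_nu_bound(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(100, 2))
        y = X @ [0.4, -0.3] + rng.normal(0, 0.1, 100)
        for nu in (0.3, 0.6):
            est = RatioNuSVR(C=10.0, nu=nu).fit(X, y)
            assert est.sv_fraction_ >= nu - 0.1

    def test_deterministic_for_fixed_inputs(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(60, 2))
        y = X @ [0.4, -0.3] + rng.normal(0, 0.05, 60)
        m1 = fit_nusvr(X, y)
        m2 = fit_nusvr(X, y)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.intercept == m2.intercept


class TestPredictLinear:
    def test_zero_weights_constant_intercept(self):
        from oscibp.models import LinearModel

        model = LinearModel("mlr", ("a", "b"), np.zeros(2), 0.7)
        np.testing.assert_allclose(predict_linear(model, np.random.default_rng(0).normal(size=(6, 2))), 0.7)

    def test_round_trip_and_dot_product_oracle(self):
        rng = np.random.default_rng(16)
        x = np.linspace(0, 1, 20)
        A = np.column_stack([np.ones(20), x])
        y = 2.0 * x + 1.0
        model = fit_mlr(A, y)
        np.testing.assert_allclose(predict_linear(model, x[:, None]), y, atol=1e-8)

        X = rng.normal(size=(5, 1))
        manual = np.array([model.intercept + model.weights @ row for row in X])
        np.testing.assert_allclose(predict_linear(model, X), manual, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        from oscibp.models import LinearModel

        model = LinearModel("mlr", ("a",), np.ones(1), 0.0)
        with pytest.raises(ValueError, match="mismatch"):
            predict_linear(model, np.zeros((3, 2)))


class TestEnvelopeInversion:
    def test_triangular_geometry(self, triangular_owe):
        """Ratios 0.5 on a triangle with apex (100, 3) and limbs to 140/60:
        SBP at 120, DBP at 80 mmHg."""
        est = estimate_bp_from_ratios(triangular_owe, RatioPair(0.5, 0.5))
        assert est.sbp == pytest.approx(120.0, abs=0.1)
        assert est.dbp == pytest.approx(80.0, abs=0.1)

    def test_mutual_inverse_with_reference_ratios(self, processed_clean):
        from oscibp.features import reference_ratios

        owe = processed_clean.owe
        rs_sbp, rs_dbp = processed_clean.ref_sbp, processed_clean.ref_dbp
        ratios = reference_ratios(owe, rs_sbp, rs_dbp)
        est = estimate_bp_from_ratios(owe, ratios)
        assert est.sbp == pytest.approx(rs_sbp, abs=0.05)
        assert est.dbp == pytest.approx(rs_dbp, abs=0.05)

    def test_unit_ratio_degenerates_to_map(self, triangular_owe):
        est = estimate_bp_from_ratios(triangular_owe, RatioPair(1.0, 0.5))
        assert est.sbp == pytest.approx(triangular_owe.map, abs=0.05)

    def test_truncated_envelope_names_failing_side(self):
        from oscibp.envelope import OWE, fit_spline

        cp = np.array([80.0, 90, 100, 110, 120])
        amp = np.array([1.0, 2.0, 3.0, 2.8, 2.6])  # never drops to 0.3*MA on the high side
        owe = fit_spline(OWE(cp_knots=cp, amp_knots=amp, t_knots=(120 - cp) / 2.5))
        with pytest.raises(EnvelopeCrossingError, match="high"):
            estimate_bp_from_ratios(owe, RatioPair(0.3, 0.9))

    def test_ratio_clipping_bounds(self):
        assert clip_ratio(0.01) == 0.05
        assert clip_ratio(1.4) == 1.0
        assert clip_ratio(0.6) == 0.6
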