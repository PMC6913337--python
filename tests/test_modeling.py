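"""Bootstrap resampling, 0.632+ AUC, model selection, averaged fits."""

import numpy as np
import pytest

import gliorad as g
from gliorad.modeling import DEFAULT_RIDGE, _sigmoid, combine_632plus


class TestResampling:
    def test_equal_class_draw_probability(self):
        y = np.r_[np.ones(16, int), np.zeros(35, int)]
        ens = g.imbalance_adjusted_resample(y, B=1000, seed=0)
        frac_pos = np.mean(y[ens.in_bag] == 1)
        assert frac_pos == pytest.approx(0.5, abs=0.02)

    def test_minimal_cohort_size_contract(self):
        ens = g.imbalance_adjusted_resample(np.array([0, 1]), B=50, seed=1)
        assert ens.in_bag.shape == (50, 2)

    def test_uniform_mode_632_arithmetic(self):
        # plain bootstrap at N = 51: mean distinct in-bag ~ 51 x 0.632 ~ 32
        y = np.r_[np.ones(16, int), np.zeros(35, int)]
        ens = g.imbalance_adjusted_resample(y, B=500, seed=2, mode="uniform")
        distinct = np.mean([len(np.unique(bag)) for bag in ens.in_bag])
        assert distinct == pytest.approx(51 * 0.632, abs=1.0)
        oob_frac = np.mean([len(o) for o in ens.oob]) / 51
        assert oob_frac == pytest.approx(0.368, abs=0.02)

    def test_oob_is_complement_with_both_classes(self):
        y = np.r_[np.ones(5, int), np.zeros(9, int)]
        ens = g.imbalance_adjusted_resample(y, B=200, seed=3)
        for bag, out in zip(ens.in_bag, ens.oob):
            assert set(bag) | set(out) == set(range(14))
            assert not set(bag) & set(out)
            assert {0, 1} == set(y[out]) == set(y[bag])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            g.imbalance_adjusted_resample(np.ones(10, int), B=10, seed=0)

    def test_deterministic(self):
        y = np.r_[np.ones(6, int), np.zeros(10, int)]
        a = g.imbalance_adjusted_resample(y, B=20, seed=9)
        b = g.imbalance_adjusted_resample(y, B=20, seed=9)
        np.testing.assert_array_equal(a.in_bag, b.in_bag)


class TestAuc:
    def test_perfect_separation(self):
        assert g.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_enumerated_pairs(self):
        # pairs (0.9,0.4) (0.9,0.2) (0.3,0.2) concordant; (0.3,0.4) not
        assert g.auc([0.9, 0.3, 0.4, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties(self):
        assert g.auc(np.ones(6), [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            g.auc([0.1, 0.2], [1, 1])


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(10), np.zeros(30)]
        beta = g.fit_logistic(np.zeros((40, 0)), y, ridge=1e-12)
        assert beta[0] == pytest.approx(np.log(10 / 30), abs=1e-6)

    def test_separable_two_points_stay_finite(self):
        beta = g.fit_logistic(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]))
        assert np.isfinite(beta).all()

    def test_matches_independent_solver(self):
        # scikit-learn's lbfgs logistic regression as the second solver;
        # same objective with C = 1/ridge (intercept unpenalised in both)
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        X = rng.standard_normal((500, 3))
        eta = 0.5 + X @ np.array([1.0, -2.0, 0.7])
        y = (rng.random(500) < _sigmoid(eta)).astype(float)
        ridge = 1e-2
        ours = g.fit_logistic(X, y, ridge=ridge)
        skl = LogisticRegression(C=1.0 / ridge, tol=1e-10, max_iter=2000)
        skl.fit(X, y)
        ref = np.r_[skl.intercept_, skl.coef_.ravel()]
        np.testing.assert_allclose(ours, ref, rtol=0.10)

    def test_zero_variance_column_coefficient_zero(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.standard_normal(60), np.full(60, 4.0)])
        y = (X[:, 0] > 0).astype(float)
        beta = g.fit_logistic(X, y)
        assert beta[2] == 0.0


class TestAuc632Plus:
    def test_no_overfitting_reduces_to_fixed_weights(self):
        # OOB AUC equal to the apparent AUC (> 0.5) everywhere: R = 0,
        # alpha = 0.632 for all replicates
        res = combine_632plus(0.8, np.full(10, 0.8))
        np.testing.assert_allclose(res.R, 0.0)
        np.testing.assert_allclose(res.alpha, 0.632)
        assert res.estimate == pytest.approx(0.368 * 0.8 + 0.632 * 0.8)

    def test_oob_below_half_clipped_and_fully_weighted(self):
        res = combine_632plus(0.9, np.array([0.3, 0.9]))
        assert res.auc_prime[0] == 0.5
        assert res.R[0] == 1.0
        assert res.alpha[0] == pytest.approx(0.632 / (1 - 0.368))  # = 1.0
        assert res.alpha[0] == pytest.approx(1.0)

    def test_interpolating_overfitting_rate(self):
        res = combine_632plus(0.9, np.array([0.7]))
        assert res.R[0] == pytest.approx((0.9 - 0.7) / (0.9 - 0.5))

    def test_estimate_bounded_by_convex_components(self, informative_table,
                                                   small_ensemble):
        res = g.auc_632plus(["f0000", "f0001"], informative_table, small_ensemble)
        lo = min(res.apparent_auc, res.auc_prime.min())
        hi = max(res.apparent_auc, res.auc_prime.max())
        assert lo - 1e-12 <= res.estimate <= hi + 1e-12
        assert ((res.alpha >= 0.632) & (res.alpha <= 1.0)).all()

    def test_apparent_at_half_guarded(self):
        res = combine_632plus(0.5, np.array([0.6, 0.55]))
        np.testing.assert_allclose(res.R, 0.0)

    def test_ratio_rule_variant_runs(self, informative_table, small_ensemble):
        res = g.auc_632plus(["f0000"], informative_table, small_ensemble,
                            overfitting_rule="ratio")
        assert 0.0 <= res.estimate <= 1.0

    def test_missing_feature_rejected(self, informative_table, small_ensemble):
        with pytest.raises(KeyError, match="not in table"):
            g.auc_632plus(["nope"], informative_table, small_ensemble)


class TestForwardSelect:
    def test_order_one_is_exhaustive_best_single(self, informative_table,
                                                 small_ensemble):
        res = g.forward_select(informative_table.names, informative_table,
                               small_ensemble, orders=[1])
        best = max(
            informative_table.names,
            key=lambda f: g.auc_632plus([f], informative_table,
                                        small_ensemble).estimate,
        )
        assert res.per_order[1][0] == (best,)

    def test_order_exceeding_pool_rejected(self, informative_table,
                                           small_ensemble):
        with pytest.raises(ValueError, match="exceeds"):
            g.forward_select(informative_table.names[:3], informative_table,
                             small_ensemble, orders=[5])

    def test_recovers_informative_combination(self, informative_table,
                                              small_ensemble):
        res = g.forward_select(informative_table.names, informative_table,
                               small_ensemble, orders=range(1, 4))
        chosen = set(res.chosen_features)
        assert len(chosen & {"f0000", "f0001", "f0002"}) >= 2
        assert res.chosen_auc > 0.9

    def test_null_selection_does_not_inflate(self):
        # label-permuted data: the selected model's 0.632+ AUC stays modest
        # (guards against selection-bias leaks in the estimator)
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = g.generate_feature_table(
                g.TableSpec(p_features=8, informative_idx=(), seed=300 + seed)
            )
            ens = g.imbalance_adjusted_resample(table.y, B=100, seed=seed)
            res = g.forward_select(table.names, table, ens, orders=range(1, 4),
                                   starters=table.names[:3])
            ok += res.chosen_auc <= 0.75
        assert ok >= 9


class TestChooseOrder:
    def _wrap(self, aucs):
        return {i + 1: ((f"f{i}",), a) for i, a in enumerate(aucs)}

    def test_argmax(self):
        assert g.choose_order(self._wrap([0.7, 0.9, 0.85])) == 2

    def test_tie_prefers_smaller_order(self):
        assert g.choose_order(self._wrap([0.9, 0.9])) == 1

    def test_monotone_takes_last(self):
        assert g.choose_order(self._wrap(np.linspace(0.5, 0.95, 10))) == 10


class TestAverageCoefficients:
    def test_single_replicate_equals_single_fit(self, informative_table):
        ens = g.imbalance_adjusted_resample(informative_table.y, B=1, seed=4)
        model = g.average_coefficients(["f0000", "f0001"], informative_table, ens)
        idx = ens.in_bag[0]
        cols = [0, 1]
        from gliorad.modeling import _standardize

        Xz, _, _ = _standardize(informative_table.X[:, cols])
        direct = g.fit_logistic(Xz[idx], informative_table.y[idx].astype(float))
        np.testing.assert_allclose(model.coefficients, direct, atol=1e-8)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(12)
        n = 300
        X = rng.standard_normal((n, 2))
        truth = np.array([0.4, 1.2, -0.9])
        y = (rng.random(n) < _sigmoid(truth[0] + X @ truth[1:])).astype(int)
        table = g.FeatureTable(
            ids=[str(i) for i in range(n)], names=["a", "b"], X=X, y=y
        )
        ens = g.imbalance_adjusted_resample(y, B=60, seed=0, mode="uniform")
        model = g.average_coefficients(["a", "b"], table, ens)
        # features are roughly standard normal already, so z-scale ~ raw scale
        np.testing.assert_allclose(model.coefficients[1:], truth[1:], rtol=0.2)

    def test_coefficients_finite_with_separation(self, informative_table,
                                                 small_ensemble):
        model = g.average_coefficients(
            ["f0000", "f0001", "f0002"], informative_table, small_ensemble
        )
        assert np.isfinite(model.coefficients).all()
        assert model.order == 3


class TestPredict:
    def _model(self, coeffs, p):
        return g.FittedModel(
            features=[f"x{i}" for i in range(p)],
            coefficients=np.asarray(coeffs, float),
            feature_means=np.zeros(p),
            feature_sds=np.ones(p),
        )

    def test_zero_linear_predictor_gives_half(self):
        m = self._model([0.0, 1.0], 1)
        assert g.predict_probability(m, np.array([0.0])) == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        # a0 = 1, a1 = -2, x = 0.5 -> eta = 0 -> p = 0.5
        m = self._model([1.0, -2.0], 1)
        assert g.predict_probability(m, {"x0": 0.5}) == pytest.approx(0.5)

    def test_saturates_toward_one(self):
        m = self._model([0.0, 1.0], 1)
        assert g.predict_probability(m, np.array([40.0])) == pytest.approx(1.0)

    def test_missing_feature_named_in_error(self):
        m = self._model([0.0, 1.0, 1.0], 2)
        with pytest.raises(KeyError, match="x1"):
            g.predict_probability(m, {"x0": 1.0})

    def test_round_trip_serialisation(self, informative_table, small_ensemble):
        model = g.average_coefficients(["f0000"], informative_table,
                                       small_ensemble)
        back = g.FittedModel.from_dict(model.to_dict())
        p1 = g.predict_probability(model, informative_table)
        p2 = g.predict_probability(back, informative_table)
        np.testing.assert_allclose(p1, p2)
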