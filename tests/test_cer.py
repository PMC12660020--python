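"""Constant-error-rate joint model: estimation, marginals, likelihood."""

import numpy as np
import pytest

from autoscore_irt import (
    CERModel,
    ConfusionMatrix,
    ConstantErrorRates,
    Item2PL,
    Item4PL,
    JointModelCER,
    estimate_confusion,
    estimate_error_rates,
    joint_prob_cer,
    loglik_cer,
    marginal_4pl_from_2pl,
    marginal_4pl_from_4pl,
    marginal_cer_prob,
)

THETAS = np.linspace(-3, 3, 13)


class TestConfusionEstimation:
    def test_perfect_classifier_gives_identity(self):
        u = np.array([0, 1, 2, 0, 1, 2])
        np.testing.assert_allclose(
            estimate_confusion(u, u, K=3).p_v_given_u, np.eye(3)
        )

    def test_hand_counted_proportions(self):
        # counts: (0->0):8, (0->1):2, (1->1):9, (1->2):1, (2->2):10
        u = np.concatenate([np.zeros(10), np.ones(10), np.full(10, 2)])
        v = np.concatenate(
            [np.zeros(8), np.ones(2), np.ones(9), [2], np.full(10, 2)]
        )
        P = estimate_confusion(u, v, K=3).p_v_given_u
        np.testing.assert_allclose(
            P, [[0.8, 0.2, 0.0], [0.0, 0.9, 0.1], [0.0, 0.0, 1.0]]
        )

    def test_dichotomous_fn_rate(self):
        u = np.ones(100)
        v = np.concatenate([np.zeros(10), np.ones(90)])
        assert estimate_error_rates(u, v).eps_fn == pytest.approx(0.10)

    def test_unseen_category_uniform_and_flagged(self):
        conf = estimate_confusion([0, 0, 1, 1], [0, 0, 1, 1], K=3)
        assert conf.degenerate_rows.tolist() == [False, False, True]
        np.testing.assert_allclose(conf.p_v_given_u[2], [1 / 3] * 3)

    def test_strict_mode_errors_on_unseen_category(self):
        with pytest.raises(ValueError):
            estimate_confusion([0, 1], [0, 1], K=3, strict=True)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_error_rates([], [])

    def test_constant_classifier(self):
        u = np.array([0, 0, 1, 1])
        v = np.ones(4)
        rates = estimate_error_rates(u, v)
        assert rates.eps_fp == 1.0 and rates.eps_fn == 0.0

    def test_anti_informative_rates_warn(self):
        with pytest.warns(UserWarning, match="not informative"):
            ConstantErrorRates(eps_fp=0.7, eps_fn=0.6)

    def test_monte_carlo_recovery(self, rng):
        """Estimated rates fall within 3 binomial SEs of truth at n=5000."""
        n = 5000
        u = (rng.random(n) < 0.6).astype(int)
        fp_true, fn_true = 0.10, 0.05
        v = np.where(
            u == 1, rng.random(n) >= fn_true, rng.random(n) < fp_true
        ).astype(int)
        rates = estimate_error_rates(u, v)
        n0, n1 = (u == 0).sum(), (u == 1).sum()
        assert abs(rates.eps_fp - fp_true) < 3 * np.sqrt(fp_true * (1 - fp_true) / n0)
        assert abs(rates.eps_fn - fn_true) < 3 * np.sqrt(fn_true * (1 - fn_true) / n1)


class TestJointAndMarginal:
    @pytest.fixture
    def joint(self):
        rates = ConstantErrorRates(eps_fp=0.2, eps_fn=0.1)
        return JointModelCER(Item2PL(1.0, 0.0), ConfusionMatrix.from_rates(rates))

    def test_joint_normalizes(self, joint):
        for theta in (-2.0, 0.0, 1.5):
            total = sum(
                joint_prob_cer(theta, joint, u, v) for u in range(2) for v in range(2)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_joint_arithmetic(self, joint):
        # P(U=1) P(V=0|U=1) = 0.5 * 0.1
        assert joint_prob_cer(0.0, joint, 1, 0) == pytest.approx(0.05, abs=1e-12)

    def test_identity_confusion_concentrates_on_diagonal(self):
        jm = JointModelCER(Item2PL(1.0, 0.0), ConfusionMatrix.identity(2))
        assert joint_prob_cer(0.7, jm, 0, 1) == 0.0
        assert joint_prob_cer(0.7, jm, 1, 0) == 0.0

    def test_marginal_arithmetic(self, joint):
        # 0.2 * 0.5 + 0.9 * 0.5
        assert marginal_cer_prob(0.0, joint, 1) == pytest.approx(0.55, abs=1e-12)

    def test_marginal_with_identity_equals_manual(self):
        item = Item2PL(1.3, -0.4)
        jm = JointModelCER(item, ConfusionMatrix.identity(2))
        np.testing.assert_allclose(
            marginal_cer_prob(THETAS, jm, 1), item.icc(THETAS), atol=1e-15
        )

    def test_marginal_sums_to_one(self, joint):
        total = sum(marginal_cer_prob(THETAS, joint, v) for v in range(2))
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_polytomous_marginal_matches_brute_force(self, rng):
        """Random K=4 confusion matrices against an explicit total-probability sum."""

        class Categorical4:
            n_categories = 4

            def __init__(self, probs):
                self._p = probs  # (4, len(TH)) valid simplex at each theta

            def prob(self, theta, u, D=1.0):
                idx = np.searchsorted(THETAS, np.atleast_1d(theta))
                out = self._p[u, idx]
                return out if np.ndim(theta) else float(out[0])

        for _ in range(5):
            p = rng.dirichlet(np.ones(4), size=THETAS.size).T
            raw = rng.random((4, 4)) + 0.1
            conf = ConfusionMatrix(p_v_given_u=raw / raw.sum(axis=1, keepdims=True))
            jm = JointModelCER(Categorical4(p), conf)
            for v in range(4):
                brute = sum(
                    p[u] * conf.p_v_given_u[u, v] for u in range(4)
                )
                np.testing.assert_allclose(
                    marginal_cer_prob(THETAS, jm, v), brute, atol=1e-12
                )


class TestMarginal4PL:
    def test_classifier_error_rates_become_asymptotes(self):
        """FP rate 2.3% gives lower asymptote .023; FN rate 0.5% gives upper .995."""
        rates = ConstantErrorRates(eps_fp=0.023, eps_fn=0.005)
        m = marginal_4pl_from_2pl(Item2PL(1.2, 0.3), rates)
        assert m.c == pytest.approx(0.023)
        assert m.d == pytest.approx(0.995)
        assert (m.a, m.b) == (1.2, 0.3)

    def test_zero_rates_reduce_to_2pl(self):
        rates = ConstantErrorRates(0.0, 0.0)
        m = marginal_4pl_from_2pl(Item2PL(1.0, 0.0), rates, clamp=False)
        np.testing.assert_allclose(m.icc(THETAS), Item2PL(1.0, 0.0).icc(THETAS))

    def test_pointwise_agreement_with_marginalization(self):
        rates = ConstantErrorRates(eps_fp=0.2, eps_fn=0.1)
        item = Item2PL(1.1, -0.5)
        m4 = marginal_4pl_from_2pl(item, rates)
        jm = JointModelCER(item, ConfusionMatrix.from_rates(rates))
        np.testing.assert_allclose(
            m4.icc(THETAS), marginal_cer_prob(THETAS, jm, 1), atol=1e-12
        )

    def test_4pl_composition_matches_marginalization(self, rng):
        """Asymptote composition validated against brute-force total probability."""
        for _ in range(10):
            c = rng.uniform(0, 0.3)
            d = rng.uniform(0.6, 1.0)
            rates = ConstantErrorRates(rng.uniform(0, 0.3), rng.uniform(0, 0.3))
            item = Item4PL(rng.uniform(0.5, 2), rng.normal(), c=c, d=d)
            m = marginal_4pl_from_4pl(item, rates, clamp=False)
            jm = JointModelCER(item, ConfusionMatrix.from_rates(rates))
            np.testing.assert_allclose(
                m.icc(THETAS), marginal_cer_prob(THETAS, jm, 1), atol=1e-12
            )

    def test_nested_in_2pl_construction(self):
        rates = ConstantErrorRates(0.1, 0.2)
        via4 = marginal_4pl_from_4pl(Item4PL(1.0, 0.0, 0.0, 1.0), rates)
        via2 = marginal_4pl_from_2pl(Item2PL(1.0, 0.0), rates)
        assert via4.c == pytest.approx(via2.c, abs=1e-15)
        assert via4.d == pytest.approx(via2.d, abs=1e-15)
        assert (via4.a, via4.b) == (via2.a, via2.b)

    def test_anti_informative_rates_rejected(self):
        with pytest.warns(UserWarning):
            rates = ConstantErrorRates(0.6, 0.5)
        with pytest.raises(ValueError):
            marginal_4pl_from_2pl(Item2PL(1.0, 0.0), rates)


class TestLogLikelihood:
    @pytest.fixture
    def fixture_5x2(self):
        U = np.array([[1, 0], [1, 1], [0, 0], [0, 1], [1, np.nan]], dtype=float)
        V = np.array([[1, 0], [0, 1], [0, 0], [1, 1], [1, np.nan]], dtype=float)
        thetas = np.array([0.5, -0.2, 0.0, 1.0, -1.0])
        items = [Item2PL(1.0, 0.0), Item2PL(0.8, 0.5)]
        rates = [ConstantErrorRates(0.2, 0.1), ConstantErrorRates(0.1, 0.05)]
        models = [
            JointModelCER(it, ConfusionMatrix.from_rates(r))
            for it, r in zip(items, rates)
        ]
        return U, V, thetas, models

    def test_matches_hand_computation(self, fixture_5x2):
        U, V, thetas, models = fixture_5x2
        expected = 0.0
        for j, m in enumerate(models):
            for p in range(5):
                if np.isnan(U[p, j]):
                    continue
                u, v = int(U[p, j]), int(V[p, j])
                pu = m.manual_model.prob(thetas[p], u)
                pv = m.confusion.p_v_given_u[u, v]
                expected += np.log(pu) + np.log(pv)
        result = loglik_cer(U, V, thetas, models)
        assert result.total == pytest.approx(expected, rel=1e-12)

    def test_additive_decomposition_exact(self, fixture_5x2):
        U, V, thetas, models = fixture_5x2
        res = loglik_cer(U, V, thetas, models)
        assert res.total == res.manual_term + res.classifier_term

    def test_identity_confusion_zero_classifier_term(self):
        U = np.array([[1.0], [0.0], [1.0]])
        thetas = np.zeros(3)
        models = [JointModelCER(Item2PL(1.0, 0.0), ConfusionMatrix.identity(2))]
        res = loglik_cer(U, U, thetas, models)
        assert res.classifier_term == 0.0

    def test_mle_confusion_dominates_perturbations(self, small_cer_dataset, rng):
        ds = small_cer_dataset
        thetas = ds.theta
        conf_mle = [
            ConfusionMatrix.from_rates(estimate_error_rates(ds.U[:, j], ds.V[:, j]))
            for j in range(len(ds.items))
        ]
        models = [JointModelCER(it, c) for it, c in zip(ds.items, conf_mle)]
        best = loglik_cer(ds.U, ds.V, thetas, models).classifier_term
        for _ in range(5):
            perturbed = []
            for it, c in zip(ds.items, conf_mle):
                P = np.clip(c.p_v_given_u + rng.normal(0, 0.03, (2, 2)), 1e-3, None)
                P /= P.sum(axis=1, keepdims=True)
                perturbed.append(JointModelCER(it, ConfusionMatrix(P)))
            worse = loglik_cer(ds.U, ds.V, thetas, perturbed).classifier_term
            assert worse <= best + 1e-9

    def test_zero_probability_gives_neg_inf(self):
        U = np.array([[1.0]])
        V = np.array([[0.0]])
        models = [JointModelCER(Item2PL(1.0, 0.0), ConfusionMatrix.identity(2))]
        with pytest.warns(RuntimeWarning, match="zero-probability"):
            res = loglik_cer(U, V, np.zeros(1), models)
        assert res.total == -np.inf


class TestCERModelEstimator:
    def test_fit_recovers_rates_and_predicts(self, small_cer_dataset):
        ds = small_cer_dataset
        model = CERModel(items=ds.items).fit(ds.U, ds.V)
        assert len(model.error_rates_) == len(ds.items)
        assert all(isinstance(m, Item4PL) for m in model.marginal_items_)
        eap = model.predict(ds.V)
        assert eap.shape == (ds.U.shape[0],)
        assert np.corrcoef(eap, ds.theta)[0, 1] > 0.5

    def test_zero_error_rates_preserve_manual_scale(self, grid):
        """With rates (0,0) the marginal EAPs equal the manual-score EAPs."""
        items = [Item2PL(1.0, b) for b in (-1.0, 0.0, 1.0)]
        rng = np.random.default_rng(5)
        U = rng.integers(0, 2, size=(40, 3)).astype(float)
        model = CERModel(items=items).fit(U, U)
        from autoscore_irt import eap_estimates

        manual_eap, _, _ = eap_estimates(U, items, grid)
        # the marginal construction clamps rates at 1e-6, so agreement is
        # to that order rather than machine precision
        np.testing.assert_allclose(model.predict(U), manual_eap, atol=1e-4)

    def test_get_params(self):
        m = CERModel(items=[Item2PL(1.0, 0.0)], smoothing=0.5)
        assert m.get_params()["smoothing"] == 0.5
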