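"""uPCD: perturbation, conditional posteriors, chain mechanics, diagnostics."""

import numpy as np
import pytest

from lcmediate.lca import BinaryLCA
from lcmediate.linking import NonInclusivePCD, _multinomial_draw
from lcmediate.simulate import SimScenario, generate_dataset
from lcmediate.upcd import (
    UpcdConfig,
    UpcdState,
    UpdatedPCDMediation,
    diagnose_trace,
    mann_kendall,
    perturb_params,
    upcd_posterior,
)


class TestPerturbation:
    def test_zero_covariance_is_identity(self):
        rng = np.random.default_rng(0)
        est = np.array([1.0, -2.0, 0.5])
        out = perturb_params(est, np.zeros((3, 3)), rng)
        np.testing.assert_array_equal(out, est)

    def test_sample_covariance_matches_target(self):
        rng = np.random.default_rng(1)
        cov = np.array([[0.5, 0.2], [0.2, 0.4]])
        est = np.array([1.0, 2.0])
        draws = np.array([perturb_params(est, cov, rng) for _ in range(10_000)])
        np.testing.assert_allclose(np.cov(draws.T), cov, rtol=0.05)
        np.testing.assert_allclose(draws.mean(axis=0), est, atol=0.03)

    def test_negative_eigenvalues_floored(self):
        rng = np.random.default_rng(2)
        cov = np.array([[1.0, 1.5], [1.5, 1.0]])  # indefinite
        out = perturb_params(np.zeros(2), cov, rng)
        assert np.all(np.isfinite(out))


class TestConditionalPosterior:
    @pytest.fixture(scope="class")
    def fitted(self, good_dataset):
        lca = BinaryLCA(n_classes=4, random_state=0).fit(good_dataset.U)
        lca.align(good_dataset.scenario.item_profiles)
        return lca, good_dataset

    def test_null_slopes_reduce_to_unconditional(self, fitted):
        lca, ds = fitted
        alpha = np.array([-1.4, 0, 0, 0])
        beta = np.array([-0.6, 0.4, 0, 0, 0, 0, 0, 0])
        post = upcd_posterior(
            lca.class_logits_, lca.item_logits_, alpha, beta, ds.U, ds.M, ds.Y
        )
        np.testing.assert_allclose(post, lca.predict_proba(ds.U), atol=1e-12)

    def test_hand_computed_single_person(self):
        # k=2, p=2: posterior ratio has a closed form
        gamma = np.array([np.log(0.3 / 0.7)])
        tau = np.array([[2.0, -1.0], [-0.5, 0.5]])
        alpha = np.array([-1.0, 0.8])
        beta = np.array([-0.4, 0.3, 0.6, -0.2])
        U = np.array([[1.0, 0.0]])
        M = np.array([1])
        Y = np.array([1])
        from scipy.special import expit

        pi = np.array([0.3, 0.7])
        probs = expit(tau)
        num = np.empty(2)
        for x in range(2):
            pm = expit(alpha[0] + (alpha[1] if x == 0 else 0.0))
            py = expit(beta[0] + beta[1] * 1 + (beta[2] + beta[3] * 1 if x == 0 else 0.0))
            num[x] = pi[x] * probs[x, 0] * (1 - probs[x, 1]) * pm * py
        expected = num / num.sum()
        post = upcd_posterior(gamma, tau, alpha, beta, U, M, Y)
        np.testing.assert_allclose(post[0], expected, atol=1e-12)

    def test_outcome_coefficient_shifts_posterior_monotonically(self, fitted):
        lca, ds = fitted
        alpha = np.array([-1.4, 0, 0, 0])
        idx = np.nonzero(ds.Y == 1)[0][:50]
        masses = []
        for b2 in (0.0, 1.0, 2.0):
            beta = np.array([-0.6, 0.4, b2, 0, 0, 0, 0, 0])
            post = upcd_posterior(
                lca.class_logits_, lca.item_logits_, alpha, beta,
                np.asarray(ds.U, float)[idx], ds.M[idx], ds.Y[idx],
            )
            masses.append(post[:, 0].mean())
        assert masses[0] < masses[1] < masses[2]


class TestReductionToNPCD:
    def test_null_slope_posterior_draws_match_npcd(self, good_dataset):
        """Frozen null structural slopes + no perturbation: the uPCD
        imputation distribution is the unconditional posterior, i.e.
        exactly what nPCD draws from."""
        ds = good_dataset
        lca = BinaryLCA(n_classes=4, random_state=0).fit(ds.U)
        lca.align(ds.scenario.item_profiles)
        alpha = np.array([-1.39, 0, 0, 0])
        beta = np.array([-0.62, 0.41, 0, 0, 0, 0, 0, 0])
        post_u = upcd_posterior(
            lca.class_logits_, lca.item_logits_, alpha, beta, ds.U, ds.M, ds.Y
        )
        post_n = lca.predict_proba(ds.U)
        np.testing.assert_allclose(post_u, post_n, atol=1e-12)
        d1 = _multinomial_draw(post_u, np.random.default_rng(123))
        d2 = _multinomial_draw(post_n, np.random.default_rng(123))
        np.testing.assert_array_equal(d1, d2)


class TestChain:
    @pytest.fixture(scope="class")
    def small_run(self, good_scenario):
        s = SimScenario(item_profiles=good_scenario.item_profiles, n_obs=1500)
        ds = generate_dataset(s, seed=31)
        est = UpdatedPCDMediation(
            n_classes=4, burn_in=10, thin=3, n_draws=6,
            reference_profiles=s.item_profiles, random_state=77,
        ).fit(ds.U, ds.M, ds.Y)
        return est, ds

    def test_draw_count_and_spacing(self, small_run):
        est, _ = small_run
        assert est.draws_.shape[1] == 6
        np.testing.assert_array_equal(
            est.draw_iterations_, 10 + 3 * np.arange(1, 7)
        )

    def test_cell_counts_conserve_n(self, small_run):
        est, ds = small_run
        cells = np.asarray(est.state_.cell_trace)
        np.testing.assert_array_equal(cells.sum(axis=1), len(ds.M))
        sizes = np.asarray(est.state_.class_size_trace)
        np.testing.assert_array_equal(sizes.sum(axis=1), len(ds.M))

    def test_same_seed_bit_identical(self, good_scenario):
        s = SimScenario(item_profiles=good_scenario.item_profiles, n_obs=1200)
        ds = generate_dataset(s, seed=13)
        kw = dict(
            n_classes=4, burn_in=8, thin=2, n_draws=4,
            reference_profiles=s.item_profiles, random_state=55,
        )
        a = UpdatedPCDMediation(**kw).fit(ds.U, ds.M, ds.Y)
        b = UpdatedPCDMediation(**kw).fit(ds.U, ds.M, ds.Y)
        np.testing.assert_array_equal(a.effects_.estimates, b.effects_.estimates)
        np.testing.assert_array_equal(a.effects_.ses, b.effects_.ses)
        np.testing.assert_array_equal(a.draws_, b.draws_)

    def test_perturbation_inflates_pooled_se(self, good_scenario):
        ses_on, ses_off = [], []
        for rep in range(6):
            s = SimScenario(item_profiles=good_scenario.item_profiles, n_obs=1500)
            ds = generate_dataset(s, seed=400 + rep)
            kw = dict(
                n_classes=4, burn_in=20, thin=4, n_draws=12,
                reference_profiles=s.item_profiles, random_state=rep,
            )
            on = UpdatedPCDMediation(perturb=True, **kw).fit(ds.U, ds.M, ds.Y)
            off = UpdatedPCDMediation(perturb=False, **kw).fit(ds.U, ds.M, ds.Y)
            ses_on.append(on.effects_.ses[0, 0])
            ses_off.append(off.effects_.ses[0, 0])
        assert np.mean(ses_on) > np.mean(ses_off)


class TestDiagnostics:
    def _state(self, trend=False):
        rng = np.random.default_rng(3)
        t = np.arange(300)
        base = 0.01 * t if trend else np.zeros(300)
        at = rng.normal(0, 0.05, (300, 4)) + base[:, None]
        bt = rng.normal(0, 0.05, (300, 8))
        cells = np.full((300, 16), 10)
        return UpcdState(
            300, at[-1], bt[-1], np.zeros(3), np.zeros(5),
            alpha_trace=list(at), beta_trace=list(bt),
            class_size_trace=list(np.full((300, 4), 40)),
            cell_trace=list(cells),
        )

    def test_threshold_rule_strict_boundary(self):
        state = self._state()
        cohort = [1.0] * 10
        at_double = diagnose_trace(state, 2.0, cohort)
        assert at_double["threshold_se_rule"]["excluded"] is False
        above = diagnose_trace(state, 2.1, cohort)
        assert above["threshold_se_rule"]["excluded"] is True

    def test_stationary_trace_passes(self):
        report = diagnose_trace(self._state(trend=False), 1.0, [1.0] * 5)
        assert report["stationary"] is True
        assert report["pass"] is True
        assert report["empty_cell_iterations"] == 0

    def test_trending_trace_fails_stationarity(self):
        report = diagnose_trace(self._state(trend=True), 1.0, [1.0] * 5)
        assert report["stationary"] is False
        assert report["pass"] is False

    def test_single_dataset_mode_not_evaluable(self):
        report = diagnose_trace(self._state(), 1.5, None)
        assert report["threshold_se_rule"]["excluded"] is None
        assert report["threshold_se_rule"]["max_se"] == 1.5

    def test_mann_kendall_detects_trend(self):
        rng = np.random.default_rng(4)
        flat = rng.normal(size=200)
        rising = flat + 0.05 * np.arange(200)
        assert mann_kendall(flat)[1] > 0.05
        assert mann_kendall(rising)[1] < 0.01

    def test_config_validation(self):
        with pytest.raises(ValueError):
            UpcdConfig(burn_in=0)
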