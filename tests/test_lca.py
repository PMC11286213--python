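"""Latent class model: EM oracles, posteriors, entropy, covariance."""

import numpy as np
import pytest
from scipy.special import expit, logit

from lcmediate.lca import (
    BinaryLCA,
    CovariateLCA,
    DegenerateFitError,
    classification_matrix,
    modal_assign,
    relative_entropy,
)


def _two_class_data(n, p1, p2, pi1, rng, p_items=2):
    X = (rng.random(n) >= pi1).astype(int)  # 0 with prob pi1
    probs = np.array([[p1] * p_items, [p2] * p_items])
    U = (rng.random((n, p_items)) < probs[X]).astype(float)
    return U, X


class TestFitEM:
    def test_one_class_closed_form(self):
        rng = np.random.default_rng(0)
        U = (rng.random((500, 3)) < [0.2, 0.5, 0.8]).astype(float)
        lca = BinaryLCA(n_classes=1).fit(U)
        np.testing.assert_allclose(lca.class_weights_, [1.0])
        np.testing.assert_allclose(lca.item_probs_[0], U.mean(axis=0), atol=1e-12)
        # independent-Bernoulli log-likelihood
        ph = U.mean(axis=0)
        expected = np.sum(U * np.log(ph) + (1 - U) * np.log(1 - ph))
        assert lca.loglik_ == pytest.approx(expected, rel=1e-10)

    def test_two_class_parameter_recovery(self):
        rng = np.random.default_rng(42)
        # p=3 is the minimal identified two-class design
        U, _ = _two_class_data(10_000, 0.95, 0.05, 0.5, rng, p_items=3)
        lca = BinaryLCA(n_classes=2, random_state=1).fit(U)
        lca.align(np.array([[0.95] * 3, [0.05] * 3]))
        np.testing.assert_allclose(
            lca.item_probs_, [[0.95] * 3, [0.05] * 3], atol=0.02
        )
        np.testing.assert_allclose(lca.class_weights_, [0.5, 0.5], atol=0.02)

    def test_em_beats_brute_force_grid(self):
        # tiny dataset; grid over (pi_1, p_1, p_2) with items constrained
        # equal within class is a subfamily, so EM's ML must dominate it
        U = np.array([[1, 1], [1, 0], [1, 1], [0, 0], [0, 1], [0, 0]], dtype=float)
        lca = BinaryLCA(n_classes=2, random_state=0).fit(U)
        grid = np.linspace(0.025, 0.975, 20)
        best = -np.inf
        for pi1 in grid:
            for pa in grid:
                for pb in grid:
                    like = pi1 * (pa ** U * (1 - pa) ** (1 - U)).prod(axis=1) + (
                        1 - pi1
                    ) * (pb ** U * (1 - pb) ** (1 - U)).prod(axis=1)
                    best = max(best, np.log(like).sum())
        assert lca.loglik_ >= best - 1e-9

    def test_loglik_trace_monotone(self, good_dataset):
        lca = BinaryLCA(n_classes=4, random_state=3).fit(good_dataset.U)
        trace = np.asarray(lca.loglik_trace_)
        assert np.all(np.diff(trace) >= -1e-7 * np.abs(trace[:-1]))

    def test_degenerate_when_more_classes_than_patterns(self):
        U = np.tile([[0.0, 1.0], [1.0, 0.0]], (5, 1))
        with pytest.raises(DegenerateFitError):
            BinaryLCA(n_classes=3, random_state=0).fit(U)

    def test_missing_cells_fiml(self):
        rng = np.random.default_rng(11)
        U, _ = _two_class_data(2000, 0.9, 0.1, 0.5, rng, p_items=3)
        mask = rng.random(U.shape) < 0.15
        mask[mask.all(axis=1), 0] = False  # keep one observed cell per row
        U[mask] = np.nan
        lca = BinaryLCA(n_classes=2, random_state=2).fit(U)
        post = lca.predict_proba(U)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
        lca.align(np.array([[0.9] * 3, [0.1] * 3]))
        np.testing.assert_allclose(lca.item_probs_[0], [0.9] * 3, atol=0.05)

    def test_all_missing_row_rejected(self):
        U = np.array([[1.0, 0.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="at least one observed"):
            BinaryLCA(n_classes=1).fit(U)


class TestPosteriors:
    def test_single_class_posterior_is_one(self):
        U = np.array([[0.0, 1.0], [1.0, 1.0]])
        lca = BinaryLCA(n_classes=1).fit(U)
        np.testing.assert_array_equal(lca.predict_proba(U), [[1.0], [1.0]])

    def test_identical_profiles_give_uniform_posterior(self):
        lca = BinaryLCA(n_classes=2)
        lca.class_weights_ = np.array([0.5, 0.5])
        lca.item_probs_ = np.array([[0.3, 0.7], [0.3, 0.7]])
        lca._finalize()
        post = lca.predict_proba(np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_allclose(post, 0.5, atol=1e-12)

    def test_hand_computed_bayes_rule(self):
        pi = np.array([0.3, 0.7])
        probs = np.array([[0.9, 0.2], [0.4, 0.6]])
        lca = BinaryLCA(n_classes=2)
        lca.class_weights_ = pi
        lca.item_probs_ = probs
        lca._finalize()
        U = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        expected = np.empty((3, 2))
        for i, u in enumerate(U):
            num = pi * np.prod(probs**u * (1 - probs) ** (1 - u), axis=1)
            expected[i] = num / num.sum()
        np.testing.assert_allclose(lca.predict_proba(U), expected, atol=1e-12)

    def test_identical_patterns_share_posteriors(self, good_dataset):
        lca = BinaryLCA(n_classes=4, random_state=0).fit(good_dataset.U)
        post = lca.predict_proba(good_dataset.U)
        U = np.asarray(good_dataset.U)
        i, j = 0, np.nonzero((U == U[0]).all(axis=1))[0][-1]
        np.testing.assert_array_equal(post[i], post[j])


class TestEntropyAndClassification:
    def test_one_hot_entropy_is_one(self):
        post = np.eye(3)[np.array([0, 1, 2, 0])]
        assert relative_entropy(post) == pytest.approx(1.0)

    def test_uniform_entropy_is_zero(self):
        assert relative_entropy(np.full((10, 4), 0.25)) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_classification_identity(self):
        post = np.eye(4)[np.array([0, 1, 2, 3, 1, 2])]
        np.testing.assert_allclose(classification_matrix(post), np.eye(4), atol=1e-12)

    def test_uniform_ties_break_to_first_class(self):
        post = np.full((6, 3), 1.0 / 3)
        assert np.all(modal_assign(post) == 0)
        D = classification_matrix(post)
        np.testing.assert_allclose(D, np.tile([1.0, 0, 0], (3, 1)), atol=1e-12)

    def test_rows_sum_to_one(self, good_dataset):
        lca = BinaryLCA(n_classes=4, random_state=0).fit(good_dataset.U)
        post = lca.predict_proba(good_dataset.U)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
        D = classification_matrix(post)
        np.testing.assert_allclose(D.sum(axis=1), 1.0, atol=1e-10)

    def test_poor_entropy_confuses_ao_cl_with_low(self, poor_scenario):
        from lcmediate.simulate import generate_dataset

        ds = generate_dataset(poor_scenario, seed=99)
        lca = BinaryLCA(n_classes=4, random_state=5).fit(ds.U)
        lca.align(poor_scenario.item_profiles)
        D = classification_matrix(lca.predict_proba(ds.U))
        # rows: EOP, AO, CL, Low; columns: assigned class.  Leakage into
        # the Low column is worst for the AO and CL classes.
        assert D[1, 3] > D[0, 3]
        assert D[2, 3] > D[0, 3]


class TestParamCovariance:
    def test_single_item_closed_form_se(self):
        rng = np.random.default_rng(8)
        n = 4000
        U = (rng.random((n, 1)) < 0.3).astype(float)
        lca = BinaryLCA(n_classes=1).fit(U)
        cov = lca.estimate_covariance()
        phat = U.mean()
        expected = np.sqrt(1.0 / (n * phat * (1 - phat)))
        assert cov.se[-1] == pytest.approx(expected, rel=1e-3)

    def test_variance_halves_when_n_doubles(self):
        ratios = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            U1, _ = _two_class_data(600, 0.85, 0.15, 0.4, rng, p_items=3)
            U2, _ = _two_class_data(1200, 0.85, 0.15, 0.4, rng, p_items=3)
            v = []
            for U in (U1, U2):
                lca = BinaryLCA(n_classes=2, random_state=0).fit(U)
                lca.align(np.array([[0.85] * 3, [0.15] * 3]))
                v.append(np.mean(lca.estimate_covariance().se[1:] ** 2))
            ratios.append(v[0] / v[1])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)

    def test_boundary_item_probability_flagged(self):
        U = np.column_stack([np.zeros(200), np.repeat([0.0, 1.0], 100)])
        lca = BinaryLCA(n_classes=1).fit(U)
        cov = lca.estimate_covariance()
        assert cov.inflated[0]  # first item prob estimated at the clamp
        assert np.isnan(cov.se[0])


class TestCovariateLCA:
    def test_null_covariates_match_unconditional(self):
        rng = np.random.default_rng(21)
        U, _ = _two_class_data(3000, 0.9, 0.1, 0.4, rng, p_items=3)
        Z = np.zeros((3000, 1))
        un = BinaryLCA(n_classes=2, random_state=4).fit(U).align()
        co = CovariateLCA(n_classes=2, random_state=4).fit(U, Z).align()
        np.testing.assert_allclose(co.item_probs_, un.item_probs_, atol=1e-3)
        np.testing.assert_allclose(co.class_weights_, un.class_weights_, atol=1e-3)

    def test_recovers_structural_log_odds(self):
        rng = np.random.default_rng(22)
        n = 10_000
        z = rng.standard_normal(n)
        # class 0 log-odds increase by 1.0 per unit z (class 1 = reference)
        p0 = expit(-0.5 + 1.0 * z)
        X = (rng.random(n) >= p0).astype(int)
        probs = np.array([[0.9, 0.9, 0.9], [0.1, 0.1, 0.1]])
        U = (rng.random((n, 3)) < probs[X]).astype(float)
        co = CovariateLCA(n_classes=2, random_state=6).fit(U, z[:, None])
        co.align(probs)
        assert co.structural_coefs_[0, 1] == pytest.approx(1.0, abs=0.15)

    def test_posterior_monotone_in_covariate(self):
        rng = np.random.default_rng(23)
        n = 5000
        z = rng.integers(0, 2, n).astype(float)
        p0 = expit(-1.0 + 1.5 * z)
        X = (rng.random(n) >= p0).astype(int)
        probs = np.array([[0.8, 0.8], [0.2, 0.2]])
        U = (rng.random((n, 2)) < probs[X]).astype(float)
        co = CovariateLCA(n_classes=2, random_state=7).fit(U, z[:, None])
        co.align(probs)
        u_row = np.array([[1.0, 0.0]])
        p_z1 = co.predict_proba(u_row, np.array([[1.0]]))[0, 0]
        p_z0 = co.predict_proba(u_row, np.array([[0.0]]))[0, 0]
        # fitted slope for class 0 is positive, so z=1 must raise its posterior
        assert co.structural_coefs_[0, 1] > 0
        assert p_z1 > p_z0
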