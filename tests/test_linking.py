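"""Linking estimators: BCH weights, Rubin pooling, degenerate equivalences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcmediate.lca import BinaryLCA
from lcmediate.linking import (
    BCHMediation,
    InclusivePCD,
    ModalAssignmentMediation,
    NonInclusivePCD,
    OneStepMediation,
    bch_weights,
    rubin_pool,
)
from lcmediate.mediation import fit_structural, mediation_effects
from lcmediate.simulate import SimScenario, generate_dataset


def _oracle_effects(ds):
    """Mediation effects using the true class labels."""
    sp = fit_structural(ds.true_class, ds.M, ds.Y, k=4)
    return mediation_effects(sp, se=False).estimates


class TestBCHWeights:
    def test_identity_matrix_gives_one_hot(self):
        W = np.array([0, 2, 1, 3])
        h = bch_weights(np.eye(4), W)
        np.testing.assert_array_equal(h, np.eye(4)[W])

    def test_two_class_symmetric_closed_form(self):
        e = 0.2
        D = np.array([[1 - e, e], [e, 1 - e]])
        expected_inv = np.array([[1 - e, -e], [-e, 1 - e]]) / (1 - 2 * e)
        h = bch_weights(D, np.array([0, 1]))
        np.testing.assert_allclose(h, expected_inv, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        D = rng.dirichlet(np.ones(4) * 5, size=4)
        D += np.eye(4)  # diagonally dominant => invertible
        D /= D.sum(axis=1, keepdims=True)
        h = bch_weights(D, rng.integers(0, 4, 50))
        np.testing.assert_allclose(h.sum(axis=1), 1.0, atol=1e-10)

    def test_ill_conditioned_matrix_warns(self):
        D = np.full((3, 3), 1.0 / 3) + 1e-12 * np.eye(3)
        with pytest.warns(UserWarning, match="nearly singular"):
            bch_weights(D, np.array([0, 1, 2]))


class TestRubinPooling:
    def test_identical_draws_have_zero_between_variance(self):
        p = rubin_pool([0.4, 0.4, 0.4], [0.01, 0.02, 0.03])
        assert p.between_var == pytest.approx(0.0, abs=1e-30)
        assert p.total_se == pytest.approx(np.sqrt(0.02))
        assert p.mc_error == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_two_draws(self):
        p = rubin_pool([0.0, 1.0], [1.0, 1.0])
        assert p.estimate == 0.5
        assert p.between_var == pytest.approx(0.5)
        assert p.total_se**2 == pytest.approx(1.0 + 1.5 * 0.5)
        assert p.mc_error == pytest.approx(np.sqrt(0.5 / 2))

    def test_mc_error_shrinks_as_sqrt_m(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(0.3, 0.05, size=1600)
        p_small = rubin_pool(draws[:100], np.full(100, 0.01))
        p_large = rubin_pool(draws, np.full(1600, 0.01))
        assert p_large.mc_error == pytest.approx(p_small.mc_error / 4.0, rel=0.25)

    @given(
        st.lists(st.floats(-2, 2), min_size=2, max_size=30),
        st.floats(0.001, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_total_variance_identity(self, estimates, var):
        m = len(estimates)
        p = rubin_pool(estimates, [var] * m)
        assert p.total_se**2 == pytest.approx(
            p.within_var + (1 + 1 / m) * p.between_var, rel=1e-10
        )
        assert p.mc_error == pytest.approx(np.sqrt(p.between_var / m), rel=1e-10)


class TestPerfectSeparationEquivalences:
    """With one-hot posteriors, every linking method collapses onto the
    oracle analysis that uses the true class labels."""

    def test_modal_equals_oracle(self, separated_dataset):
        ds = separated_dataset
        est = ModalAssignmentMediation(
            n_classes=4, reference_profiles=ds.scenario.item_profiles, random_state=0
        ).fit(ds.U, ds.M, ds.Y)
        np.testing.assert_allclose(
            est.effects_.estimates, _oracle_effects(ds), atol=1e-6
        )

    def test_bch_equals_modal_under_identity_classification(self, separated_dataset):
        ds = separated_dataset
        kw = dict(n_classes=4, reference_profiles=ds.scenario.item_profiles)
        modal = ModalAssignmentMediation(random_state=0, **kw).fit(ds.U, ds.M, ds.Y)
        bch = BCHMediation(random_state=0, **kw).fit(ds.U, ds.M, ds.Y)
        np.testing.assert_allclose(
            bch.effects_.estimates, modal.effects_.estimates, atol=1e-4
        )

    def test_npcd_equals_modal_with_one_hot_posteriors(self, separated_dataset):
        ds = separated_dataset
        kw = dict(n_classes=4, reference_profiles=ds.scenario.item_profiles)
        modal = ModalAssignmentMediation(random_state=0, **kw).fit(ds.U, ds.M, ds.Y)
        npcd = NonInclusivePCD(n_draws=5, random_state=1, **kw).fit(ds.U, ds.M, ds.Y)
        np.testing.assert_allclose(
            npcd.effects_.estimates, modal.effects_.estimates, atol=1e-4
        )
        assert npcd.effects_.diagnostics["mc_error"].max() < 1e-8

    def test_onestep_equals_oracle(self, separated_dataset):
        ds = separated_dataset
        est = OneStepMediation(
            n_classes=4, reference_profiles=ds.scenario.item_profiles, random_state=2
        ).fit(ds.U, ds.M, ds.Y)
        np.testing.assert_allclose(
            est.effects_.estimates, _oracle_effects(ds), atol=1e-3
        )

    def test_onestep_loglik_trace_monotone(self, separated_dataset):
        ds = separated_dataset
        est = OneStepMediation(
            n_classes=4, reference_profiles=ds.scenario.item_profiles,
            n_restarts=3, random_state=2,
        ).fit(ds.U, ds.M, ds.Y)
        trace = np.asarray(est.loglik_trace_)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))


class TestPCDBehaviour:
    def test_same_seed_is_deterministic(self, good_dataset):
        ds = good_dataset
        kw = dict(
            n_classes=4,
            n_draws=8,
            reference_profiles=ds.scenario.item_profiles,
            random_state=42,
        )
        a = NonInclusivePCD(**kw).fit(ds.U, ds.M, ds.Y)
        b = NonInclusivePCD(**kw).fit(ds.U, ds.M, ds.Y)
        np.testing.assert_array_equal(a.effects_.estimates, b.effects_.estimates)
        np.testing.assert_array_equal(a.effects_.ses, b.effects_.ses)

    def test_incpcd_agrees_with_npcd_under_null_conditioning(self):
        # M and Y carry no class information, so conditioning on them
        # cannot move the posterior; both methods estimate null effects
        s = SimScenario(
            p_m_given_x=np.full(4, 0.2),
            p_y_given_x_m=np.tile([0.35, 0.45], (4, 1)),
            n_obs=4000,
        )
        ds = generate_dataset(s, seed=5)
        kw = dict(
            n_classes=4, n_draws=15,
            reference_profiles=s.item_profiles, random_state=9,
        )
        npcd = NonInclusivePCD(**kw).fit(ds.U, ds.M, ds.Y)
        incpcd = InclusivePCD(**kw).fit(ds.U, ds.M, ds.Y)
        te_n = npcd.effects_.estimates[:, 0]
        te_i = incpcd.effects_.estimates[:, 0]
        se = np.hypot(npcd.effects_.ses[:, 0], incpcd.effects_.ses[:, 0])
        assert np.all(np.abs(te_n - te_i) < 3 * se)
        assert np.all(np.abs(te_i) < 3 * incpcd.effects_.ses[:, 0] + 0.02)
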