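"""Unit and property tests for the belief model primitives."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

import intentgrid as ig
from intentgrid.core_model import CHANCE_LOGLIK, LOG_FLOOR, N_CELLS

from oracle_model import oracle_bayes_update, oracle_policy, oracle_prior


class TestSharpenedBinomial:
    def test_unit_exponent_is_plain_binomial(self):
        got = ig.sharpened_binomial(0.5, 1.0, 8)
        expected = binom.pmf(np.arange(9), 8, 0.5)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got[4] == pytest.approx(70 / 256, abs=1e-12)

    @pytest.mark.parametrize("u", [0.25, 0.475, 1.0, 2.275, 5.0])
    @pytest.mark.parametrize("p", [0.05, 0.5, 0.95])
    def test_mode_preserved_for_positive_exponent(self, p, u):
        sharpened = ig.sharpened_binomial(p, u, 8)
        plain = binom.pmf(np.arange(9), 8, p)
        assert sharpened.argmax() == plain.argmax()

    def test_zero_exponent_flattens_to_uniform(self):
        np.testing.assert_allclose(ig.sharpened_binomial(0.5, 0.0, 8), np.full(9, 1 / 9))

    def test_sharpening_and_blunting_change_entropy(self):
        def entropy(p):
            return -(p * np.log(p)).sum()

        plain = ig.sharpened_binomial(0.3, 1.0, 8)
        assert entropy(ig.sharpened_binomial(0.3, 3.0, 8)) < entropy(plain)
        assert entropy(ig.sharpened_binomial(0.3, 0.4, 8)) > entropy(plain)

    @pytest.mark.parametrize("p,u", [(0.0, 1.0), (1.0, 1.0), (-0.1, 1.0), (0.5, -1.0)])
    def test_domain_errors(self, p, u):
        with pytest.raises(ValueError):
            ig.sharpened_binomial(p, u, 8)


class TestPrior:
    def test_unit_uncertainty_is_outer_product_of_binomials(self):
        params = ig.ParticipantParams(0.5, 1.0, 0.5, 1.0, 1.0, 0.0)
        grid = ig.build_prior(params)
        pmf = binom.pmf(np.arange(9), 8, 0.5)
        np.testing.assert_allclose(grid.probs, np.outer(pmf, pmf), atol=1e-12)

    def test_huge_uncertainty_tends_to_uniform(self):
        params = ig.ParticipantParams(0.5, 1e8, 0.5, 1e8, 1.0, 0.0)
        np.testing.assert_allclose(ig.build_prior(params).probs, np.full((9, 9), 1 / 81), atol=1e-6)

    def test_lower_uncertainty_gives_sharper_marginal(self):
        def hi_entropy(u):
            params = ig.ParticipantParams(0.9, u, 0.5, 1.0, 1.0, 0.0)
            m = ig.build_prior(params).hi_marginal
            m = m[m > 0]
            return -(m * np.log(m)).sum()

        assert hi_entropy(0.5) < hi_entropy(2.0)

    def test_zero_uncertainty_rejected(self):
        with pytest.raises(ValueError):
            ig.ParticipantParams(0.5, 0.0, 0.5, 1.0, 1.0, 0.0)


class TestPolicyTemplate:
    def test_constants(self):
        c = ig.PolicyConstants()
        assert c.delta_p == pytest.approx(0.1125, abs=1e-15)
        assert c.xi == pytest.approx(0.02 / 81, abs=1e-18)

    def test_minimum_exponent_positive(self):
        c = ig.PolicyConstants()
        assert c.u_init - 2 * c.delta_p * 9 == pytest.approx(0.475)

    def test_extreme_cells_peak_at_expected_returns(self, template):
        assert template.row(0, 0).argmax() + 1 == 9  # altruistic: give 100%
        assert template.row(8, 8).argmax() + 1 == 1  # antisocial: give 0%

    def test_rows_are_normalised(self, template):
        np.testing.assert_allclose(template.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_template_matches_oracle(self, template):
        pol = oracle_policy(1.0)  # oracle folds in u_pi=1 + lapse
        got = ig.apply_policy_uncertainty(template, 1.0)
        np.testing.assert_allclose(got.probs.reshape(81, 9), pol, atol=1e-12)


class TestPolicyUncertainty:
    def test_unit_u_pi_preserves_template_up_to_lapse(self, template):
        got = ig.apply_policy_uncertainty(template, 1.0)
        expected = template.probs + ig.PolicyConstants().xi
        expected /= expected.sum(axis=2, keepdims=True)
        np.testing.assert_allclose(got.probs, expected, atol=1e-12)

    def test_large_u_pi_tends_to_uniform(self, template):
        got = ig.apply_policy_uncertainty(template, 1e8)
        np.testing.assert_allclose(got.probs, np.full((9, 9, 9), 1 / 9), atol=1e-6)

    def test_entropy_increases_with_u_pi(self, template):
        def row_entropy(u_pi):
            row = ig.apply_policy_uncertainty(template, u_pi).row(8, 8)
            return -(row * np.log(row)).sum()

        assert row_entropy(2.0) > row_entropy(1.0)

    def test_rows_bounded_below_by_lapse_floor(self, template):
        got = ig.apply_policy_uncertainty(template, 1.0)
        # after renormalisation every entry keeps at least a share of xi
        assert got.probs.min() >= ig.PolicyConstants().xi / (1 + 9 * ig.PolicyConstants().xi) * 0.99

    def test_invalid_inputs(self, template):
        with pytest.raises(ValueError):
            ig.apply_policy_uncertainty(template, 0.0)
        applied = ig.apply_policy_uncertainty(template, 1.0)
        with pytest.raises(ValueError):
            ig.apply_policy_uncertainty(applied, 1.0)


class TestBayesUpdate:
    def test_flat_prior_posterior_proportional_to_likelihood(self, policy_u1):
        post = ig.bayes_update(ig.BeliefGrid.uniform(), 3, policy_u1)
        slice_ = policy_u1.return_slice(3)
        np.testing.assert_allclose(post.probs, slice_ / slice_.sum(), atol=1e-12)

    def test_take_all_raises_mean_harmful_intent(self, policy_u1):
        post = ig.bayes_update(ig.BeliefGrid.uniform(), 1, policy_u1)
        assert post.mean_hi() > 4.0

    def test_give_all_lowers_mean_harmful_intent(self, policy_u1):
        post = ig.bayes_update(ig.BeliefGrid.uniform(), 9, policy_u1)
        assert post.mean_hi() < 4.0

    def test_matches_brute_force_oracle(self, policy_u1):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = rng.random((9, 9))
            prior = ig.BeliefGrid(w / w.sum())
            r = int(rng.integers(1, 10))
            got = ig.bayes_update(prior, r, policy_u1)
            expected = oracle_bayes_update(prior.probs.ravel(), r, oracle_policy(1.0))
            np.testing.assert_allclose(got.probs.ravel(), expected, atol=1e-12)

    def test_requires_uncertainty_applied(self, template):
        with pytest.raises(ValueError):
            ig.bayes_update(ig.BeliefGrid.uniform(), 1, template)

    def test_extreme_observation_monotonicity(self, template):
        """r=1 never lowers, and r=9 never raises, the posterior mean HI."""
        policy = ig.apply_policy_uncertainty(template, 1.0)
        rng = np.random.default_rng(3)
        for _ in range(30):
            w = rng.random((9, 9)) ** 2
            prior = ig.BeliefGrid(w / w.sum())
            assert ig.bayes_update(prior, 1, policy).mean_hi() >= prior.mean_hi() - 1e-10
            assert ig.bayes_update(prior, 9, policy).mean_hi() <= prior.mean_hi() + 1e-10

    def test_posterior_prior_kl_decreases_with_u_pi(self, template):
        prior = ig.BeliefGrid.uniform()
        kls = []
        for u_pi in [0.5, 1.0, 2.0, 4.0, 8.0]:
            policy = ig.apply_policy_uncertainty(template, u_pi)
            post = ig.bayes_update(prior, 1, policy)
            kls.append((post.probs * np.log(post.probs / prior.probs)).sum())
        assert all(a >= b - 1e-12 for a, b in zip(kls, kls[1:]))


class TestCarryOver:
    @given(st.floats(0.0, 1.0))
    def test_mixture_identity(self, eta):
        rng = np.random.default_rng(4)
        a = rng.random((9, 9))
        b = rng.random((9, 9))
        pa = ig.BeliefGrid(a / a.sum())
        pb = ig.BeliefGrid(b / b.sum())
        mixed = ig.carry_over_prior(pa, pb, eta)
        np.testing.assert_allclose(
            mixed.probs, (1 - eta) * pa.probs + eta * pb.probs, atol=1e-12
        )
        assert mixed.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_endpoints(self, policy_u1):
        pa = ig.BeliefGrid.uniform()
        pb = ig.bayes_update(pa, 1, policy_u1)
        np.testing.assert_array_equal(ig.carry_over_prior(pa, pb, 0.0).probs, pa.probs)
        np.testing.assert_array_equal(ig.carry_over_prior(pa, pb, 1.0).probs, pb.probs)

    def test_eta_out_of_range(self):
        pa = ig.BeliefGrid.uniform()
        with pytest.raises(ValueError):
            ig.carry_over_prior(pa, pa, 1.2)


class TestRatingBins:
    @pytest.mark.parametrize("rating,expected", [(50, 4), (1, 0), (100, 8), (11, 0), (12, 1)])
    def test_rating_to_bin(self, rating, expected):
        assert ig.rating_to_bin(rating) == expected

    @given(st.integers(1, 100))
    def test_bin_in_range(self, rating):
        assert 0 <= ig.rating_to_bin(rating) <= 8

    @pytest.mark.parametrize("index", range(9))
    def test_round_trip_through_bin_centres(self, index):
        assert ig.rating_to_bin(ig.bin_to_rating(index)) == index

    @pytest.mark.parametrize("rating", [0, 101, -5])
    def test_out_of_range(self, rating):
        with pytest.raises(ValueError):
            ig.rating_to_bin(rating)


class TestTrialLoglik:
    def test_uniform_belief_is_chance_floor(self):
        ll = ig.trial_loglik(ig.BeliefGrid.uniform(), 4, 4)
        assert ll == pytest.approx(math.log(1 / 81), abs=1e-12)
        assert ll == pytest.approx(-4.394, abs=5e-4)

    def test_point_mass_scores_zero(self):
        probs = np.zeros((9, 9))
        probs[2, 7] = 1.0
        assert ig.trial_loglik(ig.BeliefGrid(probs), 2, 7) == pytest.approx(0.0)

    def test_quarter_mass(self):
        probs = np.full((9, 9), 0.75 / 80)
        probs[3, 3] = 0.25
        assert ig.trial_loglik(ig.BeliefGrid(probs), 3, 3) == pytest.approx(math.log(0.25))

    def test_floor_applied_to_zero_cells(self):
        probs = np.zeros((9, 9))
        probs[0, 0] = 1.0
        assert ig.trial_loglik(ig.BeliefGrid(probs), 8, 8) == pytest.approx(LOG_FLOOR)


class TestSessionLoglik:
    def test_uninformative_parameters_hit_chance_total(self, example_session):
        flat = ig.ParticipantParams(0.5, 1e8, 0.5, 1e8, 1e8, 0.0)
        total, per_trial = ig.session_loglik(flat, example_session)
        assert total == pytest.approx(18 * CHANCE_LOGLIK, abs=1e-4)
        np.testing.assert_allclose(per_trial, CHANCE_LOGLIK, atol=1e-5)

    def test_eta_does_not_affect_first_block(self, example_session):
        base = dict(pHI0=0.6, uHI0=0.8, pSI0=0.4, uSI0=1.2, u_pi=1.0)
        _, lo = ig.session_loglik(ig.ParticipantParams(**base, eta=0.0), example_session)
        _, hi = ig.session_loglik(ig.ParticipantParams(**base, eta=1.0), example_session)
        np.testing.assert_array_equal(lo[:6], hi[:6])
        assert not np.array_equal(lo[6:], hi[6:])

    @pytest.mark.parametrize("pre_update", [False, True])
    def test_matches_step_by_step_oracle(
        self, pre_update, random_session_factory
    ):
        from oracle_model import oracle_session_loglik

        rng = np.random.default_rng(5)
        for _ in range(10):
            params, session = random_session_factory(rng)
            total, per_trial = ig.session_loglik(
                params, session, score_pre_update=pre_update
            )
            expected = oracle_session_loglik(
                {k: getattr(params, k) for k in ig.PARAM_NAMES},
                session.returns,
                session.hi_ratings,
                session.si_ratings,
                pre_update=pre_update,
            )
            np.testing.assert_allclose(per_trial, expected, atol=1e-12)
            assert total == pytest.approx(expected.sum(), abs=1e-10)


class TestInvariants:
    def test_beliefs_normalised_after_every_operation(self, example_params, policy_u1):
        grid = ig.build_prior(example_params)
        assert grid.probs.sum() == pytest.approx(1.0, abs=1e-9)
        for r in (1, 5, 9):
            grid = ig.bayes_update(grid, r, policy_u1)
            assert grid.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_session_data_validation(self):
        with pytest.raises(ValueError):
            ig.SessionData(
                participant_id="x",
                gpts=20,  # below GPTS floor of 32
                dictator_types=("fair", "unfair", "partially_fair"),
                returns=np.ones(18, int),
                hi_ratings=np.full(18, 50),
                si_ratings=np.full(18, 50),
            )
        with pytest.raises(ValueError):
            ig.SessionData(
                participant_id="x",
                gpts=50,
                dictator_types=("fair", "unfair", "partially_fair"),
                returns=np.ones(17, int),
                hi_ratings=np.full(17, 50),
                si_ratings=np.full(17, 50),
            )
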