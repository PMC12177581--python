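"""EEF model math: utility, state updates, softmax, first-choice prior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igtrl import (
    EEFAgent,
    EEFParams,
    TrialOutcome,
    choice_probabilities,
    consistency,
    default_first_choice_prior,
    derive_first_choice_prior,
    init_state,
    update_state,
    utility,
)
from conftest import make_eef_agent


class TestUtility:
    @pytest.mark.parametrize(
        "gain,loss,theta,la,expected",
        [
            (100, 0, 0.5, 1.0, 1.0),
            (100, 250, 0.5, 1.0, 1.0 - 2.5**0.5),
            (50, 50, 1.0, 2.0, -0.5),
            (0, 0, 0.7, 1.0, 0.0),
            (0, 0, 0.0, 1.0, 0.0),  # 0**0 edge defined as 0
        ],
    )
    def test_values(self, gain, loss, theta, la, expected):
        assert utility(gain, loss, theta, la) == pytest.approx(expected, abs=1e-12)

    def test_negative_amounts_rejected(self):
        with pytest.raises(ValueError):
            utility(-1, 0, 0.5)

    @given(gain=st.floats(0, 2000), theta=st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_gain_only_is_nonnegative(self, gain, theta):
        assert utility(gain, 0.0, theta) >= 0.0


class TestConsistency:
    @pytest.mark.parametrize("beta,c", [(0, 0), (3, 26), (5, 242)])
    def test_transform(self, beta, c):
        assert consistency(beta) == pytest.approx(c)

    def test_bounds(self):
        with pytest.raises(ValueError):
            consistency(5.1)


class TestStateUpdates:
    def test_init_with_prior(self):
        st_ = init_state(default_first_choice_prior())
        assert np.allclose(st_.exploitation, [0.0184, 0.0020, -0.0050, -0.0155], atol=5e-4)
        assert np.all(st_.exploration == 0)

    def test_init_without_prior(self):
        st_ = init_state(None)
        assert np.all(st_.exploitation == 0) and np.all(st_.exploration == 0)

    def test_hand_stepped_two_trials(self):
        # lam=0.5, theta=0.5, phi=2, zero start; A pays 100/0 then 100/250
        p = EEFParams(lam=0.5, theta=0.5, phi=2.0, beta=1.0)
        s0 = init_state(None)
        s1 = update_state(s0, 1, TrialOutcome(100, 0), p)
        assert np.allclose(s1.exploitation, [1, 0, 0, 0])
        assert np.allclose(s1.exploration, [0, 1, 1, 1])
        s2 = update_state(s1, 1, TrialOutcome(100, 250), p)
        assert s2.exploitation[0] == pytest.approx(0.5 + (1 - 2.5**0.5))
        assert np.allclose(s2.exploration[1:], 1.5)
        assert s2.exploration[0] == 0.0

    def test_input_state_not_mutated(self):
        p = EEFParams(lam=0.3, theta=0.5, phi=1.0, beta=1.0)
        s0 = init_state(default_first_choice_prior())
        before = s0.exploitation.copy()
        update_state(s0, 2, TrialOutcome(100, 0), p)
        assert np.array_equal(s0.exploitation, before)

    def test_chosen_deck_exploration_resets(self):
        p = EEFParams(lam=0.2, theta=0.5, phi=3.0, beta=1.0)
        s = init_state(None)
        for choice in [1, 2, 3, 1, 4]:
            s = update_state(s, choice, TrialOutcome(50, 0), p)
            assert s.exploration[choice - 1] == 0.0

    def test_full_forgetting_freezes_exploration(self):
        p = EEFParams(lam=1.0, theta=0.5, phi=4.0, beta=1.0)
        s = init_state(default_first_choice_prior())
        for choice in [1, 2, 1, 3]:
            s = update_state(s, choice, TrialOutcome(100, 150), p)
            assert np.all(s.exploration == 0)
        # chosen exploitation equals last utility only; unchosen are zero
        assert s.exploitation[2] == pytest.approx(utility(100, 150, 0.5))
        assert np.allclose(np.delete(s.exploitation, 2), 0)

    def test_exploration_fixed_point_approach(self):
        # |e_t - phi| = lam**t * |e_0 - phi| for a never-chosen deck
        lam, phi = 0.7, 3.0
        p = EEFParams(lam=lam, theta=0.5, phi=phi, beta=1.0)
        s = init_state(None)
        for t in range(1, 15):
            s = update_state(s, 1, TrialOutcome(100, 0), p)
            assert abs(s.exploration[3] - phi) == pytest.approx(lam**t * phi, rel=1e-12)

    def test_prior_decays_geometrically(self):
        lam = 0.4
        p = EEFParams(lam=lam, theta=0.5, phi=0.0, beta=1.0)
        prior = default_first_choice_prior()
        s = init_state(prior)
        for t in range(1, 6):
            s = update_state(s, 1, TrialOutcome(0.0, 0.0), p)  # no reinforcement value
            assert s.exploitation[3] == pytest.approx((1 - lam) ** t * prior.w_ini[3])

    def test_invalid_choice_rejected(self):
        p = EEFParams(lam=0.5, theta=0.5, phi=0.0, beta=1.0)
        with pytest.raises(ValueError):
            update_state(init_state(None), 0, TrialOutcome(100, 0), p)


class TestChoiceProbabilities:
    def test_zero_consistency_uniform(self):
        s = init_state(default_first_choice_prior())
        assert np.allclose(choice_probabilities(s, 0.0), 0.25)

    def test_symmetric_state_uniform(self):
        s = init_state(None)
        assert np.allclose(choice_probabilities(s, 50.0), 0.25)

    def test_prior_round_trip_frequencies(self):
        s = init_state(default_first_choice_prior())
        p = choice_probabilities(s, consistency(3.0))
        assert np.allclose(p, [0.3829, 0.2500, 0.2083, 0.1587], atol=5e-4)

    def test_sums_to_one_under_extreme_weights(self):
        from igtrl.eef import LatentState

        s = LatentState(exploitation=np.array([500.0, -500.0, 0.0, 0.0]),
                        exploration=np.zeros(4))
        p = choice_probabilities(s, 242.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)


class TestFirstChoicePrior:
    def test_published_counts(self):
        pw = derive_first_choice_prior((193, 126, 105, 80), beta=3.0)
        assert np.allclose(pw.w_ini, [0.0184, 0.0020, -0.0050, -0.0155], atol=5e-4)
        assert pw.w_ini.mean() == pytest.approx(0.0, abs=1e-9)

    def test_equal_counts_give_zero_weights(self):
        pw = derive_first_choice_prior((10, 10, 10, 10), beta=3.0)
        assert np.allclose(pw.w_ini, 0.0)

    @given(counts=st.tuples(*[st.integers(1, 500)] * 4),
           beta=st.floats(0.5, 5.0))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_inverts_softmax(self, counts, beta):
        pw = derive_first_choice_prior(counts, beta=beta)
        p = choice_probabilities(init_state(pw), consistency(beta))
        expected = np.asarray(counts) / sum(counts)
        assert np.allclose(p, expected, atol=1e-9)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            derive_first_choice_prior((0, 1, 1, 1))

    def test_beta_zero_rejected(self):
        with pytest.raises(ValueError):
            derive_first_choice_prior((1, 1, 1, 1), beta=0.0)


class TestDegeneracyProperties:
    def test_lam_one_depends_only_on_last_trial(self):
        """At full forgetting, two histories sharing only the final trial
        yield identical next-trial choice probabilities."""
        params = dict(lam=1.0, theta=0.6, phi=2.5, beta=2.0)
        hist_a = [(1, 100, 0), (2, 100, 1250), (3, 50, 0)]
        hist_b = [(4, 50, 250), (3, 50, 50)]
        probs = []
        for hist in (hist_a, hist_b):
            agent = make_eef_agent(**params)
            for deck, g, l in hist[:-1]:
                agent.update(deck, g, l)
            agent.update(3, 50, 0)  # shared final trial
            probs.append(agent.choice_probabilities())
        assert np.allclose(probs[0], probs[1], atol=1e-15)

    def test_eefla_with_unit_loss_aversion_matches_eef(self, scheme):
        from igtrl import simulate_session

        eef = make_eef_agent(lam=0.4, theta=0.5, phi=1.5, beta=2.0, la=1.0)
        ref = simulate_session(eef, scheme, n_trials=50, seed=13)
        eef.reset()
        eefla = EEFAgent(EEFParams(lam=0.4, theta=0.5, phi=1.5, beta=2.0, la=1.0))
        for t in range(ref.n_trials):
            pa = eef.choice_probabilities()
            pb = eefla.choice_probabilities()
            assert np.array_equal(pa, pb)
            eef.update(int(ref.choices[t]), float(ref.gains[t]), float(ref.losses[t]))
            eefla.update(int(ref.choices[t]), float(ref.gains[t]), float(ref.losses[t]))


class TestParamBounds:
    @pytest.mark.parametrize("kwargs", [
        dict(lam=-0.1, theta=0.5, phi=0.0, beta=1.0),
        dict(lam=0.5, theta=1.1, phi=0.0, beta=1.0),
        dict(lam=0.5, theta=0.5, phi=5.5, beta=1.0),
        dict(lam=0.5, theta=0.5, phi=0.0, beta=6.0),
        dict(lam=0.5, theta=0.5, phi=0.0, beta=1.0, la=-1.0),
    ])
    def test_out_of_bounds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EEFParams(**kwargs)
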