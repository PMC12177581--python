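"""Likelihood, fitting, information criteria, free energy, and model
comparison machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from igtrl import (
    FitConfig,
    Session,
    fit_mle,
    fixed_effects_table,
    information_criteria,
    laplace_free_energy,
    negative_log_likelihood,
    random_effects_bms,
    simulate_session,
)
from igtrl.inference import FitResult, fits_to_frame, nll_agent_route
from conftest import make_eef_agent


class TestNLL:
    def test_uniform_choice_likelihood(self):
        s = Session("u", np.ones(100, dtype=int), np.full(100, 100.0), np.zeros(100))
        nll = negative_log_likelihood("EEF", {"lam": 0.5, "theta": 0.5, "phi": 1.0, "beta": 0.0}, s)
        assert nll == pytest.approx(100 * math.log(4), abs=1e-9)

    def test_first_trial_under_prior(self):
        s = Session("one", [1], [100.0], [0.0])
        nll = negative_log_likelihood("EEF", {"lam": 0.5, "theta": 0.5, "phi": 0.0, "beta": 3.0}, s)
        assert nll == pytest.approx(-math.log(0.3829), abs=1e-3)

    def test_matches_agent_route(self, small_eef_cohort):
        cohort, truth = small_eef_cohort
        params = {"lam": 0.3, "theta": 0.7, "phi": -1.0, "beta": 1.5}
        for s in cohort:
            assert negative_log_likelihood("EEF", params, s) == pytest.approx(
                nll_agent_route("EEF", params, s), abs=1e-10
            )


class TestInformationCriteria:
    def test_printed_formulas(self):
        aic, bic = information_criteria(120.0, 4, 100)
        assert aic == pytest.approx(248.0)
        assert bic == pytest.approx(4 * math.log(100) + 240.0)
        assert bic == pytest.approx(258.42, abs=0.01)

    def test_zero_parameters(self):
        aic, bic = information_criteria(50.0, 0, 10)
        assert aic == bic == 100.0

    def test_linearity_in_k(self):
        a1, b1 = information_criteria(100.0, 3, 100)
        a2, b2 = information_criteria(100.0, 6, 100)
        assert a2 - a1 == pytest.approx(2 * 3)
        assert b2 - b1 == pytest.approx(3 * math.log(100))

    def test_fitresult_identities(self):
        f = FitResult("EEF", "s", {"lam": 0.5}, nll=80.0, k=4, n=100)
        assert f.aic == pytest.approx(2 * 4 + 160.0)
        assert f.bic == pytest.approx(4 * math.log(100) + 160.0)
        f.free_energy = -90.0
        assert f.minus2f == 180.0


class TestFitMLE:
    def test_determinism(self, small_eef_cohort):
        cohort, _ = small_eef_cohort
        cfg = FitConfig(n_starts=3, seed=5)
        f1 = fit_mle("EEF", cohort[0], cfg)
        f2 = fit_mle("EEF", cohort[0], cfg)
        assert f1.params == f2.params and f1.nll == f2.nll

    def test_more_starts_never_worse(self, small_eef_cohort):
        cohort, _ = small_eef_cohort
        n1 = fit_mle("EEF", cohort[1], FitConfig(n_starts=1, seed=9)).nll
        n10 = fit_mle("EEF", cohort[1], FitConfig(n_starts=10, seed=9)).nll
        assert n10 <= n1 + 1e-9

    def test_beats_generating_parameters_on_strong_signal(self, scheme):
        agent = make_eef_agent(lam=0.2, theta=0.8, phi=0.5, beta=5.0)
        s = simulate_session(agent, scheme, n_trials=100, seed=3)
        gen = {"lam": 0.2, "theta": 0.8, "phi": 0.5, "beta": 5.0}
        fit = fit_mle("EEF", s, FitConfig(n_starts=10, seed=1))
        assert fit.nll <= negative_log_likelihood("EEF", gen, s) + 1e-3
        assert fit.n == 100 and fit.k == 4

    def test_fit_frame_round_trip(self, small_eef_cohort):
        cohort, _ = small_eef_cohort
        fit = fit_mle("EV", cohort[0], FitConfig(n_starts=2, seed=0))
        frame = fits_to_frame([fit])
        assert frame.loc[0, "model"] == "EV"
        assert frame.loc[0, "param_w"] == pytest.approx(fit.params["w"])


class TestLaplaceFreeEnergy:
    def test_components_sum_and_bic_proximity(self, scheme):
        agent = make_eef_agent(lam=0.3, theta=0.6, phi=1.0, beta=2.5)
        s = simulate_session(agent, scheme, n_trials=100, seed=8)
        fit = fit_mle("EEF", s, FitConfig(n_starts=8, seed=2))
        F, br, fallback = laplace_free_energy("EEF", s, fit)
        assert br.total == pytest.approx(F, abs=1e-9)
        # the Laplace evidence and -BIC/2 agree to O(1) at n=100
        assert abs(-2 * F - fit.bic) < 15.0

    def test_occam_penalty_present(self, scheme):
        agent = make_eef_agent(lam=0.3, theta=0.6, phi=1.0, beta=2.5)
        s = simulate_session(agent, scheme, n_trials=100, seed=8)
        fit = fit_mle("EEF", s, FitConfig(n_starts=8, seed=2))
        F, br, _ = laplace_free_energy("EEF", s, fit)
        # evidence is below the best-fit log-likelihood: complexity costs
        assert F < -fit.nll

    def test_determinism(self, scheme):
        agent = make_eef_agent(lam=0.5, theta=0.5, phi=0.0, beta=2.0)
        s = simulate_session(agent, scheme, n_trials=60, seed=4)
        fit = fit_mle("EEF", s, FitConfig(n_starts=4, seed=7))
        F1, _, _ = laplace_free_energy("EEF", s, fit)
        F2, _, _ = laplace_free_energy("EEF", s, fit)
        assert F1 == F2


class TestFixedEffects:
    def _fits(self, model, nlls, k=4, n=100):
        return [FitResult(model, f"s{i}", {}, nll=v, k=k, n=n) for i, v in enumerate(nlls)]

    def test_reference_deltas_zero(self):
        fits = {"EEF": self._fits("EEF", [100.0] * 10), "EV": self._fits("EV", [101.0] * 10, k=3)}
        table = fixed_effects_table(fits, reference="EEF")
        assert table.loc["EEF", "delta_aic"] == 0.0
        assert table.loc["EEF", "delta_bic"] == 0.0

    def test_identical_models_zero_delta(self):
        fits = {"EEF": self._fits("EEF", [100.0] * 5), "M": self._fits("M", [100.0] * 5)}
        table = fixed_effects_table(fits, reference="EEF")
        assert table.loc["M", "delta_aic"] == 0.0

    def test_per_session_offset_accumulates(self):
        # AIC exactly 2 higher per session on 10 sessions -> delta 20
        fits = {"EEF": self._fits("EEF", [100.0] * 10),
                "M": self._fits("M", [101.0] * 10)}
        table = fixed_effects_table(fits, reference="EEF")
        assert table.loc["M", "delta_aic"] == pytest.approx(20.0)

    def test_incomplete_grid_rejected(self):
        fits = {"EEF": self._fits("EEF", [100.0] * 5), "EV": self._fits("EV", [100.0] * 4)}
        with pytest.raises(ValueError, match="incomplete"):
            fixed_effects_table(fits, reference="EEF")


class TestBMS:
    def test_identical_evidence_uniform_frequencies(self):
        E = np.zeros((20, 4))
        res = random_effects_bms(E)
        assert np.allclose(res.expected_frequencies, 0.25, atol=1e-6)

    def test_dominant_model_wins(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(50, 2))
        E[:, 0] += 20.0  # model 0 ahead by >= 20 log-units everywhere
        res = random_effects_bms(E, model_names=["good", "bad"])
        assert res.best_model() == "good"
        assert res.expected_frequencies[0] > 0.95

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        E = rng.normal(size=(30, 3))
        res = random_effects_bms(E)
        perm = [2, 0, 1]
        res_p = random_effects_bms(E[:, perm])
        assert np.allclose(res_p.expected_frequencies, res.expected_frequencies[perm], atol=1e-8)

    def test_per_session_constant_shift_invariance(self):
        rng = np.random.default_rng(2)
        E = rng.normal(size=(25, 3))
        shifted = E + rng.normal(size=(25, 1))  # constant per session
        a = random_effects_bms(E).expected_frequencies
        b = random_effects_bms(shifted).expected_frequencies
        assert np.allclose(a, b, atol=1e-6)

    def test_dataframe_input_keeps_names(self):
        df = pd.DataFrame({"EEF": [0.0, 1.0], "EV": [-5.0, -4.0]})
        res = random_effects_bms(df)
        assert res.model_names == ("EEF", "EV")
        assert res.expected_frequencies.sum() == pytest.approx(1.0)

    def test_nonfinite_evidence_rejected(self):
        with pytest.raises(ValueError):
            random_effects_bms(np.array([[0.0, np.inf]]))
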