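"""Monte-Carlo response probabilities, log-likelihood, and fitting."""

import math

import numpy as np
import pytest

import triconf as tc
from triconf.likelihood import LikelihoodEngine, response_table


def quadrature_table(s, config, sigma, criteria, rule, n_grid=4001, span=8.0):
    """Independent oracle: numerically integrate the (noise-free-decision)
    response distribution over the 1-D measurement density.

    Valid for collinear configurations (all category means on one horizontal
    line) with alpha = inf and lapse = 0: the vertical measurement component
    cancels from the posterior, so the response at measurement x is a
    deterministic function of its horizontal coordinate.
    """
    assert np.all(config.means[:, 1] == 0.0)
    var = config.category_sd**2 + sigma**2
    if sigma == 0:
        xs = np.array([s[0]])
        w = np.array([1.0])
    else:
        xs = np.linspace(s[0] - span * sigma, s[0] + span * sigma, n_grid)
        w = np.exp(-((xs - s[0]) ** 2) / (2 * sigma**2))
        w /= w.sum()
    table = np.zeros((3, 4))
    mx = config.means[:, 0]
    for x, weight in zip(xs, w):
        logp = -((x - mx) ** 2) / (2 * var)
        p = np.exp(logp - logp.max())
        p /= p.sum()
        chosen = int(np.argmax(p))
        order = np.sort(p)[::-1]
        if rule == "max":
            c = order[0]
        elif rule == "difference":
            c = order[0] - order[1]
        elif rule == "entropy":
            c = float(np.sum(p * np.log(p)))
        else:
            c = order[0] / (order[0] + order[1])
        rating = int(np.sum(c > np.asarray(criteria)))
        table[chosen, rating] += weight
    return table


class TestResponseDistribution:
    def test_table_normalization_and_floor(self, exp1_config, difference_params):
        rd = tc.response_distribution(
            np.array([0.5, 0.0]), exp1_config, difference_params, n_mc=2000, seed=3
        )
        assert rd.table.sum() == pytest.approx(1.0, abs=1e-12)
        assert rd.table.min() >= difference_params.lapse / 12 - 1e-15

    def test_pure_lapse_gives_uniform_table(self, exp1_config):
        params = tc.ObserverParams(0.5, 30.0, (0.2, 0.4, 0.7), 1.0, rule="difference")
        rd = tc.response_distribution(np.zeros(2), exp1_config, params, n_mc=500, seed=0)
        assert np.allclose(rd.table, 1 / 12, atol=1e-12)

    def test_fixed_seed_reproducible(self, exp1_config, difference_params):
        a = tc.response_distribution(np.zeros(2), exp1_config, difference_params, 2000, seed=9)
        b = tc.response_distribution(np.zeros(2), exp1_config, difference_params, 2000, seed=9)
        assert np.array_equal(a.table, b.table)

    def test_invalid_n_mc_rejected(self, exp1_config, difference_params):
        with pytest.raises(ValueError):
            tc.response_distribution(np.zeros(2), exp1_config, difference_params, n_mc=0)

    @pytest.mark.parametrize("rule", ["max", "difference"])
    def test_matches_quadrature_oracle_without_decision_noise(self, exp1_config, rule):
        sigma, criteria = 0.6, (0.3, 0.5, 0.8) if rule == "max" else (0.2, 0.4, 0.7)
        params = tc.ObserverParams(
            sigma, np.inf, criteria, 0.0, rule=rule, noise_variant="sensory"
        )
        s = np.array([1.1, 0.0])
        n_mc = 100_000
        rd = tc.response_distribution(s, exp1_config, params, n_mc=n_mc, seed=5)
        oracle = quadrature_table(s, exp1_config, sigma, criteria, rule)
        se = np.sqrt(oracle * (1 - oracle) / n_mc)
        assert np.all(np.abs(rd.table - oracle) <= 3 * se + 1e-9)

    def test_mc_convergence_between_sizes(self, exp1_config, difference_params):
        small = tc.response_distribution(
            np.array([0.3, 0.0]), exp1_config, difference_params, n_mc=10_000, seed=2
        ).table
        big = tc.response_distribution(
            np.array([0.3, 0.0]), exp1_config, difference_params, n_mc=100_000, seed=2
        ).table
        tol = 4 * np.sqrt(np.maximum(big * (1 - big), 1e-6) / 10_000)
        assert np.all(np.abs(small - big) <= tol)


class TestLogLikelihood:
    def test_single_lapse_trial(self, exp1_config):
        import pandas as pd

        trials = pd.DataFrame(
            {"config": [1], "target_x": [0.0], "target_y": [0.0],
             "response_category": [2], "confidence": [3]}
        )
        ds = tc.Dataset("s1", 1, trials)
        params = tc.ObserverParams(0.5, 30.0, (0.2, 0.4, 0.7), 1.0, rule="difference")
        ll = tc.log_likelihood(ds, params, n_mc=200, seed=0)
        assert ll == pytest.approx(math.log(1 / 12), abs=1e-9)

    def test_marginalization_bound(self, small_session, difference_params):
        joint = tc.log_likelihood(small_session, difference_params, "joint", 2000, 0)
        dec = tc.log_likelihood(small_session, difference_params, "decision_only", 2000, 0)
        conf = tc.log_likelihood(small_session, difference_params, "confidence_only", 2000, 0)
        assert joint <= dec + 1e-9
        assert joint <= conf + 1e-9

    def test_deterministic_given_seed(self, small_session, difference_params):
        a = tc.log_likelihood(small_session, difference_params, n_mc=1000, seed=4)
        b = tc.log_likelihood(small_session, difference_params, n_mc=1000, seed=4)
        assert a == b

    def test_true_parameters_beat_gross_perturbation(self, difference_params):
        wins = 0
        for rep in range(5):
            ds = tc.generate_session(1, difference_params, trials_per_config=126, seed=rep)
            ll_true = tc.log_likelihood(ds, difference_params, n_mc=1000, seed=0)
            ll_bad = tc.log_likelihood(
                ds, difference_params.replace(sigma=2 * difference_params.sigma + 0.5),
                n_mc=1000, seed=0,
            )
            wins += ll_true > ll_bad
        assert wins >= 4

    def test_empty_dataset_rejected(self, difference_params):
        import pandas as pd

        trials = pd.DataFrame(
            columns=["config", "target_x", "target_y", "response_category", "confidence"]
        )
        with pytest.raises(ValueError):
            ds = tc.Dataset("s1", 1, trials)
            tc.log_likelihood(ds, difference_params, n_mc=100)

    def test_finite_even_with_tiny_lapse(self, small_session, difference_params):
        params = difference_params.replace(lapse=1e-4)
        ll = tc.log_likelihood(small_session, params, n_mc=500, seed=0)
        assert np.isfinite(ll)


class TestFitting:
    def test_pure_lapse_data_recovers_high_lapse(self):
        params = tc.ObserverParams(0.5, 30.0, (0.2, 0.4, 0.7), 1.0, rule="difference")
        ds = tc.generate_session(1, params, trials_per_config=30, seed=1)
        res = tc.fit_subject(
            ds, rule="difference", n_mc=400, screen_n_mc=200,
            maxfev_profile=25, maxfev_criteria=20, maxfev_joint=0, seed=0,
        )
        assert res.params.lapse >= 0.9

    def test_k_bookkeeping(self, small_session):
        full = tc.ConfidenceModel(small_session, rule="max", noise_variant="both")
        sensory = tc.ConfidenceModel(small_session, rule="max", noise_variant="sensory")
        decision_only_mode = tc.ConfidenceModel(
            small_session, rule="max", noise_variant="both", mode="decision_only"
        )
        assert full.k == 6
        assert sensory.k == 5
        assert decision_only_mode.k == 3

    def test_nine_model_factorial_enumerable(self, small_session):
        models = [
            tc.ConfidenceModel(small_session, rule=r, noise_variant=v)
            for r in ("max", "difference", "entropy")
            for v in ("both", "sensory", "decision")
        ]
        assert len(models) == 9
        assert {m.k for m in models} == {5, 6}

    def test_results_object_carries_fit_metadata(self, small_session):
        res = tc.fit_subject(
            small_session, rule="difference", n_mc=300, screen_n_mc=150,
            n_screen=4, maxfev_profile=15, maxfev_criteria=10, maxfev_joint=0, seed=0,
        )
        assert res.nobs == 336
        assert res.k == 6
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.k)
        assert res.bic == pytest.approx(-2 * res.llf + res.k * math.log(336))
        assert "AIC" in res.summary()

    @pytest.mark.parametrize("mode", ["confidence_only", "decision_only"])
    def test_partial_response_modes_fit(self, small_session, mode):
        res = tc.fit_subject(
            small_session, rule="difference", mode=mode, n_mc=300, screen_n_mc=150,
            n_screen=3, restarts=1, maxfev_profile=12, maxfev_criteria=8,
            maxfev_joint=0, seed=0,
        )
        assert np.isfinite(res.llf)
        expected_k = 6 if mode == "confidence_only" else 3
        assert res.k == expected_k

    def test_from_dataframe_roundtrip(self, small_session):
        df = small_session.to_frame()
        model = tc.ConfidenceModel.from_dataframe(df, rule="max")
        assert model.nobs == len(small_session)
        assert model.dataset.experiment_id == 1
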