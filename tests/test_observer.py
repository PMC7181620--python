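"""Observer pipeline: posterior, Dirichlet noise, decision, confidence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import triconf as tc
from triconf.design import get_configuration
from triconf.observer import RULE_RANGES, RULES

from conftest import random_simplex


class TestComputePosterior:
    def test_center_point_noiseless(self, exp1_config):
        # direct evaluation: flankers get exp(-9/8) / (1 + 2 exp(-9/8))
        p = tc.compute_posterior(np.array([0.0, 0.0]), exp1_config, sigma=0.0)
        e = math.exp(-9.0 / 8.0)
        expected = np.array([e, 1.0, e]) / (1.0 + 2.0 * e)
        assert p == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx([0.1968, 0.6063, 0.1968], abs=5e-4)

    def test_equidistant_point_is_uniform(self):
        # circumcenter of the three category means sees all equally likely
        cfg = get_configuration(2, 1)
        (x1, y1), (x2, y2), (x3, y3) = cfg.means
        a = np.array([[2 * (x2 - x1), 2 * (y2 - y1)], [2 * (x3 - x2), 2 * (y3 - y2)]])
        b = np.array([x2**2 - x1**2 + y2**2 - y1**2, x3**2 - x2**2 + y3**2 - y2**2])
        center = np.linalg.solve(a, b)
        p = tc.compute_posterior(center, cfg, sigma=1.0)
        assert p == pytest.approx([1 / 3, 1 / 3, 1 / 3], abs=1e-10)

    def test_extreme_measurement_is_stable(self, exp1_config):
        p = tc.compute_posterior(np.array([-100.0, 0.0]), exp1_config, sigma=0.5)
        assert np.all(np.isfinite(p))
        assert p[0] == pytest.approx(1.0, abs=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_sensory_noise_broadens_posterior(self, exp1_config):
        x = np.array([1.0, 0.0])
        p0 = tc.compute_posterior(x, exp1_config, sigma=0.0)
        p2 = tc.compute_posterior(x, exp1_config, sigma=2.0)
        assert p2.max() < p0.max()  # larger total variance flattens beliefs

    def test_nonfinite_measurement_rejected(self, exp1_config):
        with pytest.raises(ValueError):
            tc.compute_posterior(np.array([np.nan, 0.0]), exp1_config, 0.5)


class TestNoisyPosterior:
    def test_infinite_alpha_is_identity(self, rng):
        p = np.array([0.5, 0.3, 0.2])
        q = tc.sample_noisy_posterior(p, np.inf, rng)
        assert np.array_equal(q, p)

    def test_mean_and_variance_match_dirichlet_moments(self, rng):
        p = np.array([0.5, 0.3, 0.2])
        alpha = 50.0
        q = tc.sample_noisy_posterior(np.tile(p, (100_000, 1)), alpha, rng)
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-12)
        se = np.sqrt(p * (1 - p) / (alpha + 1) / 1e5)
        assert np.all(np.abs(q.mean(axis=0) - p) < 3 * se)
        var_expected = p * (1 - p) / (alpha + 1)
        assert np.allclose(q.var(axis=0), var_expected, rtol=0.05)

    def test_invalid_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            tc.sample_noisy_posterior(np.array([0.5, 0.3, 0.2]), 0.0, rng)

    def test_degenerate_posterior_is_clamped_not_fatal(self, rng):
        q = tc.sample_noisy_posterior(np.tile([1.0, 0.0, 0.0], (1000, 1)), 20.0, rng)
        assert np.all(np.isfinite(q))
        assert q[:, 0].mean() > 0.99


class TestDecide:
    def test_argmax(self, rng):
        assert tc.decide(np.array([0.2, 0.5, 0.3]), rng) == 2
        assert tc.decide(np.array([0.999, 0.0005, 0.0005]), rng) == 1

    def test_ties_broken_uniformly(self, rng):
        q = np.tile([1 / 3, 1 / 3, 1 / 3], (9000, 1))
        picks = tc.decide(q, rng)
        freqs = np.bincount(picks, minlength=4)[1:] / 9000
        assert np.all(np.abs(freqs - 1 / 3) < 0.02)


class TestConfidenceVariable:
    def test_rule_definitions(self):
        q = np.array([0.6, 0.3, 0.1])
        assert tc.confidence_variable(q, 1, "max") == pytest.approx(0.6)
        assert tc.confidence_variable(q, 1, "difference") == pytest.approx(0.3)
        expected_entropy = sum(v * math.log(v) for v in q)
        assert tc.confidence_variable(q, 1, "entropy") == pytest.approx(expected_entropy)
        assert tc.confidence_variable(q, 1, "entropy") == pytest.approx(-0.8979, abs=5e-5)
        assert tc.confidence_variable(q, 1, "ratio") == pytest.approx(0.6 / 0.9)

    def test_uniform_posterior_floor(self):
        q = np.array([1 / 3, 1 / 3, 1 / 3])
        assert tc.confidence_variable(q, 1, "max") == pytest.approx(1 / 3)
        assert tc.confidence_variable(q, 1, "difference") == pytest.approx(0.0)
        assert tc.confidence_variable(q, 1, "entropy") == pytest.approx(-math.log(3))
        assert tc.confidence_variable(q, 1, "ratio") == pytest.approx(0.5)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            tc.confidence_variable(np.array([0.6, 0.3, 0.1]), 1, "magic")

    def test_ranges_on_random_simplex(self, rng):
        q = random_simplex(rng, 5000)
        chosen = tc.decide(q, rng)
        for rule in RULES:
            lo, hi = RULE_RANGES[rule]
            c = tc.confidence_variable(q, chosen, rule)
            assert np.all(c >= lo - 1e-12) and np.all(c <= hi + 1e-12)

    def test_vickers_averaging_identity(self, rng):
        # averaged balance of evidence ((A-B)+(A-C))/2 equals (3A-1)/2
        q = random_simplex(rng, 2000)
        a = q.max(axis=1)
        idx = q.argmax(axis=1)
        rest = q.copy()
        rest[np.arange(len(q)), idx] = np.nan
        b = np.nanmax(rest, axis=1)
        c = np.nansum(rest, axis=1) - b
        assert np.allclose(((a - b) + (a - c)) / 2, (3 * a - 1) / 2, atol=1e-12)

    def test_two_alternative_equivalence(self, rng):
        # with the third component pinned at zero, difference = 2*max - 1
        q2 = random_simplex(rng, 1000)[:, :2]
        q = np.column_stack([q2, np.zeros(len(q2))])
        q /= q.sum(axis=1, keepdims=True)
        chosen = tc.decide(q, rng)
        cmax = tc.confidence_variable(q, chosen, "max")
        cdiff = tc.confidence_variable(q, chosen, "difference")
        assert np.allclose(cdiff, 2 * cmax - 1, atol=1e-12)


class TestRateConfidence:
    def test_interval_membership(self):
        b = (0.4, 0.55, 0.8)
        assert tc.rate_confidence(0.5, b) == 2
        assert tc.rate_confidence(0.3, b) == 1
        assert tc.rate_confidence(0.95, b) == 4
        assert tc.rate_confidence(0.4, b) == 1  # boundary resolves downward

    def test_unordered_criteria_rejected(self):
        with pytest.raises(ValueError):
            tc.rate_confidence(0.5, (0.6, 0.5, 0.8))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=2))
    def test_monotone_in_confidence_variable(self, pair):
        b = (0.25, 0.5, 0.75)
        lo, hi = sorted(pair)
        assert tc.rate_confidence(lo, b) <= tc.rate_confidence(hi, b)


class TestSimulateResponse:
    def test_pure_lapse_is_uniform_over_cells(self, exp1_config, rng):
        params = tc.ObserverParams(
            sigma=0.5, alpha=30.0, criteria=(0.2, 0.4, 0.7), lapse=1.0, rule="difference"
        )
        s = np.zeros((30_000, 2))
        cat, rat = tc.simulate_responses(s, exp1_config, params, rng)
        cells = (cat - 1) * 4 + (rat - 1)
        freqs = np.bincount(cells, minlength=12) / len(cells)
        assert np.all(np.abs(freqs - 1 / 12) < 4 * np.sqrt((1 / 12) * (11 / 12) / len(cells)))

    def test_noiseless_limit_is_deterministic(self, exp1_config, rng):
        params = tc.ObserverParams(
            sigma=0.0, alpha=np.inf, criteria=(0.4, 0.6, 0.9), lapse=0.0, rule="max"
        )
        r = tc.simulate_response(np.array([-30.0, 0.0]), exp1_config, params, rng)
        assert r.category == 1 and r.rating == 4

    def test_decision_noise_alone_makes_responses_stochastic(self, exp1_config, rng):
        params = tc.ObserverParams(
            sigma=0.0,
            alpha=5.0,
            criteria=(0.2, 0.4, 0.7),
            lapse=0.0,
            rule="difference",
            noise_variant="decision",
        )
        s = np.tile([0.5, 0.0], (500, 1))
        cat, rat = tc.simulate_responses(s, exp1_config, params, rng)
        assert len(np.unique(cat)) > 1  # "late noise" varies responses at fixed s


class TestPosteriorTriple:
    def test_simplex_invariant_enforced(self):
        tc.PosteriorTriple(np.array([0.2, 0.3, 0.5]))
        with pytest.raises(ValueError):
            tc.PosteriorTriple(np.array([0.5, 0.6, 0.2]))
        with pytest.raises(ValueError):
            tc.PosteriorTriple(np.array([-0.1, 0.6, 0.5]))


class TestObserverParams:
    def test_variant_constraints_enforced(self):
        with pytest.raises(ValueError):
            tc.ObserverParams(0.5, 30.0, (0.2, 0.4, 0.7), 0.02, noise_variant="sensory")
        with pytest.raises(ValueError):
            tc.ObserverParams(0.5, 30.0, (0.2, 0.4, 0.7), 0.02, noise_variant="decision")

    def test_free_parameter_count(self):
        full = tc.ObserverParams(0.5, 30.0, (0.2, 0.4, 0.7), 0.02)
        reduced = tc.ObserverParams(0.5, np.inf, (0.2, 0.4, 0.7), 0.02, noise_variant="sensory")
        assert full.k == 6 and reduced.k == 5
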