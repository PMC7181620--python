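"""The Bayesian observer: posterior inference, decision noise, confidence.

On each trial the observer receives a noisy measurement ``x`` of the target
position (Gaussian, SD ``sigma``), computes the posterior over the three
categories under a uniform prior,

    p(C | x)  propto  N(x; m_C, (sigma_s^2 + sigma^2) I),

and then acts not on ``p`` but on a decision-noise-corrupted posterior
``q ~ Dirichlet(alpha * p)``, whose mean is ``p`` and whose spread shrinks as
the concentration ``alpha`` grows (``alpha = inf`` recovers the noiseless
posterior).  The category report is ``argmax_C q_C``.  Confidence is a scalar
read-out ``c*`` of ``q`` — which read-out is the scientific question:

* ``max``         c* = q_(1), the posterior probability of the chosen
                  category (the Bayesian confidence hypothesis);
* ``difference``  c* = q_(1) - q_(2), the balance of evidence between the
                  top two categories;
* ``entropy``     c* = sum_C q_C log q_C, the negative Shannon entropy;
* ``ratio``       c* = q_(1) / (q_(1) + q_(2)), the top-two renormalized
                  posterior (monotone in the top-two likelihood ratio).

``c*`` maps to a 1-4 rating through observer-specific criteria
b1 < b2 < b3.  A lapse rate ``lapse`` mixes in trials on which both button
presses are uniform random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .design import CategoryConfiguration

__all__ = [
    "PosteriorTriple",
    "ObserverParams",
    "BehavioralResponse",
    "RULES",
    "NOISE_VARIANTS",
    "RULE_RANGES",
    "compute_posterior",
    "sample_noisy_posterior",
    "decide",
    "confidence_variable",
    "rate_confidence",
    "simulate_response",
    "simulate_responses",
]

RULES = ("max", "difference", "entropy", "ratio")
NOISE_VARIANTS = ("both", "sensory", "decision")

#: Native range of each rule's confidence variable on the 3-simplex.
RULE_RANGES = {
    "max": (1.0 / 3.0, 1.0),
    "difference": (0.0, 1.0),
    "entropy": (-math.log(3.0), 0.0),
    "ratio": (0.5, 1.0),
}

#: Floor applied to posterior components before Dirichlet sampling, so that
#: every concentration parameter alpha * p_i is strictly positive.
_POSTERIOR_EPS = 1e-6

#: Lower bound on the lapse rate during fitting; guarantees every response
#: cell has probability >= lapse/12 > 0.
LAPSE_MIN = 1e-4

_SIMPLEX_ATOL = 1e-10


def _as_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("expected 3 posterior components")
    if np.any(p < -_SIMPLEX_ATOL) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-8):
        raise ValueError("posterior components must be nonnegative and sum to 1")
    return p


@dataclass(frozen=True)
class PosteriorTriple:
    """A point on the 3-simplex: category probabilities (true or noisy)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", _as_simplex(self.probs))


@dataclass(frozen=True)
class BehavioralResponse:
    """One trial's two button presses: a category and a confidence rating."""

    category: int
    rating: int

    def __post_init__(self) -> None:
        if self.category not in (1, 2, 3):
            raise ValueError("category must be 1, 2 or 3")
        if self.rating not in (1, 2, 3, 4):
            raise ValueError("rating must be between 1 and 4")


@dataclass(frozen=True)
class ObserverParams:
    """Observer parameters theta = (sigma, alpha, b1, b2, b3, lapse) plus the
    model identity (confidence rule x noise variant).

    ``noise_variant`` controls which noise sources exist: ``both`` (sensory +
    decision), ``sensory`` (alpha = inf), ``decision`` (sigma = 0).  The
    criteria live in the native range of the rule's confidence variable.
    """

    sigma: float
    alpha: float
    criteria: tuple[float, float, float]
    lapse: float
    rule: str = "difference"
    noise_variant: str = "both"

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown confidence rule {self.rule!r}; expected one of {RULES}")
        if self.noise_variant not in NOISE_VARIANTS:
            raise ValueError(
                f"unknown noise variant {self.noise_variant!r}; expected one of {NOISE_VARIANTS}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive (or inf)")
        if self.noise_variant == "sensory" and not math.isinf(self.alpha):
            raise ValueError("sensory-only variant requires alpha = inf")
        if self.noise_variant == "decision" and self.sigma != 0.0:
            raise ValueError("decision-only variant requires sigma = 0")
        b1, b2, b3 = self.criteria
        if not (b1 < b2 < b3):
            raise ValueError("criteria must satisfy b1 < b2 < b3")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")
        object.__setattr__(self, "criteria", (float(b1), float(b2), float(b3)))

    @property
    def k(self) -> int:
        """Number of free parameters when this model is fitted jointly:
        6 for the full model, 5 when one noise source is removed."""
        return 6 if self.noise_variant == "both" else 5

    def replace(self, **kwargs) -> "ObserverParams":
        return replace(self, **kwargs)


def compute_posterior(
    x: np.ndarray, config: CategoryConfiguration, sigma: float
) -> np.ndarray:
    """Posterior over the three categories given measurement(s) ``x``.

    ``x`` has shape ``(..., 2)``; the result has shape ``(..., 3)``.  Uses a
    log-sum-exp evaluation so that measurements far from all category means
    still yield finite, normalized posteriors.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("measurement contains non-finite values")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    var = config.category_sd**2 + sigma**2
    d2 = ((x[..., None, :] - config.means) ** 2).sum(axis=-1)  # (..., 3)
    logp = -d2 / (2.0 * var)
    logp -= logp.max(axis=-1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=-1, keepdims=True)
    return p


def sample_noisy_posterior(
    p: np.ndarray, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw noisy posterior(s) ``q ~ Dirichlet(alpha * p)``.

    ``p`` has shape ``(..., 3)``.  ``alpha = inf`` returns ``p`` unchanged
    (no decision noise).  Components of ``p`` below a small floor are clamped
    and the vector renormalized so every Dirichlet concentration is positive;
    the clamp perturbs E[q] by at most the floor value.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive (or inf)")
    p = np.asarray(p, dtype=float)
    if math.isinf(alpha):
        return p.copy()
    pc = np.clip(p, _POSTERIOR_EPS, None)
    pc = pc / pc.sum(axis=-1, keepdims=True)
    g = rng.standard_gamma(alpha * pc)
    # For very small concentrations individual gamma draws can underflow to
    # zero, but the sum stays positive because max_i alpha*p_i >= alpha/3.
    return g / g.sum(axis=-1, keepdims=True)


def decide(q: np.ndarray, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Category report: argmax of the (noisy) posterior, 1-based.

    Exact ties are broken uniformly at random; with continuous noise they
    have measure zero but arise in the noiseless reduced models.
    """
    q = np.asarray(q, dtype=float)
    qmax = q.max(axis=-1, keepdims=True)
    is_max = q == qmax
    n_max = is_max.sum(axis=-1)
    if np.any(n_max > 1):
        rng = np.random.default_rng() if rng is None else rng
        scores = np.where(is_max, rng.random(q.shape), -1.0)
        idx = scores.argmax(axis=-1)
    else:
        idx = q.argmax(axis=-1)
    return idx + 1


def _top_two(q: np.ndarray, chosen: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Largest and second-largest components given the chosen (argmax) index."""
    q = np.asarray(q, dtype=float)
    chosen0 = np.asarray(chosen) - 1
    q1 = np.take_along_axis(q, chosen0[..., None], axis=-1)[..., 0]
    masked = q.copy()
    np.put_along_axis(masked, chosen0[..., None], -np.inf, axis=-1)
    q2 = masked.max(axis=-1)
    return q1, q2


def confidence_variable(q: np.ndarray, chosen: np.ndarray, rule: str) -> np.ndarray:
    """The internal confidence variable c* read out from ``q``.

    ``chosen`` is the 1-based reported category (the argmax of ``q`` up to
    the tie rule).  Entropy uses the natural logarithm with 0*log 0 = 0.
    """
    if rule not in RULES:
        raise ValueError(f"unknown confidence rule {rule!r}; expected one of {RULES}")
    q = np.asarray(q, dtype=float)
    if rule == "entropy":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(q > 0, q * np.log(np.where(q > 0, q, 1.0)), 0.0)
        return terms.sum(axis=-1)
    q1, q2 = _top_two(q, chosen)
    if rule == "max":
        return q1
    if rule == "difference":
        return q1 - q2
    return q1 / (q1 + q2)  # ratio


def rate_confidence(c_star: np.ndarray, criteria: tuple[float, float, float]) -> np.ndarray:
    """Map the confidence variable to a 1-4 rating via criteria b1 < b2 < b3.

    rating = 1 + #{i : c* > b_i}; equality with a criterion resolves to the
    lower rating (measure zero under noise).
    """
    b1, b2, b3 = criteria
    if not (b1 < b2 < b3):
        raise ValueError("criteria must satisfy b1 < b2 < b3")
    c = np.asarray(c_star, dtype=float)
    rating = 1 + (c > b1).astype(np.int64) + (c > b2) + (c > b3)
    if rating.ndim == 0:
        return rating[()]
    return rating


def simulate_response(
    s: np.ndarray,
    config: CategoryConfiguration,
    params: ObserverParams,
    rng: np.random.Generator,
) -> BehavioralResponse:
    """Simulate the observer's two responses on a single trial at target ``s``."""
    cat, rat = simulate_responses(np.asarray(s, dtype=float)[None, :], config, params, rng)
    return BehavioralResponse(category=int(cat[0]), rating=int(rat[0]))


def simulate_responses(
    s: np.ndarray,
    config: CategoryConfiguration,
    params: ObserverParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized trial simulation at target positions ``s`` (shape (n, 2)).

    Returns ``(categories, ratings)`` each of shape ``(n,)``.  On a lapse
    trial (probability ``lapse``) both responses are independent uniform
    button presses; otherwise the full measurement -> posterior -> noisy
    posterior -> decision -> rating pipeline runs.
    """
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    x = s if params.sigma == 0 else rng.normal(s, params.sigma)
    p = compute_posterior(x, config, params.sigma)
    q = sample_noisy_posterior(p, params.alpha, rng)
    cat = decide(q, rng)
    c_star = confidence_variable(q, cat, params.rule)
    rat = rate_confidence(c_star, params.criteria)
    if params.lapse > 0:
        is_lapse = rng.random(n) < params.lapse
        n_lapse = int(is_lapse.sum())
        if n_lapse:
            cat = np.asarray(cat).copy()
            rat = np.asarray(rat).copy()
            cat[is_lapse] = rng.integers(1, 4, size=n_lapse)
            rat[is_lapse] = rng.integers(1, 5, size=n_lapse)
    return np.asarray(cat), np.asarray(rat)
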