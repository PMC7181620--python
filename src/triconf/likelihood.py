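"""Monte-Carlo response probabilities and the trial log-likelihood.

The measurement ``x`` is internal to the observer, so model predictions for
a target position ``s`` are obtained by simulation: draw many measurements
``x ~ N(s, sigma^2 I)``, push each through posterior -> Dirichlet decision
noise -> decision -> rating, and tabulate the joint distribution
p(category, rating | s; theta) as relative frequencies, finally mixed with
the uniform lapse distribution.  The default is 10,000 simulated
measurements per position.

Fitting evaluates this likelihood at many parameter vectors, so the module
keeps a precomputed :class:`LikelihoodEngine` per dataset: trial positions
are deduplicated per configuration, the measurement-noise standard normals
are drawn once (common random numbers across parameter evaluations), and
the Dirichlet gamma stream is re-seeded identically on every evaluation.
The objective is therefore a deterministic function of theta, which keeps
derivative-free optimization stable.  Configurations whose category means
share a vertical coordinate (Experiments 1 and 3) are evaluated in one
dimension, since the vertical measurement component then cancels from the
posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import Dataset
from .design import CategoryConfiguration, standard_configurations
from .observer import ObserverParams

__all__ = [
    "ResponseDistribution",
    "response_distribution",
    "response_table",
    "log_likelihood",
    "LikelihoodEngine",
    "MODES",
    "DEFAULT_N_MC",
]

MODES = ("joint", "confidence_only", "decision_only")

#: Default number of simulated measurements per target position.
DEFAULT_N_MC = 10_000

_EPS = 1e-6  # posterior floor before Dirichlet sampling

#: Probability of the observed cell on a lapse trial, per fitting mode.
_UNIFORM_CELL = {"joint": 1.0 / 12.0, "confidence_only": 0.25, "decision_only": 1.0 / 3.0}


@dataclass(frozen=True)
class ResponseDistribution:
    """Estimated joint response probabilities at one target position.

    ``table[c, r]`` is p(category c+1, rating r+1 | s; theta), a 3 x 4 array
    whose entries sum to one and are each at least lapse/12.
    """

    s: np.ndarray
    table: np.ndarray
    n_mc: int
    seed: int

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (3, 4):
            raise ValueError("table must be 3 x 4")
        if abs(t.sum() - 1.0) > 1e-10 or np.any(t < 0):
            raise ValueError("table entries must be nonnegative and sum to 1")
        object.__setattr__(self, "table", t)

    def expected_confidence(self) -> float:
        return float((self.table.sum(axis=0) * np.arange(1, 5)).sum())


def _is_collinear(config: CategoryConfiguration) -> bool:
    return bool(np.all(config.means[:, 1] == config.means[0, 1]))


def _simulate_chosen_cstar(
    positions: np.ndarray,
    config: CategoryConfiguration,
    sigma: float,
    alpha: float,
    rule: str,
    z: np.ndarray,
    gamma_rng: Optional[np.random.Generator],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized non-lapse pipeline at ``positions`` (n, 2).

    ``z`` holds pre-drawn standard normals, shape (n, n_mc) when the config
    is collinear (1-D sufficient statistics) else (n, n_mc, 2).  Returns
    0-based chosen categories and the confidence variable, each (n, n_mc).
    """
    means = config.means
    var = config.category_sd**2 + sigma**2
    collinear = z.ndim == 2
    if collinear:
        x = positions[:, 0][:, None] + sigma * z  # (n, n_mc)
        d2 = (x[..., None] - means[:, 0]) ** 2  # (n, n_mc, 3)
    else:
        x = positions[:, None, :] + sigma * z  # (n, n_mc, 2)
        d2 = ((x[..., None, :] - means) ** 2).sum(axis=-1)
    np.multiply(d2, -1.0 / (2.0 * var), out=d2)
    d2 -= d2.max(axis=-1, keepdims=True)
    p = np.exp(d2, out=d2)
    p /= p.sum(axis=-1, keepdims=True)

    if math.isinf(alpha):
        q = p
    else:
        np.clip(p, _EPS, None, out=p)
        p /= p.sum(axis=-1, keepdims=True)
        g = gamma_rng.standard_gamma(alpha * p)
        q = g  # unnormalized; all read-outs below are scale-aware

    chosen = q.argmax(axis=-1).astype(np.int8)
    total = q.sum(axis=-1)
    top = q.max(axis=-1)
    if rule == "entropy":
        with np.errstate(divide="ignore", invalid="ignore"):
            glg = np.where(q > 0, q * np.log(np.where(q > 0, q, 1.0)), 0.0)
        cstar = glg.sum(axis=-1) / total - np.log(total)
    else:
        second = total - top - q.min(axis=-1)
        if rule == "max":
            cstar = top / total
        elif rule == "difference":
            cstar = (top - second) / total
        else:  # ratio
            cstar = top / (top + second)
    return chosen, cstar


def _ratings_from_cstar(cstar: np.ndarray, criteria: tuple[float, float, float]) -> np.ndarray:
    b1, b2, b3 = criteria
    return (cstar > b1).astype(np.int8) + (cstar > b2) + (cstar > b3)  # 0-based


def response_table(
    positions: np.ndarray,
    config: CategoryConfiguration,
    params: ObserverParams,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> np.ndarray:
    """Response-probability tables at many positions, shape (n, 3, 4).

    Lapse-mixed: each cell is (1 - lapse) * MC frequency + lapse / 12.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be at least 1")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = positions.shape[0]
    ss = np.random.SeedSequence([seed, config.experiment_id, config.config_id])
    z_rng, gamma_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
    shape = (n, n_mc) if _is_collinear(config) else (n, n_mc, 2)
    z = np.zeros(shape) if params.sigma == 0 else z_rng.standard_normal(shape)
    chosen, cstar = _simulate_chosen_cstar(
        positions, config, params.sigma, params.alpha, params.rule, z, gamma_rng
    )
    ratings = _ratings_from_cstar(cstar, params.criteria)
    cell = chosen.astype(np.int64) * 4 + ratings  # (n, n_mc), values 0..11
    tables = np.empty((n, 3, 4))
    for i in range(n):
        tables[i] = np.bincount(cell[i], minlength=12).reshape(3, 4) / n_mc
    lam = params.lapse
    return (1.0 - lam) * tables + lam / 12.0


def response_distribution(
    s: np.ndarray,
    config: CategoryConfiguration,
    params: ObserverParams,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> ResponseDistribution:
    """Monte-Carlo estimate of p(category, rating | s; theta) at one position."""
    s = np.asarray(s, dtype=float).reshape(2)
    table = response_table(s[None, :], config, params, n_mc=n_mc, seed=seed)[0]
    return ResponseDistribution(s=s, table=table, n_mc=n_mc, seed=seed)


class LikelihoodEngine:
    """Precomputed per-dataset state for fast repeated likelihood evaluation.

    Trials are grouped by configuration; unique positions are sorted so the
    common-random-number streams are a deterministic function of
    (base seed, configuration, position rank).
    """

    def __init__(
        self,
        dataset: Dataset,
        n_mc: int = DEFAULT_N_MC,
        seed: int = 0,
        designs: Optional[list[CategoryConfiguration]] = None,
    ):
        if len(dataset) == 0:
            raise ValueError("dataset has no trials")
        if n_mc < 1:
            raise ValueError("n_mc must be at least 1")
        self.n_mc = int(n_mc)
        self.seed = int(seed)
        self.n_trials = len(dataset)
        configs = designs or standard_configurations(dataset.experiment_id)
        by_id = {c.config_id: c for c in configs}
        self._groups = []
        trials = dataset.trials
        for cid, sub in trials.groupby("config"):
            if int(cid) not in by_id:
                raise ValueError(f"trial references unknown configuration {cid}")
            cfg = by_id[int(cid)]
            pos = sub[["target_x", "target_y"]].to_numpy(dtype=float)
            # Deduplicate by exact coordinates (no silent binning).
            uniq, inverse = np.unique(pos, axis=0, return_inverse=True)
            order = np.lexsort((uniq[:, 1], uniq[:, 0]))
            rank = np.empty_like(order)
            rank[order] = np.arange(len(order))
            uniq_sorted = uniq[order]
            pos_idx = rank[inverse]
            ss = np.random.SeedSequence([self.seed, cfg.experiment_id, cfg.config_id])
            z_child, gamma_child = ss.spawn(2)
            shape = (
                (len(uniq_sorted), self.n_mc)
                if _is_collinear(cfg)
                else (len(uniq_sorted), self.n_mc, 2)
            )
            z = np.random.default_rng(z_child).standard_normal(shape)
            self._groups.append(
                {
                    "config": cfg,
                    "positions": uniq_sorted,
                    "pos_idx": pos_idx,
                    "obs_cat": sub["response_category"].to_numpy(dtype=np.int8) - 1,
                    "obs_rat": sub["confidence"].to_numpy(dtype=np.int8) - 1,
                    "z": z,
                    "gamma_seed": gamma_child,
                }
            )

    def simulate(self, sigma: float, alpha: float, rule: str):
        """Run the measurement/decision pipeline once for every group.

        Returns a list of (chosen, cstar) arrays aligned with the internal
        groups; the Dirichlet stream is re-seeded, so identical (sigma,
        alpha, rule) give identical output.
        """
        out = []
        for grp in self._groups:
            gamma_rng = np.random.default_rng(grp["gamma_seed"])
            # sigma = 0 degenerates to x = s inside the kernel (x = s + 0 * z).
            chosen, cstar = _simulate_chosen_cstar(
                grp["positions"], grp["config"], sigma, alpha, rule, grp["z"], gamma_rng
            )
            out.append((chosen, cstar))
        return out

    def cell_frequencies(
        self,
        sim,
        criteria: Optional[tuple[float, float, float]],
        mode: str = "joint",
    ) -> np.ndarray:
        """Per-trial non-lapse Monte-Carlo frequency of the observed response.

        Concatenated over configuration groups; the lapse mixture is applied
        separately (see :func:`lapse_cell_probability`).
        """
        parts = []
        for grp, (chosen, cstar) in zip(self._groups, sim):
            idx = grp["pos_idx"]
            if mode == "decision_only":
                freq = (chosen[idx] == grp["obs_cat"][:, None]).mean(axis=1)
            else:
                ratings = _ratings_from_cstar(cstar, criteria)
                if mode == "joint":
                    match = (chosen[idx] == grp["obs_cat"][:, None]) & (
                        ratings[idx] == grp["obs_rat"][:, None]
                    )
                    freq = match.mean(axis=1)
                elif mode == "confidence_only":
                    freq = (ratings[idx] == grp["obs_rat"][:, None]).mean(axis=1)
                else:
                    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
            parts.append(freq)
        return np.concatenate(parts)

    def loglike_from_sim(
        self,
        sim,
        criteria: Optional[tuple[float, float, float]],
        lapse: float,
        mode: str = "joint",
    ) -> float:
        """Log-likelihood given a cached pipeline simulation."""
        freqs = self.cell_frequencies(sim, criteria, mode)
        unif = _UNIFORM_CELL[mode]
        return float(np.log((1.0 - lapse) * freqs + lapse * unif).sum())

    def loglike(self, params: ObserverParams, mode: str = "joint") -> float:
        sim = self.simulate(params.sigma, params.alpha, params.rule)
        return self.loglike_from_sim(sim, params.criteria, params.lapse, mode)

    def cstar_pool(self, sim) -> np.ndarray:
        """Simulated confidence variables pooled over trials (trial-weighted)."""
        parts = [cstar[grp["pos_idx"]].ravel() for grp, (_, cstar) in zip(self._groups, sim)]
        return np.concatenate(parts)

    def rating_counts(self) -> np.ndarray:
        """Observed confidence-rating histogram (length 4) over all trials."""
        counts = np.zeros(4)
        for grp in self._groups:
            counts += np.bincount(grp["obs_rat"], minlength=4)
        return counts


def log_likelihood(
    dataset: Dataset,
    params: ObserverParams,
    mode: str = "joint",
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> float:
    """Log-likelihood of a subject's trials under one observer model.

    ``mode`` selects what is fitted: the joint (category, rating) responses,
    the confidence ratings only, or the category decisions only.  Response
    probabilities are shared across trials at identical positions and are
    deterministic given ``seed``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    engine = LikelihoodEngine(dataset, n_mc=n_mc, seed=seed)
    return engine.loglike(params, mode=mode)
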