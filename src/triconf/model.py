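"""Model and results objects for fitting confidence models to a subject.

:class:`ConfidenceModel` pairs one subject's dataset with a model identity
(confidence rule x noise variant x fitting mode) and exposes ``loglike`` and
``fit``.  ``fit`` maximizes the Monte-Carlo log-likelihood with a staged
derivative-free scheme designed for a noisy-but-deterministic objective
(common random numbers make the likelihood an exact function of theta):

1. Latin-hypercube screening over the noise parameters (sigma, log alpha)
   and the lapse rate, with the three confidence criteria profiled out by
   matching the simulated confidence-variable quantiles to the observed
   rating frequencies, at reduced Monte-Carlo fidelity;
2. Nelder-Mead refinement of the screened optimum on the same profiled
   objective;
3. a short full-fidelity Nelder-Mead polish of all free parameters.

All bounds are enforced through smooth transforms (logistic for bounded
parameters, log for the criterion spacings), so the simplex search runs
unconstrained.  The reported log-likelihood, AIC and BIC are evaluated at
the full Monte-Carlo size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc

from scipy.optimize import minimize_scalar

from .data import Dataset
from .likelihood import DEFAULT_N_MC, LikelihoodEngine, MODES, _UNIFORM_CELL
from .observer import LAPSE_MIN, NOISE_VARIANTS, RULES, RULE_RANGES, ObserverParams

__all__ = ["ConfidenceModel", "ConfidenceResults", "FitOptions", "fit_subject"]


@dataclass
class FitOptions:
    """Tunable knobs of the staged maximum-likelihood fit.

    ``n_mc`` is the Monte-Carlo size of the likelihood being maximized (and
    of every reported quantity); ``screen_n_mc`` is the cheaper fidelity the
    screening/refinement stages use internally.
    """

    n_mc: int = DEFAULT_N_MC
    screen_n_mc: int = 250
    n_screen: int = 10
    restarts: int = 2
    maxfev_profile: int = 45
    maxfev_criteria: int = 60
    maxfev_joint: int = 8
    seed: int = 0
    sigma_bounds: tuple[float, float] = (0.0, 5.0)
    alpha_bounds: tuple[float, float] = (1.0, 5000.0)
    lapse_bounds: tuple[float, float] = (LAPSE_MIN, 1.0)


def _best_lapse(
    freqs: np.ndarray, unif: float, bounds: tuple[float, float]
) -> tuple[float, float]:
    """Conditional MLE of the lapse rate given per-trial non-lapse cell
    frequencies; the mixture log-likelihood is concave in lapse, so a
    bounded 1-D search is exact.  Returns (lapse, loglike)."""

    def nll(lam):
        return -float(np.log((1.0 - lam) * freqs + lam * unif).sum())

    res = minimize_scalar(nll, bounds=bounds, method="bounded", options={"xatol": 1e-5})
    return float(res.x), -float(res.fun)


def _nelder_mead(fun, x0, maxfev, step=0.6):
    """Nelder-Mead with an explicit initial simplex of edge ``step``.

    The default simplex scales with the coordinate magnitude, which is
    degenerate near the origin of our transformed parameter space.
    """
    x0 = np.asarray(x0, dtype=float)
    simplex = np.vstack([x0, x0 + step * np.eye(len(x0))])
    return minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={
            "maxfev": maxfev,
            "xatol": 1e-3,
            "fatol": 0.02,
            "initial_simplex": simplex,
        },
    )


def _to_unit(v, lo, hi):
    return logit(np.clip((v - lo) / (hi - lo), 1e-9, 1 - 1e-9))


def _from_unit(u, lo, hi):
    return lo + (hi - lo) * expit(u)


def _quantile_criteria(
    cstar_pool: np.ndarray, rating_counts: np.ndarray, rule: str
) -> tuple[float, float, float]:
    """Criteria that reproduce the observed rating frequencies.

    Places each criterion at the simulated confidence-variable quantile of
    the observed cumulative rating frequency (clipped away from 0 and 1),
    then enforces strict ordering.
    """
    n = rating_counts.sum()
    cum = np.cumsum(rating_counts[:3]) / max(n, 1)
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    b = np.quantile(cstar_pool, cum)
    lo, hi = RULE_RANGES[rule]
    gap = 1e-5 * (hi - lo)
    b[1] = max(b[1], b[0] + gap)
    b[2] = max(b[2], b[1] + gap)
    return (float(b[0]), float(b[1]), float(b[2]))


class ConfidenceModel:
    """One subject's data paired with a confidence model to be fitted.

    Parameters
    ----------
    dataset : Dataset
        Trial-level data for one subject and one experiment.
    rule : {'max', 'difference', 'entropy', 'ratio'}
        Confidence read-out.
    noise_variant : {'both', 'sensory', 'decision'}
        Which noise sources the model contains; the reduced variants fix
        alpha = inf (sensory only) or sigma = 0 (decision only).
    mode : {'joint', 'confidence_only', 'decision_only'}
        Which responses enter the likelihood.
    """

    def __init__(
        self,
        dataset: Dataset,
        rule: str = "difference",
        noise_variant: str = "both",
        mode: str = "joint",
    ):
        if rule not in RULES:
            raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
        if noise_variant not in NOISE_VARIANTS:
            raise ValueError(
                f"unknown noise variant {noise_variant!r}; expected one of {NOISE_VARIANTS}"
            )
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        self.dataset = dataset
        self.rule = rule
        self.noise_variant = noise_variant
        self.mode = mode
        self.nobs = len(dataset)

    @classmethod
    def from_dataframe(cls, df, subject=None, experiment=None, **kwargs) -> "ConfidenceModel":
        """Build from a flat trial table with ``subject``/``experiment`` columns."""
        sub = df
        if subject is not None:
            sub = sub[sub["subject"].astype(str) == str(subject)]
        if experiment is not None:
            sub = sub[sub["experiment"] == experiment]
        if sub.empty:
            raise ValueError("no trials match the requested subject/experiment")
        subj = str(sub["subject"].iloc[0])
        exp = int(sub["experiment"].iloc[0])
        trials = sub.drop(columns=[c for c in ("subject", "experiment") if c in sub.columns])
        dataset = Dataset(subject=subj, experiment_id=exp, trials=trials.reset_index(drop=True))
        return cls(dataset, **kwargs)

    # -- free-parameter bookkeeping -------------------------------------

    @property
    def k(self) -> int:
        """Number of free parameters of this (model, mode) combination."""
        n_noise = 2 if self.noise_variant == "both" else 1
        if self.mode == "decision_only":
            return n_noise + 1  # noise + lapse
        return n_noise + 1 + 3  # noise + lapse + three criteria

    def _has_sigma(self) -> bool:
        return self.noise_variant in ("both", "sensory")

    def _has_alpha(self) -> bool:
        return self.noise_variant in ("both", "decision")

    def _make_params(self, sigma, alpha, criteria, lapse) -> ObserverParams:
        if criteria is None:
            lo, hi = RULE_RANGES[self.rule]
            criteria = (
                lo + 0.25 * (hi - lo),
                lo + 0.50 * (hi - lo),
                lo + 0.75 * (hi - lo),
            )
        return ObserverParams(
            sigma=sigma,
            alpha=alpha,
            criteria=criteria,
            lapse=lapse,
            rule=self.rule,
            noise_variant=self.noise_variant,
        )

    # -- likelihood ------------------------------------------------------

    def loglike(
        self, params: ObserverParams, n_mc: int = DEFAULT_N_MC, seed: int = 0
    ) -> float:
        engine = LikelihoodEngine(self.dataset, n_mc=n_mc, seed=seed)
        return engine.loglike(params, mode=self.mode)

    # -- fitting ---------------------------------------------------------

    def fit(self, options: Optional[FitOptions] = None, **kwargs) -> "ConfidenceResults":
        """Maximize the Monte-Carlo likelihood; returns a results object.

        Keyword arguments override individual :class:`FitOptions` fields,
        e.g. ``model.fit(n_mc=2000, seed=3)``.
        """
        opts = options or FitOptions()
        for key, val in kwargs.items():
            if not hasattr(opts, key):
                raise TypeError(f"unknown fit option {key!r}")
            setattr(opts, key, val)

        engine_screen = LikelihoodEngine(self.dataset, n_mc=opts.screen_n_mc, seed=opts.seed)
        engine_full = LikelihoodEngine(self.dataset, n_mc=opts.n_mc, seed=opts.seed)
        rating_counts = engine_full.rating_counts()
        has_sigma, has_alpha = self._has_sigma(), self._has_alpha()
        lo_a, hi_a = np.log(opts.alpha_bounds[0]), np.log(opts.alpha_bounds[1])
        fit_criteria = self.mode != "decision_only"
        unif = _UNIFORM_CELL[self.mode]
        evals = {"count": 0}

        def unpack_noise(u):
            i = 0
            if has_sigma:
                sigma = float(_from_unit(u[i], *opts.sigma_bounds))
                i += 1
            else:
                sigma = 0.0
            if has_alpha:
                alpha = math.exp(_from_unit(u[i], lo_a, hi_a))
            else:
                alpha = math.inf
            return sigma, alpha

        def score(freqs):
            # lapse is profiled out exactly (1-D concave conditional MLE)
            lapse, ll = _best_lapse(freqs, unif, opts.lapse_bounds)
            return -ll, lapse

        n_noise_dims = int(has_sigma) + int(has_alpha)

        def profile_objective(u, engine):
            """Objective over the noise parameters only: criteria set by
            quantile matching, lapse by its conditional MLE."""
            evals["count"] += 1
            sigma, alpha = unpack_noise(u)
            sim = engine.simulate(sigma, alpha, self.rule)
            criteria = (
                _quantile_criteria(engine.cstar_pool(sim), rating_counts, self.rule)
                if fit_criteria
                else None
            )
            freqs = engine.cell_frequencies(sim, criteria, self.mode)
            nll, lapse = score(freqs)
            return nll, criteria, lapse

        # Stage 1: screening at reduced MC fidelity. A Latin hypercube covers
        # the bounded box; a few canonical starts cover the plausible regime
        # (sensory noise well below the 2-deg category SD, moderate
        # decision-noise concentrations) where the sigma/alpha trade-off
        # ridge makes broad screening alone unreliable.
        sampler = qmc.LatinHypercube(d=n_noise_dims, seed=opts.seed)
        pts = logit(np.clip(sampler.random(opts.n_screen), 0.02, 0.98))
        canonical = []
        for sig0, al0 in [(0.3, 20.0), (0.3, 200.0), (1.0, 20.0), (1.0, 200.0)]:
            u = []
            if has_sigma:
                u.append(_to_unit(sig0, *opts.sigma_bounds))
            if has_alpha:
                u.append(_to_unit(math.log(al0), lo_a, hi_a))
            canonical.append(u)
        canonical = np.unique(np.array(canonical), axis=0)
        candidates = np.vstack([np.zeros(n_noise_dims), canonical, pts])
        screened = sorted(
            ((profile_objective(u, engine_screen)[0], u) for u in candidates),
            key=lambda t: t[0],
        )

        # Stage 2: Nelder-Mead over the noise parameters (profiled objective).
        stage2 = []
        for _, u0 in screened[: max(1, opts.restarts)]:
            res = _nelder_mead(
                lambda u: profile_objective(u, engine_screen)[0],
                u0,
                maxfev=opts.maxfev_profile,
            )
            stage2.append((res.fun, res.x))
        u_noise = min(stage2, key=lambda t: t[0])[1]

        # Stage 3: full-fidelity criteria refinement on the cached simulation.
        nll_best, criteria_best, lapse_best = profile_objective(u_noise, engine_full)
        if fit_criteria:
            lo, hi = RULE_RANGES[self.rule]
            sigma0, alpha0 = unpack_noise(u_noise)
            sim_full = engine_full.simulate(sigma0, alpha0, self.rule)

            def crit_vec(criteria):
                b1, b2, b3 = criteria
                return np.array(
                    [_to_unit(b1, lo, hi), np.log(max(b2 - b1, 1e-8)), np.log(max(b3 - b2, 1e-8))]
                )

            def unpack_crit(u):
                b1 = float(_from_unit(u[0], lo, hi))
                b2 = b1 + math.exp(u[1])
                b3 = b2 + math.exp(u[2])
                return (b1, b2, b3)

            def crit_objective(u):
                evals["count"] += 1
                freqs = engine_full.cell_frequencies(sim_full, unpack_crit(u), self.mode)
                return score(freqs)[0]

            res3 = _nelder_mead(
                crit_objective, crit_vec(criteria_best), maxfev=opts.maxfev_criteria, step=0.3
            )
            if res3.fun < nll_best:
                criteria_best = unpack_crit(res3.x)
                freqs = engine_full.cell_frequencies(sim_full, criteria_best, self.mode)
                nll_best, lapse_best = score(freqs)
            u_start = np.concatenate([u_noise, crit_vec(criteria_best)])
        else:
            u_start = u_noise

        # Stage 4: short joint polish of noise + criteria at full fidelity.
        def full_objective(u):
            evals["count"] += 1
            sigma, alpha = unpack_noise(u[:n_noise_dims])
            sim = engine_full.simulate(sigma, alpha, self.rule)
            criteria = unpack_crit(u[n_noise_dims:]) if fit_criteria else None
            freqs = engine_full.cell_frequencies(sim, criteria, self.mode)
            return score(freqs)[0]

        if opts.maxfev_joint > 0:
            res4 = _nelder_mead(full_objective, u_start, maxfev=opts.maxfev_joint, step=0.15)
            if res4.fun < nll_best:
                u_start = res4.x
                nll_best = float(res4.fun)
        sigma, alpha = unpack_noise(u_start[:n_noise_dims])
        criteria = unpack_crit(u_start[n_noise_dims:]) if fit_criteria else None
        sim = engine_full.simulate(sigma, alpha, self.rule)
        freqs = engine_full.cell_frequencies(sim, criteria, self.mode)
        nll_final, lapse = score(freqs)
        params = self._make_params(sigma, alpha, criteria, lapse)
        # NM stages run to a fixed evaluation budget by design; a fit is
        # flagged only when no stage produced a finite objective.
        converged = bool(np.isfinite(nll_final) and all(np.isfinite(v) for v, _ in stage2))
        return ConfidenceResults(
            model=self,
            params=params,
            llf=-nll_final,
            n_mc=opts.n_mc,
            seed=opts.seed,
            converged=converged,
            n_restarts=max(1, opts.restarts),
            n_evaluations=evals["count"],
            screen_nll=[float(v) for v, _ in screened[:5]],
        )


@dataclass
class ConfidenceResults:
    """Maximum-likelihood fit of one confidence model to one subject.

    Carries the fitted parameters, the maximized log-likelihood (at the
    fitting Monte-Carlo size), AIC/BIC, and optimizer diagnostics.
    """

    model: ConfidenceModel
    params: ObserverParams
    llf: float
    n_mc: int
    seed: int
    converged: bool
    n_restarts: int
    n_evaluations: int
    screen_nll: list = field(default_factory=list)

    @property
    def subject(self) -> str:
        return self.model.dataset.subject

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k * math.log(self.nobs)

    def simulate(self, seed: int = 0) -> Dataset:
        """Regenerate a synthetic session from the fitted parameters under
        the subject's experiment design (same trial counts per config)."""
        from .simulate import generate_session

        counts = self.model.dataset.trials["config"].value_counts()
        tpc = int(counts.max())
        return generate_session(
            self.model.dataset.experiment_id, self.params, trials_per_config=tpc, seed=seed,
            subject=f"{self.subject}-sim",
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Confidence model fit",
            "=" * 56,
            f"subject:        {self.subject}",
            f"experiment:     {self.model.dataset.experiment_id}",
            f"rule:           {p.rule}",
            f"noise variant:  {p.noise_variant}",
            f"mode:           {self.model.mode}",
            f"n trials:       {self.nobs}",
            f"n_mc:           {self.n_mc}",
            "-" * 56,
            f"sigma (deg):    {p.sigma:.4f}",
            f"alpha:          {p.alpha:.4g}",
            f"criteria:       ({p.criteria[0]:.4f}, {p.criteria[1]:.4f}, {p.criteria[2]:.4f})",
            f"lapse:          {p.lapse:.4f}",
            "-" * 56,
            f"log-likelihood: {self.llf:.2f}",
            f"k (free):       {self.k}",
            f"AIC:            {self.aic:.2f}",
            f"BIC:            {self.bic:.2f}",
            f"converged:      {self.converged}  (evaluations: {self.n_evaluations})",
            "=" * 56,
        ]
        return "\n".join(lines)


def fit_subject(
    dataset: Dataset,
    rule: str = "difference",
    noise_variant: str = "both",
    mode: str = "joint",
    options: Optional[FitOptions] = None,
    **kwargs,
) -> ConfidenceResults:
    """Convenience wrapper: build a :class:`ConfidenceModel` and fit it."""
    return ConfidenceModel(dataset, rule=rule, noise_variant=noise_variant, mode=mode).fit(
        options, **kwargs
    )
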