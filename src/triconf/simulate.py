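"""Synthetic observers and sessions with known ground-truth parameters.

Generates complete experiments — designs, target positions and simulated
responses — so that every downstream stage (likelihood, fitting, model
comparison, summaries) can be exercised and validated without any external
data.  Sessions follow the experiments' procedures: 84 trials per
configuration in Experiment 1 and 120 in Experiments 2 and 3, four
configurations randomized and interleaved, split into eight equal blocks.

Cohorts draw per-subject parameters from ranges chosen to produce realistic
behavior: sensory noise well below the 2-deg category SD, decision-noise
concentrations spanning nearly-noiseless to clearly noisy posteriors, small
lapse rates, and confidence criteria placed at the quartiles of each
subject's own simulated confidence-variable distribution so that all four
ratings are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, read_dataset, write_dataset
from .design import sample_target, standard_configurations
from .observer import RULE_RANGES, ObserverParams, confidence_variable, decide, \
    sample_noisy_posterior, compute_posterior, simulate_responses

__all__ = [
    "CohortSpec",
    "TRIALS_PER_CONFIG",
    "generate_session",
    "generate_cohort",
    "default_criteria",
    "read_dataset",
    "write_dataset",
]

#: Trials per configuration in each experiment's single one-hour session.
TRIALS_PER_CONFIG = {1: 84, 2: 120, 3: 120}

N_BLOCKS = 8

#: Default per-subject parameter ranges for synthetic cohorts.
COHORT_SIGMA_RANGE = (0.1, 1.0)
COHORT_ALPHA_RANGE = (5.0, 200.0)
COHORT_LAPSE_RANGE = (0.005, 0.05)


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    ``params`` may give explicit per-subject :class:`ObserverParams`;
    otherwise each subject's (sigma, alpha, lapse) are drawn from the
    package's default ranges (sigma uniform, alpha log-uniform, lapse
    uniform) and criteria are placed at the subject's simulated
    confidence-variable quartiles.
    """

    experiment_id: int
    n_subjects: int
    trials_per_config: Optional[int] = None
    rule: str = "difference"
    noise_variant: str = "both"
    params: Optional[Sequence[ObserverParams]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.trials_per_config is None:
            self.trials_per_config = TRIALS_PER_CONFIG[self.experiment_id]
        if self.trials_per_config < 1:
            raise ValueError("trials_per_config must be at least 1")
        if self.params is not None and len(self.params) != self.n_subjects:
            raise ValueError("params must have one entry per subject")


def default_criteria(
    rule: str,
    experiment_id: int,
    sigma: float,
    alpha: float,
    rng: np.random.Generator,
    n_sim: int = 1500,
) -> tuple[float, float, float]:
    """Criteria at the quartiles of the simulated confidence-variable
    distribution for this observer under this experiment's designs.

    Quartile placement guarantees (in expectation) that all four ratings
    occur, emulating subjects who spread their responses over the scale.
    """
    configs = standard_configurations(experiment_id)
    pools = []
    per_cfg = max(1, n_sim // len(configs))
    for cfg in configs:
        targets = np.array([sample_target(cfg, rng).position for _ in range(per_cfg)])
        x = targets if sigma == 0 else rng.normal(targets, sigma)
        p = compute_posterior(x, cfg, sigma)
        q = sample_noisy_posterior(p, alpha, rng)
        chosen = decide(q, rng)
        pools.append(confidence_variable(q, chosen, rule))
    pool = np.concatenate(pools)
    b = np.quantile(pool, [0.25, 0.5, 0.75])
    lo, hi = RULE_RANGES[rule]
    gap = 1e-6 * (hi - lo)
    b[1] = max(b[1], b[0] + gap)
    b[2] = max(b[2], b[1] + gap)
    return (float(b[0]), float(b[1]), float(b[2]))


def generate_session(
    experiment_id: int,
    params: ObserverParams,
    trials_per_config: Optional[int] = None,
    seed: int = 0,
    subject: str = "synthetic",
) -> Dataset:
    """Simulate one subject's session under an experiment's design.

    All four configurations are presented ``trials_per_config`` times in a
    randomized interleaved order and split into eight equal blocks (the
    block index is recorded but never used by the models).  The same seed
    reproduces the identical dataset.
    """
    configs = standard_configurations(experiment_id)
    tpc = TRIALS_PER_CONFIG[experiment_id] if trials_per_config is None else trials_per_config
    if tpc < 1:
        raise ValueError("trials_per_config must be at least 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, experiment_id]))
    order = np.repeat([c.config_id for c in configs], tpc)
    rng.shuffle(order)
    total = len(order)
    if total % N_BLOCKS == 0:
        blocks = np.repeat(np.arange(N_BLOCKS), total // N_BLOCKS)
    else:
        warnings.warn(
            f"{total} trials not divisible into {N_BLOCKS} equal blocks; block "
            "bookkeeping disabled (all trials assigned block 0)"
        )
        blocks = np.zeros(total, dtype=int)
    by_id = {c.config_id: c for c in configs}
    rows = []
    for cid, block in zip(order, blocks):
        cfg = by_id[int(cid)]
        target = sample_target(cfg, rng)
        cat, rat = simulate_responses(target.position[None, :], cfg, params, rng)
        rows.append(
            (
                int(cid),
                float(target.position[0]),
                float(target.position[1]),
                target.true_category,
                int(cat[0]),
                int(rat[0]),
                int(block),
            )
        )
    trials = pd.DataFrame(
        rows,
        columns=[
            "config",
            "target_x",
            "target_y",
            "true_category",
            "response_category",
            "confidence",
            "block",
        ],
    )
    trials["true_category"] = trials["true_category"].astype("Int64")
    return Dataset(subject=subject, experiment_id=experiment_id, trials=trials)


def generate_cohort(spec: CohortSpec) -> tuple[list[Dataset], pd.DataFrame]:
    """Simulate a cohort of subjects; returns datasets and a ground-truth
    ledger (one row per subject: parameters and the seeds used)."""
    master = np.random.SeedSequence(spec.seed)
    param_seed, *subject_seeds = master.spawn(spec.n_subjects + 1)
    param_rng = np.random.default_rng(param_seed)
    datasets, rows = [], []
    for i in range(spec.n_subjects):
        if spec.params is not None:
            theta = spec.params[i]
        else:
            sigma = 0.0 if spec.noise_variant == "decision" else param_rng.uniform(
                *COHORT_SIGMA_RANGE
            )
            alpha = (
                np.inf
                if spec.noise_variant == "sensory"
                else float(np.exp(param_rng.uniform(*np.log(COHORT_ALPHA_RANGE))))
            )
            lapse = param_rng.uniform(*COHORT_LAPSE_RANGE)
            criteria = default_criteria(spec.rule, spec.experiment_id, sigma, alpha, param_rng)
            theta = ObserverParams(
                sigma=sigma,
                alpha=alpha,
                criteria=criteria,
                lapse=lapse,
                rule=spec.rule,
                noise_variant=spec.noise_variant,
            )
        session_seed = int(subject_seeds[i].generate_state(1)[0] % (2**31 - 1))
        subject = f"synth{i + 1:02d}"
        ds = generate_session(
            spec.experiment_id,
            theta,
            trials_per_config=spec.trials_per_config,
            seed=session_seed,
            subject=subject,
        )
        datasets.append(ds)
        rows.append(
            {
                "subject": subject,
                "experiment": spec.experiment_id,
                "rule": theta.rule,
                "noise_variant": theta.noise_variant,
                "sigma": theta.sigma,
                "alpha": theta.alpha,
                "b1": theta.criteria[0],
                "b2": theta.criteria[1],
                "b3": theta.criteria[2],
                "lapse": theta.lapse,
                "session_seed": session_seed,
                "n_trials": len(ds),
            }
        )
    return datasets, pd.DataFrame(rows)
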