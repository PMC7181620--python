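"""AIC/BIC model comparison with bootstrap CIs, and model recovery.

Model comparison follows the group-sum convention: the information
criterion is computed per subject, summed across subjects, and the
difference between models is reported with a 95% percentile bootstrap
confidence interval obtained by resampling subjects with replacement.

Model recovery checks that the comparison procedure identifies the true
generating model: for each candidate generator, synthetic datasets are
simulated from known per-subject parameters under a given experiment
design, every candidate model is fitted to each dataset, and the
group-summed AICs are collected into a generator x fitted matrix whose
diagonal should be minimal in every row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ConfidenceResults, FitOptions, fit_subject
from .observer import ObserverParams
from .simulate import generate_session

__all__ = [
    "information_criteria",
    "group_delta",
    "GroupDelta",
    "comparison_table",
    "ComparisonTable",
    "model_recovery",
    "RecoveryMatrix",
]

DEFAULT_N_BOOT = 10_000


def information_criteria(fit: ConfidenceResults) -> tuple[float, float]:
    """(AIC, BIC) of a fit: -2 logL + 2k and -2 logL + k log n."""
    if fit.nobs <= 0:
        raise ValueError("fit has no observations")
    return fit.aic, fit.bic


@dataclass(frozen=True)
class GroupDelta:
    """Group-summed AIC difference (alt - ref) with a bootstrap CI."""

    delta: float
    ci_low: float
    ci_high: float
    per_subject: np.ndarray
    n_boot: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_subject", np.asarray(self.per_subject, dtype=float))


def group_delta(
    fits_ref: Sequence[ConfidenceResults],
    fits_alt: Sequence[ConfidenceResults],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    criterion: str = "aic",
) -> GroupDelta:
    """Summed-criterion difference between two models over the same subjects.

    ``delta`` > 0 means the reference model (first argument) fits better.
    The CI is the 2.5/97.5 percentile interval of the subject-resampled sum.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    ref_subjects = [f.subject for f in fits_ref]
    alt_subjects = [f.subject for f in fits_alt]
    if ref_subjects != alt_subjects:
        raise ValueError("fit lists must cover the same subjects in the same order")
    vals_ref = np.array([getattr(f, criterion) for f in fits_ref])
    vals_alt = np.array([getattr(f, criterion) for f in fits_alt])
    per_subject = vals_alt - vals_ref
    n = len(per_subject)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    sums = per_subject[idx].sum(axis=1)
    lo, hi = np.percentile(sums, [2.5, 97.5])
    return GroupDelta(
        delta=float(per_subject.sum()),
        ci_low=float(lo),
        ci_high=float(hi),
        per_subject=per_subject,
        n_boot=n_boot,
    )


@dataclass
class ComparisonTable:
    """Per-subject and group-summed criteria for a set of models, with
    deltas relative to a reference model and bootstrap CIs."""

    per_subject: pd.DataFrame  # subjects x models
    reference: str
    deltas: pd.DataFrame  # models x [delta, ci_low, ci_high]

    @property
    def group_sums(self) -> pd.Series:
        return self.per_subject.sum(axis=0)


def comparison_table(
    fits_by_model: Mapping[str, Sequence[ConfidenceResults]],
    reference: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    criterion: str = "aic",
) -> ComparisonTable:
    """Assemble the group model-comparison table (delta = model - reference)."""
    if reference not in fits_by_model:
        raise ValueError(f"reference model {reference!r} not among fitted models")
    subjects = [f.subject for f in fits_by_model[reference]]
    per_subject = pd.DataFrame(
        {
            name: [getattr(f, criterion) for f in fits]
            for name, fits in fits_by_model.items()
        },
        index=subjects,
    )
    rows = {}
    for name, fits in fits_by_model.items():
        gd = group_delta(
            fits_by_model[reference], fits, n_boot=n_boot, seed=seed, criterion=criterion
        )
        rows[name] = {"delta": gd.delta, "ci_low": gd.ci_low, "ci_high": gd.ci_high}
    return ComparisonTable(
        per_subject=per_subject, reference=reference, deltas=pd.DataFrame(rows).T
    )


@dataclass
class RecoveryMatrix:
    """Generator x fitted grid of group-summed AIC plus win counts.

    ``summed_aic.loc[g, f]`` is the AIC of fitted model ``f`` summed over
    all synthetic subjects generated from model ``g``; ``win_counts`` counts
    the subjects for which each fitted model attained the lowest AIC.
    """

    summed_aic: pd.DataFrame
    win_counts: pd.DataFrame
    failures: list = field(default_factory=list)

    def diagonal_recovered(self) -> bool:
        """True when the generating model has the lowest group-summed AIC in
        every row (the recovery success condition)."""
        return all(
            self.summed_aic.loc[g].idxmin() == g for g in self.summed_aic.index
        )


def model_recovery(
    experiment_id: int,
    generator_params: Mapping[str, Sequence[ObserverParams]],
    model_set: Optional[Sequence[str]] = None,
    seed: int = 0,
    trials_per_config: Optional[int] = None,
    fit_options: Optional[FitOptions] = None,
    mode: str = "joint",
) -> RecoveryMatrix:
    """Simulate-and-refit confusion analysis over a set of confidence rules.

    ``generator_params`` maps each generating rule to its per-subject
    parameters.  For each generator, one synthetic session per subject is
    simulated under the experiment's design, every rule in ``model_set`` is
    fitted to each session, and group-summed AICs are accumulated.
    """
    generators = list(generator_params)
    fitted_rules = list(model_set) if model_set is not None else generators
    opts = fit_options or FitOptions()
    aic = pd.DataFrame(0.0, index=generators, columns=fitted_rules)
    wins = pd.DataFrame(0, index=generators, columns=fitted_rules)
    failures = []
    for g_idx, gen in enumerate(generators):
        for s_idx, theta in enumerate(generator_params[gen]):
            data_seed = int(
                np.random.SeedSequence([seed, g_idx, s_idx]).generate_state(1)[0]
                % (2**31 - 1)
            )
            ds = generate_session(
                experiment_id,
                theta,
                trials_per_config=trials_per_config,
                seed=data_seed,
                subject=f"{gen}-{s_idx + 1:02d}",
            )
            subject_aics = {}
            for rule in fitted_rules:
                try:
                    res = fit_subject(
                        ds,
                        rule=rule,
                        noise_variant=theta.noise_variant,
                        mode=mode,
                        options=FitOptions(**vars(opts)),
                    )
                except Exception as err:  # noqa: BLE001 - flagged, not fatal
                    failures.append((gen, s_idx, rule, repr(err)))
                    aic.loc[gen, rule] = np.nan
                    continue
                aic.loc[gen, rule] += res.aic
                subject_aics[rule] = res.aic
            if subject_aics:
                wins.loc[gen, min(subject_aics, key=subject_aics.get)] += 1
    return RecoveryMatrix(summed_aic=aic, win_counts=wins, failures=failures)
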