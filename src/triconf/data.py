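"""Trial-level behavioral datasets and their CSV round-trip.

A :class:`Dataset` holds one subject's session of one experiment: per trial
the stimulus configuration, target position (degrees of visual angle), the
true generating category (Experiment 3 only), the reported category (1-3)
and the confidence rating (1-4).  The on-disk format is a plain CSV with
columns ``subject, experiment, config, target_x, target_y, true_category,
response_category, confidence`` (plus an optional ``block`` column recording
the within-session block index).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .design import standard_configurations

__all__ = ["Dataset", "read_dataset", "write_dataset", "DATASET_COLUMNS"]

DATASET_COLUMNS = [
    "subject",
    "experiment",
    "config",
    "target_x",
    "target_y",
    "true_category",
    "response_category",
    "confidence",
    "block",
]


@dataclass
class Dataset:
    """One subject's trials for one experiment."""

    subject: str
    experiment_id: int
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.trials = self.trials.reset_index(drop=True)
        errors = validate_trials(self.experiment_id, self.trials)
        if errors:
            raise ValueError("invalid dataset:\n" + "\n".join(errors))

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def positions(self) -> np.ndarray:
        return self.trials[["target_x", "target_y"]].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = self.trials.copy()
        df.insert(0, "subject", self.subject)
        df.insert(1, "experiment", self.experiment_id)
        return df

    def equals(self, other: "Dataset") -> bool:
        if self.subject != other.subject or self.experiment_id != other.experiment_id:
            return False
        a, b = self.trials, other.trials
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col].to_numpy(), b[col].to_numpy()
            if np.issubdtype(np.asarray(x).dtype, np.floating):
                if not np.allclose(x.astype(float), y.astype(float), equal_nan=True):
                    return False
            else:
                if not (pd.Series(x).fillna(-1) == pd.Series(y).fillna(-1)).all():
                    return False
        return True


def validate_trials(experiment_id: int, trials: pd.DataFrame) -> list[str]:
    """Itemized invariant violations for a trial table (empty list = valid)."""
    errors: list[str] = []
    required = {"config", "target_x", "target_y", "response_category", "confidence"}
    missing = required - set(trials.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    if experiment_id not in (1, 2, 3):
        return [f"unknown experiment id {experiment_id!r}"]
    n_configs = len(standard_configurations(experiment_id))
    for i, row in enumerate(trials.itertuples(index=False)):
        if not 1 <= int(row.config) <= n_configs:
            errors.append(f"row {i}: config {row.config} not in experiment {experiment_id} design")
        if int(row.response_category) not in (1, 2, 3):
            errors.append(f"row {i}: response_category {row.response_category} not in 1-3")
        if int(row.confidence) not in (1, 2, 3, 4):
            errors.append(f"row {i}: confidence {row.confidence} not in 1-4")
        tc = getattr(row, "true_category", None)
        has_tc = tc is not None and not pd.isna(tc)
        if experiment_id == 3 and not has_tc:
            errors.append(f"row {i}: experiment 3 requires true_category")
        if experiment_id != 3 and has_tc:
            errors.append(f"row {i}: true_category only defined for experiment 3")
        if has_tc and int(tc) not in (1, 2, 3):
            errors.append(f"row {i}: true_category {tc} not in 1-3")
        if len(errors) > 50:
            errors.append("... further errors suppressed")
            break
    return errors


def write_dataset(dataset: Dataset, path: Union[str, Path]) -> None:
    """Write a dataset to CSV in the standard schema."""
    df = dataset.to_frame()
    for col in DATASET_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df[DATASET_COLUMNS].to_csv(path, index=False)


def read_dataset(path: Union[str, Path]) -> Dataset:
    """Read and validate a dataset from CSV.

    Raises ``ValueError`` with itemized row-level messages on any invariant
    violation (out-of-range ratings or categories, unknown configurations,
    missing true category for Experiment 3).
    """
    df = pd.read_csv(path)
    required = {"subject", "experiment", "config", "target_x", "target_y",
                "response_category", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    subjects = df["subject"].unique()
    experiments = df["experiment"].unique()
    if len(subjects) != 1 or len(experiments) != 1:
        raise ValueError("dataset CSV must contain exactly one subject and one experiment")
    trial_cols = [c for c in df.columns if c not in ("subject", "experiment")]
    trials = df[trial_cols].copy()
    if "true_category" in trials.columns:
        trials["true_category"] = trials["true_category"].astype("Int64")
    if "block" in trials.columns:
        trials["block"] = trials["block"].fillna(0).astype(int)
    return Dataset(subject=str(subjects[0]), experiment_id=int(experiments[0]), trials=trials)
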