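"""Stimulus designs for the three-alternative categorization experiments.

Three experiments share the same task: three Gaussian categories of exemplar
dots are shown on screen and the observer assigns a single target dot to one
of them, then reports confidence on a four-point scale.  This module encodes
the category geometry of each experiment (in degrees of visual angle,
screen-centered Cartesian coordinates, x rightward / y upward), the rule by
which target positions were sampled, and the exemplar-dot clouds.

Experiment 1 uses four configurations whose category centers lie on the
horizontal meridian; targets are sampled uniformly in x across the category
range (with a 0.2 deg extension) and Gaussian in y.  Experiment 2 places the
centers in the 2-D plane and samples targets uniformly from a disc of radius
2.6 deg.  Experiment 3 reuses Experiment 1's configurations but samples the
target from one of the three category distributions chosen uniformly at
random (the generative model of the task itself).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "CategoryConfiguration",
    "TargetSample",
    "standard_configurations",
    "config_to_dict",
    "config_from_dict",
    "sample_target",
    "render_exemplar_dots",
    "CATEGORY_SD",
    "EXEMPLAR_DOTS_PER_CATEGORY",
    "TARGET_X_EXTENSION",
    "DISC_RADIUS",
]

#: Common standard deviation of every category distribution, both axes (deg).
CATEGORY_SD = 2.0

#: Number of exemplar dots drawn per category on each trial.
EXEMPLAR_DOTS_PER_CATEGORY = 375

#: Horizontal extension of the Exp-1 target range beyond the outer centers (deg).
TARGET_X_EXTENSION = 0.2

#: Radius of the Exp-2 uniform target disc (deg).
DISC_RADIUS = 2.6

#: SD of the Exp-1 vertical target distribution (deg), centered at y = 0.
EXP1_TARGET_Y_SD = 2.0

# Category-center geometry per experiment, degrees from screen center.
_EXP1_X = [(-3.0, 0.0, 3.0), (-4.0, 0.0, 4.0), (-3.0, -2.0, 3.0), (-3.0, 2.0, 3.0)]
_EXP2_X = [(-2.0, 0.0, 2.0), (-1.59, 0.0, 1.59), (-2.0, -2.0, 2.0), (-2.0, 2.0, 2.0)]
_EXP2_Y = [(1.16, -2.31, 1.16), (0.94, -1.84, 0.94), (1.16, 0.0, 1.16), (1.16, 0.0, 1.16)]


@dataclass(frozen=True)
class CategoryConfiguration:
    """Geometry of one stimulus configuration: three category means and a
    shared isotropic standard deviation, all in degrees of visual angle."""

    experiment_id: int
    config_id: int
    means: np.ndarray  # shape (3, 2)
    category_sd: float = CATEGORY_SD

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        if means.shape != (3, 2):
            raise ValueError(f"means must have shape (3, 2), got {means.shape}")
        if self.category_sd <= 0:
            raise ValueError("category_sd must be positive")
        if self.experiment_id not in (1, 2, 3):
            raise ValueError(f"unknown experiment id {self.experiment_id}")
        if self.experiment_id in (1, 3) and np.any(means[:, 1] != 0.0):
            raise ValueError(
                "experiments 1 and 3 have category centers on the horizontal meridian (y = 0)"
            )
        object.__setattr__(self, "means", means)

    @property
    def x_range(self) -> tuple[float, float]:
        """Exp-1/3 target support in x: outer centers plus the extension."""
        return (
            float(self.means[:, 0].min() - TARGET_X_EXTENSION),
            float(self.means[:, 0].max() + TARGET_X_EXTENSION),
        )


@dataclass(frozen=True)
class TargetSample:
    """A sampled target position, with the generating category when the
    design defines one (Experiment 3 only)."""

    position: np.ndarray  # shape (2,)
    true_category: Optional[int] = None


def standard_configurations(experiment_id: int) -> list[CategoryConfiguration]:
    """Return the four standard configurations of an experiment.

    Experiments 1 and 3 share identical geometry (centers on the horizontal
    meridian); Experiment 2 places centers in the plane.  All use
    ``category_sd = 2`` degrees.
    """
    if experiment_id not in (1, 2, 3):
        raise ValueError(f"unknown experiment id {experiment_id!r}; expected 1, 2 or 3")
    configs = []
    if experiment_id in (1, 3):
        for i, xs in enumerate(_EXP1_X, start=1):
            means = np.column_stack([xs, np.zeros(3)])
            configs.append(CategoryConfiguration(experiment_id, i, means))
    else:
        for i, (xs, ys) in enumerate(zip(_EXP2_X, _EXP2_Y), start=1):
            means = np.column_stack([xs, ys])
            configs.append(CategoryConfiguration(experiment_id, i, means))
    return configs


def get_configuration(experiment_id: int, config_id: int) -> CategoryConfiguration:
    """Look up a single standard configuration by experiment and config id."""
    configs = standard_configurations(experiment_id)
    if not 1 <= config_id <= len(configs):
        raise ValueError(f"unknown config id {config_id!r} for experiment {experiment_id}")
    return configs[config_id - 1]


def config_to_dict(config: CategoryConfiguration) -> dict:
    """JSON-ready form of a configuration:
    ``{experiment, config, means: [[x, y] x 3], sd}`` (degrees as floats)."""
    return {
        "experiment": config.experiment_id,
        "config": config.config_id,
        "means": config.means.tolist(),
        "sd": config.category_sd,
    }


def config_from_dict(d: dict) -> CategoryConfiguration:
    """Inverse of :func:`config_to_dict`, with invariant validation."""
    return CategoryConfiguration(
        experiment_id=int(d["experiment"]),
        config_id=int(d["config"]),
        means=np.asarray(d["means"], dtype=float),
        category_sd=float(d["sd"]),
    )


def sample_target(config: CategoryConfiguration, rng: np.random.Generator) -> TargetSample:
    """Draw one target position according to the experiment's sampling rule.

    Exp 1: x uniform over the extended category range, y ~ N(0, 2 deg).
    Exp 2: uniform over a disc of radius 2.6 deg centered at the origin.
    Exp 3: a true category is chosen uniformly and the target is drawn from
    that category's Gaussian; ``true_category`` is set only in this case.
    """
    eid = config.experiment_id
    if eid == 1:
        lo, hi = config.x_range
        x = rng.uniform(lo, hi)
        y = rng.normal(0.0, EXP1_TARGET_Y_SD)
        return TargetSample(position=np.array([x, y]))
    if eid == 2:
        r = DISC_RADIUS * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        return TargetSample(position=np.array([r * np.cos(theta), r * np.sin(theta)]))
    # Experiment 3: the task's own generative model.
    c = int(rng.integers(1, 4))
    pos = rng.normal(config.means[c - 1], config.category_sd)
    return TargetSample(position=pos, true_category=c)


def render_exemplar_dots(
    config: CategoryConfiguration,
    n_per_category: int = EXEMPLAR_DOTS_PER_CATEGORY,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sample the exemplar-dot clouds shown on one trial.

    Returns an array of shape ``(3, n_per_category, 2)``; axis 0 indexes the
    category.  Dots are i.i.d. isotropic Gaussian around each category mean
    with the configuration's standard deviation.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be at least 1")
    rng = np.random.default_rng() if rng is None else rng
    dots = rng.normal(
        loc=config.means[:, None, :],
        scale=config.category_sd,
        size=(3, n_per_category, 2),
    )
    return dots
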