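"""Category structures, stimulus standardisation, and stimulus-side transforms.

A task-modality configuration is a pair of Gaussian category distributions over
a single stimulus attribute (orientation in degrees for the visual modality,
frequency in Hz for the auditory modality).  Two task structures are used:

* ``different_means`` -- the categories share a standard deviation and differ
  in mean, so a single criterion at the density crossing separates them;
* ``different_sds`` -- the categories share a mean and differ in standard
  deviation, so the optimal partition is two symmetric crossings around the
  shared mean (central values belong to the narrow category 1).

This module exposes the generative category pairs, the evidence / diagnosticity
transforms of the stimulus axis, density-crossing points, ideal-observer
category labels, and z-scoring of stimulus values against all presented values
of a configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "Task",
    "Modality",
    "CategoryPair",
    "Standardizer",
    "ConfigurationError",
    "DegenerateInputError",
    "default_category_pair",
    "evidence_for_category2",
    "category_diagnosticity",
    "fit_standardizer",
    "intersection_points",
    "ideal_category",
]


class Task(str, Enum):
    """Category structure of a session."""

    DIFFERENT_MEANS = "different_means"
    DIFFERENT_SDS = "different_sds"


class Modality(str, Enum):
    """Sensory modality of a session."""

    VISUAL = "visual"
    AUDITORY = "auditory"


class ConfigurationError(ValueError):
    """Invalid task/modality/model combination or malformed configuration."""


class DegenerateInputError(ValueError):
    """Input too degenerate for the requested operation."""


@dataclass(frozen=True)
class CategoryPair:
    """Generative model of one task-modality configuration.

    Two Gaussians over the stimulus attribute plus the prior probability of
    category 1.  Units are stimulus units (degrees or Hz), or standardized
    units after :meth:`Standardizer.transform_pair`.
    """

    task: Task
    modality: Modality
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    prior1: float = 0.5

    def __post_init__(self) -> None:
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ConfigurationError("category SDs must be positive")
        if not (0.0 < self.prior1 < 1.0):
            raise ConfigurationError("prior1 must lie strictly in (0, 1)")
        if self.task == Task.DIFFERENT_MEANS:
            if self.sigma1 != self.sigma2 or self.mu1 == self.mu2:
                raise ConfigurationError(
                    "different_means requires equal SDs and distinct means"
                )
        elif self.task == Task.DIFFERENT_SDS:
            if self.mu1 != self.mu2 or not self.sigma1 < self.sigma2:
                raise ConfigurationError(
                    "different_sds requires equal means and sigma1 < sigma2"
                )

    @property
    def prior2(self) -> float:
        return 1.0 - self.prior1


@dataclass(frozen=True)
class Standardizer:
    """Affine z-scoring transform fit to all presented stimulus values."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise DegenerateInputError("standardizer SD must be positive")

    def transform(self, s):
        return (np.asarray(s, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean

    def transform_pair(self, cp: CategoryPair) -> CategoryPair:
        """Express a category pair on the standardized axis."""
        return replace(
            cp,
            mu1=(cp.mu1 - self.mean) / self.sd,
            sigma1=cp.sigma1 / self.sd,
            mu2=(cp.mu2 - self.mean) / self.sd,
            sigma2=cp.sigma2 / self.sd,
        )


# Published category distribution parameters for the four configurations.
_DEFAULT_PAIRS: dict[tuple[Task, Modality], tuple[float, float, float, float]] = {
    (Task.DIFFERENT_MEANS, Modality.VISUAL): (-4.0, 5.0, 4.0, 5.0),
    (Task.DIFFERENT_MEANS, Modality.AUDITORY): (2300.0, 475.0, 3100.0, 475.0),
    (Task.DIFFERENT_SDS, Modality.VISUAL): (0.0, 3.0, 0.0, 12.0),
    (Task.DIFFERENT_SDS, Modality.AUDITORY): (2700.0, 125.0, 2700.0, 500.0),
}


def default_category_pair(task: Task | str, modality: Modality | str) -> CategoryPair:
    """Return the canonical category distributions for a configuration.

    Orientation units are degrees (0 = horizontal, positive = clockwise);
    frequency units are Hz.  Priors are 0.5/0.5 (equal sampling).
    """
    task = Task(task)
    modality = Modality(modality)
    try:
        mu1, s1, mu2, s2 = _DEFAULT_PAIRS[(task, modality)]
    except KeyError:  # pragma: no cover - enums make this unreachable
        raise ConfigurationError(f"unknown configuration {task}/{modality}")
    return CategoryPair(task=task, modality=modality, mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2)


def evidence_for_category2(s, cp: CategoryPair):
    """Probability-normalised evidence that a stimulus came from category 2.

    ``N(s; mu2, sigma2) / [N(s; mu1, sigma1) + N(s; mu2, sigma2)]``, computed
    in log space for numerical stability far in the tails.  Ranges over (0, 1)
    for different-means pairs; for different-SDs pairs the minimum is
    ``sigma1 / (sigma1 + sigma2)`` at the shared mean (category 1 never has
    zero support inside category 2's range).
    """
    s = np.asarray(s, dtype=float)
    log1 = norm.logpdf(s, cp.mu1, cp.sigma1)
    log2 = norm.logpdf(s, cp.mu2, cp.sigma2)
    # e = 1 / (1 + exp(log1 - log2))
    out = 1.0 / (1.0 + np.exp(log1 - log2))
    return out if out.ndim else float(out)


def category_diagnosticity(s, cp: CategoryPair):
    """Normalised density of the most probable category: max(e, 1 - e).

    Equals 0.5 where the category densities cross and approaches 1 where one
    category dominates.
    """
    e = np.asarray(evidence_for_category2(s, cp))
    out = np.maximum(e, 1.0 - e)
    return out if out.ndim else float(out)


def fit_standardizer(values: Iterable[float]) -> Standardizer:
    """Fit the z-scoring transform to all presented stimulus values.

    One task-modality configuration at a time, pooled across categories and
    intensities.  Uses the population SD (ddof=0) of the supplied values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise DegenerateInputError("need at least 2 distinct stimulus values")
    return Standardizer(mean=float(arr.mean()), sd=float(arr.std()))


def intersection_points(cp: CategoryPair) -> list[float]:
    """Stimulus values where the prior-weighted category densities are equal.

    Closed-form roots of the quadratic obtained by equating log densities:
    one point for equal-SD (different-means) pairs, two points symmetric about
    the shared mean for different-SDs pairs.
    """
    lp = math.log(cp.prior1) - math.log(cp.prior2)
    if cp.sigma1 == cp.sigma2:
        if cp.mu1 == cp.mu2:
            raise DegenerateInputError("identical distributions have no unique intersection")
        # linear case: (mu2^2 - mu1^2 - 2 s (mu2 - mu1)) / (2 sigma^2) = lp
        s = (cp.mu2**2 - cp.mu1**2 + 2.0 * cp.sigma1**2 * lp) / (2.0 * (cp.mu2 - cp.mu1))
        return [float(s)]
    a = 0.5 * (1.0 / cp.sigma2**2 - 1.0 / cp.sigma1**2)
    b = cp.mu1 / cp.sigma1**2 - cp.mu2 / cp.sigma2**2
    c = (
        0.5 * (cp.mu2**2 / cp.sigma2**2 - cp.mu1**2 / cp.sigma1**2)
        + math.log(cp.sigma2 / cp.sigma1)
        + lp
    )
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise DegenerateInputError("densities do not intersect")
    r = math.sqrt(disc)
    return sorted(((-b - r) / (2.0 * a), (-b + r) / (2.0 * a)))


def ideal_category(s, cp: CategoryPair):
    """Most probable generating category for a stimulus value (1 or 2).

    Returns 2 where evidence for category 2 exceeds 0.5; exact ties are
    labelled category 1 (deterministic, measure-zero convention).
    """
    e = np.asarray(evidence_for_category2(s, cp))
    out = np.where(e > 0.5, 2, 1)
    return out if out.ndim else int(out)
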