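"""Synthetic experimental designs and simulated observers.

The generator emulates the reference session structure: testing blocks of 120
trials balanced exactly over 2 categories x 4 intensity levels (15 trials per
cell), 6 blocks per session (720 trials), stimulus values drawn from the
generating category's Gaussian, and trial order shuffled within block.
Responses are simulated under any implemented observer model: one noisy
measurement per trial, mapped through the model's decision rule (perceptual
boundaries, or the log-posterior-ratio compared with d-space boundaries, plus
one decision-noise draw when the model has it).

Everything is deterministic given a seed, so the simulator doubles as the
package's test-fixture factory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, norm

from .task_design import (
    CategoryPair,
    ConfigurationError,
    Modality,
    Standardizer,
    Task,
    default_category_pair,
    fit_standardizer,
    ideal_category,
)
from .observer_models import (
    BayesBoundaryParams,
    ModelFamily,
    ModelParams,
    ModelSpec,
    NoiseParams,
    N_INTENSITIES,
    PerceptualBoundaryParams,
    effective_category_pair,
    n_boundaries,
    region_from_index,
)
from .likelihood import TRIAL_COLUMNS, attach_standardized

__all__ = [
    "DesignSpec",
    "generate_design",
    "theoretical_standardizer",
    "simulate_dataset",
    "sample_generating_params",
    "exclude_by_accuracy",
]

_N_CATEGORIES = 2


@dataclass(frozen=True)
class DesignSpec:
    """Session structure of one task-modality configuration."""

    task: Task
    modality: Modality
    n_blocks: int = 6
    trials_per_block: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "modality", Modality(self.modality))
        cell = _N_CATEGORIES * N_INTENSITIES
        if self.trials_per_block % cell:
            raise ConfigurationError(
                f"trials_per_block must be divisible by {cell} (categories x intensities)"
            )


def generate_design(ds: DesignSpec, category_pair: CategoryPair | None = None) -> pd.DataFrame:
    """Generate the stimulus/condition table for one session.

    Within every block each category x intensity cell receives exactly
    ``trials_per_block / 8`` trials; stimulus values are drawn from the
    generating category's distribution and trial order is shuffled.
    """
    cp = category_pair or default_category_pair(ds.task, ds.modality)
    rng = np.random.default_rng(ds.seed)
    per_cell = ds.trials_per_block // (_N_CATEGORIES * N_INTENSITIES)
    frames = []
    for block in range(1, ds.n_blocks + 1):
        cats = np.repeat([1, 2], ds.trials_per_block // 2)
        intens = np.tile(np.repeat(np.arange(1, N_INTENSITIES + 1), per_cell), _N_CATEGORIES)
        mu = np.where(cats == 1, cp.mu1, cp.mu2)
        sd = np.where(cats == 1, cp.sigma1, cp.sigma2)
        s = rng.normal(mu, sd)
        order = rng.permutation(ds.trials_per_block)
        frames.append(
            pd.DataFrame(
                {
                    "block": block,
                    "task": ds.task.value,
                    "modality": ds.modality.value,
                    "s_raw": s[order],
                    "intensity": intens[order],
                    "true_category": cats[order],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def theoretical_standardizer(cp: CategoryPair) -> Standardizer:
    """Standardizer from the design's theoretical mixture moments.

    Mean and SD of the equal-weight (prior-weighted) two-Gaussian mixture;
    offered as a reproducible alternative to the empirical per-session
    standardization.
    """
    p1, p2 = cp.prior1, cp.prior2
    mean = p1 * cp.mu1 + p2 * cp.mu2
    var = p1 * (cp.sigma1**2 + cp.mu1**2) + p2 * (cp.sigma2**2 + cp.mu2**2) - mean**2
    return Standardizer(mean=mean, sd=math.sqrt(var))


def _bayes_region_indices(d: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Region index from the decision variable against decreasing k bounds."""
    # region r <-> d in (k_r, k_{r-1}]; large d -> r = 1 (category 1, conf 4)
    return 1 + np.searchsorted(-k, -d, side="left").astype(int)


def simulate_dataset(
    design: pd.DataFrame,
    spec: ModelSpec,
    params: ModelParams,
    *,
    standardizer_policy: str = "empirical",
    seed: int = 0,
    category_pair: CategoryPair | None = None,
    participant: str = "sim",
) -> pd.DataFrame:
    """Simulate one observer's responses to a generated design.

    Stimuli are standardized per session (empirically by default, matching
    how the real data are treated; ``standardizer_policy='theoretical'`` uses
    the design's mixture moments instead).  Each trial draws one measurement
    x ~ N(z, sigma_i^2) and maps it deterministically through the model's
    decision rule; decision-noise models add one Normal(0, sigma_d) draw to
    the log posterior ratio before the boundary comparison.
    """
    task = Task(design["task"].iloc[0])
    modality = Modality(design["modality"].iloc[0])
    spec.validate_modality(modality)
    if spec.task != task:
        raise ConfigurationError("model task does not match the design's task")
    cp = category_pair or default_category_pair(task, modality)
    if standardizer_policy == "empirical":
        standardizer = fit_standardizer(design["s_raw"].to_numpy())
    elif standardizer_policy == "theoretical":
        standardizer = theoretical_standardizer(cp)
    else:
        raise ConfigurationError(f"unknown standardizer policy {standardizer_policy!r}")
    cp_std = standardizer.transform_pair(cp)

    rng = np.random.default_rng(seed)
    s_raw = design["s_raw"].to_numpy(dtype=float)
    intensity = design["intensity"].to_numpy(dtype=int)
    z = standardizer.transform(s_raw)

    noise = params.noise
    if spec.odn:
        sinus = np.abs(np.sin(np.pi * s_raw / 90.0))
        sigma = (noise.gamma_by_intensity[intensity - 1] + noise.psi * sinus) / standardizer.sd
    else:
        sigma = noise.sigma_by_intensity[intensity - 1]
    x = rng.normal(z, sigma)

    if not spec.is_bayes:
        pb = params.boundary
        if spec.family == ModelFamily.DISTANCE:
            b = np.broadcast_to(pb.k, (x.size,) + pb.k.shape)
        else:
            a = {ModelFamily.LINEAR: 1.0, ModelFamily.QUADRATIC: 2.0}.get(spec.family, pb.a)
            b = pb.k + pb.m * sigma[:, None] ** a
        from .observer_models import _assemble_cuts, _check_ordering

        cuts = _assemble_cuts(task, b)
        _check_ordering(task, cuts)
        v = x if task == Task.DIFFERENT_MEANS else np.abs(x)
        r = 1 + np.sum(cuts <= v[:, None], axis=-1)
    else:
        from .observer_models import lppr

        cp_eff = effective_category_pair(spec, params, cp_std)
        d = lppr(x, sigma, cp_eff, spec)
        if spec.decision_noise and params.boundary.sigma_d > 0:
            # one decision-noise draw per trial, from the central-98% truncated
            # Gaussian that the likelihood's quantile quadrature marginalises
            u = rng.uniform(0.01, 0.99, size=x.shape)
            d = d + params.boundary.sigma_d * norm.ppf(u)
        r = _bayes_region_indices(np.asarray(d), params.boundary.k)

    regions = [region_from_index(int(ri)) for ri in r]
    out = design.copy()
    out.insert(0, "participant", participant)
    out["z"] = z
    out["response_category"] = [g.category for g in regions]
    out["confidence"] = [g.confidence for g in regions]
    out["response_r"] = r.astype(int)
    return out


def sample_generating_params(
    spec: ModelSpec,
    seed: int = 0,
    *,
    category_pair: CategoryPair | None = None,
    modality: Modality | str | None = None,
) -> ModelParams:
    """Draw a constraint-satisfying generating parameter set for a model.

    Ranges emulate the spread of fitted participant parameters: noise SDs
    span roughly 0.5-8 standardized units and decrease over intensity;
    boundary base positions and scales grow with the response index so the
    realized boundaries stay strictly ordered at every drawn noise level.
    """
    rng = np.random.default_rng(seed)
    if category_pair is None:
        mod = Modality(modality) if modality is not None else (
            Modality.VISUAL if spec.odn else Modality.AUDITORY
        )
        category_pair = default_category_pair(spec.task, mod)
    std = theoretical_standardizer(category_pair)
    cp_std = std.transform_pair(category_pair)

    sig4 = rng.uniform(0.5, 1.0)
    ratios = rng.uniform(1.3, 2.2, size=3)
    sig = sig4 * np.concatenate([np.cumprod(ratios[::-1])[::-1], [1.0]])
    if spec.odn:
        noise = NoiseParams(
            gamma_by_intensity=sig * std.sd, psi=rng.uniform(0.0, 0.5) * std.sd
        )
    else:
        noise = NoiseParams(sigma_by_intensity=sig)

    nb = n_boundaries(spec.task, spec.family)
    if not spec.is_bayes:
        scaled = spec.family != ModelFamily.DISTANCE
        if spec.task == Task.DIFFERENT_MEANS:
            k1 = rng.uniform(-0.15, 0.15)
            # base positions stay flat for scaled families (the sigma term
            # carries most of the boundary spread, as in fitted data); the
            # distance family needs the full spread in k itself
            lo, hi = (0.08, 0.45) if scaled else (0.25, 1.0)
            gaps = rng.uniform(lo, hi, size=3)
            k = np.concatenate([[k1], abs(k1) + np.cumsum(gaps)])
        else:
            lo, hi = (0.05, 0.35) if scaled else (0.1, 0.55)
            k = rng.uniform(0.02, 0.12) + np.concatenate(
                [[0.0], np.cumsum(rng.uniform(lo, hi, size=nb - 1))]
            )
        m = None
        a = 1.0
        if scaled:
            # independent sorted scales: the sigma-scaling profile is not
            # proportional to the base positions, as in fitted data
            m = np.sort(rng.uniform(0.05, 2.0, size=nb))
        if spec.family == ModelFamily.FREE_EXPONENT:
            a = rng.uniform(1.2, 2.5)
        elif spec.family == ModelFamily.QUADRATIC:
            a = 2.0
        return ModelParams(noise=noise, boundary=PerceptualBoundaryParams(k=k, m=m, a=a))

    if spec.task == Task.DIFFERENT_MEANS:
        k1 = rng.uniform(1.0, 2.5)
        kd = k1 - np.concatenate([[0.0], np.cumsum(rng.uniform(0.3, 0.8, size=6))])
    else:
        k1 = rng.uniform(0.1, 0.6)
        kd = k1 - np.concatenate([[0.0], np.cumsum(rng.uniform(0.2, 0.8, size=6))])
    sigma_d = rng.uniform(0.15, 0.5) if spec.decision_noise else 0.0
    sub = {}
    if spec.free_prior:
        if spec.task == Task.DIFFERENT_MEANS:
            sub = dict(
                subjective_mu1=cp_std.mu1 * rng.uniform(0.75, 1.25),
                subjective_sigma1=cp_std.sigma1 * rng.uniform(0.75, 1.25),
            )
        else:
            s1 = cp_std.sigma1 * rng.uniform(0.75, 1.25)
            s2 = cp_std.sigma2 * rng.uniform(0.75, 1.25)
            s2 = max(s2, s1 * 1.05)
            sub = dict(subjective_sigma1=s1, subjective_sigma2=s2)
    return ModelParams(
        noise=noise, boundary=BayesBoundaryParams(k=kd, sigma_d=sigma_d, **sub)
    )


def exclude_by_accuracy(
    trials: pd.DataFrame,
    category_pair: CategoryPair | None = None,
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Quality-control test on highest-intensity categorisation accuracy.

    A response is correct when it matches the most probable generating
    category for the stimulus value.  One-sided exact binomial test of
    accuracy against chance (0.5) on highest-intensity trials; returns
    ``(keep, p_value)`` where ``keep`` is False (exclude) when p >= alpha.
    """
    task = Task(trials["task"].iloc[0])
    modality = Modality(trials["modality"].iloc[0])
    cp = category_pair or default_category_pair(task, modality)
    top = trials[trials["intensity"] == int(trials["intensity"].max())]
    if len(top) == 0:
        raise ConfigurationError("no highest-intensity trials present")
    ideal = np.asarray(ideal_category(top["s_raw"].to_numpy(), cp))
    n_correct = int((top["response_category"].to_numpy(dtype=int) == ideal).sum())
    p = binomtest(n_correct, len(top), 0.5, alternative="greater").pvalue
    return bool(p < alpha), float(p)
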