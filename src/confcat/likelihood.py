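"""Exact response probabilities and dataset log-likelihoods.

Response probabilities are Gaussian probability masses of the measurement
distribution N(z, sigma_i^2) between adjacent realized boundaries, computed by
differences of the normal CDF (no numerical integration).  For the
different-SDs task a region is the union of two intervals symmetric about the
centre, handled through the CDF of |x|.

The decision-noise Bayesian variant marginalises Gaussian noise on the
d-space boundaries with the 101-node quantile quadrature spanning the 1st to
99th percentile; corresponding draws are paired across boundaries (perfectly
correlated boundary noise) and weighted by the normal density at each node.

Trial data live in a pandas DataFrame, one row per trial, with columns
``participant, task, modality, s_raw, intensity, true_category,
response_category, confidence`` (plain delimited text on disk); the reader
validates ranges and adds the standardized value ``z`` and region index
``response_r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm

from .task_design import (
    CategoryPair,
    ConfigurationError,
    DegenerateInputError,
    Modality,
    Standardizer,
    Task,
    default_category_pair,
    fit_standardizer,
)
from .observer_models import (
    ModelFamily,
    ModelParams,
    ModelSpec,
    OrderingViolationError,
    _assemble_cuts,
    _check_ordering,
    bayes_perceptual_boundaries,
    effective_category_pair,
    index_from_region,
    n_boundaries,
)

__all__ = [
    "PROB_FLOOR",
    "N_DNOISE_DRAWS",
    "TRIAL_COLUMNS",
    "PreparedData",
    "prepare_dataset",
    "response_probability_matrix",
    "response_probabilities",
    "response_probabilities_dnoise",
    "dataset_loglik",
    "count_parameters",
    "read_trials",
    "write_trials",
    "attach_standardized",
]

#: Floor applied to per-trial response probabilities before taking logs.  The
#: models have no lapse process, so a single extreme observation would
#: otherwise contribute -inf; the floor is far below any realistic trial
#: probability and does not affect model ranking.
PROB_FLOOR = 1e-12

#: Number of quantile-quadrature nodes for the decision-noise marginalisation.
N_DNOISE_DRAWS = 101

TRIAL_COLUMNS = [
    "participant",
    "task",
    "modality",
    "s_raw",
    "intensity",
    "true_category",
    "response_category",
    "confidence",
]


@dataclass(frozen=True)
class PreparedData:
    """Arrays extracted from a trial table, ready for likelihood evaluation."""

    task: Task
    modality: Modality
    z: np.ndarray
    s_raw: np.ndarray
    intensity: np.ndarray  # 1..4
    response_r: np.ndarray  # 1..8
    cp_std: CategoryPair
    standardizer: Standardizer

    @property
    def n(self) -> int:
        return int(self.z.size)


def attach_standardized(
    trials: pd.DataFrame, standardizer: Optional[Standardizer] = None
) -> tuple[pd.DataFrame, Standardizer]:
    """Add/overwrite the z and response_r columns of a trial table.

    The standardizer defaults to the empirical mean/SD of all presented
    stimulus values in the table (one task-modality configuration at a time).
    """
    if standardizer is None:
        standardizer = fit_standardizer(trials["s_raw"].to_numpy())
    out = trials.copy()
    out["z"] = standardizer.transform(out["s_raw"].to_numpy())
    out["response_r"] = [
        index_from_region(int(c), int(f))
        for c, f in zip(out["response_category"], out["confidence"])
    ]
    return out, standardizer


def prepare_dataset(
    trials: pd.DataFrame,
    category_pair: Optional[CategoryPair] = None,
    standardizer: Optional[Standardizer] = None,
) -> PreparedData:
    """Validate a trial table and extract likelihood-ready arrays.

    All trials must share one task and one modality.  The category pair
    defaults to the canonical parameters for that configuration and is
    expressed on the standardized axis.
    """
    if len(trials) == 0:
        raise DegenerateInputError("empty trial set")
    tasks = set(trials["task"])
    modalities = set(trials["modality"])
    if len(tasks) != 1 or len(modalities) != 1:
        raise ConfigurationError("trials must share a single task and modality")
    task = Task(tasks.pop())
    modality = Modality(modalities.pop())
    intensity = trials["intensity"].to_numpy(dtype=int)
    if intensity.min() < 1 or intensity.max() > 4:
        raise ConfigurationError("intensity must be in 1..4")
    trials, standardizer = attach_standardized(trials, standardizer)
    if category_pair is None:
        category_pair = default_category_pair(task, modality)
    cp_std = standardizer.transform_pair(category_pair)
    return PreparedData(
        task=task,
        modality=modality,
        z=trials["z"].to_numpy(dtype=float),
        s_raw=trials["s_raw"].to_numpy(dtype=float),
        intensity=intensity,
        response_r=trials["response_r"].to_numpy(dtype=int),
        cp_std=cp_std,
        standardizer=standardizer,
    )


def _trial_sigmas(spec: ModelSpec, params: ModelParams, data: PreparedData) -> np.ndarray:
    """Per-trial measurement-noise SD in standardized units."""
    noise = params.noise
    idx = data.intensity - 1
    if not spec.odn:
        if noise.sigma_by_intensity is None:
            raise ConfigurationError("sigma_by_intensity required without ODN")
        return noise.sigma_by_intensity[idx]
    spec.validate_modality(data.modality)
    if noise.gamma_by_intensity is None:
        raise ConfigurationError("gamma_by_intensity required with ODN")
    sinus = np.abs(np.sin(np.pi * data.s_raw / 90.0))
    return (noise.gamma_by_intensity[idx] + noise.psi * sinus) / data.standardizer.sd


def _region_masses(z: np.ndarray, sigma: np.ndarray, cuts: np.ndarray, task: Task) -> np.ndarray:
    """Gaussian masses of the 8 regions; cuts broadcast against (n,) trials.

    ``cuts`` has trailing axis 7 and any leading axes broadcastable with z.
    Returns shape ``broadcast(cuts[..., 0], z).shape + (8,)``.
    """
    zs = z[..., None]
    ss = sigma[..., None]
    if task == Task.DIFFERENT_MEANS:
        F = ndtr((cuts - zs) / ss)
    else:
        # P(|x| < b) for each threshold; thresholds may include collapsed zeros
        F = ndtr((cuts - zs) / ss) - ndtr((-cuts - zs) / ss)
    shape = F.shape[:-1] + (1,)
    zeros = np.zeros(shape)
    ones = np.ones(shape)
    return np.diff(np.concatenate([zeros, F, ones], axis=-1), axis=-1)


def _nonbayes_cuts(spec: ModelSpec, params: ModelParams, sigma: np.ndarray) -> np.ndarray:
    pb = params.boundary
    if spec.family == ModelFamily.DISTANCE:
        b = np.broadcast_to(pb.k, sigma.shape + pb.k.shape)
    else:
        if spec.family == ModelFamily.LINEAR:
            a = 1.0
        elif spec.family == ModelFamily.QUADRATIC:
            a = 2.0
        else:
            a = pb.a
        b = pb.k + pb.m * sigma[..., None] ** a
    cuts = _assemble_cuts(spec.task, np.asarray(b, dtype=float))
    _check_ordering(spec.task, cuts)
    return cuts


def _dnoise_nodes(sigma_d: float, n_draws: int = N_DNOISE_DRAWS) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced offsets spanning the 1st..99th percentile, with
    density-proportional weights normalised to sum 1."""
    lo, hi = norm.ppf(0.01), norm.ppf(0.99)
    u = np.linspace(lo, hi, n_draws)
    w = norm.pdf(u)
    return u * sigma_d, w / w.sum()


def response_probability_matrix(
    spec: ModelSpec, params: ModelParams, data: PreparedData
) -> np.ndarray:
    """(n_trials, 8) matrix of response-region probabilities.

    Rows sum to 1 (the boundaries partition the real line).  Raises
    :class:`OrderingViolationError` when a non-Bayesian parameter set yields
    non-monotone realized boundaries at any fitted noise level; the fitter
    treats that as a rejection.
    """
    sigma = _trial_sigmas(spec, params, data)
    z = data.z
    if not spec.is_bayes:
        cuts = _nonbayes_cuts(spec, params, sigma)
        return _region_masses(z, sigma, cuts, spec.task)
    bp = params.boundary
    cp_eff = effective_category_pair(spec, params, data.cp_std)
    if spec.decision_noise and bp.sigma_d > 0:
        offsets, w = _dnoise_nodes(bp.sigma_d, N_DNOISE_DRAWS)
        kd = bp.k + offsets[:, None, None]  # (J, 1, 7)
        cuts = bayes_perceptual_boundaries(spec, kd, sigma, cp_eff)  # (J, n, 7)
        # region masses are linear in the boundary CDF values, so the
        # weighted mean over corresponding draws contracts before the diff
        zs = z[:, None]
        ss = sigma[:, None]
        np.subtract(cuts, zs, out=cuts)
        np.divide(cuts, ss, out=cuts)
        if spec.task == Task.DIFFERENT_MEANS:
            F = ndtr(cuts)
        else:
            # P(|x| < b): second term uses -b - z = -(b + z)
            F = ndtr(cuts)
            np.add(cuts, 2.0 * zs / ss, out=cuts)
            F -= ndtr(np.negative(cuts, out=cuts))
        G = np.tensordot(w, F, axes=(0, 0))  # (n, 7)
        pad = np.empty((z.size, 8))
        pad[:, 0] = G[:, 0]
        pad[:, 1:7] = np.diff(G, axis=-1)
        pad[:, 7] = 1.0 - G[:, -1]
        return pad
    cuts = bayes_perceptual_boundaries(spec, bp.k, sigma, cp_eff)
    return _region_masses(z, sigma, cuts, spec.task)


def _single_trial_data(trial, cp_std: CategoryPair, standardizer: Standardizer) -> PreparedData:
    return PreparedData(
        task=Task(trial["task"]),
        modality=Modality(trial["modality"]),
        z=np.atleast_1d(np.asarray(trial["z"], dtype=float)),
        s_raw=np.atleast_1d(np.asarray(trial["s_raw"], dtype=float)),
        intensity=np.atleast_1d(np.asarray(trial["intensity"], dtype=int)),
        response_r=np.atleast_1d(np.asarray(trial.get("response_r", 1), dtype=int)),
        cp_std=cp_std,
        standardizer=standardizer,
    )


def response_probabilities(
    trial, spec: ModelSpec, params: ModelParams,
    cp_std: CategoryPair, standardizer: Standardizer,
) -> np.ndarray:
    """Probabilities of the 8 responses for a single trial (mapping-like row)."""
    data = _single_trial_data(trial, cp_std, standardizer)
    return response_probability_matrix(spec, params, data)[0]


def response_probabilities_dnoise(
    trial, spec: ModelSpec, params: ModelParams,
    cp_std: CategoryPair, standardizer: Standardizer,
) -> np.ndarray:
    """Single-trial probabilities under the decision-noise marginalisation."""
    if not spec.decision_noise:
        raise ConfigurationError("spec does not include decision noise")
    return response_probabilities(trial, spec, params, cp_std, standardizer)


def loglik_from_matrix(probs: np.ndarray, response_r: np.ndarray) -> float:
    """Sum of floored log probabilities of the observed responses."""
    p = probs[np.arange(response_r.size), response_r - 1]
    return float(np.sum(np.log(np.maximum(p, PROB_FLOOR))))


def dataset_loglik(
    trials: pd.DataFrame | PreparedData,
    spec: ModelSpec,
    params: ModelParams,
    category_pair: Optional[CategoryPair] = None,
    standardizer: Optional[Standardizer] = None,
) -> float:
    """Log-likelihood of a dataset: sum over trials of log P(observed r).

    Each probability is floored at :data:`PROB_FLOOR` before the log.
    """
    data = (
        trials
        if isinstance(trials, PreparedData)
        else prepare_dataset(trials, category_pair, standardizer)
    )
    probs = response_probability_matrix(spec, params, data)
    return loglik_from_matrix(probs, data.response_r)


def count_parameters(
    spec: ModelSpec, task: Optional[Task | str] = None, cross_modal_mode: Optional[str] = None
) -> int:
    """Exact free-parameter count of a model.

    Noise contributes 4 sigmas, or 4 gammas + psi with ODN.  Non-Bayesian
    boundaries contribute 4 (different means) or 7 (different SDs) base
    positions, plus as many scale parameters for the scaled families, plus the
    exponent for the free-exponent family.  Bayesian models contribute 7
    d-space boundaries, +1 for decision noise, +2 for free category
    distribution parameters.  Cross-modal free-exponent modes follow their
    sharing rules (``common``, ``different_noise``, ``flexible``).
    """
    task = Task(task) if task is not None else spec.task
    nb = n_boundaries(task, spec.family)
    if cross_modal_mode is not None:
        if spec.family != ModelFamily.FREE_EXPONENT or spec.odn:
            raise ConfigurationError("cross-modal modes apply to the plain free-exponent model")
        single_shared = nb + nb + 1  # k, m, a
        if cross_modal_mode == "common":
            return 4 + single_shared
        if cross_modal_mode == "different_noise":
            return 8 + single_shared
        if cross_modal_mode == "flexible":
            return 2 * (4 + single_shared)
        raise ConfigurationError(f"unknown cross-modal mode {cross_modal_mode!r}")
    z = 5 if spec.odn else 4
    if spec.is_bayes:
        z += nb
        if spec.decision_noise:
            z += 1
        if spec.free_prior:
            z += 2
        return z
    z += nb
    if spec.family != ModelFamily.DISTANCE:
        z += nb
    if spec.family == ModelFamily.FREE_EXPONENT:
        z += 1
    return z


def read_trials(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited trial table, validate ranges, and standardize.

    The file must carry the :data:`TRIAL_COLUMNS` header.  The standardizer is
    fit per task-modality configuration present in the file.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"trial table missing columns: {missing}")
    for col, lo, hi in [
        ("intensity", 1, 4),
        ("true_category", 1, 2),
        ("response_category", 1, 2),
        ("confidence", 1, 4),
    ]:
        vals = df[col].to_numpy(dtype=int)
        if vals.min() < lo or vals.max() > hi:
            raise ConfigurationError(f"column {col} outside [{lo}, {hi}]")
    parts = []
    for _, group in df.groupby(["task", "modality"], sort=False):
        g, _ = attach_standardized(group)
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def write_trials(trials: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write the canonical trial columns as delimited text."""
    trials[TRIAL_COLUMNS].to_csv(path, sep=sep, index=False)
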