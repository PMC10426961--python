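"""Observer models: parameterisations, noise rules, decision variables, boundaries.

Every model partitions the standardized stimulus axis into eight response
regions, one per (category, confidence) combination.  The region index ``r``
runs 1..8: r = 1..4 are category-1 responses with confidence 4..1, r = 5..8
category-2 responses with confidence 1..4, so confidence grows with distance
from the category criterion on both sides.

Three classes are implemented:

* unscaled evidence strength (``distance``): perceptual boundaries fixed
  across sensory-uncertainty levels, b_r = k_r;
* scaled evidence strength (``linear``, ``quadratic``, ``free_exponent``):
  boundaries move with the estimated measurement-noise SD sigma,
  b_r(sigma) = k_r + m_r * sigma**a with a = 1, 2, or free in (1, 10];
* Bayesian (``bayes_lppr``): boundaries live in log-posterior-probability-ratio
  (d) space and are mapped into perceptual space at each sigma, optionally with
  Gaussian decision noise on d or free (subjective) category-distribution
  parameters.

In the different-means task the realized perceptual partition is the seven
cut-points (-b4, -b3, -b2, b1, b2, b3, b4); b1 is the (free) category
criterion and +-b2..b4 are symmetric confidence criteria.  In the
different-SDs task the partition is symmetric about the shared category mean
(b0 = 0 on the standardized axis): seven |x| thresholds b1 < ... < b7, with
|x| < b4 giving category 1 (the narrow central category).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .task_design import CategoryPair, ConfigurationError, Modality, Task

__all__ = [
    "ModelFamily",
    "ModelSpec",
    "NoiseParams",
    "PerceptualBoundaryParams",
    "BayesBoundaryParams",
    "ModelParams",
    "ResponseRegion",
    "OrderingViolationError",
    "N_INTENSITIES",
    "n_boundaries",
    "region_from_index",
    "index_from_region",
    "sigma_for_trial",
    "perceptual_boundaries",
    "lppr",
    "lppr_coefficients",
    "invert_lppr",
    "bayes_perceptual_boundaries",
    "response_region",
    "effective_category_pair",
]

N_INTENSITIES = 4
N_REGIONS = 8
_N_BAYES_BOUNDS = 7


class ModelFamily(str, Enum):
    DISTANCE = "distance"
    LINEAR = "linear"
    QUADRATIC = "quadratic"
    FREE_EXPONENT = "free_exponent"
    BAYES_LPPR = "bayes_lppr"


class OrderingViolationError(ValueError):
    """Realized boundaries are not strictly increasing at some sigma."""


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one model: family, task, and optional variant flags."""

    family: ModelFamily
    task: Task
    odn: bool = False
    decision_noise: bool = False
    free_prior: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ModelFamily(self.family))
        object.__setattr__(self, "task", Task(self.task))
        if (self.decision_noise or self.free_prior) and self.family != ModelFamily.BAYES_LPPR:
            raise ConfigurationError("decision_noise/free_prior require the bayes_lppr family")

    @property
    def is_bayes(self) -> bool:
        return self.family == ModelFamily.BAYES_LPPR

    @property
    def token(self) -> str:
        """Short string identity used in result tables and the CLI."""
        base = "bayes" if self.is_bayes else self.family.value
        flags = []
        if self.odn:
            flags.append("odn")
        if self.decision_noise:
            flags.append("dnoise")
        if self.free_prior:
            flags.append("prior")
        return "+".join([base] + flags)

    @classmethod
    def from_token(cls, token: str, task: Task | str) -> "ModelSpec":
        parts = token.split("+")
        base = parts[0]
        flags = set(parts[1:])
        family = ModelFamily.BAYES_LPPR if base == "bayes" else ModelFamily(base)
        return cls(
            family=family,
            task=Task(task),
            odn="odn" in flags,
            decision_noise="dnoise" in flags,
            free_prior="prior" in flags,
        )

    def validate_modality(self, modality: Modality | str) -> None:
        if self.odn and Modality(modality) != Modality.VISUAL:
            raise ConfigurationError("orientation-dependent noise is visual-only")


def n_boundaries(task: Task, family: ModelFamily = ModelFamily.DISTANCE) -> int:
    """Number of free boundary parameters for a task.

    Non-Bayesian models use 4 (different means: b1..b4) or 7 (different SDs:
    b1..b7); Bayesian models always use 7 d-space boundaries.
    """
    if family == ModelFamily.BAYES_LPPR:
        return _N_BAYES_BOUNDS
    return 4 if Task(task) == Task.DIFFERENT_MEANS else 7


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise parameters across the four intensity levels.

    ``sigma_by_intensity`` is indexed by intensity level 1..4 (position 0 is
    level 1, the weakest signal / largest noise) and must be non-increasing.
    With orientation-dependent noise (ODN, visual only), the per-intensity
    baseline ``gamma_by_intensity`` and sinusoid amplitude ``psi`` are in raw
    degrees: sigma(I, s) = gamma_I + psi * |sin(pi * s / 90)|, converted to
    standardized units by the configuration's standardizer SD.
    """

    sigma_by_intensity: Optional[np.ndarray] = None
    gamma_by_intensity: Optional[np.ndarray] = None
    psi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_by_intensity", "gamma_by_intensity"):
            v = getattr(self, name)
            if v is not None:
                arr = np.asarray(v, dtype=float)
                if arr.shape != (N_INTENSITIES,):
                    raise ConfigurationError(f"{name} must have {N_INTENSITIES} entries")
                if not np.all(arr > 0):
                    raise ConfigurationError(f"{name} must be positive")
                if np.any(np.diff(arr) > 0):
                    raise ConfigurationError(f"{name} must be non-increasing in intensity")
                object.__setattr__(self, name, arr)
        if self.psi < 0:
            raise ConfigurationError("psi must be non-negative")
        if self.sigma_by_intensity is None and self.gamma_by_intensity is None:
            raise ConfigurationError("either sigma_by_intensity or gamma_by_intensity required")


@dataclass(frozen=True)
class PerceptualBoundaryParams:
    """Non-Bayesian boundary parameters: b_r(sigma) = k_r + m_r * sigma**a.

    ``m`` is absent for the distance family (boundaries fixed at k) and is
    unconstrained in sign; validity of a parameter set is judged on the
    realized boundaries at the fitted sigma levels, not on k or m directly.
    """

    k: np.ndarray
    m: Optional[np.ndarray] = None
    a: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", np.asarray(self.k, dtype=float))
        if self.m is not None:
            m = np.asarray(self.m, dtype=float)
            if m.shape != self.k.shape:
                raise ConfigurationError("k and m must have the same length")
            object.__setattr__(self, "m", m)


@dataclass(frozen=True)
class BayesBoundaryParams:
    """Bayesian boundaries in d space, plus optional variant parameters.

    ``k`` holds 7 log-posterior-ratio boundaries, strictly decreasing in the
    response index (d favours category 1 when positive, so high-d regions are
    high-confidence category 1).  ``sigma_d`` is the decision-noise SD in d
    units.  The subjective generative-model fields replace the true category
    parameters in the free-prior variant (mu1/sigma1 for different means,
    sigma1/sigma2 for different SDs).
    """

    k: np.ndarray
    sigma_d: float = 0.0
    subjective_mu1: Optional[float] = None
    subjective_sigma1: Optional[float] = None
    subjective_sigma2: Optional[float] = None

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        if k.shape != (_N_BAYES_BOUNDS,):
            raise ConfigurationError(f"bayes k must have {_N_BAYES_BOUNDS} entries")
        if not np.all(np.diff(k) < 0):
            raise ConfigurationError("bayes k must be strictly decreasing in r")
        if self.sigma_d < 0:
            raise ConfigurationError("sigma_d must be non-negative")
        object.__setattr__(self, "k", k)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of one model: noise plus boundary parameters."""

    noise: NoiseParams
    boundary: PerceptualBoundaryParams | BayesBoundaryParams


@dataclass(frozen=True)
class ResponseRegion:
    """One of the eight category-confidence response regions."""

    r: int
    category: int
    confidence: int


def region_from_index(r: int) -> ResponseRegion:
    """Map region index 1..8 to its (category, confidence) pair."""
    if not 1 <= r <= N_REGIONS:
        raise ValueError(f"region index {r} outside 1..{N_REGIONS}")
    if r <= 4:
        return ResponseRegion(r=r, category=1, confidence=5 - r)
    return ResponseRegion(r=r, category=2, confidence=r - 4)


def index_from_region(category: int, confidence: int) -> int:
    """Inverse of :func:`region_from_index`."""
    if category not in (1, 2) or not 1 <= confidence <= 4:
        raise ValueError("category must be 1|2 and confidence 1..4")
    return 5 - confidence if category == 1 else 4 + confidence


def sigma_for_trial(
    noise: NoiseParams,
    intensity: int,
    s_deg: Optional[float] = None,
    odn: bool = False,
    sd_deg: Optional[float] = None,
) -> float:
    """Measurement-noise SD (standardized units) for one trial.

    Without ODN this is simply the fitted sigma at the trial's intensity.
    With ODN the rectified 2-cycle sinusoid of the raw orientation (degrees)
    is added to the intensity baseline and the result divided by the
    standardizer SD ``sd_deg`` to express it on the standardized axis.
    """
    if not 1 <= intensity <= N_INTENSITIES:
        raise ConfigurationError(f"intensity must be 1..{N_INTENSITIES}")
    if not odn:
        if noise.sigma_by_intensity is None:
            raise ConfigurationError("sigma_by_intensity required without ODN")
        return float(noise.sigma_by_intensity[intensity - 1])
    if s_deg is None or sd_deg is None:
        raise ConfigurationError("ODN requires the raw orientation and standardizer SD")
    if noise.gamma_by_intensity is None:
        raise ConfigurationError("gamma_by_intensity required with ODN")
    gamma = noise.gamma_by_intensity[intensity - 1]
    return float((gamma + noise.psi * abs(math.sin(math.pi * s_deg / 90.0))) / sd_deg)


def _exponent(spec: ModelSpec, pb: PerceptualBoundaryParams) -> float:
    if spec.family == ModelFamily.LINEAR:
        return 1.0
    if spec.family == ModelFamily.QUADRATIC:
        return 2.0
    return pb.a


def perceptual_boundaries(spec: ModelSpec, pb: PerceptualBoundaryParams, sigma) -> np.ndarray:
    """Realized non-Bayesian boundaries at a noise level.

    Returns the ordered 7-vector partitioning the standardized axis: the
    cut-points (-b4, -b3, -b2, b1, b2, b3, b4) for different means, or the
    |x| thresholds (b1..b7) for different SDs.  ``sigma`` may be a scalar or
    an array (leading axis), in which case the result has shape (..., 7).
    Raises :class:`OrderingViolationError` if the realized vector is not
    strictly increasing (different SDs additionally requires b1 > 0).
    """
    if spec.is_bayes:
        raise ConfigurationError("use bayes_perceptual_boundaries for Bayesian models")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ConfigurationError("sigma must be positive")
    if spec.family == ModelFamily.DISTANCE:
        b = np.broadcast_to(pb.k, sigma.shape + pb.k.shape).copy()
    else:
        if pb.m is None:
            raise ConfigurationError("scaled families require the m vector")
        b = pb.k + pb.m * sigma[..., None] ** _exponent(spec, pb)
    cuts = _assemble_cuts(spec.task, b)
    _check_ordering(spec.task, cuts)
    return cuts


def _assemble_cuts(task: Task, b: np.ndarray) -> np.ndarray:
    """Build the 7 ordered cut-points from the per-task boundary vector."""
    if task == Task.DIFFERENT_MEANS:
        if b.shape[-1] != 4:
            raise ConfigurationError("different_means uses 4 boundary parameters")
        b1, b2, b3, b4 = np.moveaxis(b, -1, 0)
        return np.stack([-b4, -b3, -b2, b1, b2, b3, b4], axis=-1)
    if b.shape[-1] != 7:
        raise ConfigurationError("different_sds uses 7 boundary parameters")
    return b


def _check_ordering(task: Task, cuts: np.ndarray) -> None:
    ok = np.all(np.diff(cuts, axis=-1) > 0)
    if task == Task.DIFFERENT_SDS:
        ok = ok and np.all(cuts[..., 0] > 0)
    if not ok:
        raise OrderingViolationError("realized boundaries are not strictly increasing")


def effective_category_pair(spec: ModelSpec, params: ModelParams, cp_std: CategoryPair) -> CategoryPair:
    """Category pair the (Bayesian) observer believes in, standardized units.

    Equal to the true standardized pair unless the model has free category
    distribution parameters, in which case the subjective values replace the
    task-relevant fields (mu1/sigma1 for different means, sigma1/sigma2 for
    different SDs; the different-means pair stays mean-symmetric).
    """
    if not (spec.is_bayes and spec.free_prior):
        return cp_std
    bp = params.boundary
    if spec.task == Task.DIFFERENT_MEANS:
        mu1 = bp.subjective_mu1 if bp.subjective_mu1 is not None else cp_std.mu1
        s1 = bp.subjective_sigma1 if bp.subjective_sigma1 is not None else cp_std.sigma1
        return CategoryPair(
            task=spec.task, modality=cp_std.modality,
            mu1=mu1, sigma1=s1, mu2=-mu1, sigma2=s1, prior1=cp_std.prior1,
        )
    s1 = bp.subjective_sigma1 if bp.subjective_sigma1 is not None else cp_std.sigma1
    s2 = bp.subjective_sigma2 if bp.subjective_sigma2 is not None else cp_std.sigma2
    return CategoryPair(
        task=spec.task, modality=cp_std.modality,
        mu1=cp_std.mu1, sigma1=s1, mu2=cp_std.mu2, sigma2=s2, prior1=cp_std.prior1,
    )


def lppr_coefficients(sigma, cp_std: CategoryPair, task: Task):
    """Coefficients of the closed-form log posterior probability ratio.

    For different means d = slope * x + lp0 with slope = 2*mu1/(sigma^2+sigma1^2);
    for different SDs d = A - B * x^2 with
    A = 0.5*log((sigma^2+sigma2^2)/(sigma^2+sigma1^2)) + lp0 and
    B = (sigma2^2-sigma1^2) / (2*(sigma^2+sigma1^2)*(sigma^2+sigma2^2)).
    lp0 is the log prior ratio log(p1/p2) (zero under equal priors).
    Broadcasts over ``sigma``.
    """
    sigma = np.asarray(sigma, dtype=float)
    lp0 = math.log(cp_std.prior1 / cp_std.prior2)
    v1 = sigma**2 + cp_std.sigma1**2
    if task == Task.DIFFERENT_MEANS:
        slope = 2.0 * cp_std.mu1 / v1
        return slope, lp0
    v2 = sigma**2 + cp_std.sigma2**2
    A = 0.5 * np.log(v2 / v1) + lp0
    B = (cp_std.sigma2**2 - cp_std.sigma1**2) / (2.0 * v1 * v2)
    return A, B


def lppr(x, sigma, cp_std: CategoryPair, spec: ModelSpec):
    """Log posterior probability ratio d = log p(C=1|x) / p(C=2|x).

    Task-specific closed form for a measurement x on the standardized axis at
    measurement-noise SD sigma; positive d favours category 1.  The
    different-means form assumes mean-symmetric standardized categories
    (mu2 = -mu1) and the different-SDs form equal means at 0, which the
    standardization of the balanced designs guarantees.
    """
    x = np.asarray(x, dtype=float)
    if spec.task == Task.DIFFERENT_MEANS:
        slope, lp0 = lppr_coefficients(sigma, cp_std, spec.task)
        out = slope * x + lp0
    else:
        A, B = lppr_coefficients(sigma, cp_std, spec.task)
        out = A - B * x**2
    return out if np.ndim(out) else float(out)


def invert_lppr(k_d: float, sigma: float, cp_std: CategoryPair, spec: ModelSpec):
    """Perceptual-space location of a d-space boundary at noise level sigma.

    Different means: the unique x with d(x) = k_d.  Different SDs: the
    non-negative |x| with d(|x|) = k_d, or ``None`` when k_d exceeds the
    maximum attainable d (the central region is then empty; its response has
    zero probability mass).
    """
    if not np.isfinite(k_d) or not np.isfinite(sigma):
        raise FloatingPointError("non-finite inputs to invert_lppr")
    if spec.task == Task.DIFFERENT_MEANS:
        slope, lp0 = lppr_coefficients(sigma, cp_std, spec.task)
        return float((k_d - lp0) / slope)
    A, B = lppr_coefficients(sigma, cp_std, spec.task)
    if k_d > A:
        return None
    return float(math.sqrt((A - k_d) / B))


def bayes_perceptual_boundaries(
    spec: ModelSpec, k_d: np.ndarray, sigma, cp_std: CategoryPair
) -> np.ndarray:
    """Map a strictly decreasing d-space boundary vector into perceptual space.

    Returns the same 7-vector convention as :func:`perceptual_boundaries`
    (different-means cut-points, or different-SDs |x| thresholds where
    unreachable boundaries collapse onto 0, leaving empty central regions).
    ``sigma`` and the trailing boundary axis broadcast: ``k_d`` may be shaped
    (..., 7) to carry decision-noise draws.
    """
    k_d = np.asarray(k_d, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if spec.task == Task.DIFFERENT_MEANS:
        if not cp_std.mu1 < 0:
            raise ConfigurationError(
                "different_means Bayesian models require the standardized mu1 < 0"
            )
        slope, lp0 = lppr_coefficients(sigma, cp_std, spec.task)
        return (k_d - lp0) / np.asarray(slope)[..., None]
    A, B = lppr_coefficients(sigma, cp_std, spec.task)
    arg = (np.asarray(A)[..., None] - k_d) / np.asarray(B)[..., None]
    return np.sqrt(np.clip(arg, 0.0, None))


def response_region(x: float, boundaries: np.ndarray, task: Task | str) -> ResponseRegion:
    """Deterministic region lookup for a measurement against realized boundaries.

    Intervals are half-open, closed on the left.  For the different-SDs task
    the lookup is on |x| (the partition is symmetric about the centre).
    """
    task = Task(task)
    boundaries = np.asarray(boundaries, dtype=float)
    v = x if task == Task.DIFFERENT_MEANS else abs(x)
    r = int(np.searchsorted(boundaries, v, side="right")) + 1
    return region_from_index(r)
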