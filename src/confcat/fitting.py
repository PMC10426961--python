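"""Maximum-likelihood fitting, information criteria, and model comparison.

Each model is fit by bounded local optimisation (L-BFGS-B) from ``n_starts``
seeded random initialisations, on a transformed parameter space in which the
hard constraints are box bounds:

* the measurement-noise SDs are the smallest sigma (intensity 4) plus
  non-negative increments toward intensity 1, enforcing the monotonicity
  constraint (higher intensity, less noise);
* Bayesian d-space boundaries are a first boundary plus negative gaps,
  enforcing strict decrease;
* the free exponent is fit as log(a - 1), keeping a in (1, 10].

Non-Bayesian base positions k and scales m are fit raw (m is sign-free);
ordering of the *realized* boundaries at every fitted sigma is enforced by a
penalty on the objective, so the optimum always satisfies the constraint and
violating parameter vectors are never returned.

Model comparison uses AIC = 2z - 2 logL and BIC = -2 logL + z log(n) per
participant; group sums add AIC across participants, while the group BIC sums
the likelihood terms and penalises the total parameter count against the total
trial count.  AIC is authoritative when AIC and BIC disagree on the preferred
model (it recovers models better in the recovery analyses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .task_design import CategoryPair, ConfigurationError, DegenerateInputError, Standardizer, Task
from .observer_models import (
    BayesBoundaryParams,
    ModelFamily,
    ModelParams,
    ModelSpec,
    NoiseParams,
    N_INTENSITIES,
    OrderingViolationError,
    PerceptualBoundaryParams,
    n_boundaries,
)
from .likelihood import (
    PreparedData,
    count_parameters,
    loglik_from_matrix,
    prepare_dataset,
    response_probability_matrix,
)

__all__ = [
    "FitResult",
    "ComparisonTable",
    "FittingError",
    "CROSS_MODAL_MODES",
    "fit_model",
    "information_criteria",
    "compare_models",
    "fit_cross_modal",
    "fit_cross_modal_suite",
    "core_model_tokens",
]

CROSS_MODAL_MODES = ("common", "different_noise", "flexible")

# Documented initialisation ranges (standardized units); see docs/methods.md.
_SIGMA_INIT = (0.2, 8.0)
_SIGMA_BOUNDS = (0.01, 10.0)
_SIGMA_INC_BOUNDS = (0.0, 10.0)
_KM_BOUNDS = (-40.0, 40.0)
_A_INIT = (1.1, 4.0)
_LOG_A_BOUNDS = (math.log(1e-6), math.log(9.0))
_KD_FIRST_BOUNDS = (-20.0, 20.0)
_KD_GAP_BOUNDS = (1e-3, 10.0)
_SIGMA_D_BOUNDS = (0.0, 5.0)
_PENALTY = 1e8


class FittingError(RuntimeError):
    """All optimizer starts failed to produce a valid fit."""


def information_criteria(loglik: float, z: int, n: int) -> tuple[float, float]:
    """Per-participant AIC and BIC from a log-likelihood."""
    if n < 1 or z < 0:
        raise ValueError("need n >= 1 and z >= 0")
    aic = 2.0 * z - 2.0 * loglik
    bic = -2.0 * loglik + z * math.log(n)
    return aic, bic


def _sigma_to_increments(sigmas: np.ndarray) -> np.ndarray:
    """(sigma1..sigma4 non-increasing) -> (base=sigma4, inc3, inc2, inc1)."""
    s = np.asarray(sigmas, dtype=float)
    return np.array([s[3], s[2] - s[3], s[1] - s[2], s[0] - s[1]])


def _increments_to_sigma(t: np.ndarray) -> np.ndarray:
    base, i3, i2, i1 = t
    s4 = base
    s3 = s4 + i3
    s2 = s3 + i2
    s1 = s2 + i1
    return np.array([s1, s2, s3, s4])


class _Packer:
    """Transforms between the optimizer vector and a :class:`ModelParams`.

    Built per (spec, task, standardizer SD, standardized category pair); all
    hard constraints except realized-boundary ordering are box bounds here.
    """

    def __init__(self, spec: ModelSpec, cp_std: CategoryPair, sd_deg: float):
        self.spec = spec
        self.cp_std = cp_std
        self.sd_deg = sd_deg
        self.nb = n_boundaries(spec.task, spec.family)
        bounds: list[tuple[float, float]] = []
        scale = sd_deg if spec.odn else 1.0
        bounds.append((_SIGMA_BOUNDS[0] * scale, _SIGMA_BOUNDS[1] * scale))
        bounds += [(0.0, _SIGMA_INC_BOUNDS[1] * scale)] * 3
        if spec.odn:
            bounds.append((0.0, 5.0 * sd_deg))  # psi
        if not spec.is_bayes:
            bounds += [_KM_BOUNDS] * self.nb  # k
            if spec.family != ModelFamily.DISTANCE:
                bounds += [_KM_BOUNDS] * self.nb  # m
            if spec.family == ModelFamily.FREE_EXPONENT:
                bounds.append(_LOG_A_BOUNDS)
        else:
            bounds.append(_KD_FIRST_BOUNDS)
            bounds += [_KD_GAP_BOUNDS] * (self.nb - 1)
            if spec.decision_noise:
                bounds.append(_SIGMA_D_BOUNDS)
            if spec.free_prior:
                if spec.task == Task.DIFFERENT_MEANS:
                    bounds.append((-10.0, -1e-3))  # subjective mu1 (< 0)
                    bounds.append((0.02, 5.0))  # subjective sigma1
                else:
                    bounds.append((0.01, 3.0))  # subjective sigma1
                    bounds.append((1e-3, 8.0))  # sigma2 - sigma1
        self.bounds = bounds

    @property
    def n_params(self) -> int:
        return len(self.bounds)

    # -- noise block ------------------------------------------------------
    def _unpack_noise(self, t: np.ndarray) -> tuple[NoiseParams, int]:
        sig = _increments_to_sigma(t[:4])
        if self.spec.odn:
            return NoiseParams(gamma_by_intensity=sig, psi=float(t[4])), 5
        return NoiseParams(sigma_by_intensity=sig), 4

    def _init_noise(self, rng: np.random.Generator) -> list[float]:
        scale = self.sd_deg if self.spec.odn else 1.0
        sig = np.sort(rng.uniform(*_SIGMA_INIT, size=N_INTENSITIES))[::-1] * scale
        out = list(_sigma_to_increments(sig))
        if self.spec.odn:
            out.append(rng.uniform(0.0, 1.0) * self.sd_deg)
        return out

    # -- boundary blocks --------------------------------------------------
    def unpack(self, t: np.ndarray) -> ModelParams:
        t = np.asarray(t, dtype=float)
        noise, i = self._unpack_noise(t)
        spec = self.spec
        if not spec.is_bayes:
            k = t[i : i + self.nb]
            i += self.nb
            m = None
            a = 1.0
            if spec.family != ModelFamily.DISTANCE:
                m = t[i : i + self.nb]
                i += self.nb
            if spec.family == ModelFamily.FREE_EXPONENT:
                a = 1.0 + math.exp(t[i])
                i += 1
            return ModelParams(noise=noise, boundary=PerceptualBoundaryParams(k=k, m=m, a=a))
        kd = t[i] - np.concatenate([[0.0], np.cumsum(t[i + 1 : i + self.nb])])
        i += self.nb
        sigma_d = 0.0
        sub = {}
        if spec.decision_noise:
            sigma_d = float(t[i])
            i += 1
        if spec.free_prior:
            if spec.task == Task.DIFFERENT_MEANS:
                sub = dict(subjective_mu1=float(t[i]), subjective_sigma1=float(t[i + 1]))
            else:
                sub = dict(
                    subjective_sigma1=float(t[i]),
                    subjective_sigma2=float(t[i] + t[i + 1]),
                )
            i += 2
        return ModelParams(
            noise=noise, boundary=BayesBoundaryParams(k=kd, sigma_d=sigma_d, **sub)
        )

    def pack(self, params: ModelParams) -> np.ndarray:
        """Inverse of :meth:`unpack` (used for warm starts)."""
        spec = self.spec
        noise = params.noise
        sig = noise.gamma_by_intensity if spec.odn else noise.sigma_by_intensity
        t = list(_sigma_to_increments(sig))
        if spec.odn:
            t.append(noise.psi)
        b = params.boundary
        if not spec.is_bayes:
            t += list(np.asarray(b.k, dtype=float))
            if spec.family != ModelFamily.DISTANCE:
                t += list(np.asarray(b.m, dtype=float))
            if spec.family == ModelFamily.FREE_EXPONENT:
                t.append(math.log(max(b.a - 1.0, 1e-6)))
        else:
            t.append(float(b.k[0]))
            t += list(-np.diff(b.k))
            if spec.decision_noise:
                t.append(b.sigma_d)
            if spec.free_prior:
                if spec.task == Task.DIFFERENT_MEANS:
                    t += [b.subjective_mu1, b.subjective_sigma1]
                else:
                    t += [b.subjective_sigma1, b.subjective_sigma2 - b.subjective_sigma1]
        vec = np.asarray(t, dtype=float)
        lo = np.array([b_[0] for b_ in self.bounds])
        hi = np.array([b_[1] for b_ in self.bounds])
        return np.clip(vec, lo, hi)

    def _clip(self, vec: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(np.asarray(vec, dtype=float), lo, hi)

    def data_start(self, data: PreparedData, rng: np.random.Generator) -> np.ndarray:
        """Jittered start with boundaries near the response-frequency
        quantiles of the data, which keeps the initial boundaries inside the
        measurement mass and away from probability-floor plateaus."""
        spec = self.spec
        sig = np.array([1.8, 1.3, 0.95, 0.7]) * rng.uniform(0.6, 1.6)
        counts = np.bincount(data.response_r, minlength=9)[1:]
        cum = np.cumsum(counts)[:-1] / counts.sum()
        cum = np.clip(cum + np.arange(7) * 1e-4, 0.01, 0.99)
        cum = np.maximum.accumulate(cum + np.linspace(0, 1e-3, 7))
        if not spec.is_bayes:
            v = data.z if spec.task == Task.DIFFERENT_MEANS else np.abs(data.z)
            q = np.quantile(v, cum)
            jit = 1.0 + rng.uniform(-0.15, 0.15, size=7)
            q = np.sort(q * jit + rng.uniform(-0.05, 0.05, size=7))
            if spec.task == Task.DIFFERENT_MEANS:
                k = np.array([
                    q[3],
                    max((q[4] - q[2]) / 2, abs(q[3]) + 0.05),
                    0.0, 0.0,
                ])
                k[2] = max((q[5] - q[1]) / 2, k[1] + 0.05)
                k[3] = max((q[6] - q[0]) / 2, k[2] + 0.05)
            else:
                k = np.maximum.accumulate(np.maximum(q, 0.01) + np.linspace(0, 1e-3, 7))
            t = list(_sigma_to_increments(sig * (self.sd_deg if spec.odn else 1.0)))
            if spec.odn:
                t.append(rng.uniform(0.0, 0.5) * self.sd_deg)
            t += list(k)
            if spec.family != ModelFamily.DISTANCE:
                t += list(rng.uniform(0.02, 0.3) * (1.0 + np.arange(self.nb)))
            if spec.family == ModelFamily.FREE_EXPONENT:
                t.append(math.log(rng.uniform(*_A_INIT) - 1.0))
            return self._clip(t)
        from .observer_models import lppr

        sigma_tr = sig[data.intensity - 1]
        d = np.asarray(lppr(data.z, sigma_tr, self.cp_std, spec))
        kd = np.quantile(d, 1.0 - cum)
        kd = np.minimum.accumulate(kd - np.linspace(0, 1e-3, 7))
        t = list(_sigma_to_increments(sig * (self.sd_deg if spec.odn else 1.0)))
        if spec.odn:
            t.append(rng.uniform(0.0, 0.5) * self.sd_deg)
        t.append(kd[0])
        t += list(np.maximum(-np.diff(kd), _KD_GAP_BOUNDS[0] * 2))
        if spec.decision_noise:
            t.append(rng.uniform(0.05, 0.6))
        if spec.free_prior:
            if spec.task == Task.DIFFERENT_MEANS:
                t += [self.cp_std.mu1 * rng.uniform(0.8, 1.2),
                      self.cp_std.sigma1 * rng.uniform(0.8, 1.2)]
            else:
                t += [self.cp_std.sigma1 * rng.uniform(0.8, 1.2),
                      (self.cp_std.sigma2 - self.cp_std.sigma1) * rng.uniform(0.8, 1.2)]
        return self._clip(t)

    def sample_init(self, rng: np.random.Generator) -> np.ndarray:
        spec = self.spec
        t = self._init_noise(rng)
        if not spec.is_bayes:
            if spec.task == Task.DIFFERENT_MEANS:
                k1 = rng.uniform(-0.5, 0.5)
                k = [k1, abs(k1) + rng.uniform(0.1, 1.5)]
                k.append(k[-1] + rng.uniform(0.1, 2.0))
                k.append(k[-1] + rng.uniform(0.1, 2.5))
            else:
                k = [rng.uniform(0.02, 0.4)]
                for _ in range(6):
                    k.append(k[-1] + rng.uniform(0.05, 1.5))
            t += k
            if spec.family != ModelFamily.DISTANCE:
                m = [rng.uniform(0.0, 0.6)]
                for _ in range(self.nb - 1):
                    m.append(m[-1] + rng.uniform(0.0, 0.8))
                t += m
            if spec.family == ModelFamily.FREE_EXPONENT:
                t.append(math.log(rng.uniform(*_A_INIT) - 1.0))
        else:
            t.append(rng.uniform(0.3, 2.5))
            t += list(rng.uniform(0.15, 1.2, size=self.nb - 1))
            if spec.decision_noise:
                t.append(rng.uniform(0.05, 0.8))
            if spec.free_prior:
                if spec.task == Task.DIFFERENT_MEANS:
                    t.append(self.cp_std.mu1 * rng.uniform(0.7, 1.3))
                    t.append(self.cp_std.sigma1 * rng.uniform(0.7, 1.3))
                else:
                    t.append(self.cp_std.sigma1 * rng.uniform(0.7, 1.3))
                    t.append((self.cp_std.sigma2 - self.cp_std.sigma1) * rng.uniform(0.7, 1.3))
        vec = np.asarray(t, dtype=float)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(vec, lo, hi)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    spec: ModelSpec
    params: ModelParams | dict
    theta_hat: np.ndarray
    loglik: float
    z: int
    n: int
    aic: float
    bic: float
    n_starts: int
    converged_starts: int
    seed: int
    cross_modal_mode: Optional[str] = None

    @property
    def token(self) -> str:
        if self.cross_modal_mode is not None:
            return f"{self.spec.token}[{self.cross_modal_mode}]"
        return self.spec.token


def _negloglik(spec: ModelSpec, params: ModelParams, data: PreparedData) -> float:
    try:
        probs = response_probability_matrix(spec, params, data)
    except OrderingViolationError:
        return math.nan
    return -loglik_from_matrix(probs, data.response_r)


def _objective_factory(spec, packer: _Packer, datasets: Sequence[PreparedData]):
    def objective(t: np.ndarray) -> float:
        params = packer.unpack(t)
        total = 0.0
        for data in datasets:
            nll = _negloglik(spec, params, data)
            if math.isnan(nll):
                return _PENALTY * (1.0 + _ordering_violation(spec, params, data))
            total += nll
        return total

    return objective


def _ordering_violation(spec: ModelSpec, params: ModelParams, data: PreparedData) -> float:
    """Magnitude of the realized-boundary ordering violation (0 when valid)."""
    from .likelihood import _nonbayes_cuts, _trial_sigmas  # non-Bayes only

    sigma = _trial_sigmas(spec, params, data)
    pb = params.boundary
    if spec.family == ModelFamily.DISTANCE:
        b = np.broadcast_to(pb.k, sigma.shape + pb.k.shape)
    else:
        a = {"linear": 1.0, "quadratic": 2.0}.get(spec.family.value, pb.a)
        b = pb.k + pb.m * sigma[..., None] ** a
    from .observer_models import _assemble_cuts

    cuts = _assemble_cuts(spec.task, np.asarray(b, dtype=float))
    viol = float(np.sum(np.clip(-np.diff(cuts, axis=-1), 0.0, None)))
    if spec.task == Task.DIFFERENT_SDS:
        viol += float(np.sum(np.clip(-cuts[..., 0], 0.0, None)))
    return viol


def _build_starts(
    packer, n_starts: int, rng: np.random.Generator,
    extra_starts: Sequence[np.ndarray], data: Optional[PreparedData] = None,
) -> list[np.ndarray]:
    """Random starts, mixed ~half/half with data-driven quantile starts."""
    starts = [np.asarray(s, dtype=float) for s in extra_starts]
    n_data = (n_starts + 1) // 2 if data is not None and hasattr(packer, "data_start") else 0
    starts += [packer.data_start(data, rng) for _ in range(n_data)]
    starts += [packer.sample_init(rng) for _ in range(n_starts - n_data)]
    return starts


def _run_starts(
    objective, packer, n_starts: int, seed: int,
    extra_starts: Sequence[np.ndarray], ftol: float, maxfun: int,
    data: Optional[PreparedData] = None,
):
    rng = np.random.default_rng(seed)
    starts = _build_starts(packer, n_starts, rng, extra_starts, data)
    best = None
    converged = 0
    for t0 in starts:
        res = minimize(
            objective,
            t0,
            method="L-BFGS-B",
            bounds=packer.bounds,
            options={"ftol": ftol, "maxfun": maxfun},
        )
        # res.fun can disagree with f(res.x) after abnormal line-search
        # termination; re-evaluate so the reported optimum is exact
        res.fun = objective(res.x)
        valid = res.fun < _PENALTY / 2
        if valid and res.success:
            converged += 1
        if valid and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FittingError(
            f"all {len(starts)} starts failed for {packer.spec.token}; "
            "no valid parameter vector found"
        )
    return best, converged, len(starts)


def fit_model(
    trials: pd.DataFrame | PreparedData,
    spec: ModelSpec,
    *,
    category_pair: Optional[CategoryPair] = None,
    standardizer: Optional[Standardizer] = None,
    n_starts: int = 20,
    seed: int = 0,
    extra_starts: Sequence[np.ndarray] = (),
    ftol: float = 1e-6,
    maxfun: int = 3000,
) -> FitResult:
    """Maximum-likelihood fit of one model to one participant-configuration.

    Runs ``n_starts`` seeded random initialisations (plus any ``extra_starts``
    in optimizer space, e.g. embedded solutions of nested models) and returns
    the incumbent; deterministic given ``seed``.
    """
    data = (
        trials
        if isinstance(trials, PreparedData)
        else prepare_dataset(trials, category_pair, standardizer)
    )
    spec.validate_modality(data.modality)
    if spec.task != data.task:
        raise ConfigurationError("model task does not match the data's task")
    packer = _Packer(spec, data.cp_std, data.standardizer.sd)
    objective = _objective_factory(spec, packer, [data])
    if spec.decision_noise:
        # coarse-to-fine continuation: multi-start on a 21-node quadrature,
        # then polish the incumbent (and any warm starts) at full resolution
        import confcat.likelihood as _lik

        full = _lik.N_DNOISE_DRAWS
        try:
            _lik.N_DNOISE_DRAWS = 21
            coarse, converged, total = _run_starts(
                objective, packer, n_starts, seed, extra_starts, ftol, maxfun, data=data
            )
        finally:
            _lik.N_DNOISE_DRAWS = full
        polish_starts = [coarse.x] + [np.asarray(s, dtype=float) for s in extra_starts]
        best, conv_fine, n_fine = _run_starts(
            objective, packer, 0, seed, polish_starts, ftol, maxfun
        )
        converged = conv_fine
        total += n_fine
    else:
        best, converged, total = _run_starts(
            objective, packer, n_starts, seed, extra_starts, ftol, maxfun, data=data
        )
    params = packer.unpack(best.x)
    loglik = -float(best.fun)
    z = count_parameters(spec)
    aic, bic = information_criteria(loglik, z, data.n)
    return FitResult(
        spec=spec, params=params, theta_hat=np.asarray(best.x, dtype=float),
        loglik=loglik, z=z, n=data.n, aic=aic, bic=bic,
        n_starts=total, converged_starts=converged, seed=seed,
    )


@dataclass(frozen=True)
class ComparisonTable:
    """Per-participant fits for a model set, with group-level criteria."""

    fits: Mapping[str, Mapping[str, FitResult]]  # participant -> token -> fit
    summary: pd.DataFrame  # one row per model token
    per_participant: pd.DataFrame  # one row per participant x model

    @property
    def preferred_counts(self) -> pd.Series:
        return self.summary["n_preferred"]

    def best_model(self, criterion: str = "aic") -> str:
        col = {"aic": "aic_sum", "bic": "bic_sum"}[criterion]
        return str(self.summary[col].idxmin())


def _preferred_token(row_fits: Mapping[str, FitResult], criterion: str = "aic") -> str:
    # lowest criterion; ties broken by smaller parameter count, then token
    def key(item):
        token, fit = item
        value = fit.aic if criterion == "aic" else fit.bic
        return (round(value, 9), fit.z, token)

    return min(row_fits.items(), key=key)[0]


def compare_models(
    fits: Mapping[str, Mapping[str, FitResult]], criterion: str = "aic"
) -> ComparisonTable:
    """Aggregate per-participant fits into group AIC/BIC sums and counts.

    ``fits`` maps participant id -> model token -> :class:`FitResult`; every
    participant must have a fit for every model.  The per-participant
    preferred model uses the lowest AIC (authoritative on AIC/BIC
    disagreement) unless ``criterion='bic'`` is requested explicitly.
    """
    participants = list(fits)
    if not participants:
        raise DegenerateInputError("no fits supplied")
    tokens = sorted(fits[participants[0]])
    for p in participants:
        if sorted(fits[p]) != tokens:
            missing = set(tokens) ^ set(fits[p])
            raise ConfigurationError(f"incomplete comparison: participant {p} differs on {missing}")
    rows = []
    for p in participants:
        preferred = _preferred_token(fits[p], criterion)
        for token in tokens:
            f = fits[p][token]
            rows.append(
                dict(
                    participant=p, model=token, loglik=f.loglik, z=f.z, n=f.n,
                    aic=f.aic, bic=f.bic, preferred=(token == preferred),
                )
            )
    per = pd.DataFrame(rows)
    summary_rows = []
    for token in tokens:
        sub = per[per["model"] == token]
        zB = int(sub["z"].sum())
        nB = int(sub["n"].sum())
        bic_sum = float((-2.0 * sub["loglik"]).sum() + zB * math.log(nB))
        summary_rows.append(
            dict(
                model=token,
                aic_sum=float(sub["aic"].sum()),
                bic_sum=bic_sum,
                n_preferred=int(sub["preferred"].sum()),
            )
        )
    summary = pd.DataFrame(summary_rows).set_index("model")
    return ComparisonTable(fits=fits, summary=summary, per_participant=per)


class _JointPacker:
    """Packer for cross-modal free-exponent fits with shared parameters."""

    def __init__(self, mode: str, packer_v: _Packer, packer_a: _Packer):
        if mode not in ("common", "different_noise"):
            raise ConfigurationError(f"joint packing undefined for mode {mode!r}")
        self.mode = mode
        self.pv = packer_v
        self.pa = packer_a
        self.nb = packer_v.nb
        shared = [_KM_BOUNDS] * (2 * self.nb) + [_LOG_A_BOUNDS]
        noise = [(_SIGMA_BOUNDS[0], _SIGMA_BOUNDS[1])] + [(0.0, _SIGMA_INC_BOUNDS[1])] * 3
        self.bounds = (noise if mode == "common" else noise + noise) + shared
        self.spec = packer_v.spec

    @property
    def n_noise(self) -> int:
        return 4 if self.mode == "common" else 8

    def unpack(self, t: np.ndarray) -> tuple[ModelParams, ModelParams]:
        t = np.asarray(t, dtype=float)
        noise_v = NoiseParams(sigma_by_intensity=_increments_to_sigma(t[:4]))
        if self.mode == "common":
            noise_a = noise_v
        else:
            noise_a = NoiseParams(sigma_by_intensity=_increments_to_sigma(t[4:8]))
        i = self.n_noise
        k = t[i : i + self.nb]
        m = t[i + self.nb : i + 2 * self.nb]
        a = 1.0 + math.exp(t[i + 2 * self.nb])
        bnd = PerceptualBoundaryParams(k=k, m=m, a=a)
        return ModelParams(noise=noise_v, boundary=bnd), ModelParams(noise=noise_a, boundary=bnd)

    def sample_init(self, rng: np.random.Generator) -> np.ndarray:
        base = self.pv.sample_init(rng)
        noise = list(base[:4])
        if self.mode == "different_noise":
            noise += list(self.pa.sample_init(rng)[:4])
        return np.asarray(noise + list(base[4:]), dtype=float)

    def data_start(self, data: PreparedData, rng: np.random.Generator) -> np.ndarray:
        base = self.pv.data_start(data, rng)
        noise = list(base[:4])
        if self.mode == "different_noise":
            noise += noise
        return np.asarray(noise + list(base[4:]), dtype=float)

    def embed(self, params: ModelParams) -> np.ndarray:
        """Warm start from a single-modality (or common-mode) solution."""
        t = list(_sigma_to_increments(params.noise.sigma_by_intensity))
        if self.mode == "different_noise":
            t = t + t
        b = params.boundary
        t += list(b.k) + list(b.m) + [math.log(max(b.a - 1.0, 1e-6))]
        vec = np.asarray(t, dtype=float)
        lo = np.array([x[0] for x in self.bounds])
        hi = np.array([x[1] for x in self.bounds])
        return np.clip(vec, lo, hi)


def fit_cross_modal(
    trials_visual: pd.DataFrame | PreparedData,
    trials_auditory: pd.DataFrame | PreparedData,
    mode: str,
    *,
    n_starts: int = 20,
    seed: int = 0,
    extra_starts: Sequence[np.ndarray] = (),
    ftol: float = 1e-6,
    maxfun: int = 4000,
) -> FitResult:
    """Fit the free-exponent model to both modalities simultaneously.

    ``common`` shares the noise SDs and all boundary parameters across
    modalities; ``different_noise`` frees the noise SDs per modality but
    shares (k, m, a); ``flexible`` frees everything, and is computed as the
    two independent single-modality fits (their optimum coincides with the
    joint one).  Standardization and category parameters are per modality.
    """
    if mode not in CROSS_MODAL_MODES:
        raise ConfigurationError(f"unknown cross-modal mode {mode!r}")
    dv = (
        trials_visual
        if isinstance(trials_visual, PreparedData)
        else prepare_dataset(trials_visual)
    )
    da = (
        trials_auditory
        if isinstance(trials_auditory, PreparedData)
        else prepare_dataset(trials_auditory)
    )
    if dv.task != da.task:
        raise ConfigurationError("cross-modal fits require both datasets to share the task")
    spec = ModelSpec(family=ModelFamily.FREE_EXPONENT, task=dv.task)
    n = dv.n + da.n
    z = count_parameters(spec, dv.task, cross_modal_mode=mode)

    if mode == "flexible":
        ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
        fv = fit_model(dv, spec, n_starts=n_starts, seed=int(ss[0]), ftol=ftol, maxfun=maxfun)
        fa = fit_model(da, spec, n_starts=n_starts, seed=int(ss[1]), ftol=ftol, maxfun=maxfun)
        loglik = fv.loglik + fa.loglik
        aic, bic = information_criteria(loglik, z, n)
        return FitResult(
            spec=spec, params={"visual": fv.params, "auditory": fa.params},
            theta_hat=np.concatenate([fv.theta_hat, fa.theta_hat]),
            loglik=loglik, z=z, n=n, aic=aic, bic=bic,
            n_starts=fv.n_starts + fa.n_starts,
            converged_starts=fv.converged_starts + fa.converged_starts,
            seed=seed, cross_modal_mode=mode,
        )

    pv = _Packer(spec, dv.cp_std, dv.standardizer.sd)
    pa = _Packer(spec, da.cp_std, da.standardizer.sd)
    joint = _JointPacker(mode, pv, pa)

    def objective(t: np.ndarray) -> float:
        params_v, params_a = joint.unpack(t)
        total = 0.0
        for params, data in ((params_v, dv), (params_a, da)):
            nll = _negloglik(spec, params, data)
            if math.isnan(nll):
                return _PENALTY * (1.0 + _ordering_violation(spec, params, data))
            total += nll
        return total

    best, converged, total_starts = _run_starts(
        objective, joint, n_starts, seed, extra_starts, ftol, maxfun, data=dv
    )
    params_v, params_a = joint.unpack(best.x)
    loglik = -float(best.fun)
    aic, bic = information_criteria(loglik, z, n)
    return FitResult(
        spec=spec, params={"visual": params_v, "auditory": params_a},
        theta_hat=np.asarray(best.x, dtype=float),
        loglik=loglik, z=z, n=n, aic=aic, bic=bic,
        n_starts=total_starts, converged_starts=converged,
        seed=seed, cross_modal_mode=mode,
    )


def fit_cross_modal_suite(
    trials_visual, trials_auditory, *, n_starts: int = 20, seed: int = 0, **kw
) -> dict[str, FitResult]:
    """Fit all three sharing modes, warm-starting each from the more
    constrained mode's solution so the nesting hierarchy is respected."""
    dv = (
        trials_visual
        if isinstance(trials_visual, PreparedData)
        else prepare_dataset(trials_visual)
    )
    da = (
        trials_auditory
        if isinstance(trials_auditory, PreparedData)
        else prepare_dataset(trials_auditory)
    )
    common = fit_cross_modal(dv, da, "common", n_starts=n_starts, seed=seed, **kw)
    spec = common.spec
    pv = _Packer(spec, dv.cp_std, dv.standardizer.sd)
    pa = _Packer(spec, da.cp_std, da.standardizer.sd)
    dn_joint = _JointPacker("different_noise", pv, pa)
    dn = fit_cross_modal(
        dv, da, "different_noise", n_starts=n_starts, seed=seed + 1,
        extra_starts=[dn_joint.embed(common.params["visual"])], **kw
    )
    # flexible: two independent fits, warm-started from the shared solution
    ss = np.random.SeedSequence(seed + 2).generate_state(2) % (2**31)
    fv = fit_model(
        dv, spec, n_starts=n_starts, seed=int(ss[0]),
        extra_starts=[pv.pack(dn.params["visual"])], **kw
    )
    fa = fit_model(
        da, spec, n_starts=n_starts, seed=int(ss[1]),
        extra_starts=[pa.pack(dn.params["auditory"])], **kw
    )
    z = count_parameters(spec, dv.task, cross_modal_mode="flexible")
    loglik = fv.loglik + fa.loglik
    n = dv.n + da.n
    aic, bic = information_criteria(loglik, z, n)
    flexible = FitResult(
        spec=spec, params={"visual": fv.params, "auditory": fa.params},
        theta_hat=np.concatenate([fv.theta_hat, fa.theta_hat]),
        loglik=loglik, z=z, n=n, aic=aic, bic=bic,
        n_starts=fv.n_starts + fa.n_starts,
        converged_starts=fv.converged_starts + fa.converged_starts,
        seed=seed + 2, cross_modal_mode="flexible",
    )
    return {"common": common, "different_noise": dn, "flexible": flexible}


def core_model_tokens(modality) -> list[str]:
    """The core model set for one modality (ODN variants are visual-only)."""
    from .task_design import Modality

    if Modality(modality) == Modality.VISUAL:
        return [
            "distance", "linear", "quadratic", "free_exponent", "free_exponent+odn",
            "bayes", "bayes+odn", "bayes+dnoise", "bayes+prior",
        ]
    return [
        "distance", "linear", "quadratic", "free_exponent",
        "bayes", "bayes+dnoise", "bayes+prior",
    ]
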