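"""Model-recovery (confusability) and parameter-recovery studies.

Model recovery: for each generating model, draw generating parameters,
simulate a balanced session, fit every candidate model, and record which one
wins by the chosen information criterion; aggregating over datasets gives the
confusability matrix (rows: generating model; columns: selecting model).
Distinguishable models show diagonal dominance.

Parameter recovery: simulate-fit loops under a single model, reporting the
correlation between generating and recovered values for every named
parameter.

Default problem sizes are desk scale (20 datasets of 360 trials, 10 optimizer
starts); the full-scale analysis (100 datasets of 720 trials) is reachable
through the same arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task_design import ConfigurationError, Modality, Task
from .observer_models import ModelFamily, ModelParams, ModelSpec
from .fitting import FitResult, FittingError, fit_model
from .synthetic_data import DesignSpec, generate_design, sample_generating_params, simulate_dataset

__all__ = [
    "ConfusabilityMatrix",
    "ParameterRecoveryResult",
    "model_recovery",
    "parameter_recovery",
    "named_parameters",
]


@dataclass(frozen=True)
class ConfusabilityMatrix:
    """Selection probabilities: P(model Y selected | data generated by X)."""

    matrix: pd.DataFrame  # rows: generating model, columns: fitted model
    n_datasets: int
    n_trials: int
    criterion: str
    seed: int
    failures: pd.DataFrame  # per-cell fitting-failure counts
    matrices: Optional[dict] = None  # per-criterion matrices from the same fits

    def diagonal_dominant(self) -> bool:
        """True when every row's diagonal entry is the row maximum."""
        m = self.matrix.to_numpy()
        return bool(np.all(np.diag(m) >= m.max(axis=1) - 1e-12))

    def diagonal_mass(self, criterion: Optional[str] = None) -> float:
        """Sum of diagonal selection probabilities under a criterion."""
        m = self.matrix if criterion is None else self.matrices[criterion]
        return float(np.trace(m.to_numpy()))


def _nested_warm_starts(fit_spec: ModelSpec, results: dict[str, FitResult], trials) -> list:
    """Embed an already-fitted nested model's solution as an extra start.

    A decision-noise model nests the corresponding noise-free model at
    sigma_d = 0, so the base fit (when in the model set) seeds the larger one.
    """
    if not fit_spec.decision_noise:
        return []
    from dataclasses import replace as _replace

    base_token = _replace(fit_spec, decision_noise=False).token
    base = results.get(base_token)
    if base is None:
        return []
    from .fitting import _Packer
    from .likelihood import prepare_dataset
    from .observer_models import BayesBoundaryParams, ModelParams

    data = trials if not hasattr(trials, "columns") else prepare_dataset(trials)
    packer = _Packer(fit_spec, data.cp_std, data.standardizer.sd)
    b = base.params.boundary
    embedded = ModelParams(
        noise=base.params.noise,
        boundary=BayesBoundaryParams(k=b.k, sigma_d=1e-3),
    )
    return [packer.pack(embedded)]


def _winner(results: dict[str, FitResult], criterion: str) -> str:
    def key(item):
        token, fit = item
        value = fit.aic if criterion == "aic" else fit.bic
        return (round(value, 9), fit.z, token)

    return min(results.items(), key=key)[0]


def model_recovery(
    model_set: Sequence[ModelSpec | str],
    *,
    task: Task | str = Task.DIFFERENT_MEANS,
    modality: Modality | str = Modality.AUDITORY,
    n_datasets: int = 20,
    n_trials: int = 360,
    criterion: str = "aic",
    seed: int = 0,
    n_starts: int = 10,
    ftol: float = 1e-6,
) -> ConfusabilityMatrix:
    """Confusability matrix over a model set at configurable scale.

    ``n_trials`` must fit the balanced design (divisible by 8); each dataset
    is one balanced block of that size.  Fitting failures are recorded per
    cell and the affected dataset contributes to no winner.
    """
    task = Task(task)
    modality = Modality(modality)
    specs = [
        s if isinstance(s, ModelSpec) else ModelSpec.from_token(s, task) for s in model_set
    ]
    if not specs:
        raise ConfigurationError("model_set must be non-empty")
    if n_datasets < 1 or n_trials < 1:
        raise ConfigurationError("n_datasets and n_trials must be >= 1")
    tokens = [s.token for s in specs]
    counts = {c: pd.DataFrame(0.0, index=tokens, columns=tokens) for c in ("aic", "bic")}
    failures = pd.DataFrame(0, index=tokens, columns=tokens)
    wins_per_row = {t: 0 for t in tokens}
    seeds = np.random.SeedSequence(seed).generate_state(3 * len(specs) * n_datasets) % (2**31)
    si = 0
    for gen_spec in specs:
        for i in range(n_datasets):
            theta = sample_generating_params(gen_spec, seed=int(seeds[si]), modality=modality)
            design = generate_design(
                DesignSpec(task=task, modality=modality, n_blocks=1,
                           trials_per_block=n_trials, seed=int(seeds[si + 1]))
            )
            trials = simulate_dataset(design, gen_spec, theta, seed=int(seeds[si + 2]))
            si += 3
            results: dict[str, FitResult] = {}
            failed = False
            order = sorted(range(len(specs)), key=lambda j: specs[j].decision_noise)
            for j in order:
                fit_spec = specs[j]
                extra = _nested_warm_starts(fit_spec, results, trials)
                try:
                    results[fit_spec.token] = fit_model(
                        trials, fit_spec, n_starts=n_starts, extra_starts=extra,
                        seed=int((seeds[si - 1] + 7919 * (j + 1)) % (2**31)), ftol=ftol,
                    )
                except FittingError:
                    failures.loc[gen_spec.token, fit_spec.token] += 1
                    failed = True
            if failed or not results:
                continue
            for crit in ("aic", "bic"):
                counts[crit].loc[gen_spec.token, _winner(results, crit)] += 1
            wins_per_row[gen_spec.token] += 1
    denom = pd.Series(wins_per_row).replace(0, np.nan)
    matrices = {c: counts[c].div(denom, axis=0).fillna(0.0) for c in counts}
    return ConfusabilityMatrix(
        matrix=matrices[criterion], n_datasets=n_datasets, n_trials=n_trials,
        criterion=criterion, seed=seed, failures=failures, matrices=matrices,
    )


def named_parameters(spec: ModelSpec, params: ModelParams) -> dict[str, float]:
    """Flatten a parameter set into named scalars for recovery bookkeeping."""
    out: dict[str, float] = {}
    noise = params.noise
    if spec.odn:
        for i, g in enumerate(noise.gamma_by_intensity, start=1):
            out[f"gamma_{i}"] = float(g)
        out["psi"] = float(noise.psi)
    else:
        for i, s in enumerate(noise.sigma_by_intensity, start=1):
            out[f"sigma_{i}"] = float(s)
    b = params.boundary
    if spec.is_bayes:
        for i, k in enumerate(b.k, start=1):
            out[f"kd_{i}"] = float(k)
        if spec.decision_noise:
            out["sigma_d"] = float(b.sigma_d)
        if spec.free_prior:
            for name in ("subjective_mu1", "subjective_sigma1", "subjective_sigma2"):
                v = getattr(b, name)
                if v is not None:
                    out[name] = float(v)
    else:
        for i, k in enumerate(b.k, start=1):
            out[f"k_{i}"] = float(k)
        if b.m is not None:
            for i, m in enumerate(b.m, start=1):
                out[f"m_{i}"] = float(m)
        if spec.family == ModelFamily.FREE_EXPONENT:
            out["a"] = float(b.a)
    return out


@dataclass(frozen=True)
class ParameterRecoveryResult:
    """Generating-vs-recovered scatter data and per-parameter correlations."""

    spec: ModelSpec
    generating: pd.DataFrame  # one row per dataset
    recovered: pd.DataFrame
    correlations: pd.Series
    n_failures: int


def parameter_recovery(
    spec: ModelSpec,
    *,
    modality: Modality | str = Modality.AUDITORY,
    n_datasets: int = 20,
    n_trials: int = 720,
    seed: int = 0,
    n_starts: int = 10,
    ftol: float = 1e-6,
) -> ParameterRecoveryResult:
    """Simulate-fit loop under a single model; correlations per parameter."""
    modality = Modality(modality)
    if n_trials % 8:
        raise ConfigurationError("n_trials must be divisible by 8 for a balanced design")
    seeds = np.random.SeedSequence(seed).generate_state(4 * n_datasets) % (2**31)
    gen_rows, rec_rows = [], []
    failures = 0
    for i in range(n_datasets):
        s0, s1, s2, s3 = (int(v) for v in seeds[4 * i : 4 * i + 4])
        theta = sample_generating_params(spec, seed=s0, modality=modality)
        design = generate_design(
            DesignSpec(task=spec.task, modality=modality, n_blocks=1,
                       trials_per_block=n_trials, seed=s1)
        )
        trials = simulate_dataset(design, spec, theta, seed=s2)
        try:
            fit = fit_model(trials, spec, n_starts=n_starts, seed=s3, ftol=ftol)
        except FittingError:
            failures += 1
            continue
        gen_rows.append(named_parameters(spec, theta))
        rec_rows.append(named_parameters(spec, fit.params))
    gen = pd.DataFrame(gen_rows)
    rec = pd.DataFrame(rec_rows)
    corr = {}
    for col in gen.columns:
        g, r = gen[col].to_numpy(), rec[col].to_numpy()
        if np.std(g) == 0 or np.std(r) == 0:
            corr[col] = np.nan
        else:
            corr[col] = float(np.corrcoef(g, r)[0, 1])
    return ParameterRecoveryResult(
        spec=spec, generating=gen, recovered=rec,
        correlations=pd.Series(corr), n_failures=failures,
    )
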