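"""Visualisation of model fits: predicted vs observed response curves.

Combined category/confidence responses are coded on a signed scale (polarity
is the category, magnitude the confidence: category 1 -> -4..-1, category
2 -> +1..+4).  Predicted responses are generated by sampling, kept strictly
separate from the analytic likelihood used for fitting: 100 measurement
samples per trial are pushed through the model's decision rule and averaged
(decision-noise models additionally average over 100 boundary draws per
sample).  Stimulus values are binned with equal-count bins.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .task_design import Task
from .observer_models import ModelParams, ModelSpec, region_from_index
from .likelihood import PreparedData, prepare_dataset
from .synthetic_data import _bayes_region_indices

__all__ = ["signed_response", "predicted_signed_responses", "plot_model_fit"]


def signed_response(category, confidence):
    """Signed combined response: -confidence for category 1, +confidence for 2."""
    category = np.asarray(category, dtype=int)
    confidence = np.asarray(confidence, dtype=float)
    return np.where(category == 1, -confidence, confidence)


def _signed_of_regions(r: np.ndarray) -> np.ndarray:
    table = np.array([signed_response(g.category, g.confidence)
                      for g in (region_from_index(i) for i in range(1, 9))])
    return table[r - 1]


def predicted_signed_responses(
    spec: ModelSpec,
    params: ModelParams,
    data: PreparedData,
    n_samples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Mean predicted signed response per trial from measurement sampling."""
    from .likelihood import _trial_sigmas
    from .observer_models import _assemble_cuts, lppr, effective_category_pair

    rng = np.random.default_rng(seed)
    sigma = _trial_sigmas(spec, params, data)
    x = rng.normal(data.z[:, None], sigma[:, None], size=(data.n, n_samples))
    if not spec.is_bayes:
        pb = params.boundary
        if pb.m is None:
            b = np.broadcast_to(pb.k, (data.n,) + pb.k.shape)
        else:
            a = {"linear": 1.0, "quadratic": 2.0}.get(spec.family.value, pb.a)
            b = pb.k + pb.m * sigma[:, None] ** a
        cuts = _assemble_cuts(spec.task, b)  # (n, 7)
        v = x if spec.task == Task.DIFFERENT_MEANS else np.abs(x)
        r = 1 + np.sum(cuts[:, None, :] <= v[..., None], axis=-1)
    else:
        cp_eff = effective_category_pair(spec, params, data.cp_std)
        d = lppr(x, sigma[:, None], cp_eff, spec)
        if spec.decision_noise and params.boundary.sigma_d > 0:
            from scipy.stats import norm as _norm

            u = rng.uniform(0.01, 0.99, size=(n_samples,))
            eps = params.boundary.sigma_d * _norm.ppf(u)
            d = d[..., None] + eps  # (n, n_samples, n_draws)
        r = _bayes_region_indices(np.asarray(d), params.boundary.k)
    signed = _signed_of_regions(np.asarray(r, dtype=int))
    while signed.ndim > 1:
        signed = signed.mean(axis=-1)
    return signed


def plot_model_fit(
    trials: pd.DataFrame,
    spec: ModelSpec,
    params: ModelParams,
    *,
    n_bins: int = 12,
    n_samples: int = 100,
    seed: int = 0,
    ax: Optional[plt.Axes] = None,
    title: Optional[str] = None,
):
    """Observed and predicted signed responses over equal-count stimulus bins,
    one line per intensity level."""
    data = prepare_dataset(trials)
    predicted = predicted_signed_responses(spec, params, data, n_samples=n_samples, seed=seed)
    observed = _signed_of_regions(data.response_r)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = plt.cm.viridis(np.linspace(0.15, 0.9, 4))
    edges = np.quantile(data.s_raw, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    bins = np.clip(np.searchsorted(edges, data.s_raw, side="right") - 1, 0, n_bins - 1)
    for level in range(1, 5):
        mask = data.intensity == level
        if not mask.any():
            continue
        df = pd.DataFrame(
            {"bin": bins[mask], "obs": observed[mask], "pred": predicted[mask],
             "s": data.s_raw[mask]}
        ).groupby("bin").mean()
        ax.plot(df["s"], df["pred"], color=colors[level - 1], label=f"intensity {level}")
        ax.plot(df["s"], df["obs"], "s", color=colors[level - 1], markersize=4)
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.set_xlabel("stimulus value")
    ax.set_ylabel("signed category/confidence response")
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title)
    return ax
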