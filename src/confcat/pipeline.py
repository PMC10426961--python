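"""Run configuration and end-to-end pipeline execution.

A :class:`RunConfig` is a plain, fully serialisable description of a run
(stages, configuration, model list, fitting/recovery settings, master seed,
output directory); :func:`run_pipeline` executes the requested stages and
writes delimited result tables, figures, and a JSON manifest with the seeds
and versions needed to regenerate every output.  Re-running an identical
config reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .task_design import ConfigurationError, Modality, Task
from .observer_models import ModelSpec
from .likelihood import read_trials, write_trials
from .fitting import compare_models, core_model_tokens, fit_cross_modal_suite, fit_model
from .recovery import model_recovery
from .synthetic_data import DesignSpec, generate_design, sample_generating_params, simulate_dataset

logger = logging.getLogger("confcat")

__all__ = ["RunConfig", "run_pipeline"]

_VALID_STAGES = ("simulate", "fit", "compare", "crossmodal", "recover", "plot")


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    stages: list[str] = field(default_factory=lambda: ["simulate", "compare"])
    task: str = "different_means"
    modality: str = "auditory"
    models: Optional[list[str]] = None  # default: core set for the modality
    input_trials: Optional[str] = None  # existing trial table; else simulate
    input_trials_second_modality: Optional[str] = None  # for crossmodal
    output_dir: str = "confcat_run"
    seed: int = 0
    # simulate settings
    generating_model: str = "free_exponent"
    n_participants: int = 1
    n_blocks: int = 6
    trials_per_block: int = 120
    # fitting settings
    n_starts: int = 20
    ftol: float = 1e-6
    # recovery settings
    recovery_models: list[str] = field(
        default_factory=lambda: ["distance", "free_exponent", "bayes", "bayes+dnoise"]
    )
    recovery_n_datasets: int = 20
    recovery_n_trials: int = 360
    recovery_criterion: str = "aic"
    # plotting
    plot_bins: int = 12

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in _VALID_STAGES]
        if bad:
            raise ConfigurationError(f"stages: unknown stage(s) {bad}")
        Task(self.task)
        Modality(self.modality)
        if self.trials_per_block % 8:
            raise ConfigurationError("trials_per_block: must be divisible by 8")
        if self.n_starts < 1 or self.n_participants < 1:
            raise ConfigurationError("n_starts/n_participants: must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _simulate_stage(config: RunConfig, out: Path, manifest: dict) -> pd.DataFrame:
    spec = ModelSpec.from_token(config.generating_model, config.task)
    seeds = np.random.SeedSequence(config.seed).generate_state(3 * config.n_participants) % (2**31)
    frames = []
    for p in range(config.n_participants):
        s0, s1, s2 = (int(v) for v in seeds[3 * p : 3 * p + 3])
        theta = sample_generating_params(spec, seed=s0, modality=config.modality)
        design = generate_design(
            DesignSpec(task=config.task, modality=config.modality,
                       n_blocks=config.n_blocks, trials_per_block=config.trials_per_block,
                       seed=s1)
        )
        frames.append(
            simulate_dataset(design, spec, theta, seed=s2, participant=f"sim{p + 1:02d}")
        )
    trials = pd.concat(frames, ignore_index=True)
    path = out / "trials.tsv"
    write_trials(trials, path)
    manifest["outputs"]["trials.tsv"] = dict(
        stage="simulate", generating_model=spec.token, seed=config.seed,
        n_rows=int(len(trials)),
    )
    logger.info("simulated %d trials -> %s", len(trials), path)
    return trials


def _load_trials(config: RunConfig, out: Path, manifest: dict) -> pd.DataFrame:
    if config.input_trials:
        return read_trials(config.input_trials)
    if (out / "trials.tsv").exists():
        return read_trials(out / "trials.tsv")
    raise ConfigurationError("input_trials: no trial table available; run the simulate stage")


def _fit_stage(config: RunConfig, trials: pd.DataFrame, out: Path, manifest: dict):
    tokens = config.models or core_model_tokens(config.modality)
    fits = {}
    seeds = np.random.SeedSequence(config.seed + 1).generate_state(
        len(tokens) * trials["participant"].nunique()
    ) % (2**31)
    i = 0
    for participant, sub in trials.groupby("participant", sort=True):
        fits[participant] = {}
        for token in tokens:
            spec = ModelSpec.from_token(token, config.task)
            fits[participant][token] = fit_model(
                sub, spec, n_starts=config.n_starts, seed=int(seeds[i]), ftol=config.ftol
            )
            i += 1
            logger.info("fit %s / %s: loglik=%.2f", participant, token,
                        fits[participant][token].loglik)
    table = compare_models(fits)
    table.per_participant.to_csv(out / "fits.tsv", sep="\t", index=False)
    table.summary.to_csv(out / "model_comparison.tsv", sep="\t")
    manifest["outputs"]["fits.tsv"] = dict(stage="fit", models=tokens, seed=config.seed + 1)
    manifest["outputs"]["model_comparison.tsv"] = dict(stage="compare", criterion="aic")
    return fits, table


def _crossmodal_stage(config: RunConfig, trials: pd.DataFrame, out: Path, manifest: dict):
    if not config.input_trials_second_modality:
        raise ConfigurationError(
            "input_trials_second_modality: required for the crossmodal stage"
        )
    other = read_trials(config.input_trials_second_modality)
    by_modality = {m: t for m, t in
                   pd.concat([trials, other], ignore_index=True).groupby("modality")}
    if set(by_modality) != {"visual", "auditory"}:
        raise ConfigurationError("crossmodal stage needs one visual and one auditory table")
    rows = []
    for participant in sorted(set(by_modality["visual"]["participant"])):
        tv = by_modality["visual"][by_modality["visual"]["participant"] == participant]
        ta = by_modality["auditory"][by_modality["auditory"]["participant"] == participant]
        suite = fit_cross_modal_suite(
            tv, ta, n_starts=config.n_starts, seed=config.seed + 2, ftol=config.ftol
        )
        for mode, fit in suite.items():
            rows.append(dict(participant=participant, mode=mode, loglik=fit.loglik,
                             z=fit.z, n=fit.n, aic=fit.aic, bic=fit.bic))
    df = pd.DataFrame(rows)
    df.to_csv(out / "crossmodal.tsv", sep="\t", index=False)
    manifest["outputs"]["crossmodal.tsv"] = dict(stage="crossmodal", seed=config.seed + 2)
    return df


def _recover_stage(config: RunConfig, out: Path, manifest: dict):
    cm = model_recovery(
        config.recovery_models, task=config.task, modality=config.modality,
        n_datasets=config.recovery_n_datasets, n_trials=config.recovery_n_trials,
        criterion=config.recovery_criterion, seed=config.seed + 3,
        n_starts=max(2, config.n_starts // 2),
    )
    cm.matrix.to_csv(out / "confusability.tsv", sep="\t")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(cm.matrix.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(cm.matrix.columns)), cm.matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.matrix.index)), cm.matrix.index)
    ax.set_xlabel("selected model")
    ax.set_ylabel("generating model")
    for (i, j), v in np.ndenumerate(cm.matrix.to_numpy()):
        ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                color="white" if v < 0.6 else "black", fontsize=8)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(out / "confusability.png", dpi=150)
    plt.close(fig)
    manifest["outputs"]["confusability.tsv"] = dict(
        stage="recover", seed=config.seed + 3,
        n_datasets=cm.n_datasets, n_trials=cm.n_trials, criterion=cm.criterion,
    )
    return cm


def _plot_stage(config: RunConfig, trials: pd.DataFrame, fits, out: Path, manifest: dict):
    from .plots import plot_model_fit
    import matplotlib.pyplot as plt

    for participant, model_fits in fits.items():
        best = min(model_fits.values(), key=lambda f: f.aic)
        ax = plot_model_fit(
            trials[trials["participant"] == participant], best.spec, best.params,
            n_bins=config.plot_bins, seed=config.seed + 4,
            title=f"{participant}: {best.token}",
        )
        name = f"fit_{participant}.png"
        ax.figure.savefig(out / name, dpi=150)
        plt.close(ax.figure)
        manifest["outputs"][name] = dict(stage="plot", participant=str(participant),
                                         model=best.token, seed=config.seed + 4)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = dict(version=__version__, seed=config.seed,
                          config=dataclasses.asdict(config), outputs={})
    trials = None
    fits = None
    if "simulate" in config.stages:
        trials = _simulate_stage(config, out, manifest)
    needs_trials = {"fit", "compare", "crossmodal", "plot"} & set(config.stages)
    if needs_trials and trials is None:
        trials = _load_trials(config, out, manifest)
    if {"fit", "compare", "plot"} & set(config.stages):
        fits, _ = _fit_stage(config, trials, out, manifest)
    if "crossmodal" in config.stages:
        _crossmodal_stage(config, trials, out, manifest)
    if "recover" in config.stages:
        _recover_stage(config, out, manifest)
    if "plot" in config.stages and fits:
        _plot_stage(config, trials, fits, out, manifest)
    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
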