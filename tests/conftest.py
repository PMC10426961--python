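"""Shared fixtures: small simulated sessions and standardized category pairs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from confcat.observer_models import ModelSpec
from confcat.synthetic_data import (
    DesignSpec,
    generate_design,
    sample_generating_params,
    simulate_dataset,
    theoretical_standardizer,
)
from confcat.task_design import default_category_pair
from confcat.likelihood import prepare_dataset


def make_session(token, task, modality, n_trials=240, seed=0):
    """One simulated observer: (spec, generating params, trial table)."""
    spec = ModelSpec.from_token(token, task)
    theta = sample_generating_params(spec, seed=seed, modality=modality)
    design = generate_design(
        DesignSpec(task=task, modality=modality, n_blocks=1,
                   trials_per_block=n_trials, seed=seed + 1)
    )
    trials = simulate_dataset(design, spec, theta, seed=seed + 2)
    return spec, theta, trials


@pytest.fixture(scope="session")
def session_factory():
    return make_session


@pytest.fixture(scope="session")
def std_pairs():
    """Standardized category pairs (theoretical moments) for all configurations."""
    out = {}
    for task in ("different_means", "different_sds"):
        for modality in ("visual", "auditory"):
            cp = default_category_pair(task, modality)
            out[(task, modality)] = theoretical_standardizer(cp).transform_pair(cp)
    return out


@pytest.fixture(scope="session")
def linear_session():
    """A linear-observer session reused by several fitting tests."""
    spec, theta, trials = make_session("linear", "different_means", "auditory",
                                       n_trials=360, seed=100)
    return spec, theta, trials, prepare_dataset(trials)
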