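"""Response-probability masses, decision-noise quadrature, dataset likelihoods."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from confcat.task_design import DegenerateInputError, Standardizer, default_category_pair
from confcat.observer_models import (
    BayesBoundaryParams,
    ModelParams,
    ModelSpec,
    NoiseParams,
    PerceptualBoundaryParams,
    bayes_perceptual_boundaries,
)
from confcat.likelihood import (
    PROB_FLOOR,
    _dnoise_nodes,
    _region_masses,
    count_parameters,
    dataset_loglik,
    prepare_dataset,
    read_trials,
    response_probabilities,
    response_probability_matrix,
    write_trials,
)
from confcat.synthetic_data import sample_generating_params
from tests.conftest import make_session


ALL_VARIANTS = [
    ("distance", "different_means", "auditory"),
    ("linear", "different_sds", "auditory"),
    ("quadratic", "different_means", "visual"),
    ("free_exponent", "different_sds", "visual"),
    ("free_exponent+odn", "different_means", "visual"),
    ("bayes", "different_means", "auditory"),
    ("bayes+odn", "different_sds", "visual"),
    ("bayes+dnoise", "different_sds", "auditory"),
    ("bayes+prior", "different_means", "auditory"),
]


@pytest.mark.parametrize("token,task,modality", ALL_VARIANTS)
def test_probabilities_sum_to_one(token, task, modality):
    spec, theta, trials = make_session(token, task, modality, n_trials=160, seed=13)
    data = prepare_dataset(trials)
    probs = response_probability_matrix(spec, theta, data)
    assert probs.shape == (160, 8)
    assert np.all(probs >= -1e-12)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)


def test_symmetric_trial_has_mirror_probabilities():
    """With b1 = 0 and symmetric confidence cuts, a measurement distribution
    centred on the criterion assigns mirror-equal masses to paired regions."""
    spec = ModelSpec(family="distance", task="different_means")
    theta = ModelParams(
        noise=NoiseParams(sigma_by_intensity=[2.0, 1.5, 1.0, 0.8]),
        boundary=PerceptualBoundaryParams(k=[0.0, 0.6, 1.2, 2.0]),
    )
    cp = default_category_pair("different_means", "auditory")
    std = Standardizer(mean=2700.0, sd=620.0)
    trial = dict(task="different_means", modality="auditory",
                 s_raw=2700.0, z=0.0, intensity=2, response_r=1)
    p = response_probabilities(trial, spec, theta, std.transform_pair(cp), std)
    np.testing.assert_allclose(p, p[::-1], atol=1e-12)


@pytest.mark.parametrize("token,task", [
    ("linear", "different_sds"),
    ("bayes", "different_means"),
])
def test_region_masses_match_measurement_simulation(token, task):
    """10^6 simulated measurements of one trial against the CDF masses."""
    spec = ModelSpec.from_token(token, task)
    theta = sample_generating_params(spec, seed=3, modality="auditory")
    _, _, trials = make_session(token, task, "auditory", n_trials=8, seed=3)
    data = prepare_dataset(trials)
    probs = response_probability_matrix(spec, theta, data)
    rng = np.random.default_rng(99)
    n = 10**6
    i = 2  # one arbitrary trial
    sigma = theta.noise.sigma_by_intensity[data.intensity[i] - 1]
    x = rng.normal(data.z[i], sigma, size=n)
    if not spec.is_bayes:
        a = 1.0
        b = theta.boundary.k + theta.boundary.m * sigma**a
        from confcat.observer_models import _assemble_cuts

        cuts = _assemble_cuts(spec.task, b)
    else:
        cuts = bayes_perceptual_boundaries(spec, theta.boundary.k, sigma, data.cp_std)
    v = x if task == "different_means" else np.abs(x)
    r = 1 + np.sum(np.asarray(cuts)[None, :] <= v[:, None], axis=1)
    freq = np.bincount(r, minlength=9)[1:] / n
    se = np.sqrt(probs[i] * (1 - probs[i]) / n)
    assert np.all(np.abs(freq - probs[i]) <= 3 * se + 1e-12)


def test_dnoise_zero_noise_limit_equals_base_model():
    spec_d = ModelSpec.from_token("bayes+dnoise", "different_sds")
    spec_0 = ModelSpec.from_token("bayes", "different_sds")
    theta = sample_generating_params(spec_d, seed=5, modality="auditory")
    theta0 = ModelParams(
        noise=theta.noise, boundary=BayesBoundaryParams(k=theta.boundary.k, sigma_d=0.0)
    )
    _, _, trials = make_session("bayes", "different_sds", "auditory", n_trials=80, seed=5)
    data = prepare_dataset(trials)
    np.testing.assert_allclose(
        response_probability_matrix(spec_d, theta0, data),
        response_probability_matrix(spec_0, theta0, data),
        atol=1e-14,
    )


def test_dnoise_quadrature_converges_with_draw_count():
    """Coarser quantile rules approach a dense reference monotonically."""
    spec = ModelSpec.from_token("bayes+dnoise", "different_sds")
    theta = sample_generating_params(spec, seed=5, modality="auditory")
    _, _, trials = make_session("bayes+dnoise", "different_sds", "auditory",
                                n_trials=40, seed=5)
    data = prepare_dataset(trials)
    sigma = theta.noise.sigma_by_intensity[data.intensity - 1]

    def quad(n_draws):
        off, w = _dnoise_nodes(theta.boundary.sigma_d, n_draws)
        kd = theta.boundary.k + off[:, None, None]
        cuts = bayes_perceptual_boundaries(spec, kd, sigma, data.cp_std)
        masses = _region_masses(data.z, sigma, cuts, spec.task)
        return np.tensordot(w, masses, axes=(0, 0))

    ref = quad(8001)
    errs = [np.abs(quad(n) - ref).max() for n in (11, 101, 1001)]
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-4


def test_dnoise_quadrature_matches_sampled_marginalisation():
    """1e5 draws of the truncated decision noise, each propagated through the
    exact per-draw region masses, agree with the quantile quadrature."""
    spec = ModelSpec.from_token("bayes+dnoise", "different_means")
    theta = sample_generating_params(spec, seed=8, modality="auditory")
    _, _, trials = make_session("bayes+dnoise", "different_means", "auditory",
                                n_trials=8, seed=8)
    data = prepare_dataset(trials)
    probs = response_probability_matrix(spec, theta, data)
    rng = np.random.default_rng(123)
    n = 10**5
    eps = theta.boundary.sigma_d * norm.ppf(rng.uniform(0.01, 0.99, size=n))
    sigma = data.intensity * 0.0 + theta.noise.sigma_by_intensity[data.intensity - 1]
    kd = theta.boundary.k + eps[:, None, None]
    cuts = bayes_perceptual_boundaries(spec, kd, sigma, data.cp_std)
    masses = _region_masses(data.z, sigma, cuts, spec.task).mean(axis=0)
    # sampling SE of a mean of bounded [0,1] masses, plus quadrature error
    assert np.abs(masses - probs).max() < 3.5 / math.sqrt(n) + 2e-3


def test_dataset_loglik_additivity_and_oracle(linear_session):
    spec, theta, trials, data = linear_session
    one = trials.iloc[[0]]
    two = pd.concat([one, one], ignore_index=True)
    std = data.standardizer
    cp = default_category_pair("different_means", "auditory")
    ll1 = dataset_loglik(one, spec, theta, category_pair=cp, standardizer=std)
    ll2 = dataset_loglik(two, spec, theta, category_pair=cp, standardizer=std)
    assert ll2 == pytest.approx(2 * ll1, abs=1e-9)

    # naive per-trial loop over a 50-trial fixture
    sub = trials.iloc[:50]
    expected = 0.0
    d50 = prepare_dataset(sub, category_pair=cp, standardizer=std)
    for i in range(d50.n):
        trial = dict(task="different_means", modality="auditory",
                     s_raw=d50.s_raw[i], z=d50.z[i], intensity=int(d50.intensity[i]))
        p = response_probabilities(trial, spec, theta, d50.cp_std, std)
        expected += math.log(max(p[d50.response_r[i] - 1], PROB_FLOOR))
    assert dataset_loglik(d50, spec, theta) == pytest.approx(expected, abs=1e-9)

    with pytest.raises(DegenerateInputError):
        dataset_loglik(trials.iloc[:0], spec, theta)


def test_probability_floor_bounds_loglik(linear_session):
    spec, theta, trials, data = linear_session
    ll = dataset_loglik(data, spec, theta)
    assert ll >= data.n * math.log(PROB_FLOOR)


@pytest.mark.parametrize("token,task,expected", [
    ("distance", "different_means", 8),
    ("distance", "different_sds", 11),
    ("linear", "different_means", 12),
    ("linear", "different_sds", 18),
    ("quadratic", "different_sds", 18),
    ("free_exponent", "different_means", 13),
    ("free_exponent", "different_sds", 19),
    ("free_exponent+odn", "different_means", 14),
    ("bayes", "different_means", 11),
    ("bayes", "different_sds", 11),
    ("bayes+odn", "different_sds", 12),
    ("bayes+dnoise", "different_means", 12),
    ("bayes+prior", "different_sds", 13),
])
def test_count_parameters(token, task, expected):
    spec = ModelSpec.from_token(token, task)
    assert count_parameters(spec) == expected
    # the optimizer's packed vector enumerates exactly the same parameters
    from confcat.fitting import _Packer
    from confcat.synthetic_data import theoretical_standardizer

    modality = "visual" if spec.odn else "auditory"
    cp = default_category_pair(task, modality)
    std = theoretical_standardizer(cp)
    packer = _Packer(spec, std.transform_pair(cp), std.sd)
    assert packer.n_params == expected


def test_count_parameters_relations_and_cross_modal():
    for task in ("different_means", "different_sds"):
        free = count_parameters(ModelSpec.from_token("free_exponent", task))
        quad = count_parameters(ModelSpec.from_token("quadratic", task))
        assert free - quad == 1
    spec = ModelSpec.from_token("free_exponent", "different_means")
    assert count_parameters(spec, cross_modal_mode="common") == 13
    assert count_parameters(spec, cross_modal_mode="different_noise") == 17
    assert count_parameters(spec, cross_modal_mode="flexible") == 26
    sds = ModelSpec.from_token("free_exponent", "different_sds")
    assert count_parameters(sds, cross_modal_mode="common") == 19
    assert count_parameters(sds, cross_modal_mode="different_noise") == 23
    assert count_parameters(sds, cross_modal_mode="flexible") == 38


def test_trial_table_roundtrip(tmp_path, linear_session):
    _, _, trials, _ = linear_session
    path = tmp_path / "trials.tsv"
    write_trials(trials, path)
    back = read_trials(path)
    assert len(back) == len(trials)
    np.testing.assert_allclose(back["s_raw"], trials["s_raw"])
    np.testing.assert_array_equal(back["response_r"], trials["response_r"])
    # validation: out-of-range confidence
    bad = trials.copy()
    bad.loc[bad.index[0], "confidence"] = 7
    write_trials(bad, path)
    with pytest.raises(Exception):
        read_trials(path)
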