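"""Boundary rules, the log-posterior-ratio decision variable, response regions."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from confcat.task_design import ConfigurationError
from confcat.observer_models import (
    ModelSpec,
    NoiseParams,
    PerceptualBoundaryParams,
    BayesBoundaryParams,
    OrderingViolationError,
    bayes_perceptual_boundaries,
    index_from_region,
    invert_lppr,
    lppr,
    perceptual_boundaries,
    region_from_index,
    response_region,
    sigma_for_trial,
)


def test_model_spec_flags_and_tokens():
    spec = ModelSpec.from_token("bayes+dnoise", "different_sds")
    assert spec.is_bayes and spec.decision_noise and not spec.free_prior
    assert spec.token == "bayes+dnoise"
    for token in ["distance", "linear", "free_exponent+odn", "bayes+prior"]:
        assert ModelSpec.from_token(token, "different_means").token == token
    with pytest.raises(ConfigurationError):
        ModelSpec(family="linear", task="different_means", decision_noise=True)
    with pytest.raises(ConfigurationError):
        ModelSpec.from_token("free_exponent+odn", "different_means").validate_modality("auditory")


def test_region_bijection():
    seen = set()
    for r in range(1, 9):
        reg = region_from_index(r)
        assert index_from_region(reg.category, reg.confidence) == r
        seen.add((reg.category, reg.confidence))
    assert seen == {(c, f) for c in (1, 2) for f in (1, 2, 3, 4)}
    assert region_from_index(1).category == 1 and region_from_index(1).confidence == 4
    assert region_from_index(5) == region_from_index(5)
    with pytest.raises(ValueError):
        region_from_index(9)


def test_sigma_for_trial_odn_trigonometry():
    noise = NoiseParams(gamma_by_intensity=[4.0, 3.0, 2.0, 1.0], psi=2.0)
    sd = 6.4
    # rectified 2-cycle sinusoid of raw orientation: zero at 0 and 90 deg,
    # peak at 45 deg
    assert sigma_for_trial(noise, 2, s_deg=0.0, odn=True, sd_deg=sd) == pytest.approx(3.0 / sd)
    assert sigma_for_trial(noise, 2, s_deg=45.0, odn=True, sd_deg=sd) == pytest.approx(5.0 / sd)
    assert sigma_for_trial(noise, 2, s_deg=90.0, odn=True, sd_deg=sd) == pytest.approx(
        3.0 / sd, abs=1e-12
    )
    plain = NoiseParams(sigma_by_intensity=[2.0, 1.5, 1.0, 0.5])
    assert sigma_for_trial(plain, 4) == 0.5
    with pytest.raises(ConfigurationError):
        sigma_for_trial(plain, 2, odn=True)  # missing orientation / gamma


def test_noise_monotonicity_enforced():
    with pytest.raises(ConfigurationError):
        NoiseParams(sigma_by_intensity=[1.0, 2.0, 0.5, 0.4])
    with pytest.raises(ConfigurationError):
        NoiseParams(sigma_by_intensity=[1.0, 0.5, 0.4, -0.1])


def test_distance_boundaries_ignore_sigma():
    spec = ModelSpec(family="distance", task="different_means")
    pb = PerceptualBoundaryParams(k=[0.1, 0.5, 1.0, 1.8])
    b1 = perceptual_boundaries(spec, pb, 0.3)
    b2 = perceptual_boundaries(spec, pb, 5.0)
    np.testing.assert_array_equal(b1, b2)
    np.testing.assert_allclose(b1, [-1.8, -1.0, -0.5, 0.1, 0.5, 1.0, 1.8])


def test_free_exponent_nests_linear_and_quadratic():
    k = np.array([0.05, 0.4, 0.9, 1.3, 1.8, 2.2, 3.0])
    m = np.array([0.1, 0.2, 0.35, 0.5, 0.7, 0.9, 1.2])
    for sigma in (0.4, 1.0, 3.7):
        for a, family in [(1.0, "linear"), (2.0, "quadratic")]:
            free = perceptual_boundaries(
                ModelSpec(family="free_exponent", task="different_sds"),
                PerceptualBoundaryParams(k=k, m=m, a=a), sigma,
            )
            fixed = perceptual_boundaries(
                ModelSpec(family=family, task="different_sds"),
                PerceptualBoundaryParams(k=k, m=m), sigma,
            )
            np.testing.assert_array_equal(free, fixed)


def test_linear_boundary_shift_is_proportional_to_sigma():
    spec = ModelSpec(family="linear", task="different_means")
    k = np.array([0.0, 0.5, 1.0, 1.5])
    m = np.array([0.2, 0.4, 0.6, 0.8])
    pb = PerceptualBoundaryParams(k=k, m=m)
    s1, s2 = 0.5, 2.5
    b1 = perceptual_boundaries(spec, pb, s1)
    b2 = perceptual_boundaries(spec, pb, s2)
    # right-hand boundaries b1..b4 sit at positions 3..6 of the cut vector
    np.testing.assert_allclose(b2[3:] - b1[3:], m * (s2 - s1), atol=1e-12)


def test_ordering_violation_raises():
    spec = ModelSpec(family="linear", task="different_means")
    pb = PerceptualBoundaryParams(k=[0.0, 0.5, 1.0, 1.5], m=[0.0, -2.0, 0.0, 0.0])
    with pytest.raises(OrderingViolationError):
        perceptual_boundaries(spec, pb, 2.0)  # b2 crosses below b1
    sds = ModelSpec(family="distance", task="different_sds")
    with pytest.raises(OrderingViolationError):
        perceptual_boundaries(sds, PerceptualBoundaryParams(k=[-0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2]), 1.0)


@pytest.mark.parametrize("task,modality", [
    ("different_means", "visual"), ("different_means", "auditory"),
    ("different_sds", "visual"), ("different_sds", "auditory"),
])
def test_lppr_matches_predictive_density_oracle(task, modality, std_pairs):
    """Closed forms equal log N(x; mu1, s^2+s1^2) - log N(x; mu2, s^2+s2^2)."""
    cp = std_pairs[(task, modality)]
    spec = ModelSpec(family="bayes_lppr", task=task)
    x = np.linspace(-4, 4, 161)
    for sigma in (0.3, 0.9, 2.4):
        d = lppr(x, sigma, cp, spec)
        oracle = norm.logpdf(x, cp.mu1, math.hypot(sigma, cp.sigma1)) - norm.logpdf(
            x, cp.mu2, math.hypot(sigma, cp.sigma2)
        )
        np.testing.assert_allclose(d, oracle, atol=1e-9)


def test_lppr_symmetries(std_pairs):
    dm = std_pairs[("different_means", "visual")]
    spec_dm = ModelSpec(family="bayes_lppr", task="different_means")
    assert lppr(0.0, 1.0, dm, spec_dm) == pytest.approx(0.0, abs=1e-12)
    x = np.linspace(0.01, 3, 50)
    sds = std_pairs[("different_sds", "auditory")]
    spec_sds = ModelSpec(family="bayes_lppr", task="different_sds")
    np.testing.assert_allclose(
        lppr(x, 0.7, sds, spec_sds), lppr(-x, 0.7, sds, spec_sds), atol=1e-12
    )
    # monotonicity: d decreasing in x for x > 0 (DS), strictly monotone (DM)
    assert np.all(np.diff(lppr(x, 0.7, sds, spec_sds)) < 0)
    assert np.all(np.diff(lppr(np.linspace(-3, 3, 100), 0.7, dm, spec_dm)) < 0)


def test_invert_lppr_roundtrip_and_empty_region(std_pairs):
    dm = std_pairs[("different_means", "auditory")]
    spec_dm = ModelSpec(family="bayes_lppr", task="different_means")
    assert invert_lppr(0.0, 0.8, dm, spec_dm) == pytest.approx(0.0, abs=1e-12)
    for k_d in (-1.5, -0.2, 0.4, 2.0):
        x = invert_lppr(k_d, 0.8, dm, spec_dm)
        assert lppr(x, 0.8, dm, spec_dm) == pytest.approx(k_d, abs=1e-10)
    sds = std_pairs[("different_sds", "visual")]
    spec_sds = ModelSpec(family="bayes_lppr", task="different_sds")
    sigma = 0.6
    A = lppr(0.0, sigma, sds, spec_sds)  # maximum attainable d
    assert invert_lppr(A + 0.1, sigma, sds, spec_sds) is None
    x = invert_lppr(A - 0.05, sigma, sds, spec_sds)
    assert x is not None and x > 0
    # bisection oracle on the closed form
    root = brentq(lambda v: lppr(v, sigma, sds, spec_sds) - (A - 0.05), 1e-9, 10.0)
    assert x == pytest.approx(root, rel=1e-9)


def test_bayes_boundaries_order_and_clipping(std_pairs):
    k = np.array([2.0, 1.2, 0.6, 0.0, -0.6, -1.2, -2.0])
    dm = std_pairs[("different_means", "visual")]
    spec = ModelSpec(family="bayes_lppr", task="different_means")
    cuts = bayes_perceptual_boundaries(spec, k, 0.9, dm)
    assert np.all(np.diff(cuts) > 0)  # decreasing d -> increasing x (mu1 < 0)
    sds = std_pairs[("different_sds", "auditory")]
    spec_sds = ModelSpec(family="bayes_lppr", task="different_sds")
    sigma = 0.5
    A = lppr(0.0, sigma, sds, spec_sds)
    k_hi = A + np.array([0.5, 0.2, -0.1, -0.5, -1.0, -1.5, -2.0])
    b = bayes_perceptual_boundaries(spec_sds, k_hi, sigma, sds)
    assert b[0] == 0.0 and b[1] == 0.0  # unreachable boundaries collapse to 0
    assert np.all(np.diff(b) >= 0) and b[-1] > 0
    with pytest.raises(ConfigurationError):
        BayesBoundaryParams(k=k[::-1])  # increasing k is invalid


def test_bayes_k_must_decrease():
    BayesBoundaryParams(k=[3, 2, 1, 0, -1, -2, -3])
    with pytest.raises(ConfigurationError):
        BayesBoundaryParams(k=[3, 3, 1, 0, -1, -2, -3])
    with pytest.raises(ConfigurationError):
        BayesBoundaryParams(k=[3, 2, 1, 0, -1, -2, -3], sigma_d=-0.1)


def test_response_region_lookup():
    cuts = np.array([-1.8, -1.0, -0.5, 0.1, 0.5, 1.0, 1.8])
    reg = response_region(-5.0, cuts, "different_means")
    assert (reg.category, reg.confidence) == (1, 4)
    assert response_region(5.0, cuts, "different_means").category == 2
    # half-open, closed on the left: x exactly at a cut joins the right region
    assert response_region(0.1, cuts, "different_means").category == 2
    b = np.array([0.2, 0.4, 0.7, 1.0, 1.4, 1.9, 2.6])
    assert response_region(0.0, b, "different_sds").confidence == 4
    assert response_region(0.0, b, "different_sds").category == 1
    # symmetric lookup on |x|
    for x in (0.3, 0.9, 1.6, 3.0):
        a = response_region(x, b, "different_sds")
        c = response_region(-x, b, "different_sds")
        assert (a.category, a.confidence) == (c.category, c.confidence)


@pytest.mark.parametrize("task", ["different_means", "different_sds"])
def test_sweep_hits_all_eight_regions(task):
    if task == "different_means":
        bounds = np.array([-1.8, -1.0, -0.5, 0.1, 0.5, 1.0, 1.8])
        xs = np.linspace(-3, 3, 1201)
    else:
        bounds = np.array([0.2, 0.4, 0.7, 1.0, 1.4, 1.9, 2.6])
        xs = np.linspace(-4, 4, 1601)
    seen = {response_region(x, bounds, task).r for x in xs}
    assert seen == set(range(1, 9))
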