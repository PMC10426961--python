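# Methods

`confcat` models combined category-and-confidence judgements in two-alternative
forced-choice (2AFC) categorisation with a 4-point confidence scale, within the
signal-detection framework: the observer receives a noisy measurement of a
one-dimensional stimulus attribute, transforms it into a decision variable, and
compares that variable with an ordered set of criteria that partition the
response space into eight category-confidence regions.

## Task structures

Each task-modality configuration is a pair of Gaussian category distributions
over orientation (degrees) or frequency (Hz):

| task | modality | category 1 | category 2 |
|---|---|---|---|
| different means | visual | N(−4°, 5°) | N(+4°, 5°) |
| different means | auditory | N(2300 Hz, 475 Hz) | N(3100 Hz, 475 Hz) |
| different SDs | visual | N(0°, 3°) | N(0°, 12°) |
| different SDs | auditory | N(2700 Hz, 125 Hz) | N(2700 Hz, 500 Hz) |

Priors are 0.5/0.5 (`prior1` is kept as a field for generality but neither
varied nor fitted). Orientation is treated as linear rather than circular: the
design uses a narrow range of orientations, so wrap-around is irrelevant. In
the different-means task the optimal criterion is the single density crossing
(0° / 2700 Hz); in the different-SDs task the two crossings (±5.16°; 2485 and
2915 Hz) bound a central interval assigned to the narrow category 1. Evidence
for category 2 is the category-2 density normalised by the summed densities; in
the different-SDs task it never falls below σ₁/(σ₁+σ₂) = 0.2. Category
diagnosticity is the same normalisation applied to the more probable category,
ranging from 0.5 (at a crossing) to 1.

Stimulus values are z-scored per configuration against all presented values
(`Z = (s − μ)/sd`); every model operates on the standardized axis. For
simulated sessions the default is the empirical mean/SD of that session's
stimuli, matching how real data would be treated; a theoretical-moments policy
(the balanced two-Gaussian mixture) is available when cross-session
reproducibility of the transform matters.

## Observer models

Measurement noise is Gaussian, `x ~ N(z, σ_I²)`, with a separate σ per
intensity level I ∈ {1..4} under a monotonicity constraint (higher intensity,
less noise); no functional form in intensity is imposed. The
orientation-dependent-noise (ODN) variant, visual modality only, adds a
rectified 2-cycle sinusoid of the raw orientation:
`σ(I, s) = γ_I + ψ·|sin(πs/90)|`. The sinusoid operates in degrees (its 90°
period is physical); the result is divided by the configuration's standardizer
SD before use on the standardized axis. Whether that conversion happens in
degree or standardized units is a genuine ambiguity; the degree-space reading
keeps the oblique-effect period tied to physical orientation.

Eight response regions r = 1..8 map bijectively to (category, confidence):
r = 1..4 are category 1 with confidence 4..1 and r = 5..8 category 2 with
confidence 1..4. In the different-means task the partition is the seven
cut-points (−b₄, −b₃, −b₂, b₁, b₂, b₃, b₄): b₁ is a free category criterion
(fitted values sit near, but not exactly at, zero) and the confidence criteria
are symmetric about zero. In the different-SDs task the partition is symmetric
about the centre b₀, fixed at 0 on the standardized axis: seven |x| thresholds
b₁ < … < b₇, with |x| < b₄ giving category 1.

* **Unscaled evidence strength** (`distance`): b_r = k_r, independent of σ.
* **Scaled evidence strength** (`linear`, `quadratic`, `free_exponent`):
  b_r(σ) = k_r + m_r σ^a with a = 1, 2, or free. m is unconstrained in sign;
  what must hold is strict ordering of the realized boundaries at every fitted
  σ. The free exponent is constrained to (1, 10]; the upper bound is purely a
  numerical-stability choice.
* **Bayesian** (`bayes`): the decision variable is the log posterior
  probability ratio d = log p(C=1|x) − log p(C=2|x), compared with seven free
  boundaries k₁ > … > k₇ in d space (positive d favours category 1, so k is
  stored strictly decreasing in r). Closed forms:
  d = 2xμ₁/(σ²+σ₁²) (different means, with mean-symmetric standardized
  categories) and d = ½·log[(σ²+σ₂²)/(σ²+σ₁²)] − x²(σ₂²−σ₁²)/[2(σ²+σ₁²)(σ²+σ₂²)]
  (different SDs), plus the log prior ratio (zero here). Both equal the log
  ratio of the predictive densities N(x; μ_C, σ²+σ_C²). Variants: decision
  noise (Gaussian noise of SD σ_d on d) and free category-distribution
  parameters (subjective μ₁/σ₁ or σ₁/σ₂ replacing the true values; the
  different-means subjective pair stays mean-symmetric and μ₁ is kept
  negative so the decision variable keeps its orientation).

Boundaries in d space are mapped to perceptual space by inverting the closed
forms at each fitted σ. In the different-SDs task a boundary with k_d above
the maximum attainable d (which is A = d(0)) is unreachable: it collapses onto
the centre, the corresponding central region is empty, and its response
probability is 0 — a legal outcome guarded by the likelihood floor.

## Likelihood

Response probabilities are exact Gaussian masses between adjacent realized
boundaries, computed by CDF differences (differences of P(|x| < b) in the
different-SDs task, which also guarantees each 8-vector sums to 1). The
dataset log-likelihood sums the log probability of each observed response,
flooring each probability at 1e−12: the models have no lapse process, so a
single extreme observation would otherwise contribute −∞. The floor is an
implementation guard far below any realistic trial probability.

Decision noise is marginalised with a quantile quadrature: 101 evenly spaced
nodes spanning the 1st–99th percentile of N(k_r, σ_d²), paired as
*corresponding draws* across boundaries (perfectly correlated boundary noise —
a single shared draw of the noise, not independent noise per boundary),
weighted by the normal density at each node and normalised. Because this rule
truncates the outer 2% of the noise distribution, the package defines the
decision-noise distribution operationally as that central-98% truncated
Gaussian and uses it identically in the simulator (one inverse-CDF draw per
trial). Simulation and likelihood then describe the same generative process;
the quadrature's residual discretization error is ~1e−3 at 101 nodes (measured
against an 8001-node reference) and vanishes as the node count grows. The
practical difference from an untruncated Gaussian is negligible at fitted
σ_d values.

Parameter counts: 4 noise SDs (or 4 γ + ψ with ODN); plus 4 or 7 base
positions k (different means / different SDs), as many scales m for the scaled
families, and the exponent for `free_exponent`; Bayesian models have 7 d-space
boundaries, +1 for decision noise, +2 for free category parameters. Examples:
different-means distance 8, free-exponent 13; different-SDs linear 18,
Bayesian 11.

## Fitting

Maximum likelihood per participant-configuration via bounded L-BFGS-B from
`n_starts` seeded initialisations (default 20), on a transformed space where
the hard constraints are box bounds:

* σ parameterised from the smallest value (intensity 4) upward by
  non-negative increments — equivalent to the monotonicity constraint but
  box-boundable;
* Bayesian k as a first boundary minus positive gaps (strict decrease);
* the exponent as log(a−1), with a ∈ (1, 10].

Non-Bayesian k and m are fitted raw; ordering of the *realized* boundaries at
every fitted σ is enforced by a large penalty with a hinge term proportional
to the violation, so the optimizer is steered back and violating vectors are
never returned (fits are verified post hoc). Initialisation mixes random draws
from documented ranges (σ in [0.2, 8] standardized units, spanning the spread
of fitted values; boundary positions and scales of order 1) with data-driven
starts that place boundaries at response-frequency quantiles of the measurement
axis (d-space quantiles for Bayesian models) — the latter avoid
probability-floor plateaus far from the data. Convergence tolerance is 1e−6 on
the objective, below the 1e−3 tolerance used by the nesting checks.
Everything is deterministic given the seed.

Model comparison uses AIC = 2z − 2 log L and BIC = −2 log L + z·log n per
participant; group-level AIC sums per-participant AICs, while group-level BIC
sums the likelihood terms and penalises the pooled parameter count against the
pooled trial count. When AIC and BIC disagree on a preferred model, AIC is
authoritative (it recovers the generating model more reliably in the recovery
analyses below). Ties break toward fewer parameters, then lexicographic model
token.

Cross-modal joint fits of the free-exponent model share parameters at three
levels: `common` (one σ per intensity and one k, m, a for both modalities),
`different_noise` (σ free per intensity per modality; k, m, a shared — the
exponent is grouped with the boundary parameters as shared, since it is part
of the boundary rule rather than the noise model), and `flexible` (everything
free; computed as the two independent single-modality fits, whose optimum
coincides with the joint one). `fit_cross_modal_suite` warm-starts each mode
from the more constrained mode's solution, so the nesting hierarchy
(flexible ≥ different-noise ≥ common in log-likelihood) holds to optimizer
tolerance by construction.

## Synthetic data

The generator reproduces the session structure: testing blocks of 120 trials
balanced exactly (15 trials per category × intensity cell), 6 blocks per
session (720 trials), stimulus values drawn from the generating category's
Gaussian, trial order shuffled within block. Training blocks (highest
intensity, feedback) can be generated but are excluded from fitting, as in the
study design. Simulated observers draw one measurement per trial and apply the
model's decision rule exactly; the separate 100-sample averaging used for
visualisation is a plotting device and never enters fitting.

Generating-parameter draws for recovery studies emulate the spread of fitted
participant parameters: σ₄ ~ U(0.5, 1) with step ratios U(1.3, 2.2) (so
σ₁/σ₄ spans ≈2–10); base positions k of order 0–2 with a flatter profile for
scaled families (whose σ term carries most of the boundary spread); scales m
drawn as independent sorted values in [0.05, 2] so the scaling profile is not
proportional to the base positions — fitted parameter tables show exactly this
non-proportionality, and it is what makes the scaled-evidence and Bayesian
classes distinguishable; exponent a ~ U(1.2, 2.5); Bayesian d-boundaries as a
first boundary U(1, 2.5) (different means) or U(0.1, 0.6) (different SDs)
minus positive gaps; σ_d ~ U(0.15, 0.5); subjective category parameters
within ±25% of truth. All draws satisfy the type invariants by construction
and are verified against realized-boundary ordering at the drawn σ levels.

What the generator does *not* emulate: lapses, response-time structure,
sequential effects, learning across blocks, and any departure from Gaussian
measurement noise. Passing tests therefore demonstrate internal consistency of
the method (generator ↔ likelihood ↔ fitter) and its behaviour under the
models' own assumptions, not robustness of the conclusions to real-data
violations of those assumptions.

Participant-level quality control mirrors the study's exclusion rule: a
one-sided exact binomial test of highest-intensity categorisation accuracy
against chance (0.5), where a response is correct when it matches the most
probable generating category; p ≥ 0.05 excludes. One-sided because the rule is
"significantly *above* chance".

## Recovery analyses

Model recovery simulates datasets from each model in a candidate set, fits
every candidate to every dataset, and records the winner by information
criterion; the resulting confusability matrix is row-stochastic, and
distinguishable models show diagonal dominance. Both AIC and BIC winners are
recorded from the same fits; AIC yields at least as much diagonal mass, which
is the basis for preferring it. Within a recovery run, decision-noise fits are
warm-started from the corresponding noise-free Bayesian fit of the same
dataset (the models nest at σ_d = 0), which both speeds fitting and enforces
the nesting at the optimum.

Parameter recovery runs a simulate-fit loop under a single model and reports
generating-vs-recovered correlations per named parameter.

Default API scales are desk scale (20 datasets × 360 trials, 10 optimizer
starts), with study scale (100 × 720) reachable through the same arguments.
The shipped acceptance test runs model recovery on the different-SDs task at
8 datasets × 360 trials per generating model with 2 optimizer starts. The
task choice matters: on the different-means task the Bayesian boundary
profile is a constrained quadratic that free-exponent observers with a ≈ 2
can mimic, so those two models stay confusable even at the study's full
trial count, whereas the different-SDs mapping is rigidly nonlinear and the
classes separate cleanly — the same asymmetry that drives the Bayesian
class's poor fit on that task. Parameter recovery in the acceptance test
keeps 20 synthetic participants of 720 trials with the desk-scale 10 starts. Monte-Carlo generator/likelihood checks use 1e5
draws against a 3-binomial-SE band, plus an absolute 3-count slack to cover
near-zero cells (where the normal approximation to the binomial fails), and,
for the decision-noise variant, the measured quadrature discretization bound.

## Numerical choices

* Probability floor 1e−12 before logs (no lapse process).
* Region masses by CDF differences; never numerical integration.
* Penalty 1e8·(1 + violation) for realized-boundary ordering violations.
* Exact ties at evidence 0.5 label category 1 (deterministic, measure zero).
* Interval membership is half-open, closed on the left.
* Different-SDs centre b₀ fixed at 0 on the standardized axis (not fitted).
* Optimizer ftol 1e−6, maxfun 3000 (4000 for joint fits).

## Known limitations

* The different-means Bayesian boundary profile is an affine function of σ²
  shared across boundaries, which a free-exponent observer with a ≈ 2 and
  near-proportional (k, m) can mimic; model recovery between those two models
  on the different-means task is intrinsically weaker than on the
  different-SDs task, where the Bayesian mapping is rigidly nonlinear.
* Fits are point estimates; no uncertainty on parameters is reported.
* The optimizer settings (start counts, bounds, tolerances) are this
  package's choices, documented above, not prescribed by the modelling
  framework.
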