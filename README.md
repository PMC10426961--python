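# confcat

Signal-detection models of **confidence in 2AFC categorisation**: fitting,
comparison, and recovery analyses for per-trial category + confidence data.

## The problem

In a categorisation session, an observer sees (or hears) a stimulus drawn from
one of two Gaussian category distributions over a single attribute —
orientation of a grating, or frequency of a tone — reports the category, and
rates confidence on a 4-point scale. Stimulus intensity (contrast or loudness)
varies over four levels, manipulating sensory uncertainty independently of the
category evidence. The scientific question is *how* observers map evidence
strength and sensory uncertainty onto confidence, formalised as three model
classes:

1. **Unscaled evidence strength** — confidence depends only on the distance
   between the internal measurement `x ~ N(z, σ_I²)` and fixed criteria:
   `b_r = k_r`.
2. **Scaled evidence strength** — the criteria move with the estimated
   noise level: `b_r(σ) = k_r + m_r σ^a`, with a linear (`a = 1`), quadratic
   (`a = 2`) or freely estimated exponent.
3. **Bayesian** — the observer computes the log posterior probability ratio
   `d = log [p(C=1|x) / p(C=2|x)]` and compares it with fixed criteria in
   `d` space; variants add Gaussian decision noise on `d` or subjective
   (freely estimated) category-distribution parameters.

The seven criteria per model partition the axis into eight
category-confidence response regions; trial likelihoods are exact Gaussian
masses between adjacent realized criteria, models are fit per participant by
maximum likelihood and compared with AIC/BIC, and the full pipeline is
validated by parameter- and model-recovery studies on synthetic sessions. The
package is aimed at psychophysicists and computational cognitive scientists
who need a tested, reusable implementation of this model family — including
the synthetic-data generator, so every stage is testable without any
behavioural dataset.

## Worked example

Simulate one auditory different-means session (720 trials) from a
scaled-evidence-strength observer, then let three models compete:

```python
import confcat as cc

spec = cc.ModelSpec.from_token("linear", "different_means")
theta = cc.sample_generating_params(spec, seed=12, modality="auditory")
design = cc.generate_design(cc.DesignSpec(task="different_means",
                                          modality="auditory", seed=13))
trials = cc.simulate_dataset(design, spec, theta, seed=14)

fits = {"sim": {tok: cc.fit_model(trials, cc.ModelSpec.from_token(tok, "different_means"),
                                  n_starts=5, seed=0)
                for tok in ["distance", "linear", "bayes"]}}
print(cc.compare_models(fits).summary)
```

which prints

```
              aic_sum      bic_sum  n_preferred
model
bayes     1944.958236  1995.329999            0
distance  2008.830229  2045.464239            0
linear    1867.406138  1922.357152            1
```

The generating (linear) model wins by both summed AIC and summed BIC, and is
the preferred model for the simulated participant; the distance model pays for
ignoring sensory uncertainty, and the Bayesian observer's rigid boundary
scaling fits these data worse than the free linear scaling. `fit_model`
returns the fitted parameters, log-likelihood, parameter count and
information criteria; `cc.exclude_by_accuracy(trials)` applies the
binomial-test quality-control rule before any fitting.

The same machinery runs from the shell:

```bash
confcat simulate --task different_sds --modality auditory --model bayes \
    --seed 3 --out trials.tsv
confcat compare --input trials.tsv --task different_sds --out-dir results/
confcat recover --task different_sds --datasets 8 --trials 360 --out-dir recovery/
```

and `confcat run --config run.yaml` executes a fully serialised pipeline
(simulate → fit → compare → cross-modal → recover → plot) whose outputs are
bit-reproducible given the seed.

## Cross-modal parameter sharing

`fit_cross_modal_suite(trials_visual, trials_auditory)` fits the
free-exponent model jointly to both modalities under three sharing regimes —
common settings, modality-specific noise, and fully flexible — whose
log-likelihoods are nested; comparing them asks whether one parameterisation
of the confidence computation serves both modalities.

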