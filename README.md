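# graphppl

A compact probabilistic-programming library for Bayesian modeling in the
life sciences, built on its own symbolic tensor graph with reverse-mode
automatic differentiation.  It is aimed at the kind of models that come up
in biostatistics and epidemiology — change-point count models, ranking
models, over-dispersed community count tables — and at users who want the
whole inference stack (model → joint log-density → sampler → labeled
summaries) to be small enough to read.

## What it does

**Models** are built by registering named random variables in a
`ProbModel`: free (latent) variables, observed variables (NaN entries are
split off and imputed as latent variables), and named deterministic nodes.
The joint log-density over the unconstrained reparameterization is

    logp(θ̃) = Σ_i log p(θ_i | parents) + Σ_i log |d backward_i / d θ̃_i| + Σ_j log p(y_j | θ)

where bounded variables are mapped to the real line (log, scaled log-odds,
or stick-breaking transforms) with the Jacobian correction added, e.g. a
half-normal `b` is sampled through `b_log__ = log(b)` and contributes
`logp(b) + b_log__`.

**Inference**:

* `sample` — MCMC with automatic kernel assignment: a No-U-Turn sampler
  (multinomial trajectory sampling, generalized U-turn check across sub-tree
  boundaries, dual-averaging step size, diagonal mass adaptation) for the
  continuous block, adaptive random-walk Metropolis for each discrete
  variable, composed Metropolis-within-Gibbs.
* `find_MAP` — quasi-Newton optimization of the joint density.
* `smc_sample` / `abc_smc` — likelihood-tempered sequential Monte Carlo
  with adaptive tempering, systematic resampling, MH/independent-MH
  mutation, the log marginal likelihood as a by-product, and an ABC mode
  driven by a user simulator and distance.
* `fit_advi` — mean-field automatic-differentiation variational inference
  (KL operator, location-scale reparameterization gradients, Adam).
* `sample_prior_predictive` / `sample_posterior_predictive` /
  `compute_log_likelihood` — forward sampling and pointwise likelihoods from
  the same model definition.

Results come back as a `TraceStore` of labeled xarray groups (posterior,
prior, predictive, sample_stats, log_likelihood, observed_data) with
chain/draw dimensions and user coordinates, plus `summarize` (mean, sd, 94%
HDI, MCSE, rank-normalized split R-hat and bulk/tail ESS).

## Worked example

The bundled regression fixture is 50 x-values evenly spaced on [-1, 1] with
y = 3x + standard-normal noise from `numpy.random.default_rng(seed=0)`:

```python
import graphppl as gp

model = gp.build_regression_model()          # a ~ N(0,1), b ~ HalfNormal(1)
logp = model.compile_logp()
print(logp({"a": 0.5, "b_log__": 1.2}))      # -73.39055683392552

fit = gp.find_MAP(model)
print(fit["a"], fit["b"])                    # 0.1264670505850711 3.385014839756904

trace = gp.sample(model, draws=1000, tune=1000, chains=4, seed=1)
print(gp.summarize(trace, var_names=["a", "b"]).round(3))
```

which prints

```
    mean     sd  hdi_3%  hdi_97%  mcse_mean  mcse_sd  ess_bulk  ess_tail  r_hat
a  0.133  0.133  -0.118    0.385      0.004    0.003  1249.452  1030.558  1.003
b  3.385  0.231   2.938    3.804      0.003    0.002  4584.934  2836.956  1.001
```

The intercept is indistinguishable from zero and the slope posterior is
centered on 3.385 with sd 0.231 — the generating slope 3 is inside the 94%
HDI.  The change-point model for the UK coal-mining disaster series
(`gp.build_coal_model()`; 111 yearly counts, 2 missing values imputed
automatically) is sampled the same way; the 94% HDI of the switch-point
posterior spans 1885–1894 and the accident rate drops from about 3 to about
1 per year across it.

A thin CLI wraps the bundled case studies:

```bash
graphppl run coal --draws 1000 --tune 1000 --chains 4 --seed 1 --out out/
```

writes `out/trace.zip`, `out/summary.csv` and the model DAG as
`out/model.dot`.

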