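# Methods

## The computational substrate

All densities are expressions over a symbolic tensor DAG (`graphppl.tensor`).
Nodes are inputs, constants or operator applications; construction records
only the rank (scalar/vector/matrix) and full shape checking is deferred to
evaluation, which follows NumPy broadcasting.  Compilation means: rewrite
the graph to a fixed point (constant folding, `exp(log u) -> u`,
`log(exp u) -> u`, `log(1+u) -> log1p(u)`, `log(sum(exp u)) -> logsumexp`,
common-subexpression elimination; pass cap 100 guarantees termination),
topologically order it, and freeze an interpreter plan.  There is a single
double-precision interpreter backend; the compile step buys plan caching and
simplification, not code generation, and repeated evaluation of the same
inputs is bitwise identical.

Gradients are symbolic reverse-mode vector-Jacobian products.  Broadcasting
is undone by a `sum_to` plumbing operation that sums a gradient down to the
shape of the value it belongs to at run time, which keeps the rule set small
without static shapes.  `switch(cond, a, b)` evaluates both branches
(needed for vectorized condition arrays such as the year grid in the
change-point model); out-of-support branches may therefore produce NaN/inf
*inside* discarded branches, which is why evaluation runs under silenced
floating-point warnings.

## Distributions and transforms

Every family implements an elementwise closed-form log-density built from
graph primitives (hence differentiable), seeded draws through
`numpy.random.Generator`, and a default initial value.  Out-of-support
values yield `-inf` rather than raising, because samplers probe boundaries;
invalid *parameters* raise on numeric paths in strict mode (default) and
propagate NaN otherwise — the symbolic log-density path always propagates
NaN since it cannot inspect values at build time.

Default initial values are means, with two deliberate exceptions: the
log-normal uses its median `exp(mu)` (finite-variance robustness) and
discrete families round to a lattice point (floor of the midpoint for the
discrete uniform, so `DiscreteUniform(1851, 1961)` starts at 1906).

The Dirichlet-multinomial is the marginalized Pólya form,
`log C(n;x) + log B(x + a) - log B(a)` through log-gamma terms; its variance
exceeds the matched-mean multinomial variance by `(n + a0)/(1 + a0)`, which
is the over-dispersion the family exists for.  Censoring lumps tail mass
onto the bounds via the base log-CDF/survival; truncation renormalizes by
the log of the CDF difference (computed as `logcdf(u) + log1mexp(...)` for
stability) and draws by rejection.

Transforms: positive support maps through `log(x - lower)`; doubly-bounded
support through the scaled log-odds `u = log((x-a)/(b-x))`; the simplex
through centered stick-breaking with K-1 coordinates (zero maps to the
uniform point).  Discrete variables, including the discrete uniform
switch-point, get no transform.  Transforms apply to sampling only; traces,
predictive draws and summaries always report constrained values.

## Model assembly

`ProbModel` is an explicit builder (variables declared in dependency order)
rather than a context manager, so the contract is language-agnostic.  The
joint log-density substitutes every random-variable node with the
back-transformed value of its unconstrained input node and sums per-variable
contributions plus log-Jacobians.

Missing observed values (NaN markers in a float container, also for
discrete data) split the observation vector: the missing part becomes a free
variable whose "prior" is the likelihood family evaluated at the missing
indices, and the full vector is reassembled with a scatter so the observed
part contributes data terms and the missing part contributes its own prior
terms through the same expression.  The combined vector is traced under the
original name; the DAG export shows the observed part (gray, plate 109 for
the coal series) and missing part (plate 2) separately.

## MCMC

Continuous variables share one NUTS block; each discrete variable gets its
own adaptive random-walk Metropolis kernel (Gaussian increments, rounded for
integer support, scale tuned every 100 iterations toward a 0.1–0.7
acceptance band); kernels compose as Metropolis-within-Gibbs.

NUTS uses multinomial sampling over the doubling trajectory (node weights
`exp(H - H0)`, progressive sampling biased toward the new sub-tree) and a
generalized U-turn criterion on momentum sums, checked for the combined tree
*and* across both sub-tree boundaries at every merge.  Divergence is an
energy error above 1000.  Step size follows Nesterov dual averaging
(gamma=0.05, t0=10, kappa=0.75, target acceptance 0.8, initial step found by
a doubling search crossing 0.5 acceptance); the anchor at `log(10*eps0)`
deliberately biases the first iterates upward.  The diagonal mass matrix is
re-estimated over expanding windows (first window after 25+25 iterations,
doubling, with a 50-iteration terminal buffer), each estimate regularized as
`(n/(n+5)) var + 1e-3 (5/(n+5))` so it stays positive even for constant
draws; dual averaging restarts when the metric changes.

Initialization is the default initial point plus Uniform(-1, 1) jitter per
continuous coordinate in transformed space, re-jittered up to 100 times
until the joint density is finite (the error names the offending term).
Chains run sequentially; every chain derives its generator from
`SeedSequence(seed).spawn(chain)` so runs are bitwise reproducible per
(seed, chain index).  Tuning draws are discarded by default; deterministic
nodes are recomputed from posterior draws rather than stored while stepping.

`find_MAP` optimizes the transformed joint density **without** the Jacobian
terms (the mode of the constrained-space density, computed in unconstrained
coordinates) by L-BFGS-B with exact gradients.  This convention reproduces
the transcript values of the worked regression example; note it makes the
MAP of a lone half-normal collapse toward zero, which is a property of the
convention, not a defect.

## SMC and ABC

Tempering bridges prior to posterior via `prior * likelihood^beta`.  Each
stage raises beta by bisection (50 iterations, tolerance 1e-10) so the
relative ESS of the incremental weights is 0.5, accumulates the stage
log-mean weight into the log marginal likelihood, resamples systematically,
and runs 5 MH passes per particle — random-walk proposals with the ensemble
covariance scaled by 2.38^2/d, or independent proposals from the
ensemble-moment normal (useful without gradients).  ABC replaces the
likelihood with the Gaussian kernel `exp(-d^2 / (2 eps^2))` of the simulator
distance; simulator exceptions yield `-inf` pseudo-likelihood and a warning
count.  The beta ladder, acceptance rates and evidence increments are
returned in `sample_stats`.

## Variational inference

The objective abstraction is operator/approximation/test-function/distance;
only the KL operator with identity distance ships, for which the test
function provably drops out (asserted in tests by swapping test functions).
The family is the mean-field normal over transformed coordinates, scale
parameterized by softplus.  Gradients use the location-scale
reparameterization with the entropy term differentiated analytically
(`d/dsigma E[log q] = -1/sigma`), optimized by Adam (lr 1e-2 default,
1 MC draw per step).  Because single-draw Adam jitters around the optimum
at stationarity, the returned parameters are Polyak-averaged over the final
25% of iterations.

## Summaries

HDI is the shortest interval containing `ceil(prob*n)` sorted draws (94%
default).  R-hat is rank-normalized split R-hat (maximum of the location
and folded-scale versions); ESS is rank-normalized bulk ESS and tail ESS
(minimum over the 5%/95% exceedance indicators) with FFT autocovariances and
Geyer's initial positive monotone pair truncation; ties get average ranks.
MCSE of the mean is `sd/sqrt(ess_bulk)`; MCSE of the sd uses the standard
delta-method approximation.  Constant chains report R-hat as NaN on purpose:
an undefined variance ratio should be visible, not masked as 1.0.  These
estimators match the arviz implementations to numerical precision on iid
input (cross-checked in tests, where arviz serves as the independent oracle
only).

Traces persist as a single zip of JSON metadata plus `.npy` arrays —
a documented container with bitwise round-trip, chosen over NetCDF groups
so the on-disk format has no dependencies beyond NumPy.

## Synthetic generators and what they do not show

* The regression fixture is exactly the documented generating process
  (50 points, slope 3, unit noise, PCG64 seed 0); three reported numbers
  depend on the realized noise stream, so the generator is pinned to the
  default NumPy bit generator.
* The Bradley-Terry generator draws skills from Normal(0, sigma^2)
  (sigma = 1 default, so ~95% of skills fall in (-2, 2)), uniformly random
  distinct pairings, and logistic win probabilities.  Defaults: 20 players,
  2,000 matches.  It does not emulate longitudinal skill drift, surface
  effects or scheduling structure of real match data.
* The forest-count generator draws each row of a 10x5 table (row total 100)
  from a Dirichlet-multinomial with a skewed composition and concentration
  10 — over-dispersed but exchangeable rows; real community tables add
  spatial correlation and unequal sampling effort that it does not model.

Passing tests on these generators show the inference machinery recovers
parameters under the assumed generative processes; they say nothing about
model misspecification on real data.

## Problem sizes used in the shipped checks

The reproduction runs use the study sizes: 4 chains x (1000 tune + 1000
draws) for both the coal and regression fits.  Property checks run at
deliberately reduced sizes chosen for tight-but-cheap Monte-Carlo error:
SMC evidence with 800 particles, ADVI with 10,000 steps, rank-calibration
with 120–150 replicates of 63 posterior draws each, KS draw checks with
5,000 draws per family, quadrature normalization on 20,001–120,001-point
grids.

## Known limitations

* Single interpreter backend: evaluation cost is per-graph-node Python
  dispatch; large-data models pay interpreter overhead per leapfrog step.
* Simplex transforms support one simplex vector per variable (no batched
  simplex dims); missing-value splitting supports 1-D observation vectors
  and scalar-event families.
* No sparse-matrix operations; dense graphs only.
* The Metropolis kernel for the discrete switch-point mixes by rounded
  Gaussian increments; multimodal discrete posteriors with distant modes
  would need a specialized proposal.
* SMC mutation kernels are MH/IMH only (no HMC mutation), and the ABC
  bandwidth eps is fixed, not annealed.
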