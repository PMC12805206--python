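# Methods

## Model

`omrfdiff` works with the ordinal Markov random field (OMRF), the
exponential-family joint distribution over `p` ordinal variables

    P(x) ∝ exp( Σ_i μ_{i,x_i} + Σ_{i<j} σ_ij x_i x_j ),

where `x_i ∈ {0,…,m_i}` are category indices, `μ_{ic}` are category
thresholds with the baseline `μ_{i0} = 0` fixed for identifiability, and
`σ_ij` is a symmetric pairwise interaction matrix with zero diagonal.  The
full conditionals are adjacent-category logit models,

    P(X_i = c | x_{−i}) ∝ exp( μ_{ic} + c · Σ_{j≠i} σ_ij x_j ),

and the interaction enters as the product of category indices
(linear-by-linear association).  Because the sufficient statistics are built
from cumulative indicators, the model uses only the *order* of the
categories: any order-preserving relabeling leaves the likelihood
bit-identical.  With all `m_i = 1` the model is exactly the Ising model —
both facts are verified by the test suite against independent enumeration
oracles.

### Two groups

For two independent samples every parameter is written as an overall value
plus a group contrast carried half-and-half:

    group 1 = φ − δ/2,   group 2 = φ + δ/2,

so `δ = group2 − group1` and `φ` is the group average.  Group labels map to
1/2 by first appearance in the data (configurable); the sign of every `δ`
depends on this coding, so it is echoed in all reports.

The joint normalizing constant sums over `Π_i (m_i+1)` configurations and is
intractable beyond toy sizes (an exact enumeration oracle with a 10^7-state
guard is provided for testing).  All inference therefore targets the
**pseudoposterior**: priors combined with the pseudolikelihood, the product
of full conditionals over rows and variables of both groups.  Pseudolikelihood
posteriors are consistent but not exact finite-sample posteriors; in our
recovery experiments their 3-sd coverage of generating interactions sits
near, but slightly below, the nominal Gaussian level (~96–97% at n = 2000
per group, p = 6, four categories).

### Category alignment across groups

Thresholds attach to categories, so a category observed in only one group
has no estimable difference.  Two strategies:

* **Free** — each group's coding squeezes out its own unobserved categories;
  group thresholds are estimated independently and the threshold-difference
  test is disabled (interaction differences remain testable).
* **Collapse** — a category unobserved in *either* group merges into the
  next lower category (next higher when the lowest is missing) in *both*
  groups, preserving a common coding.  Interior categories merge downward
  even when observed in the other group: symmetric treatment is the point of
  Collapse mode.  Categories observed in neither group are removed outright.

A variable left with fewer than two observed categories in either group is
an error.  The alignment plan (explicit old→new code maps per group) is
serialized into every report for audit.

## Priors

| component | prior | default |
|---|---|---|
| overall thresholds `μ` | beta-prime on `exp(μ)` | a = b = 1 (standard logistic on `μ`) |
| overall interactions `σ` | Cauchy(0, s) | s = 2.5 |
| difference slabs `δ` | Cauchy(0, s) | s = 1.0 (thresholds and interactions; separately overridable) |
| difference indicators | Bernoulli(π) or BetaBernoulli(α, β) | π = 0.5; α = β = 1 |

The spike is an exact point mass: an excluded difference is stored as
literal zero, and the zero-consistency `indicator = 0 ⟺ parameter = 0`
holds in every posterior draw.  Bernoulli(½) makes every configuration of
differences equally likely a priori; BetaBernoulli(1, 1) makes the *count*
of included differences uniform, the standard multiplicity correction.
Threshold-difference indicators are per variable and govern the whole
threshold-difference vector ("is there any difference in this variable's
marginal profile?"), interaction indicators are per pair.  The continuous
scale defaults (2.5 and 1.0) are package conventions exposed in
`PriorConfig`; all reported analyses echo the full prior configuration.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs over four parameter families:
overall thresholds (scalar moves), overall interactions (scalar moves),
threshold-difference vectors (joint diagonal-Gaussian vector moves — the
test concerns the whole vector), and interaction differences (scalar
moves).  Parameters start at zero, proposal scales at one.  Each burn-in
update adjusts the scale by a Robbins–Monro recursion on the log scale,
`log s ← log s + step^(−0.6) · (accepted − 0.44)`, clipped to [1e−3, 100];
adaptation freezes after burn-in so the main phase keeps the exact invariant
distribution.  The family order is reshuffled every iteration (systematic
sweep within a family); this grouping keeps one update per block per sweep
while letting the inner loops run inside compiled kernels.

**Selection mode** adds a pairwise Metropolis step that flips each
difference indicator together with its parameter (no reversible-jump
machinery): a 0→1 move draws the candidate from the tuned Gaussian proposal
centered at zero and accepts with pseudolikelihood × slab ÷ proposal
density × conditional prior odds of inclusion; 1→0 is the exact reverse.
Under the beta-Bernoulli prior the odds condition on the number of other
included indicators in the same family.  The burn-in is split in half:
phase 1 tunes proposals with all differences free (no indicator moves),
phase 2 adds indicator updates.  Defaults: 10,000 main iterations after
2 × 2,500 burn-in, all configurable.

Correctness is validated three ways rather than step-for-step against any
particular implementation: (i) with zero observations the sampler must
reproduce its prior exactly — Bernoulli/beta-Bernoulli indicator marginals
and count distributions, and Cauchy slab marginals (KS test); (ii) on a
p = 2 binary toy with fixed overall parameters the posterior inclusion
probability must match 1-D quadrature of the spike-and-slab pseudoposterior
(observed agreement ~2·10⁻⁴ at 200k iterations, tolerance 0.02); (iii)
estimation-mode posteriors must cover generating parameters.

### Implementation note

The hot path avoids per-row transcendentals: per group the sampler caches
`E = exp(X σ_g)` and the per-column conditional normalizers, so a block
update costs a numerator change that is a constant times a sufficient
statistic (category counts, or `Σ_t x_i x_j`) plus chunked
log-normalizer-ratio sums (one `log` per 8 rows).  Caches are multiplicative
and refreshed from the additive rest scores every 1,000 iterations to stop
floating-point drift.  Overflowing proposals yield −∞ acceptance ratios
(rejection), so reachable states are always finite.  Kernels compile with
numba; a pure-Python fallback exists for debugging only.  One `numpy`
Generator seeded from the run seed drives everything; runs are bit-identical
given the seed.

## Inference outputs

Posterior inclusion probability (pip) = mean of the indicator chain.
Inclusion Bayes factor `BF_10 = [pip/(1−pip)] / prior_odds`, with
`prior_odds` = π/(1−π) or α/β.  A pip of exactly 0 or 1 only bounds the BF:
it is clamped to `1/(2T)` from the boundary and flagged, so users never see
an unbounded BF silently.  Summaries report model-averaged moments and 95%
central intervals (type-7 quantiles) for every parameter and, for tested
effects, moments conditional on inclusion — omitted (reported as missing,
not zero) when the effect was included in fewer than 10 draws.

## Synthetic data generator

The generator emulates a two-group psychometric simulation:

* **Overall network** — each of the `p(p−1)/2` potential interactions is
  retained independently with probability `density` (0.15 sparse, 1 dense);
  nonzero values are drawn from an interaction pool.  Empirical pools can be
  supplied; the default is a **synthetic** shifted-gamma surrogate
  (shape 2, scale 0.1, shift −0.05 → mean 0.15, right-skewed, mostly
  positive), standing in for the right-skewed, predominantly positive
  partial-association distributions typical of questionnaire networks.
  Thresholds default to Gaussian draws (mean 0, sd 0.5), giving roughly
  balanced 4-point Likert-style marginals.
* **Group differences** — a `prop_diff` fraction of all pairs (rounded to a
  count) receives `δ` with `|δ| ~ Uniform(diff_low, diff_high)` and a fair
  random sign; defaults 0.1–0.5.  Threshold differences are zero: the
  harness targets interaction differences, and the analysis model
  correspondingly assumes threshold equality.
* **Marginal comparability across densities** — sparsifying a mostly
  positive network shifts marginals downward, confounding density with
  marginal location.  When `density < 1` the generator re-centers thresholds
  by a deterministic log-odds fixed-point pass so the sparse model's exact
  marginals match those of its dense counterpart (skipped with a warning
  beyond the enumeration guard).
* **Safeguard** — the whole process (truth and data) is resampled until the
  second-most frequent category of every variable in both groups has at
  least `min_second_category_count` (default 10) observations; under the
  default design the mean resample count is well below one.

Exact sampling inverts the enumerated joint pmf; beyond the guard, a
vectorized single-site Gibbs sampler (default 1,000 sweeps from uniform
starts) is used, cross-validated against exact moments.

What the generator does *not* emulate: empirically calibrated parameter
values from a specific instrument, missing data, local dependence or method
factors, and more than two groups.  Passing tests therefore demonstrate
internal validity of the machinery under the stated design, not performance
guarantees on any particular empirical dataset.

## Evaluation

Structure recovery is scored threshold-free: pip values are used directly as
scores and summarized by the ROC curve and its area, computed via the
Mann–Whitney identity with midrank ties (equal to trapezoidal integration of
the staircase; cross-checked against scikit-learn).  AUC 0.5 is chance.
`run_simulation_cell` derives per-replicate substreams from one seed, with
the truth model on its own stream, so condition cells that differ only in
sample size share truth draws and sample-size comparisons are paired.

## Problem sizes used in the shipped checks

The package's own validation runs use deliberately scaled-down designs
chosen to make Monte-Carlo error small relative to each check's margin:
prior recovery at 20–40k iterations; quadrature agreement on a p = 2 binary
toy at 200k iterations; evidence growth at p = 4 binary, n ∈ {100, 500,
2000} per group, 10 seeds; recovery coverage at p = 6, four categories,
n = 2000 per group, ~10 seeds; the harness at p = 6, density 1,
prop_diff 0.3, 20 replicates, n ∈ {200, 1000}.  At 20 replicates the AUC
difference between the two sample sizes carries noticeable replicate noise
(paired sd ≈ 0.2): in a dense network a single partial-association
difference shifts the marginal moments of many null edges, and the smallest
drawn `|δ|` values are near-undetectable at either sample size.  Full-scale
designs with ~100 replicates resolve the gradient clearly.

## Known limitations

* Pseudolikelihood, not full likelihood: consistent, but finite-sample
  evidence calibration can differ from the exact posterior's.
* Random-walk updates mix slowly for strongly coupled dense networks; no
  gradient-based proposals are implemented.
* Exactly two independent groups; no repeated measures, no covariates.
* Missing data are rejected at construction rather than modeled.
* The stochastic block indicator prior is not offered for difference
  indicators (only Bernoulli and beta-Bernoulli).
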