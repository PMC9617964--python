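# Methods

This note defines the statistical procedures and data-generating processes
(DGPs) implemented in `permnet`, the defaults they use, and the reasoning
behind the design choices that were genuinely open.

## Data model

A weighted undirected network on *n* nodes is a symmetric real matrix over
unordered node pairs (`DyadMatrix`). Self-dyads do not exist: the diagonal
is stored as zero and never read by any analysis. Node strength is the row
sum `s_i = Σ_{j≠i} w_ij`, so total strength is exactly twice the total edge
weight. Dyadic analyses vectorise a matrix over its *n(n−1)/2* unordered
pairs in fixed lexicographic order; with a seeded generator this makes
every permutation test bit-reproducible. Node indices are 0-based in the
library and 1-based in all CSV formats.

## Inference procedures

**Nodal LM.** Simple linear regression of a node vector on another, with
intercept; the slope gets a two-sided t-test on *n − 2* degrees of freedom.

**Node-label permutation test.** The same slope statistic; the null is
built from `n_perm` uniformly random permutations of the response labels.
The two-sided p-value uses the add-one estimator
`p = (1 + #{|β*| ≥ |β̂|}) / (n_perm + 1)`, which counts the observed
statistic in its own null and so is valid (never zero) for any `n_perm`.
Two-sidedness is defined by the |slope| ordering.

**Dyadic LM.** Both dyad vectors are mean-centred and a no-intercept least
squares fit `ỹ = β x̃` is computed; this is algebraically identical to
intercept-including simple regression on the raw vectors, and the t-test
uses *n(n−1)/2 − 2* degrees of freedom. Each unordered dyad enters once
(upper triangle); symmetric matrices carry one observation per dyad, and
duplicating ordered copies would only rescale degrees of freedom without
adding information.

**QAP.** The quadratic assignment procedure reports the unadjusted dyadic
LM slope and replaces only its p-value: the null is formed by applying
`n_perm` uniform random node relabellings to the predictor matrix —
moving all of a node's edges simultaneously, which preserves the
dependence of dyads on their member nodes — and recomputing the slope.
Permuting the predictor rather than the response is an arbitrary choice
for a two-matrix test; the two are equivalent in distribution.

**MMLM.** The multimembership linear model

    y_ij = β x_ij + u_i + u_j + ε_ij,   ε_ij ~ N(0, σ²)

gives every dyad the effects of both of its member nodes. The design
matrix is the x dyad vector plus *n* node-incidence columns (two 1s per
row). Because the objective is quadratic, the model is solved as an exact
dense least-squares problem rather than by a generic numerical optimiser:
the minimiser is identical, deterministic, and testable against the normal
equations. `u` is treated as a vector of fixed unknowns (no shrinkage).
Inference on β is a Wald t-test with *n(n−1)/2 − (n+1)* residual degrees
of freedom. A rank-deficient design (for example a predictor matrix that
is constant across dyads, which lies inside the incidence span) raises a
degenerate-design error naming the dependent columns. Note the incidence
columns span the intercept, so the β estimate is centring-invariant.

**Exact enumeration oracle.** For instances with at most 7 nodes (5040
permutations) the full permutation null can be enumerated; the exact
two-sided p-value is the proportion of the enumeration, which includes the
identity, at least as extreme as the observed statistic. This exists to
validate the sampled tests and refuses larger sizes.

## Data-generating processes

All four DGPs default to *n* = 20 nodes and retain every latent variable in
the returned sample so that constructions can be verified term by term.
Replicate *k* of a study uses an independent child stream of the master
seed, so any single replicate can be regenerated in isolation.

### Trait-based gregariousness network (nodal)

Each individual receives a gregariousness score `g_i ~ Poisson(λ)`,
λ = 5 by default. In each of *P* = 60 sampling periods a pair interacts
with probability `(g_i + g_j) · c`; the edge weight is the interaction
count divided by *P* (a simple rate index — strength-on-trait regression
p-values are invariant to this scaling). The proportionality constant
defaults to `c = 1 / (2(λ + 6√λ))`, which keeps the probability inside
[0, 1] for all but astronomically unlikely Poisson draws (~10⁻¹¹ per dyad
at the default λ); a probability outside [0, 1] is a hard configuration
error, never a silent clip, so the bound is chosen to make that error
practically unreachable while preserving meaningful gregariousness
contrast. Sex is Bernoulli(0.5) under the null; under the effect,
`P(sex = 1) = 1/2 + w·(rank(g_i)/(n+1) − 1/2)` with full weight `w = 1` by
default — rank-based so the probability is guaranteed valid for any
gregariousness distribution. The null false-positive rate of
strength-on-sex regression is insensitive to all of these constants; the
effect-case power does depend on them, so power for this scenario is a
property of the chosen defaults rather than a universal quantity.

### Two-clique network (nodal)

Nodes join one of two cliques with equal probability. Dyads within a
clique carry an edge with probability 0.8, between cliques 0.4; present
edges get U(0,1) weights. The covariate is

    t_i = β_s · s_i + 1.0 · v_{clique(i)} + 0.5 · ε_i,

with per-clique values `v ~ U(0,1)`, noise `ε_i ~ U(0,1)`, and
`β_s ∈ {0, 0.05}`. Under the null (β_s = 0) the covariate still tracks
clique membership while strength tracks clique *size* — a stochastic
confound that inflates the false positive rate of both the LM and the
node-label permutation test to roughly 14% at these defaults. The clique
and noise coefficients are not identified by the scenario definition; the
noise coefficient of 0.5 was fixed once so that the null inflation sits in
the published regime for this kind of confound (~13–14%), and the
package's qualitative claims (inflation well above the nominal level,
LM ≡ permutation) hold across a wide band of these coefficients. Power at
β_s = 0.05 is likewise coefficient-dependent (~34% here) and is not
treated as a portable quantity.

### Node-dependent dyadic matrices

For `r, s ~ U(0,1)ⁿ` and dyad noise `x'_ij, y'_ij ~ U(0,1)` drawn once per
unordered pair:

    x_ij = r_i + r_j + x'_ij
    y_ij = β′ x_ij + (1 − β′)(s_i + s_j + y'_ij)

with β′ = 0 (null) or β′ = 0.20 (effect). Both matrices carry additive
node effects; under the null they are independent, but the naive dyadic LM
treats the 190 dyads as independent observations and its false positive
rate is grossly inflated (~37%), while QAP and the MMLM — which encode the
same node-dependence assumption by constraint and by explicit terms
respectively — hold the level. At β′ = 1, y equals x exactly.

### Clique-dependent dyadic matrices

As above, plus `K` = 10 cliques: each clique is a uniformly random 4-node
subset (cliques may overlap) with a value `c_k ~ U(0,1)`. A node's clique
load is `h_i = Σ_{k ∋ i} c_k`, and the scaled load of both member nodes,
`0.25 · (h_i + h_j)`, is added to the structural part of *both* matrices:

    x_ij = r_i + r_j + x'_ij + 0.25 (h_i + h_j)
    y_ij = β′ x_ij + (1 − β′)(s_i + s_j + y'_ij + 0.25 (h_i + h_j))

The shared load makes x and y genuinely associated under β′ = 0: the
naive LM is both biased (null slope median ≈ 0.2) and wildly anticonservative
(~66% false positives); QAP is intermediate (~20%) because relabelling one
matrix destroys the cross-matrix alignment of the shared component and so
its null distribution is centred at zero while the observed slope is not;
the MMLM absorbs the load exactly into its node effects and keeps both an
unbiased slope and a ~5% false positive rate. The design choice that the
clique influence is mediated by member nodes (rather than attaching an
extra value directly to within-clique dyads) is deliberate: a shared
dyad-level component orthogonal to the node-incidence span is *amplified*
by the multimembership projection (removing node structure shrinks the
predictor variance faster than the shared covariance), which contradicts
the observed behaviour of multimembership models in this setting —
unbiased estimates and nominal error rates. The load scale of 0.25 was
fixed once to put the naive-LM bias in the published regime (~0.2); with
`shared_clique_values = False` the response cliques draw independent
values and the confound disappears, giving a clean negative control.
`K = 0` reduces the process exactly (bit-for-bit at equal seed) to the
node-dependent DGP.

## Experiment harness

`run_scenario` simulates each replicate once and applies every method
appropriate to the scenario to the same sample (nodal: LM + node-label
permutation with 10,000 permutations; dyadic: LM + QAP with 1000
permutations + MMLM), recording slope and p per (replicate, method).
Summaries are pure functions of the records: positive rate at α = 0.05,
the median and equal-tailed 95% empirical interval of the slope estimates
(linear-interpolation quantiles), the wrong-sign share, and the share that
is wrong-signed *and* significant at the same α. Default study size is
1000 replicates; the CLI's `--profile quick` (200 replicates, 2000 nodal /
500 QAP permutations) trades Monte-Carlo precision for speed. The
full-scale studies each take seconds to a couple of minutes on one CPU
because permuted slopes are computed as vectorised gathers rather than
per-permutation refits.

## Numerical choices and degenerate inputs

- Matrix CSVs are symmetrised by averaging the two triangles; asymmetry
  beyond 1e−9 is an error, not a warning.
- Permutation p-values live in `[1/(n_perm+1), 1]` by construction; the
  |statistic| comparison uses a 1e−12 slack so ties (for example an
  all-zero null) count as at-least-as-extreme.
- A constant predictor (nodal or dyadic) raises a degenerate-design error;
  a constant response yields slope 0 and p = 1.
- Quantiles everywhere use numpy's linear-interpolation definition.
- Wrong-sign rates are reported as NaN under the null, where no true
  direction exists.

## What the simulations do and do not show

The DGPs are deliberately minimal: uniform edge weights and covariates, no
sampling error in edge observation (except the trait scenario's binomial
sampling), no missing nodes, no directed or temporal structure. Passing
the studies shows that each method behaves as its assumptions predict
under a *known* dependence structure; it does not show that any particular
empirical network satisfies those assumptions, and constants that the
scenario definitions leave free (trait-simulation sampling constants, the
two-clique covariate coefficients, the clique-load scale) make the
*power* of the confounded scenarios a property of this package's defaults
rather than a universal number. Quantities that are robust to those
constants — null error rates of correctly-specified methods, the
LM/permutation equivalence, the LM > QAP > MMLM ordering under clique
confounding, and the entire node-dependence study, whose DGP is fully
specified — are the ones asserted in the test suite.

Known limitations: the MMLM treats node effects as fixed unknowns (no
shrinkage, no REML); the upper tail of its effect-estimate distribution in
the node-dependence study is slightly narrower here than optimiser-based
fits of the same model tend to report, consistent with the absence of
optimisation jitter in an exact solve; MRQAP variants (multiple
predictors, double semi-partialling), GLM links, and Bayesian
multimembership fits are out of scope.
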