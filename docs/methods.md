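# Methods

## Model and assumptions

`blcmdx` implements a two-class latent class model for K ≥ 2 binary
diagnostic tests applied to one population. The latent disease status is
Bernoulli(π); given status, each test is Bernoulli with success
probability Se_k (diseased) or 1 − Sp_k (non-diseased). Selected disjoint
test pairs may be conditionally dependent within each class: the pair's
within-class 2×2 joint is its independence table shifted by an additive
covariance (Cd for the diseased class, Cn for the non-diseased), positive
cells where the two results agree, negative where they differ. Requiring
all four joint cells to be non-negative yields the admissible interval
`cov_bounds(p_i, p_j)`; the interval always contains zero and collapses
for a perfect test. Cell probabilities for a full result pattern multiply
the independent tests' margins by each pair's joint cell and mix the two
classes; the observed 2^K table is multinomial in these cells. The
multinomial coefficient is constant in the parameters and omitted from
all log-likelihood values.

Assumptions worth stating plainly: two latent classes (a heterogeneous
"non-diseased" class, e.g. mixing MCI and cognitively normal subjects in
the AD analysis, is absorbed into one class); dependence only within the
declared pairs and only at second order; one population with a common π;
dichotomization of the underlying scores fixed upstream.

## Identifiability and priors

With K = 3 and one dependent pair the model has 9 free parameters against
7 multinomial degrees of freedom, so it is **not identified by the data
alone**: the likelihood is constant along a ridge that trades the
dependent pair's accuracies against the covariances and π. Informative
priors are therefore not a convenience but part of the model. This drives
two design facts:

- The packaged analyses use the study's informative Beta priors
  (effective prior sample sizes in the tens to hundreds); covariances get
  nominal Uniform(−1, 1) priors whose density is truncated to the
  admissible region at evaluation time — equivalent to the rejection
  behavior of a general-purpose Gibbs sampler.
- The simulation-based recovery study elicits weakly informative priors
  *centered on the generating values* (mode at the truth, 5th percentile
  0.15 below it, effective prior sample size ≈ 25). With priors centered
  elsewhere, the posterior mean moves along the likelihood ridge by
  roughly the prior's pull regardless of n — measured at ≈ 0.09 for the
  dependent pair's sensitivities with mode-0.75 priors at n = 20,000.
  That is a property of the model class, not a sampler defect, and the
  recovery tolerances (|bias| < 0.03, coverage compatible with 95%) are
  meaningful only in the truth-consistent prior regime that mirrors how
  the method is used.

Prior elicitation follows the diagnostic-testing convention: a central
value (mode by default, mean optionally) plus one percentile constraint,
solved along a one-dimensional concentration family by bracketed root
finding to |quantile error| < 1e−6, with infeasible combinations rejected
rather than approximated.

## Sampling protocol

Metropolis-within-Gibbs, one parameter per step: probability parameters
propose on the logit scale (with the Jacobian correction), covariances
propose on their natural scale with the step rescaled to the current
admissible interval width. Step sizes adapt toward 0.44 acceptance during
burn-in (Robbins–Monro with decaying gain) and freeze afterwards, so
retained draws come from a fixed kernel. Defaults follow the study
protocol — 100,000 iterations, the first 50,000 as burn-in/adaptation,
thinning 10, one chain — retaining 5,000 draws; a multi-chain mode feeds
the split-chain scale-reduction diagnostic. Initial points draw the
probability parameters from their priors with covariances at zero (always
admissible); a non-finite starting density triggers bounded retries, then
an explicit error. Identical seeds reproduce chains bitwise.

The mirror mode (π ↔ 1−π, Se ↔ 1−Sp) is left to the informative priors by
default, which suppress it completely in the packaged analyses; an
optional per-test constraint Se + Sp > 1 is available for weakly
identified settings and is OFF by default.

Summaries report pooled posterior means, medians and equal-tailed 95%
percentile intervals (the common general-purpose-sampler default; HPD
intervals could differ in the second decimal but means are unaffected).
Youden's index per test is computed from the posterior means,
J = Se_mean + Sp_mean − 1, with the draw-wise version and its interval
reported alongside. Effective sample size uses the truncated
autocorrelation sum (Geyer-style pairwise truncation); the convergence
flag requires ESS ≥ 400 per parameter and split-Rhat < 1.05 when two or
more chains exist. A posterior-predictive cell check reports, per cell,
the posterior mean expected count and the fraction of draws whose
expected count exceeds the observed count.

## Cutoff selection

For continuous scores with reference labels, ROC candidate rules are the
midpoints between adjacent distinct observed scores plus the two extreme
rules. Tests are directional: MoCA/MMSE code impairment as a *low* score,
ADAS-cog as a *high* score. The optimal rule maximizes Youden's J; ties
break toward higher sensitivity, then toward the rule classifying more
subjects positive (the screening-friendly choice — unspecified in the
source conventions). Cutpoints are reported in midpoint form together
with a rendered inequality on the observed grid ("< 22" for
lower-is-positive integer scores, "≥ 13" for higher-is-positive scores,
using the smallest observed score strictly above the cutpoint).

## Synthetic data

The generator emulates exactly the structure the analysis assumes:
multinomial tables from the model's cell probabilities, or subject-level
draws (latent status, then pair results from the same margins-plus-
covariance 2×2 joint, then independent tests) with optional
class-conditional normal scores whose locations/scales can be set to
realistic test values (e.g. MoCA ≈ 17 ± 4 impaired vs 26 ± 2.5 healthy).
It does **not** emulate covariate structure (age, education), item-level
or longitudinal behavior, score discreteness/ceiling effects, or a third
latent class — so passing recovery tests demonstrate internal consistency
of model + sampler + summaries, not robustness to those real-data
features. `recovery_study` closes the loop (simulate → fit → summarize)
and reports per-parameter posterior-mean bias and 95%-interval coverage,
recording rather than dropping replicate failures.

## Numerical choices and problem sizes

- Cell probabilities are exact products/sums on 2^K-vectors; admissibility
  violations raise identified errors, and the log-posterior is −∞ outside
  the truncated region (covariance proposals there are rejected).
- Zero-count cells contribute exactly zero to the log-likelihood; a
  zero-probability cell with a positive count gives −∞.
- The test suite runs the two study analyses at the full 100,000-iteration
  protocol; the recovery study uses 20 replicates at n = 20,000 with
  20,000-iteration chains (2,000 retained draws each), and the conjugate
  sampler check uses 16,000-iteration chains — sizes chosen to keep Monte
  Carlo error well below the tolerances they are checked against.

## Known limitations

- The reported study tables cannot all be reproduced simultaneously at
  tight tolerance from the printed inputs under this parameterization;
  an independent general-purpose Gibbs engine (JAGS, exercised in the
  test suite's cross-engine check) agrees with this implementation on
  the same inputs, so the residual gaps trace to the original
  computation's unpublished details rather than to this package. The
  affected quantities are the MCI prevalence and the ADAS-cog accuracies
  in the MCI analysis.
- Single-population design: no multi-population (Hui–Walter) or
  covariate-adjusted variants.
- Dependence is pairwise, additive and disjoint; three-way terms and
  random-effects (latent trait) dependence are out of scope.
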