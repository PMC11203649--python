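# Methods

## The problem and the model

Respondent-driven sampling (RDS) surveys hidden populations — here,
Venezuelan migrant women of reproductive age in two Brazilian cities — by
letting participants recruit their own peers with a fixed number of coupons
(three per participant). Because no sampling frame exists, inference rests on
two modeling ideas:

1. **Random-walk selection.** A member's chance of being invited is taken to
   be proportional to her network degree (the number of eligible
   acquaintances she reports). The RDS-II estimator therefore weights each
   respondent by the inverse of her reported degree; a category's prevalence
   is the ratio of the weighted count to the total weight. Self-reported
   degrees are noisy, so they are truncated to [3, 150] before inversion
   (configurable), and weights are rescaled to sum to the number of non-seed
   respondents so that weighted and unweighted counts sit side by side.
   Seeds — hand-picked, not sampled — are excluded from all estimation but
   kept as roots of the recruitment forest, because wave structure needs
   them. Zero or missing degrees are raised to the truncation floor rather
   than dropped: dropping would silently change the estimator's denominator.

2. **First-order Markov recruitment.** The category of a recruit is modeled
   as depending only on her recruiter's category. The recruiter -> recruit
   transition matrix estimated from the coupon edges yields (a) a homophily
   diagnostic — are the conditional recruit distributions homogeneous across
   recruiter categories? — and (b) the equilibrium (stationary) distribution
   the sample composition approaches as waves accumulate, plus the number of
   waves needed to get within a tolerance of it. The homogeneity test is a
   Pearson chi-square on the raw pair-count table, without continuity
   correction. Conditional rows are *reported* weighted by the recruit's
   RDS-II weight (so the Total row agrees with the weighted prevalence
   table), but the test always uses raw counts: a count-based test applied to
   weighted proportions would need effective-sample-size machinery the design
   does not provide. Pairs whose recruiter is a seed are excluded from the
   cross-tab; the seeds' recruits still enter prevalence tables.

## The synthetic-data generator

The simulator provides ground truth for every downstream stage. Its defaults
reproduce the surveyed study conditions: marginal category distributions and
transition rows from the published city tables, 6 seeds / 755 recruits
(Manaus) or 9 seeds / 1,259 recruits (Boa Vista), three coupons per
participant, and coupon acceptance probabilities 0.87 (Manaus) and 0.67
(Boa Vista), set once to match the reported ~2.6 and ~2 recruits per
recruiter. Degrees follow a discrete lognormal (median 15, sigma 0.9 —
median chosen inside the plausible range of "acquaintances known by name",
sigma giving the heavy right tail typical of self-reported network sizes)
clamped to [3, 150], independent of all attributes.

Two recruitment modes exist because no single simple simulator serves both
validation jobs:

- **degree_proportional** draws each recruit from the unrecruited members of
  a finite population (default 20,000 — at least 20x any target sample, so
  without-replacement depletion is negligible) with probability proportional
  to degree, via exponential-race (Gumbel top-k) sampling. Attributes are
  independent of degree, which makes the RDS-II estimator consistent; this
  mode backs the estimator-recovery checks. An optional symmetric
  same-category kernel induces homophily; recovery guarantees hold only
  without it.
- **category_markov** draws each recruit's categories directly from the
  recruiter's transition rows (degree and remaining attributes independent).
  This is the Markov abstraction itself and backs the homophily/equilibrium
  machinery, including the null calibration of the chi-square (homogeneous
  rows = the marginal).

Seeds are the highest-degree members satisfying per-seed stratification
constraints (by default cycling migratory status x age group) — a
deterministic surrogate for "well-connected, diverse" seed selection.
An optional logistic outcome model overwrites health-service use with draws
from specified odds ratios on the published dichotomizations; its intercept
is calibrated by bisection so the population prevalence matches a target.

What the generator does *not* emulate: a static underlying social network
(recruits are drawn from the population, not from a fixed ego network),
differential coupon refusal by category, degree misreporting, multi-city
chains, or temporal change in the population. Passing recovery tests
therefore shows the estimators are correct *under the random-walk and Markov
models*, not that those models hold in any particular field setting.

## Variance estimation

The recruitment design is treated as a cluster sample whose clusters are the
recruit-sets of each recruiter. The default chain (tree) bootstrap resamples
seeds with replacement and then, recursively down each chain, resamples
every selected recruiter's recruit-set with replacement; weights are
recomputed inside every replicate so weighting uncertainty propagates.
Intervals are percentile intervals (robust for proportions near 0 or 1);
B defaults to 1,000.

A measured property users should know: under *independent* recruitment (no
homophily), multi-level resampling double-counts variance — in simulation at
the study scale the bootstrap SD is about 1.8x the true sampling SD of the
prevalence estimator, and empirical coverage of nominal 95% intervals is
~99%. The intervals are conservative, by design erring on the side of the
dependence the chain structure is meant to capture. Two alternative schemes
are provided for sensitivity analysis: `scheme="cluster"` (one-level,
in-place recruit-set resampling; anti-conservative, ~77% coverage in the
same experiment) and whole-chain resampling, which with only 6-9 chains
suffers the classic few-cluster percentile undercoverage (~88%). Neither
replaces the default.

## Outcome models

Bivariate screens report the weighted outcome prevalence per category with a
joint Wald test from a bivariate weight-weighted logistic fit (model-based
covariance). The multivariate model uses the published dichotomizations
(age 15-24 vs 25+, college vs not, pregnant, fair/poor vs good health,
irregular vs not irregular) and maximizes the weight-weighted log-likelihood
by IRLS with step-halving on deviance increase; convergence is a maximum
coefficient change below 1e-8 within 100 iterations, and weights are
rescaled to mean 1 so deviances are comparable across datasets. Confidence
intervals for odds ratios come from the chain bootstrap (the model refit on
every replicate) because RDS weights are not classical survey weights; a
recruiter-clustered sandwich covariance is available as a fast alternative.

Numerical edge cases: a rank-deficient design raises immediately;
(quasi-)separation raises by default, naming the runaway term. Bootstrap
refits instead pin a separated coefficient at +-15 on the log-odds scale and
keep the replicate — a diverged replicate belongs in the tail of the
percentile distribution, and dropping such replicates would bias intervals
toward narrowness precisely for sparse covariates (replicated chains often
lose all events in a rare cell, e.g. pregnancy x service use).

In replicate-recovery summaries, odds ratios are averaged on the log scale
(geometric mean). The sampling distribution of an exponentiated coefficient
is right-skewed; at the study's sample size the arithmetic mean of the
pregnancy OR across replicates exceeds the generating value by over 20%
while the geometric mean sits within 8% — the log scale is where the
estimator is (asymptotically) symmetric.

## Other numerical choices

- Stationary distributions solve the linear system (P^T - I, 1)pi = (0, 1)
  by least squares; reducibility is detected on the positive-support digraph
  and reported with the absorbing class. Waves-to-equilibrium iterates the
  start distribution and counts steps until the sup-norm distance to the
  stationary vector falls below the tolerance (default 0.01, cap 1,000).
- The sample-size formula is ceil(deff * z^2 * p(1-p) / e^2). With the
  survey's inputs (p=0.19, e=0.04, 95%, deff=2) it yields 740.
- Missing category values are dropped per variable with renormalization and
  a logged count; the eligibility filter splices the recruits of an excluded
  participant onto her nearest retained ancestor (or promotes them to roots)
  so chains stay analyzable.
- Acceptance experiments use 300 replicates for recovery means and the
  full study-scale samples per replicate; the bootstrap-calibration
  experiment uses 200 datasets with B=200; the type-I calibration uses 500
  null simulations. These sizes give Monte-Carlo standard errors an order of
  magnitude below the tolerances they are compared against.

## Known limitations

- RDS-II consistency requires the random-walk model; with homophily
  configured, the estimator is biased and the package makes no correction
  (no successive-sampling or model-assisted estimators).
- The chain bootstrap is conservative under independence (above); no
  analytic RDS variance estimator is provided.
- Homophily tests on small samples attach a warning when >20% of expected
  cell counts fall below 1, but no exact test is offered.
- The pipeline analyzes cities independently; pooled models with a city term
  are out of scope.
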