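# Methods

## Transmission model

The host is female-diploid / male-haploid for its sex chromosomes (XX
females, X0 males). The species actually carries two distinct X
chromosomes; they are modelled as a single co-segregating linked unit, so
"X" below stands for the full X complement. Independent segregation of the
two X's is deliberately not modelled — the offspring-class arithmetic is
identical under the composite notation, and no data distinguish the two.

Assumptions:

* all fathers are X0 males (the only male karyotype);
* symbiont transmission is exclusively maternal and perfect — every
  offspring of an infected mother is infected, and the father's infection
  state is irrelevant to karyotype outcomes (cytoplasmic incompatibility by
  a co-infecting symbiont is outside this model and is the reason all
  modelled sires can be taken as uninfected);
* gamete segregation is fair: XX mothers always transmit X, X0 parents
  transmit X with probability ½;
* 00 zygotes are inviable; XX zygotes are female; X0 zygotes of infected
  mothers develop female with probability φ ∈ (0, 1] (feminization
  success), else male; X0 zygotes of uninfected mothers are male.

Daughter production per mother, weighting X0 mothers' egg output by ρ:

| mother | XX daughters | X0 daughters | inviable |
|--------|-------------|--------------|----------|
| XX (infected) | ½ | φ/2 | 0 |
| X0 (infected) | ρ·¼ | ρ·φ/2 | ρ·¼ |

With x the fraction of infected females that are XX, the next generation's
fraction is x' = (x/2 + ρ(1−x)/4) / (x(1+φ)/2 + ρ(1−x)(¼+φ/2)). Mothers
are composed into the next generation by viable daughter output (not total
eggs laid); this is the natural weighting when the census is of adult
females. The fixed point solves a quadratic (for ρ = 1: x² + 2φx − 1 = 0);
the solver takes the admissible closed-form root and verifies it against
the recursion, with 10,000-step fixed-point iteration as an independent
verification path in the tests. Degenerate input φ = 0 with x = 0 is
rejected: no infected female population can exist without feminization
once all females are X0.

Feminization failure leaks males into broods of infected mothers: the male
fraction among viable adult offspring is (1−φ)/2 · (x + ρ(1−x)) / (x +
¾ρ(1−x)), strictly decreasing from ½ (φ → 0) to 0 (φ = 1), so φ is
estimated from an observed brood sex ratio by bisection on [0, 1]
(default tolerance 1e-8; monotonicity makes the bracket valid).

## Expected undeveloped eggs

Background per-egg mortality b is estimated from the non-feminizing
symbiotypes as the pooled ratio (total undeveloped / total eggs) after the
exclusion filters; a mean-of-per-brood-proportions variant exists behind
`method="mean"` for sensitivity analysis, but the pooled form is the
per-egg probability that the multiplicative composition requires. The 00
loss and background mortality compose multiplicatively: an egg develops
iff it is not a 00 zygote and survives background mortality, giving

    e_XX = b,   e_X0 = 1 − 0.75(1 − b),   E(q) = 1 − (1 − q/4)(1 − b)

for a population whose mothers are X0 with probability q (the equilibrium
q\* of the symbiotype's φ). E(q) equals the mixture q·e_X0 + (1−q)·e_XX
exactly; both monotonicity in q and b and this identity are property-tested.

## Monte Carlo interval

For each feminizing symbiotype the observed eggs-per-eggmass values are
held fixed and brood outcomes are resimulated: every draw assigns each
brood a maternal karyotype (X0 with probability q\*), samples the
undeveloped count from Binomial(n_i, e_karyotype), and records the mean of
per-brood proportions (a pooled-proportion statistic is available via
`statistic="pooled"`). Karyotypes are redrawn on every draw, so the
interval carries karyotype uncertainty as well as binomial noise — with 30
broods of ~16 eggs this yields intervals of width ≈ 0.11, dominated by the
karyotype layer. Defaults: 500,000 draws, 95% empirical quantile interval
with linear interpolation between order statistics. Egg counts are sorted
before simulation so the sampled distribution is invariant to brood
ordering (the statistic is symmetric in broods); a single master seed
spawns independent per-symbiotype streams via `numpy.random.SeedSequence`.

## Overdispersion-corrected statistics

Egg viability is modelled as grouped binomial counts with a logistic link,
fitted by IRLS (statsmodels GLM provides the fitting engine; the response
is the per-brood failure proportion with variance weights w_i·n_i).
Williams' moment correction estimates a heterogeneity parameter δ such
that, after refitting with weights w_i = 1/(1 + δ(n_i − 1)), the weighted
Pearson χ² equals its residual degrees of freedom; δ is found by bracketed
root-finding (Brent, tolerance 1e-8, delta floored at 0 — negative
overdispersion is out of scope) rather than the classical one-step moment
update, which targets the same condition but converges more slowly.
Identifiability edge case: if every brood has a single egg, all weights are
1 for any δ and the fit is returned with δ = 0 and a warning. Groups whose
eggs all developed (or all failed) have infinite ML log-odds; such fits
are flagged and coefficients are reported capped at ±15 on the logit
scale. Dummy coding uses a configurable reference level; deviances are
invariant to the choice (tested).

Nested model comparisons are deviance-difference tests against χ² with df
equal to the parameter-count difference. The reduced model is refit with
the full model's Williams weights held fixed — standard practice for
quasi-likelihood nested tests and the only construction under which the
deviance difference has a χ² reference. Simulation tests confirm that the
corrected test's type-I error under a beta-binomial null is near nominal
while the uncorrected test's is badly inflated.

Total eggs per brood are compared with a one-way fixed-effects linear
model. The feminized-vs-unfeminized comparison is a planned contrast of
the two set averages of group means on the pooled residual mean square
(df = residual df of the six-group model). All-pairs comparisons use the
studentized range with the Tukey–Kramer denominator for unequal group
sizes (exclusions unbalance the groups; tail probabilities from
scipy.stats.studentized_range, accurate well past 1e-6). The compact
letter display uses the insert-and-absorb algorithm over groups sorted by
mean; its output equals the maximal-clique cover of the non-significance
graph, verified in the tests against an exhaustive-subset oracle for up to
six groups. Degenerate data: if all observations are identical the F
statistic is reported as 0 (nothing varies); zero residual variance with
non-zero group differences is an error, since F is then unbounded.

## Synthetic data generator

`generate_study` emulates the experimental design: six symbiotypes
(U, R, RT, RTW1, RTW12, RTW123; a symbiotype feminizes iff it carries the
first *Wolbachia* strain), 30 females each, one eggmass per female. Per
female: a mating Bernoulli (failure probability 0.061); for feminizing
symbiotypes a latent karyotype draw (X0 with the equilibrium probability
implied by that symbiotype's φ); an egg count from a negative binomial
(mean/dispersion parameterisation, truncated at 1 egg; Poisson optional);
independent per-egg failures at e_XX or e_X0; and a symbiotype-mismatch
flag at rate 0.006. Zero-egg females are recorded as unmated (the design
distinguishes mating failure from laying an eggmass that entirely fails).
The latent karyotype column is emitted only on request so the default
output mimics what an experimenter can observe.

Calibration defaults, chosen once as the study conditions:

* φ = 0.862 (RTW1), 0.874 (RTW12), 0.937 (RTW123) — the per-symbiotype
  feminization-success estimates are not printed in the main text, so these
  are back-calculated so that the equilibrium chain reproduces the reported
  per-symbiotype expected undeveloped proportions (0.170 / 0.171 / 0.176 at
  b = 0.04); they are calibration defaults, not ground truth;
* b = 0.04 — the reported background failure rate;
* mean eggs per eggmass 18.75 (non-feminized) and 15.75 (feminized),
  back-calculated from the reported per-eggmass means and the ~16%
  reduction;
* egg-count dispersion k = 20 (variance ≈ mean + mean²/20, mildly
  overdispersed) — clutch-size variance is not reported, and moderate
  overdispersion is biologically typical and exercises the Williams
  machinery; this is an assumption.

What the generator does not emulate: brood-level heterogeneity in the
per-egg failure rate within a karyotype (failures are exactly binomial
given the karyotype, so overdispersion in feminized groups arises solely
from the latent karyotype mixture and non-feminized groups are pure
binomial), multi-generation pedigrees, male genotypes, cytoplasmic
incompatibility, or lifetime fecundity beyond the first eggmass. Passing
tests therefore show that the pipeline recovers the model's own structure
at experimental scale, not that real broods satisfy these distributional
assumptions — in particular, inferential statistics computed on synthetic
data (deviances, F, t) sit at the same order as, but not numerically equal
to, values obtainable from the real dataset.

## Problem sizes

The test suite and acceptance script use: 500,000 Monte Carlo draws for
intervals (the analysis default), 500 replications for interval coverage
and for the power of the feminization test at 30 females per symbiotype,
1,000 replications for type-I error of the corrected deviance test, 200
replications for the null behaviour of the Williams δ estimate, a
100,000-mother / 50-generation Wright–Fisher oracle for the equilibrium,
and 10⁶-offspring stochastic oracles for sex-ratio expectations. These
sizes give Monte Carlo standard errors comfortably below the tolerances
asserted.

## Known limitations

* The recursion weights mothers by viable daughter output; if the original
  derivation weighted by total eggs laid instead, equilibria would differ
  in the third decimal for φ near 1 (the two weightings coincide at φ = 1
  only in the numerator; the choice made here is stated above).
* Williams' correction is a moment method; with very few broods (residual
  df near 1) δ is noisy, and the χ² reference for the corrected deviance
  test is asymptotic.
* The compact-letter-display algorithm is exact but exponential in the
  worst case; it is intended for the handful of groups a symbiotype
  experiment produces.
* `estimate_phi_from_sex_ratio` assumes the sampled broods come from a
  population at the transmission equilibrium.
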