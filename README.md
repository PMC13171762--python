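# femcost

Fitness costs of endosymbiont feminization in hosts with XX/X0 sex
determination.

Maternally inherited bacteria such as *Wolbachia* can feminize their hosts:
genetic X0 males develop as functional, egg-laying females. In an XX/X0
system this manipulation carries a built-in cost. A feminized X0 mother can
provision an X chromosome to only half of her eggs, so when she is mated to
an X0 male a quarter of her zygotes receive no sex chromosome at all (00)
and are presumed inviable. `femcost` packages the quantitative machinery
needed to test this hypothesis against brood-level egg-count data: the
karyotype-transmission recursion and its equilibrium, expected
undeveloped-egg proportions, Monte Carlo confidence intervals, and
overdispersion-corrected brood statistics. It is aimed at researchers
studying reproductive manipulation by heritable symbionts.

## The model

Females are genetic XX or feminized X0 (the host's two distinct X
chromosomes are treated as one linked unit); all fathers are X0 males, and
symbiont transmission is strictly maternal and perfect. Crossing gametes:

* infected XX mother → ½ XX + ½ X0 offspring, all infected;
* infected X0 mother → ¼ XX + ½ X0 + ¼ 00 (inviable), all infected.

An infected X0 individual becomes a functional female with probability φ
(the feminization success); with probability 1 − φ it develops as a male.
Writing x for the fraction of infected females that are XX and ρ for the
relative egg output of X0 mothers, one generation maps

    x' = [ x/2 + ρ(1−x)/4 ] / [ x(1+φ)/2 + ρ(1−x)(1/4 + φ/2) ],

whose fixed point (for ρ = 1) solves x² + 2φx − 1 = 0. At φ = 1 the
equilibrium is x\* = √2 − 1 ≈ 0.414, i.e. q\* = 1 − x\* ≈ 0.586 of infected
females are feminized X0. The expected proportion of undeveloped eggs with
background per-egg mortality b (estimated from non-feminizing symbiotypes,
composed multiplicatively) is

    E = 1 − (1 − q*/4)(1 − b),

and φ itself can be estimated from observed brood sex ratios, since the
male fraction among viable offspring is strictly decreasing in φ.

Inference on brood data uses grouped binomial logistic regression with
Williams' correction for overdispersion (weights 1/(1 + δ(n−1)) with δ
chosen so the weighted Pearson χ² equals its residual df), χ²
deviance-difference tests, and a one-way linear model on total eggs with a
planned feminized-vs-unfeminized contrast and Tukey–Kramer letters.

## Worked example

```sh
python examples/01_equilibrium_and_expectations.py
```

prints

```
perfect feminization: x_XX* = 0.41421, q_X0* = 0.58579
expected undeveloped eggs, no background mortality: 0.14645

per-symbiotype expectations with a 4% background failure rate:
symbiotype    phi   q_x0  expected_undeveloped
      RTW1 0.8620 0.5418                0.1700
     RTW12 0.8740 0.5459                0.1710
    RTW123 0.9370 0.5666                0.1760

sex ratio 0.0580 among viable offspring implies phi = 0.9000
```

Read: at the φ = 1 equilibrium, 59% of infected females are feminized X0,
and the 00 rule alone predicts 14.6% undeveloped eggs; with a 4% background
failure rate and realistic (imperfect) feminization the expectation rises
to about 17–18% — roughly four times the background rate. The other
examples simulate the Monte Carlo interval for a finite experiment
(`02_monte_carlo_ci.py`), run the Williams-corrected statistics
(`03_overdispersion_stats.py`), and chain the whole pipeline on a synthetic
study (`04_full_pipeline.py`). The same stages are exposed as shell
subcommands: `femcost simulate | equilibrium | expect | mc-ci | stats |
run-all`.

Synthetic studies come from `femcost.generate_study`, which emulates the
experimental design (six symbiotypes × 30 females, latent maternal
karyotypes, per-egg development outcomes, mating failures, and the
exclusion filters for unmated and zero-development broods). Validation
against the study's deposited dataset is available through
`femcost.validate_against_dataset(path)` once the archive
(DOI 10.5281/zenodo.19656452) has been downloaded locally.

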