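# Methods

## Decision problem and tree structure

The package models a societal decision between two reproductive-care
strategies for couples planning a pregnancy: universal natural conception
(status quo) versus two-step pre-pregnancy carrier screening for recessive
deafness genes with risk-stratified follow-up. Each strategy is a finite
chance tree over couple genotypes, family decisions and birth outcomes;
every leaf ends in exactly one of `healthy_birth`, `deaf_birth` or
`no_birth` and carries a four-component payoff vector (cost, deaf-birth
indicator, healthy-birth indicator, lifetime QALY). Expected values are
exact probability-weighted sums (rollback); no cycles, no time steps.

The two strategies are deliberately separate trees rather than branches of
a root decision node: comparison (ΔC, ΔE, ICER, dominance) is performed
externally, which keeps probabilistic re-evaluation simple and matches the
two-row presentation of results.

Couple genotypes are the product of the wife's and husband's marginal
frequencies (no assortative mating). A `concordance` factor is available
to up-weight carrier×carrier pairings (e.g. same-gene assortment) with
renormalization; it defaults to 1, i.e. independence.

### Branch probabilities

Genotype prevalences come from the screening survey (wife: bi-allelic
0.0050, carrier 0.1572, negative 0.8378; husband: 0.0074 / 0.1370 /
0.8556). Decision probabilities: high-risk couples give birth with
probability 0.1930; medium-risk couples choose ART+PGT 0.1774,
amniocentesis 0.7096, natural conception 0.0565, no children 0.0565
(medium-high and medium-low share this distribution, which is stated once
for "medium-risk families"); after a positive amniocentesis the birth
probability is 0.1930. Outcome probabilities are Mendelian where they can
be (amniocentesis positive rate 0.5 / 0.25; natural deaf-birth risk 0.5 /
0.25 for the two medium categories) and near-degenerate elsewhere (0.999
deaf given a confirmed positive, 0.001 residual risk after ART, a negative
amniocentesis, or for low-risk couples).

The natural deaf-birth probability of a high-risk (bi-allelic ×
bi-allelic) couple is not separately published; the package uses 0.999,
symmetric with the confirmed-positive birth probability. This choice
reproduces the published arm-level deaf probabilities (0.0073 / 0.0022) to
the printed precision.

### Costs

Screening costs 64.20 USD per person screened (52.20 assay + 9.00 labor +
3.00 promotion); the husband's test is charged only when the cascade
reaches him. ART+PGT adds 11,940.30 + 28.70 productivity loss;
amniocentesis 2,686.60 + 14.40. Every path ending in a birth carries the
651.00 delivery ("reproductive") cost — including ART births, where it is
additive. Termination after a positive amniocentesis carries no extra
cost (none is published). Under the cost-utility model, birth leaves add
the individual's discounted lifetime medical expenditure minus lifetime
income (healthy: 6,961.40 − 115,622.00; disabled: 11,142.40 − 65,996.00);
childless leaves carry no future terms, which is why the screening arm's
expected utility (21.99) sits below the status quo (22.09).

The reconstructed screening-arm expected cost is 816.85 USD versus the
published 817.60 (residual < 0.1 %, origin unknown — possibly a different
husband-screening or termination cost convention); the residual is
documented rather than calibrated away.

## Economic constants

All lifetime quantities use a calibrated discounted lifetime factor
22.0527 = 115,622 / 5,243 (lifetime income of a healthy individual over
2021 per-capita disposable income). Neither standard annuity timing
reproduces this factor from an explicit horizon at the stated 5 % discount
rate, and the underlying national life table is not available to the
package, so the factor is exposed as a first-class parameter
(`econ.lifetime_factor`) with `discounted_lifetime_factor(rate, horizon,
timing)` available for users who want to supply their own survival
horizon. The deaf lifetime QALY defaults to the reporting-rounded 20.1
(22.1 × 0.91 = 20.111 unrounded) because the headline utilities were
evidently computed with rounded constants; `derive_deaf_qaly` returns the
unrounded product. The willingness-to-pay threshold is three times 2021
per-capita GDP for a whole healthy life: 3 × 12,086 × 22.1 ≈ 801,302 USD.

The published 2021 disabled income (2,992.70/yr, lifetime 65,996) is not
reproducible from the published 2018 base and 7.56 %/yr growth rate
(projection gives ≈2,539.70); the published value is used because the
lifetime figure derives from it.

## Sensitivity analyses

**One-way (tornado).** Each scalar parameter is pushed to ±10 %
(literature / expert / Mendelian provenance) or ±20 % (survey-derived
values), with probability blocks renormalized proportionally and spans
clipped to [0, 1] with a warning. The reported statistic is the
sign-folded ratio ΔC/|ΔE| (cost per unit effect magnitude), which remains
meaningful when the screening arm is dominated.

**Threshold.** The medium-risk ART uptake is swept over [0, 1]. Default
reallocation is *none-absorbing*: amniocentesis and natural-conception
probabilities are held at base and the no-children mass absorbs the
change, falling back to proportional rescaling of the other choices once
it hits zero (above uptake ≈0.234). A *proportional* rule (rescale all
three non-ART choices) is available. The break-even uptake at which the
screening arm stops losing healthy births relative to the status quo is
found by root bracketing to 1e-6; under the default rule it is ≈17.1 %
(≈15.9 % proportional). The none-absorbing rule is the default because it
comes closest to the published ≈17.4 % threshold; the exact reallocation
convention behind that figure is not stated, and the two rules bracket the
plausible range.

**Probabilistic.** Costs are gamma-distributed (method of moments,
default coefficient of variation 0.2). Probabilities are beta with
standard deviation `cv × min(m, 1−m)` around base `m` (default cv 0.1) —
the usual cv-times-mean rule for small probabilities, kept feasible near
m = 1 where a cv-times-mean beta does not exist. Complementary pairs are
renormalized; the four-way medium-risk decision is a single Dirichlet draw
whose concentration gives the largest component that relative spread.
Genotype prevalences and Mendelian segregation ratios are never sampled
(the former are measured on 6,740 individuals, the latter are laws). The
deaf utility weight is beta-sampled and the deaf QALY scaled by
`w / w_base`, so the zero-cv limit reproduces the deterministic comparison
bit-for-bit. Published distribution hyper-parameters are not available;
the cv defaults are the package's own choice and fully configurable. Each
draw rebuilds both trees; the acceptability curve uses the net monetary
benefit rule `λ·ΔE − ΔC ≥ 0`, which stays defined at ΔE = 0; the scatter
summary is a normal-theory 95 % ellipse (mean, covariance, χ²₂ radius).

## Synthetic cohorts

`cohort.generate_cohort` draws individual couples with independent spousal
genotypes; `two_step_screen` applies the cascade (husband tested iff wife
positive — partner recruitment is 100 %, as observed); `simulate_families`
samples each family's decisions sequentially and charges exactly the costs
the analytic payoff function assigns to the corresponding tree path. A
large simulated cohort is therefore an end-to-end Monte Carlo oracle for
the analytic model, and the test suite requires agreement within 3
standard errors at 200,000 couples. What the generator does *not* emulate:
per-mutation allele structure (45 variants collapse to a three-state
genotype), site stratification, assortative mating, repeat pregnancies,
screening test error, or any correlation between family decisions and
unobserved covariates — so passing tests demonstrate internal consistency
of the decision model, not external validity of the published decision
probabilities.

## Numerical conventions and problem sizes

Probability-sum checks use an absolute tolerance of 1e-9; rollback versus
exhaustive path enumeration must agree to 1e-12 relative. Branch order is
part of a tree's definition, so microsimulation seeds are portable.
Families-needed figures are reported rounded to integers; CSV output uses
two decimals for money and six for probabilities. Default analysis sizes:
10,000 PSA draws, 200,000-path microsimulation, a 101-point uptake grid —
the full deterministic analysis runs in milliseconds and the complete PSA
for all three payoff models in well under a minute on one CPU.

## Known limitations

* Static tree: no Markov extension for age-varying severity or mortality.
* Deafness severity is not subgrouped; a single 0.91 utility weight is
  taken as given.
* The ≈0.7 USD screening-arm cost residual and the published full-uptake
  ICER (69,994.4/case, which no reconstruction from the published costs
  reproduces — the package computes ≈56,000) are unresolved discrepancies
  in the source figures, documented rather than fitted.
* Willingness-to-pay for birth-count outcomes (models 1–2) has no
  accepted threshold; acceptability analysis is most meaningful for the
  utility model.
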