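# deafcea

Decision-analytic cost-effectiveness analysis of **pre-pregnancy carrier
screening for autosomal-recessive deafness** (the common *GJB2* /
*SLC26A4* recessive genotypes), for health-economics researchers and
policy analysts who want a fully scriptable, testable alternative to
point-and-click decision-tree software.

## The model

A cohort of couples planning pregnancy is compared under two strategies:

* **Status quo** — no screening; every couple conceives naturally and the
  probability of a deaf child follows Mendelian segregation for the
  couple's (latent) genotype pair.
* **Two-step screening** — the woman is genotyped first; her partner is
  genotyped only if she carries at least one pathogenic allele (cascade
  screening). Couples are then classified as high risk (bi-allelic ×
  bi-allelic), medium-high (bi-allelic × carrier, segregation risk 1/2),
  medium-low (carrier × carrier, risk 1/4) or low (any screen-negative
  spouse). High-risk couples choose between natural conception and
  childlessness; medium-risk couples choose between ART with PGT,
  amniocentesis (with a birth/termination decision after a positive fetal
  diagnosis), unassisted conception, and childlessness.

Each strategy is an explicit probability tree whose leaves carry a payoff
vector; expected values are obtained by rollback. Three payoff models are
built from one topology:

1. **deaf** — effectiveness = P(deaf birth); screening is evaluated by the
   *reduction* in deaf births (cost per case averted, |ΔC/ΔE|);
2. **healthy** — effectiveness = P(healthy birth); standard ICER
   ΔC/ΔE per additional healthy birth;
3. **utility** — effectiveness = expected lifetime QALYs (22.1 healthy,
   20.1 deaf, 0 no birth, 5 % annual discount); costs additionally include
   each born individual's discounted lifetime medical expenditure minus
   lifetime income.

For two strategies with expected costs `C` and effects `E`,
`ICER = (C_screen − C_sq) / (E_screen − E_sq)`; a strategy that costs more
and yields less effect is *dominated*. Probabilistic sensitivity analysis
draws parameters (gamma for costs, beta/Dirichlet for probabilities),
re-evaluates the tree per draw, and summarises the (ΔE, ΔC) cloud by a
cost-effectiveness acceptability curve
`CEAC(λ) = P(λ·ΔE − ΔC ≥ 0)` and a 95 % normal-theory coverage ellipse.

All monetary values are 2021 USD. Default parameters are the published
survey/literature values and ship with the package; everything is
overridable from a flat JSON config (`cea params --export defaults.cfg`).

## Worked example

```python
from deafcea import default_parameters, run_model, families_needed, ModelVariant

p = default_parameters()
mr = run_model(p, ModelVariant.DEAF_COUNT)
print(f"status quo: cost {mr.status_quo.cost:.2f}, "
      f"P(deaf) {mr.status_quo.expected['eff_deaf']:.4f}")
print(f"screening:  cost {mr.screening.cost:.2f}, "
      f"P(deaf) {mr.screening.expected['eff_deaf']:.4f}")
print(f"dE = {mr.comparison.delta_eff:.4f}  -> "
      f"{families_needed(mr.comparison)} families per deaf birth averted")
print(f"cost per deaf birth averted: {mr.comparison.cost_per_case_averted:,.0f} USD")
```

prints

```
status quo: cost 651.00, P(deaf) 0.0073
screening:  cost 816.85, P(deaf) 0.0022
dE = -0.0051  -> 196 families per deaf birth averted
cost per deaf birth averted: 32,506 USD
```

i.e. screening costs ≈166 USD more per family, cuts the deaf-birth
probability from 0.73 % to 0.22 %, and one deaf birth is averted for every
196 couples screened at ≈32.5 k USD per case. The same call with
`ModelVariant.HEALTHY_COUNT` gives the healthy-birth ICER (≈1.19 M USD per
additional healthy birth — large because screening also removes births),
and `ModelVariant.UTILITY` shows screening is dominated from the societal
QALY perspective.

The same results from the shell:

```sh
cea run --model deaf --out table_deaf.csv
cea threshold --grid 0:1:0.01 --out uptake_curve.csv
cea psa --model healthy --n 10000 --seed 42 --out draws.csv --ceac ceac.csv
cea simulate --n-females 6200 --seed 7 --out cohort_summary.csv
```

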