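# ironmr — serum iron and Parkinson disease risk by Mendelian randomization

`ironmr` implements a summary-level, two-sample Mendelian randomization (MR)
analysis of the causal effect of serum iron on Parkinson disease (PD) risk,
using three iron-modifying variants — *HFE* rs1800562 (C282Y), *HFE*
rs1799945 (H63D) and *TMPRSS6* rs855791 (V736A) — as genetic instruments.
It is written for epidemiologists and statistical geneticists who work from
aggregate association statistics: no individual-level data are required at
any stage.

## The statistical core

For instrument *j*, with the gene–disease effect log OR<sub>PD/allele</sub>
(log odds ratio per effect-allele copy) and the gene–biomarker effect
β<sub>iron/allele</sub> (biomarker SDs per allele copy), the causal estimate
is the Wald ratio

    log OR_PD/iron = log OR_PD/allele / beta_iron/allele

with a first-order delta-method standard error (zero covariance term, since
the two effects come from non-overlapping samples):

    se² = se_num²/β² + num²·se_den²/β⁴

Per-study gene–disease estimates, and the per-instrument MR estimates, are
pooled by inverse-variance fixed-effect meta-analysis. Cochran's Q and
I² = max(0, (Q − df)/Q)·100 quantify heterogeneity; across instruments,
excess heterogeneity is the operational signal of pleiotropy. Instrument
strength is F = R²(n − 2)/(1 − R²) with R² = 2f(1 − f)β² for an additive
biallelic variant on a unit-variance trait. The per-SD odds ratio is
re-expressed per measurement unit as OR^(units/SD), and absolute risk is
projected under the rare-disease approximation OR ≈ RR.

The package also contains a synthetic-cohort generator (`ironmr.simulate`)
that draws genotypes in Hardy–Weinberg proportions, builds a standardized
biomarker with additive effects, generates a rare disease through a
calibrated logistic model, and summarizes disjoint biomarker/disease
cohorts by the same marginal regressions a consortium would run — so the
entire chain can be validated by parameter recovery with known truth,
including pleiotropy and confounding scenarios.

## Worked example

```python
>>> from ironmr import or_ci_to_log_scale, se_from_symmetric_ci
>>> from ironmr.assoc import AssociationEstimate, VariantInstrument, SD_UNITS
>>> from ironmr.mr import wald_ratio
>>> num = or_ci_to_log_scale(0.97, 0.94, 0.99)          # gene–PD, per allele
>>> den = AssociationEstimate(scale=SD_UNITS, beta=0.19,
...                           se=se_from_symmetric_ci(0.17, 0.21))
>>> est = wald_ratio(num, den, VariantInstrument("rs855791", "TMPRSS6", "G", "A", 0.40))
>>> round(est.odds_ratio, 3), round(est.se, 3)
(0.852, 0.07)
```

The analysis itself is a sequence of drivers over the library:

```sh
python analysis/01_reproduce_study.py     # published-aggregate chain
python analysis/02_synthetic_cohorts.py   # per-study path on synthetic cohorts
python analysis/03_parameter_recovery.py  # coverage / type-I / pleiotropy
```

`01_reproduce_study.py` prints, among other lines:

```
  rs855791 (TMPRSS6): iron 0.19 SD/allele, PD OR 0.970/allele -> MR OR 0.852/SD (weight 39.7%)
Combined MR estimate: OR 0.90 per SD (95% CI 0.82-0.98; p = 0.016)
Heterogeneity across instruments: Q = 1.03 (df = 2), I² = 0% (95% CI 0%-80%), het p = 0.60
```

Read: each SD (37.6 µg/dL) of genetically higher serum iron is associated
with roughly 10% lower odds of PD; the three instruments agree (I² = 0%),
consistent with no detectable pleiotropy. The combined estimate differs
from the published 0.88 only through the two-decimal rounding of the
published inputs, which are all this package ships. The same report
converts the estimate to an OR of ~0.997 per µg/dL, a ~3% relative risk
reduction per 10 µg/dL, and a projected drop from 100 to 88 PD cases per
10,000 under a one-SD iron increase.

The equivalent CLI: `ironmr reproduce`, `ironmr meta`, `ironmr mr`,
`ironmr simulate` (see `--help`).

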