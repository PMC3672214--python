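# Methods

## Estimand and identification

The quantity of interest is the causal log odds ratio of Parkinson disease
(PD) per one standard deviation (SD) of serum iron, written γ. Three
variants with established effects on iron — *HFE* rs1800562, *HFE*
rs1799945, *TMPRSS6* rs855791 — serve as instruments. Identification rests
on the usual instrumental-variable conditions: each variant is associated
with iron, is independent of confounders of the iron–PD relationship
(alleles are assigned at conception), and affects PD only through iron (no
pleiotropy). The first condition is checked by F statistics; the third is
probed, not guaranteed, by comparing the three instrument-specific
estimates — under validity they share one estimand and should differ only
by sampling error, so across-instrument heterogeneity (Q, I²) is the
pleiotropy diagnostic. With only three instruments this diagnostic has low
power; a null I² is consistent with, not proof of, no pleiotropy.

## Estimator chain

All computation is on the log-odds scale; odds-ratio confidence intervals
are converted at ingest via beta = ln OR, se = (ln hi − ln lo)/(2z), with z
the full-precision normal quantile (1.959964… at the 95% level, never the
rounded 1.96). Effects are harmonized to the iron-increasing allele:
swapped alleles negate the effect and complement the frequency; palindromic
pairs (A/T, C/G) are oriented by allele frequency only when both
frequencies lie outside 0.5 ± 0.08 (a conventional window in summary-data
MR), otherwise the record is rejected as ambiguous. The additive (0/1/2
dosage) model is the only genetic model.

Per variant, gene–disease studies are pooled by inverse-variance
fixed-effect meta-analysis (weights 1/se²). The Wald ratio divides the
pooled gene–disease log odds ratio by the pooled gene–iron effect; its
standard error is the first-order delta method with zero covariance, exact
for the two-sample design (no cohort contributes to both sides). A
second-order variant (`delta2`, adding se²·se²/β⁴) is available by flag;
the first-order form is the default because the instruments here are
strong (|β|/se ≈ 19–40), where the higher-order term is negligible (the
tests bound the first-order error against a 10⁶-draw parametric bootstrap
at 3%). Instruments are combined by the same fixed-effect pooling.
Fixed-effect, not random-effects, pooling is used throughout the
reproduction; a DerSimonian–Laird option exists for exploration only.

The I² confidence interval uses the test-based ln-H method
(H = √(Q/df); se(ln H) from the Q > df and Q ≤ df branches respectively),
with the lower bound truncated at zero. Degenerate corners — df = 1 with
Q ≤ df, or Q ≈ 0 — return the uninformative (0%, 100%) with a warning.
With one estimate (df = 0) heterogeneity is reported as not applicable
rather than zero.

Instrument strength: F = R²(n − 2)/(1 − R²), with R² = 2f(1 − f)β² for an
additive variant on a unit-variance trait. For the combined instruments two
conventions are computed and labeled: treating the summed R² as one
composite instrument (`pooled_r2`, the reproduction default, which is the
convention closest to the study's published combined value) and the
multi-regressor form ((ΣR²/(1 − ΣR²))·(n − k − 1)/k, `k_adjusted`).

Reporting conversions: an odds ratio per SD becomes OR^(units/SD) per
measurement unit (serum-iron SD = 37.6 µg/dL); relative risk reduction is
(1 − OR)·100 and absolute risk is projected as baseline × OR, both under
the rare-disease approximation OR ≈ RR (PD prevalence ≈ 1% above age 60,
taken as 100 per 10,000; a warning fires above 10% baseline prevalence
where the approximation fails). Full precision is kept everywhere;
rounding to published precision happens only in the report layer.

## Reproduction inputs

The bundled fixture carries the published per-variant aggregates: gene–iron
effects 0.37/0.19/0.19 SD per allele (95% CIs 0.33–0.41, 0.17–0.21,
0.17–0.21; n = 21,567) and pooled gene–PD odds ratios 0.97 (0.92–1.02),
0.99 (0.96–1.03), 0.97 (0.94–0.99) from 20,809 cases and 88,892 controls.
The underlying per-study consortium rows were never published, so the
fixture enters the chain at the pooled level; the per-study meta-analysis
and sensitivity paths are validated on synthetic cohorts instead
(`analysis/02`, `analysis/03`). For the same reason the fixture's
sensitivity pass excludes nothing and the reproduction report carries no
separate sensitivity estimate. Fixture effect-allele frequencies are
0.07/0.15/0.40: the last is the published frequency for rs855791; the two
*HFE* frequencies are back-derived from the published variance-explained
values (1.7% and 0.9%) via R² = 2f(1 − f)β² and rounded to two decimals.
Reproduced values agree with published ones to within the rounding of the
published inputs: the pooled per-SD odds ratio computes to 0.899 against
the published 0.88 (the published inputs carry only two decimals), and the
across-instrument I² is exactly 0% (Q = 1.03 < df = 2). The published I²
interval upper bounds (85%/90%) cannot be matched exactly because the
source does not state its interval method; our ln-H interval is printed
alongside. Fixture integrity is enforced by sha256 checksums recorded in
the pipeline.

## Synthetic-data generator

The generator emulates the study's statistical structure: unlinked
biallelic variants in Hardy–Weinberg proportions at given frequencies; a
standardized biomarker X = Σβⱼ(gⱼ − 2fⱼ) + cU + ε with residual variance
set so Var(X) = 1; a binary disease from
P(D|X,g,U) = logistic(α + γX + Σδⱼgⱼ + c′U), with α calibrated by bisection
to a target population prevalence within 10⁻⁴; disjoint biomarker and
disease cohorts (the two-sample design); per-cohort summary statistics by
per-variant linear regression (closed-form OLS, cross-checked against
statsmodels) and per-variant logistic regression (statsmodels). δⱼ ≠ 0
injects directional pleiotropy; a nonzero confounder effect pair (c, c′)
is the knob that biases a naive biomarker–disease regression while the MR
chain stays consistent. One master seed (NumPy PCG64) spawns per-stage and
per-replicate streams, so every path is deterministic under a fixed seed.

What it does not emulate: linkage disequilibrium, population
stratification beyond a per-cohort boolean flag, covariate adjustment
(summaries are treated as unbiased, which is exactly what the chain
assumes), age-at-onset structure, and case-control ascertainment subtleties
beyond drawing fixed case/control numbers from disjoint pools. Passing
recovery tests therefore show the chain is correct under its own
assumptions, not that those assumptions hold in any particular real
dataset.

Study-scale defaults (`paper_like()`): three instruments at frequencies
0.07/0.15/0.45 and effects 0.37/0.19/0.19 SD per allele, ten biomarker
cohorts totalling ~21,600, nineteen case-control sets (~1,100 cases /
~4,700 controls each) at 1% prevalence, true OR 0.88 per SD. A `scale`
argument shrinks all sample sizes proportionally; `analysis/02` runs at
10% scale to keep a single demonstration run in seconds.

Recovery experiments (`analysis/03`, and the operating-characteristic
tests) use 50,000 individuals per replicate: half in five biomarker
cohorts, half as two disease pools at 2% prevalence from which 200 cases
and 800 controls each are drawn (a 1:4 ratio); 200 replicates for coverage
and type-I error, 80 per arm for the pleiotropy contrast. These sizes put
every instrument well into the strong-instrument regime while keeping a
full experiment under half a minute; replicates that leave a pool short of
the requested cases (binomially rare at these sizes) are skipped and
counted. Observed characteristics at these conditions: coverage ~93%,
type-I error ~8% at nominal 5% (fixed-effect pooling with estimated
weights at k = 3 is known to be slightly anticonservative), delta-method
SE within a few percent of the empirical SD, and a δ = 0.1 direct effect
on one instrument roughly quadruples the absolute bias and visibly
inflates mean Q and I².

## Numerical conventions and edge cases

- Validation is eager: standard errors must be positive, confidence bounds
  must bracket the estimate, case/control counts must not exceed the total.
- A zero gene–biomarker effect makes the Wald ratio undefined; the
  low-level operation raises, the pipeline drops the instrument with a
  logged warning.
- Duplicate study identifiers within a variant's meta-analysis and
  duplicate instrument identifiers in the combination step are rejected.
- Summary tables are UTF-8 TSV with reals written to 12 significant
  digits; a write/read round trip preserves them to that precision, and
  malformed rows are reported with their row numbers.
- The tie between weights and heterogeneity: Q is computed around the
  fixed-effect pooled estimate with the same 1/se² weights used for
  pooling, so Q is invariant to shifting all effects and to rescaling all
  (beta, se) pairs by a common factor.

## Limitations

Beyond the generator's simplifications above: the Wald estimator for
binary outcomes is itself approximate under the rare-disease assumption
(bias typically within ~10% of the estimate in the regime considered
here); no MR-Egger, weighted-median or mode-based estimators are provided,
so directional pleiotropy is detected (via heterogeneity) but not
corrected; and with three instruments the heterogeneity test is
underpowered, which is a property of the design, not of the
implementation.
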