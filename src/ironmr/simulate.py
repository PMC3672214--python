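"""Synthetic cohorts with the statistical structure the MR chain assumes.

The generator draws unlinked biallelic variants in Hardy–Weinberg
proportions, builds a standardized biomarker with additive per-allele
effects (plus an optional shared confounder), and generates a rare binary
disease from the biomarker through a logistic model whose intercept is
calibrated to a target population prevalence.  Individuals are then
partitioned into disjoint biomarker and disease cohorts — the two-sample
design — and per-cohort summary statistics are estimated by the same
marginal regressions a consortium would run (per-variant linear regression
for the biomarker, per-variant logistic regression in each case-control
set).

Because the causal effect (log odds of disease per biomarker SD), the
per-allele effects, and the pleiotropy and confounding knobs are all known
inputs, the module supports end-to-end parameter recovery: bias, empirical
versus delta-method standard errors, confidence-interval coverage, type-I
error, and the behaviour of the across-instrument heterogeneity diagnostic
under directional pleiotropy.

Randomness: one master integer seed feeds a named generator
(NumPy PCG64 via ``default_rng``); per-replicate and per-stage streams are
spawned from it so every path is reproducible across platforms.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .assoc import (
    LOG_ODDS,
    SD_UNITS,
    AssociationEstimate,
    StudyAssociation,
    ValidationError,
    VariantInstrument,
)
from .pipeline import run_mr_analysis

__all__ = [
    "SimulationConfig",
    "paper_like",
    "simulate_genotypes",
    "simulate_biomarker",
    "simulate_disease",
    "summaries_from_cohorts",
    "simulate_cohorts",
    "recover_parameters",
    "RecoverySummary",
    "truth_table",
]

logger = logging.getLogger("ironmr")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative specification of one synthetic study.

    ``variants`` is a sequence of ``(rsid, effect_allele_freq, beta_sd)``
    triples: per-allele effects on the standardized biomarker.
    ``true_or_per_sd`` is the causal odds ratio of disease per biomarker SD
    (the estimand).  ``pleiotropy_delta`` gives each variant a direct
    log-odds effect on disease that bypasses the biomarker (0 = valid
    instrument).  ``confounder_effect = (on biomarker, on log-odds)``
    shares a standard-normal confounder between the two equations, which
    biases a naive biomarker–disease regression but not the MR chain.
    ``biomarker_fraction`` of individuals form the biomarker cohorts; the
    rest are the disease pool (disjoint samples, two-sample design).
    """

    n_individuals: int
    variants: tuple[tuple[str, float, float], ...]
    seed: int = 0
    n_cohorts_biomarker: int = 1
    n_cohorts_disease: int = 1
    true_or_per_sd: float = 0.88
    baseline_prevalence: float = 0.01
    n_case: int = 200
    n_control: int = 800
    pleiotropy_delta: tuple[float, ...] | None = None
    confounder_effect: tuple[float, float] = (0.0, 0.0)
    biomarker_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValidationError("n_individuals must be positive")
        if not self.variants:
            raise ValidationError("need at least one variant")
        for rsid, f, _ in self.variants:
            if not 0.0 < f < 1.0:
                raise ValidationError(f"{rsid}: allele frequency must be in (0,1), got {f}")
        if self.genetic_variance + self.confounder_effect[0] ** 2 >= 1.0:
            raise ValidationError(
                "genetic plus confounder variance must leave positive residual variance"
            )
        if not 0.0 < self.baseline_prevalence < 0.5:
            raise ValidationError(
                f"baseline_prevalence must be in (0, 0.5), got {self.baseline_prevalence}"
            )
        if self.pleiotropy_delta is not None and len(self.pleiotropy_delta) != len(self.variants):
            raise ValidationError("pleiotropy_delta needs one entry per variant")
        if not 0.0 < self.biomarker_fraction < 1.0:
            raise ValidationError("biomarker_fraction must be in (0,1)")
        if self.true_or_per_sd <= 0.0:
            raise ValidationError("true_or_per_sd must be positive")

    @property
    def freqs(self) -> np.ndarray:
        return np.array([f for _, f, _ in self.variants])

    @property
    def betas(self) -> np.ndarray:
        return np.array([b for _, _, b in self.variants])

    @property
    def genetic_variance(self) -> float:
        """Biomarker variance explained by the variants: sum 2f(1-f)beta²."""
        f, b = self.freqs, self.betas
        return float(np.sum(2.0 * f * (1.0 - f) * b**2))

    @property
    def gamma(self) -> float:
        """Causal log odds ratio per biomarker SD."""
        return math.log(self.true_or_per_sd)

    @property
    def deltas(self) -> np.ndarray:
        if self.pleiotropy_delta is None:
            return np.zeros(len(self.variants))
        return np.asarray(self.pleiotropy_delta, dtype=float)


def paper_like(seed: int = 0, scale: float = 1.0, **overrides) -> SimulationConfig:
    """Configuration emulating the iron study's design.

    Three instruments at the study's effect sizes and frequencies
    (0.37/0.19/0.19 SD per allele at frequencies 0.07/0.15/0.45), ten
    biomarker cohorts totalling ~21,600 individuals, nineteen case-control
    disease sets at ~1% population prevalence with roughly 1,100 cases and
    4,700 controls each.  ``scale`` shrinks every sample size for quick
    runs; alleles are coded A/G so that harmonization never depends on
    strand-ambiguity frequency rules.
    """
    n_bio = max(200, int(round(21_567 * scale)))
    n_case = max(20, int(round(1_095 * scale)))
    n_control = max(80, int(round(4_678 * scale)))
    # disease pools must comfortably contain the requested cases at ~1%
    # prevalence even when the floors above kick in at tiny scales
    n_dis = max(int(round(2_100_000 * scale)), int(19 * n_case / 0.01 * 2))
    cfg = dict(
        n_individuals=n_bio + n_dis,
        variants=(
            ("rs1800562", 0.07, 0.37),
            ("rs1799945", 0.15, 0.19),
            ("rs855791", 0.45, 0.19),
        ),
        seed=seed,
        n_cohorts_biomarker=10,
        n_cohorts_disease=19,
        true_or_per_sd=0.88,
        baseline_prevalence=0.01,
        n_case=n_case,
        n_control=n_control,
        biomarker_fraction=n_bio / (n_bio + n_dis),
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def _streams(config: SimulationConfig, n: int = 4):
    children = np.random.SeedSequence(config.seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Dosage matrix (individuals × variants) of 0/1/2 effect-allele copies.

    Each column is two independent Bernoulli(f) allele draws per individual,
    i.e. Hardy–Weinberg proportions at frequency f, independent across
    variants (no linkage disequilibrium).
    """
    rng = rng or _streams(config)[0]
    return rng.binomial(2, config.freqs, size=(config.n_individuals, len(config.variants))).astype(
        np.int8
    )


def simulate_biomarker(
    genotypes: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    confounder: np.ndarray | None = None,
) -> np.ndarray:
    """Standardized biomarker: X = sum_j beta_j (g_j - 2 f_j) + c U + eps.

    The residual variance is chosen so Var(X) = 1 in the population;
    genotype centering makes the population mean 0.
    """
    rng = rng or _streams(config)[1]
    f, b = config.freqs, config.betas
    x = (genotypes - 2.0 * f) @ b
    c_bio = config.confounder_effect[0]
    if confounder is not None and c_bio != 0.0:
        x = x + c_bio * confounder
    resid_var = 1.0 - config.genetic_variance - c_bio**2
    x = x + rng.normal(0.0, math.sqrt(resid_var), size=genotypes.shape[0])
    return x


def _calibrate_intercept(lp: np.ndarray, prevalence: float, tol: float = 1e-4) -> float:
    """Bisect the logistic intercept so the mean population risk hits
    ``prevalence`` within ``tol``."""
    lo, hi = -30.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        risk = float(np.mean(expit(mid + lp)))
        if abs(risk - prevalence) < tol * 0.1:
            return mid
        if risk > prevalence:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def simulate_disease(
    biomarker: np.ndarray,
    genotypes: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    confounder: np.ndarray | None = None,
) -> np.ndarray:
    """Binary disease labels from a logistic model on the biomarker.

    P(D | X, g, U) = logistic(alpha + gamma X + sum_j delta_j g_j + c' U)
    with gamma = ln(true_or_per_sd); alpha is calibrated by bisection so
    the population prevalence matches ``baseline_prevalence`` within 1e-4.
    """
    rng = rng or _streams(config)[2]
    lp = config.gamma * biomarker
    deltas = config.deltas
    if np.any(deltas != 0.0):
        lp = lp + genotypes @ deltas
    c_dis = config.confounder_effect[1]
    if confounder is not None and c_dis != 0.0:
        lp = lp + c_dis * confounder
    alpha = _calibrate_intercept(lp, config.baseline_prevalence)
    return (rng.random(lp.shape[0]) < expit(alpha + lp)).astype(np.int8)


def _linear_marginal(x: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Slope and SE of the simple regression of x on dosage g (closed-form OLS)."""
    n = x.shape[0]
    gc = g - g.mean()
    ssg = float(gc @ gc)
    if ssg == 0.0:
        raise ValidationError("monomorphic genotype column in cohort")
    slope = float(gc @ x) / ssg
    resid = x - x.mean() - slope * gc
    sigma2 = float(resid @ resid) / (n - 2)
    return slope, math.sqrt(sigma2 / ssg)


def _logistic_marginal(y: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Per-allele log odds ratio and SE from a logistic fit with intercept."""
    design = sm.add_constant(g.astype(float))
    fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
    return float(fit.params[1]), float(fit.bse[1])


def _partition(n_total: int, n_bio: int, n_bio_cohorts: int, n_dis_cohorts: int):
    bio_bounds = np.linspace(0, n_bio, n_bio_cohorts + 1).astype(int)
    dis_bounds = np.linspace(n_bio, n_total, n_dis_cohorts + 1).astype(int)
    bio = [np.arange(bio_bounds[i], bio_bounds[i + 1]) for i in range(n_bio_cohorts)]
    dis = [np.arange(dis_bounds[i], dis_bounds[i + 1]) for i in range(n_dis_cohorts)]
    return bio, dis


def summaries_from_cohorts(
    genotypes: np.ndarray,
    biomarker: np.ndarray,
    labels: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    bio_flags: Sequence[bool] | None = None,
    dis_flags: Sequence[bool] | None = None,
) -> tuple[list[StudyAssociation], list[StudyAssociation]]:
    """Per-cohort summary statistics in the exchange-record form.

    The first ``biomarker_fraction`` of individuals are split into
    biomarker cohorts (biomarker re-standardized within each cohort, then
    per-variant linear regression); the remainder form disease pools from
    which each case-control set draws its configured numbers of cases and
    controls before per-variant logistic regression.  ``bio_flags`` /
    ``dis_flags`` assign the population-stratification-adjusted flag per
    cohort (default: all adjusted).
    """
    rng = rng or _streams(config)[3]
    n = config.n_individuals
    n_bio = int(round(n * config.biomarker_fraction))
    bio_cohorts, dis_pools = _partition(
        n, n_bio, config.n_cohorts_biomarker, config.n_cohorts_disease
    )
    if bio_flags is None:
        bio_flags = [True] * len(bio_cohorts)
    if dis_flags is None:
        dis_flags = [True] * len(dis_pools)

    bio_records: list[StudyAssociation] = []
    for i, (idx, flag) in enumerate(zip(bio_cohorts, bio_flags)):
        x = biomarker[idx]
        x = (x - x.mean()) / x.std(ddof=1)
        for j, (rsid, _, _) in enumerate(config.variants):
            g = genotypes[idx, j].astype(float)
            slope, se = _linear_marginal(x, g)
            variant = VariantInstrument(
                rsid=rsid,
                gene_label="SIM",
                effect_allele="G",
                other_allele="A",
                effect_allele_freq=float(g.mean() / 2.0),
            )
            bio_records.append(
                StudyAssociation(
                    study_id=f"sim-bio-{i}",
                    variant=variant,
                    estimate=AssociationEstimate(
                        scale=SD_UNITS, beta=slope, se=se, n=idx.size
                    ),
                    design="gwa",
                    pop_strat_adjusted=bool(flag),
                    population="synthetic",
                )
            )

    dis_records: list[StudyAssociation] = []
    for i, (idx, flag) in enumerate(zip(dis_pools, dis_flags)):
        y = labels[idx]
        cases = idx[y == 1]
        controls = idx[y == 0]
        if cases.size < config.n_case or controls.size < config.n_control:
            raise ValidationError(
                f"disease pool {i} has {cases.size} cases / {controls.size} controls; "
                f"requested {config.n_case}/{config.n_control}"
            )
        chosen_cases = rng.choice(cases, size=config.n_case, replace=False)
        chosen_controls = rng.choice(controls, size=config.n_control, replace=False)
        sample = np.concatenate([chosen_cases, chosen_controls])
        y_s = np.concatenate(
            [np.ones(config.n_case, dtype=np.int8), np.zeros(config.n_control, dtype=np.int8)]
        )
        for j, (rsid, _, _) in enumerate(config.variants):
            g = genotypes[sample, j].astype(float)
            beta, se = _logistic_marginal(y_s, g)
            variant = VariantInstrument(
                rsid=rsid,
                gene_label="SIM",
                effect_allele="G",
                other_allele="A",
                effect_allele_freq=float(genotypes[chosen_controls, j].mean() / 2.0),
            )
            dis_records.append(
                StudyAssociation(
                    study_id=f"sim-dis-{i}",
                    variant=variant,
                    estimate=AssociationEstimate(
                        scale=LOG_ODDS,
                        beta=beta,
                        se=se,
                        n=config.n_case + config.n_control,
                        n_case=config.n_case,
                        n_control=config.n_control,
                    ),
                    design="gwa",
                    pop_strat_adjusted=bool(flag),
                    population="synthetic",
                )
            )
    return bio_records, dis_records


def simulate_cohorts(
    config: SimulationConfig,
    bio_flags: Sequence[bool] | None = None,
    dis_flags: Sequence[bool] | None = None,
) -> tuple[list[StudyAssociation], list[StudyAssociation]]:
    """Generate one synthetic study end to end: genotypes -> biomarker ->
    disease -> two-sample per-cohort summaries."""
    rng_g, rng_x, rng_d, rng_s = _streams(config)
    genotypes = simulate_genotypes(config, rng_g)
    confounder = None
    if config.confounder_effect != (0.0, 0.0):
        confounder = rng_x.standard_normal(config.n_individuals)
    biomarker = simulate_biomarker(genotypes, config, rng_x, confounder)
    labels = simulate_disease(biomarker, genotypes, config, rng_d, confounder)
    return summaries_from_cohorts(
        genotypes, biomarker, labels, config, rng_s, bio_flags, dis_flags
    )


def truth_table(config: SimulationConfig) -> list[tuple[str, float]]:
    """(parameter, value) rows describing the generative truth."""
    rows = [
        ("gamma_log_or_per_sd", config.gamma),
        ("or_per_sd", config.true_or_per_sd),
        ("baseline_prevalence", config.baseline_prevalence),
        ("genetic_variance", config.genetic_variance),
    ]
    for (rsid, f, b), d in zip(config.variants, config.deltas):
        rows += [
            (f"eaf:{rsid}", f),
            (f"beta_sd:{rsid}", b),
            (f"pleiotropy_delta:{rsid}", float(d)),
        ]
    return rows


@dataclass(frozen=True)
class RecoverySummary:
    """Operating characteristics of the full chain over replicates."""

    n_replicates: int
    gamma_true: float
    mean_gamma_hat: float
    bias: float
    empirical_se: float
    mean_delta_se: float
    coverage: float
    reject_rate: float
    mean_i2: float
    mean_q: float
    n_failed: int
    gamma_hats: tuple[float, ...] = field(repr=False, default=())


def recover_parameters(
    config: SimulationConfig,
    n_replicates: int = 200,
    level: float = 0.95,
) -> RecoverySummary:
    """Replicate the generate -> summarize -> MR chain and measure recovery.

    Reports the mean combined estimate, its bias against the generative
    gamma, the empirical SD of the estimates against the mean delta-method
    SE, confidence-interval coverage, the rejection rate of the combined
    test at the nominal level, and the mean across-instrument Q and I²
    (the pleiotropy diagnostic).  Replicate r uses the r-th spawn of the
    master seed, so results are reproducible and replicates independent.
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(n_replicates)
    gamma = config.gamma
    hats, ses, covered, rejected, i2s, qs = [], [], [], [], [], []
    n_failed = 0
    from dataclasses import replace as dc_replace

    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        rep_config = dc_replace(config, seed=rep_seed)
        try:
            bio, dis = simulate_cohorts(rep_config)
            result = run_mr_analysis(bio, dis, level=level)
        except (ValidationError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            warnings.warn(f"replicate {rep} failed: {exc}", stacklevel=2)
            n_failed += 1
            continue
        c = result.combined
        hats.append(c.pooled_beta)
        ses.append(c.pooled_se)
        covered.append(c.ci_low <= gamma <= c.ci_high)
        rejected.append(c.p < 1.0 - level)
        i2s.append(c.i2 if c.i2 is not None else 0.0)
        qs.append(c.q)
    hats_arr = np.asarray(hats)
    return RecoverySummary(
        n_replicates=len(hats),
        gamma_true=gamma,
        mean_gamma_hat=float(hats_arr.mean()),
        bias=float(hats_arr.mean() - gamma),
        empirical_se=float(hats_arr.std(ddof=1)),
        mean_delta_se=float(np.mean(ses)),
        coverage=float(np.mean(covered)),
        reject_rate=float(np.mean(rejected)),
        mean_i2=float(np.mean(i2s)),
        mean_q=float(np.mean(qs)),
        n_failed=n_failed,
        gamma_hats=tuple(hats_arr.tolist()),
    )
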