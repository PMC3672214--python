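import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ironmr.assoc import (
    LOG_ODDS,
    SD_UNITS,
    AssociationEstimate,
    UnitScale,
    VariantInstrument,
    or_ci_to_log_scale,
    se_from_symmetric_ci,
)
from ironmr.mr import wald_ratio
from ironmr.simulate import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Published per-variant aggregates of the iron study, the raw input of the
# reproduction chain: (rsid, gene, effect allele, other allele, frequency),
# gene-iron effect in SD/allele with 95% CI, gene-PD odds ratio with 95% CI.
VARIANTS = (
    ("rs1800562", "HFE", "A", "G", 0.07),
    ("rs1799945", "HFE", "G", "C", 0.15),
    ("rs855791", "TMPRSS6", "G", "A", 0.40),
)
IRON_PER_ALLELE = ((0.37, 0.33, 0.41), (0.19, 0.17, 0.21), (0.19, 0.17, 0.21))
PD_OR_PER_ALLELE = ((0.97, 0.92, 1.02), (0.99, 0.96, 1.03), (0.97, 0.94, 0.99))
IRON_SD = 37.6
GIS_N = 21_567


@pytest.fixture(scope="session")
def unit_scale():
    return UnitScale(sd_in_units=IRON_SD, unit_name="µg/dL")


@pytest.fixture(scope="session")
def published_wald_estimates():
    """The three per-instrument Wald ratios built from published aggregates."""
    estimates = []
    for (rsid, gene, ea, oa, eaf), (b, blo, bhi), (o, olo, ohi) in zip(
        VARIANTS, IRON_PER_ALLELE, PD_OR_PER_ALLELE
    ):
        variant = VariantInstrument(rsid, gene, ea, oa, eaf)
        numerator = or_ci_to_log_scale(o, olo, ohi)
        denominator = AssociationEstimate(
            scale=SD_UNITS, beta=b, se=se_from_symmetric_ci(blo, bhi), n=GIS_N
        )
        estimates.append(wald_ratio(numerator, denominator, variant))
    return estimates


@pytest.fixture(scope="session")
def recovery_config():
    """Study conditions for parameter recovery: 50,000 individuals split
    half into five biomarker cohorts and half into two 1:4 case-control
    sets at 2% prevalence, instruments at the study's effect sizes."""
    return SimulationConfig(
        n_individuals=50_000,
        variants=(
            ("rs1800562", 0.07, 0.37),
            ("rs1799945", 0.15, 0.19),
            ("rs855791", 0.45, 0.19),
        ),
        seed=7,
        n_cohorts_biomarker=5,
        n_cohorts_disease=2,
        true_or_per_sd=0.88,
        baseline_prevalence=0.02,
        n_case=200,
        n_control=800,
        biomarker_fraction=0.5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
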