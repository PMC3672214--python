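"""Wald-ratio Mendelian randomization from aggregate statistics.

Each genetic instrument yields a causal estimate as the ratio of its
gene–disease log odds ratio (per allele) to its gene–biomarker effect (in
biomarker SDs per allele):

    log OR_disease/biomarker = log OR_disease/allele / beta_biomarker/allele

The ratio's standard error comes from the first-order delta method with a
zero covariance term — exact for a two-sample design where numerator and
denominator are estimated in non-overlapping samples.  Multiple instruments
are combined by inverse-variance fixed-effect meta-analysis, with I² across
instruments serving as the pleiotropy diagnostic; instrument strength is
summarized by F statistics from the variance explained.

Unit conversions (per-SD odds ratio to per-measurement-unit, relative and
absolute risk changes under the rare-disease approximation OR ~ RR) are
collected here because they are part of how the causal estimate is
reported.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .assoc import (
    LOG_ODDS,
    SD_UNITS,
    AssociationEstimate,
    UnitScale,
    ValidationError,
    VariantInstrument,
)
from .meta import MetaResult, pool_fixed

__all__ = [
    "DivisionError",
    "WaldRatioEstimate",
    "InstrumentStrength",
    "MRResult",
    "wald_ratio",
    "delta_se",
    "combine_instruments",
    "f_statistic",
    "f_combined",
    "r2_from_af_beta",
    "beta_sd_to_units",
    "or_per_sd_to_per_unit",
    "relative_risk_reduction",
    "project_absolute_risk",
    "mr_report_tables",
]

DELTA_METHODS = ("delta1", "delta2")


class DivisionError(ValidationError):
    """Wald ratio undefined: the gene–biomarker effect is zero.

    Such an instrument carries no information about the biomarker and
    should be removed from the instrument set.
    """


@dataclass(frozen=True)
class WaldRatioEstimate:
    """Per-instrument causal estimate: log-odds of disease per biomarker SD."""

    instrument: VariantInstrument
    ratio: float
    se: float
    method: str
    numerator: AssociationEstimate
    denominator: AssociationEstimate

    def __post_init__(self) -> None:
        if self.method not in DELTA_METHODS:
            raise ValidationError(f"method must be one of {DELTA_METHODS}, got {self.method!r}")
        if not (math.isfinite(self.se) and self.se > 0.0):
            raise ValidationError(f"se must be positive, got {self.se}")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.ratio)


@dataclass(frozen=True)
class InstrumentStrength:
    """F statistic of one instrument, with the R² and n it derives from."""

    r2: float
    n: int
    f: float

    def __post_init__(self) -> None:
        expected = f_statistic(self.r2, self.n)
        if not math.isclose(self.f, expected, rel_tol=1e-9):
            raise ValidationError(
                f"f = {self.f} inconsistent with r2 = {self.r2}, n = {self.n} "
                f"(expected {expected})"
            )


@dataclass(frozen=True)
class MRResult:
    """Combined MR estimate with per-instrument detail and strength."""

    combined: MetaResult
    per_instrument: tuple[WaldRatioEstimate, ...]
    f_stats: tuple[float, ...] | None = None
    f_combined: float | None = None
    unit_scale: UnitScale | None = None

    def __post_init__(self) -> None:
        if self.f_stats is not None and len(self.f_stats) != len(self.per_instrument):
            raise ValidationError("need one F statistic per instrument")


def _check_scales(numerator: AssociationEstimate, denominator: AssociationEstimate) -> None:
    if numerator.scale != LOG_ODDS:
        raise ValidationError(f"numerator must be on the log-odds scale, got {numerator.scale!r}")
    if denominator.scale != SD_UNITS:
        raise ValidationError(f"denominator must be in SD units, got {denominator.scale!r}")


def wald_ratio(
    numerator: AssociationEstimate,
    denominator: AssociationEstimate,
    instrument: VariantInstrument | None = None,
    method: str = "delta1",
) -> WaldRatioEstimate:
    """Wald-type causal estimate: ratio of gene–disease to gene–biomarker effect."""
    _check_scales(numerator, denominator)
    if denominator.beta == 0.0:
        raise DivisionError(
            "gene-biomarker effect is zero; remove this instrument from the analysis"
        )
    ratio = numerator.beta / denominator.beta
    se = delta_se(numerator, denominator, method)
    if instrument is None:
        instrument = VariantInstrument("unnamed", "", "A", "G")
    return WaldRatioEstimate(
        instrument=instrument,
        ratio=ratio,
        se=se,
        method=method,
        numerator=numerator,
        denominator=denominator,
    )


def delta_se(
    numerator: AssociationEstimate,
    denominator: AssociationEstimate,
    method: str = "delta1",
) -> float:
    """Delta-method standard error of the Wald ratio.

    First order (``delta1``), with b the denominator effect and a the
    numerator effect::

        se² = se_a²/b² + a² se_b²/b⁴

    The covariance term is zero by the two-sample design.  ``delta2`` adds
    the second-order term se_a² se_b² / b⁴.
    """
    _check_scales(numerator, denominator)
    if method not in DELTA_METHODS:
        raise ValidationError(f"method must be one of {DELTA_METHODS}, got {method!r}")
    b = denominator.beta
    if b == 0.0:
        raise DivisionError(
            "gene-biomarker effect is zero; remove this instrument from the analysis"
        )
    var = numerator.se**2 / b**2 + numerator.beta**2 * denominator.se**2 / b**4
    if method == "delta2":
        var += numerator.se**2 * denominator.se**2 / b**4
    return math.sqrt(var)


def combine_instruments(
    estimates: Sequence[WaldRatioEstimate], level: float = 0.95
) -> MRResult:
    """Pool per-instrument Wald ratios by fixed-effect meta-analysis.

    Heterogeneity across instruments (Q, I² with its CI) is reported as the
    pleiotropy diagnostic: valid instruments targeting the same causal
    effect should differ only by sampling error.
    """
    if len(estimates) == 0:
        raise ValidationError("need at least one instrument")
    rsids = [e.instrument.rsid for e in estimates]
    dupes = {r for r in rsids if rsids.count(r) > 1}
    if dupes:
        raise ValidationError(f"duplicate instrument rsid(s): {', '.join(sorted(dupes))}")
    combined = pool_fixed([(e.ratio, e.se) for e in estimates], level=level)
    return MRResult(combined=combined, per_instrument=tuple(estimates))


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F statistic: F = R² (n - 2) / (1 - R²)."""
    if not 0.0 <= r2 < 1.0:
        raise ValidationError(f"r2 must be in [0,1), got {r2}")
    if n <= 2:
        raise ValidationError(f"n must exceed 2, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


def f_combined(
    r2_list: Sequence[float], n: int, formula: str = "pooled_r2"
) -> float:
    """Overall F statistic for several independent instruments.

    ``pooled_r2`` treats the summed R² as one composite instrument:
    F = (sum R²)(n - 2)/(1 - sum R²); ``k_adjusted`` is the multi-regressor
    form F = (sum R²/(1 - sum R²)) (n - k - 1)/k.
    """
    if len(r2_list) == 0:
        raise ValidationError("need at least one r2")
    if any(r2 < 0.0 for r2 in r2_list):
        raise ValidationError("r2 values must be nonnegative")
    total = float(sum(r2_list))
    if total >= 1.0:
        raise ValidationError(f"summed r2 must be below 1, got {total}")
    k = len(r2_list)
    if formula == "pooled_r2":
        return f_statistic(total, n)
    if formula == "k_adjusted":
        if n <= k + 1:
            raise ValidationError(f"n must exceed k + 1 = {k + 1}, got {n}")
        return (total / (1.0 - total)) * ((n - k - 1) / k)
    raise ValidationError(f"formula must be 'pooled_r2' or 'k_adjusted', got {formula!r}")


def r2_from_af_beta(f: float, beta_sd: float) -> float:
    """Variance explained by an additive biallelic variant on a unit-variance
    trait: R² = 2 f (1 - f) beta²."""
    if not 0.0 < f < 1.0:
        raise ValidationError(f"allele frequency must be in (0,1), got {f}")
    return 2.0 * f * (1.0 - f) * beta_sd**2


def beta_sd_to_units(beta_sd: float, scale: UnitScale) -> float:
    """Convert an effect in biomarker SDs to measurement units."""
    return beta_sd * scale.sd_in_units


def or_per_sd_to_per_unit(or_sd: float, scale: UnitScale, units: float = 1.0) -> float:
    """Rescale an odds ratio per biomarker SD to one per ``units`` of
    measurement: OR^(units/sd_in_units)."""
    if or_sd <= 0.0:
        raise ValidationError(f"odds ratio must be positive, got {or_sd}")
    return or_sd ** (units / scale.sd_in_units)


def relative_risk_reduction(or_value: float) -> float:
    """(1 - OR) × 100, under the rare-disease approximation OR ~ RR.

    Negative values indicate a risk increase.
    """
    if or_value <= 0.0:
        raise ValidationError(f"odds ratio must be positive, got {or_value}")
    return (1.0 - or_value) * 100.0


def project_absolute_risk(baseline_per_10k: float, or_value: float) -> float:
    """Project an absolute rate per 10,000 under the rare-disease
    approximation: baseline × OR.

    Warns above 10% baseline prevalence, where OR no longer approximates
    the risk ratio.
    """
    if baseline_per_10k <= 0.0:
        raise ValidationError(f"baseline rate must be positive, got {baseline_per_10k}")
    if or_value <= 0.0:
        raise ValidationError(f"odds ratio must be positive, got {or_value}")
    if baseline_per_10k > 1000.0:
        warnings.warn(
            "baseline prevalence above 10%: odds ratio no longer approximates "
            "the risk ratio, projection is unreliable",
            stacklevel=2,
        )
    return baseline_per_10k * or_value


def mr_report_tables(result: MRResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular MR report: per-instrument odds ratios plus the combined row,
    and the instrument-strength table (r2, n, F)."""
    from .assoc import z_quantile

    level = result.combined.level
    z = z_quantile(level)
    rows = []
    for est, wt in zip(result.per_instrument, result.combined.weights):
        rows.append({
            "label": est.instrument.rsid,
            "or_per_sd": math.exp(est.ratio),
            "ci_low": math.exp(est.ratio - z * est.se),
            "ci_high": math.exp(est.ratio + z * est.se),
            "weight_pct": 100.0 * wt,
            "is_pooled": False,
        })
    c = result.combined
    rows.append({
        "label": "combined",
        "or_per_sd": math.exp(c.pooled_beta),
        "ci_low": math.exp(c.ci_low),
        "ci_high": math.exp(c.ci_high),
        "weight_pct": 100.0,
        "is_pooled": True,
    })
    instruments = pd.DataFrame(rows)
    strength_rows = []
    if result.f_stats is not None:
        for est, f in zip(result.per_instrument, result.f_stats):
            den = est.denominator
            strength_rows.append({
                "label": est.instrument.rsid,
                "r2": r2_from_af_beta(est.instrument.effect_allele_freq, den.beta)
                if est.instrument.effect_allele_freq is not None
                else float("nan"),
                "n": den.n,
                "f": f,
            })
    strength = pd.DataFrame(strength_rows, columns=["label", "r2", "n", "f"])
    return instruments, strength
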