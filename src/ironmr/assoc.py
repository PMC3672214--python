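"""Domain types, scale conversions, allele harmonization and summary-table I/O.

Aggregate genetic association statistics are the raw material of a
summary-level Mendelian randomization analysis: per-variant effects on a
standardized quantitative biomarker (here serum iron, in SD units per
effect-allele copy) and per-variant, per-study effects on a binary disease
(log odds ratios per allele).  This module defines the in-memory containers
for those records, the conversions between printed odds-ratio confidence
intervals and log-odds standard errors, the allele-harmonization step that
puts every estimate on the same effect allele, and a tab-separated exchange
format with strict per-row validation.

All internal effect sizes for binary outcomes live on the log-odds scale;
odds-ratio confidence intervals are accepted at ingest and converted
immediately.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SD_UNITS",
    "LOG_ODDS",
    "ValidationError",
    "FormatError",
    "HarmonizationError",
    "AmbiguityError",
    "VariantInstrument",
    "AssociationEstimate",
    "StudyAssociation",
    "UnitScale",
    "z_quantile",
    "or_ci_to_log_scale",
    "se_from_symmetric_ci",
    "harmonize_to_effect_allele",
    "read_summary_table",
    "write_summary_table",
    "SUMMARY_COLUMNS",
]

#: Scale labels for :class:`AssociationEstimate`.
SD_UNITS = "sd-units"
LOG_ODDS = "log-odds"

_SCALES = frozenset({SD_UNITS, LOG_ODDS})
_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_DESIGNS = frozenset({"candidate", "gwa", "immunochip"})

#: Half-width of the allele-frequency window around 0.5 inside which a
#: strand-ambiguous (palindromic) variant cannot be oriented by frequency.
AMBIGUOUS_FREQ_WINDOW = 0.08

#: Columns of the tab-separated summary-statistic exchange format, in order.
SUMMARY_COLUMNS = [
    "study_id", "rsid", "gene", "effect_allele", "other_allele", "eaf",
    "scale", "beta", "se", "or", "ci_low", "ci_high", "p", "n",
    "n_case", "n_control", "design", "pop_strat_adjusted", "population",
]


class ValidationError(ValueError):
    """An input violates a domain invariant."""


class FormatError(ValidationError):
    """A summary table is structurally malformed (missing columns, bad rows)."""


class HarmonizationError(ValueError):
    """Two variant records cannot be reconciled to a common effect allele."""


class AmbiguityError(HarmonizationError):
    """A palindromic allele pair cannot be oriented from the available data."""


def z_quantile(level: float) -> float:
    """Two-sided standard-normal quantile for a confidence ``level``.

    ``z_quantile(0.95)`` is Phi^-1(0.975) = 1.959964..., used at full
    precision throughout (never the rounded 1.96).
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0,1), got {level}")
    return float(stats.norm.ppf((1.0 + level) / 2.0))


@dataclass(frozen=True)
class VariantInstrument:
    """A biallelic variant used as a genetic instrument.

    ``effect_allele`` is the allele whose per-copy effect the associated
    estimates describe (for the iron study, the iron-increasing allele);
    ``effect_allele_freq`` is its population frequency when known.
    """

    rsid: str
    gene_label: str
    effect_allele: str
    other_allele: str
    effect_allele_freq: float | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in _BASES:
                raise ValidationError(f"allele must be one of A/C/G/T, got {allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError("effect and other allele must differ")
        f = self.effect_allele_freq
        if f is not None and not 0.0 < f < 1.0:
            raise ValidationError(f"effect_allele_freq must be in (0,1), got {f}")

    @property
    def is_strand_ambiguous(self) -> bool:
        """True for palindromic pairs (A/T or C/G) whose strand cannot be
        told from the allele labels alone."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class AssociationEstimate:
    """An effect size on a declared scale with its uncertainty.

    ``scale`` is ``"sd-units"`` (biomarker SDs per allele copy) or
    ``"log-odds"`` (log odds ratio per allele copy).  Confidence bounds,
    when present, are stored on the same scale as ``beta``.
    """

    scale: str
    beta: float
    se: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n: int | None = None
    n_case: int | None = None
    n_control: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValidationError(f"scale must be one of {sorted(_SCALES)}, got {self.scale!r}")
        if not math.isfinite(self.beta):
            raise ValidationError("beta must be finite")
        if not (math.isfinite(self.se) and self.se > 0.0):
            raise ValidationError(f"se must be positive, got {self.se}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValidationError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not self.ci_low < self.ci_high:  # type: ignore[operator]
                raise ValidationError("ci_low must be < ci_high")
            if not self.ci_low <= self.beta <= self.ci_high:  # type: ignore[operator]
                raise ValidationError("beta must lie inside its confidence interval")
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p_value must be in (0,1], got {self.p_value}")
        for name in ("n", "n_case", "n_control"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if None not in (self.n, self.n_case, self.n_control):
            if self.n < self.n_case + self.n_control:  # type: ignore[operator]
                raise ValidationError("n must be >= n_case + n_control")


@dataclass(frozen=True)
class StudyAssociation:
    """One study's estimate of a variant's effect on biomarker or disease."""

    study_id: str
    variant: VariantInstrument
    estimate: AssociationEstimate
    design: str = "gwa"
    pop_strat_adjusted: bool = True
    population: str = ""

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")
        if self.design not in _DESIGNS:
            raise ValidationError(f"design must be one of {sorted(_DESIGNS)}, got {self.design!r}")


@dataclass(frozen=True)
class UnitScale:
    """Mapping between biomarker SD units and measurement units.

    For serum iron the study SD is 37.6 µg/dL.
    """

    sd_in_units: float
    unit_name: str = "µg/dL"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sd_in_units) and self.sd_in_units > 0.0):
            raise ValidationError(f"sd_in_units must be positive, got {self.sd_in_units}")


def or_ci_to_log_scale(
    or_value: float,
    ci_low: float,
    ci_high: float,
    level: float = 0.95,
    **extra,
) -> AssociationEstimate:
    """Convert a printed odds ratio with confidence interval to log-odds.

    beta = ln(OR) and se = (ln(ci_high) - ln(ci_low)) / (2 z), with z the
    standard-normal quantile at (1 + level)/2.  Keyword extras (``p_value``,
    ``n_case``...) are forwarded to the resulting estimate.
    """
    for name, v in (("or_value", or_value), ("ci_low", ci_low), ("ci_high", ci_high)):
        if not (math.isfinite(v) and v > 0.0):
            raise ValidationError(f"{name} must be a positive real, got {v}")
    if not ci_low <= or_value <= ci_high:
        raise ValidationError(
            f"odds ratio {or_value} outside its confidence interval [{ci_low}, {ci_high}]"
        )
    z = z_quantile(level)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return AssociationEstimate(
        scale=LOG_ODDS,
        beta=math.log(or_value),
        se=se,  # se == 0 (degenerate CI) is rejected by the estimate invariant
        ci_low=math.log(ci_low),
        ci_high=math.log(ci_high),
        **extra,
    )


def se_from_symmetric_ci(low: float, high: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric confidence interval: (high-low)/(2z)."""
    if not low < high:
        raise ValidationError(f"need low < high, got [{low}, {high}]")
    return (high - low) / (2.0 * z_quantile(level))


def _flip_estimate(est: AssociationEstimate) -> AssociationEstimate:
    """Re-express an estimate per copy of the opposite allele."""
    ci_low = -est.ci_high if est.ci_high is not None else None
    ci_high = -est.ci_low if est.ci_low is not None else None
    return replace(est, beta=-est.beta, ci_low=ci_low, ci_high=ci_high)


def harmonize_to_effect_allele(
    assoc: StudyAssociation, target: VariantInstrument
) -> StudyAssociation:
    """Re-express a study estimate per copy of ``target.effect_allele``.

    Handles swapped effect/other alleles (beta sign negated, CI bounds
    swapped and negated, allele frequency complemented) and strand
    complements.  Palindromic pairs (A/T, C/G) carry no strand information
    in their labels, so orientation is resolved by allele frequency only
    when both frequencies are known and both lie outside
    ``0.5 ± AMBIGUOUS_FREQ_WINDOW``; frequencies on the same side of 0.5
    mean same orientation, opposite sides mean a flip.
    """
    va = assoc.variant
    if va.rsid != target.rsid:
        raise HarmonizationError(f"rsid mismatch: {va.rsid} vs {target.rsid}")
    comp = _COMPLEMENT
    pa = (va.effect_allele, va.other_allele)
    pt = (target.effect_allele, target.other_allele)

    if va.is_strand_ambiguous or target.is_strand_ambiguous:
        if {*pa} not in ({*pt}, {comp[pt[0]], comp[pt[1]]}):
            raise HarmonizationError(
                f"{va.rsid}: allele pair {pa} irreconcilable with {pt}"
            )
        fa, ft = va.effect_allele_freq, target.effect_allele_freq
        if fa is None or ft is None:
            raise AmbiguityError(
                f"{va.rsid}: palindromic pair needs frequencies on both sides to orient"
            )
        if abs(fa - 0.5) <= AMBIGUOUS_FREQ_WINDOW or abs(ft - 0.5) <= AMBIGUOUS_FREQ_WINDOW:
            raise AmbiguityError(
                f"{va.rsid}: allele frequency too close to 0.5 "
                f"(|f-0.5| <= {AMBIGUOUS_FREQ_WINDOW}) to orient a palindromic pair"
            )
        flip = (fa - 0.5) * (ft - 0.5) < 0.0
    elif pa == pt:
        flip = False
    elif pa == (pt[1], pt[0]):
        flip = True
    elif (comp[pa[0]], comp[pa[1]]) == pt:
        flip = False
    elif (comp[pa[0]], comp[pa[1]]) == (pt[1], pt[0]):
        flip = True
    else:
        raise HarmonizationError(f"{va.rsid}: allele pair {pa} irreconcilable with {pt}")

    if flip:
        freq = None if va.effect_allele_freq is None else 1.0 - va.effect_allele_freq
        variant = replace(
            target,
            effect_allele_freq=target.effect_allele_freq
            if target.effect_allele_freq is not None
            else freq,
        )
        return replace(assoc, variant=variant, estimate=_flip_estimate(assoc.estimate))
    variant = replace(
        target,
        effect_allele_freq=target.effect_allele_freq
        if target.effect_allele_freq is not None
        else va.effect_allele_freq,
    )
    return replace(assoc, variant=variant)


# ---------------------------------------------------------------------------
# Tab-separated exchange format


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(round(v))


def _row_to_record(row: pd.Series) -> StudyAssociation:
    variant = VariantInstrument(
        rsid=str(row["rsid"]),
        gene_label="" if pd.isna(row["gene"]) else str(row["gene"]),
        effect_allele=str(row["effect_allele"]).upper(),
        other_allele=str(row["other_allele"]).upper(),
        effect_allele_freq=_opt_float(row["eaf"]),
    )
    scale = str(row["scale"])
    beta, se = _opt_float(row["beta"]), _opt_float(row["se"])
    or_value = _opt_float(row["or"])
    ci_low, ci_high = _opt_float(row["ci_low"]), _opt_float(row["ci_high"])
    common = dict(
        p_value=_opt_float(row["p"]),
        n=_opt_int(row["n"]),
        n_case=_opt_int(row["n_case"]),
        n_control=_opt_int(row["n_control"]),
    )
    if or_value is not None:
        if scale != LOG_ODDS:
            raise ValidationError(
                "odds-ratio columns are only valid with scale 'log-odds', "
                f"row declares {scale!r}"
            )
        if ci_low is None or ci_high is None:
            raise ValidationError("'or' requires ci_low and ci_high")
        estimate = or_ci_to_log_scale(or_value, ci_low, ci_high, **common)
    elif beta is not None and se is not None:
        estimate = AssociationEstimate(
            scale=scale, beta=beta, se=se, ci_low=ci_low, ci_high=ci_high, **common
        )
    else:
        raise ValidationError("row must populate (beta, se) or (or, ci_low, ci_high)")
    raw_flag = row["pop_strat_adjusted"]
    if isinstance(raw_flag, str):
        if raw_flag.lower() not in ("true", "false"):
            raise ValidationError(f"pop_strat_adjusted must be true/false, got {raw_flag!r}")
        flag = raw_flag.lower() == "true"
    else:
        flag = bool(raw_flag)
    return StudyAssociation(
        study_id=str(row["study_id"]),
        variant=variant,
        estimate=estimate,
        design=str(row["design"]),
        pop_strat_adjusted=flag,
        population="" if pd.isna(row["population"]) else str(row["population"]),
    )


def read_summary_table(source) -> list[StudyAssociation]:
    """Read a tab-separated summary-statistic table into validated records.

    ``source`` is a path or text stream.  Rows failing a type or invariant
    check are collected and reported together with their 1-based data row
    numbers in a :class:`FormatError`.
    """
    frame = pd.read_csv(source, sep="\t", dtype={"study_id": str, "rsid": str}, na_filter=True)
    missing = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    records: list[StudyAssociation] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            records.append(_row_to_record(row))
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise FormatError("invalid summary rows: " + "; ".join(problems))
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, ".12g")
    return str(value)


def write_summary_table(records: Iterable[StudyAssociation], dest=None) -> pd.DataFrame:
    """Serialize records to the exchange format.

    Returns the table as a DataFrame of strings; when ``dest`` (path or
    stream) is given the TSV is written there too.  Reals are rendered to 12
    significant digits so a write/read round trip preserves them.
    """
    rows = []
    for rec in records:
        est, var = rec.estimate, rec.variant
        rows.append({
            "study_id": rec.study_id,
            "rsid": var.rsid,
            "gene": var.gene_label,
            "effect_allele": var.effect_allele,
            "other_allele": var.other_allele,
            "eaf": _fmt(var.effect_allele_freq),
            "scale": est.scale,
            "beta": _fmt(est.beta),
            "se": _fmt(est.se),
            "or": "",
            "ci_low": _fmt(est.ci_low),
            "ci_high": _fmt(est.ci_high),
            "p": _fmt(est.p_value),
            "n": _fmt(est.n),
            "n_case": _fmt(est.n_case),
            "n_control": _fmt(est.n_control),
            "design": rec.design,
            "pop_strat_adjusted": _fmt(rec.pop_strat_adjusted),
            "population": rec.population,
        })
    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS, dtype=str)
    if dest is not None:
        frame.to_csv(dest, sep="\t", index=False)
    return frame
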