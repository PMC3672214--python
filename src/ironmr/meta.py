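"""Inverse-variance meta-analysis with heterogeneity diagnostics.

Fixed-effect pooling is the workhorse of the whole analysis: it combines
per-study gene–disease log odds ratios into one estimate per variant, and
later combines per-instrument Mendelian randomization estimates into a
single causal estimate.  Cochran's Q and the derived I² quantify
between-estimate heterogeneity; across instruments, excess heterogeneity is
the operational signal of pleiotropy.

Estimate i with standard error se_i receives weight w_i = 1/se_i²; the
pooled effect is sum(w_i b_i)/sum(w_i) with standard error sum(w_i)^-1/2.
Q = sum(w_i (b_i - pooled)²) is chi-square on k-1 degrees of freedom under
homogeneity, and I² = max(0, (Q - df)/Q) × 100 is the percentage of total
variation attributed to heterogeneity rather than sampling error.  The I²
confidence interval uses the test-based ln-H method with
H = sqrt(Q/df).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import ValidationError, z_quantile

__all__ = [
    "DegreesOfFreedomError",
    "MetaResult",
    "pool_fixed",
    "pool_random",
    "cochran_q",
    "i_squared",
    "i_squared_ci",
    "forest_table",
]


class DegreesOfFreedomError(ValidationError):
    """Heterogeneity statistics need at least two estimates."""


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect with heterogeneity diagnostics.

    Heterogeneity fields (``q`` aside) are ``None`` when only one estimate
    was pooled (df = 0): I² is not applicable there, not zero.  ``weights``
    are normalized to sum to 1.
    """

    pooled_beta: float
    pooled_se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    het_p: float | None
    i2: float | None
    i2_ci_low: float | None
    i2_ci_high: float | None
    k: int
    weights: tuple[float, ...]
    level: float


def _as_arrays(estimates: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) == 0:
        raise ValidationError("need at least one estimate to pool")
    betas = np.asarray([b for b, _ in estimates], dtype=float)
    ses = np.asarray([s for _, s in estimates], dtype=float)
    if not np.all(np.isfinite(betas)) or not np.all(np.isfinite(ses)):
        raise ValidationError("estimates must be finite")
    if np.any(ses <= 0.0):
        raise ValidationError("all standard errors must be positive")
    return betas, ses


def pool_fixed(estimates: Sequence[tuple[float, float]], level: float = 0.95) -> MetaResult:
    """Inverse-variance fixed-effect pooling of ``(beta, se)`` pairs.

    With a single estimate the input is returned unchanged (q = 0, df = 0,
    heterogeneity not applicable).
    """
    betas, ses = _as_arrays(estimates)
    k = betas.size
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    z_stat = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    z = z_quantile(level)
    if k >= 2:
        q, df, het_p = cochran_q(estimates, pooled)
        i2 = i_squared(q, df)
        with warnings.catch_warnings():
            # the uninformative-interval warning is useful when i_squared_ci
            # is called directly, noise when pooling many small metas
            warnings.simplefilter("ignore", UserWarning)
            i2_lo, i2_hi = i_squared_ci(q, df, level)
    else:
        q, df = 0.0, 0
        het_p = i2 = i2_lo = i2_hi = None
    return MetaResult(
        pooled_beta=pooled,
        pooled_se=pooled_se,
        z=z_stat,
        p=p,
        ci_low=pooled - z * pooled_se,
        ci_high=pooled + z * pooled_se,
        q=q,
        df=df,
        het_p=het_p,
        i2=i2,
        i2_ci_low=i2_lo,
        i2_ci_high=i2_hi,
        k=k,
        weights=tuple((w / np.sum(w)).tolist()),
        level=level,
    )


def pool_random(estimates: Sequence[tuple[float, float]], level: float = 0.95) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    Provided for completeness; the reproduction of the iron study uses
    fixed-effect pooling throughout.
    """
    betas, ses = _as_arrays(estimates)
    if betas.size < 2:
        return pool_fixed(estimates, level)
    w = 1.0 / ses**2
    pooled_fe = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - pooled_fe) ** 2))
    df = betas.size - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    inflated = [(b, math.sqrt(s**2 + tau2)) for b, s in zip(betas, ses)]
    result = pool_fixed(inflated, level)
    # report heterogeneity of the original estimates, not the inflated ones
    het_p = float(stats.chi2.sf(q, df))
    i2 = i_squared(q, df)
    i2_lo, i2_hi = i_squared_ci(q, df, level)
    return MetaResult(
        pooled_beta=result.pooled_beta,
        pooled_se=result.pooled_se,
        z=result.z,
        p=result.p,
        ci_low=result.ci_low,
        ci_high=result.ci_high,
        q=q,
        df=df,
        het_p=het_p,
        i2=i2,
        i2_ci_low=i2_lo,
        i2_ci_high=i2_hi,
        k=result.k,
        weights=result.weights,
        level=level,
    )


def cochran_q(
    estimates: Sequence[tuple[float, float]], pooled_beta: float
) -> tuple[float, int, float]:
    """Cochran's Q around ``pooled_beta``: (q, df, upper-tail chi-square p)."""
    betas, ses = _as_arrays(estimates)
    if betas.size < 2:
        raise DegreesOfFreedomError("Cochran's Q needs at least two estimates")
    w = 1.0 / ses**2
    q = float(np.sum(w * (betas - pooled_beta) ** 2))
    df = betas.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def i_squared(q: float, df: int) -> float:
    """I² heterogeneity percentage, truncated below at zero."""
    if df < 1:
        raise DegreesOfFreedomError(f"I² needs df >= 1, got {df}")
    if q < 0.0:
        raise ValidationError(f"q must be nonnegative, got {q}")
    if q == 0.0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def i_squared_ci(q: float, df: int, level: float = 0.95) -> tuple[float, float]:
    """Test-based confidence interval for I² via ln H, H = sqrt(Q/df).

    se(ln H) is (ln Q - ln df) / (2 (sqrt(2Q) - sqrt(2 df - 1))) when
    Q > df, otherwise sqrt(1/(2(df-1)) (1 - 1/(3 (df-1)²))) (needs df >= 2).
    The interval for H maps to I² = max(0, 1 - 1/H²) × 100; the lower bound
    is truncated at 0.  Degenerate corners (df = 1 with Q <= df, or Q ~ 0)
    carry no information about heterogeneity and return (0, 100) with a
    warning.
    """
    if df < 1:
        raise DegreesOfFreedomError(f"I² CI needs df >= 1, got {df}")
    if q <= 0.0:
        warnings.warn("Q ~ 0: I² confidence interval is uninformative", stacklevel=2)
        return 0.0, 100.0
    if q > df:
        se_ln_h = (math.log(q) - math.log(df)) / (
            2.0 * (math.sqrt(2.0 * q) - math.sqrt(2.0 * df - 1.0))
        )
    else:
        if df < 2:
            warnings.warn(
                "df = 1 with Q <= df: I² confidence interval is uninformative",
                stacklevel=2,
            )
            return 0.0, 100.0
        m = df - 1
        se_ln_h = math.sqrt(1.0 / (2.0 * m) * (1.0 - 1.0 / (3.0 * m**2)))
    ln_h = 0.5 * (math.log(q) - math.log(df))
    z = z_quantile(level)
    h_low = math.exp(ln_h - z * se_ln_h)
    h_high = math.exp(ln_h + z * se_ln_h)

    def to_i2(h: float) -> float:
        return max(0.0, 1.0 - 1.0 / h**2) * 100.0

    return to_i2(h_low), to_i2(h_high)


def forest_table(
    labels: Sequence[str],
    estimates: Sequence[tuple[float, float]],
    result: MetaResult,
) -> pd.DataFrame:
    """Forest-plot export: per-estimate rows plus the pooled row.

    Columns ``label, beta, se, ci_low, ci_high, weight_pct, is_pooled`` are
    consumable by any plotting layer.
    """
    if len(labels) != len(estimates):
        raise ValidationError("labels and estimates must have the same length")
    z = z_quantile(result.level)
    rows = [
        {
            "label": lab,
            "beta": b,
            "se": s,
            "ci_low": b - z * s,
            "ci_high": b + z * s,
            "weight_pct": 100.0 * wt,
            "is_pooled": False,
        }
        for lab, (b, s), wt in zip(labels, estimates, result.weights)
    ]
    rows.append(
        {
            "label": "pooled",
            "beta": result.pooled_beta,
            "se": result.pooled_se,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "weight_pct": 100.0,
            "is_pooled": True,
        }
    )
    return pd.DataFrame(rows)
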