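"""Wald ratios, delta-method uncertainty, instrument strength, conversions."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ironmr.assoc import (
    LOG_ODDS,
    SD_UNITS,
    AssociationEstimate,
    UnitScale,
    ValidationError,
    VariantInstrument,
)
from ironmr.mr import (
    DivisionError,
    combine_instruments,
    delta_se,
    f_combined,
    f_statistic,
    mr_report_tables,
    or_per_sd_to_per_unit,
    project_absolute_risk,
    r2_from_af_beta,
    relative_risk_reduction,
    beta_sd_to_units,
    wald_ratio,
)


def _num(beta, se):
    return AssociationEstimate(scale=LOG_ODDS, beta=beta, se=se)


def _den(beta, se):
    return AssociationEstimate(scale=SD_UNITS, beta=beta, se=se)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "num_beta, den_beta, expected",
        [
            (math.log(0.97), 0.19, -0.16031),
            (math.log(0.97), 0.37, -0.08232),
            (0.0, 0.19, 0.0),
        ],
    )
    def test_ratio(self, num_beta, den_beta, expected):
        est = wald_ratio(_num(num_beta, 0.013), _den(den_beta, 0.01))
        assert est.ratio == pytest.approx(expected, abs=5e-5)

    def test_zero_denominator_advises_removal(self):
        with pytest.raises(DivisionError, match="remove"):
            wald_ratio(_num(0.1, 0.01), _den(0.0, 0.01))

    def test_mismatched_scales_rejected(self):
        with pytest.raises(ValidationError):
            wald_ratio(_den(0.1, 0.01), _den(0.2, 0.01))

    def test_sign_consistency(self):
        est = wald_ratio(_num(-0.03, 0.01), _den(0.19, 0.01))
        assert math.copysign(1, est.ratio) == math.copysign(1, -0.03) * math.copysign(1, 0.19)


class TestDeltaSE:
    def test_first_order_value(self):
        """Frozen closed-form value for the strongest published instrument."""
        se = delta_se(_num(-0.030459, 0.013221), _den(0.19, 0.010204))
        assert se == pytest.approx(0.070109, abs=2e-5)

    def test_exact_instrument_limit(self):
        """As the denominator SE vanishes the ratio SE tends to se_num/|b|."""
        se = delta_se(_num(-0.03, 0.013), _den(0.19, 1e-12))
        assert se == pytest.approx(0.013 / 0.19, rel=1e-9)

    @given(
        a=st.floats(-0.5, 0.5),
        sa=st.floats(0.001, 0.5),
        b=st.floats(0.05, 1.0),
        sb=st.floats(0.001, 0.5),
    )
    def test_second_order_never_smaller(self, a, sa, b, sb):
        d1 = delta_se(_num(a, sa), _den(b, sb), "delta1")
        d2 = delta_se(_num(a, sa), _den(b, sb), "delta2")
        assert d2 >= d1

    def test_matches_parametric_bootstrap(self, rng):
        """In the strong-instrument regime the first-order delta SE matches
        the Monte-Carlo SD of the ratio of independent normal draws."""
        num, den = _num(-0.030459, 0.013221), _den(0.19, 0.010204)
        draws_num = rng.normal(num.beta, num.se, size=1_000_000)
        draws_den = rng.normal(den.beta, den.se, size=1_000_000)
        mc_sd = np.std(draws_num / draws_den, ddof=1)
        assert delta_se(num, den) == pytest.approx(mc_sd, rel=0.03)


class TestCombineInstruments:
    def test_published_aggregates(self, published_wald_estimates):
        result = combine_instruments(published_wald_estimates)
        assert math.exp(result.combined.pooled_beta) == pytest.approx(0.8986, abs=5e-4)
        assert result.combined.i2 == 0.0

    def test_single_instrument_passthrough(self, published_wald_estimates):
        est = published_wald_estimates[0]
        result = combine_instruments([est])
        assert result.combined.pooled_beta == pytest.approx(est.ratio)
        assert result.combined.pooled_se == pytest.approx(est.se)

    def test_identical_pair_shrinks_se(self, published_wald_estimates):
        import dataclasses

        a = published_wald_estimates[0]
        b = dataclasses.replace(
            a, instrument=dataclasses.replace(a.instrument, rsid="rs-other")
        )
        result = combine_instruments([a, b])
        assert result.combined.pooled_beta == pytest.approx(a.ratio)
        assert result.combined.pooled_se == pytest.approx(a.se / math.sqrt(2))

    def test_duplicate_rsid_rejected(self, published_wald_estimates):
        with pytest.raises(ValidationError, match="duplicate"):
            combine_instruments([published_wald_estimates[0]] * 2)

    def test_permutation_invariance(self, published_wald_estimates):
        a = combine_instruments(published_wald_estimates)
        b = combine_instruments(published_wald_estimates[::-1])
        assert a.combined.pooled_beta == pytest.approx(b.combined.pooled_beta, rel=1e-12)


class TestInstrumentStrength:
    def test_published_scale(self):
        # from the published rounded variance explained at the iron-study n
        assert f_statistic(0.017328, 21_567) == pytest.approx(380.3, abs=0.1)

    def test_small_example(self):
        assert f_statistic(0.5, 4) == pytest.approx(2.0)

    def test_monotone_in_r2_and_n(self):
        assert f_statistic(0.02, 1000) > f_statistic(0.01, 1000)
        assert f_statistic(0.01, 2000) > f_statistic(0.01, 1000)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            f_statistic(1.5, 100)
        with pytest.raises(ValidationError):
            f_statistic(0.1, 2)

    def test_combined_reduces_to_single(self):
        assert f_combined([0.5], 4, "pooled_r2") == pytest.approx(f_statistic(0.5, 4))

    def test_combined_published_inputs(self):
        f = f_combined([0.017, 0.009, 0.017], 21_567, "pooled_r2")
        assert 960 <= f <= 985

    def test_combined_k_adjusted(self):
        f = f_combined([0.017, 0.009, 0.017], 21_567, "k_adjusted")
        expected = (0.043 / 0.957) * ((21_567 - 4) / 3)
        assert f == pytest.approx(expected, rel=1e-12)

    def test_combined_saturated_rejected(self):
        with pytest.raises(ValidationError):
            f_combined([0.6, 0.5], 100)

    @pytest.mark.parametrize(
        "f, beta, expected",
        [(0.40, 0.19, 0.017328), (0.5, 1.0, 0.5), (0.3, 0.0, 0.0)],
    )
    def test_variance_explained(self, f, beta, expected):
        assert r2_from_af_beta(f, beta) == pytest.approx(expected, rel=1e-9)


class TestConversions:
    def test_sd_to_units(self, unit_scale):
        assert beta_sd_to_units(0.37, unit_scale) == pytest.approx(13.9, abs=0.05)
        assert beta_sd_to_units(0.19, unit_scale) == pytest.approx(7.1, abs=0.05)
        assert beta_sd_to_units(0.0, unit_scale) == 0.0

    def test_or_per_unit(self, unit_scale):
        assert or_per_sd_to_per_unit(0.88, unit_scale, 1.0) == pytest.approx(0.997, abs=5e-4)
        assert or_per_sd_to_per_unit(0.88, unit_scale, 37.6) == pytest.approx(0.88)
        assert or_per_sd_to_per_unit(0.88, unit_scale, 10.0) == pytest.approx(0.9666, abs=5e-4)

    @given(or_sd=st.floats(0.5, 2.0), units=st.floats(0.5, 50.0))
    def test_per_unit_round_trip(self, or_sd, units):
        """per-SD -> per-unit -> per-SD is the identity."""
        scale = UnitScale(37.6)
        per_unit = or_per_sd_to_per_unit(or_sd, scale, units)
        back = per_unit ** (scale.sd_in_units / units)
        assert back == pytest.approx(or_sd, rel=1e-12)

    @pytest.mark.parametrize(
        "or_value, expected", [(0.997, 0.3), (1.0, 0.0), (0.88, 12.0)]
    )
    def test_relative_risk_reduction(self, or_value, expected):
        assert relative_risk_reduction(or_value) == pytest.approx(expected, abs=0.05)

    def test_risk_increase_is_negative(self):
        assert relative_risk_reduction(1.1) == pytest.approx(-10.0)

    @pytest.mark.parametrize(
        "baseline, or_value, expected", [(100, 0.88, 88), (100, 1.0, 100), (100, 0.5, 50)]
    )
    def test_absolute_projection(self, baseline, or_value, expected):
        assert project_absolute_risk(baseline, or_value) == pytest.approx(expected)

    def test_projection_warns_outside_rare_disease_regime(self):
        with pytest.warns(UserWarning, match="risk ratio"):
            project_absolute_risk(2000, 0.9)


class TestReportTables:
    def test_instrument_and_strength_tables(self, published_wald_estimates):
        from ironmr.mr import MRResult, combine_instruments

        base = combine_instruments(published_wald_estimates)
        result = MRResult(
            combined=base.combined,
            per_instrument=base.per_instrument,
            f_stats=(382.0, 199.0, 379.0),
        )
        instruments, strength = mr_report_tables(result)
        assert len(instruments) == 4
        assert instruments["is_pooled"].tolist() == [False, False, False, True]
        assert instruments["weight_pct"][:3].sum() == pytest.approx(100.0)
        assert len(strength) == 3
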