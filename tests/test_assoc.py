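"""Scale conversions, allele harmonization, and summary-table round trips."""
import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ironmr.assoc import (
    LOG_ODDS,
    SD_UNITS,
    AmbiguityError,
    AssociationEstimate,
    FormatError,
    HarmonizationError,
    StudyAssociation,
    ValidationError,
    VariantInstrument,
    harmonize_to_effect_allele,
    or_ci_to_log_scale,
    read_summary_table,
    se_from_symmetric_ci,
    write_summary_table,
    z_quantile,
)


class TestScaleConversions:
    @pytest.mark.parametrize(
        "or_value, lo, hi, beta, se",
        [
            (0.88, 0.82, 0.95, -0.1278, 0.0375),
            (0.97, 0.94, 0.99, -0.03046, 0.01322),
        ],
    )
    def test_or_ci_to_log_scale(self, or_value, lo, hi, beta, se):
        est = or_ci_to_log_scale(or_value, lo, hi)
        assert est.scale == LOG_ODDS
        assert est.beta == pytest.approx(beta, abs=5e-5)
        assert est.se == pytest.approx(se, abs=5e-5)
        assert est.ci_low == pytest.approx(math.log(lo))
        assert est.ci_high == pytest.approx(math.log(hi))

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValidationError):
            or_ci_to_log_scale(1.0, 1.0, 1.0)

    def test_or_outside_ci_rejected(self):
        with pytest.raises(ValidationError):
            or_ci_to_log_scale(0.80, 0.82, 0.95)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValidationError):
            or_ci_to_log_scale(bad, 0.5, 1.5)

    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (0.17, 0.21, 0.01020),
            (0.33, 0.41, 0.02041),
            (-1.959964, 1.959964, 1.0),
        ],
    )
    def test_se_from_symmetric_ci(self, lo, hi, expected):
        assert se_from_symmetric_ci(lo, hi) == pytest.approx(expected, abs=5e-5)

    def test_se_from_inverted_ci_rejected(self):
        with pytest.raises(ValidationError):
            se_from_symmetric_ci(0.21, 0.17)

    def test_full_precision_quantile(self):
        assert z_quantile(0.95) == pytest.approx(1.959963984540054, rel=1e-12)

    @given(
        or_value=st.floats(0.1, 10.0),
        half=st.floats(0.01, 1.0),
        level=st.floats(0.5, 0.999),
    )
    def test_log_scale_round_trip(self, or_value, half, level):
        """Exponentiating the converted beta and CI recovers the inputs."""
        lo, hi = or_value * math.exp(-half), or_value * math.exp(half)
        est = or_ci_to_log_scale(or_value, lo, hi, level)
        assert math.exp(est.beta) == pytest.approx(or_value, rel=1e-12)
        assert math.exp(est.ci_low) == pytest.approx(lo, rel=1e-12)
        assert math.exp(est.ci_high) == pytest.approx(hi, rel=1e-12)


def _assoc(ea="A", oa="G", beta=0.19, freq=0.60, ci=(0.17, 0.21), rsid="rs1"):
    return StudyAssociation(
        study_id="s1",
        variant=VariantInstrument(rsid, "GENE", ea, oa, freq),
        estimate=AssociationEstimate(
            scale=SD_UNITS, beta=beta, se=0.01, ci_low=ci[0], ci_high=ci[1]
        ),
    )


class TestHarmonization:
    def test_matching_alleles_identity(self):
        target = VariantInstrument("rs1", "GENE", "A", "G", 0.60)
        out = harmonize_to_effect_allele(_assoc(), target)
        assert out.estimate == _assoc().estimate

    def test_swapped_alleles_flip_sign_and_frequency(self):
        target = VariantInstrument("rs1", "GENE", "G", "A")
        out = harmonize_to_effect_allele(_assoc(beta=0.19, freq=0.60), target)
        assert out.estimate.beta == pytest.approx(-0.19)
        assert out.estimate.ci_low == pytest.approx(-0.21)
        assert out.estimate.ci_high == pytest.approx(-0.17)
        assert out.variant.effect_allele_freq == pytest.approx(0.40)

    def test_strand_complement_same_orientation(self):
        target = VariantInstrument("rs1", "GENE", "T", "C", 0.60)
        out = harmonize_to_effect_allele(_assoc("A", "G"), target)
        assert out.estimate.beta == pytest.approx(0.19)

    def test_strand_complement_swapped(self):
        target = VariantInstrument("rs1", "GENE", "C", "T")
        out = harmonize_to_effect_allele(_assoc("A", "G"), target)
        assert out.estimate.beta == pytest.approx(-0.19)

    def test_irreconcilable_pair(self):
        target = VariantInstrument("rs1", "GENE", "A", "C")
        with pytest.raises(HarmonizationError):
            harmonize_to_effect_allele(_assoc("A", "G"), target)

    def test_palindromic_near_half_frequency_ambiguous(self):
        """An A/T variant at frequency 0.49 cannot be oriented."""
        target = VariantInstrument("rs1", "GENE", "A", "T", 0.49)
        with pytest.raises(AmbiguityError):
            harmonize_to_effect_allele(_assoc("A", "T", freq=0.49, ci=(0.17, 0.21)), target)

    def test_palindromic_missing_frequency_ambiguous(self):
        target = VariantInstrument("rs1", "GENE", "A", "T", 0.2)
        with pytest.raises(AmbiguityError):
            harmonize_to_effect_allele(_assoc("A", "T", freq=None), target)

    def test_palindromic_opposite_sides_flip(self):
        target = VariantInstrument("rs1", "GENE", "A", "T", 0.2)
        out = harmonize_to_effect_allele(_assoc("A", "T", freq=0.8), target)
        assert out.estimate.beta == pytest.approx(-0.19)

    def test_palindromic_same_side_identity(self):
        target = VariantInstrument("rs1", "GENE", "C", "G", 0.15)
        out = harmonize_to_effect_allele(_assoc("C", "G", freq=0.17), target)
        assert out.estimate.beta == pytest.approx(0.19)

    @given(beta=st.floats(-1, 1, allow_nan=False), freq=st.floats(0.05, 0.95))
    def test_swap_is_involution(self, beta, freq):
        """Flipping to the other allele twice returns the original record."""
        rec = _assoc(beta=beta, freq=freq, ci=(beta - 0.1, beta + 0.1))
        swapped_target = VariantInstrument("rs1", "GENE", "G", "A", 1 - freq)
        back_target = VariantInstrument("rs1", "GENE", "A", "G", freq)
        once = harmonize_to_effect_allele(rec, swapped_target)
        twice = harmonize_to_effect_allele(once, back_target)
        assert twice.estimate.beta == pytest.approx(rec.estimate.beta)
        assert twice.estimate.ci_low == pytest.approx(rec.estimate.ci_low)
        assert twice.variant.effect_allele_freq == pytest.approx(freq)


class TestDomainInvariants:
    def test_identical_alleles_rejected(self):
        with pytest.raises(ValidationError):
            VariantInstrument("rs1", "G", "A", "A")

    def test_beta_outside_ci_rejected(self):
        with pytest.raises(ValidationError):
            AssociationEstimate(scale=SD_UNITS, beta=0.5, se=0.1, ci_low=0.1, ci_high=0.3)

    def test_counts_consistency(self):
        with pytest.raises(ValidationError):
            AssociationEstimate(
                scale=LOG_ODDS, beta=0.0, se=0.1, n=10, n_case=8, n_control=8
            )

    def test_unknown_design_rejected(self):
        with pytest.raises(ValidationError):
            StudyAssociation(
                study_id="s",
                variant=VariantInstrument("rs1", "G", "A", "G"),
                estimate=AssociationEstimate(scale=SD_UNITS, beta=0.0, se=1.0),
                design="exome",
            )


records_strategy = st.lists(
    st.tuples(
        st.sampled_from(["rs1", "rs2", "rs3"]),
        st.floats(0.05, 0.95),
        st.floats(-2, 2),
        st.floats(0.001, 1.0),
        st.booleans(),
    ),
    min_size=1,
    max_size=8,
)


class TestSummaryTable:
    def test_fixture_gene_iron_rows(self):
        from ironmr.pipeline import fixture_path

        records = read_summary_table(str(fixture_path("gene_iron.tsv")))
        assert len(records) == 3
        assert all(r.estimate.scale == SD_UNITS for r in records)
        assert [r.variant.rsid for r in records] == ["rs1800562", "rs1799945", "rs855791"]
        assert [r.estimate.beta for r in records] == [0.37, 0.19, 0.19]

    def test_fixture_gene_pd_converted_to_log_odds(self):
        from ironmr.pipeline import fixture_path

        records = read_summary_table(str(fixture_path("gene_pd.tsv")))
        assert len(records) == 3
        assert all(r.estimate.scale == LOG_ODDS for r in records)
        assert records[2].estimate.beta == pytest.approx(math.log(0.97))

    def test_empty_table(self):
        from ironmr.assoc import SUMMARY_COLUMNS

        stream = io.StringIO("\t".join(SUMMARY_COLUMNS) + "\n")
        assert read_summary_table(stream) == []

    def test_missing_column(self):
        stream = io.StringIO("study_id\trsid\n")
        with pytest.raises(FormatError, match="missing mandatory column"):
            read_summary_table(stream)

    def test_invalid_row_reported_with_number(self):
        frame = write_summary_table([_assoc()])
        frame.loc[0, "se"] = "0"
        stream = io.StringIO(frame.to_csv(sep="\t", index=False))
        with pytest.raises(FormatError, match="row 1"):
            read_summary_table(stream)

    def test_or_with_sd_units_scale_rejected(self):
        frame = write_summary_table([_assoc()])
        frame.loc[0, ["beta", "se", "or", "ci_low", "ci_high"]] = ["", "", "0.9", "0.8", "1.0"]
        stream = io.StringIO(frame.to_csv(sep="\t", index=False))
        with pytest.raises(FormatError, match="log-odds"):
            read_summary_table(stream)

    @given(records_strategy)
    def test_write_read_round_trip(self, rows):
        """Writing then reading preserves every field to 12 significant digits."""
        records = []
        for i, (rsid, freq, beta, se, flag) in enumerate(rows):
            records.append(
                StudyAssociation(
                    study_id=f"study-{i}",
                    variant=VariantInstrument(rsid, "GENE", "A", "G", freq),
                    estimate=AssociationEstimate(scale=SD_UNITS, beta=beta, se=se, n=100),
                    design="candidate",
                    pop_strat_adjusted=flag,
                    population="EUR",
                )
            )
        stream = io.StringIO()
        write_summary_table(records, stream)
        stream.seek(0)
        back = read_summary_table(stream)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.study_id == b.study_id
            assert a.variant.rsid == b.variant.rsid
            assert a.pop_strat_adjusted == b.pop_strat_adjusted
            assert b.variant.effect_allele_freq == pytest.approx(
                a.variant.effect_allele_freq, rel=1e-11
            )
            assert b.estimate.beta == pytest.approx(a.estimate.beta, rel=1e-11, abs=1e-12)
            assert b.estimate.se == pytest.approx(a.estimate.se, rel=1e-11)
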