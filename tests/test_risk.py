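import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ravarkit import (
    ValidationError,
    copy_number,
    grs,
    lifetime_risk,
    marker_rgr,
    overall_rgr,
    predict,
    prune_ld,
)

from conftest import make_marker


class TestPruneLd:
    def test_smallest_p_per_locus(self):
        markers = [
            make_marker("rsA", locus="L1", p_value=1e-10),
            make_marker("rsB", locus="L1", p_value=1e-6),
            make_marker("rsC", locus="L2", p_value=1e-8),
        ]
        assert [m.variant_id for m in prune_ld(markers)] == ["rsA", "rsC"]

    def test_single_marker_identity(self):
        markers = [make_marker("rsA")]
        assert prune_ld(markers) == markers

    def test_tie_breaks_lexicographically(self):
        markers = [
            make_marker("rsB", locus="L1", p_value=1e-8),
            make_marker("rsA", locus="L1", p_value=1e-8),
        ]
        assert [m.variant_id for m in prune_ld(markers)] == ["rsA"]

    def test_fixture_hla_block_leads_with_strongest_snp(self, table1_records):
        """Of the six HLA-DRB1 SNPs in the fixture, pruning keeps rs2157337
        (P = 1e-299, European)."""
        from ravarkit.risk import RiskMarker

        hla = [r for r in table1_records if r.odds_ratio is not None]
        panel = [
            RiskMarker(
                variant_id=r.variant_id,
                risk_allele=r.risk_allele or "A",
                r=r.odds_ratio,
                p=0.3,
                p_value=r.p_value,
                locus_id="HLA-DRB1",
                population=r.population,
            )
            for r in hla
            if r.variant_id
            in {"rs13192471", "rs2157337", "rs2516049", "rs6457617", "rs660895", "rs6910071"}
        ]
        (lead,) = prune_ld(panel)
        assert lead.variant_id == "rs2157337"
        assert lead.p_value == 1e-299

    def test_output_size_equals_number_of_loci(self):
        markers = [
            make_marker(f"rs{i}", locus=f"L{i % 4}", p_value=10 ** -(i + 2))
            for i in range(12)
        ]
        assert len(prune_ld(markers)) == 4


class TestGrs:
    def test_no_risk_alleles_scores_zero(self):
        markers = [make_marker("rsA"), make_marker("rsB", locus="L2")]
        assert grs(markers, {"rsA": 0, "rsB": 0}) == 0.0

    def test_log_or_arithmetic(self):
        markers = [make_marker("rsA", r=1.5), make_marker("rsB", r=2.0, locus="L2")]
        expected = math.log(1.5) + 2 * math.log(2.0)
        assert grs(markers, {"rsA": 1, "rsB": 2}) == pytest.approx(expected, rel=1e-12)

    def test_null_marker_contributes_nothing(self):
        markers = [make_marker("rsA", r=1.0)]
        assert grs(markers, {"rsA": 2}) == 0.0

    def test_missing_genotype_skipped(self):
        markers = [make_marker("rsA", r=2.0), make_marker("rsB", r=3.0, locus="L2")]
        assert grs(markers, {"rsA": 1}) == pytest.approx(math.log(2.0))

    def test_additive_over_disjoint_sets(self):
        a = [make_marker("rsA", r=1.4), make_marker("rsB", r=1.9, locus="L2")]
        b = [make_marker("rsC", r=0.8, locus="L3")]
        genotype = {"rsA": 1, "rsB": 2, "rsC": 1}
        assert grs(a + b, genotype) == pytest.approx(grs(a, genotype) + grs(b, genotype))


class TestMarkerRgr:
    def test_null_marker_is_average(self):
        for p in (0.1, 0.5, 0.9):
            for x in (0, 1, 2):
                assert marker_rgr(make_marker(r=1.0, p=p), x) == pytest.approx(1.0)

    def test_fixed_allele_homozygote_is_average(self):
        assert marker_rgr(make_marker(r=2.0, p=1.0), 2) == pytest.approx(1.0)

    def test_hand_expanded_hwe_example(self):
        # r=2, p=0.5: s = 4, a = 0.25*4 + 0.5*2 + 0.25 = 2.25
        assert marker_rgr(make_marker(r=2.0, p=0.5), 2) == pytest.approx(4 / 2.25)

    @pytest.mark.parametrize("p,x", [(0.0, 1), (0.0, 2), (1.0, 0), (1.0, 1)])
    def test_impossible_genotypes_rejected(self, p, x):
        with pytest.raises(ValidationError):
            marker_rgr(make_marker(r=1.5, p=p), x)

    def test_hwe_normalization_grid(self):
        """Sum over genotypes of HWE weight times RGR is exactly 1: the
        defining baseline property, checked by explicit three-term sums."""
        for r in (0.2, 0.5, 0.9, 1.0, 1.3, 2.0, 5.0):
            for p in (0.01, 0.1, 0.3, 0.5, 0.7, 0.95):
                marker = make_marker(r=r, p=p)
                weights = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
                total = sum(w * marker_rgr(marker, x) for x, w in zip((0, 1, 2), weights))
                assert abs(total - 1.0) < 1e-12

    @given(
        r=st.floats(0.1, 10.0, allow_nan=False),
        p=st.floats(0.01, 0.99, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_copy_number(self, r, p):
        marker = make_marker(r=r, p=p)
        values = [marker_rgr(marker, x) for x in (0, 1, 2)]
        if r > 1:
            assert values[0] < values[1] < values[2]
        elif r < 1:
            assert values[0] > values[1] > values[2]

    def test_allele_relabeling_symmetry(self):
        """Swapping risk and non-risk labels (r -> 1/r, p -> 1-p, X -> 2-X)
        leaves the relative risk unchanged."""
        for r, p, x in itertools.product((0.3, 0.8, 1.5, 2.5), (0.1, 0.4, 0.8), (0, 1, 2)):
            direct = marker_rgr(make_marker(r=r, p=p), x)
            flipped = marker_rgr(make_marker(r=1 / r, p=1 - p), 2 - x)
            assert abs(direct - flipped) < 1e-12 * max(direct, 1.0)


class TestOverallRgr:
    def test_all_null_markers(self):
        markers = [make_marker(f"rs{i}", r=1.0, locus=f"L{i}") for i in range(3)]
        assert overall_rgr(markers, {f"rs{i}": 1 for i in range(3)}) == pytest.approx(1.0)

    def test_product_of_per_marker_values(self):
        a = make_marker("rsA", r=2.0, p=0.5)
        b = make_marker("rsB", r=1.0, p=0.3, locus="L2")
        value = overall_rgr([a, b], {"rsA": 2, "rsB": 1})
        assert value == pytest.approx(marker_rgr(a, 2) * marker_rgr(b, 1))

    def test_empty_panel_is_one(self):
        assert overall_rgr([], {}) == 1.0

    def test_multiplicative_over_disjoint_sets(self, five_marker_panel):
        genotype = {m.variant_id: 1 for m in five_marker_panel}
        left, right = five_marker_panel[:2], five_marker_panel[2:]
        assert overall_rgr(five_marker_panel, genotype) == pytest.approx(
            overall_rgr(left, genotype) * overall_rgr(right, genotype)
        )


class TestLifetimeRisk:
    def test_worked_example(self):
        """Overall RGR 2.6 at 1% prevalence gives a 2.6% lifetime risk."""
        assert lifetime_risk(2.6, 0.01) == pytest.approx(0.026, rel=1e-12)

    def test_average_individual_has_prevalence_risk(self):
        assert lifetime_risk(1.0, 0.01) == pytest.approx(0.01)

    def test_capped_at_one(self):
        assert lifetime_risk(200.0, 0.01) == 1.0

    @pytest.mark.parametrize("prevalence", [0.0, -0.1, 1.0, 2.0])
    def test_invalid_prevalence_rejected(self, prevalence):
        with pytest.raises(ValidationError):
            lifetime_risk(1.5, prevalence)


class TestGenotypeParsing:
    def test_copy_number_counts_risk_allele(self):
        marker = make_marker(allele="A")
        assert copy_number(marker, "AA") == 2
        assert copy_number(marker, "AG") == 1
        assert copy_number(marker, "GG") == 0

    def test_unknown_allele_names_the_marker(self):
        with pytest.raises(ValidationError, match="rsX"):
            copy_number(make_marker(), "AZ")

    def test_malformed_genotype_rejected(self):
        with pytest.raises(ValidationError):
            copy_number(make_marker(), "AGG")


class TestPredict:
    def test_result_is_internally_consistent(self, five_marker_panel):
        genotype = {"rs1": 1, "rs2": 2, "rs3": 0, "rs5": 1}  # rs4 untyped
        result = predict(five_marker_panel, genotype, prevalence=0.01)
        assert result.n_markers_used == 4
        assert result.overall_rgr == pytest.approx(
            math.prod(result.per_marker_rgr.values())
        )
        assert result.lifetime_risk == pytest.approx(
            min(result.overall_rgr * 0.01, 1.0)
        )

    def test_prunes_linked_markers(self):
        markers = [
            make_marker("rsA", r=2.0, locus="L1", p_value=1e-12),
            make_marker("rsB", r=3.0, locus="L1", p_value=1e-6),
        ]
        result = predict(markers, {"rsA": 1, "rsB": 1}, prevalence=0.01)
        assert set(result.per_marker_rgr) == {"rsA"}
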