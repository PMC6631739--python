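"""Unit and property tests for the closed-form metric layer."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from stillmetrics import (
    BirthCounts,
    DomainError,
    InconsistencyError,
    adjusted_expectancy,
    compute_nmr,
    compute_sale,
    compute_slbr,
    compute_stbr,
    growth_decomposition,
    le_decrement,
    live_births_from_nmr,
    pct_change,
    rate_gap,
    ratio_slbr_nmr,
    ratio_stbr_nmr,
    slbr_to_stbr,
    stbr_to_slbr,
    stillbirth_yll,
    yll_in_units,
)

RATES = st.floats(min_value=0.0, max_value=500.0, allow_nan=False)
COUNTS = st.floats(min_value=0.0, max_value=1e8)
POSITIVE_COUNTS = st.floats(min_value=1.0, max_value=1e8)


# ---------------------------------------------------------------------------
# Rate definitions
# ---------------------------------------------------------------------------

class TestRateDefinitions:
    @pytest.mark.parametrize(
        "sb, lb, expected",
        [
            (0, 500, 0.0),
            (13, 1000, 13.0),
            # highest-rate country in the reference tables
            (45_090, 1_000_000, 45.09),
        ],
    )
    def test_slbr_definition(self, sb, lb, expected):
        counts = BirthCounts(stillbirths=sb, live_births=lb, neonatal_deaths=0)
        assert compute_slbr(counts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "sb, lb, expected",
        [
            (0, 500, 0.0),
            (700, 700, 500.0),          # SB = LB gives exactly half
            (45_090, 1_000_000, 1000 * 45_090 / 1_045_090),
        ],
    )
    def test_stbr_definition(self, sb, lb, expected):
        counts = BirthCounts(stillbirths=sb, live_births=lb, neonatal_deaths=0)
        assert compute_stbr(counts) == pytest.approx(expected)

    def test_stbr_matches_printed_pakistan_value(self):
        counts = BirthCounts(stillbirths=45_090, live_births=1_000_000,
                             neonatal_deaths=0)
        assert compute_stbr(counts) == pytest.approx(43.145, abs=5e-4)

    @pytest.mark.parametrize("nm, lb, expected", [(0, 100, 0.0), (30, 1000, 30.0)])
    def test_nmr_definition(self, nm, lb, expected):
        counts = BirthCounts(stillbirths=0, live_births=lb, neonatal_deaths=nm)
        assert compute_nmr(counts) == pytest.approx(expected)

    def test_equal_counts_force_ratio_100(self):
        counts = BirthCounts(stillbirths=45_090, live_births=1_000_000,
                             neonatal_deaths=45_090)
        assert compute_nmr(counts) == pytest.approx(45.09)
        ratio = ratio_slbr_nmr(compute_slbr(counts), compute_nmr(counts))
        assert 100 * ratio == pytest.approx(100.0)

    def test_zero_live_births_is_a_domain_error(self):
        counts = BirthCounts(stillbirths=5, live_births=0, neonatal_deaths=0)
        with pytest.raises(DomainError):
            compute_slbr(counts)
        with pytest.raises(DomainError):
            compute_nmr(counts)

    def test_zero_total_births_is_a_domain_error(self):
        counts = BirthCounts(stillbirths=0, live_births=0, neonatal_deaths=0)
        with pytest.raises(DomainError):
            compute_stbr(counts)

    def test_counts_validation(self):
        with pytest.raises(DomainError):
            BirthCounts(stillbirths=-1, live_births=10, neonatal_deaths=0)
        with pytest.raises(InconsistencyError):
            BirthCounts(stillbirths=0, live_births=10, neonatal_deaths=11)

    def test_total_births_is_derived(self):
        counts = BirthCounts(stillbirths=3, live_births=7, neonatal_deaths=1)
        assert counts.total_births == 10


# ---------------------------------------------------------------------------
# Interconversion and the gap identity
# ---------------------------------------------------------------------------

class TestConversion:
    @pytest.mark.parametrize(
        "slbr, expected_stbr",
        [
            (0.0, 0.0),
            (45.09, 1000 * 45.09 / 1045.09),   # ~43.14, printed 43.15
            (41.58, 1000 * 41.58 / 1041.58),   # rounds to Chad's 39.92
        ],
    )
    def test_slbr_to_stbr(self, slbr, expected_stbr):
        assert slbr_to_stbr(slbr) == pytest.approx(expected_stbr)

    def test_chad_conversion_rounds_to_printed_value(self):
        assert round(slbr_to_stbr(41.58), 2) == 39.92

    @pytest.mark.parametrize(
        "stbr, expected_slbr",
        [(0.0, 0.0), (43.15, 1000 * 43.15 / 956.85)],
    )
    def test_stbr_to_slbr(self, stbr, expected_slbr):
        assert stbr_to_slbr(stbr) == pytest.approx(expected_slbr)

    def test_stbr_to_slbr_recovers_printed_slbr(self):
        # converting the printed total-birth rate back lands on the
        # printed live-birth rate within rounding of the inputs
        assert stbr_to_slbr(43.15) == pytest.approx(45.09, abs=0.01)

    @pytest.mark.parametrize("bad", [-1.0, float("nan")])
    def test_conversion_domain_errors(self, bad):
        with pytest.raises(DomainError):
            slbr_to_stbr(bad)
        with pytest.raises(DomainError):
            stbr_to_slbr(bad)

    def test_stbr_at_or_above_1000_rejected(self):
        with pytest.raises(DomainError):
            stbr_to_slbr(1000.0)

    @given(RATES)
    def test_round_trip_is_identity(self, slbr):
        assert stbr_to_slbr(slbr_to_stbr(slbr)) == pytest.approx(
            slbr, rel=1e-9, abs=1e-9
        )

    @given(st.floats(min_value=0.0, max_value=1e6), POSITIVE_COUNTS)
    def test_gap_identity_from_counts(self, sb, lb):
        """SLBR - STBR == SLBR * STBR / 1000 exactly, for any counts."""
        counts = BirthCounts(stillbirths=sb, live_births=lb, neonatal_deaths=0)
        slbr, stbr = compute_slbr(counts), compute_stbr(counts)
        assert slbr - stbr == pytest.approx(slbr * stbr / 1000.0,
                                            rel=1e-9, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=1e6), POSITIVE_COUNTS,
           st.floats(min_value=0.0, max_value=1e6), POSITIVE_COUNTS)
    def test_both_rates_rank_countries_identically(self, sb1, lb1, sb2, lb2):
        c1 = BirthCounts(stillbirths=sb1, live_births=lb1, neonatal_deaths=0)
        c2 = BirthCounts(stillbirths=sb2, live_births=lb2, neonatal_deaths=0)
        d_slbr = compute_slbr(c1) - compute_slbr(c2)
        d_stbr = compute_stbr(c1) - compute_stbr(c2)
        if abs(d_slbr) > 1e-9:
            assert math.copysign(1, d_slbr) == math.copysign(1, d_stbr)

    def test_rate_gap_reference_rows(self):
        # the two largest-gap countries in the reference table
        assert rate_gap(45.09, 43.15) == pytest.approx(1.94)
        assert rate_gap(38.10, 36.70) == pytest.approx(1.40)
        assert rate_gap(0.0, 0.0) == 0.0

    def test_rate_gap_rejects_inconsistent_pair(self):
        with pytest.raises(InconsistencyError):
            rate_gap(10.0, 20.0)


# ---------------------------------------------------------------------------
# Live births from NMR; the stillbirth:NMR ratios
# ---------------------------------------------------------------------------

class TestLiveBirthDerivation:
    @pytest.mark.parametrize(
        "nm, nmr, expected",
        [(0, 5.0, 0.0), (50, 25.0, 2000.0), (1000, 7.5, 1000 * 1000 / 7.5)],
    )
    def test_back_derivation(self, nm, nmr, expected):
        assert live_births_from_nmr(nm, nmr) == pytest.approx(expected)

    def test_zero_rate_with_deaths_is_inconsistent(self):
        with pytest.raises(InconsistencyError):
            live_births_from_nmr(10, 0.0)

    def test_zero_rate_zero_deaths_is_indeterminate(self):
        with pytest.raises(DomainError, match="supply live_births"):
            live_births_from_nmr(0, 0.0)


class TestRatios:
    def test_equal_rates_give_unit_ratio(self):
        assert ratio_slbr_nmr(12.0, 12.0) == pytest.approx(1.0)

    def test_world_2015_display_value(self):
        # ratio x100 as printed for the 2015 world row
        nmr = 18.73 / 0.977
        assert 100 * ratio_slbr_nmr(18.73, nmr) == pytest.approx(97.7)

    def test_equal_counts_cancel_live_births(self):
        for lb in (1e3, 1e6):
            counts = BirthCounts(stillbirths=500, live_births=lb,
                                 neonatal_deaths=500)
            r = ratio_slbr_nmr(compute_slbr(counts), compute_nmr(counts))
            assert r == pytest.approx(1.0)

    def test_stbr_ratio_zero_when_no_stillbirths(self):
        assert ratio_stbr_nmr(0.0, 20.0) == 0.0

    def test_stbr_ratio_shrinks_by_live_birth_share(self):
        # SB = NM with LB = TB/2 gives exactly 0.5
        counts = BirthCounts(stillbirths=1000, live_births=1000,
                             neonatal_deaths=1000)
        stbr, nmr = compute_stbr(counts), compute_nmr(counts)
        assert ratio_stbr_nmr(stbr, nmr, lb_share=0.5) == pytest.approx(0.5)

    @given(st.floats(min_value=0.0, max_value=1e6), POSITIVE_COUNTS,
           st.floats(min_value=1.0, max_value=1e6))
    def test_stbr_ratio_identity_and_bound(self, sb, lb, nm):
        """STBR:NMR == SLBR:NMR x LB/TB, hence never larger."""
        nm = min(nm, lb)
        counts = BirthCounts(stillbirths=sb, live_births=lb,
                             neonatal_deaths=nm)
        slbr_nmr = ratio_slbr_nmr(compute_slbr(counts), compute_nmr(counts))
        stbr_nmr = ratio_stbr_nmr(compute_stbr(counts), compute_nmr(counts))
        lb_share = lb / counts.total_births
        assert stbr_nmr == pytest.approx(slbr_nmr * lb_share, rel=1e-9)
        assert stbr_nmr <= slbr_nmr + 1e-12

    def test_zero_nmr_rejected(self):
        with pytest.raises(DomainError):
            ratio_slbr_nmr(10.0, 0.0)
        with pytest.raises(DomainError):
            ratio_stbr_nmr(10.0, 0.0)

    def test_bad_lb_share_rejected(self):
        with pytest.raises(DomainError):
            ratio_stbr_nmr(10.0, 20.0, lb_share=1.5)


# ---------------------------------------------------------------------------
# SALE, decrement, YLL
# ---------------------------------------------------------------------------

class TestAdjustedExpectancy:
    def test_no_stillbirths_leaves_le_unchanged(self):
        assert compute_sale(71.0, 0.0) == 71.0
        assert le_decrement(71.0, 0.0) == 0.0

    def test_worked_example(self):
        # 71 years of LE with 13 stillbirths per 1000 live births:
        # 71000 person-years spread over 1013 total births ~ 70 years
        sale = compute_sale(71.0, 13.0)
        assert sale == pytest.approx(71000 / 1013)
        assert round(sale) == 70

    @pytest.mark.parametrize(
        "le, slbr, sale_2dp, dec_2dp",
        [
            (66.38, 45.09, 63.52, 2.86),   # Pakistan
            (53.05, 44.81, 50.77, 2.28),   # Nigeria
            (51.87, 41.58, 49.80, 2.07),   # Chad
        ],
    )
    def test_reference_country_rows(self, le, slbr, sale_2dp, dec_2dp):
        assert round(compute_sale(le, slbr), 2) == sale_2dp
        assert round(le_decrement(le, slbr), 2) == dec_2dp

    @given(st.floats(min_value=1.0, max_value=120.0), RATES)
    def test_sale_bounds_and_decrement_consistency(self, le, slbr):
        sale = compute_sale(le, slbr)
        assert 0 < sale <= le
        assert le - sale == pytest.approx(le_decrement(le, slbr),
                                          rel=1e-9, abs=1e-12)

    def test_decrement_consistency_on_grid(self):
        """le - SALE == decrement formula over a dense (le, slbr) grid."""
        for le10 in range(400, 901, 25):
            for slbr10 in range(0, 601, 20):
                le, slbr = le10 / 10.0, slbr10 / 10.0
                assert le - compute_sale(le, slbr) == pytest.approx(
                    le_decrement(le, slbr), rel=1e-9, abs=1e-12
                )

    def test_sale_monotone_decreasing_in_slbr(self):
        values = [compute_sale(70.0, s) for s in (0, 5, 13, 30, 60)]
        assert values == sorted(values, reverse=True)

    def test_decrement_monotone_in_both_arguments(self):
        assert le_decrement(70.0, 20.0) > le_decrement(70.0, 10.0)
        assert le_decrement(80.0, 20.0) > le_decrement(70.0, 20.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            compute_sale(-1.0, 10.0)
        with pytest.raises(DomainError):
            le_decrement(70.0, -1.0)


class TestYLL:
    def test_zero_decrement_means_zero_loss(self):
        assert stillbirth_yll(70.0, 70.0, 1e6) == 0.0

    def test_unit_check(self):
        # one year lost per live birth over a 100,000-birth cohort
        yll = stillbirth_yll(71.0, 70.0, 100_000)
        assert yll == pytest.approx(100_000)
        assert yll_in_units(yll, "1e5") == pytest.approx(1.0)

    def test_reference_magnitude(self):
        # decrement 2.86 years over ~5.33M live births ~ 15.24M person-years
        lb = 152.4e5 / 2.86
        assert lb == pytest.approx(5.33e6, rel=1e-2)
        yll = stillbirth_yll(66.38, 66.38 - 2.86, lb)
        assert yll_in_units(yll, "1e5") == pytest.approx(152.4)
        assert yll_in_units(yll, "1e6") == pytest.approx(15.24)

    def test_sale_above_le_rejected(self):
        with pytest.raises(InconsistencyError):
            stillbirth_yll(70.0, 71.0, 1000)

    def test_unknown_unit_rejected(self):
        with pytest.raises(DomainError):
            yll_in_units(1.0, "fortnights")

    def test_bundle_consistency(self):
        adj = adjusted_expectancy(66.38, 45.09, 5.33e6)
        assert adj.decrement == pytest.approx(adj.le - adj.sale)
        assert adj.yll == pytest.approx(adj.decrement * 5.33e6)


# ---------------------------------------------------------------------------
# Growth decomposition and percentage change
# ---------------------------------------------------------------------------

class TestGrowth:
    def test_no_change_gives_all_zero(self):
        g = growth_decomposition(10.0, 10.0, 0.8, 0.8)
        assert g.g_slbr == g.g_ratio == g.g_nmr_additive == g.g_nmr_exact == 0.0

    def test_richer_group_slbr_decline(self):
        g = growth_decomposition(11.33, 7.40, 75.1, 101.5)
        assert 100 * abs(g.g_slbr) == pytest.approx(34.7, abs=0.05)

    def test_additive_and_exact_variants_differ_at_large_changes(self):
        g = growth_decomposition(11.33, 7.40, 75.1, 101.5)
        assert g.g_nmr_additive == pytest.approx(g.g_slbr - g.g_ratio)
        assert g.g_nmr_exact == pytest.approx(
            (1 + g.g_slbr) / (1 + g.g_ratio) - 1
        )
        # simple-percentage arithmetic overstates the NMR decline
        assert g.g_nmr_exact == pytest.approx(-0.517, abs=0.005)
        assert abs(g.g_nmr_additive - g.g_nmr_exact) > 0.1

    @given(st.floats(min_value=-0.01, max_value=0.01),
           st.floats(min_value=-0.01, max_value=0.01))
    def test_variants_agree_to_first_order(self, gv, gw):
        g = growth_decomposition(10.0, 10.0 * (1 + gv), 1.0, 1.0 + gw)
        assert abs(g.g_nmr_additive - g.g_nmr_exact) < 5e-4

    @given(st.floats(min_value=0.1, max_value=100),
           st.floats(min_value=0.1, max_value=100),
           st.floats(min_value=0.1, max_value=100),
           st.floats(min_value=0.1, max_value=100))
    def test_log_growth_rates_decompose_exactly(self, v0, v1, w0, w1):
        """log(ratio growth) == log(SLBR growth) - log(NMR growth) exactly
        on any consistent (SLBR, ratio, NMR = SLBR/ratio) triple."""
        n0, n1 = v0 / w0, v1 / w1
        lhs = math.log(w1 / w0)
        rhs = math.log(v1 / v0) - math.log(n1 / n0)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_zero_baseline_rejected(self):
        with pytest.raises(DomainError):
            growth_decomposition(0.0, 1.0, 1.0, 1.0)


class TestPctChange:
    @pytest.mark.parametrize(
        "old, new, magnitude, expected_1dp",
        [
            (10.0, 10.0, False, 0.0),
            (33.97, 25.28, True, 25.6),    # poorer-group rate reduction
            (11.33, 7.40, True, 34.7),     # richer-group rate reduction
            (84.9, 97.0, False, 14.3),     # poorer-group ratio increase
        ],
    )
    def test_reference_percentages(self, old, new, magnitude, expected_1dp):
        assert round(pct_change(old, new, magnitude_only=magnitude), 1) \
            == expected_1dp

    def test_sign_is_kept_unless_magnitude_requested(self):
        assert pct_change(20.0, 10.0) == -50.0
        assert pct_change(20.0, 10.0, magnitude_only=True) == 50.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(DomainError):
            pct_change(0.0, 5.0)
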