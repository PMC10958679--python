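"""Dose categorisation, LAR cubics and lifetime effective risk."""

import numpy as np
import pytest

from mammodose.dosimetry import DoseProfile
from mammodose.risk import (
    DEFAULT_BOUNDARIES,
    CategoryMGDTable,
    DoseCategoryBoundaries,
    ScreeningRegimen,
    assign_category,
    build_regimen,
    build_risk_report,
    compute_category_medians,
    compute_tertile_boundaries,
    effective_risk,
    lifetime_effective_risk,
    risk_to_percent,
)


class TestAssignCategory:
    @pytest.mark.parametrize(
        "msr, expected",
        [
            (2.158, "low"),      # worked example
            (3.413, "medium"),   # boundary belongs to the upper band
            (4.346, "high"),
            (4.345, "medium"),
            (10.0, "high"),
        ],
    )
    def test_half_open_bands(self, msr, expected):
        assert assign_category(msr, DEFAULT_BOUNDARIES) == expected

    def test_nonpositive_msr_rejected(self):
        with pytest.raises(ValueError):
            assign_category(0.0)

    def test_default_boundaries_are_the_cohort_tertiles(self):
        assert DEFAULT_BOUNDARIES.low_upper_mGy == 3.413
        assert DEFAULT_BOUNDARIES.medium_upper_mGy == 4.346


class TestTertileBoundaries:
    def test_hand_computed_tertiles(self):
        b = compute_tertile_boundaries([1, 1, 1, 2, 2, 2, 3, 3, 3])
        assert b.low_upper_mGy == pytest.approx(5 / 3)
        assert b.medium_upper_mGy == pytest.approx(7 / 3)

    def test_identical_values_are_degenerate(self):
        with pytest.raises(ValueError):
            compute_tertile_boundaries([2.0] * 10)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compute_tertile_boundaries([1.0, 2.0])

    def test_tertiles_split_a_cohort_into_thirds(self):
        rng = np.random.default_rng(3)
        msr = rng.lognormal(np.log(3.7), 0.25, size=3000)
        b = compute_tertile_boundaries(msr)
        cats = [assign_category(v, b) for v in msr]
        for cat in ("low", "medium", "high"):
            assert cats.count(cat) == pytest.approx(1000, abs=2)


class TestCategoryMedians:
    def _profile(self, base, category):
        return DoseProfile(tuple(base + 0.01 * i for i in range(36)), category=category)

    def test_single_profile_per_category_is_identity(self):
        profiles = [self._profile(b, c) for b, c in ((2.5, "low"), (3.8, "medium"), (4.9, "high"))]
        table = compute_category_medians(profiles)
        for profile in profiles:
            for age in range(40, 76):
                assert table.mgd(profile.category, age) == pytest.approx(profile.dose_at(age))

    def test_median_is_idempotent_over_duplicates(self):
        p = self._profile(3.0, "medium")
        single = compute_category_medians(
            [p, self._profile(2.0, "low"), self._profile(5.0, "high")]
        )
        doubled = compute_category_medians(
            [p, p, self._profile(2.0, "low"), self._profile(5.0, "high")]
        )
        assert single.per_category["medium"] == doubled.per_category["medium"]

    def test_empty_category_named_in_error(self):
        with pytest.raises(ValueError, match="high"):
            compute_category_medians(
                [self._profile(2.0, "low"), self._profile(3.8, "medium")]
            )

    def test_published_table_is_ordered_at_every_age(self, category_table):
        for age in range(40, 76):
            low = category_table.mgd("low", age)
            med = category_table.mgd("medium", age)
            high = category_table.mgd("high", age)
            assert low < med < high


class TestLar:
    def test_anchor_values(self, lar_model):
        assert lar_model.lar(40, "incidence", 1.5) == pytest.approx(1.4095714286, abs=1e-6)
        assert lar_model.lar(60, "incidence", 1.5) == pytest.approx(0.3074285714, abs=1e-6)

    def test_ddref_scaling_identity(self, lar_model):
        for endpoint in ("incidence", "mortality"):
            for age in range(40, 81, 5):
                base = lar_model.lar(age, endpoint, 1.5)
                # the scaling is exact up to the tables' printed precision
                assert lar_model.lar(age, endpoint, 1.0) == pytest.approx(1.5 * base, rel=1e-6)
                assert lar_model.lar(age, endpoint, 2.0) == pytest.approx(0.75 * base, rel=1e-6)

    def test_positive_and_strictly_decreasing_over_age(self, lar_model):
        for endpoint in ("incidence", "mortality"):
            values = [lar_model.lar(a, endpoint, 1.5) for a in range(40, 81)]
            assert all(v > 0 for v in values)
            assert all(a > b for a, b in zip(values, values[1:]))

    def test_unsupported_ddref_and_age_rejected(self, lar_model):
        with pytest.raises(ValueError):
            lar_model.lar(50, "incidence", 1.2)
        with pytest.raises(ValueError):
            lar_model.lar(39, "incidence", 1.5)
        with pytest.raises(ValueError):
            lar_model.lar(81, "incidence", 1.5)


class TestEffectiveRisk:
    def test_published_per_visit_cell(self, category_table, lar_model):
        value = effective_risk(category_table.mgd("low", 50), lar_model.lar(50, "incidence", 1.0))
        assert value == pytest.approx(2.956, abs=0.001)

    def test_zero_dose_and_unit_dose(self, lar_model):
        lar = lar_model.lar(55, "mortality", 2.0)
        assert effective_risk(0.0, lar) == 0.0
        assert effective_risk(1.0, lar) == lar

    def test_sample_of_published_per_visit_table(self, category_table, lar_model):
        # frozen printed per-visit risk values (category x age x DDREF)
        printed = [
            ("low", 40, "incidence", 1.0, 5.170),
            ("medium", 50, "incidence", 2.0, 2.032),
            ("high", 60, "incidence", 1.5, 1.548),
            ("low", 74, "mortality", 1.0, 0.150),
            ("high", 75, "mortality", 2.0, 0.121),
            ("medium", 65, "mortality", 1.5, 0.263),
        ]
        for cat, age, endpoint, ddref, expected in printed:
            value = effective_risk(
                category_table.mgd(cat, age), lar_model.lar(age, endpoint, ddref)
            )
            assert value == pytest.approx(expected, abs=0.001), (cat, age, endpoint, ddref)


class TestRegimens:
    @pytest.mark.parametrize(
        "preset, n_visits",
        [("australia_full", 23), ("australia_biennial", 13), ("uk", 7), ("usa", 21)],
    )
    def test_preset_visit_counts(self, preset, n_visits):
        assert build_regimen(preset).n_visits == n_visits

    def test_interval_regimen_matches_worked_example(self):
        regimen = build_regimen(start_age=56, end_age=74, interval_years=2)
        assert regimen.visit_ages == (56, 58, 60, 62, 64, 66, 68, 70, 72, 74)

    def test_uk_preset_is_seven_triennial_visits_from_50(self):
        assert build_regimen("uk").visit_ages == (50, 53, 56, 59, 62, 65, 68)

    def test_out_of_range_and_empty_rejected(self):
        with pytest.raises(ValueError):
            build_regimen([38, 40])
        with pytest.raises(ValueError):
            ScreeningRegimen("empty", ())
        with pytest.raises(ValueError):
            build_regimen("sweden")


class TestLifetimeEffectiveRisk:
    def test_single_visit_regimen_equals_per_visit_cell(self, category_table, lar_model):
        regimen = build_regimen([50])
        value = lifetime_effective_risk("low", regimen, "incidence", 1.0, category_table, lar_model)
        assert value == pytest.approx(2.956, abs=0.001)

    def test_ddref_ratios_are_exact(self, category_table, lar_model):
        regimen = build_regimen("australia_biennial")
        for cat in ("low", "medium", "high"):
            for endpoint in ("incidence", "mortality"):
                l1 = lifetime_effective_risk(cat, regimen, endpoint, 1.0, category_table, lar_model)
                l15 = lifetime_effective_risk(cat, regimen, endpoint, 1.5, category_table, lar_model)
                l2 = lifetime_effective_risk(cat, regimen, endpoint, 2.0, category_table, lar_model)
                assert l1 > l15 > l2
                assert l15 == pytest.approx(l1 * 2 / 3, rel=1e-9)
                assert l2 == pytest.approx(l1 / 2, rel=1e-9)

    def test_category_monotonicity(self, category_table, lar_model):
        regimen = build_regimen("usa")
        values = [
            lifetime_effective_risk(c, regimen, "incidence", 1.5, category_table, lar_model)
            for c in ("low", "medium", "high")
        ]
        assert values[0] < values[1] < values[2]

    def test_adding_a_visit_strictly_increases_ler(self, category_table, lar_model):
        base = build_regimen([50, 52, 54])
        extended = build_regimen([50, 52, 54, 56])
        for endpoint in ("incidence", "mortality"):
            assert lifetime_effective_risk(
                "low", extended, endpoint, 2.0, category_table, lar_model
            ) > lifetime_effective_risk("low", base, endpoint, 2.0, category_table, lar_model)

    def test_report_sums_and_percent_presentation(self, category_table, lar_model):
        regimen = build_regimen("australia_biennial")
        report = build_risk_report("low", regimen, 2.0, category_table, lar_model)
        assert report.ler_incidence == pytest.approx(
            sum(v.risk_incidence for v in report.per_visit)
        )
        assert report.percent_incidence == pytest.approx(report.ler_incidence / 1000)

    def test_risk_to_percent(self):
        assert risk_to_percent(8.64) == pytest.approx(0.00864)
        assert risk_to_percent(0) == 0.0
        assert risk_to_percent(100000) == 100.0
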