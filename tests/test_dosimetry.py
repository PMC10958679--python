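"""Air kerma, conversion factors, per-visit aggregation and dose profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammodose.curves import eval_curve
from mammodose.dosimetry import (
    DoseProfile,
    FactorDomainError,
    QAParameters,
    aggregate_visit_dose,
    compute_mgd,
    estimate_hvl,
    incident_air_kerma,
    interpolate_factors,
    predict_lifetime_doses,
)
from mammodose.exposure import build_exposure_plan


@pytest.fixture(scope="module")
def simple_qa():
    return QAParameters(
        tube_output_coeff=0.05, kvp_exponent=3.0, sid_mm=700.0, isd_mm=25.0,
        hvl_model={"W/Rh": (0.2, 0.01)},
    )


class TestIncidentAirKerma:
    def test_hand_computed_value(self, simple_qa):
        # 100 * 0.05 * 28^3 / (700-25-50)^2 = 109760/390625
        k = incident_air_kerma(100, 28, simple_qa, 50)
        assert k == pytest.approx(109760 / 390625)

    def test_zero_mas_gives_zero(self, simple_qa):
        assert incident_air_kerma(0, 28, simple_qa, 50) == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(mas=st.floats(1, 500), kvp=st.floats(24, 36), cbt=st.floats(20, 110))
    def test_linearity_in_mas(self, simple_qa, mas, kvp, cbt):
        k1 = incident_air_kerma(mas, kvp, simple_qa, cbt)
        k2 = incident_air_kerma(2 * mas, kvp, simple_qa, cbt)
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_nonpositive_focus_skin_distance_rejected(self, simple_qa):
        with pytest.raises(ValueError, match="focus-to-skin"):
            incident_air_kerma(100, 28, simple_qa, 700)


class TestHvl:
    def test_linear_model(self, simple_qa):
        assert estimate_hvl(28, "W/Rh", simple_qa) == pytest.approx(0.48)

    def test_zero_slope_is_constant(self):
        qa = QAParameters(0.05, 3.0, 700.0, 25.0, {"W/Rh": (0.42, 0.0)})
        assert estimate_hvl(25, "W/Rh", qa) == estimate_hvl(37, "W/Rh", qa) == 0.42

    def test_missing_target_filter_is_configuration_error(self, simple_qa):
        with pytest.raises(ValueError, match="W/Ag"):
            estimate_hvl(30, "W/Ag", simple_qa)


class TestFactorInterpolation:
    def test_grid_node_is_exact(self, factor_tables):
        hvl = factor_tables.g_axes[0][1]
        cbt = factor_tables.g_axes[1][2]
        assert factor_tables.g(hvl, cbt) == pytest.approx(factor_tables.g_values[1, 2])

    def test_midpoint_is_arithmetic_mean(self, factor_tables):
        h = factor_tables.g_axes[0]
        cbt = factor_tables.g_axes[1][0]
        mid = factor_tables.g((h[0] + h[1]) / 2, cbt)
        assert mid == pytest.approx((factor_tables.g_values[0, 0] + factor_tables.g_values[1, 0]) / 2)

    def test_unit_tables_give_unity(self, unit_factor_tables):
        g, c, s = interpolate_factors(unit_factor_tables, 0.5, 60.0, 30.0, "W/Rh")
        assert (g, c, s) == (1.0, 1.0, 1.0)

    def test_out_of_grid_query_refused(self, factor_tables):
        with pytest.raises(FactorDomainError):
            factor_tables.g(10.0, 60.0)
        with pytest.raises(FactorDomainError):
            factor_tables.c(0.5, 60.0, 150.0)
        with pytest.raises(FactorDomainError):
            factor_tables.s("Mo/Mo")


class TestComputeMgd:
    def test_identity_and_product(self):
        assert compute_mgd(1, 1, 1, 1) == 1.0
        assert compute_mgd(0.281, 0.4, 1.1, 1.0) == pytest.approx(0.123640)

    def test_scaling_in_kerma(self):
        base = compute_mgd(0.3, 0.4, 1.05, 1.0)
        assert compute_mgd(0.6, 0.4, 1.05, 1.0) == pytest.approx(2 * base)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_mgd(0.0, 0.4, 1.0, 1.0)


class TestAggregateVisitDose:
    def test_bilateral_mean_of_per_breast_sums(self):
        assert aggregate_visit_dose({"L": [1.0, 1.2], "R": [1.1, 1.3]}) == pytest.approx(2.3)

    def test_single_laterality_sum_not_averaged(self):
        # post-mastectomy: the one breast's summed dose is reported as-is
        assert aggregate_visit_dose({"L": [1.0, 1.2]}) == pytest.approx(2.2)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(x=st.floats(0.01, 10))
    def test_symmetric_breasts_give_per_breast_dose(self, x):
        assert aggregate_visit_dose({"L": [x], "R": [x]}) == pytest.approx(x)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_visit_dose({})


class TestLifetimeDoses:
    def _plan(self, published, **kwargs):
        params = dict(age=56, mbd_pct=26.68, cbt_mm=40.75, mas=88.8)
        params.update(kwargs)
        return build_exposure_plan(
            mbd_family=published.mbd_family, cbt_family=published.cbt_family,
            mas_family=published.mas_family, lookup=published.kvp_tf_lookup, **params
        )

    def test_profile_has_36_positive_doses_and_median_msr(self, published, qa, factor_tables):
        profile = predict_lifetime_doses(self._plan(published), qa, factor_tables)
        assert len(profile.per_age_mgd) == 36
        assert all(d > 0 for d in profile.per_age_mgd)
        assert profile.mgd_msr == pytest.approx(float(np.median(profile.per_age_mgd)))

    def test_single_age_hand_oracle(self, published, qa, factor_tables):
        """The pipeline's age-56 entry equals the hand-chained formulas."""
        plan = self._plan(published)
        entry = plan[56]
        hvl = estimate_hvl(entry.kvp, entry.target_filter, qa)
        k = incident_air_kerma(entry.mas, entry.kvp, qa, entry.cbt_mm)
        g, c, s = interpolate_factors(
            factor_tables, hvl, entry.cbt_mm, entry.mbd_pct, entry.target_filter
        )
        per_image = compute_mgd(k, g, c, s)
        visit = aggregate_visit_dose({"L": [per_image] * 2, "R": [per_image] * 2})
        profile = predict_lifetime_doses(plan, qa, factor_tables)
        assert profile.dose_at(56) == pytest.approx(visit, rel=1e-12)

    def test_mgd_linear_in_mas(self, published, qa, factor_tables):
        import dataclasses

        plan = self._plan(published)
        scaled = dataclasses.replace(
            plan,
            entries=tuple(dataclasses.replace(e, mas=2 * e.mas) for e in plan.entries),
        )
        p1 = predict_lifetime_doses(plan, qa, factor_tables)
        p2 = predict_lifetime_doses(scaled, qa, factor_tables)
        assert np.allclose(np.array(p2.per_age_mgd), 2 * np.array(p1.per_age_mgd))

    def test_two_projections_double_single_projection(self, published, qa, factor_tables):
        plan = self._plan(published)
        p1 = predict_lifetime_doses(plan, qa, factor_tables, projections_per_breast=1)
        p2 = predict_lifetime_doses(plan, qa, factor_tables, projections_per_breast=2)
        assert np.allclose(2 * np.array(p1.per_age_mgd), np.array(p2.per_age_mgd))

    def test_domain_error_names_the_age(self, published, qa, unit_factor_tables):
        import dataclasses

        plan = self._plan(published)
        bad = dataclasses.replace(
            plan,
            entries=(dataclasses.replace(plan.entries[0], mbd_pct=150.0),)
            + plan.entries[1:],
        )
        with pytest.raises(ValueError, match="age 40"):
            predict_lifetime_doses(bad, qa, unit_factor_tables)


class TestDoseProfile:
    def test_requires_36_positive_values(self):
        with pytest.raises(ValueError):
            DoseProfile((1.0,) * 35)
        with pytest.raises(ValueError):
            DoseProfile((1.0,) * 35 + (-0.1,))

    def test_even_length_median_is_mean_of_central_pair(self):
        values = tuple(float(i) for i in range(1, 37))
        assert DoseProfile(values).mgd_msr == pytest.approx((18 + 19) / 2)
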