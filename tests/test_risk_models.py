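"""Unit and property tests for the injury-risk function family."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from thoriarv import risk_models as rm


class TestWeibull:
    def test_zero_metric_gives_zero_risk(self):
        assert rm.HIC_RISK_MODEL.risk(0.0) == 0.0

    def test_risk_at_scale_is_one_minus_inv_e(self):
        assert rm.HIC_RISK_MODEL.risk(671.0) == pytest.approx(1 - math.exp(-1))

    def test_hic_risk_near_five_percent_at_published_nominal_limit(self):
        assert rm.HIC_RISK_MODEL.risk(340.0) == pytest.approx(0.0507, abs=5e-4)

    @pytest.mark.parametrize("p, expected", [(0.05, 338.455), (0.19, 468.700)])
    def test_hic_iarv_inversions(self, p, expected):
        assert rm.HIC_RISK_MODEL.iarv(p) == pytest.approx(expected, abs=5e-3)

    def test_iarv_limit_to_zero(self):
        assert rm.HIC_RISK_MODEL.iarv(1e-300) == pytest.approx(0.0, abs=1e-9)
        # and monotonically shrinks as p -> 0
        assert (rm.HIC_RISK_MODEL.iarv(1e-9) < rm.HIC_RISK_MODEL.iarv(1e-6)
                < rm.HIC_RISK_MODEL.iarv(1e-3))

    def test_missing_scale_raises(self):
        with pytest.raises(rm.MissingParameterError):
            rm.BRIC_RISK_MODEL.risk(0.5, level=1)
        with pytest.raises(rm.MissingParameterError):
            rm.BRIC_RISK_MODEL.iarv(0.05, level=1)

    def test_invalid_probability_raises(self):
        for p in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                rm.HIC_RISK_MODEL.iarv(p)


class TestOrderedProbit:
    def test_midpoint_risk_is_half(self):
        model = rm.NECK_TENSION_MODEL
        x = model.cut_points[1] / model.slope
        assert model.risk(x, 1) == pytest.approx(0.5)

    def test_neck_tension_nominal_probability(self):
        assert rm.NECK_TENSION_MODEL.risk(880.0, 1) == pytest.approx(0.050, abs=1e-3)

    def test_chest_risk_at_zero_deflection_is_tiny(self):
        assert rm.CHEST_DEFLECTION_MODEL.risk(0.0, 1) == pytest.approx(
            1 - norm.cdf(4.17), rel=1e-12)

    @pytest.mark.parametrize("model, p, level, expected", [
        (rm.NECK_TENSION_MODEL, 0.05, 1, 878.33),
        (rm.CHEST_DEFLECTION_MODEL, 0.19, 1, 31.96),
        (rm.ANKLE_INVERSION_EVERSION_MODEL, 0.01, 2, 16.74),
    ])
    def test_iarv_inversions(self, model, p, level, expected):
        assert model.iarv(p, level) == pytest.approx(expected, abs=5e-2)

    def test_severity_levels_are_ordered(self):
        for x in np.linspace(0.0, 3000.0, 50):
            risks = [rm.NECK_TENSION_MODEL.risk(x, n) for n in (1, 2, 3, 4)]
            assert all(a >= b for a, b in zip(risks, risks[1:]))

    def test_unordered_cut_points_rejected(self):
        with pytest.raises(ValueError):
            rm.OrderedProbitRiskModel(cut_points={1: 5.0, 2: 4.0}, slope=0.1)


class TestLogistic:
    @pytest.mark.parametrize("model, p, expected", [
        (rm.THOR_LATERAL_FORCE_MODEL, 0.01, 1643.5),
        (rm.DUMA_FOREARM_MODEL, 0.04, 36.96),
        (rm.ANKLE_DORSIFLEXION_MODEL, 0.01, 17.87),
        (rm.ANKLE_DORSIFLEXION_MODEL, 0.04, 30.94),
        (rm.ADFS_PMHS_MODEL, 0.01, 3.34),
        (rm.ADFS_PMHS_MODEL, 0.04, 5.54),
        (rm.ADFS_THOR_MODEL, 0.01, 8.14),
    ])
    def test_iarv_inversions(self, model, p, expected):
        assert model.iarv(p) == pytest.approx(expected, abs=5e-2)

    def test_dorsiflexion_median_is_location(self):
        # at p = 0.5 the log-odds term vanishes
        assert rm.ANKLE_DORSIFLEXION_MODEL.iarv(0.5) == pytest.approx(60.23)

    def test_bass_forearm_nominal_clamps_to_zero_with_warning(self):
        with pytest.warns(rm.ClampedInversionWarning):
            assert rm.BASS_FOREARM_MODEL.iarv(0.01) == 0.0

    def test_bass_forearm_off_nominal(self):
        # published as 18.6 Nm; the closed form gives 18.53
        assert rm.BASS_FOREARM_MODEL.iarv(0.04) == pytest.approx(18.53, abs=0.01)

    def test_fmvss_chest_33_percent_at_63mm(self):
        assert rm.fmvss_chest_risk(63.0, 3) == pytest.approx(0.33, abs=5e-3)

    def test_fmvss_intercept_risk_at_zero_deflection(self):
        # the curves do not pass through the origin
        assert rm.fmvss_chest_risk(0.0, 2) == pytest.approx(
            1 / (1 + math.exp(1.8706)), rel=1e-12)

    def test_fmvss_levels_are_ordered(self):
        for d in np.linspace(0, 120, 25):
            risks = [rm.fmvss_chest_risk(d, n) for n in (2, 3, 4, 5)]
            assert all(a >= b for a, b in zip(risks, risks[1:]))

    def test_ncap_chest_risk(self):
        assert rm.NCAP_CHEST_MODEL.risk(63.0, 45.0) == pytest.approx(0.654, abs=2e-3)
        assert rm.NCAP_CHEST_MODEL.risk(63.0, 65.0) > rm.NCAP_CHEST_MODEL.risk(63.0, 45.0)
        assert rm.NCAP_CHEST_MODEL.risk(70.0, 45.0) > rm.NCAP_CHEST_MODEL.risk(63.0, 45.0)


class TestNeckCompression:
    def test_tolerance_arithmetic(self):
        model = rm.NECK_COMPRESSION_MODEL
        assert model.tolerance(59, 2, 1) == pytest.approx(2130.488)
        assert model.tolerance(59, 2, 0) == pytest.approx(1465.488)

    def test_female_tolerance_lower_than_male(self):
        model = rm.NECK_COMPRESSION_MODEL
        for age in (35, 47, 56):
            assert model.tolerance(age, 2, 0) < model.tolerance(age, 2, 1)

    def test_risk_requires_beta5(self):
        with pytest.raises(rm.MissingParameterError, match="beta5"):
            rm.NECK_COMPRESSION_MODEL.risk(1000, 47, 2, 1)
        with pytest.raises(rm.MissingParameterError, match="beta5"):
            rm.NECK_COMPRESSION_MODEL.iarv(0.01, 47, 2, 1)

    @pytest.mark.parametrize("beta5", [1e-3, 5e-3, 2e-2])
    def test_iarv_at_half_equals_tolerance_for_any_beta5(self, beta5):
        model = rm.NeckCompressionModel(beta5=beta5)
        assert model.iarv(0.5, 52, 2, 0) == pytest.approx(model.tolerance(52, 2, 0))


class TestDRISpinal:
    def test_intercept_is_one_percent(self):
        assert rm.DRI_SPINAL_MODEL.dri_at_risk(1.0) == pytest.approx(15.8)

    def test_five_percent_dri(self):
        assert rm.DRI_SPINAL_MODEL.dri_at_risk(5.0) == pytest.approx(18.407, abs=1e-3)

    def test_risk_at_dri(self):
        assert rm.DRI_SPINAL_MODEL.risk_percent(19.53) == pytest.approx(10.0, rel=1e-3)

    def test_round_trip(self):
        for pct in (0.5, 1.0, 5.0, 19.0, 50.0):
            dri = rm.DRI_SPINAL_MODEL.dri_at_risk(pct)
            assert rm.DRI_SPINAL_MODEL.risk_percent(dri) == pytest.approx(pct, rel=1e-12)

    def test_non_positive_risk_rejected(self):
        with pytest.raises(ValueError):
            rm.DRI_SPINAL_MODEL.dri_at_risk(0.0)


class TestHipFracture:
    def test_neutral_posture_median_force(self):
        model = rm.HIP_FRACTURE_MODEL
        median = math.exp(-0.2141 + 0.0114 * 178)
        assert model.risk(median, 178) == pytest.approx(0.5)

    def test_monotone_in_force(self):
        model = rm.HIP_FRACTURE_MODEL
        forces = np.linspace(1.0, 15.0, 40)
        risks = [model.risk(f, 178) for f in forces]
        assert all(b > a for a, b in zip(risks, risks[1:]))

    def test_statures_order_the_curve(self):
        # taller crewmembers tolerate more force at the same risk
        model = rm.HIP_FRACTURE_MODEL
        assert model.iarv(0.01, 150) < model.iarv(0.01, 178) < model.iarv(0.01, 190)


class TestFRI:
    def test_half_risk_at_mu(self):
        model = rm.FRIModel(fracture_force=4000.0, mu=1.0, phi=8.0)
        assert model.risk(4000.0) == pytest.approx(0.5)

    def test_large_phi_approaches_step(self):
        model = rm.FRIModel(fracture_force=4000.0, mu=1.0, phi=500.0)
        assert model.risk(3800.0) < 1e-8
        assert model.risk(4200.0) > 1 - 1e-8

    def test_scale_invariance_of_the_force_ratio(self):
        a = rm.FRIModel(fracture_force=4000.0, mu=1.0, phi=8.0)
        b = rm.FRIModel(fracture_force=8000.0, mu=1.0, phi=8.0)
        assert a.risk(3000.0) == pytest.approx(b.risk(6000.0))


class TestShoulderAge:
    @pytest.mark.parametrize("p, expected", [(0.01, 2730.7), (0.04, 3299.3)])
    def test_eldest_astronaut_iarvs(self, p, expected):
        assert rm.SHOULDER_AGE_MODEL.iarv(p, 56) == pytest.approx(expected, abs=0.5)

    def test_age_ratio_is_exponential(self):
        young = rm.SHOULDER_AGE_MODEL.iarv(0.01, 35)
        old = rm.SHOULDER_AGE_MODEL.iarv(0.01, 56)
        assert young / old == pytest.approx(math.exp(0.0055 * 21), rel=1e-12)

    def test_iarv_increases_with_probability(self):
        assert rm.SHOULDER_AGE_MODEL.iarv(0.04, 56) > rm.SHOULDER_AGE_MODEL.iarv(0.01, 56)


# --------------------------------------------------------------------------
# Cross-model properties
# --------------------------------------------------------------------------

MONOTONE_FORWARD = [
    ("hic", lambda x: rm.HIC_RISK_MODEL.risk(x, 1), 0.0, 2000.0),
    ("neck", lambda x: rm.NECK_TENSION_MODEL.risk(x, 1), 0.0, 4000.0),
    ("chest", lambda x: rm.CHEST_DEFLECTION_MODEL.risk(x, 1), 0.0, 120.0),
    ("dorsiflexion", rm.ANKLE_DORSIFLEXION_MODEL.risk, 0.0, 150.0),
    ("acetabular", rm.THOR_LATERAL_FORCE_MODEL.risk, 0.0, 12000.0),
    ("adfs", rm.ADFS_THOR_MODEL.risk, 0.0, 30.0),
    ("shoulder", lambda x: rm.SHOULDER_AGE_MODEL.risk(x, 56), 0.0, 8000.0),
]


@pytest.mark.parametrize("name, fwd, lo, hi", MONOTONE_FORWARD,
                         ids=[m[0] for m in MONOTONE_FORWARD])
def test_forward_risk_is_non_decreasing(name, fwd, lo, hi):
    grid = np.linspace(lo, hi, 400)
    risks = np.array([fwd(x) for x in grid])
    assert (np.diff(risks) >= -1e-15).all()


INVERTIBLE = [
    ("hic", lambda p: rm.HIC_RISK_MODEL.iarv(p, 1),
     lambda x: rm.HIC_RISK_MODEL.risk(x, 1), 3000.0),
    ("neck", lambda p: rm.NECK_TENSION_MODEL.iarv(p, 1),
     lambda x: rm.NECK_TENSION_MODEL.risk(x, 1), 4000.0),
    ("chest", lambda p: rm.CHEST_DEFLECTION_MODEL.iarv(p, 1),
     lambda x: rm.CHEST_DEFLECTION_MODEL.risk(x, 1), 150.0),
    ("dorsiflexion", rm.ANKLE_DORSIFLEXION_MODEL.iarv,
     rm.ANKLE_DORSIFLEXION_MODEL.risk, 200.0),
    ("acetabular", rm.THOR_LATERAL_FORCE_MODEL.iarv,
     rm.THOR_LATERAL_FORCE_MODEL.risk, 20000.0),
    ("shoulder", lambda p: rm.SHOULDER_AGE_MODEL.iarv(p, 47),
     lambda x: rm.SHOULDER_AGE_MODEL.risk(x, 47), 9000.0),
]


@pytest.mark.parametrize("name, inv, fwd, hi", INVERTIBLE,
                         ids=[m[0] for m in INVERTIBLE])
@settings(max_examples=60, derandomize=True)
@given(p=st.floats(min_value=1e-4, max_value=0.999))
def test_closed_form_inverse_round_trips(name, inv, fwd, hi, p):
    x = inv(p)
    if x <= 0:
        return  # clamped region of origin-missing logistic curves
    assert fwd(x) == pytest.approx(p, rel=1e-9)


@pytest.mark.parametrize("name, inv, fwd, hi", INVERTIBLE,
                         ids=[m[0] for m in INVERTIBLE])
def test_closed_form_inverse_matches_bisection_oracle(name, inv, fwd, hi):
    """The analytic inversion agrees with a brute-force numerical root of
    the forward risk curve."""
    for p in (0.003, 0.01, 0.04, 0.05, 0.19, 0.5):
        x_closed = inv(p)
        if x_closed <= 0:
            continue
        x_num = brentq(lambda x: fwd(x) - p, 1e-9, hi, xtol=1e-10)
        assert x_closed == pytest.approx(x_num, rel=1e-6)


@settings(max_examples=50, derandomize=True)
@given(shape=st.floats(min_value=0.5, max_value=10),
       scale=st.floats(min_value=1e-2, max_value=1e4),
       p=st.floats(min_value=1e-4, max_value=0.999))
def test_weibull_round_trip_over_random_parameters(shape, scale, p):
    model = rm.WeibullRiskModel(shape=shape, scales={1: scale})
    assert model.risk(model.iarv(p, 1), 1) == pytest.approx(p, rel=1e-9)
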