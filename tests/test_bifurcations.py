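import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coromorph import (
    Bifurcation,
    CenterlinePoint,
    ValidationError,
    VesselSegment,
    angle_ratio_correlation,
    bifurcation_table,
    extract_bifurcations,
    fit_murray_exponent,
    murray_residual,
    sample_bifurcations,
)

from conftest import build_network, straight_segment


def y_network(angle1_deg, angle2_deg, rotation_deg=0.0):
    """Mother along +X (after rotation) with daughters at the given absolute
    directions relative to the mother axis."""

    def rot(d):
        t = math.radians(rotation_deg + d)
        return (math.cos(t), math.sin(t))

    mother = straight_segment("1", None, direction=rot(0), length=400.0,
                              n_points=9, outer_d=400.0, inner_d=320.0)
    tip = (mother.points[-1].x, mother.points[-1].y)
    d1 = straight_segment("2", "1", start=tip, direction=rot(angle1_deg),
                          length=400.0, n_points=9, outer_d=300.0, inner_d=240.0)
    d2 = straight_segment("3", "1", start=tip, direction=rot(angle2_deg),
                          length=400.0, n_points=9, outer_d=260.0, inner_d=208.0)
    return build_network(mother, d1, d2)


class TestExtraction:
    def test_collinear_and_perpendicular_daughters(self):
        net = y_network(0.0, 90.0)
        (b,) = extract_bifurcations(net)
        # larger daughter continues the mother's course
        assert b.angle_1 == pytest.approx(180.0, abs=1e-9)
        assert b.angle_2 == pytest.approx(90.0, abs=1e-9)
        assert b.r_m == pytest.approx(160.0)
        assert (b.r_d1, b.r_d2) == pytest.approx((120.0, 104.0))

    def test_symmetric_y_at_45_degrees(self):
        net = y_network(45.0, -45.0)
        (b,) = extract_bifurcations(net)
        assert b.angle_1 == pytest.approx(135.0, abs=0.5)
        assert b.angle_2 == pytest.approx(135.0, abs=0.5)

    @pytest.mark.parametrize("rotation", [30.0, 137.0, 260.0])
    def test_angles_invariant_under_rigid_rotation(self, rotation):
        ref = extract_bifurcations(y_network(60.0, -30.0))[0]
        rot = extract_bifurcations(y_network(60.0, -30.0, rotation))[0]
        assert rot.angle_1 == pytest.approx(ref.angle_1, abs=1e-6)
        assert rot.angle_2 == pytest.approx(ref.angle_2, abs=1e-6)

    def test_single_child_at_tip_is_continuation_not_bifurcation(self):
        mother = straight_segment("1", None, length=400.0, n_points=5)
        cont = straight_segment("2", "1", start=(400.0, 0.0), length=300.0,
                                n_points=5, outer_d=280.0, inner_d=224.0)
        assert extract_bifurcations(build_network(mother, cont)) == []

    def test_midsegment_child_creates_continuation_daughter(self):
        mother = straight_segment("1", None, length=600.0, n_points=13)
        side = straight_segment("2", "1", start=(300.0, 0.0),
                                direction=(0, 1), length=300.0,
                                outer_d=150.0, inner_d=120.0, n_points=7)
        (b,) = extract_bifurcations(build_network(mother, side))
        # continuation keeps the mother's lumen; side branch is perpendicular
        assert b.r_d1 == pytest.approx(120.0)
        assert b.angle_1 == pytest.approx(180.0, abs=1e-9)
        assert b.r_d2 == pytest.approx(60.0)
        assert b.angle_2 == pytest.approx(90.0, abs=1e-9)

    def test_flow_distance_of_branch_point(self):
        net = y_network(45.0, -45.0)
        (b,) = extract_bifurcations(net)
        assert b.flow_distance == pytest.approx(400.0)


class TestMurrayResidual:
    def test_symmetric_murray_solution_is_exact(self):
        r = 100.0 / 2.0 ** (1.0 / 3.0)
        b = Bifurcation(100.0, r, r, 135.0, 135.0)
        assert murray_residual(b) == pytest.approx(0.0, abs=1e-12)

    def test_continuation_limit(self):
        b = Bifurcation(100.0, 100.0, 1e-6, 180.0, 90.0)
        assert murray_residual(b) == pytest.approx(0.0, abs=1e-12)

    def test_equal_radii_give_log10_two(self):
        b = Bifurcation(100.0, 100.0, 100.0, 150.0, 150.0)
        assert murray_residual(b) == pytest.approx(math.log10(2.0), abs=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_uniform_rescaling(self, scale):
        base = Bifurcation(120.0, 100.0, 70.0, 160.0, 120.0)
        scaled = Bifurcation(120.0 * scale, 100.0 * scale, 70.0 * scale,
                             160.0, 120.0)
        assert murray_residual(scaled) == pytest.approx(
            murray_residual(base), abs=1e-9)

    def test_rejects_invalid_radii_and_angles(self):
        with pytest.raises(ValidationError):
            Bifurcation(-1.0, 50.0, 50.0, 120.0, 120.0)
        with pytest.raises(ValidationError):
            Bifurcation(100.0, 50.0, 50.0, 181.0, 120.0)


class TestExponentFit:
    @pytest.mark.parametrize("gamma", [2.0, 3.0, 4.0])
    def test_noise_free_recovery_to_three_decimals(self, gamma):
        bifs = sample_bifurcations(200, gamma=gamma, seed=11)
        fit = fit_murray_exponent(bifs)
        assert fit.gamma_hat == pytest.approx(gamma, abs=1e-3)
        assert fit.n == 200

    def test_noisy_recovery_within_band(self):
        bifs = sample_bifurcations(200, gamma=3.0, seed=0,
                                   radius_noise_sigma=0.05)
        fit = fit_murray_exponent(bifs)
        assert abs(fit.gamma_hat - 3.0) < 0.15
        assert fit.residual_sd > 0

    def test_identical_ratios_warn_low_identifiability(self):
        r1 = 100.0 / 2.0 ** (1.0 / 3.0)
        bifs = [Bifurcation(100.0 * s, r1 * s, r1 * s, 135.0, 135.0)
                for s in (1.0, 1.5, 2.0, 2.5)]
        with pytest.warns(UserWarning, match="identical radius ratios"):
            fit_murray_exponent(bifs)

    def test_needs_three_bifurcations(self):
        bifs = sample_bifurcations(2, seed=1)
        with pytest.raises(ValidationError):
            fit_murray_exponent(bifs)


class TestAngleRatioCorrelation:
    def test_exactly_linear_negative_relation(self):
        bifs = []
        rng = np.random.default_rng(5)
        for _ in range(30):
            r_m = rng.uniform(60, 200)
            r1, r2 = 0.9 * r_m, rng.uniform(0.4, 0.8) * r_m
            a = lambda rd: 180.0 - 20.0 * (r_m / rd - 1.0)
            bifs.append(Bifurcation(r_m, r1, r2, a(r1), a(r2)))
        r, p = angle_ratio_correlation(bifs)
        assert r == pytest.approx(-1.0, abs=1e-9)
        assert p < 1e-10

    def test_generator_angle_law_is_significantly_negative(self):
        bifs = sample_bifurcations(100, seed=8)
        r, p = angle_ratio_correlation(bifs)
        assert r < 0
        assert p < 0.05

    def test_constant_angle_is_undefined(self):
        bifs = [Bifurcation(100.0, 80.0, 60.0 + i, 120.0, 120.0)
                for i in range(5)]
        with pytest.raises(ValidationError, match="zero variance"):
            angle_ratio_correlation(bifs)


def test_bifurcation_table_columns_and_residuals():
    bifs = sample_bifurcations(10, seed=3)
    tab = bifurcation_table(bifs)
    assert len(tab) == 10
    assert tab["residual"].iloc[0] == pytest.approx(murray_residual(bifs[0]))
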