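import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cornerflow.corner import (ConcentrationBracket, CornerSpec,
                               SurfactantSeries, concus_finn_flow,
                               critical_concentration, critical_corner_angle,
                               max_rise_height)
from cornerflow.errors import InvalidInputError, InvalidParameterError
from cornerflow.younglaplace import FluidProperties


def fluid(gamma=0.030, theta=60.0, rho=1000.0, g=9.81):
    return FluidProperties(density=rho, surface_tension=gamma,
                           contact_angle_deg=theta, gravity=g)


class TestConcusFinn:
    def test_flow_at_30(self):
        pred = concus_finn_flow(30.0, 60.0)
        assert pred.flows == "yes"
        assert pred.margin_deg == pytest.approx(15.0)

    def test_no_flow_at_90(self):
        pred = concus_finn_flow(90.0, 60.0)
        assert pred.flows == "no"
        assert pred.margin_deg == pytest.approx(-15.0)

    def test_marginal_at_60(self):
        assert concus_finn_flow(60.0, 60.0, tolerance_deg=1.0).flows == "marginal"

    @pytest.mark.parametrize("alpha,theta", [(0.0, 60.0), (180.0, 60.0),
                                             (30.0, -1.0), (30.0, 181.0)])
    def test_out_of_range(self, alpha, theta):
        with pytest.raises(InvalidParameterError):
            concus_finn_flow(alpha, theta)

    @given(alpha=st.floats(1.0, 179.0), theta=st.floats(0.0, 89.999))
    @settings(max_examples=200, deadline=None)
    def test_consistency_with_critical_angle(self, alpha, theta):
        # flow at zero tolerance iff the opening is below the critical angle
        flows = concus_finn_flow(alpha, theta, tolerance_deg=0.0).flows == "yes"
        assert flows == (alpha < critical_corner_angle(theta))


class TestCriticalCornerAngle:
    def test_sixty(self):
        assert critical_corner_angle(60.0) == pytest.approx(60.0)

    def test_ninety_gives_zero(self):
        assert critical_corner_angle(90.0) == 0.0

    def test_perfect_wetting(self):
        assert critical_corner_angle(0.0) == pytest.approx(180.0)

    def test_nonwetting_clamped(self):
        assert critical_corner_angle(120.0) == 0.0

    def test_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            critical_corner_angle(-5.0)


class TestMaxRiseHeight:
    def test_worked_example(self):
        # 2 * 30 mN/m * cos 60 / (1000 * 9.81 * 225 um) = 13.6 mm at 3 s.f.
        h = max_rise_height(fluid(), CornerSpec(30.0, 225e-6))
        assert float(f"{h * 1e3:.3g}") == 13.6

    def test_ninety_degrees_gives_zero(self):
        assert max_rise_height(fluid(theta=90.0), CornerSpec(30.0, 225e-6)) == 0.0

    def test_inverse_in_gap(self):
        h1 = max_rise_height(fluid(), CornerSpec(30.0, 225e-6))
        h2 = max_rise_height(fluid(), CornerSpec(30.0, 450e-6))
        assert h2 == pytest.approx(h1 / 2.0)

    def test_linear_in_gamma(self):
        h1 = max_rise_height(fluid(gamma=0.030), CornerSpec(30.0, 225e-6))
        h2 = max_rise_height(fluid(gamma=0.060), CornerSpec(30.0, 225e-6))
        assert h2 == pytest.approx(2.0 * h1)

    @given(theta=st.floats(0.0, 89.0))
    @settings(max_examples=60, deadline=None)
    def test_decreasing_in_theta(self, theta):
        h1 = max_rise_height(fluid(theta=theta), CornerSpec(30.0, 225e-6))
        h2 = max_rise_height(fluid(theta=theta + 0.5), CornerSpec(30.0, 225e-6))
        assert h2 < h1

    def test_independent_of_alpha(self):
        hs = {max_rise_height(fluid(), CornerSpec(a, 225e-6))
              for a in (10.0, 30.0, 50.0)}
        assert len(hs) == 1

    def test_bad_gap(self):
        with pytest.raises(InvalidParameterError):
            CornerSpec(30.0, -1e-6)


def _series(thetas, concs=None):
    thetas = np.asarray(thetas, dtype=float)
    if concs is None:
        concs = np.logspace(-5, -2, thetas.size)
    return SurfactantSeries(concs, np.full(thetas.size, 0.03), thetas)


class TestCriticalConcentration:
    def test_bracketing(self):
        # theta crosses 75 deg (the alpha=30 flow threshold) between the
        # 3rd and 4th concentrations
        concs = np.array([3e-5, 1e-4, 3e-4, 1e-3])
        series = _series([120.0, 110.0, 80.0, 60.0], concs)
        bracket = critical_concentration(series, 30.0)
        assert bracket == ConcentrationBracket(3e-4, 1e-3)

    def test_paper_like_bracket(self):
        concs = np.array([3e-5, 1e-4, 3e-4, 1e-3])
        series = _series([120.0, 100.0, 65.0, 60.0], concs)
        assert critical_concentration(series, 30.0) == ConcentrationBracket(1e-4, 3e-4)

    def test_never_wetting(self):
        assert critical_concentration(_series([120.0] * 5), 30.0) is None

    def test_always_flowing(self):
        series = _series([40.0] * 5)
        bracket = critical_concentration(series, 30.0)
        assert bracket.c_low is None
        assert bracket.c_high == series.concentrations[0]

    def test_grid_refinement_invariance(self):
        # adding points outside the crossing interval leaves the bracket alone
        coarse = SurfactantSeries(np.array([1e-5, 1e-4, 3e-4, 1e-3]),
                                  np.full(4, 0.03),
                                  np.array([120.0, 100.0, 70.0, 60.0]))
        fine = SurfactantSeries(np.array([1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 3e-3]),
                                np.full(6, 0.03),
                                np.array([120.0, 115.0, 100.0, 70.0, 60.0, 58.0]))
        assert (critical_concentration(coarse, 30.0)
                == critical_concentration(fine, 30.0)
                == ConcentrationBracket(1e-4, 3e-4))

    def test_first_crossing_wins_on_nonmonotone_theta(self):
        series = _series([120.0, 70.0, 100.0, 60.0])
        bracket = critical_concentration(series, 30.0)
        assert bracket.c_high == series.concentrations[1]


class TestSurfactantSeries:
    def test_nonincreasing_concentrations_rejected(self):
        with pytest.raises(InvalidInputError):
            SurfactantSeries(np.array([1e-4, 1e-4]), np.array([0.03, 0.03]),
                             np.array([60.0, 60.0]))

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            SurfactantSeries(np.array([]), np.array([]), np.array([]))

    def test_negative_gamma_rejected(self):
        with pytest.raises(InvalidInputError):
            SurfactantSeries(np.array([1e-4]), np.array([-0.01]), np.array([60.0]))

    def test_csv_round_trip(self, tmp_path):
        series = _series([120.0, 90.0, 60.0])
        path = tmp_path / "series.csv"
        series.to_csv(path)
        back = SurfactantSeries.from_csv(path)
        np.testing.assert_allclose(back.concentrations, series.concentrations)
        np.testing.assert_allclose(back.contact_angles_deg, series.contact_angles_deg)
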