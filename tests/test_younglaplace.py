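import numpy as np
import pytest

from cornerflow.errors import (InsufficientProfileError, InvalidParameterError)
from cornerflow.younglaplace import (DropProfile, FluidProperties, PendantFit,
                                     bond_number, fit_pendant_profile,
                                     integrate_drop_profile, profile_residual)

from conftest import GRAVITY, WATER_DENSITY


class TestIntegrateDropProfile:
    def test_zero_bond_is_a_sphere(self):
        # gravity-free limit: every point on the circle of radius b about (0, b)
        b = 1e-3
        prof = integrate_drop_profile(0.0, b, arc_length_max=2e-3)
        dev = np.abs(np.hypot(prof.x, prof.z - b) - b)
        assert dev.max() < 1e-6

    def test_tiny_bond_is_a_sphere(self):
        b = 1e-3
        prof = integrate_drop_profile(1e-7, b, arc_length_max=2e-3)
        dev = np.abs(np.hypot(prof.x, prof.z - b) - b)
        assert dev.max() < 1e-6

    @pytest.mark.parametrize("bond,b", [(0.0, 1e-3), (0.3, 1.5e-3), (0.8, 2e-3)])
    def test_apex_anchoring(self, bond, b):
        prof = integrate_drop_profile(bond, b, arc_length_max=2 * b)
        assert prof.x[0] == 0.0
        assert prof.z[0] == 0.0
        assert np.all(prof.x >= 0)

    def test_agrees_with_finer_step_oracle(self):
        # independent oracle: same ODE re-integrated at 10x finer step
        b = 1e-3
        coarse = integrate_drop_profile(0.3, b, arc_length_max=2 * b, step=b / 200)
        fine = integrate_drop_profile(0.3, b, arc_length_max=2 * b, step=b / 2000)

        def arc(p):
            return np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(p.x),
                                                             np.diff(p.z)))])
        s_c, s_f = arc(coarse), arc(fine)
        xf = np.interp(s_c, s_f, fine.x)
        zf = np.interp(s_c, s_f, fine.z)
        assert np.abs(coarse.x - xf).max() < 1e-7
        assert np.abs(coarse.z - zf).max() < 1e-7

    def test_pendant_widens_relative_to_sphere(self):
        # gravity stretches a hanging drop: wider than the bond=0 sphere at
        # equal z near the apex
        b = 1e-3
        sphere = integrate_drop_profile(0.0, b, arc_length_max=1.5 * b)
        pendant = integrate_drop_profile(0.3, b, arc_length_max=1.5 * b)
        z_grid = np.linspace(0.1 * b, 0.8 * b, 20)
        x_sphere = np.interp(z_grid, sphere.z, sphere.x)
        x_pendant = np.interp(z_grid, pendant.z, pendant.x)
        assert np.all(x_pendant > x_sphere)

    def test_deterministic(self):
        a = integrate_drop_profile(0.4, 1e-3)
        b = integrate_drop_profile(0.4, 1e-3)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.z, b.z)

    def test_profile_closes_sets_flag(self):
        # a gravity-flattened sitting drop turns past pi within this arc
        prof = integrate_drop_profile(1.0, 1.5e-3, arc_length_max=6e-3,
                                      orientation="sessile")
        assert prof.closed

    @pytest.mark.parametrize("kwargs", [
        {"bond": 0.3, "apex_radius": -1e-3},
        {"bond": -0.1, "apex_radius": 1e-3},
        {"bond": 0.3, "apex_radius": 1e-3, "step": -1e-6},
        {"bond": 0.3, "apex_radius": 1e-3, "arc_length_max": 1e-9, "step": 1e-6},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            integrate_drop_profile(**kwargs)


class TestDropProfileInvariants:
    def test_apex_must_be_first(self):
        with pytest.raises(InvalidParameterError):
            DropProfile(np.array([1e-4, 0.0]), np.array([0.0, 1e-4]))

    def test_negative_x_rejected(self):
        with pytest.raises(InvalidParameterError):
            DropProfile(np.array([0.0, -1e-4]), np.array([0.0, 1e-4]))

    def test_bad_orientation(self):
        with pytest.raises(InvalidParameterError):
            DropProfile(np.array([0.0, 1e-4]), np.array([0.0, 1e-4]),
                        orientation="upside-down")


def _forward_profile(gamma, b, drho=WATER_DENSITY, arc=None):
    beta = bond_number(gamma, drho, b)
    return integrate_drop_profile(beta, b, arc_length_max=arc or 3 * b)


class TestFitPendantProfile:
    def test_round_trip_72(self):
        prof = _forward_profile(0.072, 1.5e-3)
        fit = fit_pendant_profile(prof, WATER_DENSITY)
        assert abs(fit.surface_tension - 0.072) / 0.072 < 0.005
        assert fit.converged

    def test_round_trip_30(self):
        # low-tension supernatant regime
        prof = _forward_profile(0.030, 1.5e-3)
        fit = fit_pendant_profile(prof, WATER_DENSITY)
        assert abs(fit.surface_tension - 0.030) / 0.030 < 0.005

    def test_round_trip_with_point_noise(self, rng):
        gamma, b = 0.072, 1.5e-3
        prof = _forward_profile(gamma, b)
        noisy = DropProfile(
            np.clip(prof.x + np.concatenate([[0], rng.normal(0, 2e-6, len(prof) - 1)]),
                    0, None),
            prof.z + np.concatenate([[0], rng.normal(0, 2e-6, len(prof) - 1)]),
        )
        fit = fit_pendant_profile(noisy, WATER_DENSITY)
        assert abs(fit.surface_tension - gamma) / gamma < 0.03

    def test_scale_equivariance(self):
        gamma, b, k = 0.045, 1.2e-3, 2.0
        prof = _forward_profile(gamma, b)
        fit1 = fit_pendant_profile(prof, WATER_DENSITY)
        fit2 = fit_pendant_profile(prof.scaled(k), WATER_DENSITY)
        assert fit2.apex_radius == pytest.approx(k * fit1.apex_radius, rel=1e-2)
        assert fit2.bond_number == pytest.approx(fit1.bond_number, rel=1e-2)
        assert fit2.surface_tension == pytest.approx(k ** 2 * fit1.surface_tension,
                                                     rel=1e-2)

    def test_optimum_not_worse_than_init(self):
        prof = _forward_profile(0.050, 1.2e-3)
        from cornerflow.younglaplace import _apex_circle_radius
        b0 = _apex_circle_radius(prof)
        init_residual = profile_residual(prof, b0, 0.2)
        fit = fit_pendant_profile(prof, WATER_DENSITY)
        assert fit.rmse <= init_residual + 1e-15

    def test_too_few_points(self):
        prof = integrate_drop_profile(0.3, 1e-3, arc_length_max=2e-3)
        short = DropProfile(prof.x[:10], prof.z[:10])
        with pytest.raises(InsufficientProfileError):
            fit_pendant_profile(short, WATER_DENSITY)

    def test_collinear_points(self):
        z = np.linspace(0, 1e-3, 30)
        prof = DropProfile(np.zeros_like(z), z)
        with pytest.raises(InsufficientProfileError):
            fit_pendant_profile(prof, WATER_DENSITY)

    def test_bad_density(self):
        prof = _forward_profile(0.072, 1.5e-3)
        with pytest.raises(InvalidParameterError):
            fit_pendant_profile(prof, -5.0)


class TestDomainTypes:
    def test_pendant_fit_invariants(self):
        with pytest.raises(InvalidParameterError):
            PendantFit(surface_tension=-1.0, apex_radius=1e-3, bond_number=0.2,
                       rmse=0.0, converged=False)
        with pytest.raises(InvalidParameterError):
            PendantFit(surface_tension=0.07, apex_radius=1e-3, bond_number=-0.2,
                       rmse=0.0, converged=False)

    def test_fluid_properties_invariants(self):
        with pytest.raises(InvalidParameterError):
            FluidProperties(density=-1.0)
        with pytest.raises(InvalidParameterError):
            FluidProperties(contact_angle_deg=200.0)

    def test_bond_number_value(self):
        # beta = drho g b^2 / gamma, hand-checked
        assert bond_number(0.072, 1000.0, 1.5e-3, 9.81) == pytest.approx(
            1000.0 * 9.81 * 1.5e-3 ** 2 / 0.072)
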