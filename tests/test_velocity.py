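"""Velocity solutions: rational-image algebra, series/inversion paths, limits."""

import numpy as np
import pytest

from hemoflow import (DegenerateModeError, SeriesControl, classical_velocity,
                      figure_defaults, laplace_velocity_mode, mode_coefficients,
                      velocity_fluid, velocity_gm0, velocity_particle)
from hemoflow.specfun import ml_neg
from hemoflow.velocity import mode_image_from_partial_fractions


def momentum_residual(l, n, dp, basis):
    """|bracket * image - rhs| of the transformed momentum balance,
    with the bracket rebuilt directly from the coupled ODE system."""
    eps = basis.roots[n]
    j1v = basis.j1_at_roots[n]
    e2 = eps * eps
    y = l**dp.alpha
    bracket = y + e2 + dp.M0 + dp.Pc - dp.Pc / (dp.Pm * y + 1.0)
    a1, a2 = e2 / dp.Pr, e2 / dp.Sc
    F0 = dp.A0 / l + dp.A1 * l / (l * l + dp.omega**2)
    rhs = (eps * j1v / l + F0 * j1v / eps
           + dp.Gr * (1 / l - l ** (dp.alpha - 1) / (y + a1)) * j1v / eps
           + dp.Gm * (1 / l - l ** (dp.alpha - 1) / (y + a2)) * j1v / eps)
    img = laplace_velocity_mode(l, n, dp, basis)
    return np.abs(bracket * img - rhs) / np.abs(rhs)


class TestModeCoefficients:
    @pytest.mark.parametrize("n", [0, 5, 17])
    def test_vieta_relations(self, n, basis, rng):
        dp = figure_defaults(M=rng.uniform(0.1, 3), Pc=rng.uniform(0, 2),
                             Pm=rng.uniform(0.2, 3))
        mc = mode_coefficients(n, dp, basis)
        Y0, Y1 = mc.upsilon[0], mc.upsilon[1]
        assert mc.Y3 + mc.Y4 == pytest.approx(Y0, rel=1e-12)
        assert mc.Y3 * mc.Y4 == pytest.approx(Y1, rel=1e-12)
        assert mc.upsilon[5] == pytest.approx(Y0) and mc.upsilon[6] == pytest.approx(Y1)

    def test_recombined_partial_fractions_equal_direct_image(self, dp, basis, rng):
        l = rng.uniform(0.1, 3.0, 20) + 1j * rng.uniform(-3.0, 3.0, 20)
        for n in (0, 4, 12):
            mc = mode_coefficients(n, dp, basis)
            direct = laplace_velocity_mode(l, n, dp, basis)
            recombined = mode_image_from_partial_fractions(mc, dp.alpha, l, dp.Gr, dp.Gm)
            np.testing.assert_allclose(recombined, direct, rtol=1e-8)

    def test_single_phase_limit(self, basis):
        # Pc = 0, Pm -> inf: the rational factor degenerates to one pole at
        # eps^2 + M0 (single-phase Brinkman MHD mode)
        dp = figure_defaults(Pc=0.0, Pm=1e8)
        mc = mode_coefficients(2, dp, basis)
        e2 = basis.roots[2] ** 2
        assert mc.Y3 == pytest.approx(e2 + dp.M0, rel=1e-6)
        l = 0.7 + 0.9j
        y = l**dp.alpha
        factor = (y + mc.Y2) / ((y + mc.Y3) * (y + mc.Y4))
        assert factor == pytest.approx(1.0 / (y + e2 + dp.M0), rel=1e-6)

    def test_printed_coefficient_ledger_cross_check(self, dp, basis):
        mc = mode_coefficients(3, dp, basis)
        # the one unambiguous printed constant equals the computed residue
        assert mc.p[3] == pytest.approx(mc.c4, rel=1e-12)
        assert mc.p[8] == pytest.approx(mc.p[4] + mc.p[6], rel=1e-12)

    def test_degenerate_root_raises(self):
        basis_small = __import__("hemoflow").HankelBasis.build(3)
        eps2 = basis_small.roots[0] ** 2
        # engineer Pc = 0 with eps^2 + M0 = 1/Pm exactly
        dp = figure_defaults(Pc=0.0, M=0.0, beta1=0.0, Pm=1.0 / eps2)
        with pytest.raises(DegenerateModeError):
            mode_coefficients(0, dp, basis_small)


class TestLaplaceImage:
    def test_forcing_free_image_is_boundary_term_alone(self, basis):
        dp = figure_defaults(Gr=0.0, Gm=0.0, A0=0.0, A1=0.0)
        n, l = 1, 0.8 + 0.4j
        eps, j1v = basis.roots[n], basis.j1_at_roots[n]
        y = l**dp.alpha
        mc = mode_coefficients(n, dp, basis)
        expected = (eps * j1v / l) * (y + mc.Y2) / ((y + mc.Y3) * (y + mc.Y4))
        assert laplace_velocity_mode(l, n, dp, basis) == pytest.approx(expected, rel=1e-12)

    def test_momentum_residual_vanishes(self, dp, basis, rng):
        l = rng.uniform(0.2, 2.0, 10) + 1j * rng.uniform(-2.0, 2.0, 10)
        for n in (0, 6):
            assert np.max(momentum_residual(l, n, dp, basis)) < 1e-10

    def test_final_value_theorem_steady_mode(self, basis):
        # l*image -> steady mode value as l -> 0+ along the real axis;
        # cross-checked against the independent steady-state balance
        # (alpha = 1 so the approach to the limit is O(l), not O(l^alpha))
        dp = figure_defaults(A1=0.0, alpha=1.0)
        n = 0
        l = 1e-9
        lim = float((l * laplace_velocity_mode(l, n, dp, basis)).real)
        eps, j1v = basis.roots[n], basis.j1_at_roots[n]
        e2 = eps * eps
        # steady per-mode balance: (e2 + M0) fH = eps J1 + (A0+Gr+Gm) J1/eps
        steady = (eps * j1v + (dp.A0 + dp.Gr + dp.Gm) * j1v / eps) / (e2 + dp.M0)
        assert lim == pytest.approx(steady, rel=1e-6)

    def test_forcing_pole_proximity_rejected(self, dp, basis):
        with pytest.raises(ValueError, match="pole"):
            laplace_velocity_mode(1j * dp.omega, 0, dp, basis)


class TestTimeDomain:
    def test_wall_velocity_is_exactly_one(self, dp, ctrl):
        tau = np.linspace(0, 2, 9)
        v = velocity_fluid(np.array([1.0]), tau, dp, ctrl)
        np.testing.assert_array_equal(v.f, 1.0)

    def test_initial_interior_velocity_within_ripple(self, dp):
        xi = np.linspace(0, 0.9, 10)
        v = velocity_fluid(xi, np.array([0.0]), dp, SeriesControl(n_modes=80))
        assert np.max(np.abs(v.f)) < 0.1

    def test_series_and_inversion_paths_agree(self, dp):
        ctrl = SeriesControl(n_modes=25)
        xi = np.linspace(0, 1, 7)
        tau = np.array([0.25, 1.0, 2.0])
        fs = velocity_fluid(xi, tau, dp, ctrl)
        fi = velocity_fluid(xi, tau, dp, ctrl, path="ilt")
        scale = max(1.0, float(np.max(np.abs(fs.f))))
        assert np.max(np.abs(fs.f - fi.f)) / scale < 1e-4

    def test_alpha_one_matches_classical_closed_form(self, dp, ctrl):
        dp1 = dp.replace(alpha=1.0)
        xi = np.linspace(0, 1, 9)
        tau = np.linspace(0, 2, 17)
        fr = velocity_particle(xi, tau, dp1, ctrl)
        cl = classical_velocity(xi, tau, dp1, ctrl)
        scale = max(1.0, float(np.max(np.abs(cl.f))))
        assert np.max(np.abs(fr.f - cl.f)) / scale < 1e-8
        assert np.max(np.abs(fr.g - cl.g)) / scale < 1e-8

    def test_classical_matches_inversion_path(self, dp):
        ctrl = SeriesControl(n_modes=25)
        dp1 = dp.replace(alpha=1.0)
        xi = np.linspace(0, 1, 5)
        tau = np.array([0.5, 1.5])
        cl = classical_velocity(xi, tau, dp1, ctrl)
        fi = velocity_fluid(xi, tau, dp1, ctrl, path="ilt")
        scale = max(1.0, float(np.max(np.abs(cl.f))))
        assert np.max(np.abs(cl.f - fi.f)) / scale < 1e-6

    def test_no_oscillatory_forcing_drops_trig_terms(self, ctrl):
        # A1 = 0: the classical response carries no cos/sin component, so
        # the late-time solution of the forcing-free, undamped (M0 = 0)
        # wall-driven problem approaches 1 uniformly.  (With M0 > 0 the
        # steady profile is the Bessel-I shape I0(sqrt(M0) xi)/I0(sqrt(M0)),
        # not unity.)
        dp0 = figure_defaults(A1=0.0, A0=0.0, Gr=0.0, Gm=0.0, alpha=1.0,
                              M=0.0, beta1=0.0)
        cl = classical_velocity(np.linspace(0, 1, 9), np.array([0.0, 60.0]), dp0, ctrl)
        np.testing.assert_allclose(cl.f[:, 1], 1.0, atol=1e-8)


class TestParticleVelocity:
    def test_particles_start_from_rest(self, dp, ctrl):
        tau = np.linspace(0, 1, 33)
        v = velocity_particle(np.linspace(0, 1, 5), tau, dp, ctrl)
        np.testing.assert_allclose(v.g[:, 0], 0.0, atol=1e-14)

    def test_wall_particles_follow_relaxation_response(self, dp, ctrl):
        # g(1,tau) = 1 - E_alpha(-tau^alpha/Pm): the fractional analogue of
        # the 1 - exp(-b tau) wall condition with b = 1/Pm
        tau = np.linspace(0, 1.5, 61)
        v = velocity_particle(np.array([1.0]), tau, dp, ctrl)
        ref = 1.0 - ml_neg(dp.alpha, 1.0, tau**dp.alpha / dp.Pm)
        np.testing.assert_allclose(v.g[0], ref, atol=1e-12)

    def test_classical_wall_closed_form(self, ctrl):
        dp1 = figure_defaults(alpha=1.0)
        tau = np.linspace(0, 2, 81)
        v = velocity_particle(np.array([1.0]), tau, dp1, ctrl)
        np.testing.assert_allclose(v.g[0], 1 - np.exp(-tau / dp1.Pm), atol=1e-12)

    def test_particles_lag_wall_at_early_times(self, dp, ctrl):
        tau = np.linspace(0, 0.5, 21)
        v = velocity_particle(np.array([1.0]), tau, dp, ctrl)
        assert np.all(v.g[0, 1:] <= v.f[0, 1:] + 1e-12)

    def test_nonuniform_grid_rejected(self, dp, ctrl):
        with pytest.raises(ValueError, match="uniform"):
            velocity_particle(np.array([0.5]), np.array([0.0, 0.1, 0.3]), dp, ctrl)


class TestGm0Limit:
    def test_identity_with_general_solution_at_gm_zero(self, dp, ctrl):
        xi = np.linspace(0, 1, 6)
        tau = np.array([0.5, 1.0])
        direct = velocity_fluid(xi, tau, dp.replace(Gm=0.0), ctrl)
        special = velocity_gm0(xi, tau, dp, ctrl)
        np.testing.assert_array_equal(direct.f, special.f)

    def test_independent_of_schmidt_number(self, dp, ctrl):
        xi = np.linspace(0, 1, 5)
        tau = np.array([1.0])
        a = velocity_gm0(xi, tau, dp.replace(Sc=10.0), ctrl)
        b = velocity_gm0(xi, tau, dp.replace(Sc=1.9e4), ctrl)
        np.testing.assert_allclose(a.f, b.f, atol=1e-12)

    def test_matches_inversion_path(self, dp):
        ctrl = SeriesControl(n_modes=20)
        xi = np.linspace(0, 1, 5)
        tau = np.array([0.5, 1.5])
        s = velocity_gm0(xi, tau, dp, ctrl)
        i = velocity_gm0(xi, tau, dp, ctrl, path="ilt")
        scale = max(1.0, float(np.max(np.abs(s.f))))
        assert np.max(np.abs(s.f - i.f)) / scale < 1e-4
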