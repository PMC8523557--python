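import numpy as np
import pytest

from ciliaflow import (
    Conventions,
    FlowParameters,
    ParameterError,
    dpdx_perturb,
    momentum_series,
    psi_perturb,
    sigma_perturb,
    solve_thermal_bvp,
    theta_perturb,
    thermal_constants,
    u_perturb,
    wall_state,
)
from conftest import PRESETS


def fd_derivative(f, y, step=1e-5, order=1):
    """High-order central finite difference of a scalar function."""
    if order == 1:
        return (f(y - 2 * step) - 8 * f(y - step) + 8 * f(y + step)
                - f(y + 2 * step)) / (12 * step)
    raise ValueError


@pytest.mark.parametrize("preset", PRESETS)
@pytest.mark.parametrize("series", ["derived", "printed"])
class TestStreamFunctionBCs:
    def test_boundary_conditions(self, preset, series):
        """psi(0)=0, psi(h)=q, psi_y(h)=u_h, psi_yy(0)=0 at every order."""
        p = FlowParameters(conventions=Conventions(series=series), **preset)
        x = 0.3
        w = wall_state(x, p)
        assert psi_perturb(0.0, x, p) == pytest.approx(0.0, abs=1e-12)
        # wall streamline: q = F/2 under the printed BC convention
        assert psi_perturb(w.h, x, p) == pytest.approx(p.F / 2, abs=1e-10)
        assert u_perturb(w.h, x, p) == pytest.approx(w.u_h, abs=1e-10)
        # centreline symmetry psi_yy(0) = u'(0) = 0 (one-sided 2nd-order stencil)
        dy = 1e-4
        slope = (-3 * u_perturb(0.0, x, p) + 4 * u_perturb(dy, x, p)
                 - u_perturb(2 * dy, x, p)) / (2 * dy)
        assert slope == pytest.approx(0.0, abs=1e-6)

    def test_u_is_y_derivative_of_psi(self, preset, series):
        p = FlowParameters(conventions=Conventions(series=series), **preset)
        x, h = 0.2, wall_state(0.2, p).h
        for y in (0.3 * h, 0.7 * h):
            du = fd_derivative(lambda t: psi_perturb(t, x, p), y)
            assert u_perturb(y, x, p) == pytest.approx(du, abs=1e-8)


class TestSeries:
    def test_newtonian_axis_velocity_closed_form(self, table_params):
        # zeta = 0, y = 0: u = -u_h/2 + 3F/(4h)
        p = table_params.with_(zeta=0.0)
        w = wall_state(1.0, p)
        expected = -w.u_h / 2 + 3 * p.F / (4 * w.h)
        assert u_perturb(0.0, 1.0, p) == pytest.approx(expected, abs=1e-14)

    def test_continuity_in_zeta(self, table_params):
        """Series truncation: psi(zeta) -> psi(0) linearly as zeta -> 0."""
        y, x = 0.5, 1.0
        base = psi_perturb(y, x, table_params.with_(zeta=0.0))
        gaps = [abs(psi_perturb(y, x, table_params.with_(zeta=z)) - base)
                for z in (1e-3, 1e-4, 1e-5)]
        assert gaps[0] < 1e-3 and gaps[1] / gaps[0] == pytest.approx(0.1, rel=0.05)

    def test_derived_first_order_matches_printed_with_full_flux(self):
        """The printed O(zeta) term corresponds to a wall flux of F, not F/2.

        Re-deriving the expansion with q = F reproduces the printed
        first-order coefficient exactly, pinning the misprint to the flux.
        """
        h, uh, F = 1.15, -1.0006, 0.1
        psis, _ = momentum_series(h, uh, q=F)
        y = np.linspace(0, h, 7)
        K = -F + h * uh
        printed = 27 * K**3 * y * (h**2 - y**2) ** 2 / (20 * h**9)
        derived = np.polynomial.polynomial.polyval(y, psis[1])
        np.testing.assert_allclose(derived, printed, atol=1e-12)

    def test_domain_error(self, table_params):
        with pytest.raises(ParameterError, match="y must lie"):
            psi_perturb(1.2, 1.0, table_params)   # h(1) = 1.15

    def test_dpdx_newtonian_closed_form(self, table_params):
        p = table_params.with_(zeta=0.0)
        w = wall_state(1.0, p)
        expected = -3 * (p.F - 2 * w.h * w.u_h) / (2 * w.h**3)
        assert dpdx_perturb(1.0, p) == pytest.approx(expected, abs=1e-12)
        # printed expression agrees at zeta = 0
        pp = p.with_(conventions=Conventions(series="printed"))
        assert dpdx_perturb(1.0, pp) == pytest.approx(expected, abs=1e-12)

    def test_dpdx_equals_third_derivative_of_psi0(self, table_params):
        """At zeta=0 the pressure gradient is psi0''' (constant in y)."""
        p = table_params.with_(zeta=0.0)
        w = wall_state(1.0, p)
        psis, As = momentum_series(w.h, w.u_h, p.flux())
        third = 6.0 * psis[0][3]          # cubic coefficient * 3!
        assert dpdx_perturb(1.0, p) == pytest.approx(third, abs=1e-14)

    def test_printed_dpdx_first_order_matches_derived(self, table_params):
        """The printed O(zeta) pressure-gradient coefficient is consistent
        with the derived expansion at flux q = F/2 (F0=F, F1=0)."""
        p = table_params
        d = dpdx_perturb(1.0, p.with_(conventions=Conventions(series="printed")))
        w = wall_state(1.0, p)
        _, As = momentum_series(w.h, w.u_h, p.flux())
        assert d == pytest.approx(As[0] + p.zeta * As[1], abs=1e-12)


class TestThermal:
    def test_boundary_conditions(self, thermal_params):
        c = thermal_constants(thermal_params, 1.0)
        h = c.h
        p = thermal_params
        assert theta_perturb(0.0, 1.0, p, c) == pytest.approx(0.0, abs=1e-9)
        assert theta_perturb(h, 1.0, p, c) == pytest.approx(1.0, abs=1e-9)
        assert sigma_perturb(0.0, 1.0, p, c) == pytest.approx(0.0, abs=1e-9)
        assert sigma_perturb(h, 1.0, p, c) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("thermal", ["derived", "printed"])
    def test_affine_combination(self, thermal_params, thermal):
        """sigma + (Nt/Nb)*theta is affine in y (concentration equation
        integrated twice), for both series conventions."""
        p = thermal_params.with_(conventions=Conventions(thermal=thermal))
        c = thermal_constants(p, 1.0)
        y = np.linspace(0, c.h, 41)
        comb = sigma_perturb(y, 1.0, p, c) + (p.Nt / p.Nb) * theta_perturb(y, 1.0, p, c)
        coef = np.polyfit(y, comb, 1)
        assert np.max(np.abs(comb - np.polyval(coef, y))) < 1e-8

    def test_nt_zero_concentration_is_linear(self, thermal_params):
        p = thermal_params.with_(Nt=0.0)
        c = thermal_constants(p, 1.0)
        y = np.linspace(0, c.h, 11)
        np.testing.assert_allclose(sigma_perturb(y, 1.0, p, c), y / c.h, atol=1e-10)

    def test_no_dissipation_exponential_profile(self, thermal_params):
        """Ec=0, Nt=0: theta solves theta'' + (Pr*Nb/h)*theta' = 0 exactly,
        i.e. the saturating exponential between the wall values."""
        p = thermal_params.with_(Ec=0.0, Nt=0.0)
        c = thermal_constants(p, 1.0)
        y = np.linspace(0, c.h, 21)
        k = p.Pr * p.Nb / c.h
        exact = (1 - np.exp(-k * y)) / (1 - np.exp(-k * c.h))
        np.testing.assert_allclose(theta_perturb(y, 1.0, p, c), exact, atol=1e-12)

    def test_constants_reproduce_numerical_bvp_at_zeta0(self, thermal_params):
        p = thermal_params.with_(zeta=0.0)
        t = solve_thermal_bvp(p, 1.0)
        c = thermal_constants(p, 1.0)
        sup = np.max(np.abs(theta_perturb(t.y, 1.0, p, c) - t.theta))
        assert sup < 1e-4

    def test_first_order_correction_against_bvp(self, thermal_params):
        t = solve_thermal_bvp(thermal_params, 1.0)
        c = thermal_constants(thermal_params, 1.0)
        sup = np.max(np.abs(theta_perturb(t.y, 1.0, thermal_params, c) - t.theta))
        assert sup < 5e-3

    def test_nb_zero_rejected(self):
        with pytest.raises(ParameterError, match="Nb"):
            FlowParameters(Nb=0.0)
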