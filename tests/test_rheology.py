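import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from wallspot.rheology import (characteristic_path, omega_of_age,
                               resting_length, sigma_H_base,
                               sigma_H_expansin_rest, sigma_H_expansin_visc,
                               viscosity)


def _ode_sigma(alpha, omega_fn, t_end, E_rest=0.0, rtol=1e-11):
    """Independent Maxwell-element integration along a characteristic."""
    def rhs(t, s):
        sig, L0 = s
        L = math.exp(alpha * t)
        dL0 = E_rest * (L / L0 - 1.0)
        ds = alpha * L / L0 - L / L0**2 * dL0
        return [ds - omega_fn(t) * sig, dL0]

    sol = solve_ivp(rhs, (0.0, t_end), [0.0, 1.0], rtol=rtol, atol=1e-13)
    return sol.y[0, -1], sol.y[1, -1]


class TestBaseStress:
    def test_zero_at_deposition(self):
        assert sigma_H_base(1.0, 2.0, 1.0) == 0.0

    def test_elastic_limit(self):
        L = np.array([1.0, 2.0, 5.0])
        assert np.allclose(sigma_H_base(L, 1.0, 0.0), L - 1.0)

    def test_closed_form_value(self):
        assert sigma_H_base(2.0, 1.0, 1.0) == pytest.approx(0.75, rel=1e-14)

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 10.0])
    @pytest.mark.parametrize("omega", [0.2, 1.0, 5.0])
    def test_matches_ode_oracle(self, alpha, omega):
        t_end = math.log(4.0) / alpha   # L = 4
        ref, _ = _ode_sigma(alpha, lambda t: omega, t_end)
        assert sigma_H_base(4.0, alpha, omega) == pytest.approx(ref, rel=1e-8)

    def test_elastic_bound(self):
        L = np.geomspace(1.0, 1e3, 50)
        for omega in (0.0, 0.5, 3.0):
            sig = sigma_H_base(L, 2.0, omega)
            assert np.all(sig >= -1e-14)
            assert np.all(sig <= L - 1.0 + 1e-12)


class TestViscosity:
    def test_initial_and_enzyme_free(self):
        assert viscosity(0.0, 1.0, 3.0) == 1.0
        assert np.all(viscosity(np.linspace(0, 5, 7), 0.0, 3.0) == 1.0)

    def test_logistic_value_against_ode(self):
        sol = solve_ivp(lambda t, m: 1.0 * m * (1 - 3.0 * m), (0, 1), [1.0],
                        rtol=1e-12, atol=1e-14)
        assert viscosity(1.0, 1.0, 3.0) == pytest.approx(sol.y[0, -1], rel=1e-9)
        assert viscosity(1.0, 1.0, 3.0) == pytest.approx(0.44165, abs=5e-5)

    def test_relaxes_to_target(self):
        t = np.linspace(0, 50, 200)
        mu = viscosity(t, 2.0, 3.0)
        assert np.all(np.diff(mu) <= 1e-15)
        assert mu[-1] == pytest.approx(1 / 3.0, rel=1e-8)

    def test_omega_identity(self):
        # omega(t) = omega0 (M + (1-M) e^{-E t}) = omega0 / mu(t)
        t = np.linspace(0, 3, 11)
        assert np.allclose(omega_of_age(t, 1.7, 3.0, 2.0),
                           1.7 / viscosity(t, 2.0, 3.0), rtol=1e-13)


class TestRestingLength:
    def test_enzyme_free_identity(self):
        t, L = characteristic_path(1.0, 2.0)
        assert np.all(resting_length(t, L, 0.0) == 1.0)

    def test_strong_enzyme_tracks_extension(self):
        # quasi-steady balance gives L0/L -> 1 - alpha L0 L / E + ...
        t, L = characteristic_path(1.0, 3.0, dt=1e-5)
        r500 = resting_length(t, L, 500.0)[-1] / L[-1]
        r5000 = resting_length(t, L, 5000.0)[-1] / L[-1]
        assert r500 < r5000 < 1.0
        assert r5000 == pytest.approx(1.0, abs=5e-3)

    def test_bounds_invariant(self):
        t, L = characteristic_path(5.0, 1.5)
        L0 = resting_length(t, L, 1.0)
        assert np.all(L0 >= 1.0) and np.all(L0 <= L + 1e-12)

    def test_matches_adaptive_ode(self):
        alpha, E = 1.0, 1.0
        t, L = characteristic_path(alpha, 1.0)
        L0 = resting_length(t, L, E)
        _, ref = _ode_sigma(alpha, lambda t: 0.0, 1.0, E_rest=E)
        assert L0[-1] == pytest.approx(ref, rel=1e-6)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            characteristic_path(1.0, 1.0, dt=0.0)
        with pytest.raises(ValueError):
            resting_length(np.array([0.0]), np.array([1.0]), 1.0)


class TestExpansinRestLength:
    def test_enzyme_free_collapses_to_closed_form(self):
        t, L = characteristic_path(2.0, 1.0)
        sig = sigma_H_expansin_rest(t, L, 2.0, 1.0, 0.0)
        assert np.allclose(sig, sigma_H_base(L, 2.0, 1.0), rtol=1e-12)

    def test_zero_at_deposition(self):
        t, L = characteristic_path(5.0, 0.4)
        assert sigma_H_expansin_rest(t, L, 5.0, 1.0, 1.0)[0] == 0.0

    def test_relaxation_lowers_stress(self):
        # material reaching y = 0.5 at alpha = 5
        alpha = 5.0
        t, L = characteristic_path(alpha, math.log(2.0) / alpha)
        on = sigma_H_expansin_rest(t, L, alpha, 1.0, 1.0)[-1]
        off = sigma_H_base(2.0, alpha, 1.0)
        assert on < off

    @pytest.mark.parametrize("alpha,E", [(1.0, 0.5), (5.0, 1.0), (10.0, 3.0)])
    def test_matches_ode_oracle(self, alpha, E):
        t_end = math.log(8.0) / alpha
        t, L = characteristic_path(alpha, t_end)
        sig = sigma_H_expansin_rest(t, L, alpha, 1.0, E)[-1]
        ref, _ = _ode_sigma(alpha, lambda t: 1.0, t_end, E_rest=E)
        assert sig == pytest.approx(ref, rel=1e-5)


class TestExpansinViscosity:
    def test_zero_at_deposition(self):
        assert sigma_H_expansin_visc(1.0, 2.0, 1.0, 3.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_ratio_reduces_to_base(self):
        y = 0.3
        got = sigma_H_expansin_visc(y, 2.0, 1.5, 1.0, 1.0)
        assert got == pytest.approx(sigma_H_base(1 / y, 2.0, 1.5), rel=1e-8)

    def test_continuous_at_vanishing_rate(self):
        got = sigma_H_expansin_visc(0.4, 3.0, 1.0, 3.0, 1e-7)
        assert got == pytest.approx(sigma_H_base(2.5, 3.0, 1.0), rel=1e-4)

    def test_zero_rate_dispatch_error(self):
        with pytest.raises(ValueError, match="sigma_H_base"):
            sigma_H_expansin_visc(0.5, 2.0, 1.0, 3.0, 0.0)

    @pytest.mark.parametrize("alpha,E", [(5.0, 1.0), (2.0, 0.3), (20.0, 2.0)])
    def test_matches_ode_oracle(self, alpha, E):
        y = 0.2
        t_end = math.log(1.0 / y) / alpha
        omega_fn = lambda t: omega_of_age(t, 1.0, 3.0, E)
        ref, _ = _ode_sigma(alpha, omega_fn, t_end)
        got = sigma_H_expansin_visc(y, alpha, 1.0, 3.0, E)
        assert got == pytest.approx(ref, rel=1e-5)

    def test_elastic_bound_all_regimes(self):
        y = np.array([0.9, 0.5, 0.1, 0.01])
        L = 1.0 / y
        for sig in (sigma_H_base(L, 5.0, 1.0),
                    sigma_H_expansin_visc(y, 5.0, 1.0, 3.0, 1.0)):
            sig = np.asarray(sig)
            assert np.all(sig >= 0.0) and np.all(sig <= L - 1.0 + 1e-10)
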