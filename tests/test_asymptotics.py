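import math

import numpy as np
import pytest

from wallspot.asymptotics import (approx_G, approx_n, approx_n_hot,
                                  derive_expansion_constants, optimal_delta,
                                  sigma_infinity_parts,
                                  sigma_infinity_simplified, switchover,
                                  trig_expansion)
from wallspot.crosslink_dynamics import G_integral, hotspot_density
from wallspot.kinematics import axial_projection, cellulose_extension
from wallspot.parameters import table1_preset
from wallspot.stress_resultant import stress_resultant_steady


class TestSwitchover:
    def test_scales_linearly_with_sensitivities(self, preset):
        p = preset.with_(alpha=10.0)
        chi, chi_hot = switchover(p)
        chi2, chi_hot2 = switchover(p.with_(gamma=2 * p.gamma,
                                            beta_hot=2 * p.beta_hot))
        assert chi2 == pytest.approx(2 * chi, rel=1e-12)
        assert chi_hot2 == pytest.approx(2 * chi_hot, rel=1e-12)

    def test_no_hotspot_cutting_no_switchover(self, preset):
        _, chi_hot = switchover(preset.with_(alpha=10.0, beta_hot=0.0))
        assert chi_hot == 0.0

    def test_log_domain_guard(self, preset):
        with pytest.raises(ValueError, match="Q or alpha"):
            switchover(preset.with_(alpha=0.05))

    def test_sits_on_survival_shoulder(self):
        # the switch-over must land where the exact drop-off actually happens
        p = table1_preset(alpha=10.0)
        _, chi_hot = switchover(p)
        assert 0.05 < hotspot_density(chi_hot, p) < 0.95


class TestPiecewiseSurvival:
    def test_outer_branch_is_logarithmic(self, preset):
        p = preset.with_(alpha=10.0)
        assert approx_G(0.5, p) == pytest.approx(math.log(2.0), rel=1e-12)

    def test_exact_when_sensitivity_vanishes(self):
        p = table1_preset(alpha=2.0, gamma=0.0, beta_hot=0.0)
        y = np.array([0.9, 0.3, 0.01])
        assert np.allclose(approx_G(y, p), np.log(1 / y), rtol=1e-12)
        assert np.allclose(approx_n(y, p), y ** (1 / 2.0), rtol=1e-12)
        assert np.allclose(approx_n_hot(y, p), y ** (1 / 2.0), rtol=1e-12)

    def test_inner_branch_converges_towards_outer_wall(self):
        # leading-order inner form; relative error shrinks as y/gamma -> 0
        p = table1_preset(alpha=1.0, gamma=0.05)
        err = [abs(approx_G(y, p) / G_integral(y, p) - 1.0)
               for y in (0.01, 0.005, 0.003)]
        assert err[0] < 0.3
        assert err[2] < 0.05
        assert err[0] > err[1] > err[2]

    def test_inner_branch_double_exponential_collapse(self):
        p = table1_preset(alpha=10.0)
        assert approx_n_hot(1e-4, p) < 1e-300
        assert approx_n(1e-4, p) < 1e-300

    def test_branches_bracket_exact_at_switchover(self):
        # measured behaviour at the matching point: inner 2.3x, outer 3.9x
        p = table1_preset(alpha=10.0)
        _, chi_hot = switchover(p)
        exact = hotspot_density(chi_hot, p)
        outer = chi_hot ** (1 / p.alpha)
        approx = approx_n_hot(chi_hot, p)
        assert max(approx / exact, exact / approx) < 4.5
        assert max(outer / exact, exact / outer) < 4.5


class TestTrigExpansion:
    def test_large_y_leading_term(self):
        T = math.tan(0.1)
        assert trig_expansion(0.9, 0.1, 0.05) == pytest.approx(
            T / 0.9, rel=2e-2)

    def test_middle_region_anchor(self):
        # at y = tan(theta0) the projection factor is exactly 1/sqrt(2)
        T = math.tan(0.1)
        assert trig_expansion(T, 0.1, 0.05) == pytest.approx(1 / math.sqrt(2),
                                                             rel=1e-12)

    def test_mean_squared_error_target(self):
        delta = optimal_delta(0.1)
        grid = np.linspace(1e-4, 1.0, 10_000)
        err = trig_expansion(grid, 0.1, delta) - axial_projection(grid, 0.1)
        assert float(np.mean(err * err)) <= 1e-3

    def test_transverse_angle_rejected(self):
        with pytest.raises(ValueError):
            trig_expansion(0.5, 0.0, 0.05)


@pytest.fixture(scope="module")
def consts():
    return derive_expansion_constants(table1_preset(alpha=50.0))


class TestExpansionConstants:
    def test_inner_boundary_continuity(self, consts):
        # region-1 form at y = 1 must equal the deposition value L_C = 1
        T = math.tan(consts.theta0)
        assert consts.b1 * (1 + T * T / 2) == pytest.approx(1.0, rel=1e-14)

    def test_region_boundaries_continuous(self, consts):
        y_lo, y_hi = consts.region_bounds
        for yb in (y_lo, y_hi):
            below = float(consts.lc_piecewise(yb * (1 - 1e-9)))
            above = float(consts.lc_piecewise(yb * (1 + 1e-9)))
            assert below == pytest.approx(above, rel=1e-6)

    def test_outer_wall_hyperbolic_structure(self, consts):
        # fully reoriented fibres co-stretch: L_C ~ b3 / y near the cut-off
        lc = consts.lc_piecewise(np.array([2e-4, 1e-4]))
        assert lc[1] / lc[0] == pytest.approx(2.0, rel=5e-3)

    def test_piecewise_matches_exact_extension(self, consts, y_grid):
        exact = cellulose_extension(y_grid, consts.theta0)
        rel = np.abs(consts.lc_piecewise(y_grid) / exact - 1.0)
        assert float(rel.max()) < 0.05

    def test_integer_correction_exponents(self, consts):
        assert all(isinstance(q, int) for q in consts.H_powers)

    def test_transverse_angle_rejected(self):
        with pytest.raises(ValueError):
            derive_expansion_constants(table1_preset(theta0=0.0))


class TestReducedResultant:
    def test_weights_gate_their_terms(self, consts):
        p = table1_preset(alpha=50.0, a1=0.0)
        assert sigma_infinity_parts(p, consts)[1] == 0.0
        p = table1_preset(alpha=50.0, a2=0.0)
        assert sigma_infinity_parts(p, consts)[2] == 0.0

    def test_geometry_term_independent_of_rates(self, consts):
        s1_a = sigma_infinity_parts(table1_preset(alpha=2.0), consts)[0]
        s1_b = sigma_infinity_parts(table1_preset(alpha=80.0, beta_hot=0.05,
                                                  gamma=0.1), consts)[0]
        assert s1_a == s1_b

    def test_full_expansion_tracks_quadrature(self, consts):
        p = table1_preset(alpha=50.0)
        full = sum(sigma_infinity_parts(p, consts))
        quad = stress_resultant_steady(p).total
        assert abs(full / quad - 1.0) < 0.1

    def test_simplified_tracks_quadrature(self, consts):
        p = table1_preset(alpha=50.0)
        simp = sigma_infinity_simplified(p, consts, "large_alpha")
        quad = stress_resultant_steady(p).total
        assert abs(simp / quad - 1.0) < 0.15

    def test_small_rate_branch_drops_power_terms(self, consts):
        # Z^{1/alpha} -> 0, so the small-alpha branch is smooth through 0
        p = table1_preset(alpha=0.2)
        val = sigma_infinity_simplified(p, consts, "small_alpha")
        assert np.isfinite(val) and val > 0

    def test_large_rate_branch_levels_out(self, consts):
        # the limit drifts only double-logarithmically through the shrinking
        # switch-over position: sub-percent change per decade of strain rate
        v = [sigma_infinity_simplified(table1_preset(alpha=a), consts,
                                       "large_alpha")
             for a in (1e4, 1e6)]
        assert v[1] == pytest.approx(v[0], rel=2e-2)

    def test_unknown_regime_rejected(self, consts):
        with pytest.raises(ValueError):
            sigma_infinity_simplified(table1_preset(), consts, "medium")

    def test_variants_nearly_coincident(self, consts):
        # the two reductions differ from each other by less than either
        # differs from the quadrature value, across rates and sensitivities
        for bh, g in ((0.01, 0.05), (0.05, 0.05), (0.01, 0.1)):
            for a in (1.0, 10.0, 100.0):
                p = table1_preset(alpha=a, beta_hot=bh, gamma=g)
                quad = stress_resultant_steady(p).total
                full = sum(sigma_infinity_parts(p, consts))
                simp = sigma_infinity_simplified(p, consts, "large_alpha")
                worst = max(abs(full - quad), abs(simp - quad))
                assert abs(full - simp) < worst
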