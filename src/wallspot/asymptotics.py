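"""Leading-order reduction of the steady stress resultant.

Both breakage sensitivities are small, so the bond-survival profiles are
near power laws ``y^(k0_ratio/alpha)`` and ``y^(1/alpha)`` down to narrow
switch-over positions ``chi`` and ``chi_hot`` where survival collapses; the
trigonometric projection factor and the cellulose extension admit piecewise
Taylor expansions in three regions of the wall split at ``tan(theta0)+delta``
and ``tan(theta0)/2``.  Carrying the expansions through the resultant
integral reduces it to elementary power integrals:

    Sigma_inf ~ Sigma1 + Sigma2(alpha) + Sigma3(alpha) + Gamma alpha,

where Sigma1 is pure fibre geometry (independent of rates), Sigma2 the
a1-weighted cellulose-via-hotspot term and Sigma3 the a2-weighted
hemicellulose term.  All expansion constants are derived here from the
stated recipe — squaring the projection expansion, integrating, Taylor
expanding the exponential and imposing continuity — rather than transcribed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

from .kinematics import axial_projection
from .parameters import WallParameters

__all__ = [
    "AsymptoticConstants",
    "approx_G",
    "approx_n",
    "approx_n_hot",
    "switchover",
    "trig_expansion",
    "optimal_delta",
    "derive_expansion_constants",
    "sigma_infinity_parts",
    "sigma_infinity_simplified",
]

DEFAULT_Q = 10.0


def _breve_alpha(p: WallParameters) -> float:
    return p.alpha / (p.alpha + p.omega0)


def switchover(p: WallParameters, Q: float = DEFAULT_Q) -> tuple[float, float]:
    """Switch-over positions ``(chi, chi_hot)`` of the survival collapse.

    ``chi = gamma * breve_alpha / sqrt(ln(alpha Q / k0_ratio))`` and
    analogously for ``chi_hot`` with ``beta_hot``; both scale linearly with
    their sensitivity.  ``Q`` is the derivative threshold picking where the
    inner branch takes over.
    """
    ba = _breve_alpha(p)
    log_hemi = p.alpha * Q / p.k0_ratio
    log_hot = p.alpha * Q
    if log_hemi <= 1.0 or log_hot <= 1.0:
        raise ValueError(
            "switch-over undefined: alpha*Q must exceed max(1, k0_ratio); "
            "increase Q or alpha")
    chi = p.gamma * ba / math.sqrt(math.log(log_hemi))
    chi_hot = p.beta_hot * ba / math.sqrt(math.log(log_hot))
    return chi, chi_hot


def _inner_G(y, scale: float, ba: float):
    """Inner-branch approximation ``y^2/(2 ba^2 s^2) exp(ba^2 s^2 / y^2)``."""
    y = np.asarray(y, dtype=float)
    c = ba * ba * scale * scale
    return y * y / (2.0 * c) * np.exp(np.minimum(c / (y * y), 700.0))


def approx_G(y, p: WallParameters, Q: float = DEFAULT_Q):
    """Piecewise approximation of the hemicellulose breakage integral G.

    Outer branch ``ln(1/y)`` for y above the switch-over, inner
    exponentially growing branch below; exact everywhere when gamma = 0.
    """
    y = np.asarray(y, dtype=float)
    if p.gamma == 0.0:
        out = np.log(1.0 / y)
        return out if out.shape else float(out)
    chi, _ = switchover(p, Q)
    out = np.where(y >= chi, np.log(1.0 / np.maximum(y, 1e-300)),
                   _inner_G(y, p.gamma, _breve_alpha(p)))
    return out if out.shape else float(out)


def approx_n(y, p: WallParameters, Q: float = DEFAULT_Q):
    """Piecewise bond-number approximation, ``y^(k0_ratio/alpha)`` outer."""
    out = np.exp(-np.minimum(p.k0_ratio / p.alpha * np.asarray(approx_G(y, p, Q)), 745.0))
    return out if out.shape else float(out)


def approx_n_hot(y, p: WallParameters, Q: float = DEFAULT_Q):
    """Piecewise hotspot-density approximation, ``y^(1/alpha)`` outer.

    The inner branch decays double-exponentially towards the outer wall.
    """
    y = np.asarray(y, dtype=float)
    if p.beta_hot == 0.0:
        out = y ** (1.0 / p.alpha)
        return out if out.shape else float(out)
    _, chi_hot = switchover(p, Q)
    G_hot = np.where(y >= chi_hot, np.log(1.0 / np.maximum(y, 1e-300)),
                     _inner_G(y, p.beta_hot, _breve_alpha(p)))
    out = np.exp(-np.minimum(G_hot / p.alpha, 745.0))
    return out if out.shape else float(out)


# --- piecewise trigonometric projection -----------------------------------

def _trig_series(theta0: float) -> tuple[dict, list, dict]:
    """Coefficient tables of the three-region projection expansion.

    Region 1 is the large-y Laurent series of tan(theta0)/sqrt(tan^2+y^2);
    region 2 the 4th-order Taylor series about y = tan(theta0) (coefficients
    returned in powers of (y - tan theta0)); region 3 the small-y series.
    """
    T = math.tan(theta0)
    s1 = {-1: T, -3: -T**3 / 2, -5: 3 * T**5 / 8, -7: -5 * T**7 / 16}
    r2 = math.sqrt(2.0)
    s2_z = [1 / r2, -1 / (2 * r2 * T), 1 / (8 * r2 * T**2),
            1 / (16 * r2 * T**3), -13 / (128 * r2 * T**4)]
    s3 = {0: 1.0, 2: -1 / (2 * T**2), 4: 3 / (8 * T**4), 6: -5 / (16 * T**6)}
    return s1, s2_z, s3


def trig_expansion(y, theta0: float, delta: float):
    """Piecewise polynomial approximation of ``sin(arctan(tan(theta0)/y))``.

    Regions split at ``tan(theta0) + delta`` and ``tan(theta0)/2``; at
    ``y = tan(theta0)`` the middle branch anchors at 1/sqrt(2).
    """
    if theta0 <= 0:
        raise ValueError("theta0 must be strictly positive")
    T = math.tan(theta0)
    s1, s2_z, s3 = _trig_series(theta0)
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)

    m1 = y > T + delta
    m3 = y <= T / 2
    m2 = ~(m1 | m3)

    y1 = y[m1]
    out[m1] = sum(c * y1**k for k, c in s1.items())
    z = y[m2] - T
    out[m2] = sum(c * z**i for i, c in enumerate(s2_z))
    y3 = y[m3]
    out[m3] = sum(c * y3**k for k, c in s3.items())
    return out if out.shape else float(out)


@lru_cache(maxsize=16)
def optimal_delta(theta0: float, epsilon: float = 1e-4, n_grid: int = 10_000) -> float:
    """Region-boundary offset minimising the projection mean-squared error.

    One-dimensional minimisation of the MSE of :func:`trig_expansion`
    against the exact projection factor on a uniform grid over
    [epsilon, 1]; frozen per theta0.
    """
    grid = np.linspace(epsilon, 1.0, n_grid)
    exact = axial_projection(grid, theta0)
    T = math.tan(theta0)

    def mse(delta):
        err = trig_expansion(grid, theta0, delta) - exact
        return float(np.mean(err * err))

    res = minimize_scalar(mse, bounds=(1e-6, min(4.0 * T, 1.0 - T - 1e-6)),
                          method="bounded", options={"xatol": 1e-7})
    return float(res.x)


# --- derived expansion constants ------------------------------------------

def _poly_mul(a: dict, b: dict) -> dict:
    out: dict = {}
    for ka, ca in a.items():
        for kb, cb in b.items():
            out[ka + kb] = out.get(ka + kb, 0.0) + ca * cb
    return out


def _poly_add(a: dict, b: dict, sb: float = 1.0) -> dict:
    out = dict(a)
    for k, c in b.items():
        out[k] = out.get(k, 0.0) + sb * c
    return out


def _poly_eval(a: dict, y: float) -> float:
    return sum(c * y**k for k, c in a.items())


def _power_integral(power: float, y1: float, y2: float) -> float:
    if abs(power + 1.0) < 1e-12:
        return math.log(y2 / y1)
    return (y2 ** (power + 1.0) - y1 ** (power + 1.0)) / (power + 1.0)


@dataclass(frozen=True)
class AsymptoticConstants:
    """Derived expansion coefficients for one (theta0, delta, Q) geometry.

    ``b0..b3`` fix the piecewise cellulose-extension form (b1 from
    L_C(1) = 1, b2 and b3 from continuity at the region boundaries); the
    H-series carries the region-2 exponential correction; each region's
    resultant integrand ``(L_C - 1) sin(theta)`` is stored as a Laurent
    table so the alpha-dependent pieces reduce to power integrals.
    """

    theta0: float
    delta: float
    Q: float
    b0: float
    b1: float
    b2: float
    b3: float
    H_powers: tuple = field(repr=False)
    H_coeffs: tuple = field(repr=False)
    region_bounds: tuple = ()          # (tan/2, tan + delta)
    c_list: tuple = ()                 # per-region Sigma1 contributions
    laurent: tuple = field(default=(), repr=False)  # per-region (powers, coeffs)

    def lc_piecewise(self, y):
        """Evaluate the derived piecewise cellulose-extension approximation."""
        T = math.tan(self.theta0)
        y = np.asarray(y, dtype=float)
        out = np.empty_like(y)
        y2b, y1b = self.region_bounds
        m1 = y > y1b
        m3 = y <= y2b
        m2 = ~(m1 | m3)
        out[m1] = self.b1 * (1.0 + T * T / (2.0 * y[m1] ** 2))
        H = np.zeros_like(y[m2])
        for q, pc in zip(self.H_powers, self.H_coeffs):
            H += pc * (y[m2] / T) ** q
        out[m2] = self.b2 * y[m2] ** (-self.b0) * (1.0 - H + H * H / 2.0)
        out[m3] = self.b3 / y[m3] * (1.0 + y[m3] ** 2 / (2.0 * T * T))
        return out if out.shape else float(out)


def derive_expansion_constants(p: WallParameters, delta: float | None = None,
                               Q: float = DEFAULT_Q) -> AsymptoticConstants:
    """Carry out the expansion recipe and return the derived constants.

    Squares the piecewise projection series, integrates it against 1/y,
    Taylor expands the exponential of the result and imposes L_C(1) = 1 plus
    continuity at both region boundaries; then multiplies out the piecewise
    ``(L_C - 1) sin(theta)`` integrand into Laurent tables and evaluates the
    geometry-only resultant term Sigma1.
    """
    if p.theta0 <= 0:
        raise ValueError("expansion requires theta0 > 0")
    T = math.tan(p.theta0)
    if delta is None:
        delta = optimal_delta(p.theta0, p.epsilon)
    y_hi = T + delta        # region-1/2 boundary
    y_lo = T / 2.0          # region-2/3 boundary
    s1, s2_z, s3 = _trig_series(p.theta0)

    # region 2 series in plain powers of y (binomial shift from y - T)
    s2: dict = {}
    for i, c in enumerate(s2_z):
        shift = {0: 1.0}
        for _ in range(i):
            shift = _poly_mul(shift, {1: 1.0, 0: -T})
        s2 = _poly_add(s2, {k: c * v for k, v in shift.items()})

    # L_C region 1: b1 (1 + T^2/(2 y^2)) with L_C(1) = 1
    b1 = 1.0 / (1.0 + T * T / 2.0)
    lc1 = {0: b1, -2: b1 * T * T / 2.0}

    # L_C region 2: b2 y^(-b0) (1 - H + H^2/2), H from the squared series
    s2_sq = _poly_mul(s2, s2)
    b0 = s2_sq.get(0, 0.0)
    # antiderivative correction series; the additive constant is free (it is
    # absorbed into b2), so centre it at the expansion point y = T to keep
    # the quadratic truncation of exp(-H) accurate across the region
    H = {k: c / k for k, c in s2_sq.items() if k != 0}
    H = _poly_add(H, {0: -_poly_eval(H, T)})
    corr = _poly_add({0: 1.0}, H, -1.0)
    corr = _poly_add(corr, _poly_mul(H, H), 0.5)
    lc1_at = _poly_eval(lc1, y_hi)
    b2 = lc1_at * y_hi ** b0 / _poly_eval(corr, y_hi)
    lc2 = {k: b2 * c for k, c in corr.items()}   # times y^(-b0), tracked apart

    # L_C region 3: b3 / y (1 + y^2/(2T^2)), continuity at y_lo
    lc2_at = _poly_eval(lc2, y_lo) * y_lo ** (-b0)
    b3 = lc2_at * y_lo / (1.0 + y_lo**2 / (2 * T * T))
    lc3 = {-1: b3, 1: b3 / (2 * T * T)}

    # Laurent tables of (L_C - 1) * sin(theta) per region
    def integrand_table(lc: dict, s: dict, shift_power: float = 0.0) -> tuple:
        tab = _poly_mul(lc, s)
        if shift_power:
            tab = {k + shift_power: c for k, c in tab.items()}
        tab = _poly_add(tab, s, -1.0)
        items = sorted(tab.items())
        return tuple(k for k, _ in items), tuple(c for _, c in items)

    reg1 = integrand_table(lc1, s1)
    reg2 = integrand_table(lc2, s2, shift_power=-b0)
    reg3 = integrand_table(lc3, s3)
    bounds = ((y_hi, 1.0), (y_lo, y_hi), (p.epsilon, y_lo))
    c_list = []
    for (powers, coeffs), (a, b) in zip((reg1, reg2, reg3), bounds):
        c_list.append(sum(c * _power_integral(k, a, b)
                          for k, c in zip(powers, coeffs)))

    # store the correction series in the form sum_i p_i (y/T)^{q_i}
    Hs = sorted(H.items())
    return AsymptoticConstants(
        theta0=p.theta0, delta=delta, Q=Q, b0=b0, b1=b1, b2=b2, b3=b3,
        H_powers=tuple(int(k) for k, _ in Hs),
        H_coeffs=tuple(c * T**k for k, c in Hs),
        region_bounds=(y_lo, y_hi), c_list=tuple(c_list),
        laurent=(reg1, reg2, reg3),
    )


def sigma_infinity_parts(p: WallParameters,
                         consts: AsymptoticConstants) -> tuple[float, float, float]:
    """Full-expansion steady resultant parts ``(Sigma1, Sigma2, Sigma3)``.

    Sigma1 is alpha-independent geometry; Sigma2 integrates the power-law
    hotspot survival ``y^(1/alpha)`` against the piecewise cellulose
    integrand down to the switch-over ``chi_hot`` (survival collapses below
    it); Sigma3 is the closed-form hemicellulose term cut at ``chi``.
    """
    sigma1 = sum(consts.c_list)

    chi, chi_hot = switchover(p, consts.Q)
    inv_a = 1.0 / p.alpha
    y_lo, y_hi = consts.region_bounds
    cut = max(chi_hot, p.epsilon)
    bounds = ((max(y_hi, cut), 1.0), (max(y_lo, cut), y_hi), (cut, y_lo))
    sigma2 = 0.0
    for (powers, coeffs), (a, b) in zip(consts.laurent, bounds):
        if b <= a:
            continue
        sigma2 += sum(c * _power_integral(k + inv_a, a, b)
                      for k, c in zip(powers, coeffs))
    sigma2 *= p.a1

    ba = _breve_alpha(p)
    k0r, omega = p.k0_ratio, p.omega0
    sigma3 = p.a2 * ba * (
        p.alpha / (k0r + 1.0) * (1.0 - chi ** ((k0r + 1.0) * inv_a))
        - (1.0 - chi ** ((k0r + omega + 1.0) * inv_a + 1.0))
        / (inv_a * (k0r + omega + 1.0) + 1.0))
    return sigma1, sigma2, sigma3


def sigma_infinity_simplified(p: WallParameters, consts: AsymptoticConstants,
                              regime: str) -> float:
    """Reduced steady resultant in the small- or large-strain-rate regime.

    In the small-alpha branch every ``Z^(1/alpha)`` term is negligible
    (Z < 1); the large-alpha branch keeps them and tends to a finite
    constant as alpha grows, which is why the resultant plateaus.
    """
    T = math.tan(consts.theta0)
    sigma1 = sum(consts.c_list)
    ba = _breve_alpha(p)
    k0r, omega = p.k0_ratio, p.omega0
    inv_a = 1.0 / p.alpha
    if regime == "small_alpha":
        a1_term = p.a1 * p.alpha * T * (consts.b1 - 1.0)
        a2_term = p.a2 * ba * (p.alpha / (k0r + 1.0)
                               - 1.0 / (inv_a * (k0r + omega + 1.0) + 1.0))
        return sigma1 + a1_term + a2_term + p.Gamma * p.alpha
    if regime == "large_alpha":
        chi, chi_hot = switchover(p, consts.Q)
        a1_term = p.a1 * p.alpha * (
            T * (consts.b1 - 1.0)
            + T * (1.0 - consts.b1) * (consts.delta + T) ** inv_a
            + consts.b3 * (T / 2.0) ** inv_a
            - consts.b3 * chi_hot ** inv_a)
        a2_term = p.a2 * ba * (
            p.alpha / (k0r + 1.0) * (1.0 - chi ** ((k0r + 1.0) * inv_a))
            - 1.0 / (inv_a * (k0r + omega + 1.0) + 1.0))
        return sigma1 + a1_term + a2_term + p.Gamma * p.alpha
    raise ValueError("regime must be 'small_alpha' or 'large_alpha'")
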