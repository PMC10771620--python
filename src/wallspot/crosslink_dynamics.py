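"""Load-dependent crosslink breakage and the surviving bond densities.

Hotspot and hemicellulose bonds break at rates that grow exponentially with
the elastic energy stored in the strands (a Bell-type law).  Along a material
characteristic the survival fractions integrate to

    n(y)     = exp(-(k0_ratio/alpha) * G(y)),
    n_hot(y) = exp(-(1/alpha) * G_hot(y)),

where ``G`` and ``G_hot`` accumulate the breakage-rate excess over the
material's transit from deposition (y = 1) to its current position.  The
hotspot rate couples to the hemicellulose number: a hotspot with all strands
intact (n = 1) breaks at the unstressed baseline rate regardless of load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from ._quadrature import clamped_exp, refine_until, suffix_cumulative_gauss
from .parameters import WallParameters
from .rheology import sigma_H_base

__all__ = [
    "BondState",
    "breakage_rates",
    "sigma_H_of_y",
    "G_integral",
    "bond_number",
    "G_hot_integral",
    "hotspot_density",
    "CrosslinkProfiles",
]


@dataclass(frozen=True)
class BondState:
    """Survival fractions and instantaneous breakage rates of one cohort."""

    n: float
    n_hot: float
    k_off: float
    k_off_hot: float

    def __post_init__(self) -> None:
        if not 0 < self.n <= 1 or not 0 < self.n_hot <= 1:
            raise ValueError("bond fractions must lie in (0, 1]")


def breakage_rates(sigma_H, n, p: WallParameters):
    """Nondimensional breakage rates ``(k_off, k_off_hot)`` at a given load.

    ``k_off = k0_ratio * exp(gamma^2 varsigma sigma_H^2)`` and
    ``k_off_hot = exp(beta_hot^2 varsigma_hot (1 - n) sigma_H^2)``; an intact
    hotspot (n = 1) keeps its baseline rate 1 under any load.
    """
    sigma_H = np.asarray(sigma_H, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(sigma_H < 0):
        raise ValueError("sigma_H must be nonnegative")
    if np.any(n <= 0) or np.any(n > 1):
        raise ValueError("n must lie in (0, 1]")
    s2 = sigma_H * sigma_H
    k_off = p.k0_ratio * clamped_exp(p.gamma**2 * p.varsigma * s2)
    k_off_hot = clamped_exp(p.beta_hot**2 * p.varsigma_hot * (1.0 - n) * s2)
    if k_off.shape or k_off_hot.shape:
        return k_off, k_off_hot
    return float(k_off), float(k_off_hot)


def sigma_H_of_y(p: WallParameters) -> Callable:
    """Steady expanding-region hemicellulose stress profile for a regime.

    Returns a vectorised callable sigma_H(y) on (0, 1] matching the active
    enzyme mode; under either expansin mechanism the stress depends on
    position only through the material age, so a single characteristic
    solution serves the whole region.
    """
    if p.enzyme_mode == "none" or p.E == 0.0:
        return lambda y: sigma_H_base(1.0 / np.asarray(y, dtype=float),
                                      p.alpha, p.omega0)
    if p.enzyme_mode == "expansin_rest_length":
        from .rheology import characteristic_path, sigma_H_expansin_rest
        t_end = math.log(1.0 / p.epsilon) / p.alpha + 1e-12
        dt = min(1e-3, 0.01 / p.alpha)
        prev = None
        for _ in range(8):  # halve the step until the stress settles
            t, L = characteristic_path(p.alpha, t_end, dt)
            sig = sigma_H_expansin_rest(t, L, p.alpha, p.omega0, p.E)
            if prev is not None and abs(sig[-1] - prev) < 1e-6 * (1 + abs(sig[-1])):
                break
            prev = sig[-1]
            dt /= 2
        # age t <-> position y = exp(-alpha t); interpolate sigma*y (bounded)
        u = -p.alpha * t
        interp = PchipInterpolator(u[::-1], (sig * np.exp(u))[::-1])

        def rest_profile(y):
            y = np.asarray(y, dtype=float)
            out = interp(np.log(y)) / y
            return out if out.shape else float(out)

        return rest_profile
    if p.enzyme_mode == "expansin_viscosity":
        pw = p.omega0 * p.M / p.alpha
        q = p.omega0 * (p.M - 1.0) / p.E
        r = p.E / p.alpha
        u_min = math.log(p.epsilon)

        def build(n_panels):
            def integrand_u(u):
                yh = np.exp(u)
                return yh ** (-1.0 - pw) * np.exp(q * yh**r)

            edges, tail = suffix_cumulative_gauss(integrand_u, u_min, 0.0,
                                                  n_panels)
            ye = np.exp(edges)
            sig_edges = ye**pw * np.exp(-q * ye**r) * tail
            return PchipInterpolator(edges, sig_edges * ye)

        probe_u = np.linspace(u_min, 0.0, 37)
        interp = refine_until(build, lambda f: f(probe_u), rtol=1e-10)

        def visc_profile(y):
            y = np.asarray(y, dtype=float)
            out = interp(np.log(y)) / y
            return out if out.shape else float(out)

        return visc_profile
    raise ValueError(f"unknown enzyme mode {p.enzyme_mode!r}")


def _check_y(y, p: WallParameters) -> float:
    y = float(y)
    if not p.epsilon <= y <= 1.0 + 1e-15:
        raise ValueError(f"y = {y} outside [epsilon, 1]")
    return min(y, 1.0)


def G_integral(y, p: WallParameters, sigma: Callable | None = None) -> float:
    """Accumulated hemicellulose breakage-rate excess from y to the inner wall.

    ``G(y) = int_y^1 exp(gamma^2 varsigma sigma_H(y')^2) / y' dy'``; reduces
    exactly to ``ln(1/y)`` for gamma = 0.  Evaluated by adaptive quadrature
    in log position.
    """
    y = _check_y(y, p)
    if y == 1.0:
        return 0.0
    if sigma is None:
        sigma = sigma_H_of_y(p)
    c = p.gamma**2 * p.varsigma
    if c == 0.0:
        return math.log(1.0 / y)

    def integrand_u(u):
        s = sigma(np.exp(np.asarray(u, dtype=float)))
        return clamped_exp(c * s * s)

    val, _ = quad(integrand_u, math.log(y), 0.0, limit=400,
                  epsabs=1e-13, epsrel=1e-11)
    return float(val)


def bond_number(y, p: WallParameters, sigma: Callable | None = None) -> float:
    """Surviving hemicellulose fraction ``n = exp(-(k0_ratio/alpha) G(y))``.

    gamma = 0 gives the power law ``y^(k0_ratio/alpha)`` exactly.
    """
    return math.exp(-min(p.k0_ratio / p.alpha * G_integral(y, p, sigma), 745.0))


def G_hot_integral(y, p: WallParameters, sigma: Callable | None = None,
                   profiles: "CrosslinkProfiles | None" = None) -> float:
    """Accumulated hotspot breakage-rate excess from y to the inner wall.

    The integrand couples to the hemicellulose survival n(y') (via the inner
    integral G), taken from a precomputed profile to keep the nesting cheap.
    Reduces to ``ln(1/y)`` for beta_hot = 0.
    """
    y = _check_y(y, p)
    if y == 1.0:
        return 0.0
    c = p.beta_hot**2 * p.varsigma_hot
    if c == 0.0:
        return math.log(1.0 / y)
    if sigma is None:
        sigma = sigma_H_of_y(p)
    if profiles is None:
        profiles = CrosslinkProfiles(p, sigma=sigma)

    def integrand_u(u):
        yh = np.exp(np.asarray(u, dtype=float))
        s = sigma(yh)
        return clamped_exp(c * (1.0 - profiles.n(yh)) * s * s)

    val, _ = quad(integrand_u, math.log(y), 0.0, limit=400,
                  epsabs=1e-13, epsrel=1e-11)
    return float(val)


def hotspot_density(y, p: WallParameters, sigma: Callable | None = None,
                    profiles: "CrosslinkProfiles | None" = None) -> float:
    """Surviving hotspot fraction ``n_hot = exp(-(1/alpha) G_hot(y))``.

    beta_hot = 0 gives ``y^(1/alpha)`` exactly; for loaded hotspots the
    density collapses rapidly below the switch-over position.
    """
    g = G_hot_integral(y, p, sigma, profiles)
    return math.exp(-min(g / p.alpha, 745.0))


class CrosslinkProfiles:
    """Bond-survival profiles on [epsilon, 1] from cumulative quadrature.

    Builds ``G``, ``n``, ``G_hot`` and ``n_hot`` on a shared panel grid in
    log position, refined by doubling until the hotspot density settles, and
    exposes them as monotone interpolants.  This is the bulk evaluation path
    used by the stress-resultant assembly; the module-level point functions
    serve as its independent adaptive-quadrature counterpart.
    """

    def __init__(self, p: WallParameters, sigma: Callable | None = None,
                 rtol: float = 1e-9, n0: int = 512):
        self.p = p
        self.sigma = sigma if sigma is not None else sigma_H_of_y(p)
        self._u_min = math.log(p.epsilon)
        probe = np.exp(np.linspace(self._u_min, 0.0, 41))
        built = refine_until(self._build, lambda b: b["n_hot"](np.log(probe)),
                             rtol=rtol, n0=n0)
        self._interp = built

    def _build(self, n_panels: int) -> dict:
        p, sigma = self.p, self.sigma
        c_hemi = p.gamma**2 * p.varsigma
        c_hot = p.beta_hot**2 * p.varsigma_hot

        def g_integrand(u):
            s = sigma(np.exp(u))
            return clamped_exp(c_hemi * s * s)

        edges, G_edges = suffix_cumulative_gauss(g_integrand, self._u_min, 0.0,
                                                 n_panels)
        # cap far beyond where survival underflows; keeps interpolation finite
        G_edges = np.minimum(G_edges, 1e15)
        n_edges = np.exp(-np.minimum(p.k0_ratio / p.alpha * G_edges, 745.0))
        with np.errstate(over="ignore", divide="ignore"):
            n_interp = PchipInterpolator(edges, n_edges)

        def ghot_integrand(u):
            s = sigma(np.exp(u))
            return clamped_exp(c_hot * (1.0 - n_interp(u)) * s * s)

        _, Ghot_edges = suffix_cumulative_gauss(ghot_integrand, self._u_min,
                                                0.0, n_panels)
        Ghot_edges = np.minimum(Ghot_edges, 1e15)
        nhot_edges = np.exp(-np.minimum(Ghot_edges / p.alpha, 745.0))
        # the G interpolants span hundreds of decades across the collapsed
        # region; Pchip's slope harmonic mean overflows harmlessly there
        with np.errstate(over="ignore", divide="ignore"):
            return {
                "G": PchipInterpolator(edges, G_edges),
                "n": n_interp,
                "G_hot": PchipInterpolator(edges, Ghot_edges),
                "n_hot": PchipInterpolator(edges, nhot_edges),
            }

    def _eval(self, name: str, y):
        y = np.asarray(y, dtype=float)
        out = self._interp[name](np.log(y))
        return out if out.shape else float(out)

    def G(self, y):
        return self._eval("G", y)

    def n(self, y):
        return np.clip(self._eval("n", y), 0.0, 1.0)

    def G_hot(self, y):
        return self._eval("G_hot", y)

    def n_hot(self, y):
        return np.clip(self._eval("n_hot", y), 0.0, 1.0)
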