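"""Assembly of the axial stress resultant of the composite wall.

The thickness-integrated axial stress is

    Sigma = int_eps^1 (1 + a1 n_hot) sigma_C + a2 n n_hot sigma_H dy
            + Gamma alpha,

with ``sigma_C = (L_C - 1) sin(theta)`` the cellulose contribution.  Three
structural terms are tracked separately: cellulose crosslinked by non-hotspot
components, cellulose crosslinked by the surviving hotspots (weight a1) and
the hemicellulose inside the hotspots themselves (weight a2); pectin adds the
extensional-viscosity term ``Gamma alpha``.

The transient resultant splits the wall into the thinning region (material
present at t = 0, uniform in position) of width ``exp(-alpha t) - eps`` and
the expanding region of later-deposited material; the former is exhausted
once ``exp(-alpha t)`` falls below the outer cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from ._quadrature import gauss_panels, refine_until
from .crosslink_dynamics import CrosslinkProfiles, sigma_H_of_y
from .kinematics import axial_projection, cellulose_extension
from .parameters import WallParameters

__all__ = [
    "StressBreakdown",
    "cellulose_stress",
    "stress_resultant_steady",
    "stress_resultant_time",
    "sweep_alpha",
]


@dataclass(frozen=True)
class StressBreakdown:
    """Stress resultant split into its structural contributions."""

    sigma_C_term: float          # cellulose, non-hotspot crosslinks
    hotspot_cellulose_term: float  # cellulose via surviving hotspots (a1)
    hotspot_term: float          # hemicellulose inside hotspots (a2)
    pectin_term: float           # Gamma * alpha
    total: float

    def __post_init__(self) -> None:
        parts = (self.sigma_C_term + self.hotspot_cellulose_term
                 + self.hotspot_term + self.pectin_term)
        if not math.isclose(parts, self.total, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("breakdown parts do not sum to the total")


def cellulose_stress(L_C, theta):
    """Axial cellulose stress ``(L_C - 1) sin(theta)``; zero at deposition."""
    L_C = np.asarray(L_C, dtype=float)
    if np.any(L_C < 1.0 - 1e-12):
        raise ValueError("cellulose extension must be at least 1")
    out = (L_C - 1.0) * np.sin(theta)
    return out if out.shape else float(out)


class _SteadyAssembly:
    """Cumulative steady-state integrand profiles for one parameter set.

    Caches the bond-survival profiles and, per structural term, the
    cumulative integral from the outer cut-off so that both the steady
    resultant and the expanding-region part of the transient come from a
    single quadrature pass.
    """

    def __init__(self, p: WallParameters, rtol: float = 1e-9):
        self.p = p
        self.sigma = sigma_H_of_y(p)
        self.profiles = CrosslinkProfiles(p, sigma=self.sigma)
        u_min = math.log(p.epsilon)
        T0 = p.theta0

        def term_fns(u):
            y = np.exp(u)
            lc = cellulose_extension(y, T0)
            sig_c = (lc - 1.0) * axial_projection(y, T0) if T0 > 0 else np.zeros_like(y)
            nh = self.profiles.n_hot(y)
            f1 = sig_c * y                       # dy = y du
            f2 = p.a1 * nh * sig_c * y
            f3 = p.a2 * self.profiles.n(y) * nh * self.sigma(y) * y
            return f1, f2, f3

        def build(n_panels):
            nodes, weights, edges = gauss_panels(u_min, 0.0, n_panels)
            fs = term_fns(nodes)
            cums = [np.concatenate(([0.0], np.cumsum(np.sum(f * weights, axis=1))))
                    for f in fs]
            return edges, cums

        def probe(obj):
            _, cums = obj
            return np.array([c[-1] for c in cums])

        edges, cums = refine_until(build, probe, rtol=rtol, n0=512)
        self._totals = [c[-1] for c in cums]
        # int_{y}^{1} = total - int_{eps}^{y}; near-flat stretches give
        # denormal slopes whose harmonic mean overflows harmlessly
        with np.errstate(over="ignore", divide="ignore"):
            self._cum_interp = [PchipInterpolator(edges, c) for c in cums]

    def steady_terms(self) -> tuple[float, float, float]:
        return tuple(self._totals)

    def expanding_terms(self, y_low: float) -> tuple[float, float, float]:
        u = math.log(min(max(y_low, self.p.epsilon), 1.0))
        return tuple(max(t - float(ci(u)), 0.0)
                     for t, ci in zip(self._totals, self._cum_interp))


@lru_cache(maxsize=32)
def _assembly(p: WallParameters) -> _SteadyAssembly:
    return _SteadyAssembly(p)


def _breakdown(p: WallParameters, terms) -> StressBreakdown:
    t1, t2, t3 = terms
    pectin = p.Gamma * p.alpha
    return StressBreakdown(t1, t2, t3, pectin, t1 + t2 + t3 + pectin)


def stress_resultant_steady(p: WallParameters) -> StressBreakdown:
    """Steady-state stress resultant over [epsilon, 1] plus the pectin term.

    With theta0 = 0 and a2 = 0 both fibre terms vanish and the resultant is
    the pectin contribution alone; at fixed other parameters the resultant
    grows with strain rate and plateaus once the hotspots saturate.
    """
    return _breakdown(p, _assembly(p).steady_terms())


def stress_resultant_time(t: float, p: WallParameters) -> StressBreakdown:
    """Transient stress resultant at time t since the onset of stretching.

    The thinning-region material (present at t = 0) contributes uniformly
    over a width ``exp(-alpha t) - eps`` (dropped once exhausted); material
    deposited later fills the expanding region above it.  Tends to the
    steady resultant as t grows.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    asm = _assembly(p)
    y_t = math.exp(-p.alpha * t)
    terms = list(asm.expanding_terms(y_t))
    width = y_t - p.epsilon
    if width > 0:
        # thinning-region fields: age t, extension exp(alpha t), survival
        # evaluated at the matching extension 1/L = y_t
        from .kinematics import cellulose_extension_time, fibre_angle
        L = 1.0 / y_t
        lc = cellulose_extension_time(t, p.theta0, p.alpha)
        sig_c = cellulose_stress(lc, fibre_angle(L, p.theta0))
        nh = float(asm.profiles.n_hot(y_t))
        nn = float(asm.profiles.n(y_t))
        sig_h = float(asm.sigma(y_t))
        terms[0] += width * sig_c
        terms[1] += width * p.a1 * nh * sig_c
        terms[2] += width * p.a2 * nn * nh * sig_h
    return _breakdown(p, terms)


def sweep_alpha(p: WallParameters, alphas, scenario: str = "alpha_sweep") -> pd.DataFrame:
    """Steady-state resultant across strain rates, as a tidy table.

    One row per alpha with the breakdown columns used by the CSV interface;
    deterministic row order follows the input sequence.
    """
    rows = []
    for a in alphas:
        if a <= 0:
            raise ValueError("strain rates must be strictly positive")
        pa = p.with_(alpha=float(a))
        b = stress_resultant_steady(pa)
        rows.append({
            "scenario": scenario, "alpha": float(a), "t": math.nan,
            "theta0": p.theta0, "beta_hot": p.beta_hot, "gamma": p.gamma,
            "E": p.E, "a1": p.a1, "Sigma": b.total,
            "Sigma_cellulose": b.sigma_C_term,
            "Sigma_hotcellulose": b.hotspot_cellulose_term,
            "Sigma_hotspot": b.hotspot_term,
            "Sigma_pectin": b.pectin_term,
        })
    return pd.DataFrame(rows)
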