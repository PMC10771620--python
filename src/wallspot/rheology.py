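"""Hemicellulose (Maxwell-element) stress under the three enzyme regimes.

Each hotspot's hemicellulose strands are Maxwell elements — a linear spring
(stress ``sigma_H``, equal to the elastic strain) in series with a dashpot of
viscosity ratio ``mu``.  The stress along a material characteristic obeys

    d(sigma_H)/dt + omega * sigma_H = ds/dt,   omega = omega0 / mu,

with ``s = L/L0 - 1`` the wall strain relative to the spring resting length.
Expansin may act by growing the resting length ``L0`` (stress relaxation by
slippage) or by lowering the dashpot viscosity towards ``1/M``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.signal import lfilter

__all__ = [
    "RheologyState",
    "sigma_H_base",
    "viscosity",
    "omega_of_age",
    "characteristic_path",
    "resting_length",
    "sigma_H_expansin_rest",
    "sigma_H_expansin_visc",
]


@dataclass(frozen=True)
class RheologyState:
    """Per-cohort rheological variables (all nondimensional)."""

    sigma_H: float   # hemicellulose stress = elastic strain
    mu: float        # dashpot viscosity ratio, in [1/M, 1]
    L0: float        # spring resting length ratio, in [1, L]
    omega: float     # omega0 / mu


def sigma_H_base(L, alpha: float, omega: float):
    """Enzyme-free hemicellulose stress as a function of extension.

    ``sigma_H = alpha/(alpha + omega) * (L - L^(-omega/alpha))``; zero at
    deposition (L = 1), tending to the purely elastic L - 1 as omega -> 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be strictly positive")
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    L = np.asarray(L, dtype=float)
    out = alpha / (alpha + omega) * (L - L ** (-omega / alpha))
    return out if out.shape else float(out)


def viscosity(t_since_deposition, E: float, M: float):
    """Dashpot viscosity ratio under expansin, ``1/(M + (1-M) e^(-E t))``.

    Starts at 1 at deposition and relaxes monotonically to 1/M.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    if E < 0:
        raise ValueError("E must be nonnegative")
    t = np.asarray(t_since_deposition, dtype=float)
    out = 1.0 / (M + (1.0 - M) * np.exp(-E * t))
    return out if out.shape else float(out)


def omega_of_age(t_since_deposition, omega0: float, M: float, E: float):
    """Maxwell rate ratio ``omega0 (M + (1-M) e^(-E t))`` under expansin."""
    t = np.asarray(t_since_deposition, dtype=float)
    out = omega0 * (M + (1.0 - M) * np.exp(-E * t))
    return out if out.shape else float(out)


def characteristic_path(alpha: float, t_end: float, dt: float | None = None):
    """Uniform material-age grid and extension along one characteristic.

    The default step is ``min(1e-3, 0.01/alpha)``, fine enough that the
    forward-difference resting length below is converged at the tolerances
    used in the stress assembly.
    """
    if dt is None:
        dt = min(1e-3, 0.01 / alpha)
    if dt <= 0:
        raise ValueError("step size must be strictly positive")
    n = max(2, int(math.ceil(t_end / dt)) + 1)
    t = np.linspace(0.0, t_end, n)
    return t, np.exp(alpha * t)


def resting_length(t, L, E: float):
    """Spring resting length along a characteristic by forward differencing.

    Integrates ``dL0/dt = E (L/L0 - 1)`` with L0(0) = 1 on the supplied grid;
    the result always satisfies ``1 <= L0 <= L``.
    """
    t = np.asarray(t, dtype=float)
    L = np.asarray(L, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("path grid must be strictly increasing with >= 2 samples")
    if E < 0:
        raise ValueError("E must be nonnegative")
    L0 = np.empty_like(L)
    L0[0] = 1.0
    if E == 0.0:
        L0[:] = 1.0
        return L0
    cur = 1.0
    for k in range(t.size - 1):
        # two-stage forward difference (explicit trapezoid)
        h = t[k + 1] - t[k]
        f0 = E * (L[k] / cur - 1.0)
        pred = cur + h * f0
        cur = cur + 0.5 * h * (f0 + E * (L[k + 1] / pred - 1.0))
        cur = min(max(cur, 1.0), L[k + 1])  # invariant 1 <= L0 <= L
        L0[k + 1] = cur
    return L0


def sigma_H_expansin_rest(t, L, alpha: float, omega: float, E: float,
                          L0=None):
    """Hemicellulose stress when expansin grows the spring resting length.

    Evaluates the integrating-factor solution of the Maxwell equation with
    strain ``s = L/L0 - 1`` along the characteristic, ``L0`` from
    :func:`resting_length` unless supplied.  Returned on the path grid.
    With E = 0 this is exactly the enzyme-free closed form.
    """
    t = np.asarray(t, dtype=float)
    L = np.asarray(L, dtype=float)
    if E == 0.0:
        return sigma_H_base(L, alpha, omega)
    if L0 is None:
        L0 = resting_length(t, L, E)
    s = L / np.asarray(L0, dtype=float) - 1.0
    # sigma_H(t) = s(t) - omega * int_0^t e^{-omega (t - t')} s(t') dt',
    # accumulated with the exponentially weighted trapezoid recurrence
    # I_k = a I_{k-1} + (dt/2)(a s_{k-1} + s_k), a = e^{-omega dt}.
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt):
        raise ValueError("path grid must be uniform")
    a = math.exp(-omega * dt)
    c = np.zeros_like(s)
    c[1:] = 0.5 * dt * (a * s[:-1] + s[1:])
    I = lfilter([1.0], [1.0, -a], c)
    return s - omega * I


def sigma_H_expansin_visc(y, alpha: float, omega0: float, M: float, E: float):
    """Hemicellulose stress when expansin lowers the dashpot viscosity.

    Steady expanding-region stress at position y, from the integrating-factor
    solution with ``omega(t) = omega0 (M + (1-M) e^(-E t))``:

        sigma_H(y) = int_y^1 (y/y')^(omega0 M / alpha) y'^(-2)
                     * exp(q (y'^(E/alpha) - y^(E/alpha))) dy',

    with ``q = omega0 (M-1) / E``.  Continuous with the enzyme-free form as
    E -> 0+ and identical to it when M = 1.
    """
    if E <= 0:
        raise ValueError(
            "E must be strictly positive; use sigma_H_base with omega = omega0 for E = 0")
    if M < 1:
        raise ValueError("M must be at least 1")
    p = omega0 * M / alpha
    q = omega0 * (M - 1.0) / E
    r = E / alpha

    def one(yv: float) -> float:
        yp = yv ** r

        def integrand(yh):
            return (yv / yh) ** p * yh ** -2.0 * np.exp(q * (yh ** r - yp))

        # log-position substitution keeps the integrand mild near small y
        def integrand_u(u):
            yh = np.exp(u)
            return integrand(yh) * yh

        val, _ = quad(integrand_u, math.log(yv), 0.0, limit=200,
                      epsabs=1e-12, epsrel=1e-11)
        return val

    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y > 1):
        raise ValueError("position y must lie in (0, 1]")
    if y.shape:
        return np.array([one(v) for v in y.ravel()]).reshape(y.shape)
    return one(float(y))
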