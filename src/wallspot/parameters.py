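"""Parameter sets for the cell-wall model and their nondimensionalisation.

The wall is described either by dimensional physical constants
(:class:`DimensionalParameters`) or by the nondimensional groups that fully
determine a simulation (:class:`WallParameters`).  Time is scaled with the
unstressed hotspot breakage rate, lengths with the wall thickness, and the
stress resultant with the cellulose stiffness density ``E* = nu_C * h * rho``.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Literal

__all__ = [
    "EnzymeMode",
    "DimensionalParameters",
    "WallParameters",
    "nondimensionalise",
    "table1_preset",
    "load_config",
]

EnzymeMode = Literal["none", "expansin_rest_length", "expansin_viscosity"]

_ENZYME_MODES = ("none", "expansin_rest_length", "expansin_viscosity")


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


@dataclass(frozen=True)
class DimensionalParameters:
    """Physical constants of the wall, SI units unless noted.

    ``mu0``/``mu1`` are the initial and target dashpot viscosities of the
    hemicellulose Maxwell elements; ``beta`` and ``gamma`` are the raw
    load-sensitivity parameters of hotspot and single-crosslink breakage.
    """

    nu_C: float = 140e9        # cellulose Young's modulus (Pa)
    nu_H: float = 7e9          # hemicellulose Young's modulus (Pa)
    mu0: float = 0.15          # initial dashpot viscosity (model units)
    mu1: float = 0.05          # target dashpot viscosity under expansin
    k0: float = 1.0            # unstressed hemicellulose breakage rate (1/s)
    k0_hot: float = 1.0        # unstressed hotspot breakage rate (1/s)
    n0: float = 1.0            # initial hemicellulose number per hotspot
    n0_hot: float = 1.0        # initial hotspot density
    rho: float = 2.0           # cellulose density (per n0*n0_hot/rho = 0.5)
    h: float = 1e-7            # wall thickness (m)
    A: float = 0.1             # cellulose crosslink stress modifier
    Gamma_dim: float = 0.0     # pectin stiffness density
    kappa: float = 2.0         # hemicellulose spring stiffness
    l0: float = 1.0            # hemicellulose resting length
    kbT: float = 1.0           # thermal energy
    E_dim: float = 0.0         # expansin action rate (1/s)
    beta: float = 0.01         # raw hotspot breakage sensitivity
    gamma: float = 0.05        # hemicellulose breakage sensitivity
    alpha_star: float = 1.0    # imposed strain rate (1/s)
    theta0: float = 0.1        # deposition angle (rad)

    def __post_init__(self) -> None:
        positive = (
            "nu_C", "nu_H", "mu0", "mu1", "k0", "k0_hot", "n0", "n0_hot",
            "rho", "h", "kappa", "l0", "kbT", "A", "alpha_star",
        )
        for name in positive:
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        for name in ("E_dim", "Gamma_dim", "beta", "gamma"):
            _require(getattr(self, name) >= 0, f"{name} must be nonnegative")
        _require(self.mu1 <= self.mu0, "mu1 must not exceed mu0")
        _require(self.beta < self.gamma or self.beta == self.gamma == 0.0,
                 "beta must be smaller than gamma (hotspots stronger than single crosslinks)")
        _require(0 <= self.theta0 < math.pi / 2, "theta0 must lie in [0, pi/2)")

    @property
    def stress_scale(self) -> float:
        """The stress-resultant scale ``E* = nu_C * h * rho``."""
        return self.nu_C * self.h * self.rho


@dataclass(frozen=True)
class WallParameters:
    """Nondimensional groups that fully determine a simulation.

    ``alpha`` is the strain rate relative to the unstressed hotspot breakage
    rate, ``omega0 = nu_H / (mu0 k0_hot)`` the elastic-to-viscous rate ratio
    of the Maxwell elements, ``beta_hot = sqrt(n0) beta`` and ``gamma`` the
    breakage sensitivities, ``a1`` the hotspot-cellulose crosslink modifier
    and ``a2`` the hemicellulose-to-cellulose stiffness-density ratio.
    """

    alpha: float = 1.0
    theta0: float = 0.1
    beta_hot: float = 0.01
    gamma: float = 0.05
    k0_ratio: float = 1.0
    varsigma: float = 1.0
    varsigma_hot: float = 1.0
    omega0: float = 1.0
    a1: float = 0.1
    a2: float = 0.025
    Gamma: float = 0.0
    epsilon: float = 1e-4
    M: float = 3.0
    E: float = 0.0
    enzyme_mode: EnzymeMode = "none"
    stress_scale: float = field(default=1.0, compare=False)

    def __post_init__(self) -> None:
        _require(self.alpha > 0, "alpha must be strictly positive")
        _require(0 <= self.theta0 < math.pi / 2, "theta0 must lie in [0, pi/2)")
        _require(0 < self.epsilon < 1, "epsilon must lie in (0, 1)")
        _require(self.M >= 1, "M = mu0/mu1 must be at least 1")
        for name in ("beta_hot", "gamma", "E", "Gamma", "a1", "a2",
                     "varsigma", "varsigma_hot"):
            _require(getattr(self, name) >= 0, f"{name} must be nonnegative")
        _require(self.k0_ratio > 0, "k0_ratio must be strictly positive")
        _require(self.omega0 > 0, "omega0 must be strictly positive")
        _require(self.enzyme_mode in _ENZYME_MODES,
                 f"enzyme_mode must be one of {_ENZYME_MODES}")

    @property
    def omega(self) -> float:
        """Maxwell rate ratio at deposition (mu = 1), constant when no enzyme acts."""
        return self.omega0

    def with_(self, **changes) -> "WallParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


def nondimensionalise(p: DimensionalParameters) -> WallParameters:
    """Reduce dimensional constants to the nondimensional groups.

    Rates are scaled with ``k0_hot``, so ``alpha = alpha*/k0_hot`` and
    ``k0_ratio = k0/k0_hot``; the breakage-energy constant is
    ``varsigma = kappa l0^2 / (2 kbT)``; the recorded ``stress_scale``
    re-dimensionalises the stress resultant via ``Sigma* = E* Sigma``.
    """
    E_star = p.stress_scale
    enzyme_mode: EnzymeMode = "none"
    E_nd = 0.0
    if p.E_dim > 0:
        # Dimensional expansin rate maps differently under the two mechanisms;
        # default to the viscosity scaling, overridable on the result.
        enzyme_mode = "expansin_viscosity"
        E_nd = p.E_dim / p.k0_hot
    return WallParameters(
        alpha=p.alpha_star / p.k0_hot,
        theta0=p.theta0,
        beta_hot=math.sqrt(p.n0) * p.beta,
        gamma=p.gamma,
        k0_ratio=p.k0 / p.k0_hot,
        varsigma=p.kappa * p.l0**2 / (2 * p.kbT),
        varsigma_hot=p.kappa * p.l0**2 / (2 * p.kbT),
        omega0=p.nu_H / (p.mu0 * p.k0_hot),
        a1=p.A * p.n0_hot,
        a2=p.n0 * p.n0_hot * p.nu_H / (p.rho * p.nu_C),
        Gamma=p.Gamma_dim * p.k0_hot / E_star,
        M=p.mu0 / p.mu1,
        E=E_nd,
        enzyme_mode=enzyme_mode,
        stress_scale=E_star,
    )


def table1_preset(**overrides) -> WallParameters:
    """The default nondimensional parameter set used throughout the study.

    theta0 = 0.1, k0_ratio = 1, varsigma = varsigma_hot = 1, epsilon = 1e-4,
    a1 = 0.1, a2 = 0.025, M = mu0/mu1 = 3 and Gamma = 0, with
    beta_hot = 0.01 and gamma = 0.05 as the baseline breakage sensitivities.
    omega0 defaults to 1 (order-unity Maxwell rate ratio); see the methods
    note for the rationale.
    """
    base = dict(
        alpha=1.0, theta0=0.1, beta_hot=0.01, gamma=0.05, k0_ratio=1.0,
        varsigma=1.0, varsigma_hot=1.0, omega0=1.0, a1=0.1, a2=0.025,
        Gamma=0.0, epsilon=1e-4, M=3.0, E=0.0, enzyme_mode="none",
    )
    base.update(overrides)
    return WallParameters(**base)


_WALL_FIELDS = {f.name for f in fields(WallParameters)}


def load_config(path: str | Path) -> tuple[WallParameters, dict]:
    """Read a TOML or JSON config with ``[params]`` and ``[scenario]`` blocks.

    All ``[params]`` keys are optional and mirror :class:`WallParameters`
    field names; missing values fall back to :func:`table1_preset`.  Returns
    the parameters and the raw scenario mapping (possibly empty).
    """
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = tomllib.loads(text.decode())
    raw = data.get("params", {})
    unknown = set(raw) - _WALL_FIELDS
    if unknown:
        raise ParameterError(
            f"unknown [params] keys {sorted(unknown)}; valid keys are {sorted(_WALL_FIELDS)}")
    return table1_preset(**raw), data.get("scenario", {})
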