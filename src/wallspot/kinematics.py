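"""Material transport through the wall thickness.

Material moves along characteristics ``y = y_i exp(-alpha (t - tau))`` of the
incompressible flow, stretching axially at the imposed strain rate.  Two
material families coexist: the *thinning* region ``y <= exp(-alpha t)``
(material already present at t = 0, extension uniform in y) and the
*expanding* region (material deposited at the inner surface at tau > 0, whose
extension is fixed by its position, ``L = 1/y``).

Cellulose fibres are deposited at angle ``theta0`` from the transverse axis
and reorient with the flow; their angle depends on position only through the
segment extension, ``theta = arctan(tan(theta0) L)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "MaterialState",
    "segment_extension",
    "fibre_angle",
    "axial_projection",
    "cellulose_extension",
    "cellulose_extension_time",
]

Region = Literal["thinning", "expanding"]


@dataclass(frozen=True)
class MaterialState:
    """Snapshot of a material cohort along its characteristic."""

    y: float
    t: float
    tau: float
    L: float
    theta: float
    L_C: float
    region: Region


def segment_extension(y, t: float = 0.0, region: Region = "expanding",
                      alpha: float = 1.0):
    """Extension ratio of a wall segment.

    Expanding-region material is stretched in inverse proportion to its
    position (``L = 1/y``); thinning-region material extends uniformly as
    ``exp(alpha t)`` regardless of position.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("position y must lie in [0, 1]")
    if region == "expanding":
        return 1.0 / y
    if region == "thinning":
        return np.broadcast_to(np.exp(alpha * t), y.shape).copy() if y.shape \
            else float(np.exp(alpha * t))
    raise ValueError(f"unknown region {region!r}")


def fibre_angle(L, theta0: float):
    """Cellulose angle from the transverse axis, ``arctan(tan(theta0) L)``.

    Monotone increasing in the extension and saturating at pi/2 as the
    fibres become fully axial.  ``theta0 = 0`` pins the fibres transverse
    for all time.
    """
    if not 0 <= theta0 < math.pi / 2:
        raise ValueError("theta0 must lie in [0, pi/2)")
    return np.arctan(np.tan(theta0) * np.asarray(L, dtype=float))


def axial_projection(y, theta0: float):
    """``sin(theta)`` at position y in the expanding region, evaluated stably.

    Uses ``sin(arctan(tan(theta0)/y)) = tan(theta0)/sqrt(tan^2(theta0)+y^2)``.
    """
    T = math.tan(theta0)
    y = np.asarray(y, dtype=float)
    return T / np.sqrt(T * T + y * y)


def _log_LC(y, T: float):
    """log L_C in the expanding region; elementary antiderivative of
    sin^2(theta(y'))/y' with theta = arctan(T/y')."""
    y = np.asarray(y, dtype=float)
    return 0.5 * (np.log(T * T + y * y) - math.log(T * T + 1.0)) - np.log(y)


def cellulose_extension(y, theta0: float):
    """Steady-state cellulose extension ratio in the expanding region.

    ``L_C(y) = exp(int_y^1 sin^2(theta(y'))/y' dy')`` with
    ``theta(y') = arctan(tan(theta0)/y')``; evaluated in closed form as
    ``sqrt(tan^2(theta0) + y^2) / (y sqrt(tan^2(theta0) + 1))``.
    L_C(1) = 1 and L_C grows monotonically towards the outer wall, reaching
    the co-stretching limit 1/y for fully axial fibres.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y > 1):
        raise ValueError("position y must lie in (0, 1]")
    if theta0 == 0.0:
        return np.ones_like(y) if y.shape else 1.0
    out = np.exp(_log_LC(y, math.tan(theta0)))
    return out if out.shape else float(out)


def cellulose_extension_time(t, theta0: float, alpha: float = 1.0):
    """Cellulose extension of thinning-region material after time t.

    Same integral as :func:`cellulose_extension` under the change of
    variables ``y = exp(-alpha t)``, so the two families agree where their
    extensions match.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if theta0 == 0.0:
        return np.ones_like(t) if t.shape else 1.0
    out = np.exp(_log_LC(np.exp(-alpha * t), math.tan(theta0)))
    return out if out.shape else float(out)
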