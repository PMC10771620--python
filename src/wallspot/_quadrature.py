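"""Quadrature helpers shared across modules.

Most wall-profile integrals are taken in the log-position variable
``u = ln y`` where the integrands are smooth; cumulative values at panel
boundaries are accumulated from composite fixed-order Gauss-Legendre rules,
which keeps nested integrals (hotspot survival inside the stress resultant)
at linear cost.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EXP_CLAMP", "clamped_exp", "gauss_panels", "cumulative_gauss",
           "suffix_cumulative_gauss", "refine_until"]

# exp() argument cap: large enough that bond survival already underflows to
# zero at the cap, small enough to keep panel sums finite in double precision.
EXP_CLAMP = 350.0


def clamped_exp(x):
    """exp with the argument clipped at EXP_CLAMP; overflow-free."""
    return np.exp(np.minimum(x, EXP_CLAMP))


def gauss_panels(a: float, b: float, n_panels: int, order: int = 6):
    """Nodes and weights of a composite Gauss-Legendre rule on [a, b].

    Returns ``(nodes, weights, edges)`` where nodes/weights are shaped
    ``(n_panels, order)`` and ``edges`` are the n_panels+1 panel boundaries.
    """
    x, w = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(a, b, n_panels + 1)
    half = 0.5 * (edges[1:] - edges[:-1])
    mid = 0.5 * (edges[1:] + edges[:-1])
    nodes = mid[:, None] + half[:, None] * x[None, :]
    weights = half[:, None] * w[None, :]
    return nodes, weights, edges


def cumulative_gauss(f, a: float, b: float, n_panels: int, order: int = 6):
    """Cumulative integral of ``f`` from ``a`` to each panel edge of [a, b].

    ``f`` must accept an ndarray.  Returns ``(edges, cumulative)`` with
    ``cumulative[0] = 0`` and ``cumulative[-1] = int_a^b f``.
    """
    nodes, weights, edges = gauss_panels(a, b, n_panels, order)
    panel_sums = np.sum(f(nodes) * weights, axis=1)
    cum = np.concatenate(([0.0], np.cumsum(panel_sums)))
    return edges, cum


def suffix_cumulative_gauss(f, a: float, b: float, n_panels: int, order: int = 6):
    """Integral of ``f`` from each panel edge of [a, b] up to ``b``.

    Accumulated from the top edge downward, so edges near ``b`` keep full
    relative precision even when the integrand explodes towards ``a``
    (a prefix cumulative would cancel catastrophically there).
    """
    nodes, weights, edges = gauss_panels(a, b, n_panels, order)
    panel_sums = np.sum(f(nodes) * weights, axis=1)
    tail = np.concatenate((np.cumsum(panel_sums[::-1])[::-1], [0.0]))
    return edges, tail


def refine_until(compute, probe, rtol: float = 1e-9, n0: int = 256,
                 n_max: int = 1 << 16):
    """Double a panel count until a probe functional of the result settles.

    ``compute(n)`` builds the object at resolution n; ``probe(obj)`` maps it
    to an ndarray compared between successive refinements.  Returns the
    finest object computed.
    """
    n = n0
    obj = compute(n)
    ref = np.asarray(probe(obj), dtype=float)
    while n < n_max:
        n *= 2
        nxt = compute(n)
        val = np.asarray(probe(nxt), dtype=float)
        err = np.max(np.abs(val - ref) / (1.0 + np.abs(val)))
        obj, ref = nxt, val
        if err < rtol:
            break
    return obj
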