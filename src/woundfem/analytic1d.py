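"""Closed-form 1D displacement solutions.

On ``(0, L)`` with zero boundary displacement the balance of momentum reduces
(for unit stiffness) to the Poisson problem ``-u'' = f``.  Three exact
solutions are available:

* :func:`u1_exact` — the smoothed-particle solution: a superposition of erf
  profiles, one per cell, each solving the dipole forcing of a single
  Gaussian mollifier plus the linear correction that restores the boundary
  conditions.
* :func:`u2_exact` — the continuum solution for a cell density concentrated
  on a subdomain ``(a, b)``: a difference of two Dirichlet Green's-function
  kernels, piecewise linear in ``x``.
* :func:`u_limit_piecewise` — the explicit three-branch piecewise-linear
  limit of the particle solution as the cell spacing tends to zero, equal to
  :func:`u2_exact` identically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .cells import CellConfig1D

__all__ = ["Domain1D", "greens_G", "u2_exact", "u1_exact", "u_limit_piecewise"]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class Domain1D:
    """Computational domain ``(0, L)`` with the wound subdomain ``(a, b)``."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0 < self.a < self.b < self.L):
            raise ValueError("need 0 < a < b < L")


def greens_G(x, xp: float, L: float):
    """Dirichlet Green's function of ``-d^2/dx^2`` on ``(0, L)``:
    ``G(x, x') = (1 - x'/L) x - max(x - x', 0)``; vanishes at both ends and is
    symmetric in its arguments."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > L):
        raise ValueError("evaluation point outside [0, L]")
    if not (0 < xp < L):
        raise ValueError("source point must lie strictly inside (0, L)")
    return (1.0 - xp / L) * x - np.maximum(x - xp, 0.0)


def u2_exact(x, P: float, dom: Domain1D, scale: float = 1.0):
    """Continuum (cell-density) displacement ``scale * P * (G(x,a) - G(x,b))``.

    ``scale`` carries the constant cell density on ``(a, b)`` when the density
    is not normalised to one (e.g. ``Ns / (b - a)`` for ``Ns`` cells).
    """
    return scale * P * (greens_G(x, dom.a, dom.L) - greens_G(x, dom.b, dom.L))


def u1_exact(
    x,
    cells: CellConfig1D,
    variance_len: float,
    L: float,
    magnitude_mode: str = "fem",
):
    """Smoothed-particle displacement as a superposition of erf profiles.

    Parameters
    ----------
    cells : CellConfig1D
        Cell positions and the force constant ``P``.
    variance_len : float
        Spread of the Gaussian mollifier (a standard deviation): the cell
        spacing ``ds`` in ``"eq5"`` mode, the mollifier width ``eps`` in
        ``"fem"`` mode.
    magnitude_mode : {"eq5", "fem"}
        ``"eq5"``: force prefactor ``P * ds`` (the scaling under which the
        particle solution converges to the continuum one as ``ds -> 0``).
        ``"fem"``: prefactor ``P`` — the exact solution of the boundary value
        problem the finite-element assembly discretises.
    """
    if not variance_len > 0:
        raise ValueError("mollifier spread must be positive")
    if cells.count == 0:
        raise ValueError("need at least one cell")
    if magnitude_mode not in ("eq5", "fem"):
        raise ValueError("magnitude_mode must be 'eq5' or 'fem'")
    w = variance_len
    pref = cells.P * (w if magnitude_mode == "eq5" else 1.0)
    x = np.asarray(x, dtype=float)
    s = cells.positions[..., None] if x.ndim else cells.positions
    terms = 0.5 * (
        (x / L - 1.0) * erf(s / (_SQRT2 * w))
        + (x / L) * erf((L - s) / (_SQRT2 * w))
        - erf((x - s) / (_SQRT2 * w))
    )
    return pref * terms.sum(axis=0)


def u_limit_piecewise(x, P: float, dom: Domain1D):
    """Piecewise-linear limit of the particle solution as the spacing -> 0.

    Equal to ``P * ((b-a) x / L - clip(x-a, 0, b-a))``: linear up to ``a``,
    descending through the wound, linear back to zero at ``L``.  Coincides
    with :func:`u2_exact` (scale 1) at every point.
    """
    x = np.asarray(x, dtype=float)
    return P * ((dom.b - dom.a) * x / dom.L - np.clip(x - dom.a, 0.0, dom.b - dom.a))
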