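"""Gaussian mollifiers and their masses and dipoles.

A biological cell pulling on the extracellular matrix is modelled as a
regularised force dipole: the derivative (1D) or gradient (2D) of a narrow
Gaussian of standard deviation ``epsilon`` centred at the cell.  Everything
the force assemblies need from that kernel reduces to *masses* — integrals of
the Gaussian over mesh elements — which this module evaluates exactly (erf in
1D, separable erf products for rectangles) or to a requested tolerance
(divergence-theorem edge quadrature for general polygons/triangles).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import erf, ndtr

__all__ = [
    "Mollifier1D",
    "Mollifier2D",
    "gauss1d",
    "dipole_1d",
    "interval_mass_1d",
    "gauss2d",
    "ball_mass_2d",
    "region_mass_2d",
]

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)

#: beyond this many standard deviations the residual Gaussian mass is below
#: double precision resolution (exp(-50) ~ 2e-22), so regions are skipped.
_TAIL_CUTOFF = 10.0


@dataclass(frozen=True)
class Mollifier1D:
    """Gaussian approximation of the Dirac delta on the line.

    Parameters
    ----------
    epsilon : float
        Standard deviation of the Gaussian (the mollifier width).
    mu : float
        Centre of the kernel, i.e. the cell position.
    """

    epsilon: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"mollifier width must be positive, got {self.epsilon}")


@dataclass(frozen=True)
class Mollifier2D:
    """Isotropic bivariate Gaussian delta approximation.

    ``epsilon`` is the common standard deviation of both coordinates and
    ``center`` the cell position.  The mass inside any ball of radius ``R``
    about the centre is ``1 - exp(-R^2 / (2 eps^2))``.
    """

    epsilon: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"mollifier width must be positive, got {self.epsilon}")
        c = np.asarray(self.center, dtype=float).reshape(2)
        object.__setattr__(self, "center", (float(c[0]), float(c[1])))


def gauss1d(x, m: Mollifier1D):
    """Evaluate the 1D Gaussian kernel ``(1/sqrt(2 pi eps^2)) exp(-(x-mu)^2/(2 eps^2))``."""
    x = np.asarray(x, dtype=float)
    z = (x - m.mu) / m.epsilon
    return np.exp(-0.5 * z * z) / (m.epsilon * _SQRT2PI)


def dipole_1d(x, m: Mollifier1D):
    """Derivative of :func:`gauss1d` — the regularised force dipole. Odd about ``mu``."""
    x = np.asarray(x, dtype=float)
    return -(x - m.mu) / m.epsilon**2 * gauss1d(x, m)


def interval_mass_1d(l, r, m: Mollifier1D):
    """Exact Gaussian mass of the interval ``[l, r]`` via the error function.

    Returns ``(erf((r-mu)/(sqrt(2) eps)) - erf((l-mu)/(sqrt(2) eps))) / 2``.
    """
    l = np.asarray(l, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(l > r):
        raise ValueError("invalid interval: left endpoint exceeds right endpoint")
    s = _SQRT2 * m.epsilon
    return 0.5 * (erf((r - m.mu) / s) - erf((l - m.mu) / s))


def gauss2d(points, m: Mollifier2D):
    """Evaluate the bivariate Gaussian kernel at ``points`` of shape (..., 2)."""
    p = np.asarray(points, dtype=float)
    d = p - np.asarray(m.center)
    r2 = np.sum(d * d, axis=-1)
    return np.exp(-0.5 * r2 / m.epsilon**2) / (2.0 * math.pi * m.epsilon**2)


def ball_mass_2d(R, m: Mollifier2D):
    """Mass of the bivariate Gaussian inside a ball of radius ``R`` about its centre.

    Closed form ``1 - exp(-R^2 / (2 eps^2))``; monotone in ``R`` with limit 1.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("ball radius must be nonnegative")
    return -np.expm1(-0.5 * (R / m.epsilon) ** 2)


# --- polygon masses -------------------------------------------------------
#
# For a polygon P and the standard bivariate Gaussian, the divergence theorem
# applied to the field F = (0, phi(x) Phi(y)) (with div F = phi(x) phi(y))
# turns the area integral into 1D edge integrals:
#
#   mass(P) = sum_edges  -(x1 - x0) * int_0^1 phi(x(t)) Phi(y(t)) dt
#
# for a counter-clockwise vertex ordering.  Each edge integrand is smooth, so
# adaptive Gauss-Kronrod quadrature reaches the requested tolerance cheaply.


def _phi(x: float) -> float:
    return math.exp(-0.5 * x * x) / _SQRT2PI


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _point_in_polygon(v: np.ndarray) -> bool:
    """Crossing-number test for the origin against polygon ``v``."""
    inside = False
    n = len(v)
    for i in range(n):
        x0, y0 = v[i]
        x1, y1 = v[(i + 1) % n]
        if (y0 > 0.0) != (y1 > 0.0):
            xc = x0 + (0.0 - y0) / (y1 - y0) * (x1 - x0)
            if xc > 0.0:
                inside = not inside
    return inside


def _min_dist_origin(v: np.ndarray) -> float:
    """Distance from the origin to polygon ``v`` (0 if the origin is inside)."""
    if _point_in_polygon(v):
        return 0.0
    best = math.inf
    n = len(v)
    for i in range(n):
        p0 = v[i]
        d = v[(i + 1) % n] - p0
        denom = float(d @ d)
        t = 0.0 if denom == 0.0 else min(1.0, max(0.0, float(-(p0 @ d)) / denom))
        q = p0 + t * d
        best = min(best, math.hypot(q[0], q[1]))
    return best


def _polygon_mass_std(v: np.ndarray, tol: float) -> float:
    """Standard-Gaussian mass of the polygon ``v`` (already in sigma units)."""
    if _min_dist_origin(v) > _TAIL_CUTOFF:
        return 0.0
    total = 0.0
    n = len(v)
    eps_edge = tol / max(3, n)
    for i in range(n):
        x0, y0 = v[i]
        x1, y1 = v[(i + 1) % n]
        dx, dy = x1 - x0, y1 - y0
        if dx == 0.0:
            continue
        # phi(x) bounds the integrand: skip edges entirely in the x-tail,
        # and edges whose y stays deep in the lower Phi-tail.
        if min(abs(x0), abs(x1)) > _TAIL_CUTOFF and x0 * x1 > 0:
            continue
        if max(y0, y1) < -_TAIL_CUTOFF:
            continue
        val, _ = integrate.quad(
            lambda t: _phi(x0 + t * dx) * ndtr(y0 + t * dy),
            0.0,
            1.0,
            epsabs=eps_edge,
            epsrel=1e-10,
            limit=200,
        )
        total -= dx * val
    return min(max(total, 0.0), 1.0)


def region_mass_2d(region, m: Mollifier2D, tol: float = 1e-10) -> float:
    """Gaussian mass of a rectangle or simple polygon (e.g. a mesh triangle).

    Parameters
    ----------
    region : array-like
        Either a ``(2, 2)`` array ``[[xmin, ymin], [xmax, ymax]]`` describing
        an axis-aligned rectangle (evaluated exactly as a product of two
        interval masses), or a ``(k, 2)`` array of polygon vertices, k >= 3.
    m : Mollifier2D
        The kernel.
    tol : float
        Absolute tolerance for the polygon quadrature.

    A degenerate (zero-area) region yields mass 0 with a warning.
    """
    if not tol > 0:
        raise ValueError("tolerance must be positive")
    v = np.asarray(region, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
        raise ValueError("region must be (2,2) rectangle corners or (k>=3,2) polygon vertices")
    cx, cy = m.center
    if v.shape[0] == 2:
        (x0, y0), (x1, y1) = v
        if x1 < x0 or y1 < y0:
            raise ValueError("rectangle corners must be [[xmin,ymin],[xmax,ymax]]")
        if x1 == x0 or y1 == y0:
            warnings.warn("degenerate region with zero area; mass is 0", stacklevel=2)
            return 0.0
        s = m.epsilon
        mx = ndtr((x1 - cx) / s) - ndtr((x0 - cx) / s)
        my = ndtr((y1 - cy) / s) - ndtr((y0 - cy) / s)
        return float(mx * my)
    w = (v - np.array([cx, cy])) / m.epsilon
    a = _signed_area(w)
    if a == 0.0:
        warnings.warn("degenerate region with zero area; mass is 0", stacklevel=2)
        return 0.0
    if a < 0.0:
        w = w[::-1]
    return _polygon_mass_std(w, tol)
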