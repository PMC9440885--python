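"""Diagnostics: norms, RMS nodal error, convergence rates, contraction ratios
and the consistency gap between the two force models.

All norms integrate the P1 interpolant exactly element-by-element (no
quadrature error): on an interval ``(h/3)(a^2 + ab + b^2)``, on a triangle
``(A/12)[(sum u_i)^2 + sum u_i^2]`` per component; gradients are constant per
element for the H1 seminorm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fem1d import DisplacementField1D
from .fem2d import DisplacementField2D

__all__ = [
    "ReductionReport",
    "ConvergenceReport",
    "GapNorms",
    "l2_norm",
    "h1_seminorm",
    "h1_norm",
    "rms_error",
    "convergence_rate",
    "nested_difference_norms",
    "reduction_ratio_1d",
    "area_reduction_2d",
    "shoelace_area",
    "consistency_gap",
]


@dataclass(frozen=True)
class ReductionReport:
    """Shrinkage of the wound subdomain under the displacement field."""

    original_measure: float
    deformed_measure: float

    @property
    def reduction_percent(self) -> float:
        return 100.0 * (self.original_measure - self.deformed_measure) / self.original_measure

    @property
    def relative_percent(self) -> float:
        return 100.0 - self.reduction_percent


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-level norms on nested meshes (h, h/2, h/4, ...) and the estimated
    order from norms of successive solution differences."""

    mesh_sizes: tuple
    level_norms: tuple
    difference_norms: tuple
    rate: float


@dataclass(frozen=True)
class GapNorms:
    """Norms of the difference between the particle and density solutions."""

    l2: float
    sup: float
    h1: float


# --- norms ----------------------------------------------------------------


def _l2sq_1d(field: DisplacementField1D) -> float:
    u = field.values
    h = field.mesh.h
    return float((h / 3.0) * np.sum(u[:-1] ** 2 + u[:-1] * u[1:] + u[1:] ** 2))


def _l2sq_2d(field: DisplacementField2D) -> float:
    total = 0.0
    for c in range(2):
        u = field.values[field.mesh.triangles, c]  # (M, 3)
        total += float(np.sum(field.mesh.areas / 12.0 * (u.sum(axis=1) ** 2 + (u**2).sum(axis=1))))
    return total


def l2_norm(field) -> float:
    """Exact L2 norm of the P1 interpolant (components summed in quadrature)."""
    if isinstance(field, DisplacementField1D):
        return np.sqrt(_l2sq_1d(field))
    if isinstance(field, DisplacementField2D):
        return np.sqrt(_l2sq_2d(field))
    raise TypeError("expected a 1D or 2D displacement field")


def h1_seminorm(field) -> float:
    """Exact H1 seminorm — element-wise constant gradients."""
    if isinstance(field, DisplacementField1D):
        du = np.diff(field.values) / field.mesh.h
        return float(np.sqrt(np.sum(field.mesh.h * du**2)))
    if isinstance(field, DisplacementField2D):
        total = 0.0
        for c in range(2):
            u = field.values[field.mesh.triangles, c]
            grad = np.einsum("ki,kid->kd", u, field.mesh.grads)
            total += float(np.sum(field.mesh.areas * (grad**2).sum(axis=1)))
        return float(np.sqrt(total))
    raise TypeError("expected a 1D or 2D displacement field")


def h1_norm(field) -> float:
    """Full H1 norm: sqrt(L2^2 + seminorm^2); never below the L2 norm."""
    return float(np.sqrt(l2_norm(field) ** 2 + h1_seminorm(field) ** 2))


def rms_error(field: DisplacementField1D, reference) -> float:
    """Root-mean-square nodal difference against a callable exact solution,
    averaged over all mesh nodes (boundary included)."""
    x = field.mesh.nodes
    diff = np.asarray(reference(x), dtype=float) - field.values
    return float(np.sqrt(np.mean(diff**2)))


# --- convergence ----------------------------------------------------------


def convergence_rate(diff_coarse: float, diff_fine: float) -> float:
    """Observed order ``log2(||u_h - u_{h/2}|| / ||u_{h/2} - u_{h/4}||)``."""
    if diff_fine == 0:
        raise ZeroDivisionError("undefined rate: zero fine-level difference norm")
    return float(np.log2(diff_coarse / diff_fine))


def nested_difference_norms(fields) -> tuple:
    """L2 norms of successive differences, all measured on the finest mesh.

    ``fields`` are solutions on nested meshes, coarse first; each is
    interpolated to the finest mesh's nodes (exact for nested P1 spaces at
    nodes) before subtracting.
    """
    fields = list(fields)
    if len(fields) < 2:
        raise ValueError("need at least two nested solutions")
    fine = fields[-1]
    if isinstance(fine, DisplacementField1D):
        nodes = fine.mesh.nodes
        nodal = [f(nodes) for f in fields]
        make = lambda v: DisplacementField1D(fine.mesh, v)
    else:
        nodes = fine.mesh.points
        nodal = [f(nodes) for f in fields]
        make = lambda v: DisplacementField2D(fine.mesh, v)
    return tuple(l2_norm(make(b - a)) for a, b in zip(nodal[:-1], nodal[1:]))


# --- contraction ratios ---------------------------------------------------


def reduction_ratio_1d(field: DisplacementField1D, a: float, b: float) -> ReductionReport:
    """Relative shrinkage of ``(a, b)`` from the interpolated endpoint
    displacements: deformed length ``(b + u(b)) - (a + u(a))``."""
    if not a < b:
        raise ValueError("need a < b")
    ua, ub = field(a), field(b)
    deformed = (b + ub) - (a + ua)
    if deformed <= 0:
        raise ValueError("deformed subdomain is inverted")
    return ReductionReport(original_measure=b - a, deformed_measure=float(deformed))


def shoelace_area(ring: np.ndarray) -> float:
    """Signed polygon area of a ring of vertices (not closed)."""
    v = np.asarray(ring, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def area_reduction_2d(deformed: np.ndarray, original: np.ndarray) -> ReductionReport:
    """Wound-area shrinkage from shoelace areas of the sampled polygons."""
    a0 = shoelace_area(original)
    a1 = shoelace_area(deformed)
    if a0 * a1 < 0:
        warnings.warn("deformed polygon changed orientation; using signed areas", stacklevel=2)
    return ReductionReport(original_measure=abs(a0), deformed_measure=abs(a1))


# --- consistency gap ------------------------------------------------------


def consistency_gap(u_sp, u_den) -> GapNorms:
    """L2, sup and H1 norms of the particle-vs-density nodal difference field."""
    if type(u_sp) is not type(u_den):
        raise ValueError("fields must be of the same dimensionality")
    if isinstance(u_sp, DisplacementField1D):
        if not u_sp.mesh.compatible_with(u_den.mesh):
            raise ValueError("fields live on incompatible meshes")
        diff = DisplacementField1D(u_sp.mesh, u_sp.values - u_den.values)
        sup = float(np.max(np.abs(diff.values)))
    else:
        if not u_sp.mesh.compatible_with(u_den.mesh):
            raise ValueError("fields live on incompatible meshes")
        diff = DisplacementField2D(u_sp.mesh, u_sp.values - u_den.values)
        sup = float(np.max(np.linalg.norm(diff.values, axis=1)))
    return GapNorms(l2=l2_norm(diff), sup=sup, h1=h1_norm(diff))
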