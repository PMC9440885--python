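"""P1 finite elements for ``-u'' = f`` on ``(0, L)`` with zero boundary values.

Two forcings are assembled, both in the integrated-by-parts form (kernel
against the *derivative* of the hat function), which is exact because the hat
derivatives are constant per element:

* smoothed-particle: ``F_j = -P * sum_i sum_e (phi_j'|_e) * mass_i(e)`` with
  the per-element Gaussian masses evaluated by erf;
* cell density: ``F_j = -P * sum_e n_c(e) * (phi_j'|_e) * h``, exact for a
  piecewise-constant density.

Because both load vectors are integrated exactly, the discrete solution is
*nodally exact*: it agrees with the closed-form solution of the same
continuous problem at every mesh node (a special property of 1D P1 elements).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import ndtr

from .cells import CellConfig1D, DensityField1D
from .meshes import Mesh1D

__all__ = [
    "DisplacementField1D",
    "assemble_stiffness_1d",
    "load_sp_1d",
    "load_density_1d",
    "solve_1d",
    "evaluate_1d",
]


@dataclass
class DisplacementField1D:
    """Nodal displacement on a :class:`Mesh1D`; piecewise-linear in between."""

    mesh: Mesh1D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != self.mesh.n_nodes:
            raise ValueError("need one displacement value per mesh node")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > self.mesh.L):
            raise ValueError("evaluation point outside [0, L]")
        return np.interp(x, self.mesh.nodes, self.values)


def assemble_stiffness_1d(mesh: Mesh1D) -> sp.csr_matrix:
    """Unconstrained tridiagonal stiffness matrix: interior stencil
    ``(-1/h, 2/h, -1/h)``; rows sum to zero (constants in the kernel)."""
    n = mesh.n_nodes
    h = mesh.h
    main = np.full(n, 2.0 / h)
    main[0] = main[-1] = 1.0 / h
    off = np.full(n - 1, -1.0 / h)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def load_sp_1d(mesh: Mesh1D, cells: CellConfig1D, epsilon: float) -> np.ndarray:
    """Smoothed-particle load vector from exact per-element Gaussian masses.

    Self-equilibrated: entries sum to zero to rounding because each cell's
    element masses enter once with each sign through the hat derivatives.
    """
    if not epsilon > 0:
        raise ValueError("mollifier width must be positive")
    s = cells.positions
    if np.any(s <= 0) or np.any(s >= mesh.L):
        raise ValueError("cell positions must lie strictly inside (0, L)")
    # CDF of each cell's Gaussian at every node -> per-element masses.
    C = ndtr((mesh.nodes[None, :] - s[:, None]) / epsilon)
    mass = (C[:, 1:] - C[:, :-1]).sum(axis=0)  # (n_elements,)
    F = np.zeros(mesh.n_nodes)
    coef = cells.P / mesh.h
    F[:-1] += coef * mass  # right element of node j: phi_j' = -1/h
    F[1:] -= coef * mass  # left element of node j: phi_j' = +1/h
    return F


def load_density_1d(mesh: Mesh1D, density: DensityField1D, P: float) -> np.ndarray:
    """Cell-density load vector, exact for the piecewise-constant density."""
    if not mesh.compatible_with(density.mesh):
        raise ValueError("density field lives on an incompatible mesh")
    n = density.values
    F = np.zeros(mesh.n_nodes)
    F[:-1] += P * n
    F[1:] -= P * n
    return F


def solve_1d(mesh: Mesh1D, load: np.ndarray) -> DisplacementField1D:
    """Sparse direct solve with homogeneous Dirichlet ends (exact zeros)."""
    load = np.asarray(load, dtype=float)
    if len(load) != mesh.n_nodes:
        raise ValueError("load vector size does not match the mesh")
    K = assemble_stiffness_1d(mesh)
    interior = np.arange(1, mesh.n_nodes - 1)
    u = np.zeros(mesh.n_nodes)
    Kii = K[interior][:, interior].tocsc()
    u[interior] = spla.spsolve(Kii, load[interior])
    return DisplacementField1D(mesh, u)


def evaluate_1d(field: DisplacementField1D, x):
    """Piecewise-linear interpolation of the nodal values at ``x``."""
    return field(x)
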