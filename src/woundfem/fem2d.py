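"""P1 triangular finite elements for plane-strain linear elasticity.

The static Navier-Cauchy balance ``-div(sigma) = f`` is discretised with
constant-strain triangles under the isotropic plane-strain Hooke law

    sigma = E/(1+nu) * [ eps + tr(eps) * nu/(1-2 nu) * I ],

homogeneous Dirichlet conditions on the outer boundary, and one of two body
forces: the smoothed-particle sum of Gaussian force dipoles, or the
divergence of the piecewise-constant cell-density tensor ``P * n_c * I``.
Both loads are assembled in the integrated-by-parts (divergence) form, where
``div(phi)`` is constant per triangle, so only per-triangle Gaussian masses
(SP) or exact density integrals are needed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cells import CellConfig2D, DensityField2D
from .kernels import Mollifier2D, region_mass_2d
from .meshes import TriMesh, structured_trimesh  # noqa: F401  (re-export)

__all__ = [
    "ElasticParams",
    "WoundGeometry",
    "DisplacementField2D",
    "structured_trimesh",
    "assemble_stiffness_2d",
    "load_sp_2d",
    "load_density_2d",
    "solve_2d",
    "deformed_boundary",
]


@dataclass(frozen=True)
class ElasticParams:
    """Isotropic material: Young's modulus ``E`` and Poisson ratio ``nu``."""

    E: float = 1.0
    nu: float = 0.49

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError("Young's modulus must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must satisfy 0 <= nu < 0.5 (incompressible limit excluded)")


@dataclass(frozen=True)
class WoundGeometry:
    """Outer tissue rectangle and the wound rectangle strictly inside it."""

    omega: tuple
    wound: tuple

    def __post_init__(self) -> None:
        (X0, Y0), (X1, Y1) = np.asarray(self.omega, dtype=float)
        (w0, v0), (w1, v1) = np.asarray(self.wound, dtype=float)
        if not (X0 < w0 < w1 < X1 and Y0 < v0 < v1 < Y1):
            raise ValueError("wound rectangle must lie strictly inside the tissue domain")

    @property
    def wound_corners(self) -> np.ndarray:
        """Corners of the wound boundary, counter-clockwise, not closed."""
        (w0, v0), (w1, v1) = np.asarray(self.wound, dtype=float)
        return np.array([[w0, v0], [w1, v0], [w1, v1], [w0, v1]])

    @property
    def wound_area(self) -> float:
        (w0, v0), (w1, v1) = np.asarray(self.wound, dtype=float)
        return float((w1 - w0) * (v1 - v0))


@dataclass
class DisplacementField2D:
    """Nodal displacement vectors (N, 2) on a :class:`TriMesh`."""

    mesh: TriMesh
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1, 2)
        if len(self.values) != self.mesh.n_nodes:
            raise ValueError("need one displacement vector per mesh node")

    def __call__(self, points):
        """Piecewise-linear interpolation at ``points`` of shape (..., 2)."""
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(-1, 2)
        tri = self.mesh.trifinder(flat[:, 0], flat[:, 1])
        tri = np.asarray(tri)
        if np.any(tri < 0):
            # points numerically on the hull can miss; nudge towards the centre
            centre = self.mesh.points.mean(axis=0)
            diag = np.ptp(self.mesh.points, axis=0).max()
            bad = tri < 0
            moved = flat[bad] + 1e-9 * diag * np.sign(centre - flat[bad])
            tri2 = np.asarray(self.mesh.trifinder(moved[:, 0], moved[:, 1]))
            if np.any(tri2 < 0):
                raise ValueError("evaluation point outside the mesh")
            flat = flat.copy()
            flat[bad] = moved
            tri[bad] = tri2
        out = np.empty((len(flat), 2))
        for i, (p, k) in enumerate(zip(flat, tri)):
            lam = self.mesh.barycentric(int(k), p)
            out[i] = lam @ self.values[self.mesh.triangles[int(k)]]
        return out.reshape(pts.shape)


def _elastic_moduli(mat: ElasticParams) -> np.ndarray:
    c = mat.E / ((1.0 + mat.nu) * (1.0 - 2.0 * mat.nu))
    return c * np.array(
        [
            [1.0 - mat.nu, mat.nu, 0.0],
            [mat.nu, 1.0 - mat.nu, 0.0],
            [0.0, 0.0, (1.0 - 2.0 * mat.nu) / 2.0],
        ]
    )


def assemble_stiffness_2d(mesh: TriMesh, mat: ElasticParams) -> sp.csr_matrix:
    """Global stiffness with dofs ``(2 v, 2 v + 1)`` per node ``v``.

    Symmetric; before constraints rigid translations lie in the nullspace.
    """
    D = _elastic_moduli(mat)
    g = mesh.grads  # (M, 3, 2)
    M = mesh.n_triangles
    B = np.zeros((M, 3, 6))
    B[:, 0, 0::2] = g[:, :, 0]
    B[:, 1, 1::2] = g[:, :, 1]
    B[:, 2, 0::2] = g[:, :, 1]
    B[:, 2, 1::2] = g[:, :, 0]
    Ke = np.einsum("kia,ij,kjb,k->kab", B, D, B, mesh.areas, optimize=True)
    dofs = np.empty((M, 6), dtype=int)
    dofs[:, 0::2] = 2 * mesh.triangles
    dofs[:, 1::2] = 2 * mesh.triangles + 1
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    n = 2 * mesh.n_nodes
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def load_sp_2d(
    mesh: TriMesh,
    cells: CellConfig2D,
    epsilon: float,
    tol: float = 1e-10,
) -> np.ndarray:
    """Smoothed-particle load: ``-P * sum_i sum_k div(phi)|_k * mass_i(e_k)``.

    Per-triangle Gaussian masses are evaluated only for triangles within the
    kernel's numerical support (10 standard deviations); beyond that the mass
    is below double-precision resolution.
    """
    if not epsilon > 0:
        raise ValueError("mollifier width must be positive")
    if epsilon > mesh.min_edge_length / 3.0 * (1.0 + 1e-9):
        warnings.warn(
            "mollifier width exceeds a third of the smallest element edge; "
            "per-element masses will be far from cell counts",
            stacklevel=2,
        )
    F = np.zeros(2 * mesh.n_nodes)
    cutoff = 10.0 * epsilon + mesh.circumscribed_radius
    for s in cells.positions:
        if mesh.find_triangle(s) < 0:
            raise ValueError(f"cell position {tuple(s)} outside the meshed domain")
        near = np.flatnonzero(np.linalg.norm(mesh.centroids - s, axis=1) <= cutoff)
        moll = Mollifier2D(epsilon, (s[0], s[1]))
        for k in near:
            mass = region_mass_2d(mesh.points[mesh.triangles[k]], moll, tol)
            if mass == 0.0:
                continue
            for i, v in enumerate(mesh.triangles[k]):
                F[2 * v] -= cells.P * mesh.grads[k, i, 0] * mass
                F[2 * v + 1] -= cells.P * mesh.grads[k, i, 1] * mass
    return F


def load_density_2d(mesh: TriMesh, density: DensityField2D, P: float) -> np.ndarray:
    """Cell-density load: ``-P * sum_k n_c(e_k) * div(phi)|_k * A(e_k)``, exact."""
    if not mesh.compatible_with(density.mesh):
        raise ValueError("density field lives on an incompatible mesh")
    F = np.zeros(2 * mesh.n_nodes)
    w = P * density.values * mesh.areas  # per-triangle cell weight times P
    contrib = -w[:, None, None] * mesh.grads  # (M, 3, 2)
    np.add.at(F, 2 * mesh.triangles, contrib[:, :, 0])
    np.add.at(F, 2 * mesh.triangles + 1, contrib[:, :, 1])
    return F


def solve_2d(
    mesh: TriMesh,
    mat: ElasticParams,
    load: np.ndarray,
    boundary_values: np.ndarray | None = None,
) -> DisplacementField2D:
    """Sparse direct solve with Dirichlet conditions on the outer boundary.

    ``boundary_values`` (N, 2) prescribes nonzero boundary displacement (used
    by the patch test); the default is homogeneous (exact zeros on the hull).
    """
    load = np.asarray(load, dtype=float)
    n = 2 * mesh.n_nodes
    if len(load) != n:
        raise ValueError("load vector size does not match the mesh")
    K = assemble_stiffness_2d(mesh, mat)
    bnodes = mesh.boundary_nodes
    bdofs = np.concatenate([2 * bnodes, 2 * bnodes + 1])
    u = np.zeros(n)
    if boundary_values is not None:
        bv = np.asarray(boundary_values, dtype=float).reshape(-1, 2)
        u[2 * bnodes] = bv[bnodes, 0]
        u[2 * bnodes + 1] = bv[bnodes, 1]
    mask = np.ones(n, dtype=bool)
    mask[bdofs] = False
    interior = np.flatnonzero(mask)
    rhs = load[interior] - K[interior][:, bdofs] @ u[bdofs]
    u[interior] = spla.spsolve(K[interior][:, interior].tocsc(), rhs)
    return DisplacementField2D(mesh, u.reshape(-1, 2))


def deformed_boundary(
    field: DisplacementField2D,
    polyline: np.ndarray,
    samples_per_edge: int = 50,
) -> np.ndarray:
    """Displace a closed polyline by the field: each sample ``x -> x + u(x)``.

    ``polyline`` holds the ring's corner vertices (not repeated); each edge is
    sampled ``samples_per_edge`` times.  Returns the displaced ring vertices.
    """
    ring = np.asarray(polyline, dtype=float).reshape(-1, 2)
    if samples_per_edge < 1:
        raise ValueError("need at least one sample per edge")
    ts = np.arange(samples_per_edge) / samples_per_edge
    pts = []
    for i in range(len(ring)):
        p0, p1 = ring[i], ring[(i + 1) % len(ring)]
        pts.append(p0 + ts[:, None] * (p1 - p0))
    pts = np.concatenate(pts)
    return pts + field(pts)
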