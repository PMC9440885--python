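"""Cell configurations and position <-> density conversions.

The agent-based force model needs cell *positions*; the continuum model needs
a piecewise-constant cell *density* per mesh element.  This module holds both
representations and the two upscaling/downscaling algorithms connecting them:

* positions -> density: count cells per element and divide by the element
  measure.  A cell sitting exactly on a shared mesh node (1D) or face/vertex
  (2D) is split between the adjacent elements — one half per side of an
  interior node or face, and proportionally to the incident angle over 2*pi
  at a vertex — so total cell weight is conserved.
* density -> positions: integrate an analytic density over bins (1D) or tiles
  (2D), round to a per-bin cell count, and place that many cells inside the
  bin (deterministic equispaced by default, seeded uniform as an option).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .meshes import Mesh1D, TriMesh

__all__ = [
    "CellConfig1D",
    "CellConfig2D",
    "DensityField1D",
    "DensityField2D",
    "uniform_cells_1d",
    "density_from_positions_1d",
    "positions_from_density_1d",
    "density_from_positions_2d",
    "positions_from_density_2d",
    "random_cells_2d",
]

#: relative (to element size) tolerance for deciding that a cell sits exactly
#: on a mesh node / edge / vertex.
_SNAP_RTOL = 1e-9


@dataclass
class CellConfig1D:
    """Cell centre positions on the line, sorted, plus a force magnitude ``P``."""

    positions: np.ndarray
    P: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.sort(np.asarray(self.positions, dtype=float).ravel())
        self.P = float(self.P)

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass
class CellConfig2D:
    """Cell centre positions in the plane plus a force magnitude ``P``."""

    positions: np.ndarray
    P: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.P = float(self.P)

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass
class DensityField1D:
    """Piecewise-constant cell density ``n_c`` per element of a :class:`Mesh1D`."""

    mesh: Mesh1D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != self.mesh.n_elements:
            raise ValueError("density values must have one entry per mesh element")
        if np.any(self.values < 0):
            raise ValueError("cell density must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        """Per-element cell counts ``N_c = h * n_c``."""
        return self.mesh.h * self.values

    @property
    def total_weight(self) -> float:
        return float(self.counts.sum())


@dataclass
class DensityField2D:
    """Piecewise-constant cell density per triangle of a :class:`TriMesh`."""

    mesh: TriMesh
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != self.mesh.n_triangles:
            raise ValueError("density values must have one entry per triangle")
        if np.any(self.values < 0):
            raise ValueError("cell density must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        """Per-triangle cell counts ``N_c = A(e_k) * n_c(e_k)``."""
        return self.mesh.areas * self.values

    @property
    def total_weight(self) -> float:
        return float(self.counts.sum())


def uniform_cells_1d(a: float, b: float, Ns: int, P: float = 1.0) -> CellConfig1D:
    """``Ns`` equispaced cells in ``(a, b)``: spacing ``ds = (b-a)/Ns``, first
    cell at ``a + ds/2``, last at ``b - ds/2``."""
    if not a < b:
        raise ValueError("invalid subdomain: need a < b")
    if Ns < 1:
        raise ValueError("need at least one cell")
    ds = (b - a) / Ns
    return CellConfig1D(a + (np.arange(Ns) + 0.5) * ds, P=P)


def density_from_positions_1d(cells: CellConfig1D, mesh: Mesh1D) -> DensityField1D:
    """Count cells per element and divide by ``h``.

    A cell exactly on an interior node contributes one half to each adjacent
    element; a cell on a boundary node contributes fully to the single
    adjacent element.  Total weight equals the number of cells.
    """
    h = mesh.h
    snap = _SNAP_RTOL * h
    w = np.zeros(mesh.n_elements)
    for s in cells.positions:
        if s < -snap or s > mesh.L + snap:
            raise ValueError(f"cell position {s} outside domain [0, {mesh.L}]")
        jn = int(round(s / h))
        if 0 <= jn <= mesh.n_elements and abs(s - jn * h) <= snap:
            if jn == 0:
                w[0] += 1.0
            elif jn == mesh.n_elements:
                w[-1] += 1.0
            else:
                w[jn - 1] += 0.5
                w[jn] += 0.5
        else:
            e = min(max(int(math.floor(s / h)), 0), mesh.n_elements - 1)
            w[e] += 1.0
    return DensityField1D(mesh, w / h)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _check_nonnegative_1d(nc, l: float, r: float) -> None:
    xs = np.linspace(l, r, 33)
    vals = np.asarray([nc(x) for x in xs], dtype=float)
    if np.any(vals < -1e-12 * max(1.0, float(np.abs(vals).max()))):
        raise ValueError("cell density function is negative inside the domain")


def positions_from_density_1d(
    nc,
    L: float,
    d: float,
    P: float = 1.0,
    placement: str = "equispaced",
    seed: int | None = None,
) -> CellConfig1D:
    """Generate cell positions from an analytic density ``nc`` on ``(0, L)``.

    The domain is split into bins of length ``d`` (a trailing shorter bin if
    ``d`` does not divide ``L``).  Per bin the count is the integral of ``nc``
    rounded half-away-from-zero; cells are placed at the midpoints of that
    many equal subintervals (``placement="equispaced"``) or i.i.d. uniform
    within the bin (``placement="uniform"``, reproducible via ``seed``).
    """
    if not d > 0:
        raise ValueError("bin length must be positive")
    if placement not in ("equispaced", "uniform"):
        raise ValueError("placement must be 'equispaced' or 'uniform'")
    rng = np.random.default_rng(seed)
    edges = list(np.arange(0.0, L, d)) + [L]
    positions: list[np.ndarray] = []
    for l, r in zip(edges[:-1], edges[1:]):
        if r - l <= 0:
            continue
        _check_nonnegative_1d(nc, l, r)
        total, _ = integrate.quad(nc, l, r, limit=200)
        if total < -1e-9:
            raise ValueError("cell density integrates to a negative count")
        count = _round_half_away(max(total, 0.0))
        if count == 0:
            continue
        if placement == "equispaced":
            positions.append(l + (np.arange(count) + 0.5) * (r - l) / count)
        else:
            positions.append(np.sort(rng.uniform(l, r, count)))
    pos = np.concatenate(positions) if positions else np.empty(0)
    return CellConfig1D(pos, P=P)


def density_from_positions_2d(cells: CellConfig2D, mesh: TriMesh) -> DensityField2D:
    """Count cells per triangle and divide by the triangle area.

    A cell strictly inside a triangle counts 1 there; a cell on a face shared
    by two triangles counts one half to each; a cell on a vertex counts, per
    incident triangle, the incident angle divided by ``2 pi``.
    """
    w = np.zeros(mesh.n_triangles)
    bary_tol = _SNAP_RTOL
    for p in cells.positions:
        k = mesh.find_triangle(p)
        if k < 0:
            raise ValueError(f"cell position {tuple(p)} outside the meshed domain")
        lam = mesh.barycentric(k, p)
        zero = np.abs(lam) <= bary_tol
        n_zero = int(zero.sum())
        tri = mesh.triangles[k]
        if n_zero == 0:
            w[k] += 1.0
        elif n_zero == 1:
            vs = tuple(sorted(int(v) for v, z in zip(tri, zero) if not z))
            sharing = mesh.edge_to_triangles[vs]
            for t in sharing:
                w[t] += 1.0 / len(sharing)
        else:
            v = int(tri[np.argmax(lam)])
            for t in mesh.vertex_to_triangles[v]:
                w[t] += mesh.vertex_angle(t, v) / (2.0 * math.pi)
    return DensityField2D(mesh, w / mesh.areas)


def random_cells_2d(
    region,
    Ns: int,
    min_sep: float = 0.2,
    seed: int | None = None,
    P: float = 1.0,
    max_attempts_per_cell: int = 2000,
) -> CellConfig2D:
    """``Ns`` cells i.i.d. uniform in a rectangle, rejection-sampled so that
    pairwise distances stay >= ``min_sep``.  Deterministic for a fixed seed."""
    if Ns < 0:
        raise ValueError("cell count must be nonnegative")
    (x0, y0), (x1, y1) = np.asarray(region, dtype=float)
    area = (x1 - x0) * (y1 - y0)
    if Ns > 0 and Ns * min_sep**2 > 0.7 * area:
        raise ValueError("infeasible packing: region too small for Ns cells at min_sep")
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_cell * max(Ns, 1)
    while len(pts) < Ns:
        if attempts > budget:
            raise RuntimeError("infeasible packing: rejection sampler exceeded max attempts")
        attempts += 1
        cand = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        if pts and np.min(np.linalg.norm(np.asarray(pts) - cand, axis=1)) < min_sep:
            continue
        pts.append(cand)
    positions = np.asarray(pts) if pts else np.empty((0, 2))
    meta = {"min_sep": float(min_sep), "seed": seed, "region": ((float(x0), float(y0)), (float(x1), float(y1)))}
    return CellConfig2D(positions, P=P, metadata=meta)


def positions_from_density_2d(
    nc,
    domain,
    cell_side: float = 1.0,
    seed: int | None = None,
    P: float = 1.0,
) -> CellConfig2D:
    """Generate cell positions from an analytic 2D density.

    The rectangle ``domain`` is tiled with squares of side ``cell_side``; per
    square the count is the integral of ``nc`` (vectorised ``nc(x, y)``) by
    Gauss-Legendre product quadrature, rounded half-away-from-zero, and that
    many points are placed uniform-random (seeded) in the square.
    """
    if not cell_side > 0:
        raise ValueError("tile side must be positive")
    (x0, y0), (x1, y1) = np.asarray(domain, dtype=float)
    rng = np.random.default_rng(seed)
    gl_x, gl_w = np.polynomial.legendre.leggauss(24)
    xs = list(np.arange(x0, x1, cell_side)) + [x1]
    ys = list(np.arange(y0, y1, cell_side)) + [y1]
    positions: list[np.ndarray] = []
    for yl, yr in zip(ys[:-1], ys[1:]):
        for xl, xr in zip(xs[:-1], xs[1:]):
            if xr - xl <= 0 or yr - yl <= 0:
                continue
            qx = 0.5 * (xr - xl) * gl_x + 0.5 * (xr + xl)
            qy = 0.5 * (yr - yl) * gl_x + 0.5 * (yr + yl)
            vals = np.asarray(nc(qx[:, None], qy[None, :]), dtype=float)
            if np.any(vals < -1e-12 * max(1.0, float(np.abs(vals).max()))):
                raise ValueError("cell density function is negative inside the domain")
            total = 0.25 * (xr - xl) * (yr - yl) * float(gl_w @ vals @ gl_w)
            count = _round_half_away(max(total, 0.0))
            if count:
                px = rng.uniform(xl, xr, count)
                py = rng.uniform(yl, yr, count)
                positions.append(np.column_stack([px, py]))
    pos = np.concatenate(positions) if positions else np.empty((0, 2))
    return CellConfig2D(pos, P=P, metadata={"cell_side": float(cell_side), "seed": seed})
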