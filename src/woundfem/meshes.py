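"""Uniform 1D meshes and conforming triangular meshes of rectangles.

Both force models are discretised with P1 Lagrangian elements, so a mesh is
nodes plus connectivity; per-element measures (lengths / areas) and constant
shape-function gradients are precomputed here and shared by the assemblies
and the cell-counting routines.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["Mesh1D", "TriMesh", "structured_trimesh"]


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


@dataclass(frozen=True)
class Mesh1D:
    """Uniform partition of ``(0, L)`` into ``n_elements`` intervals."""

    L: float
    n_elements: int

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError("domain length must be positive")
        if self.n_elements < 2:
            raise ValueError("mesh too coarse: need at least 2 elements")

    @property
    def h(self) -> float:
        return self.L / self.n_elements

    @property
    def n_nodes(self) -> int:
        return self.n_elements + 1

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n_nodes)

    def refine(self) -> "Mesh1D":
        """Halve the element size; every coarse node remains a fine node."""
        return Mesh1D(self.L, 2 * self.n_elements)

    def compatible_with(self, other: "Mesh1D") -> bool:
        return self.n_elements == other.n_elements and np.isclose(self.L, other.L)


class TriMesh:
    """Conforming triangle mesh: ``points`` (N, 2) and ``triangles`` (M, 3).

    Triangles are re-oriented counter-clockwise on construction.  Constant
    P1 shape-function gradients, element areas, boundary topology and a fast
    point locator (matplotlib's trapezoid map) are cached lazily.
    """

    def __init__(self, points, triangles):
        self.points = np.asarray(points, dtype=float)
        tris = np.asarray(triangles, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (N, 2)")
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise ValueError("triangles must have shape (M, 3)")
        p = self.points[tris]
        cross = _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        flip = cross < 0
        tris[flip] = tris[flip][:, ::-1]
        if np.any(cross == 0):
            raise ValueError("mesh contains degenerate (zero-area) triangles")
        self.triangles = tris

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @cached_property
    def areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        return 0.5 * np.abs(_cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))

    @cached_property
    def grads(self) -> np.ndarray:
        """Gradients of the three barycentric shape functions, shape (M, 3, 2)."""
        p = self.points[self.triangles]
        g = np.empty((self.n_triangles, 3, 2))
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            g[:, i, 0] = p[:, j, 1] - p[:, k, 1]
            g[:, i, 1] = p[:, k, 0] - p[:, j, 0]
        return g / (2.0 * self.areas)[:, None, None]

    @cached_property
    def centroids(self) -> np.ndarray:
        return self.points[self.triangles].mean(axis=1)

    @cached_property
    def circumscribed_radius(self) -> np.ndarray:
        """Max vertex distance from the centroid, per triangle."""
        p = self.points[self.triangles]
        return np.linalg.norm(p - self.centroids[:, None, :], axis=2).max(axis=1)

    @cached_property
    def min_edge_length(self) -> float:
        p = self.points[self.triangles]
        e = np.concatenate([p[:, 1] - p[:, 0], p[:, 2] - p[:, 1], p[:, 0] - p[:, 2]])
        return float(np.linalg.norm(e, axis=1).min())

    @cached_property
    def edge_to_triangles(self) -> dict:
        out: dict[tuple[int, int], list[int]] = {}
        for k, tri in enumerate(self.triangles):
            for i in range(3):
                e = tuple(sorted((int(tri[i]), int(tri[(i + 1) % 3]))))
                out.setdefault(e, []).append(k)
        return out

    @cached_property
    def vertex_to_triangles(self) -> dict:
        out: dict[int, list[int]] = {}
        for k, tri in enumerate(self.triangles):
            for v in tri:
                out.setdefault(int(v), []).append(k)
        return out

    @cached_property
    def boundary_nodes(self) -> np.ndarray:
        nodes: set[int] = set()
        for edge, tris in self.edge_to_triangles.items():
            if len(tris) == 1:
                nodes.update(edge)
        return np.array(sorted(nodes), dtype=int)

    @cached_property
    def _triangulation(self):
        from matplotlib.tri import Triangulation

        return Triangulation(self.points[:, 0], self.points[:, 1], self.triangles)

    @cached_property
    def trifinder(self):
        return self._triangulation.get_trifinder()

    def find_triangle(self, point) -> int:
        """Index of a triangle containing ``point`` (−1 if outside the mesh)."""
        x, y = np.asarray(point, dtype=float)
        return int(self.trifinder(x, y))

    def barycentric(self, k: int, point) -> np.ndarray:
        """Barycentric coordinates of ``point`` in triangle ``k``."""
        tri = self.triangles[k]
        p = np.asarray(point, dtype=float)
        lam12 = self.grads[k, 1:] @ (p - self.points[tri[0]])
        return np.array([1.0 - lam12.sum(), lam12[0], lam12[1]])

    def vertex_angle(self, k: int, v: int) -> float:
        """Interior angle of triangle ``k`` at its (global) vertex ``v``."""
        tri = list(self.triangles[k])
        i = tri.index(v)
        p = self.points[self.triangles[k]]
        a = p[(i + 1) % 3] - p[i]
        b = p[(i + 2) % 3] - p[i]
        cosang = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        return float(np.arccos(np.clip(cosang, -1.0, 1.0)))

    def compatible_with(self, other: "TriMesh") -> bool:
        return (
            self.points.shape == other.points.shape
            and self.triangles.shape == other.triangles.shape
            and np.allclose(self.points, other.points)
            and np.array_equal(self.triangles, other.triangles)
        )


def structured_trimesh(rect, nx: int, ny: int, diagonal: str = "ne") -> TriMesh:
    """Structured triangulation of an axis-aligned rectangle.

    The rectangle ``[[xmin, ymin], [xmax, ymax]]`` is divided into ``nx * ny``
    squares, each split into two triangles along the chosen diagonal
    (``"ne"`` = lower-left to upper-right, ``"nw"`` = the other one).
    """
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 subdivisions per direction")
    (x0, y0), (x1, y1) = np.asarray(rect, dtype=float)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate rectangle")
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    X, Y = np.meshgrid(xs, ys)
    points = np.column_stack([X.ravel(), Y.ravel()])
    tris = []
    for j in range(ny):
        for i in range(nx):
            n00 = j * (nx + 1) + i
            n10 = n00 + 1
            n01 = n00 + (nx + 1)
            n11 = n01 + 1
            if diagonal == "ne":
                tris.append((n00, n10, n11))
                tris.append((n00, n11, n01))
            elif diagonal == "nw":
                tris.append((n00, n10, n01))
                tris.append((n10, n11, n01))
            else:
                raise ValueError("diagonal must be 'ne' or 'nw'")
    return TriMesh(points, np.array(tris, dtype=int))
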