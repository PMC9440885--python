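"""2D plane-strain assembly, loads (with quadrature oracle), solves, boundary tracking."""
import numpy as np
import pytest
from scipy import integrate

import woundfem as wf
from woundfem.cells import DensityField2D, density_from_positions_2d
from woundfem.fem2d import (
    ElasticParams,
    WoundGeometry,
    assemble_stiffness_2d,
    deformed_boundary,
    load_density_2d,
    load_sp_2d,
    solve_2d,
    structured_trimesh,
)
from woundfem.kernels import gauss2d, Mollifier2D


def mirror_symmetric_mesh(n):
    """Triangulation of (-1,1)^2 symmetric under x -> -x: squares left of the
    axis split along the 'ne' diagonal, squares right of it along 'nw'."""
    xs = np.linspace(-1, 1, n + 1)
    X, Y = np.meshgrid(xs, xs)
    points = np.column_stack([X.ravel(), Y.ravel()])
    tris = []
    for j in range(n):
        for i in range(n):
            n00 = j * (n + 1) + i
            n10, n01, n11 = n00 + 1, n00 + (n + 1), n00 + (n + 2)
            if 0.5 * (xs[i] + xs[i + 1]) < 0:
                tris += [(n00, n10, n11), (n00, n11, n01)]
            else:
                tris += [(n00, n10, n01), (n10, n11, n01)]
    return wf.TriMesh(points, np.array(tris))


class TestStructuredMesh:
    def test_counts_and_areas(self):
        mesh = structured_trimesh(((0, 0), (1, 1)), 2, 2)
        assert mesh.n_nodes == 9
        assert mesh.n_triangles == 8
        assert mesh.areas.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(mesh.areas > 0)

    def test_alternative_diagonal(self):
        a = structured_trimesh(((0, 0), (2, 1)), 4, 3, diagonal="ne")
        b = structured_trimesh(((0, 0), (2, 1)), 4, 3, diagonal="nw")
        assert a.areas.sum() == pytest.approx(b.areas.sum())
        assert not np.array_equal(a.triangles, b.triangles)

    def test_boundary_nodes_of_unit_square(self):
        mesh = structured_trimesh(((0, 0), (1, 1)), 3, 3)
        onb = (
            (mesh.points[:, 0] == 0) | (mesh.points[:, 0] == 1)
            | (mesh.points[:, 1] == 0) | (mesh.points[:, 1] == 1)
        )
        assert set(mesh.boundary_nodes) == set(np.flatnonzero(onb))

    def test_degenerate_rectangle_rejected(self):
        with pytest.raises(ValueError):
            structured_trimesh(((0, 0), (0, 1)), 2, 2)


class TestStiffness2D:
    def test_symmetric_and_rigid_translation_in_nullspace(self, small_trimesh):
        K = assemble_stiffness_2d(small_trimesh, ElasticParams(E=2.0, nu=0.3))
        assert abs(K - K.T).max() < 1e-12
        const = np.tile([0.7, -0.3], small_trimesh.n_nodes)
        assert np.abs(K @ const).max() < 1e-12

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            ElasticParams(E=1.0, nu=0.5)

    def test_patch_test_linear_field_reproduced_exactly(self, small_trimesh):
        """Dirichlet data from a linear displacement field is reproduced at
        interior nodes to solver precision (constant-strain completeness)."""
        A = np.array([[0.3, 0.1], [0.2, -0.4]])
        exact = small_trimesh.points @ A.T
        u = solve_2d(small_trimesh, ElasticParams(E=1.0, nu=0.3), np.zeros(2 * small_trimesh.n_nodes), boundary_values=exact)
        assert np.abs(u.values - exact).max() < 1e-12


class TestSpLoad2D:
    def test_component_sums_vanish(self, small_trimesh):
        cells = wf.CellConfig2D([[0.4, 0.6], [0.55, 0.3]], P=2.0)
        F = load_sp_2d(small_trimesh, cells, 0.05)
        assert abs(F[0::2].sum()) < 1e-10
        assert abs(F[1::2].sum()) < 1e-10

    def test_mirror_symmetry_for_centred_cell(self):
        mesh = mirror_symmetric_mesh(4)
        F = load_sp_2d(mesh, wf.CellConfig2D([[0.0, 0.0]], P=1.0), 0.08)
        # reflect x -> -x: find partner nodes, Fx flips sign, Fy preserved
        coords = {tuple(np.round(p, 12)): i for i, p in enumerate(mesh.points)}
        for i, p in enumerate(mesh.points):
            j = coords[tuple(np.round([-p[0], p[1]], 12))]
            assert F[2 * i] == pytest.approx(-F[2 * j], abs=1e-9)
            assert F[2 * i + 1] == pytest.approx(F[2 * j + 1], abs=1e-9)

    def test_matches_quadrature_of_non_integrated_forcing(self):
        """Oracle: entries equal int P grad(delta_eps) . (phi e_c) over the
        domain, computed per triangle by adaptive quadrature of the gradient
        form (no integration by parts)."""
        mesh = structured_trimesh(((0, 0), (1, 1)), 4, 4)
        s = np.array([0.45, 0.55])
        eps = 0.06
        P = 1.3
        cells = wf.CellConfig2D([s], P=P)
        F = load_sp_2d(mesh, cells, eps, tol=1e-12)
        m = Mollifier2D(eps, (s[0], s[1]))
        node = np.argmin(np.linalg.norm(mesh.points - np.array([0.5, 0.5]), axis=1))
        for comp in (0, 1):
            oracle = 0.0
            for k, tri in enumerate(mesh.triangles):
                if np.linalg.norm(mesh.centroids[k] - s) > 10 * eps + mesh.circumscribed_radius[k]:
                    continue
                if node not in tri:
                    continue
                i = list(tri).index(node)
                p0 = mesh.points[tri[0]]
                e1 = mesh.points[tri[1]] - p0
                e2 = mesh.points[tri[2]] - p0
                J = 2 * mesh.areas[k]

                def integrand(b, a):
                    pt = p0 + a * e1 + b * e2
                    lam = np.array([1 - a - b, a, b])
                    d = pt - s
                    grad_delta = -d[comp] / eps**2 * gauss2d(pt, m)
                    return P * grad_delta * lam[i]

                val, _ = integrate.dblquad(integrand, 0, 1, 0, lambda a: 1 - a, epsabs=1e-11)
                oracle += val * J
            assert F[2 * node + comp] == pytest.approx(oracle, abs=1e-8)

    def test_cell_outside_mesh_rejected(self, small_trimesh):
        with pytest.raises(ValueError):
            load_sp_2d(small_trimesh, wf.CellConfig2D([[1.5, 0.5]]), 0.05)

    def test_wide_mollifier_warns(self, small_trimesh):
        with pytest.warns(UserWarning):
            load_sp_2d(small_trimesh, wf.CellConfig2D([[0.5, 0.5]]), 0.2)


class TestDensityLoad2D:
    def test_constant_density_zero_interior_load(self, small_trimesh):
        dens = DensityField2D(small_trimesh, np.full(small_trimesh.n_triangles, 2.5))
        F = load_density_2d(small_trimesh, dens, 3.0)
        interior = np.setdiff1d(np.arange(small_trimesh.n_nodes), small_trimesh.boundary_nodes)
        for v in interior:
            assert abs(F[2 * v]) < 1e-12 and abs(F[2 * v + 1]) < 1e-12
        assert abs(F[0::2].sum()) < 1e-12 and abs(F[1::2].sum()) < 1e-12

    def test_approaches_sp_load_as_eps_shrinks(self):
        """With matching per-element weights the two load vectors agree in the
        vanishing-mollifier limit."""
        mesh = structured_trimesh(((0, 0), (1, 1)), 5, 5)
        # cells well inside their triangles so the Gaussian tail that leaks
        # across element boundaries vanishes within the eps sweep
        cells = wf.CellConfig2D([[0.35, 0.45], [0.65, 0.75]], P=1.0)
        dens = density_from_positions_2d(cells, mesh)
        Fd = load_density_2d(mesh, dens, 1.0)
        errs = []
        for eps in (0.02, 0.01, 0.005):
            Fs = load_sp_2d(mesh, cells, eps, tol=1e-12)
            errs.append(np.abs(Fs - Fd).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[-1] < 1e-4 * np.abs(Fd).max()

    def test_mesh_mismatch_rejected(self, small_trimesh):
        other = structured_trimesh(((0, 0), (1, 1)), 5, 5)
        dens = DensityField2D(other, np.zeros(other.n_triangles))
        with pytest.raises(ValueError):
            load_density_2d(small_trimesh, dens, 1.0)


class TestSolve2D:
    def test_zero_load_zero_field(self, small_trimesh):
        u = solve_2d(small_trimesh, ElasticParams(), np.zeros(2 * small_trimesh.n_nodes))
        assert np.all(u.values == 0.0)

    def test_reflection_equivariance(self):
        mesh = mirror_symmetric_mesh(6)
        mat = ElasticParams(E=1.0, nu=0.3)
        cells = wf.CellConfig2D([[0.0, 0.3], [0.0, -0.4]], P=1.0)
        u = solve_2d(mesh, mat, load_sp_2d(mesh, cells, 0.05))
        coords = {tuple(np.round(p, 12)): i for i, p in enumerate(mesh.points)}
        for i, p in enumerate(mesh.points):
            j = coords[tuple(np.round([-p[0], p[1]], 12))]
            assert u.values[i, 0] == pytest.approx(-u.values[j, 0], abs=1e-8)
            assert u.values[i, 1] == pytest.approx(u.values[j, 1], abs=1e-8)

    def test_energy_positivity_and_linearity(self, small_trimesh):
        cells = wf.CellConfig2D([[0.45, 0.5]], P=2.0)
        F = load_sp_2d(small_trimesh, cells, 0.05)
        u = solve_2d(small_trimesh, ElasticParams(E=1.0, nu=0.4), F)
        assert float(F @ u.values.ravel()) >= 0.0
        u2 = solve_2d(small_trimesh, ElasticParams(E=1.0, nu=0.4), 2 * F)
        assert np.allclose(u2.values, 2 * u.values, rtol=1e-12)


class TestDeformedBoundary:
    def test_identity_for_zero_field(self, small_trimesh):
        u = wf.DisplacementField2D(small_trimesh, np.zeros((small_trimesh.n_nodes, 2)))
        ring = np.array([[0.25, 0.25], [0.75, 0.25], [0.75, 0.75], [0.25, 0.75]])
        out = deformed_boundary(u, ring, samples_per_edge=10)
        assert out.shape == (40, 2)
        assert np.allclose(out[0], ring[0])

    def test_nodal_values_reproduced(self, small_trimesh):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(small_trimesh.n_nodes, 2)) * 0.01
        u = wf.DisplacementField2D(small_trimesh, vals)
        interior = np.setdiff1d(np.arange(small_trimesh.n_nodes), small_trimesh.boundary_nodes)
        pts = small_trimesh.points[interior]
        assert np.allclose(u(pts), vals[interior], atol=1e-12)

    def test_inward_pull_shrinks_polygon_area(self, wound2d):
        from woundfem.metrics import area_reduction_2d

        mesh = structured_trimesh(wound2d.omega, 16, 16)
        cells = wf.random_cells_2d(wound2d.wound, 40, seed=4, P=10.0)
        dens = density_from_positions_2d(cells, mesh)
        u = solve_2d(mesh, ElasticParams(E=1.0, nu=0.49), load_density_2d(mesh, dens, 10.0))
        ring = wound2d.wound_corners
        red = area_reduction_2d(deformed_boundary(u, ring, 50), ring)
        assert red.reduction_percent > 0

    def test_wound_geometry_validation(self):
        with pytest.raises(ValueError):
            WoundGeometry(((0, 0), (1, 1)), ((0.5, 0.5), (2, 2)))
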