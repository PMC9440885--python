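"""End-to-end cases: cells -> forcing -> FEM solve -> diagnostics.

These drive the standard benchmark scenarios — a 1D wound ``(a, b)`` inside
``(0, L)`` populated by uniform cells, and a 2D rectangular wound populated
by random non-overlapping cells — with both force models, and produce
reports that self-describe every numeric convention in effect.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .analytic1d import Domain1D, u1_exact, u2_exact
from .cells import (
    CellConfig1D,
    CellConfig2D,
    density_from_positions_1d,
    density_from_positions_2d,
    random_cells_2d,
    uniform_cells_1d,
)
from .fem1d import DisplacementField1D, load_density_1d, load_sp_1d, solve_1d
from .fem2d import (
    DisplacementField2D,
    ElasticParams,
    WoundGeometry,
    deformed_boundary,
    load_density_2d,
    load_sp_2d,
    solve_2d,
    structured_trimesh,
)
from .meshes import Mesh1D
from .metrics import (
    ConvergenceReport,
    area_reduction_2d,
    consistency_gap,
    convergence_rate,
    l2_norm,
    h1_norm,
    nested_difference_norms,
    reduction_ratio_1d,
    rms_error,
)

log = logging.getLogger("woundfem")

__all__ = ["Case1D", "Case2D", "run_case_1d", "run_case_2d", "converge_sweep_1d"]


@dataclass
class Case1D:
    """1D benchmark configuration (defaults: the dimensionless standard case
    E = 1, P = 0.01, L = 7, wound (2, 5), 50 uniform cells, h = 0.07)."""

    L: float = 7.0
    a: float = 2.0
    b: float = 5.0
    ns: int = 50
    P: float = 0.01
    h: float = 0.07
    eps_factor: float = 3.0
    mode: str = "both"  # sp | density | both
    placement: str = "equispaced"
    seed: int | None = None

    def domain(self) -> Domain1D:
        return Domain1D(self.L, self.a, self.b)

    def mesh(self) -> Mesh1D:
        return Mesh1D(self.L, int(round(self.L / self.h)))


@dataclass
class Case2D:
    """2D benchmark configuration (defaults: E = 1, P = 10, nu = 0.49, the
    20 x 20 tissue square with the centred 10 x 10 wound, 196 random cells)."""

    x0: float = 20.0
    y0: float = 20.0
    wx: float = 10.0
    wy: float = 10.0
    E: float = 1.0
    nu: float = 0.49
    P: float = 10.0
    nx: int = 40
    ny: int = 40
    ns: int = 196
    min_sep: float = 0.2
    eps_factor: float = 3.0
    mode: str = "both"
    diagonal: str = "ne"
    samples_per_edge: int = 50
    seed: int | None = None

    def geometry(self) -> WoundGeometry:
        o = ((-self.x0 / 2, -self.y0 / 2), (self.x0 / 2, self.y0 / 2))
        w = ((-self.wx / 2, -self.wy / 2), (self.wx / 2, self.wy / 2))
        return WoundGeometry(o, w)


def _provenance(cfg) -> dict:
    import scipy

    return {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "versions": {"woundfem": __version__, "numpy": np.__version__, "scipy": scipy.__version__},
        "conventions": {
            "eps_factor": cfg.eps_factor,
            "bin_rounding": "half-away-from-zero",
            "placement": getattr(cfg, "placement", "random-uniform"),
            "diagonal": getattr(cfg, "diagonal", None),
        },
    }


def run_case_1d(cfg: Case1D, cells: CellConfig1D | None = None):
    """Solve the 1D case with both force models; return (fields, report).

    ``fields`` maps ``"sp"``/``"density"`` to their displacement fields; the
    report carries norms, the wound reduction ratio, RMS errors against the
    closed forms, and the particle-vs-density consistency gap.
    """
    mesh = cfg.mesh()
    dom = cfg.domain()
    if cells is None:
        cells = uniform_cells_1d(cfg.a, cfg.b, cfg.ns, P=cfg.P)
    eps = mesh.h / cfg.eps_factor
    fields: dict[str, DisplacementField1D] = {}
    report = _provenance(cfg)
    report["epsilon"] = eps
    report["n_cells"] = cells.count
    if cfg.mode in ("sp", "both"):
        log.info("assembling smoothed-particle load (1D), eps=%g", eps)
        u = solve_1d(mesh, load_sp_1d(mesh, cells, eps))
        fields["sp"] = u
        nbar = cells.count / (dom.b - dom.a)
        report["sp"] = {
            "l2_norm": l2_norm(u),
            "h1_norm": h1_norm(u),
            "rms_vs_erf_closed_form": rms_error(
                u, lambda x: u1_exact(x, cells, eps, cfg.L, magnitude_mode="fem")
            ),
            "reduction_percent": reduction_ratio_1d(u, dom.a, dom.b).reduction_percent,
            "relative_percent": reduction_ratio_1d(u, dom.a, dom.b).relative_percent,
        }
        report["continuum_reference"] = {
            "mean_density": nbar,
            "reduction_percent_analytic": 100.0
            * (u2_exact(dom.a, cfg.P, dom, nbar) - u2_exact(dom.b, cfg.P, dom, nbar))
            / (dom.b - dom.a),
        }
    if cfg.mode in ("density", "both"):
        log.info("assembling cell-density load (1D)")
        density = density_from_positions_1d(cells, mesh)
        u = solve_1d(mesh, load_density_1d(mesh, density, cells.P))
        fields["density"] = u
        nbar = cells.count / (dom.b - dom.a)
        report["density"] = {
            "l2_norm": l2_norm(u),
            "h1_norm": h1_norm(u),
            "rms_vs_greens_function": rms_error(u, lambda x: u2_exact(x, cfg.P, dom, nbar)),
            "reduction_percent": reduction_ratio_1d(u, dom.a, dom.b).reduction_percent,
            "relative_percent": reduction_ratio_1d(u, dom.a, dom.b).relative_percent,
        }
    if len(fields) == 2:
        gap = consistency_gap(fields["sp"], fields["density"])
        report["gap_norms"] = {"l2": gap.l2, "sup": gap.sup, "h1": gap.h1}
    return fields, report


def run_case_2d(cfg: Case2D, cells: CellConfig2D | None = None, quad_tol: float = 1e-10):
    """Solve the 2D case with both force models; return (mesh, fields, report)."""
    geom = cfg.geometry()
    mesh = structured_trimesh(geom.omega, cfg.nx, cfg.ny, diagonal=cfg.diagonal)
    mat = ElasticParams(E=cfg.E, nu=cfg.nu)
    if cells is None:
        cells = random_cells_2d(geom.wound, cfg.ns, min_sep=cfg.min_sep, seed=cfg.seed, P=cfg.P)
    hx = cfg.x0 / cfg.nx
    eps = hx / cfg.eps_factor
    fields: dict[str, DisplacementField2D] = {}
    report = _provenance(cfg)
    report["epsilon"] = eps
    report["n_cells"] = cells.count
    ring0 = geom.wound_corners
    density = density_from_positions_2d(cells, mesh)
    if cfg.mode in ("sp", "both"):
        log.info("assembling smoothed-particle load (2D), eps=%g", eps)
        u = solve_2d(mesh, mat, load_sp_2d(mesh, cells, eps, tol=quad_tol))
        fields["sp"] = u
        red = area_reduction_2d(deformed_boundary(u, ring0, cfg.samples_per_edge), ring0)
        report["sp"] = {
            "l2_norm": l2_norm(u),
            "h1_norm": h1_norm(u),
            "reduction_percent": red.reduction_percent,
            "relative_percent": red.relative_percent,
        }
    if cfg.mode in ("density", "both"):
        log.info("assembling cell-density load (2D)")
        u = solve_2d(mesh, mat, load_density_2d(mesh, density, cells.P))
        fields["density"] = u
        red = area_reduction_2d(deformed_boundary(u, ring0, cfg.samples_per_edge), ring0)
        report["density"] = {
            "l2_norm": l2_norm(u),
            "h1_norm": h1_norm(u),
            "reduction_percent": red.reduction_percent,
            "relative_percent": red.relative_percent,
        }
    if len(fields) == 2:
        gap = consistency_gap(fields["sp"], fields["density"])
        report["gap_norms"] = {"l2": gap.l2, "sup": gap.sup, "h1": gap.h1}
    return mesh, fields, report, density, cells


def converge_sweep_1d(cfg: Case1D, levels: int = 3, mode: str = "sp") -> ConvergenceReport:
    """Solve on nested meshes h, h/2, ... with cells fixed and the mollifier
    width rescaled as (level h)/eps_factor; report per-level L2 norms and the
    observed order from successive solution differences."""
    if levels < 3:
        raise ValueError("need at least three refinement levels")
    if levels > 12:
        raise ValueError("refusing an excessive refinement sweep")
    cells = uniform_cells_1d(cfg.a, cfg.b, cfg.ns, P=cfg.P)
    mesh = cfg.mesh()
    fields = []
    sizes = []
    for _ in range(levels):
        if mode == "sp":
            load = load_sp_1d(mesh, cells, mesh.h / cfg.eps_factor)
        elif mode == "density":
            load = load_density_1d(mesh, density_from_positions_1d(cells, mesh), cells.P)
        else:
            raise ValueError("mode must be 'sp' or 'density'")
        fields.append(solve_1d(mesh, load))
        sizes.append(mesh.h)
        mesh = mesh.refine()
    diffs = nested_difference_norms(fields)
    rate = convergence_rate(diffs[-2], diffs[-1])
    return ConvergenceReport(
        mesh_sizes=tuple(sizes),
        level_norms=tuple(l2_norm(f) for f in fields),
        difference_norms=diffs,
        rate=rate,
    )
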