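"""Readers and writers: positions/solution/polyline CSV, density CSV, legacy
ASCII VTK for 2D fields, and JSON reports with full provenance."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import CellConfig1D, CellConfig2D, DensityField1D, DensityField2D
from .fem1d import DisplacementField1D
from .fem2d import DisplacementField2D
from .meshes import Mesh1D, TriMesh

__all__ = [
    "write_positions_csv",
    "read_positions_csv",
    "write_solution_csv",
    "read_solution_csv",
    "write_density_csv",
    "write_polyline_csv",
    "write_vtk",
    "write_report",
]


def write_positions_csv(cells, path) -> None:
    """Cell positions with header ``x`` (1D) or ``x,y`` (2D)."""
    if isinstance(cells, CellConfig1D):
        df = pd.DataFrame({"x": cells.positions})
    elif isinstance(cells, CellConfig2D):
        df = pd.DataFrame({"x": cells.positions[:, 0], "y": cells.positions[:, 1]})
    else:
        raise TypeError("expected a cell configuration")
    df.to_csv(path, index=False, float_format="%.17g")


def read_positions_csv(path, P: float = 1.0):
    """Read a positions CSV; the column set decides the dimensionality."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "y" in df.columns:
        return CellConfig2D(df[["x", "y"]].to_numpy(), P=P)
    return CellConfig1D(df["x"].to_numpy(), P=P)


def write_solution_csv(field: DisplacementField1D, path) -> None:
    # 17 significant digits so nodal values survive the round trip bit-exactly
    pd.DataFrame({"x": field.mesh.nodes, "u": field.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_solution_csv(path) -> DisplacementField1D:
    df = pd.read_csv(path, float_precision="round_trip")
    x = df["x"].to_numpy()
    mesh = Mesh1D(float(x[-1]), len(x) - 1)
    return DisplacementField1D(mesh, df["u"].to_numpy())


def write_density_csv(density, path) -> None:
    """Per-element density table: element index, measure (length/area), density."""
    if isinstance(density, DensityField1D):
        measure = np.full(density.mesh.n_elements, density.mesh.h)
    elif isinstance(density, DensityField2D):
        measure = density.mesh.areas
    else:
        raise TypeError("expected a density field")
    pd.DataFrame(
        {"element": np.arange(len(density.values)), "measure": measure, "density": density.values}
    ).to_csv(path, index=False)


def write_polyline_csv(ring: np.ndarray, path) -> None:
    """Ordered, closed polyline as ``x,y`` rows (first vertex repeated last)."""
    v = np.asarray(ring, dtype=float).reshape(-1, 2)
    closed = np.vstack([v, v[:1]])
    pd.DataFrame({"x": closed[:, 0], "y": closed[:, 1]}).to_csv(path, index=False, float_format="%.17g")


def write_vtk(
    mesh: TriMesh,
    path,
    displacement: DisplacementField2D | None = None,
    cell_density: DensityField2D | None = None,
    title: str = "woundfem solution",
) -> None:
    """Legacy ASCII VTK unstructured grid with a point vector field
    ``displacement`` and a cell scalar ``cell_density``."""
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{x:.17g} {y:.17g} 0" for x, y in mesh.points]
    lines.append(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    lines.append(f"CELL_TYPES {mesh.n_triangles}")
    lines += ["5"] * mesh.n_triangles
    if displacement is not None:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        lines.append("VECTORS displacement double")
        lines += [f"{u:.17g} {v:.17g} 0" for u, v in displacement.values]
    if cell_density is not None:
        lines.append(f"CELL_DATA {mesh.n_triangles}")
        lines.append("SCALARS cell_density double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.17g}" for v in cell_density.values]
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(report: dict, path) -> None:
    """JSON report, full float precision, deterministic key order."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
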