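import numpy as np
import pytest

import woundfem as wf


@pytest.fixture(scope="session")
def bench1d():
    """Standard 1D benchmark: L=7, wound (2,5), 50 uniform cells, P=0.01, h=0.07."""
    cfg = wf.Case1D()
    cells = wf.uniform_cells_1d(cfg.a, cfg.b, cfg.ns, P=cfg.P)
    return cfg, cells


@pytest.fixture(scope="session")
def bench1d_solved(bench1d):
    cfg, cells = bench1d
    fields, report = wf.run_case_1d(cfg, cells=cells)
    return cfg, cells, fields, report


@pytest.fixture(scope="session")
def wound2d():
    """Standard 2D geometry: 20x20 tissue, centred 10x10 wound, Table of
    dimensionless parameters E=1, nu=0.49, P=10."""
    return wf.WoundGeometry(((-10.0, -10.0), (10.0, 10.0)), ((-5.0, -5.0), (5.0, 5.0)))


@pytest.fixture
def small_trimesh():
    return wf.structured_trimesh(((0.0, 0.0), (1.0, 1.0)), 4, 4)


def hat_1d(mesh, j):
    """P1 hat function centred at node j, for quadrature oracles."""

    def phi(x):
        x = np.asarray(x, dtype=float)
        return np.clip(1.0 - np.abs(x - mesh.nodes[j]) / mesh.h, 0.0, None)

    return phi
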