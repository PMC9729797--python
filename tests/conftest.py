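import math

import numpy as np
import pytest

from osteolattice.geometry import TriMesh


def make_cube(edge: float = 15.0, origin=(0.0, 0.0, 0.0)) -> TriMesh:
    o = np.asarray(origin, dtype=np.float64)
    v = np.array([[x, y, z] for x in (0, edge) for y in (0, edge)
                  for z in (0, edge)], dtype=np.float64) + o
    f = np.array([[0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
                  [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
                  [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3]])
    m = TriMesh(v, f)
    if m.volume() < 0:
        m.faces = m.faces[:, ::-1]
    return m


def make_sphere(radius: float = 10.0, n: int = 40) -> TriMesh:
    th = np.linspace(0, np.pi, n)
    ph = np.linspace(0, 2 * np.pi, 2 * n, endpoint=False)
    verts = [(0.0, 0.0, radius)]
    for t in th[1:-1]:
        for p in ph:
            verts.append((radius * math.sin(t) * math.cos(p),
                          radius * math.sin(t) * math.sin(p),
                          radius * math.cos(t)))
    verts.append((0.0, 0.0, -radius))
    faces = []

    def vid(i, j):
        return 1 + (i - 1) * len(ph) + (j % len(ph))

    for j in range(len(ph)):
        faces.append((0, vid(1, j), vid(1, j + 1)))
    for i in range(1, len(th) - 2):
        for j in range(len(ph)):
            faces.append((vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)))
            faces.append((vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)))
    last = len(verts) - 1
    for j in range(len(ph)):
        faces.append((last, vid(len(th) - 2, j + 1), vid(len(th) - 2, j)))
    m = TriMesh(np.array(verts), np.array(faces))
    if m.volume() < 0:
        m.faces = m.faces[:, ::-1]
    return m


@pytest.fixture(scope="session")
def cube15():
    return make_cube(15.0)


@pytest.fixture(scope="session")
def sphere10():
    return make_sphere(10.0)


@pytest.fixture(scope="session")
def default_fixture():
    from osteolattice.fixtures import make_defect_fixture
    return make_defect_fixture(40.0, 20.0, 10.0, 0.15, 42)


@pytest.fixture(scope="session")
def default_lattice(default_fixture):
    from osteolattice.config import PipelineConfig
    from osteolattice.pipeline import build_lattice
    return build_lattice(default_fixture, PipelineConfig())


@pytest.fixture(scope="session")
def small_config(tmp_path_factory):
    """Scaled-down but structurally complete pipeline configuration."""
    from osteolattice.config import PipelineConfig
    return PipelineConfig(span_mm=24.0, height_mm=14.0, width_mm=8.0,
                          curvature=0.1, defect_fraction=0.45,
                          voxel_mm=1.25, max_iterations=2)


@pytest.fixture(scope="session")
def small_problem(small_config):
    """(design, load case) pair on the scaled-down fixture."""
    from osteolattice.model import build_load_case
    from osteolattice.pipeline import (build_design, build_fixture,
                                       build_lattice)
    fx = build_fixture(small_config)
    design = build_design(fx, build_lattice(fx, small_config), small_config)
    return design, build_load_case(fx)
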