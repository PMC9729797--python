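"""Seeded synthetic geometries: defect surrogate and solver benchmarks.

The defect fixture is a swept curved prism standing in for a unilateral
segmental mandibular-body defect: a closed outer surface, an enclosed
defect region spanning the missing segment, labeled node sets for the two
residual-bone cut planes, the occlusal load patch, the condylar support,
and eight muscle attachment sites per side.

Everything is deterministic for a fixed (parameters, seed) pair; the seed
only jitters muscle attachment positions along the surface.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError
from .fe import FEModel, assemble
from .geometry import TriMesh
from .materials import MUSCLE_NAMES, MaterialProperties

#: Placeholder unit direction vectors (left side; y mirrored for right).
#: The source anatomy reference is not reproducible here, so these are
#: fixture-defined constants, overridable through the pipeline config.
MUSCLE_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    "anterior temporalis": (-0.10, 0.15, 0.98),
    "posterior temporalis": (-0.55, 0.12, 0.83),
    "superior lateral pterygoid": (0.64, -0.76, 0.10),
    "inferior lateral pterygoid": (0.76, -0.63, -0.17),
    "medial pterygoid": (0.35, -0.49, 0.80),
    "superficial masseter": (0.20, -0.42, 0.88),
    "deep anterior masseter": (0.05, -0.55, 0.83),
    "deep posterior masseter": (-0.28, -0.55, 0.79),
}


@dataclass
class MuscleSite:
    name: str
    side: str                        # 'left' (+y) or 'right' (-y)
    point: np.ndarray                # attachment, mm, on the outer surface
    direction: np.ndarray            # unit pull direction


@dataclass
class DefectFixture:
    outer_surface: TriMesh
    defect_region: TriMesh
    stump_faces: tuple[np.ndarray, np.ndarray]   # defect-mesh vertex ids
    occlusal_nodes: np.ndarray                   # outer-mesh vertex ids
    condyle_nodes: np.ndarray                    # outer-mesh vertex ids
    muscle_sites: list[MuscleSite]
    seed: int
    params: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.outer_surface.vertices.tobytes())
        h.update(self.outer_surface.faces.tobytes())
        h.update(self.defect_region.vertices.tobytes())
        h.update(self.defect_region.faces.tobytes())
        for s in self.muscle_sites:
            h.update(s.point.tobytes())
        return h.hexdigest()

    def export(self, outdir, ascii: bool = False):
        """Write STL surfaces plus a JSON sidecar with 0-based node sets."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.outer_surface.save_stl(outdir / "outer_surface.stl", ascii=ascii)
        self.defect_region.save_stl(outdir / "defect_region.stl", ascii=ascii)
        sidecar = {
            "seed": self.seed,
            "params": self.params,
            "stump_faces": [s.tolist() for s in self.stump_faces],
            "occlusal_nodes": self.occlusal_nodes.tolist(),
            "condyle_nodes": self.condyle_nodes.tolist(),
            "muscle_sites": [
                {"name": s.name, "side": s.side,
                 "point": s.point.tolist(),
                 "direction": s.direction.tolist()}
                for s in self.muscle_sites],
        }
        (outdir / "fixture_sets.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True))


# -- swept-prism construction -----------------------------------------------

_N_SIDE = 6    # points per straight side piece
_N_ARC = 6     # points per fillet arc


def _section_profile(width: float, height: float) -> np.ndarray:
    """Closed CCW (y, z) profile of a rounded rectangle; fixed point count."""
    r = 0.2 * min(width, height)
    a = width / 2.0 - r
    b = height / 2.0 - r
    pts: list[tuple[float, float]] = []

    def side(p0, p1, n):
        for t in np.linspace(0.0, 1.0, n, endpoint=False):
            pts.append((p0[0] + t * (p1[0] - p0[0]),
                        p0[1] + t * (p1[1] - p0[1])))

    def arc(cy, cz, t0, t1, n):
        for t in np.linspace(t0, t1, n, endpoint=False):
            pts.append((cy + r * np.cos(t), cz + r * np.sin(t)))

    side((width / 2, -b), (width / 2, b), _N_SIDE)
    arc(a, b, 0.0, np.pi / 2, _N_ARC)
    side((a, height / 2), (-a, height / 2), _N_SIDE)
    arc(-a, b, np.pi / 2, np.pi, _N_ARC)
    side((-width / 2, b), (-width / 2, -b), _N_SIDE)
    arc(-a, -b, np.pi, 3 * np.pi / 2, _N_ARC)
    side((-a, -height / 2), (a, -height / 2), _N_SIDE)
    arc(a, -b, 3 * np.pi / 2, 2 * np.pi, _N_ARC)
    return np.array(pts)


def _sweep_prism(x0: float, x1: float, width: float, height: float,
                 span: float, curvature: float, n_axial: int,
                 scale: float = 1.0) -> TriMesh:
    """Closed swept prism between x0 and x1 along the curved centerline.

    The centerline lateral offset is evaluated in absolute x so that the
    defect sub-span follows the same curve as the full segment.
    """
    profile = _section_profile(width * scale, height * scale)
    n_p = len(profile)
    xs = np.linspace(x0, x1, n_axial + 1)
    verts = []
    for x in xs:
        yc = curvature * ((span / 2.0) ** 2 - (x - span / 2.0) ** 2) / span
        for (y, z) in profile:
            verts.append((x, yc + y, z))
    c0 = len(verts)
    yc0 = curvature * ((span / 2.0) ** 2 - (x0 - span / 2.0) ** 2) / span
    yc1 = curvature * ((span / 2.0) ** 2 - (x1 - span / 2.0) ** 2) / span
    verts.append((x0, yc0, 0.0))     # cap centers
    verts.append((x1, yc1, 0.0))
    verts = np.array(verts, dtype=np.float64)

    faces = []
    for i in range(n_axial):
        for j in range(n_p):
            j2 = (j + 1) % n_p
            a = i * n_p + j
            b = i * n_p + j2
            c = (i + 1) * n_p + j
            d = (i + 1) * n_p + j2
            faces.append((a, b, d))
            faces.append((a, d, c))
    for j in range(n_p):                       # start cap
        j2 = (j + 1) % n_p
        faces.append((c0, j2, j))
    base = n_axial * n_p
    for j in range(n_p):                       # end cap
        j2 = (j + 1) % n_p
        faces.append((c0 + 1, base + j, base + j2))
    mesh = TriMesh(verts, np.array(faces))
    if mesh.volume() < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def make_defect_fixture(span_mm: float = 40.0, height_mm: float = 20.0,
                        width_mm: float = 10.0, curvature: float = 0.0,
                        seed: int = 42, defect_fraction: float = 0.4,
                        n_axial: int = 32) -> DefectFixture:
    """Build the curved-prism defect surrogate with all labeled node sets.

    ``curvature`` bends the centerline laterally (0 = straight); the vertex
    count is independent of it, so meshes at different curvatures are
    directly comparable.
    """
    for name, v in (("span_mm", span_mm), ("height_mm", height_mm),
                    ("width_mm", width_mm)):
        if v <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {v}")
    if seed < 0:
        raise InvalidParameterError("seed must be non-negative")
    if not 0.1 <= defect_fraction <= 0.8:
        raise InvalidParameterError("defect_fraction must be in [0.1, 0.8]")
    if span_mm < 15.0:
        raise InvalidParameterError(
            "span must cover at least three unit-cell pitches (>= 15 mm)")

    outer = _sweep_prism(0.0, span_mm, width_mm, height_mm, span_mm,
                         curvature, n_axial)
    x_d0 = span_mm * (1.0 - defect_fraction) / 2.0
    x_d1 = span_mm * (1.0 + defect_fraction) / 2.0
    n_axial_defect = max(8, int(round(n_axial * defect_fraction)))
    defect = _sweep_prism(x_d0, x_d1, width_mm, height_mm, span_mm,
                          curvature, n_axial_defect, scale=0.96)

    dv = defect.vertices
    stump_a = np.where(np.abs(dv[:, 0] - x_d0) < 1e-9)[0]
    stump_b = np.where(np.abs(dv[:, 0] - x_d1) < 1e-9)[0]

    ov = outer.vertices
    top = ov[:, 2] > height_mm / 2.0 - 1e-6
    occlusal = np.where(top & (ov[:, 0] >= 0.05 * span_mm)
                        & (ov[:, 0] <= 0.22 * span_mm))[0]
    # both cut ends of the segment connect onward to residual mandible;
    # supporting both keeps the defect under bending + shear, not cantilever
    condyle = np.where((ov[:, 0] > span_mm - 1e-9) | (ov[:, 0] < 1e-9))[0]

    rng = np.random.default_rng(seed)
    b = height_mm / 2.0 - 0.2 * min(width_mm, height_mm)
    z_slots = np.linspace(-0.8 * b, 0.8 * b, 8)
    x_slots = np.linspace(0.60, 0.95, 8) * span_mm
    sites: list[MuscleSite] = []
    for side, sign in (("left", 1.0), ("right", -1.0)):
        for k, name in enumerate(MUSCLE_NAMES):
            x = float(np.clip(x_slots[k] + rng.uniform(-0.4, 0.4),
                              0.55 * span_mm, span_mm - 0.5))
            yc = curvature * ((span_mm / 2.0) ** 2
                              - (x - span_mm / 2.0) ** 2) / span_mm
            point = np.array([x, yc + sign * width_mm / 2.0,
                              float(z_slots[k])])
            d = np.array(MUSCLE_DIRECTIONS[name], dtype=np.float64)
            d = d * np.array([1.0, sign, 1.0])
            sites.append(MuscleSite(name, side, point,
                                    d / np.linalg.norm(d)))

    return DefectFixture(
        outer_surface=outer, defect_region=defect,
        stump_faces=(stump_a, stump_b),
        occlusal_nodes=occlusal, condyle_nodes=condyle,
        muscle_sites=sites, seed=int(seed),
        params={"span_mm": span_mm, "height_mm": height_mm,
                "width_mm": width_mm, "curvature": curvature,
                "defect_fraction": defect_fraction, "n_axial": n_axial})


# -- analytic solver benchmarks --------------------------------------------

def make_cantilever_benchmark(length_mm: float, diameter_mm: float, E: float,
                              n_elements: int = 10,
                              tip_load: float = 1.0) -> FEModel:
    """Clamped straight beam chain with a unit transverse tip load.

    Acceptance reference: Euler-Bernoulli tip deflection P L^3 / (3 E I).
    """
    if length_mm <= 0 or diameter_mm <= 0 or E <= 0:
        raise InvalidParameterError("cantilever dimensions must be positive")
    if length_mm / diameter_mm < 20:
        raise InvalidParameterError("cantilever must be slender (L/d >= 20)")
    mat = MaterialProperties("benchmark", E, 0.3)
    xs = np.linspace(0.0, length_mm, n_elements + 1)
    nodes = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
    fem = assemble(nodes,
                   beams=[(i, i + 1, diameter_mm, mat)
                          for i in range(n_elements)],
                   loads=[(n_elements, np.array([0.0, 0.0, -tip_load]))],
                   fixed=[0])
    return fem


def make_patch_test(voxel_count: int, E: float, nu: float,
                    strain: np.ndarray | None = None) -> FEModel:
    """Voxel block with a linear displacement field imposed on its boundary.

    ``strain`` is the symmetric 3x3 tensor of the constant state to impose
    (default: 1,000 ue uniaxial extension). Interior nodes are free; the
    trilinear element must reproduce the field exactly.
    """
    if voxel_count < 1:
        raise InvalidParameterError("voxel_count must be >= 1")
    if not 0.0 < nu < 0.5:
        raise InvalidParameterError("Poisson's ratio must lie in (0, 0.5)")
    if strain is None:
        strain = np.diag([1e-3, 0.0, 0.0])
    strain = np.asarray(strain, dtype=np.float64)
    if strain.shape != (3, 3) or not np.allclose(strain, strain.T):
        raise InvalidParameterError("strain must be a symmetric 3x3 tensor")

    n = int(voxel_count)
    h = 1.0
    axis = np.arange(n + 1) * h
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (n + 1) + j) * (n + 1) + k

    conn = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                conn.append([nid(i, j, k), nid(i + 1, j, k),
                             nid(i + 1, j + 1, k), nid(i, j + 1, k),
                             nid(i, j, k + 1), nid(i + 1, j, k + 1),
                             nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    mat = MaterialProperties("patch", E, nu)
    fem = assemble(nodes, voxels=np.array(conn),
                   voxel_materials=[mat] * len(conn), voxel_size=h)
    boundary = np.where((nodes == 0.0).any(axis=1)
                        | (nodes == n * h).any(axis=1))[0]
    for b in boundary:
        fem.prescribe(int(b), strain @ nodes[b])
    return fem
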