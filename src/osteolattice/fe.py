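"""Linear-elastic solver: Timoshenko beams, voxel hexahedra, grounded springs.

The discrete model mixes three element families in one symmetric sparse
system:

* two-node 3D Timoshenko beams with circular cross-section (6 dof/node)
  for lattice struts, screws and retainer frames;
* eight-node trilinear hexahedra (3 dof/node, full 2x2x2 integration) for
  the voxelized continuum (bone, graft, disc, tooth);
* grounded axial springs for the masticatory muscles.

Beam nodes are coupled to the continuum by rigid translation ties: a tied
strut node shares the translational dofs of its master voxel node while
keeping its own rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialProperties

SHEAR_CORRECTION = 0.9  # circular-section Timoshenko shear factor


class SingularModelError(RuntimeError):
    """The constrained system has rigid-body modes; lists suspect dofs."""


class AssemblyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# scalar stress / strain measures
# ---------------------------------------------------------------------------

def von_mises(stress: np.ndarray) -> float:
    """Equivalent (von-Mises) stress of a symmetric 3x3 stress tensor, MPa."""
    s = np.asarray(stress, dtype=np.float64)
    if s.shape != (3, 3):
        raise ValueError("expected a 3x3 stress tensor")
    dev = s - np.trace(s) / 3.0 * np.eye(3)
    return float(np.sqrt(1.5 * np.sum(dev * dev)))


def equivalent_strain(strain: np.ndarray) -> float:
    """Deviatoric equivalent strain of a symmetric 3x3 tensor, in microstrain.

    eps_eq = sqrt(2/3 * e:e) with e the deviatoric part; zero for pure
    volumetric strain, homogeneous of degree one.
    """
    e = np.asarray(strain, dtype=np.float64)
    if e.shape != (3, 3):
        raise ValueError("expected a 3x3 strain tensor")
    dev = e - np.trace(e) / 3.0 * np.eye(3)
    return float(np.sqrt(2.0 / 3.0 * np.sum(dev * dev)) * 1e6)


def _von_mises_voigt(s: np.ndarray) -> np.ndarray:
    """Vectorised von Mises for (n, 6) Voigt stresses [xx yy zz xy yz zx]."""
    sx, sy, sz, txy, tyz, tzx = s.T
    return np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                   + 3.0 * (txy ** 2 + tyz ** 2 + tzx ** 2))


def _equivalent_strain_voigt(e: np.ndarray) -> np.ndarray:
    """Vectorised deviatoric equivalent strain for (n, 6) engineering strains."""
    ex, ey, ez, gxy, gyz, gzx = e.T
    m = (ex + ey + ez) / 3.0
    dev2 = ((ex - m) ** 2 + (ey - m) ** 2 + (ez - m) ** 2
            + 0.5 * (gxy ** 2 + gyz ** 2 + gzx ** 2))
    return np.sqrt(2.0 / 3.0 * dev2)


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def isotropic_elasticity(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order [xx yy zz xy yz zx]."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3, 3] = D[4, 4] = D[5, 5] = mu
    return D

# VTK hexahedron corner order in natural coordinates
_HEX_XI = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                   dtype=np.float64)


def _hex8_b(xi: np.ndarray, h: float) -> np.ndarray:
    """Strain-displacement matrix (6, 24) at natural point xi for a cube
    of edge h (Jacobian is (h/2) * I)."""
    dN = np.empty((8, 3))
    for i, (a, b, c) in enumerate(_HEX_XI):
        dN[i] = [a * (1 + b * xi[1]) * (1 + c * xi[2]) / 8.0,
                 (1 + a * xi[0]) * b * (1 + c * xi[2]) / 8.0,
                 (1 + a * xi[0]) * (1 + b * xi[1]) * c / 8.0]
    dN *= 2.0 / h  # d/dx = (2/h) d/dxi
    B = np.zeros((6, 24))
    for i in range(8):
        dx, dy, dz = dN[i]
        c = 3 * i
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c] = dy
        B[3, c + 1] = dx
        B[4, c + 1] = dz
        B[4, c + 2] = dy
        B[5, c] = dz
        B[5, c + 2] = dx
    return B


def hex8_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 stiffness of an axis-aligned cube voxel, full integration."""
    D = isotropic_elasticity(E, nu)
    g = 1.0 / np.sqrt(3.0)
    detJ = (h / 2.0) ** 3
    K = np.zeros((24, 24))
    for a in (-g, g):
        for b in (-g, g):
            for c in (-g, g):
                B = _hex8_b(np.array([a, b, c]), h)
                K += B.T @ D @ B * detJ
    return K


def hex8_b_center(h: float) -> np.ndarray:
    return _hex8_b(np.zeros(3), h)


def beam_section(diameter: float) -> tuple[float, float, float]:
    """(area, second moment, polar moment) of a solid circular section."""
    if diameter <= 0:
        raise ValueError("beam diameter must be positive")
    A = np.pi * diameter ** 2 / 4.0
    I = np.pi * diameter ** 4 / 64.0
    J = 2.0 * I
    return A, I, J


def beam_local_stiffness(E: float, G: float, A: float, I: float, J: float,
                         L: float, kappa: float = SHEAR_CORRECTION) -> np.ndarray:
    """12x12 local stiffness of a 3D Timoshenko beam, circular section.

    Dof order per node: [ux uy uz rx ry rz]; local x is the beam axis.
    """
    phi = 12.0 * E * I / (kappa * G * A * L * L)
    k = np.zeros((12, 12))
    # axial
    ka = E * A / L
    k[np.ix_([0, 6], [0, 6])] += ka * np.array([[1, -1], [-1, 1]])
    # torsion
    kt = G * J / L
    k[np.ix_([3, 9], [3, 9])] += kt * np.array([[1, -1], [-1, 1]])
    # bending in local x-y plane (v, theta_z)
    c = E * I / (L ** 3 * (1 + phi))
    kb = c * np.array([
        [12, 6 * L, -12, 6 * L],
        [6 * L, (4 + phi) * L * L, -6 * L, (2 - phi) * L * L],
        [-12, -6 * L, 12, -6 * L],
        [6 * L, (2 - phi) * L * L, -6 * L, (4 + phi) * L * L]])
    k[np.ix_([1, 5, 7, 11], [1, 5, 7, 11])] += kb
    # bending in local x-z plane (w, theta_y) -- sign-flipped rotations
    kb2 = c * np.array([
        [12, -6 * L, -12, -6 * L],
        [-6 * L, (4 + phi) * L * L, 6 * L, (2 - phi) * L * L],
        [-12, 6 * L, 12, 6 * L],
        [-6 * L, (2 - phi) * L * L, 6 * L, (4 + phi) * L * L]])
    k[np.ix_([2, 4, 8, 10], [2, 4, 8, 10])] += kb2
    return k


def beam_rotation(axis: np.ndarray) -> np.ndarray:
    """3x3 rotation whose rows are the local (x, y, z) axes of a beam."""
    x = np.asarray(axis, dtype=np.float64)
    x = x / np.linalg.norm(x)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(x @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    y = np.cross(ref, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return np.vstack([x, y, z])


def beam_equivalent_stress(diameter: float, local_end_forces: np.ndarray) -> float:
    """Peak surface-fiber equivalent stress of a circular strut, MPa.

    Combines axial force, resultant bending moment and torsion at both ends:
    sigma_max = |N|/A + M*c/I, tau = T*c/J, vm = sqrt(sigma^2 + 3 tau^2).
    Equals the maximum of sqrt(sigma(theta)^2 + 3 tau^2) over the
    circumference (checked against an angular-sampling oracle in the tests).
    """
    if diameter <= 0:
        raise ValueError("zero-diameter strut")
    A, I, J = beam_section(diameter)
    c = diameter / 2.0
    f = np.asarray(local_end_forces, dtype=np.float64).reshape(12)
    best = 0.0
    for (N, T, My, Mz) in ((-f[0], -f[3], -f[4], -f[5]),
                           (f[6], f[9], f[10], f[11])):
        M = np.hypot(My, Mz)
        sigma = abs(N) / A + M * c / I
        tau = abs(T) * c / J
        best = max(best, float(np.sqrt(sigma * sigma + 3.0 * tau * tau)))
    return best


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class BeamElement:
    n1: int
    n2: int
    diameter: float
    material: MaterialProperties
    tag: str = "strut"


@dataclass
class SpringElement:
    node: int
    direction: np.ndarray
    stiffness: float

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=np.float64)
        self.direction = self.direction / np.linalg.norm(self.direction)


@dataclass
class FieldResult:
    """Solved fields: displacements (mm), element stresses (MPa), strains (ue)."""

    displacements: np.ndarray              # (n_nodes, 3)
    beam_stress: np.ndarray                # (n_beams,)
    voxel_stress: np.ndarray               # (n_voxels,) von Mises
    voxel_strain_ue: np.ndarray            # (n_voxels,) equivalent strain
    reactions: np.ndarray                  # (n_constrained_dofs,)
    constrained_dofs: np.ndarray
    residual: float

    def check_finite(self):
        for arr in (self.displacements, self.beam_stress,
                    self.voxel_stress, self.voxel_strain_ue):
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError("non-finite entries in field result")


class FEModel:
    """Assembled discrete system over a shared node table.

    Nodes may carry translational dofs (all referenced nodes), rotational
    dofs (beam-referenced nodes), or borrow their translations from a master
    node via a rigid tie.
    """

    def __init__(self, nodes: np.ndarray, voxel_size: float = 1.0,
                 strain_measure: str = "equivalent"):
        self.nodes = np.asarray(nodes, dtype=np.float64).reshape(-1, 3)
        self.voxel_size = float(voxel_size)
        self.strain_measure = strain_measure
        self.beams: list[BeamElement] = []
        self.voxels = np.empty((0, 8), dtype=np.int64)
        self.voxel_materials: list[MaterialProperties] = []
        self.springs: list[SpringElement] = []
        self.loads: list[tuple[int, np.ndarray]] = []
        self.prescribed: dict[int, np.ndarray] = {}
        self.fixed: set[int] = set()
        self.ties: dict[int, int] = {}     # slave node -> master node
        self._dofs = None

    # -- construction ---------------------------------------------------

    def add_beam(self, n1: int, n2: int, diameter: float,
                 material: MaterialProperties, tag: str = "strut"):
        if n1 == n2:
            raise AssemblyError(f"degenerate beam at node {n1}")
        self.beams.append(BeamElement(int(n1), int(n2), float(diameter),
                                      material, tag))

    def set_voxels(self, connectivity: np.ndarray,
                   materials: list[MaterialProperties]):
        self.voxels = np.asarray(connectivity, dtype=np.int64).reshape(-1, 8)
        if len(materials) != len(self.voxels):
            raise AssemblyError("one material per voxel required")
        self.voxel_materials = list(materials)

    def add_spring(self, node: int, direction, stiffness: float):
        self.springs.append(SpringElement(int(node), direction, float(stiffness)))

    def add_load(self, node: int, force):
        self.loads.append((int(node), np.asarray(force, dtype=np.float64)))

    def fix(self, nodes):
        for n in np.atleast_1d(np.asarray(nodes, dtype=np.int64)):
            self.fixed.add(int(n))

    def prescribe(self, node: int, displacement):
        self.prescribed[int(node)] = np.asarray(displacement, dtype=np.float64)

    def tie(self, slave: int, master: int):
        """Rigidly tie the slave node's translations to the master's."""
        self.ties[int(slave)] = int(master)

    # -- dof bookkeeping ------------------------------------------------

    def _owner(self, n: int) -> int:
        seen = set()
        while n in self.ties:
            if n in seen:
                raise AssemblyError(f"cyclic tie chain at node {n}")
            seen.add(n)
            n = self.ties[n]
        return n

    def _build_dofs(self):
        used = set()
        for b in self.beams:
            used.add(self._owner(b.n1))
            used.add(self._owner(b.n2))
        used.update(int(v) for v in np.unique(self.voxels))
        for s in self.springs:
            used.add(self._owner(s.node))
        for n, _ in self.loads:
            used.add(self._owner(n))
        for n in list(self.prescribed) + list(self.fixed):
            used.add(self._owner(n))
        trans = {}
        next_dof = 0
        for n in sorted(used):
            trans[n] = next_dof
            next_dof += 3
        rot = {}
        beam_nodes = sorted({b.n1 for b in self.beams}
                            | {b.n2 for b in self.beams})
        for n in beam_nodes:
            rot[n] = next_dof
            next_dof += 3
        self._dofs = (trans, rot, next_dof)
        return self._dofs

    def translation_dofs(self, node: int) -> np.ndarray:
        trans, _, _ = self._dofs or self._build_dofs()
        base = trans[self._owner(int(node))]
        return np.arange(base, base + 3)

    def _beam_dofs(self, b: BeamElement) -> np.ndarray:
        trans, rot, _ = self._dofs
        out = np.empty(12, dtype=np.int64)
        for k, n in enumerate((b.n1, b.n2)):
            t = trans[self._owner(n)]
            r = rot[n]
            out[6 * k:6 * k + 3] = (t, t + 1, t + 2)
            out[6 * k + 3:6 * k + 6] = (r, r + 1, r + 2)
        return out

    # -- assembly -------------------------------------------------------

    def system(self) -> tuple[sp.csr_matrix, np.ndarray]:
        """Global stiffness matrix and load vector (unconstrained)."""
        trans, rot, ndof = self._build_dofs()
        rows, cols, vals = [], [], []

        # voxels, grouped by material for a shared element matrix
        if len(self.voxels):
            groups: dict[tuple[float, float], list[int]] = {}
            for i, m in enumerate(self.voxel_materials):
                groups.setdefault((m.E, m.nu), []).append(i)
            tdof = np.empty((self.nodes.shape[0],), dtype=np.int64)
            tdof.fill(-1)
            for n, base in trans.items():
                tdof[n] = base
            conn = self.voxels
            edof = np.repeat(tdof[conn], 3, axis=1)
            edof[:, 1::3] += 1
            edof[:, 2::3] += 2
            for (E, nu), idx in groups.items():
                ke = hex8_stiffness(E, nu, self.voxel_size)
                ed = edof[idx]                                   # (g, 24)
                rows.append(np.repeat(ed, 24, axis=1).ravel())
                cols.append(np.tile(ed, (1, 24)).ravel())
                vals.append(np.tile(ke.ravel(), len(idx)))

        # beams
        for b in self.beams:
            p1, p2 = self.nodes[b.n1], self.nodes[b.n2]
            L = float(np.linalg.norm(p2 - p1))
            if L < 1e-12:
                raise AssemblyError(f"zero-length beam {b.n1}-{b.n2}")
            A, I, J = beam_section(b.diameter)
            kl = beam_local_stiffness(b.material.E, b.material.G, A, I, J, L)
            R = beam_rotation(p2 - p1)
            T = np.zeros((12, 12))
            for k in range(4):
                T[3 * k:3 * k + 3, 3 * k:3 * k + 3] = R
            kg = T.T @ kl @ T
            d = self._beam_dofs(b)
            rows.append(np.repeat(d, 12))
            cols.append(np.tile(d, 12))
            vals.append(kg.ravel())

        # grounded springs: k * d d^T on the node's translations
        for s in self.springs:
            d = self.translation_dofs(s.node)
            block = s.stiffness * np.outer(s.direction, s.direction)
            rows.append(np.repeat(d, 3))
            cols.append(np.tile(d, 3))
            vals.append(block.ravel())

        if rows:
            K = sp.coo_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(ndof, ndof)).tocsr()
        else:
            K = sp.csr_matrix((ndof, ndof))

        f = np.zeros(ndof)
        for n, force in self.loads:
            f[self.translation_dofs(n)] += force
        return K, f

    def _constrained(self) -> tuple[np.ndarray, np.ndarray]:
        """(dof indices, prescribed values) for all constraints."""
        trans, rot, ndof = self._dofs
        dofs, vals = [], []
        seen = set()
        for n, u in self.prescribed.items():
            for k, dof in enumerate(self.translation_dofs(n)):
                if dof not in seen:
                    dofs.append(dof)
                    vals.append(u[k])
                    seen.add(dof)
        for n in sorted(self.fixed):
            for dof in self.translation_dofs(n):
                if dof not in seen:
                    dofs.append(int(dof))
                    vals.append(0.0)
                    seen.add(int(dof))
            if n in rot:
                for dof in range(rot[n], rot[n] + 3):
                    if dof not in seen:
                        dofs.append(dof)
                        vals.append(0.0)
                        seen.add(dof)
        return (np.array(dofs, dtype=np.int64),
                np.array(vals, dtype=np.float64))


def assemble(nodes: np.ndarray, *, beams=(), voxels=None, voxel_materials=None,
             voxel_size: float = 1.0, springs=(), loads=(), fixed=(),
             prescribed=None, ties=(), tie_tolerance: float | None = None,
             strain_measure: str = "equivalent") -> FEModel:
    """Build an FEModel from element/boundary descriptions.

    ``ties`` may be explicit (slave, master) pairs; alternatively, with
    ``tie_tolerance`` set, every beam node is tied to its nearest voxel node
    within that distance, and a floating strut node raises
    :class:`AssemblyError` naming the node.
    """
    fem = FEModel(nodes, voxel_size=voxel_size, strain_measure=strain_measure)
    for b in beams:
        fem.add_beam(*b[:4], tag=b[4] if len(b) > 4 else "strut")
    if voxels is not None and len(voxels):
        fem.set_voxels(voxels, voxel_materials)
    for s in springs:
        fem.add_spring(*s)
    for n, force in loads:
        fem.add_load(n, force)
    fixed = list(fixed)
    if fixed:
        fem.fix(np.asarray(fixed, dtype=np.int64))
    for n, u in (prescribed or {}).items():
        fem.prescribe(n, u)
    for slave, master in ties:
        fem.tie(slave, master)
    if tie_tolerance is not None and len(fem.voxels):
        from scipy.spatial import cKDTree
        vox_nodes = np.unique(fem.voxels)
        tree = cKDTree(fem.nodes[vox_nodes])
        beam_nodes = sorted({b.n1 for b in fem.beams}
                            | {b.n2 for b in fem.beams})
        d, idx = tree.query(fem.nodes[beam_nodes])
        for bn, dist, j in zip(beam_nodes, d, idx):
            if dist > tie_tolerance:
                raise AssemblyError(
                    f"floating strut node {bn}: nearest voxel node is "
                    f"{dist:.3f} mm away (tolerance {tie_tolerance})")
            fem.tie(bn, int(vox_nodes[j]))
    return fem


def solve(fem: FEModel, dense: bool = False) -> FieldResult:
    """Linear static solve with support for non-zero prescribed displacements.

    Raises :class:`SingularModelError` with a list of suspect dofs when the
    constrained system still has rigid-body modes.
    """
    K, f = fem.system()
    ndof = K.shape[0]
    cdofs, cvals = fem._constrained()
    u = np.zeros(ndof)
    u[cdofs] = cvals
    free = np.ones(ndof, dtype=bool)
    free[cdofs] = False
    Kc = K.tocsc()
    Kff = Kc[free][:, free]
    rhs = f[free] - Kc[free][:, ~free] @ u[~free]

    if Kff.shape[0]:
        if dense:
            try:
                u[free] = np.linalg.solve(Kff.toarray(), rhs)
            except np.linalg.LinAlgError as exc:
                raise SingularModelError(str(exc)) from exc
        else:
            try:
                lu = spla.splu(Kff.tocsc(),
                               options={"SymmetricMode": True})
                uf = lu.solve(rhs)
            except RuntimeError as exc:
                raise SingularModelError(
                    _diagnose_singularity(Kff)) from exc
            if not np.all(np.isfinite(uf)):
                raise SingularModelError(_diagnose_singularity(Kff))
            u[free] = uf

    r = K @ u - f
    fnorm = max(np.linalg.norm(f), np.linalg.norm(r[~free]), 1e-30)
    residual = float(np.linalg.norm(r[free]) / fnorm)
    if residual > 1e-6:
        raise SingularModelError(
            f"equilibrium residual {residual:.2e}; system likely singular")
    reactions = r[cdofs]

    # recover per-node displacements (translations, honouring ties)
    trans, rot, _ = fem._dofs
    disp = np.zeros_like(fem.nodes)
    for n in range(len(fem.nodes)):
        owner = fem._owner(n)
        if owner in trans:
            base = trans[owner]
            disp[n] = u[base:base + 3]

    beam_stress = np.zeros(len(fem.beams))
    for i, b in enumerate(fem.beams):
        p1, p2 = fem.nodes[b.n1], fem.nodes[b.n2]
        L = float(np.linalg.norm(p2 - p1))
        A, I, J = beam_section(b.diameter)
        kl = beam_local_stiffness(b.material.E, b.material.G, A, I, J, L)
        R = beam_rotation(p2 - p1)
        T = np.zeros((12, 12))
        for k in range(4):
            T[3 * k:3 * k + 3, 3 * k:3 * k + 3] = R
        fl = kl @ (T @ u[fem._beam_dofs(b)])
        beam_stress[i] = beam_equivalent_stress(b.diameter, fl)

    if len(fem.voxels):
        tdof = np.full(len(fem.nodes), -1, dtype=np.int64)
        for n, base in trans.items():
            tdof[n] = base
        edof = np.repeat(tdof[fem.voxels], 3, axis=1)
        edof[:, 1::3] += 1
        edof[:, 2::3] += 2
        ue = u[edof]                                       # (n_vox, 24)
        B = hex8_b_center(fem.voxel_size)
        strains = ue @ B.T                                 # Voigt engineering
        stresses = np.empty_like(strains)
        groups: dict[tuple[float, float], list[int]] = {}
        for i, m in enumerate(fem.voxel_materials):
            groups.setdefault((m.E, m.nu), []).append(i)
        for (E, nu), idx in groups.items():
            stresses[idx] = strains[idx] @ isotropic_elasticity(E, nu).T
        voxel_stress = _von_mises_voigt(stresses)
        if fem.strain_measure == "principal":
            voxel_strain = _max_principal_strain(strains) * 1e6
        else:
            voxel_strain = _equivalent_strain_voigt(strains) * 1e6
    else:
        voxel_stress = np.zeros(0)
        voxel_strain = np.zeros(0)

    result = FieldResult(disp, beam_stress, voxel_stress, voxel_strain,
                         reactions, cdofs, residual)
    result.check_finite()
    return result


def _max_principal_strain(strains: np.ndarray) -> np.ndarray:
    out = np.empty(len(strains))
    for i, v in enumerate(strains):
        T = np.array([[v[0], v[3] / 2, v[5] / 2],
                      [v[3] / 2, v[1], v[4] / 2],
                      [v[5] / 2, v[4] / 2, v[2]]])
        out[i] = np.max(np.abs(np.linalg.eigvalsh(T)))
    return out


def _diagnose_singularity(Kff: sp.spmatrix) -> str:
    diag = np.asarray(Kff.todense()).diagonal() if Kff.shape[0] < 500 \
        else Kff.diagonal()
    bad = np.where(np.abs(diag) < 1e-10 * max(np.abs(diag).max(), 1.0))[0]
    return ("singular constrained system; near-zero stiffness at reduced "
            f"dofs {bad[:20].tolist()}")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_vtk(fem: FEModel, result: FieldResult, path):
    """Legacy-ASCII VTK unstructured grid with named result arrays."""
    lines = ["# vtk DataFile Version 3.0", "osteolattice result", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(fem.nodes)} double"]
    for p in fem.nodes:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    n_cells = len(fem.voxels) + len(fem.beams)
    size = len(fem.voxels) * 9 + len(fem.beams) * 3
    lines.append(f"CELLS {n_cells} {size}")
    for v in fem.voxels:
        lines.append("8 " + " ".join(str(int(i)) for i in v))
    for b in fem.beams:
        lines.append(f"2 {b.n1} {b.n2}")
    lines.append(f"CELL_TYPES {n_cells}")
    lines.extend(["12"] * len(fem.voxels))
    lines.extend(["3"] * len(fem.beams))
    lines.append(f"CELL_DATA {n_cells}")
    lines.append("SCALARS vm_stress_MPa double 1")
    lines.append("LOOKUP_TABLE default")
    for s in result.voxel_stress:
        lines.append(f"{s:.9g}")
    for s in result.beam_stress:
        lines.append(f"{s:.9g}")
    lines.append("SCALARS eq_strain_ue double 1")
    lines.append("LOOKUP_TABLE default")
    for s in result.voxel_strain_ue:
        lines.append(f"{s:.9g}")
    for _ in result.beam_stress:
        lines.append("0")
    lines.append(f"POINT_DATA {len(fem.nodes)}")
    lines.append("VECTORS displacement_mm double")
    for d in result.displacements:
        lines.append(f"{d[0]:.9g} {d[1]:.9g} {d[2]:.9g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
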