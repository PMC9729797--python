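"""Full evaluation model: voxelized segment + embedded lattice + load case.

The outer fixture volume is voxelized once; voxel centers are classified
into cortical shell, cancellous core, graft space (inside the defect
region, outside the strut capsules), an articular-disc layer next to the
fixed support face and a tooth patch under the bite load.  The lattice is
embedded as beam elements tied to the continuum.  Only the capsule mask
changes when the optimizer updates strut diameters, so the expensive
containment/distance classification is computed once and reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import fe
from .fixtures import DefectFixture
from .lattice import LatticeModel, capsule_union_mask
from .materials import (DEFAULT_MATERIALS, MUSCLE_FORCES, LoadCase,
                        MaterialProperties, MuscleLoad, muscle_stiffness)

# voxel label codes
EMPTY, CORTICAL, CANCELLOUS, GRAFT, DISC, TOOTH = 0, 1, 2, 3, 4, 5

_LABEL_MATERIAL = {CORTICAL: "cortical", CANCELLOUS: "cancellous",
                   DISC: "disc", TOOTH: "tooth"}


def build_load_case(fixture: DefectFixture, bite_force: float = 800.0,
                    materials: dict | None = None) -> LoadCase:
    """Default masticatory load case on the fixture.

    Muscle attachments are carried as indices into ``fixture.muscle_sites``
    and resolved to voxel nodes at assembly time.
    """
    muscles = []
    for i, site in enumerate(fixture.muscle_sites):
        muscles.append(MuscleLoad(
            name=site.name, side=site.side,
            force=MUSCLE_FORCES[site.side][site.name],
            direction=site.direction,
            spring_stiffness=muscle_stiffness(site.name),
            attachment=i))
    return LoadCase(bite_force=bite_force,
                    occlusal_nodes=fixture.occlusal_nodes,
                    muscles=muscles,
                    fixed_nodes=fixture.condyle_nodes)


@dataclass
class DesignModel:
    """Voxelized fixture + lattice, ready for per-stage assembly."""

    fixture: DefectFixture
    lattice: LatticeModel
    voxel_mm: float
    origin: np.ndarray
    shape: tuple[int, int, int]
    labels: np.ndarray                   # (nx, ny, nz) int8, strut-independent
    strut_mask: np.ndarray               # voxels swallowed by strut capsules
    materials: dict[str, MaterialProperties] = field(
        default_factory=lambda: dict(DEFAULT_MATERIALS))
    strain_measure: str = "equivalent"

    # ------------------------------------------------------------------
    @classmethod
    def build(cls, fixture: DefectFixture, lattice: LatticeModel,
              voxel_mm: float = 1.25, shell_mm: float = 1.5,
              tooth_radius_mm: float = 3.0, disc_mm: float = 2.0,
              materials: dict | None = None,
              strain_measure: str = "equivalent") -> "DesignModel":
        outer = fixture.outer_surface
        bmin, bmax = outer.bounds()
        shape = tuple(int(np.ceil((bmax[i] - bmin[i]) / voxel_mm)) + 1
                      for i in range(3))
        ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        centers = bmin + (ijk + 0.5) * voxel_mm
        inside_outer = outer.contains(centers)
        inside_defect = np.zeros(len(centers), dtype=bool)
        inside_defect[inside_outer] = fixture.defect_region.contains(
            centers[inside_outer])

        labels = np.zeros(len(centers), dtype=np.int8)
        bone = inside_outer & ~inside_defect
        labels[inside_defect] = GRAFT
        if bone.any():
            surf_d = outer.distance_to_surface(centers[bone])
            lab = np.where(surf_d < shell_mm, CORTICAL, CANCELLOUS)
            labels[np.where(bone)[0]] = lab
            # articular-disc layer against the fixed (condylar) face
            xmax = outer.vertices[:, 0].max()
            disc_sel = bone & (centers[:, 0] > xmax - disc_mm)
            labels[disc_sel] = DISC
            # tooth patch under the occlusal nodes
            occ_pts = outer.vertices[fixture.occlusal_nodes]
            if len(occ_pts):
                tree = cKDTree(occ_pts)
                d, _ = tree.query(centers[bone])
                tooth_sel = np.where(bone)[0][d < tooth_radius_mm]
                labels[tooth_sel] = TOOTH

        model = cls(fixture, lattice, float(voxel_mm),
                    np.asarray(bmin, dtype=np.float64), shape,
                    labels.reshape(shape),
                    np.zeros(shape, dtype=bool),
                    materials=dict(materials or DEFAULT_MATERIALS),
                    strain_measure=strain_measure)
        model._apply_strut_mask()
        return model

    def _apply_strut_mask(self):
        """Recompute which voxels fall inside the capsule union."""
        if self.lattice.n_struts == 0:
            self.strut_mask = np.zeros(self.shape, dtype=bool)
            return
        graft = self.labels == GRAFT
        ijk = np.argwhere(graft)
        centers = self.origin + (ijk + 0.5) * self.voxel_mm
        a, b, r = self.lattice.segments()
        hit = capsule_union_mask(centers, a, b, r)
        mask = np.zeros(self.shape, dtype=bool)
        mask[tuple(ijk[hit].T)] = True
        self.strut_mask = mask

    def with_lattice(self, lattice: LatticeModel) -> "DesignModel":
        """Same voxel grid and classification, new strut layout."""
        model = DesignModel(self.fixture, lattice, self.voxel_mm,
                            self.origin, self.shape, self.labels,
                            np.zeros(self.shape, dtype=bool),
                            materials=self.materials,
                            strain_measure=self.strain_measure)
        model._apply_strut_mask()
        return model

    # ------------------------------------------------------------------
    def _grid_assembly(self):
        """Voxel connectivity, compressed node table, label per element."""
        occupied = (self.labels != EMPTY) & ~self.strut_mask
        ijk = np.argwhere(occupied)
        nx, ny, nz = self.shape

        def raw_id(i, j, k):
            return (i * (ny + 1) + j) * (nz + 1) + k

        offs = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]])
        corners = ijk[:, None, :] + offs[None, :, :]
        raw = ((corners[..., 0] * (ny + 1) + corners[..., 1]) * (nz + 1)
               + corners[..., 2])
        used, conn = np.unique(raw, return_inverse=True)
        conn = conn.reshape(raw.shape)
        kk = used % (nz + 1)
        jj = (used // (nz + 1)) % (ny + 1)
        ii = used // ((nz + 1) * (ny + 1))
        node_xyz = self.origin + np.column_stack([ii, jj, kk]) * self.voxel_mm
        elem_labels = self.labels[tuple(ijk.T)]
        return node_xyz, conn, elem_labels

    def assemble_stage(self, graft_material: MaterialProperties,
                       load: LoadCase) -> tuple[fe.FEModel, dict]:
        """FE model for one healing stage; returns (model, metadata).

        Metadata carries the element labels and index maps needed to slice
        the solved fields into implant/graft statistics.
        """
        node_xyz, conn, elem_labels = self._grid_assembly()
        n_vox_nodes = len(node_xyz)
        nodes = np.vstack([node_xyz, self.lattice.nodes])

        mat_of = {lab: self.materials[name]
                  for lab, name in _LABEL_MATERIAL.items()}
        mat_of[GRAFT] = graft_material
        voxel_materials = [mat_of[int(l)] for l in elem_labels]

        ti = self.materials["Ti6Al4V"]
        beams = [(int(a) + n_vox_nodes, int(b) + n_vox_nodes, float(d), ti, t)
                 for (a, b), d, t in zip(self.lattice.edges,
                                         self.lattice.diameters,
                                         self.lattice.tags)]

        tree = cKDTree(node_xyz)
        ov = self.fixture.outer_surface.vertices
        _, fixed = tree.query(ov[load.fixed_nodes])
        fixed = np.unique(fixed)
        _, occ = tree.query(ov[load.occlusal_nodes])
        occ = np.setdiff1d(np.unique(occ), fixed)

        loads = []
        bite_each = (load.bite_force / len(occ)) * load.bite_direction
        for n in occ:
            loads.append((int(n), bite_each))
        springs = []
        for m in load.muscles:
            site = self.fixture.muscle_sites[m.attachment]
            _, n = tree.query(site.point)
            loads.append((int(n), m.force * m.direction))
            springs.append((int(n), m.direction, m.spring_stiffness))

        fem = fe.assemble(nodes, beams=beams, voxels=conn,
                          voxel_materials=voxel_materials,
                          voxel_size=self.voxel_mm,
                          springs=springs, loads=loads, fixed=fixed,
                          tie_tolerance=2.5 * self.voxel_mm,
                          strain_measure=self.strain_measure)
        meta = {"elem_labels": elem_labels, "conn": conn,
                "n_vox_nodes": n_vox_nodes,
                "occlusal": occ, "fixed": fixed}
        return fem, meta

    # ------------------------------------------------------------------
    def implant_stress_field(self, result: fe.FieldResult) -> np.ndarray:
        """Node-based implant stress sample: volume-weighted strut-node
        averages plus per-strut midside values (MPa).

        Fixation struts (retainer frames, screws) transfer load but are
        not a criterion target, so they are excluded from the statistic.
        """
        lat = self.lattice
        body = np.array([t in ("trabecular", "grid") for t in lat.tags])
        w = (np.pi * (lat.diameters / 2.0) ** 2) * lat.lengths()
        num = np.zeros(len(lat.nodes))
        den = np.zeros(len(lat.nodes))
        for e in np.where(body)[0]:
            for n in lat.edges[e]:
                num[n] += result.beam_stress[e] * w[e]
                den[n] += w[e]
        node_vals = num[den > 0] / den[den > 0]
        return np.concatenate([node_vals, result.beam_stress[body]])

    def graft_strain_field(self, result: fe.FieldResult,
                           meta: dict) -> np.ndarray:
        """Voxel-node averaged equivalent strain over the graft (ue)."""
        graft = meta["elem_labels"] == GRAFT
        conn = meta["conn"][graft]
        vals = result.voxel_strain_ue[graft]
        n_nodes = meta["n_vox_nodes"]
        num = np.zeros(n_nodes)
        den = np.zeros(n_nodes)
        for c, v in zip(conn, vals):
            num[c] += v
            den[c] += 1.0
        sel = den > 0
        return num[sel] / den[sel]
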