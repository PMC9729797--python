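import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_cube
from osteolattice.errors import (EmptyLatticeError, InvalidParameterError,
                                 ResolutionError)
from osteolattice.lattice import (FixationSpec, LatticeModel, StrutSpec,
                                  UnitCellSpec, assign_gradient_diameters,
                                  boolean_graft_region, build_grid_shell,
                                  cell_openings, lattice_to_surface,
                                  merge_components, place_fixation, porosity,
                                  tessellate_trabecular)


@pytest.fixture(scope="module")
def cube_lattice(cube15):
    return tessellate_trabecular(cube15, UnitCellSpec())


class TestTrabecular:
    def test_connected_and_inside(self, cube15, cube_lattice):
        assert cube_lattice.is_connected()
        # every node inside or on the region (ray-casting oracle)
        inside = cube15.contains(cube_lattice.nodes)
        on_surface = cube15.distance_to_surface(
            cube_lattice.nodes[~inside]) < 1e-3 if (~inside).any() else \
            np.empty(0, dtype=bool)
        assert inside.all() or on_surface.all()

    def test_pore_opening_scale(self, cube15, cube_lattice):
        cell = UnitCellSpec()
        openings = cell_openings(cube_lattice, cell, cube15)
        assert len(openings)
        assert abs(np.mean(openings) - cell.pore_diameter) \
            < 0.1 * cell.pore_diameter

    def test_halving_pore_octuples_struts(self, cube15, cube_lattice):
        fine = tessellate_trabecular(cube15, UnitCellSpec(pore_diameter=2.5))
        ratio = fine.n_struts / cube_lattice.n_struts
        assert abs(ratio - 8.0) < 0.15 * 8.0

    def test_rotation_equivariance(self, cube15):
        from osteolattice.geometry import TriMesh
        from scipy.spatial import cKDTree
        R = Rotation.from_euler("xyz", [20, 35, -10], degrees=True
                                ).as_matrix()
        rotated = TriMesh(cube15.vertices @ R.T, cube15.faces)
        lat1 = tessellate_trabecular(cube15,
                                     UnitCellSpec(orientation=np.eye(3)))
        lat2 = tessellate_trabecular(rotated,
                                     UnitCellSpec(orientation=np.eye(3) @ R.T))
        assert lat1.n_struts == lat2.n_struts
        d, _ = cKDTree(lat2.nodes @ R).query(lat1.nodes)
        assert d.max() < 1e-6

    def test_too_small_region_raises(self):
        with pytest.raises(EmptyLatticeError):
            tessellate_trabecular(make_cube(2.0), UnitCellSpec())

    def test_regular_dodecahedron_option(self, cube15):
        lat = tessellate_trabecular(
            cube15, UnitCellSpec(cell_kind="regular_dodecahedron_wireframe"))
        assert lat.n_struts > 0
        assert lat.is_connected()


class TestGridShell:
    def test_cube_faces_carry_3x3_grid(self, cube15):
        grid = build_grid_shell(cube15, UnitCellSpec())
        # nearest-surface-distance oracle
        d = cube15.distance_to_surface(grid.nodes)
        assert d.max() < 0.1
        g = grid.graph()
        g.remove_nodes_from(list(nx.isolates(g)))
        V, E = g.number_of_nodes(), g.number_of_edges()
        F = 2 - V + E
        assert F == 54  # 6 faces x (3x3 openings)

    def test_sphere_struts_on_surface(self, sphere10):
        grid = build_grid_shell(sphere10, UnitCellSpec())
        mids = 0.5 * (grid.nodes[grid.edges[:, 0]]
                      + grid.nodes[grid.edges[:, 1]])
        r = np.linalg.norm(mids, axis=1)
        assert np.abs(r - 10.0).max() < 0.2

    def test_sphere_opening_areas(self, sphere10):
        # per-face area check via the Euler face count: the median opening
        # (total area / number of graph faces) tracks pore^2
        cell = UnitCellSpec()
        grid = build_grid_shell(sphere10, cell)
        g = grid.graph()
        g.remove_nodes_from(list(nx.isolates(g)))
        F = 2 - g.number_of_nodes() + g.number_of_edges()
        mean_area = sphere10.area() / F
        assert abs(mean_area - cell.pore_diameter ** 2) \
            < 0.25 * cell.pore_diameter ** 2

    def test_merge_keeps_connectivity(self, cube15, cube_lattice):
        grid = build_grid_shell(cube15, UnitCellSpec())
        merged = merge_components(cube_lattice, grid)
        assert merged.is_connected()
        assert merged.n_struts <= cube_lattice.n_struts + grid.n_struts + 10

    def test_disjoint_components_tied(self):
        # zero snap tolerance between far-apart parts: explicit tie struts
        a = LatticeModel(np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                         np.array([[0, 1]]), np.array([0.5]), ["trabecular"],
                         provenance={"pore_diameter": 5.0})
        b = LatticeModel(np.array([[10.0, 0, 0], [11.0, 0, 0]]),
                         np.array([[0, 1]]), np.array([0.5]), ["grid"])
        merged = merge_components(a, b, snap_tol=0.0)
        assert merged.is_connected()
        assert merged.n_struts == 3


class TestGradient:
    def test_linear_law_endpoints(self, cube_lattice):
        spec = StrutSpec()
        lat = assign_gradient_diameters(cube_lattice, spec)
        proj = -lat.midpoints()[:, 2]
        lo, hi = proj.min(), proj.max()
        t = (proj - lo) / (hi - lo)
        expect = 0.2 + 0.6 * t
        assert np.allclose(lat.diameters, expect)
        top = lat.diameters[np.argmin(proj)]
        bottom = lat.diameters[np.argmax(proj)]
        assert top == pytest.approx(0.2, abs=1e-9)
        assert bottom == pytest.approx(0.8, abs=1e-9)
        mid_t = np.argmin(np.abs(t - 0.5))
        assert lat.diameters[mid_t] == pytest.approx(0.2 + 0.6 * t[mid_t])

    def test_degenerate_gradient(self, cube_lattice):
        lat = assign_gradient_diameters(cube_lattice,
                                        StrutSpec(d_min=0.4, d_max=0.4))
        assert np.allclose(lat.diameters, 0.4)

    def test_monotone_along_axis(self, cube_lattice):
        lat = assign_gradient_diameters(cube_lattice, StrutSpec())
        proj = lat.midpoints() @ np.array([0.0, 0.0, -1.0])
        order = np.argsort(proj)
        assert np.all(np.diff(lat.diameters[order]) >= -1e-12)

    def test_bounds_always_respected(self, cube_lattice):
        lat = assign_gradient_diameters(cube_lattice, StrutSpec())
        assert lat.diameters.min() >= 0.2 - 1e-12
        assert lat.diameters.max() <= 0.8 + 1e-12


class TestFixation:
    def test_screw_count_and_length(self, default_fixture, default_lattice):
        lat = default_lattice
        screws = [i for i, t in enumerate(lat.tags) if t == "screw"]
        assert len(screws) == 10  # 5 per side
        lengths = lat.lengths()[screws]
        assert np.allclose(lengths, 8.0, atol=1e-6)

    def test_retainers_both_sides(self, default_fixture, default_lattice):
        ret = [i for i, t in enumerate(default_lattice.tags)
               if t == "retainer"]
        assert len(ret) > 0
        mids = default_lattice.midpoints()[ret]
        assert (mids[:, 0] < 15).any() and (mids[:, 0] > 25).any()

    def test_eight_screws_rejected(self):
        with pytest.raises(InvalidParameterError):
            FixationSpec(screws_per_side=8)

    def test_four_screws_rejected(self):
        with pytest.raises(InvalidParameterError):
            FixationSpec(screws_per_side=4)


class TestBooleanGraft:
    def test_empty_lattice_keeps_region_volume(self, cube15):
        empty = LatticeModel(provenance={"pore_diameter": 5.0})
        grid = boolean_graft_region(cube15, empty, 0.5)
        assert grid.graft_volume() == pytest.approx(cube15.volume(),
                                                    rel=0.03)

    def test_single_strut_removes_cylinder(self, cube15):
        lat = LatticeModel(np.array([[-1.0, 7.5, 7.5], [16.0, 7.5, 7.5]]),
                           np.array([[0, 1]]), np.array([1.0]), ["grid"],
                           provenance={"pore_diameter": 5.0})
        grid = boolean_graft_region(cube15, lat, 0.25)
        removed = grid.region_volume() - grid.graft_volume()
        analytic = np.pi * 0.5 ** 2 * 15.0  # r^2 pi L inside the cube
        assert removed == pytest.approx(analytic, rel=0.05)

    def test_partition(self, cube15, cube_lattice):
        lat = assign_gradient_diameters(cube_lattice, StrutSpec())
        grid = boolean_graft_region(cube15, lat, 0.5)
        assert (grid.graft_mask.sum() + grid.strut_mask.sum()
                == grid.region_mask.sum())

    def test_coarse_voxel_rejected(self, cube15, cube_lattice):
        with pytest.raises(ResolutionError):
            boolean_graft_region(cube15, cube_lattice, 2.0)

    def test_nonpositive_voxel_rejected(self, cube15, cube_lattice):
        with pytest.raises(InvalidParameterError):
            boolean_graft_region(cube15, cube_lattice, -0.5)


class TestSurfaceExport:
    def test_single_strut_closed_tube(self):
        lat = LatticeModel(np.array([[0.0, 0, 0], [5.0, 0, 0]]),
                           np.array([[0, 1]]), np.array([1.0]), ["grid"])
        mesh = lattice_to_surface(lat, segments_per_circle=12)
        assert mesh.is_watertight()
        assert mesh.euler_characteristic() == 2

    def test_two_disjoint_struts_two_shells(self):
        lat = LatticeModel(
            np.array([[0.0, 0, 0], [5.0, 0, 0],
                      [0.0, 8.0, 0], [5.0, 8.0, 0]]),
            np.array([[0, 1], [2, 3]]), np.array([1.0, 1.0]),
            ["grid", "grid"])
        mesh = lattice_to_surface(lat, segments_per_circle=12)
        assert mesh.is_watertight()
        assert mesh.euler_characteristic() == 4  # two sphere-like shells

    def test_volume_matches_voxel_oracle(self):
        lat = LatticeModel(np.array([[0.0, 0, 0], [6.0, 0, 0],
                                     [3.0, 0, 0], [3.0, 5.0, 0]]),
                           np.array([[0, 1], [2, 3]]),
                           np.array([1.0, 0.8]), ["grid", "grid"])
        mesh = lattice_to_surface(lat, segments_per_circle=16)
        # voxel-counting oracle on the capsule union
        from osteolattice.lattice import capsule_union_mask
        h = 0.1
        bmin, bmax = mesh.bounds()
        axes = [np.arange(bmin[i] - h, bmax[i] + h, h) + h / 2
                for i in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        a, b, r = lat.segments()
        union = capsule_union_mask(pts, a, b, r).sum() * h ** 3
        assert mesh.volume() == pytest.approx(union, rel=0.05)

    def test_too_few_segments_rejected(self):
        lat = LatticeModel(np.array([[0.0, 0, 0], [5.0, 0, 0]]),
                           np.array([[0, 1]]), np.array([1.0]), ["grid"])
        with pytest.raises(InvalidParameterError):
            lattice_to_surface(lat, segments_per_circle=4)


class TestInvariants:
    def test_porosity_monotone_in_pore(self, cube15):
        por = []
        for pore in (4.0, 5.0, 6.5):
            lat = tessellate_trabecular(cube15,
                                        UnitCellSpec(pore_diameter=pore),
                                        default_diameter=0.5)
            por.append(porosity(lat, cube15))
        assert por[0] < por[1] < por[2]

    def test_json_round_trip(self, cube_lattice):
        back = LatticeModel.from_json(cube_lattice.to_json())
        assert np.allclose(back.nodes, cube_lattice.nodes)
        assert np.array_equal(back.edges, cube_lattice.edges)
        assert back.tags == cube_lattice.tags

    def test_no_duplicate_pairs_or_zero_length(self, default_lattice):
        key = np.sort(default_lattice.edges, axis=1)
        assert len(np.unique(key, axis=0)) == len(key)
        assert default_lattice.lengths().min() > 1e-9

    def test_body_diameters_within_bounds(self, default_lattice):
        body = [i for i, t in enumerate(default_lattice.tags)
                if t in ("trabecular", "grid")]
        d = default_lattice.diameters[body]
        assert d.min() >= 0.2 - 1e-9 and d.max() <= 0.8 + 1e-9
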