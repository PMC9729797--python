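import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from osteolattice import fe
from osteolattice.fixtures import (make_cantilever_benchmark,
                                   make_patch_test)
from osteolattice.materials import MaterialProperties


class TestScalarMeasures:
    def test_uniaxial_von_mises(self):
        s = np.diag([100.0, 0.0, 0.0])
        assert fe.von_mises(s) == pytest.approx(100.0)

    def test_hydrostatic_von_mises_zero(self):
        assert fe.von_mises(np.eye(3) * 37.2) == pytest.approx(0.0, abs=1e-9)

    def test_pure_shear_von_mises(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 10.0
        assert fe.von_mises(s) == pytest.approx(10.0 * np.sqrt(3.0))

    def test_rotational_invariance(self):
        rng = np.random.default_rng(7)
        s = np.array([[120.0, 30.0, -10.0],
                      [30.0, -80.0, 25.0],
                      [-10.0, 25.0, 40.0]])
        ref = fe.von_mises(s)
        for _ in range(100):
            R = Rotation.random(random_state=rng).as_matrix()
            assert fe.von_mises(R @ s @ R.T) == pytest.approx(ref, rel=1e-9)

    def test_equivalent_strain_hydrostatic_zero(self):
        assert fe.equivalent_strain(np.eye(3) * 1e-3) == pytest.approx(
            0.0, abs=1e-9)

    def test_equivalent_strain_homogeneous(self):
        e = np.array([[1e-3, 2e-4, 0.0], [2e-4, -3e-4, 1e-4],
                      [0.0, 1e-4, 5e-4]])
        assert fe.equivalent_strain(2 * e) == pytest.approx(
            2 * fe.equivalent_strain(e), rel=1e-12)

    def test_equivalent_strain_uniaxial_oracle(self):
        # independent brute-force of sqrt(2/3 * e_dev : e_dev), computed
        # component-wise: for uniaxial 1000 ue with lateral -nu*1000 this
        # gives (2/3)*(1+nu)*1000 = 866.666... ue at nu = 0.3
        nu = 0.3
        e = np.diag([1e-3, -nu * 1e-3, -nu * 1e-3])
        dev = e - np.trace(e) / 3.0 * np.eye(3)
        brute = np.sqrt(2.0 / 3.0 * sum(dev[i, j] ** 2
                                        for i in range(3)
                                        for j in range(3))) * 1e6
        assert brute == pytest.approx(2.0 / 3.0 * (1 + nu) * 1000.0)
        assert fe.equivalent_strain(e) == pytest.approx(brute, rel=1e-12)


class TestBeamStress:
    def test_pure_axial(self):
        d = 2.0
        A = np.pi * d ** 2 / 4
        f = np.zeros(12)
        f[0], f[6] = -100.0, 100.0
        assert fe.beam_equivalent_stress(d, f) == pytest.approx(100.0 / A)

    def test_pure_bending(self):
        d = 2.0
        M = 50.0
        f = np.zeros(12)
        f[5], f[11] = -M, M
        assert fe.beam_equivalent_stress(d, f) == pytest.approx(
            32.0 * M / (np.pi * d ** 3))

    def test_mixed_matches_angular_sampling(self):
        # oracle: maximize vm(theta) over 360 sampled circumferential angles
        d = 1.5
        A, I, J = fe.beam_section(d)
        c = d / 2
        N, T, My, Mz = 40.0, 12.0, 9.0, -6.0
        f = np.zeros(12)
        f[6], f[9], f[10], f[11] = N, T, My, Mz
        thetas = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        sigma = N / A + c / I * (My * np.sin(thetas) - Mz * np.cos(thetas))
        tau = T * c / J
        oracle = np.sqrt(sigma ** 2 + 3 * tau ** 2).max()
        assert fe.beam_equivalent_stress(d, f) == pytest.approx(
            oracle, rel=0.005)

    def test_zero_diameter_raises(self):
        with pytest.raises(ValueError):
            fe.beam_equivalent_stress(0.0, np.zeros(12))


class TestCantilever:
    def test_tip_deflection_euler_bernoulli(self):
        L, d, E = 100.0, 2.0, 110_000.0
        fem = make_cantilever_benchmark(L, d, E)
        res = fe.solve(fem)
        I = np.pi * d ** 4 / 64
        ref = L ** 3 / (3 * E * I)
        assert -res.displacements[-1, 2] == pytest.approx(ref, rel=0.01)

    def test_linearity_in_modulus(self):
        r1 = fe.solve(make_cantilever_benchmark(100, 2, 50_000.0))
        r2 = fe.solve(make_cantilever_benchmark(100, 2, 100_000.0))
        assert r1.displacements[-1, 2] == pytest.approx(
            2 * r2.displacements[-1, 2], rel=1e-9)

    def test_mesh_refinement_converged(self):
        r1 = fe.solve(make_cantilever_benchmark(100, 2, 110_000.0,
                                                n_elements=10))
        r2 = fe.solve(make_cantilever_benchmark(100, 2, 110_000.0,
                                                n_elements=20))
        t1, t2 = r1.displacements[-1, 2], r2.displacements[-1, 2]
        assert abs(t2 - t1) / abs(t1) < 1e-3

    def test_load_doubling(self):
        fem = make_cantilever_benchmark(100, 2, 110_000.0)
        r1 = fe.solve(fem)
        fem2 = make_cantilever_benchmark(100, 2, 110_000.0, tip_load=2.0)
        r2 = fe.solve(fem2)
        assert np.allclose(r2.displacements, 2 * r1.displacements,
                           rtol=1e-10, atol=1e-15)

    def test_reaction_balances_load(self):
        fem = make_cantilever_benchmark(100, 2, 110_000.0)
        res = fe.solve(fem)
        # translational reaction at the clamp equals the applied tip load
        rz = res.reactions[2]
        assert rz == pytest.approx(1.0, rel=1e-6)

    def test_not_slender_rejected(self):
        from osteolattice.errors import InvalidParameterError
        with pytest.raises(InvalidParameterError):
            make_cantilever_benchmark(10.0, 2.0, 1000.0)


class TestPatchTest:
    def test_uniaxial_recovered_exactly(self):
        fem = make_patch_test(3, 1000.0, 0.3)
        res = fe.solve(fem)
        expect = fe.equivalent_strain(np.diag([1e-3, 0, 0]))
        assert np.allclose(res.voxel_strain_ue, expect, rtol=1e-9)

    def test_imposed_equivalent_strain_1000ue(self):
        # scale a uniaxial-with-contraction state so its equivalent strain
        # is exactly 1000 ue; every element must recover it
        nu = 0.3
        base = np.diag([1.0, -nu, -nu])
        scale = 1e-3 / (fe.equivalent_strain(base) * 1e-6)
        fem = make_patch_test(2, 500.0, nu, strain=base * scale)
        res = fe.solve(fem)
        assert np.allclose(res.voxel_strain_ue, 1000.0, rtol=1e-9)

    def test_pure_shear_stress(self):
        gamma = 2e-3
        E, nu = 1000.0, 0.25
        G = E / (2 * (1 + nu))
        strain = np.zeros((3, 3))
        strain[0, 1] = strain[1, 0] = gamma / 2
        fem = make_patch_test(2, E, nu, strain=strain)
        res = fe.solve(fem)
        assert np.allclose(res.voxel_stress, np.sqrt(3) * G * gamma,
                           rtol=1e-9)

    def test_hydrostatic_zero_deviatoric(self):
        fem = make_patch_test(2, 1000.0, 0.3, strain=np.eye(3) * 1e-3)
        res = fe.solve(fem)
        assert np.allclose(res.voxel_strain_ue, 0.0, atol=1e-6)

    def test_bad_poisson_rejected(self):
        from osteolattice.errors import InvalidParameterError
        with pytest.raises(InvalidParameterError):
            make_patch_test(2, 1000.0, 0.6)


class TestAssembly:
    def test_stiffness_symmetric(self):
        fem = make_cantilever_benchmark(100, 2, 110_000.0)
        K, _ = fem.system()
        dense = K.toarray()
        assert np.allclose(dense, dense.T, rtol=1e-12, atol=1e-9)

    def test_spring_adds_exact_diagonal(self):
        fem = make_cantilever_benchmark(100, 2, 110_000.0)
        K0, _ = fem.system()
        k, direction = 123.0, np.array([0.0, 0.0, 1.0])
        fem.add_spring(5, direction, k)
        K1, _ = fem.system()
        diff = (K1 - K0).toarray()
        d = fem.translation_dofs(5)
        expect = np.zeros_like(diff)
        expect[np.ix_(d, d)] = k * np.outer(direction, direction)
        assert np.allclose(diff, expect, atol=1e-10)

    def test_dense_matches_sparse(self):
        # <= 300 dof model solved both ways
        fem = make_patch_test(2, 800.0, 0.3)
        K, _ = fem.system()
        assert K.shape[0] <= 300
        rs = fe.solve(fem, dense=False)
        rd = fe.solve(fem, dense=True)
        assert np.allclose(rs.displacements, rd.displacements,
                           rtol=1e-9, atol=1e-15)

    def test_reciprocity(self):
        L, d, E = 100.0, 2.0, 110_000.0
        mat = MaterialProperties("m", E, 0.3)
        xs = np.linspace(0, L, 11)
        nodes = np.column_stack([xs, np.zeros(11), np.zeros(11)])
        beams = [(i, i + 1, d, mat) for i in range(10)]
        f1 = fe.assemble(nodes, beams=beams, fixed=[0],
                         loads=[(4, [0, 0, 1.0])])
        u_j = fe.solve(f1).displacements[8, 2]
        f2 = fe.assemble(nodes, beams=beams, fixed=[0],
                         loads=[(8, [0, 0, 1.0])])
        u_i = fe.solve(f2).displacements[4, 2]
        assert u_j == pytest.approx(u_i, rel=1e-9)

    def test_singular_system_diagnosed(self):
        mat = MaterialProperties("m", 1000.0, 0.3)
        nodes = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        fem = fe.assemble(nodes, beams=[(0, 1, 1.0, mat)],
                          loads=[(1, [0, 0, 1.0])])  # unconstrained
        with pytest.raises(fe.SingularModelError):
            fe.solve(fem)

    def test_floating_strut_node_named(self):
        from osteolattice.fe import AssemblyError
        mat = MaterialProperties("m", 1000.0, 0.3)
        nodes = np.array([[0.0, 0, 0], [1.0, 0, 0],
                          [50.0, 50, 50], [51.0, 50, 50],
                          [0.0, 1, 0], [1.0, 1, 0], [1.0, 1, 1],
                          [0.0, 0, 1]])
        vox = np.array([[0, 1, 5, 4, 7, 6, 6, 6]])  # degenerate but indexed
        with pytest.raises(AssemblyError, match="floating strut node"):
            fe.assemble(nodes, beams=[(2, 3, 1.0, mat)], voxels=vox,
                        voxel_materials=[mat], tie_tolerance=1.0)

    def test_equilibrium_residual_small(self):
        fem = make_patch_test(3, 1500.0, 0.35)
        res = fe.solve(fem)
        assert res.residual < 1e-8


class TestStrainMeasureOption:
    def test_principal_measure_config_exposed(self):
        # uniaxial extension: the largest principal strain equals the
        # imposed axial component, unlike the deviatoric equivalent
        fem = make_patch_test(2, 1000.0, 0.3)
        fem.strain_measure = "principal"
        res = fe.solve(fem)
        assert np.allclose(res.voxel_strain_ue, 1000.0, rtol=1e-9)
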