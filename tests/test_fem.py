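"""Element matrices, assembly, boundary conditions and the harmonic solver."""

import numpy as np
import pytest
from scipy import sparse

from otomech.fem import (
    ConfigurationError,
    MaterialTable,
    SolverError,
    SystemMatrices,
    apply_boundary_springs,
    apply_dashpot,
    apply_fixed,
    assemble,
    build_middle_ear_system,
    harmonic_solve,
    pressure_load,
    tet4_mass,
    tet4_stiffness,
)

UNIT_TET = np.array(
    [[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]]
)


class TestTet4Stiffness:
    def test_symmetric_with_six_rigid_body_modes(self):
        K = tet4_stiffness(UNIT_TET, E=7.3e6, nu=0.3)
        np.testing.assert_allclose(K, K.T, atol=1e-6 * abs(K).max())
        eig = np.linalg.eigvalsh(K)
        assert (np.abs(eig[:6]) < 1e-8 * eig[-1]).all()
        assert (eig[6:] > 1e-8 * eig[-1]).all()

    def test_rigid_translation_produces_no_force(self):
        K = tet4_stiffness(UNIT_TET, E=1e6, nu=0.25)
        u = np.tile([1.0, -2.0, 0.5], 4)
        np.testing.assert_allclose(K @ u, 0.0, atol=1e-9 * abs(K).max())

    def test_patch_uniform_strain_matches_hookes_law(self):
        """Nodal forces under a linear displacement field must equal the
        closed-form isotropic stress integrated over the element faces;
        checked via the energy 1/2 u^T K u = 1/2 V sigma:epsilon."""
        E, nu = 2.3e6, 0.3
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        rng = np.random.default_rng(0)
        coords = UNIT_TET + 0.1 * rng.normal(size=(4, 3))
        grad = np.array([[3e-3, 1e-3, 0.0], [0.5e-3, -2e-3, 1e-3], [0.0, 1e-3, 4e-3]])
        eps = 0.5 * (grad + grad.T)
        u = (coords @ grad.T).ravel()
        vol = abs(np.linalg.det(coords[1:] - coords[0])) / 6
        sig = lam * np.trace(eps) * np.eye(3) + 2 * mu * eps
        energy_oracle = 0.5 * vol * np.tensordot(sig, eps)
        K = tet4_stiffness(coords, E, nu)
        assert 0.5 * u @ K @ u == pytest.approx(energy_oracle, rel=1e-10)

    def test_degenerate_element_rejected(self):
        flat = UNIT_TET.copy()
        flat[3] = flat[0]
        with pytest.raises(ValueError):
            tet4_stiffness(flat, 1e6, 0.3)


class TestTet4Mass:
    def test_mass_conservation_per_direction(self):
        rho = 1234.0
        M = tet4_mass(UNIT_TET, rho)
        vol = 1.0 / 6.0
        for d in range(3):
            sel = np.arange(d, 12, 3)
            assert M[np.ix_(sel, sel)].sum() == pytest.approx(rho * vol)

    def test_linear_in_density(self):
        M1 = tet4_mass(UNIT_TET, 1.0)
        np.testing.assert_allclose(tet4_mass(UNIT_TET, 2.0), 2 * M1)

    def test_positive_definite(self):
        M = tet4_mass(UNIT_TET, 5.0)
        assert (np.linalg.eigvalsh(M) > 0).all()


class TestAssembly:
    def test_total_mass_matches_region_densities(self, mesh, materials):
        sys = assemble(mesh, materials)
        vols = mesh.volumes()
        expected = sum(
            materials.regions[r].density * vols[mesh.region == r].sum()
            for r in set(mesh.region.tolist())
        )
        xsel = np.arange(0, sys.n_dofs, 3)
        total = sys.M[np.ix_(xsel, xsel)].sum()
        assert total == pytest.approx(expected, rel=1e-9)

    def test_stiffness_linear_in_modulus(self, mesh, materials):
        sys1 = assemble(mesh, materials)
        scaled = materials.copy()
        for r in list(scaled.regions):
            scaled = scaled.scale_youngs(r, 10.0)
        sys10 = assemble(mesh, scaled)
        d = (sys10.K - 10.0 * sys1.K).tocoo()
        assert abs(d.data).max() if d.nnz else 0.0 <= 1e-6 * abs(sys1.K).max()

    def test_symmetry_and_spd_structure(self, mesh, materials):
        sys = assemble(mesh, materials)
        for A in (sys.K, sys.M, sys.D):
            d = (A - A.T).tocoo()
            assert (abs(d.data).max() if d.nnz else 0.0) <= 1e-9 * abs(A).max()

    def test_missing_region_material_rejected(self, mesh, materials):
        broken = materials.copy()
        del broken.regions["stapedius"]
        with pytest.raises(ConfigurationError):
            assemble(mesh, broken)


def _sdof_system(k=100.0, m=1e-3, c=0.05):
    """One free node held by a grounded spring, with mass and dashpot."""
    K = sparse.csr_matrix((3, 3))
    M = sparse.csr_matrix(m * np.eye(3))
    D = sparse.csr_matrix((3, 3))
    sys = SystemMatrices(K=K, M=M, D=D, n_nodes=1)
    sys = apply_boundary_springs(sys, [0], k)
    sys = apply_dashpot(sys, [0], c, (1.0, 0.0, 0.0))
    return sys


class TestBoundaryConditions:
    def test_zero_spring_leaves_stiffness_unchanged(self, mesh, materials):
        sys = assemble(mesh, materials)
        out = apply_boundary_springs(sys, mesh.node_sets["tm_rim"], 0.0)
        assert (out.K != sys.K).nnz == 0

    def test_spring_adds_to_diagonal_only(self):
        sys = _sdof_system(k=5.0, c=0.0)
        dense = sys.K.toarray()
        np.testing.assert_allclose(dense, 5.0 * np.eye(3))

    def test_static_spring_solve_obeys_hookes_law(self):
        k, F = 250.0, 2.5e-3
        sys = _sdof_system(k=k, m=1e-9, c=0.0)
        f = np.array([F, 0, 0], dtype=complex)
        sol = harmonic_solve(sys, f, [1e-3])
        assert abs(sol.displacement[0, 0, 0]) == pytest.approx(F / k, rel=1e-6)

    def test_dashpot_rank_one_block(self):
        sys = _sdof_system(k=1.0, c=0.0)
        out = apply_dashpot(sys, [0], 3.0, (0.0, 0.0, 1.0))
        D = out.D.toarray()
        expected = np.zeros((3, 3))
        expected[2, 2] = 3.0
        np.testing.assert_allclose(D, expected)

    def test_zero_direction_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_dashpot(_sdof_system(), [0], 1.0, (0.0, 0.0, 0.0))

    def test_unknown_node_rejected(self):
        with pytest.raises(IndexError):
            apply_boundary_springs(_sdof_system(), [4], 1.0)

    def test_fixed_nodes_return_exact_zeros(self, mesh, materials):
        sys = build_middle_ear_system(
            mesh, materials, extra_fixed_sets=("attic_patch_malleus", "attic_patch_incus")
        )
        f = pressure_load(mesh, mesh.face_sets["tm_load_faces"], 1.0)
        sol = harmonic_solve(sys, f, [500.0, 2000.0])
        patch = np.concatenate(
            [mesh.node_sets["attic_patch_malleus"], mesh.node_sets["attic_patch_incus"]]
        )
        assert np.all(sol.displacement[:, patch, :] == 0.0)

    def test_anchors_remove_rigid_body_modes(self, mesh, materials):
        from scipy.sparse.linalg import eigsh

        sys = build_middle_ear_system(mesh, materials)
        free = sys.free_dofs()
        Kf = sys.K[free][:, free].tocsc()
        # shift-invert about -1: the eigenvalue nearest -1 is the smallest
        # one when K is positive (semi)definite
        smallest = eigsh(Kf, k=1, sigma=-1.0, which="LM", return_eigenvectors=False)[0]
        assert smallest > 0


class TestPressureLoad:
    def test_net_force_equals_pressure_times_area(self, mesh):
        p = 2.0
        f = pressure_load(mesh, mesh.face_sets["footplate_faces"], p).reshape(-1, 3)
        area = 3.0e-3 * 1.8e-3  # footplate plate area
        # footplate faces are flat with +x outward normals -> net force -x
        assert f[:, 0].sum() == pytest.approx(-p * area, rel=1e-9)
        assert f[:, 1].sum() == pytest.approx(0.0, abs=1e-15)

    def test_linear_in_pressure(self, mesh):
        f1 = pressure_load(mesh, mesh.face_sets["tm_load_faces"], 1.0)
        f2 = pressure_load(mesh, mesh.face_sets["tm_load_faces"], 2.0)
        np.testing.assert_allclose(f2, 2 * f1)

    def test_empty_faces_rejected(self, mesh):
        with pytest.raises(ConfigurationError):
            pressure_load(mesh, np.empty((0, 3), dtype=int), 1.0)


class TestHarmonicSolve:
    def test_matches_sdof_closed_form(self):
        k, m, c, F = 120.0, 2e-3, 0.07, 1e-3
        sys = _sdof_system(k, m, c)
        f = np.array([F, 0, 0], dtype=complex)
        freqs = [50.0, 123.0, 1234.0]
        sol = harmonic_solve(sys, f, freqs)
        for i, f_hz in enumerate(freqs):
            w = 2 * np.pi * f_hz
            oracle = F / np.sqrt((k - w * w * m) ** 2 + (w * c) ** 2)
            assert abs(sol.displacement[i, 0, 0]) == pytest.approx(oracle, rel=1e-10)

    def test_matches_dense_three_dof_solution(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(3, 3))
        K = sparse.csr_matrix(A @ A.T + 10 * np.eye(3))
        M = sparse.csr_matrix(np.diag(rng.uniform(1e-4, 1e-3, 3)))
        C = sparse.csr_matrix(0.01 * (K / abs(K).max()).toarray())
        sys = SystemMatrices(K=K, M=M, D=C, n_nodes=1)
        f = rng.normal(size=3) + 0j
        for f_hz in (60.0, 600.0):
            w = 2 * np.pi * f_hz
            dense = np.linalg.solve(
                K.toarray() + 1j * w * C.toarray() - w * w * M.toarray(), f
            )
            sol = harmonic_solve(sys, f, [f_hz])
            np.testing.assert_allclose(
                sol.displacement[0, 0], dense, rtol=1e-10
            )

    def test_static_limit_matches_static_solve(self, mesh, materials):
        from scipy.sparse.linalg import spsolve

        sys = build_middle_ear_system(mesh, materials)
        f = pressure_load(mesh, mesh.face_sets["tm_load_faces"], 1.0)
        free = sys.free_dofs()
        static = spsolve(sys.K[free][:, free].tocsc(), f[free])
        sol = harmonic_solve(sys, f, [1e-3])
        harmonic = sol.displacement[0].ravel()[free]
        # norm-wise agreement (element-wise ratios are meaningless on the
        # near-zero components of this ill-scaled field)
        assert np.linalg.norm(harmonic - static) <= 1e-3 * np.linalg.norm(static)

    def test_linearity_in_load(self, mesh, materials):
        sys = build_middle_ear_system(mesh, materials)
        f = pressure_load(mesh, mesh.face_sets["tm_load_faces"], 1.0)
        s1 = harmonic_solve(sys, f, [1000.0])
        s2 = harmonic_solve(sys, 2 * f, [1000.0])
        np.testing.assert_allclose(
            s2.displacement, 2 * s1.displacement, rtol=1e-9
        )

    def test_reciprocity(self, mesh, materials):
        """Symmetric K, M, D: response at a to a force at b equals the
        response at b to the same force at a."""
        sys = build_middle_ear_system(mesh, materials)
        free = sys.free_dofs()
        a, b = free[100], free[-100]
        fa = np.zeros(sys.n_dofs, dtype=complex)
        fa[a] = 1.0
        fb = np.zeros(sys.n_dofs, dtype=complex)
        fb[b] = 1.0
        xa = harmonic_solve(sys, fa, [700.0]).displacement.ravel()
        xb = harmonic_solve(sys, fb, [700.0]).displacement.ravel()
        assert xa[b] == pytest.approx(xb[a], rel=1e-8)

    def test_input_power_non_negative(self, mesh, materials):
        sys = build_middle_ear_system(mesh, materials)
        f = pressure_load(mesh, mesh.face_sets["tm_load_faces"], 1.0)
        sol = harmonic_solve(sys, f, [250.0, 1000.0, 4000.0])
        for i, f_hz in enumerate(sol.frequencies):
            w = 2 * np.pi * f_hz
            x = sol.displacement[i].ravel()
            power = 0.5 * np.real(np.vdot(f, 1j * w * x))
            assert power >= 0

    def test_global_stiffness_scaling_inverts_static_response(self, mesh, materials):
        sys = build_middle_ear_system(mesh, materials)
        scaled_mats = materials.copy()
        for r in list(scaled_mats.regions):
            scaled_mats = scaled_mats.scale_youngs(r, 3.0)
        scaled_mats.tm_rim_spring_stiffness *= 3.0
        sys3 = build_middle_ear_system(mesh, scaled_mats)
        f = pressure_load(mesh, mesh.face_sets["tm_load_faces"], 1.0)
        x1 = harmonic_solve(sys, f, [1e-3]).displacement.ravel()
        x3 = harmonic_solve(sys3, f, [1e-3]).displacement.ravel()
        assert np.linalg.norm(x3 - x1 / 3.0) <= 1e-6 * np.linalg.norm(x1)

    def test_insufficiently_constrained_system_raises(self):
        sys = SystemMatrices(
            K=sparse.csr_matrix((3, 3)),
            M=sparse.csr_matrix(np.diag([1e-3, 1e-3, 0.0])),
            D=sparse.csr_matrix((3, 3)),
            n_nodes=1,
        )
        # no stiffness, no damping, and one massless DOF: singular operator
        with pytest.raises((SolverError, RuntimeError)):
            harmonic_solve(sys, np.array([1.0, 0, 1.0]), [100.0])


def test_material_table_round_trip(materials, tmp_path):
    path = tmp_path / "mats.yaml"
    materials.to_yaml(path)
    again = MaterialTable.from_yaml(path)
    assert again.content_hash() == materials.content_hash()
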