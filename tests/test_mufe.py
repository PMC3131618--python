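"""Voxel FE homogenization: element, solver, orthotropy, constants."""

import itertools

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.linalg import spsolve

from itsmorph import mufe
from itsmorph.volume import BinaryVolume

VOX = 0.082


def dense_oracle_stiffness(model, eps0=1e-3):
    """Apparent stiffness via assembled sparse matrix and direct solve."""
    rows, cols, vals = [], [], []
    for e in range(model.n_elements):
        d = model.elem_dofs[e]
        rows.append(np.repeat(d, 24))
        cols.append(np.tile(d, 24))
        vals.append(model.Ke.ravel())
    K = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(model.n_dofs,) * 2,
    ).tocsr()
    free = ~model.constrained
    h = model.voxel_size_mm
    D = mufe.isotropic_stiffness(model.E_t, model.nu)
    Bmean = mufe._b_matrix(0.0, 0.0, 0.0, h)
    nz, ny, nx = model.shape
    vtot = nz * ny * nx * h**3
    C = np.zeros((6, 6))
    for case in range(6):
        E = mufe._case_strain_tensor(case, eps0)
        u = np.zeros(model.n_dofs)
        upre = (model.node_xyz * h) @ E.T
        u[model.constrained] = upre.reshape(-1)[model.constrained]
        b = -(K @ u)[free]
        u[free] = spsolve(K[free][:, free].tocsc(), b)
        C[:, case] = mufe._mean_stress(model.elem_dofs, Bmean, D, u) * h**3 / vtot / eps0
    return 0.5 * (C + C.T)


def spanning_blob(side=10, seed=0, p=0.4):
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    m = ndimage.binary_closing(rng.random((side,) * 3) < p, np.ones((2, 2, 2), bool))
    m[0] = m[-1] = True
    m[:, 0] = m[:, -1] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


class TestModel:
    def test_2x2x2_cube_has_8_elements_27_nodes(self):
        model = mufe.build_fe_model(BinaryVolume(np.ones((2, 2, 2), bool), VOX))
        assert model.n_elements == 8
        assert model.n_dofs == 27 * 3

    def test_element_count_equals_bone_voxels(self):
        m = spanning_blob(16, seed=3)
        model = mufe.build_fe_model(BinaryVolume(m, VOX))
        assert model.n_elements == int(m.sum())

    def test_interior_island_removed_and_logged(self):
        m = np.zeros((9, 9, 9), bool)
        m[:, 4, 4] = True  # spanning column
        m[4, 1, 1] = True  # floating voxel
        model = mufe.build_fe_model(BinaryVolume(m, VOX))
        assert model.meta["removed_island_voxels"] == 1
        assert model.n_elements == 9

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mufe.build_fe_model(BinaryVolume(np.zeros((4, 4, 4), bool), VOX))

    def test_element_stiffness_matches_higher_order_quadrature(self):
        # independent oracle: 4-point Gauss-Legendre per axis via numpy
        E, nu, h = 15.0, 0.3, 0.082
        Ke = mufe.hex_stiffness(E, nu, h)
        pts, wts = np.polynomial.legendre.leggauss(4)
        D = mufe.isotropic_stiffness(E, nu)
        detJ = (h / 2) ** 3
        Ko = np.zeros((24, 24))
        for (xi, wx), (eta, wy), (zeta, wz) in itertools.product(
            zip(pts, wts), repeat=3
        ):
            B = mufe._b_matrix(xi, eta, zeta, h)
            Ko += wx * wy * wz * B.T @ D @ B * detJ
        assert np.abs(Ke - Ko).max() / np.abs(Ko).max() < 1e-10
        # symmetry and rigid-body nullity
        assert np.allclose(Ke, Ke.T)
        rigid = np.tile(np.eye(3), (8, 1))
        assert np.abs(Ke @ rigid).max() < 1e-9 * np.abs(Ke).max()


class TestSolver:
    def test_solid_cube_reproduces_isotropic_stiffness(self):
        model = mufe.build_fe_model(BinaryVolume(np.ones((6, 6, 6), bool), VOX))
        C = mufe.solve_load_cases(model)
        D = mufe.isotropic_stiffness(15.0, 0.3)
        assert np.abs(C - D).max() / np.abs(D).max() < 1e-6

    @pytest.mark.parametrize("seed", [0, 1])
    def test_cg_matches_direct_solve(self, seed):
        m = spanning_blob(10, seed=seed)
        model = mufe.build_fe_model(BinaryVolume(m, VOX))
        C = mufe.solve_load_cases(model, rtol=1e-12)
        Cd = dense_oracle_stiffness(model)
        assert np.abs(C - Cd).max() / np.abs(Cd).max() < 1e-8

    def test_laminate_matches_direct_solve(self):
        m = np.zeros((8, 8, 8), bool)
        m[::2] = True  # 50% laminate of xy plates
        model = mufe.build_fe_model(BinaryVolume(m, VOX))
        C = mufe.solve_load_cases(model, rtol=1e-12)
        Cd = dense_oracle_stiffness(model)
        assert np.abs(C - Cd).max() / np.abs(Cd).max() < 1e-8
        # in-plane moduli far exceed the across-plate response
        assert C[0, 0] > 5 * abs(C[2, 2] - 0)

    def test_rotated_structure_permutes_stiffness(self):
        m = spanning_blob(8, seed=5)
        C = mufe.solve_load_cases(mufe.build_fe_model(BinaryVolume(m, VOX)), rtol=1e-12)
        # rotate 90 deg about x: (z, y, x) -> (y, -z, x) in array terms
        m_rot = np.rot90(m, k=1, axes=(0, 1))
        C_rot = mufe.solve_load_cases(
            mufe.build_fe_model(BinaryVolume(m_rot, VOX)), rtol=1e-12
        )
        # axes y<->z swap: Voigt indices (0,1,2,3,4,5)->(0,2,1,3,5,4)
        perm = [0, 2, 1, 3, 5, 4]
        np.testing.assert_allclose(
            np.abs(C_rot),
            np.abs(C[np.ix_(perm, perm)]),
            rtol=1e-6,
            atol=1e-9 * np.abs(C).max(),
        )

    def test_adding_bone_never_softens(self):
        base = np.zeros((6, 6, 6), bool)
        base[:, 2:4, 2:4] = True
        prev = None
        for grow in (0, 1, 2):
            m = base.copy()
            if grow:
                m[:, 2 - grow : 4 + grow, 2:4] = True
            C = mufe.solve_load_cases(mufe.build_fe_model(BinaryVolume(m, VOX)))
            d = np.diag(C)
            if prev is not None:
                assert (d >= prev - 1e-9).all()
            prev = d

    def test_moduli_scale_linearly_in_tissue_modulus(self):
        m = spanning_blob(8, seed=7)
        C1 = mufe.solve_load_cases(mufe.build_fe_model(BinaryVolume(m, VOX), E_t=10.0))
        C2 = mufe.solve_load_cases(mufe.build_fe_model(BinaryVolume(m, VOX), E_t=20.0))
        np.testing.assert_allclose(C2, 2 * C1, rtol=1e-6)


def min_angle_to_symmetry(R_rec, R_true):
    """Smallest rotation angle between R_rec and R_true modulo the
    orthotropy symmetry group (proper signed axis permutations)."""
    best = np.inf
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            P = np.zeros((3, 3))
            for i, (p, s) in enumerate(zip(perm, signs)):
                P[i, p] = s
            if np.linalg.det(P) < 0:
                continue
            dev = R_rec @ (P @ R_true).T
            ang = np.degrees(np.arccos(np.clip((np.trace(dev) - 1) / 2, -1, 1)))
            best = min(best, ang)
    return best


class TestOrthotropy:
    ORTHO = np.diag([10.0, 14, 20, 4, 5, 6])

    def setup_method(self):
        self.C = self.ORTHO.copy()
        self.C[:3, :3] += np.array([[0, 3, 2], [3, 0, 2.5], [2, 2.5, 0]])

    def test_orthotropic_input_returns_identity_zero_objective(self):
        R, Co = mufe.find_orthotropic_axes(self.C)
        np.testing.assert_allclose(R, np.eye(3))
        assert mufe.orthotropy_error(Co) < 1e-12

    def test_isotropic_input_returns_identity(self):
        D = mufe.isotropic_stiffness(15.0, 0.3)
        R, Co = mufe.find_orthotropic_axes(D)
        np.testing.assert_allclose(R, np.eye(3))
        assert mufe.orthotropy_error(Co) < 1e-12

    def test_construct_then_recover_within_half_degree(self):
        ang = np.deg2rad([20.0, 35.0, 50.0])
        R_true = mufe._euler_to_rot(ang)
        C_rot = mufe.rotate_stiffness(self.C, R_true)
        assert mufe.orthotropy_error(C_rot) > 1e-3  # genuinely rotated
        R_rec, C_rec = mufe.find_orthotropic_axes(C_rot)
        assert mufe.orthotropy_error(C_rec) < 1e-10
        # recovery undoes the rotation: R_rec ~ P R_true^T modulo symmetry
        assert min_angle_to_symmetry(R_rec, R_true.T) < 0.5

    def test_rotation_matches_tensor_oracle(self):
        # Voigt rotation path equals direct 4th-order tensor rotation
        rng = np.random.default_rng(2)
        A = rng.random((6, 6))
        C = 0.5 * (A + A.T) + 6 * np.eye(6)
        R = mufe._euler_to_rot(rng.uniform(0, np.pi, 3))
        T = mufe.voigt_to_tensor(C)
        Tr = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, T)
        np.testing.assert_allclose(
            mufe.rotate_stiffness(C, R), mufe.tensor_to_voigt(Tr), atol=1e-12
        )


class TestEngineeringConstants:
    def test_isotropic_closed_form(self):
        D = mufe.isotropic_stiffness(15.0, 0.3)
        c = mufe.engineering_constants(D)
        for k in ("E11", "E22", "E33"):
            assert c[k] == pytest.approx(15.0, rel=1e-12)
        for k in ("G23", "G31", "G12"):
            assert c[k] == pytest.approx(15.0 / 2.6, rel=1e-12)
        assert c["nu12"] == pytest.approx(0.3, rel=1e-12)

    def test_sorting_permutes_shears_consistently(self):
        # diagonal toy orthotropic C: E_i = C_ii with no coupling
        C = np.diag([30.0, 10.0, 20.0, 4.0, 5.0, 6.0])
        c = mufe.engineering_constants(C)
        assert (c["E11"], c["E22"], c["E33"]) == (10.0, 20.0, 30.0)
        # new axes (1,2,3) = old (y, z, x): G23'=G_old(z,x)=G31=5,
        # G31'=G_old(y,x)=G12=6, G12'=G_old(y,z)=G23=4
        assert (c["G23"], c["G31"], c["G12"]) == (5.0, 6.0, 4.0)

    def test_sorted_order_enforced(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            d = rng.uniform(5, 30, 6)
            c = mufe.engineering_constants(np.diag(d))
            assert c["E11"] <= c["E22"] <= c["E33"]

    def test_singular_rejected(self):
        C = np.diag([10.0, 10, 10, 4, 4, 0.0])
        with pytest.raises(np.linalg.LinAlgError):
            mufe.engineering_constants(C)
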