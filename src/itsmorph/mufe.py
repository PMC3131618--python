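"""Voxel-based micro-finite-element homogenization of trabecular bone.

Every bone voxel becomes one 8-node hexahedral element with identical
isotropic tissue properties (default E_t = 15 GPa, nu = 0.3 — all moduli
scale linearly in E_t, so anisotropy ratios are tissue-modulus-free). Six
load cases — three uniaxial compressions and three shears, imposed as
kinematic uniform-strain displacements on all boundary faces — yield the
full 6x6 apparent stiffness in Voigt form [11, 22, 33, 23, 31, 12] with
axes 1, 2, 3 = x, y, z (z longitudinal). The interior is solved matrix-free
by an element-by-element Jacobi-preconditioned conjugate gradient.

The best orthotropic coordinate system is found by minimizing the relative
norm of the stiffness entries that vanish under orthotropy (normal-shear
and shear-shear couplings) over rotations, with a multi-start Powell
search; engineering constants are then read from the compliance and sorted
so that E11 <= E22 <= E33 with the shear moduli relabeled consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.optimize import minimize
from scipy.sparse.linalg import LinearOperator, cg

from .volume import BinaryVolume

__all__ = [
    "FEModel",
    "StiffnessResult",
    "build_fe_model",
    "solve_load_cases",
    "find_orthotropic_axes",
    "engineering_constants",
    "hex_stiffness",
    "isotropic_stiffness",
    "rotate_stiffness",
    "orthotropy_error",
    "homogenize",
]

# Voigt pairs for [11, 22, 33, 23, 31, 12] with axes 0=x, 1=y, 2=z
_VOIGT = [(0, 0), (1, 1), (2, 2), (1, 2), (2, 0), (0, 1)]

# local node offsets (dx, dy, dz) in x-fastest order
_NODE_OFF = np.array(
    [(dx, dy, dz) for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)], dtype=np.int64
)


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness (engineering Voigt)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _shape_gradients(xi, eta, zeta):
    """d N_a / d(xi, eta, zeta) for the 8 trilinear shape functions."""
    g = np.zeros((8, 3))
    for a, (ox, oy, oz) in enumerate(_NODE_OFF):
        sx, sy, sz = 2 * ox - 1, 2 * oy - 1, 2 * oz - 1
        g[a, 0] = 0.125 * sx * (1 + sy * eta) * (1 + sz * zeta)
        g[a, 1] = 0.125 * (1 + sx * xi) * sy * (1 + sz * zeta)
        g[a, 2] = 0.125 * (1 + sx * xi) * (1 + sy * eta) * sz
    return g


def _b_matrix(xi, eta, zeta, h):
    """Strain-displacement matrix (6 x 24) at a natural coordinate point."""
    dN = _shape_gradients(xi, eta, zeta) * (2.0 / h)  # d/dx = (2/h) d/dxi
    B = np.zeros((6, 24))
    for a in range(8):
        bx, by, bz = dN[a]
        c = 3 * a
        B[0, c + 0] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c + 1] = bz
        B[3, c + 2] = by
        B[4, c + 0] = bz
        B[4, c + 2] = bx
        B[5, c + 0] = by
        B[5, c + 1] = bx
    return B


def hex_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 stiffness of a cube element, 2x2x2 Gauss (exact for trilinear).

    DOF order: node-major, components (ux, uy, uz); nodes in x-fastest
    order over the voxel corners.
    """
    D = isotropic_stiffness(E, nu)
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    detJ = (h / 2.0) ** 3
    Ke = np.zeros((24, 24))
    for zeta in gp:
        for eta in gp:
            for xi in gp:
                B = _b_matrix(xi, eta, zeta, h)
                Ke += B.T @ D @ B * detJ
    return Ke


@dataclass
class FEModel:
    """One brick element per bone voxel, single tissue material."""

    shape: tuple[int, int, int]  # (nz, ny, nx) voxel grid
    voxel_size_mm: float
    E_t: float  # tissue modulus (GPa)
    nu: float
    elem_dofs: np.ndarray  # (n_elems, 24) compact DOF ids
    Ke: np.ndarray  # (24, 24)
    n_dofs: int
    constrained: np.ndarray  # bool per DOF: on the domain boundary (KUBC)
    node_xyz: np.ndarray  # (n_nodes, 3) node coordinates in voxel units
    meta: dict = field(default_factory=dict)

    @property
    def n_elements(self) -> int:
        return self.elem_dofs.shape[0]


def build_fe_model(
    bone: BinaryVolume,
    E_t: float = 15.0,
    nu: float = 0.3,
    remove_islands: bool = True,
) -> FEModel:
    """Convert a binary volume to a voxel FE model.

    26-connected components with no voxel on the domain boundary cannot be
    loaded by the boundary displacements and are removed (their volume is
    logged in ``meta``). Warns when the mask does not span all three axis
    directions.
    """
    mask = np.asarray(bone.data, bool)
    if not mask.any():
        raise ValueError("empty bone mask")
    removed = 0
    if remove_islands:
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
        if n > 1:
            border = np.zeros_like(mask)
            border[[0, -1], :, :] = True
            border[:, [0, -1], :] = True
            border[:, :, [0, -1]] = True
            keep_ids = np.unique(lab[border & mask])
            keep_ids = keep_ids[keep_ids > 0]
            keep = np.isin(lab, keep_ids) & mask
            removed = int(mask.sum() - keep.sum())
            if removed:
                mask = keep
    if not mask.any():
        raise ValueError("no bone connected to the domain boundary")
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        if not (proj[0] and proj[-1]):
            warnings.warn(
                f"bone mask does not span axis {ax}: apparent stiffness in that "
                "direction will be (near) zero",
                stacklevel=2,
            )

    nz, ny, nx = mask.shape
    ez, ey, ex = np.nonzero(mask)
    # node ids on the (nz+1, ny+1, nx+1) grid, x-fastest
    nny, nnx = ny + 1, nx + 1
    node_ids = (
        (ez[:, None] + _NODE_OFF[None, :, 2]) * (nny * nnx)
        + (ey[:, None] + _NODE_OFF[None, :, 1]) * nnx
        + (ex[:, None] + _NODE_OFF[None, :, 0])
    )
    used, inv = np.unique(node_ids.ravel(), return_inverse=True)
    compact = inv.reshape(node_ids.shape).astype(np.int64)
    elem_dofs = (3 * compact[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)

    gz, rem = np.divmod(used, nny * nnx)
    gy, gx = np.divmod(rem, nnx)
    node_xyz = np.stack([gx, gy, gz], axis=1).astype(float)
    on_boundary = (
        (gx == 0) | (gx == nx) | (gy == 0) | (gy == ny) | (gz == 0) | (gz == nz)
    )
    if not on_boundary.any():
        raise ValueError(
            "no bone element touches the domain boundary: the kinematic "
            "boundary displacements cannot load the structure"
        )
    constrained = np.repeat(on_boundary, 3)

    Ke = hex_stiffness(E_t, nu, bone.voxel_size_mm)
    model = FEModel(
        shape=(nz, ny, nx),
        voxel_size_mm=bone.voxel_size_mm,
        E_t=E_t,
        nu=nu,
        elem_dofs=np.ascontiguousarray(elem_dofs),
        Ke=Ke,
        n_dofs=3 * used.size,
        constrained=constrained,
        node_xyz=node_xyz,
    )
    model.meta["removed_island_voxels"] = removed
    model.meta["n_bone_voxels"] = int(mask.sum())
    return model


@njit(cache=True, fastmath=True)
def _ebe_matvec(elem_dofs, Ke, u, out):
    out[:] = 0.0
    n = elem_dofs.shape[0]
    for e in range(n):
        ue = np.empty(24)
        for a in range(24):
            ue[a] = u[elem_dofs[e, a]]
        for a in range(24):
            acc = 0.0
            for b in range(24):
                acc += Ke[a, b] * ue[b]
            out[elem_dofs[e, a]] += acc
    return out


@njit(cache=True, fastmath=True)
def _ebe_diag(elem_dofs, Ke, n_dofs):
    d = np.zeros(n_dofs)
    for e in range(elem_dofs.shape[0]):
        for a in range(24):
            d[elem_dofs[e, a]] += Ke[a, a]
    return d


@njit(cache=True, fastmath=True)
def _mean_stress(elem_dofs, Bmean, D, u):
    sig = np.zeros(6)
    for e in range(elem_dofs.shape[0]):
        eps = np.zeros(6)
        for i in range(6):
            acc = 0.0
            for a in range(24):
                acc += Bmean[i, a] * u[elem_dofs[e, a]]
            eps[i] = acc
        for i in range(6):
            acc = 0.0
            for j in range(6):
                acc += D[i, j] * eps[j]
            sig[i] += acc
    return sig


def _case_strain_tensor(case: int, eps0: float) -> np.ndarray:
    """Symmetric strain tensor of load case 0..5 (Voigt order)."""
    E = np.zeros((3, 3))
    i, j = _VOIGT[case]
    if i == j:
        E[i, i] = eps0
    else:
        E[i, j] = E[j, i] = eps0 / 2.0  # engineering shear gamma = eps0
    return E


def solve_load_cases(
    model: FEModel,
    eps0: float = 1e-3,
    rtol: float = 1e-6,
    maxiter: int = 20000,
) -> np.ndarray:
    """Apparent 6x6 stiffness from six kinematic uniform-strain analyses.

    For each case, boundary nodes get u = E.x; the interior is solved by
    matrix-free element-by-element PCG (Jacobi preconditioner, relative
    residual ``rtol``); the stiffness column is mean stress / applied
    strain over the full examined volume (bone + marrow). The result is
    symmetrized. Raises on CG non-convergence.
    """
    h = model.voxel_size_mm
    D = isotropic_stiffness(model.E_t, model.nu)
    Bmean = _b_matrix(0.0, 0.0, 0.0, h)
    free = ~model.constrained
    nfree = int(free.sum())
    diag = _ebe_diag(model.elem_dofs, model.Ke, model.n_dofs)
    dfree = diag[free]
    dfree[dfree <= 0] = 1.0

    scratch = np.zeros(model.n_dofs)
    out = np.zeros(model.n_dofs)

    def apply_free(x):
        scratch[:] = 0.0
        scratch[free] = x
        _ebe_matvec(model.elem_dofs, model.Ke, scratch, out)
        return out[free].copy()

    A = LinearOperator((nfree, nfree), matvec=apply_free)
    M = LinearOperator((nfree, nfree), matvec=lambda x: x / dfree)

    nz, ny, nx = model.shape
    v_total = nx * ny * nz * h**3
    v_elem = h**3
    C = np.zeros((6, 6))
    iters = []
    for case in range(6):
        E = _case_strain_tensor(case, eps0)
        u = np.zeros(model.n_dofs)
        upre = (model.node_xyz * h) @ E.T  # (n_nodes, 3) displacements
        u_flat = upre.reshape(-1)
        u[model.constrained] = u_flat[model.constrained]
        _ebe_matvec(model.elem_dofs, model.Ke, u, out)
        b = -out[free]
        if nfree:
            count = [0]

            def cb(xk):
                count[0] += 1

            x, info = cg(A, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
            if info != 0:
                raise RuntimeError(
                    f"CG did not converge for load case {case} (info={info})"
                )
            u[free] = x
            iters.append(count[0])
        sig = _mean_stress(model.elem_dofs, Bmean, D, u) * v_elem / v_total
        C[:, case] = sig / eps0
    C = 0.5 * (C + C.T)
    model.meta["cg_iterations"] = iters
    return C


# ---- orthotropy search ----------------------------------------------------


def voigt_to_tensor(C6: np.ndarray) -> np.ndarray:
    T = np.zeros((3, 3, 3, 3))
    for p, (i, j) in enumerate(_VOIGT):
        for q, (k, l) in enumerate(_VOIGT):
            v = C6[p, q]
            T[i, j, k, l] = T[j, i, k, l] = T[i, j, l, k] = T[j, i, l, k] = v
    return T


def tensor_to_voigt(T: np.ndarray) -> np.ndarray:
    C6 = np.zeros((6, 6))
    for p, (i, j) in enumerate(_VOIGT):
        for q, (k, l) in enumerate(_VOIGT):
            C6[p, q] = T[i, j, k, l]
    return C6


def rotate_stiffness(C6: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Stiffness in the frame whose axes are the rows of R (det +1)."""
    T = voigt_to_tensor(C6)
    Tr = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, T)
    return tensor_to_voigt(Tr)


def orthotropy_error(C6: np.ndarray) -> float:
    """Relative squared norm of couplings that vanish under orthotropy."""
    off = np.concatenate(
        [
            C6[:3, 3:6].ravel(),
            np.array([C6[3, 4], C6[3, 5], C6[4, 5]]),
        ]
    )
    return float((off**2).sum() * 2.0 / (C6**2).sum())


def _euler_to_rot(angles: np.ndarray) -> np.ndarray:
    a, b, c = angles
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    Ry = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    Rx = np.array([[1.0, 0, 0], [0, cc, -sc], [0, sc, cc]])
    return Rz @ Ry @ Rx


def find_orthotropic_axes(
    C_aniso: np.ndarray,
    n_grid: int = 2,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Best orthotropic coordinate system by multi-start Powell search.

    Minimizes :func:`orthotropy_error` of the rotated stiffness over three
    Euler angles, starting from an ``n_grid``^3 angle grid (>= 8 starts).
    Returns ``(R, C_ortho)`` with the orthotropic axes as rows of R. For
    (near-)degenerate inputs whose objective at the identity is within
    ``tol`` of the best found, the identity rotation is returned.
    """
    C_aniso = 0.5 * (C_aniso + C_aniso.T)

    def f(angles):
        return orthotropy_error(rotate_stiffness(C_aniso, _euler_to_rot(angles)))

    starts = np.linspace(0.0, np.pi / 2, n_grid, endpoint=False)
    best = None
    for a in starts:
        for b in starts:
            for c in starts:
                res = minimize(
                    f,
                    x0=np.array([a, b, c]),
                    method="Powell",
                    options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 2000},
                )
                if best is None or res.fun < best.fun:
                    best = res
    f_id = f(np.zeros(3))
    if f_id <= best.fun + tol:
        R = np.eye(3)
    else:
        R = _euler_to_rot(best.x)
    return R, rotate_stiffness(C_aniso, R)


def engineering_constants(C_ortho: np.ndarray) -> dict:
    """Young's and shear moduli from the orthotropic stiffness, sorted.

    The couplings are dropped (they are the orthotropy residual), the 6x6
    is inverted to compliance, and axes are relabeled so E11 <= E22 <= E33;
    the shear moduli are permuted consistently (G23 couples axes 2 and 3,
    etc.). Raises on singular input.
    """
    Co = np.zeros((6, 6))
    Co[:3, :3] = C_ortho[:3, :3]
    Co[3:, 3:] = np.diag(np.diag(C_ortho[3:, 3:]))
    if np.linalg.matrix_rank(Co) < 6:
        raise np.linalg.LinAlgError("orthotropic stiffness is singular")
    S = np.linalg.inv(Co)
    E = 1.0 / np.diag(S)[:3]
    G = 1.0 / np.diag(S)[3:]  # [G23, G31, G12] in unsorted axes
    perm = np.argsort(E, kind="stable")

    def shear_index(i, j):
        return 3 - i - j  # {1,2}->0 (G23), {0,2}->1 (G31), {0,1}->2 (G12)

    E_sorted = E[perm]
    G_sorted = np.array(
        [
            G[shear_index(perm[1], perm[2])],
            G[shear_index(perm[0], perm[2])],
            G[shear_index(perm[0], perm[1])],
        ]
    )
    nu_mat = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            if i != j:
                nu_mat[i, j] = -S[j, i] / S[i, i]
    nu_sorted = {
        f"nu{a + 1}{b + 1}": float(nu_mat[perm[a], perm[b]])
        for a in range(3)
        for b in range(3)
        if a != b
    }
    return {
        "E11": float(E_sorted[0]),
        "E22": float(E_sorted[1]),
        "E33": float(E_sorted[2]),
        "G23": float(G_sorted[0]),
        "G31": float(G_sorted[1]),
        "G12": float(G_sorted[2]),
        "axis_permutation": [int(p) for p in perm],
        **nu_sorted,
    }


@dataclass
class StiffnessResult:
    """Apparent stiffness, best-orthotropy rotation and sorted constants."""

    C_aniso: np.ndarray
    R: np.ndarray
    C_ortho: np.ndarray
    orthotropy_objective: float
    constants: dict
    meta: dict = field(default_factory=dict)


def homogenize(
    bone: BinaryVolume,
    E_t: float = 15.0,
    nu: float = 0.3,
    eps0: float = 1e-3,
    rtol: float = 1e-6,
) -> StiffnessResult:
    """Full chain: model, six load cases, orthotropy search, constants."""
    model = build_fe_model(bone, E_t=E_t, nu=nu)
    C = solve_load_cases(model, eps0=eps0, rtol=rtol)
    R, C_o = find_orthotropic_axes(C)
    consts = engineering_constants(C_o)
    return StiffnessResult(
        C_aniso=C,
        R=R,
        C_ortho=C_o,
        orthotropy_objective=orthotropy_error(C_o),
        constants=consts,
        meta={
            "E_t": E_t,
            "nu": nu,
            "eps0": eps0,
            "cg_rtol": rtol,
            **model.meta,
        },
    )
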