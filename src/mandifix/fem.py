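"""Linear-elastic TET10 finite-element core.

Straight-edged quadratic tetrahedra (affine geometry, quadratic displacement
interpolation), 4-point Gauss quadrature (exact for the linear-strain
stiffness integrand), sparse symmetric assembly, multipoint tie constraints
eliminated through a reduction matrix, and direct/iterative solution with a
residual check.  Strains and stresses are recovered at the four integration
points of every element.

DOF ordering is node-major: dof = 3 * node + component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

# 4-point Gauss rule on the reference tetrahedron (degree-2 exact)
_GA = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_GB = (5.0 - np.sqrt(5.0)) / 20.0
GAUSS_POINTS = np.array(
    [
        [_GB, _GB, _GB],
        [_GA, _GB, _GB],
        [_GB, _GA, _GB],
        [_GB, _GB, _GA],
    ]
)  # (xi1, xi2, xi3); weight 1/4 of the element volume each

_DL = np.array(
    [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)  # barycentric gradients wrt (xi1, xi2, xi3)

_EDGE_PAIRS = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


class FEMError(RuntimeError):
    pass


def tet10_shape(bary: np.ndarray) -> np.ndarray:
    """Shape function values at barycentric coordinates (..., 4)."""
    L = np.asarray(bary)
    N = np.empty(L.shape[:-1] + (10,))
    for i in range(4):
        N[..., i] = L[..., i] * (2.0 * L[..., i] - 1.0)
    for k, (a, b) in enumerate(_EDGE_PAIRS):
        N[..., 4 + k] = 4.0 * L[..., a] * L[..., b]
    return N


def _shape_gradients_ref() -> np.ndarray:
    """dN/dxi at the 4 Gauss points: (4 gp, 10, 3)."""
    xi = GAUSS_POINTS
    L = np.concatenate([1 - xi.sum(axis=1, keepdims=True), xi], axis=1)  # (4,4)
    G = np.empty((4, 10, 3))
    for i in range(4):
        G[:, i, :] = (4.0 * L[:, i] - 1.0)[:, None] * _DL[i]
    for k, (a, b) in enumerate(_EDGE_PAIRS):
        G[:, 4 + k, :] = 4.0 * (
            L[:, a][:, None] * _DL[b] + L[:, b][:, None] * _DL[a]
        )
    return G


_GRAD_REF = _shape_gradients_ref()


def element_gradients(mesh, sl=slice(None)):
    """Physical shape gradients and volumes (optionally for an element slice).

    Returns
    -------
    grad : (n_elems, 4, 10, 3) dN/dx at the Gauss points
    vol : (n_elems,) element volumes (positive)
    """
    x = mesh.nodes[mesh.tets[sl, :4]]
    J = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)  # columns = edge vectors
    detJ = np.linalg.det(J)
    if (detJ <= 0).any():
        raise FEMError("non-positive Jacobian during assembly")
    Jinv = np.linalg.inv(J)
    grad = np.einsum("gnj,eji->egni", _GRAD_REF, Jinv)
    return grad, detJ / 6.0


def _b_matrices(grad: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, Voigt (11,22,33,12,13,23), engineering
    shear: (n, 4, 6, 30)."""
    n = grad.shape[0]
    B = np.zeros((n, 4, 6, 30))
    gx, gy, gz = grad[..., 0], grad[..., 1], grad[..., 2]
    cols = np.arange(10) * 3
    B[:, :, 0, cols] = gx
    B[:, :, 1, cols + 1] = gy
    B[:, :, 2, cols + 2] = gz
    B[:, :, 3, cols] = gy
    B[:, :, 3, cols + 1] = gx
    B[:, :, 4, cols] = gz
    B[:, :, 4, cols + 2] = gx
    B[:, :, 5, cols + 1] = gz
    B[:, :, 5, cols + 2] = gy
    return B


def element_stiffness(mesh, C_global, sl=slice(None)):
    """Batch TET10 element stiffness matrices (n, 30, 30)."""
    grad, vol = element_gradients(mesh, sl)
    B = _b_matrices(grad)
    w = vol / 4.0
    CB = np.einsum("eab,egbj->egaj", C_global, B, optimize=True)
    K = np.einsum("egai,egaj->eij", B * w[:, None, None, None], CB, optimize=True)
    return 0.5 * (K + K.transpose(0, 2, 1))


@dataclass
class TieConstraintSet:
    """Slave device nodes interpolated inside master bone elements."""

    slave_nodes: np.ndarray  # (k,)
    master_elems: np.ndarray  # (k,)
    master_nodes: np.ndarray  # (k, 10)
    weights: np.ndarray  # (k, 10), rows sum to 1

    def __len__(self):
        return self.slave_nodes.size


def build_ties(mesh, slave_nodes=None, tol: float = 0.35) -> TieConstraintSet:
    """Interpolation (no-relative-motion) constraints tying slave nodes into
    the bone volume mesh.

    Slave nodes default to the set recorded by device placement
    (node set 'tie_slaves').  Each slave is located inside a bone element;
    its displacement is constrained to the TET10 shape-function interpolation
    at that point.  Raises if a slave lies farther than `tol` (in barycentric
    excess times local element size) outside every candidate element.
    """
    if slave_nodes is None:
        slave_nodes = mesh.node_sets.get("tie_slaves")
    if slave_nodes is None or len(slave_nodes) == 0:
        return TieConstraintSet(
            np.empty(0, dtype=int),
            np.empty(0, dtype=int),
            np.empty((0, 10), dtype=int),
            np.empty((0, 10)),
        )
    slave_nodes = np.asarray(slave_nodes)
    bone = np.nonzero(~np.isin(mesh.region, ("plate", "screw")))[0]
    cent = mesh.centroids()[bone]
    tree = cKDTree(cent)
    pts = mesh.nodes[slave_nodes]
    k = min(40, bone.size)
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)

    x = mesh.corner_coords()
    master = np.full(slave_nodes.size, -1, dtype=int)
    bary = np.zeros((slave_nodes.size, 4))
    best_def = np.full(slave_nodes.size, -np.inf)
    remaining = np.arange(slave_nodes.size)
    for col in range(cand.shape[1]):
        if remaining.size == 0:
            break
        e = bone[cand[remaining, col]]
        xe = x[e]
        M = (xe[:, 1:] - xe[:, :1]).transpose(0, 2, 1)
        rhs = pts[remaining] - xe[:, 0]
        loc = np.linalg.solve(M, rhs[..., None])[..., 0]
        b = np.concatenate([1 - loc.sum(axis=1, keepdims=True), loc], axis=1)
        deficit = b.min(axis=1)
        better = deficit > best_def[remaining]
        upd = remaining[better]
        best_def[upd] = deficit[better]
        master[upd] = e[better]
        bary[upd] = b[better]
        inside = deficit >= -1e-9
        remaining = remaining[~inside]

    if (best_def < -tol).any():
        bad = int((best_def < -tol).sum())
        raise FEMError(
            f"{bad} tie slave nodes could not be projected into the bone mesh"
        )
    # clip slightly-outside points onto the element (renormalized barycentric)
    bary = np.clip(bary, 0.0, None)
    bary /= bary.sum(axis=1, keepdims=True)
    W = tet10_shape(bary)
    return TieConstraintSet(
        slave_nodes=slave_nodes,
        master_elems=master,
        master_nodes=mesh.tets[master],
        weights=W,
    )


def tie_reduction_matrix(n_nodes: int, ties: TieConstraintSet) -> sp.csr_matrix:
    """Sparse T with u_full = T @ u_reduced (slave DOFs eliminated)."""
    n_dof = 3 * n_nodes
    is_slave = np.zeros(n_nodes, dtype=bool)
    is_slave[ties.slave_nodes] = True
    kept_nodes = np.nonzero(~is_slave)[0]
    red_index = -np.ones(n_nodes, dtype=int)
    red_index[kept_nodes] = np.arange(kept_nodes.size)

    rows = [np.repeat(kept_nodes * 3, 3) + np.tile(np.arange(3), kept_nodes.size)]
    cols = [np.arange(3 * kept_nodes.size)]
    vals = [np.ones(3 * kept_nodes.size)]
    if len(ties):
        if (red_index[ties.master_nodes] < 0).any():
            raise FEMError("tie master node is itself a slave (cyclic constraint)")
        k = ties.slave_nodes.size
        sdof = (3 * ties.slave_nodes[:, None, None] + np.arange(3)[None, None, :])
        mdof = 3 * red_index[ties.master_nodes][:, :, None] + np.arange(3)[None, None, :]
        w = np.broadcast_to(ties.weights[:, :, None], (k, 10, 3))
        rows.append(np.broadcast_to(sdof, (k, 10, 3)).ravel())
        cols.append(mdof.ravel())
        vals.append(w.ravel())
    T = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, 3 * kept_nodes.size),
    ).tocsr()
    return T


@dataclass
class FESystem:
    """Assembled, tie-reduced linear system with boundary conditions."""

    mesh: object
    C_global: np.ndarray
    K_red: sp.csr_matrix
    f_red: np.ndarray
    T: sp.csr_matrix | None
    bc_mask: np.ndarray  # True = restrained reduced DOF
    ties: TieConstraintSet | None
    meta: dict = field(default_factory=dict)


@dataclass
class FESolution:
    """Displacements plus integration-point strain/stress fields."""

    mesh: object
    u: np.ndarray  # (n_nodes, 3) mm
    strain: np.ndarray  # (n_elems, 4, 6) Voigt, engineering shear
    stress: np.ndarray  # (n_elems, 4, 6) MPa
    point_weights: np.ndarray  # (n_elems, 4) volume weights, mm^3
    system: FESystem
    residual: float

    def point_regions(self) -> np.ndarray:
        return np.repeat(self.mesh.region, 4)


def stiffness_csr(mesh, C_global, elem_ids=None, chunk=10000) -> sp.csr_matrix:
    """Global stiffness contribution of a subset of elements (full DOF space)."""
    n_dof = 3 * mesh.n_nodes
    if elem_ids is None:
        elem_ids = np.arange(mesh.n_elems)
    elem_ids = np.asarray(elem_ids)
    edof = (
        3 * mesh.tets[elem_ids][:, :, None] + np.arange(3)[None, None, :]
    ).reshape(-1, 30)
    K = None
    for lo in range(0, elem_ids.size, chunk):
        hi = min(lo + chunk, elem_ids.size)
        Ke = element_stiffness(mesh, C_global[elem_ids[lo:hi]], sl=elem_ids[lo:hi])
        ed = edof[lo:hi]
        rows = np.repeat(ed, 30, axis=1).ravel()
        cols = np.tile(ed, (1, 30)).ravel()
        Kc = sp.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)
        ).tocsr()
        K = Kc if K is None else K + Kc
    return K


def assemble(mesh, C_global, ties=None, bcs=None, loads=None, K=None) -> FESystem:
    """Assemble the reduced stiffness and load vector.

    Tie slaves are eliminated first via the reduction matrix, then Dirichlet
    DOFs are flagged in the mask (rows/columns handled at solve time).
    A precomputed full stiffness K may be supplied (e.g. bone part cached
    across device materials).
    """
    n_dof = 3 * mesh.n_nodes
    if K is None:
        K = stiffness_csr(mesh, C_global)

    f = np.zeros(n_dof)
    if loads is not None:
        f = np.asarray(loads.nodal_forces, dtype=float).ravel().copy()

    T = None
    if ties is not None and len(ties):
        T = tie_reduction_matrix(mesh.n_nodes, ties)
        K_red = (T.T @ K @ T).tocsr()
        f_red = T.T @ f
    else:
        K_red, f_red = K, f

    if bcs is None:
        bc_mask = np.zeros(K_red.shape[0], dtype=bool)
    else:
        full_mask = bcs.dof_mask(mesh.n_nodes)
        if T is not None:
            # reduced DOFs correspond to non-slave nodes in original order
            is_slave = np.zeros(mesh.n_nodes, dtype=bool)
            is_slave[ties.slave_nodes] = True
            kept_dofs = np.repeat(~is_slave, 3)
            bc_mask = full_mask[kept_dofs]
        else:
            bc_mask = full_mask

    sym_err = abs(K_red - K_red.T).max()
    scale = abs(K_red).max()
    if sym_err > 1e-9 * scale:
        raise FEMError(f"stiffness not symmetric (err {sym_err:.2g})")

    sysm = FESystem(
        mesh=mesh, C_global=C_global, K_red=K_red.tocsr(), f_red=f_red,
        T=T, bc_mask=bc_mask, ties=ties,
    )
    sysm.meta["n_dof_full"] = n_dof
    return sysm


def solve(system: FESystem, rtol: float = 1e-9) -> FESolution:
    """Solve the constrained system and recover integration-point fields.

    Direct sparse LU for moderate systems; conjugate gradients with an
    incomplete-LU preconditioner for large ones.  The relative residual of
    the free-DOF system must be below `rtol`.
    """
    K, f = system.K_red, system.f_red
    free = ~system.bc_mask
    if not system.bc_mask.any():
        raise FEMError("no boundary conditions: rigid-body modes present")
    Kff = K[free][:, free].tocsc()
    ff = f[free]
    n = Kff.shape[0]

    u_free = _solve_spd(Kff, ff, n, rtol)

    res = np.linalg.norm(Kff @ u_free - ff)
    den = np.linalg.norm(ff)
    rel = res / den if den > 0 else res
    if den > 0 and rel > rtol * 10:
        raise FEMError(f"solver residual {rel:.2e} exceeds tolerance")

    u_red = np.zeros(K.shape[0])
    u_red[free] = u_free
    u_full = system.T @ u_red if system.T is not None else u_red
    u = u_full.reshape(-1, 3)

    mesh = system.mesh
    strain = np.empty((mesh.n_elems, 4, 6))
    stress = np.empty((mesh.n_elems, 4, 6))
    weights = np.empty((mesh.n_elems, 4))
    edof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 30)
    for lo in range(0, mesh.n_elems, 20000):
        hi = min(lo + 20000, mesh.n_elems)
        grad, vol = element_gradients(mesh, slice(lo, hi))
        B = _b_matrices(grad)
        ue = u_full[edof[lo:hi]]
        strain[lo:hi] = np.einsum("egij,ej->egi", B, ue, optimize=True)
        stress[lo:hi] = np.einsum(
            "eab,egb->ega", system.C_global[lo:hi], strain[lo:hi], optimize=True
        )
        weights[lo:hi] = vol[:, None] / 4.0

    return FESolution(
        mesh=mesh, u=u, strain=strain, stress=stress,
        point_weights=weights, system=system, residual=float(rel),
    )


def _solve_spd(Kff, ff, n, rtol, direct_limit: int = 25000):
    """Direct LU for small systems; for large ones, BiCGStab preconditioned
    with an incomplete LU of the symmetrically Jacobi-scaled, reverse
    Cuthill-McKee reordered matrix (deterministic for a fixed mesh).

    The Jacobi scaling tames the ~1e4 stiffness contrast between soft tissue
    and device metal; the RCM ordering keeps the incomplete factors local,
    which both cheapens the factorization and stabilizes it."""
    if n <= direct_limit:
        return spla.splu(Kff).solve(ff)
    from scipy.sparse.csgraph import reverse_cuthill_mckee

    d = Kff.diagonal()
    if (d <= 0).any():
        raise FEMError("non-positive diagonal: system not positive definite")
    ds = 1.0 / np.sqrt(d)
    Ks = (sp.diags(ds) @ Kff @ sp.diags(ds)).tocsr()
    perm = reverse_cuthill_mckee(Ks, symmetric_mode=True)
    iperm = np.empty_like(perm)
    iperm[perm] = np.arange(n)
    Kp = Ks[perm][:, perm].tocsc()
    fp = (ds * ff)[perm]
    for drop, fill in ((1e-2, 3.0), (3e-3, 4.0), (3e-4, 8.0)):
        try:
            ilu = spla.spilu(
                Kp, drop_tol=drop, fill_factor=fill,
                permc_spec="NATURAL", options=dict(SymmetricMode=True),
            )
        except (RuntimeError, MemoryError):
            continue
        M = spla.LinearOperator(Kp.shape, ilu.solve)
        u, info = spla.bicgstab(
            Kp, fp, rtol=min(rtol, 1e-10), atol=0.0, maxiter=2000, M=M
        )
        if info == 0:
            return ds * u[iperm]
    raise FEMError("iterative solver failed to converge")


def strain_energy(solution: FESolution) -> float:
    """0.5 * u^T K u of the solved reduced system."""
    K, _ = solution.system.K_red, solution.system.f_red
    free = ~solution.system.bc_mask
    u_red = np.zeros(K.shape[0])
    if solution.system.T is not None:
        # reduced displacements = kept-node DOFs of the full vector
        is_slave = np.zeros(solution.mesh.n_nodes, dtype=bool)
        is_slave[solution.system.ties.slave_nodes] = True
        u_red = solution.u.ravel()[np.repeat(~is_slave, 3)]
    else:
        u_red = solution.u.ravel()
    return 0.5 * float(u_red @ (K @ u_red))


def reaction_forces(solution: FESolution) -> dict:
    """Reactions at restrained DOFs summed per named node set, plus totals.

    Returns a dict with per-set 3-vector resultants (N), the total reaction,
    the total applied load, and the global equilibrium residual.
    """
    system = solution.system
    K, f = system.K_red, system.f_red
    if system.T is not None:
        is_slave = np.zeros(solution.mesh.n_nodes, dtype=bool)
        is_slave[system.ties.slave_nodes] = True
        u_red = solution.u.ravel()[np.repeat(~is_slave, 3)]
        red_of_node = -np.ones(solution.mesh.n_nodes, dtype=int)
        red_of_node[~is_slave] = np.arange((~is_slave).sum())
    else:
        u_red = solution.u.ravel()
        red_of_node = np.arange(solution.mesh.n_nodes)

    r = K @ u_red - f
    r_bc = np.where(system.bc_mask, r, 0.0).reshape(-1, 3)

    out = {}
    for name, nodes in solution.mesh.node_sets.items():
        idx = red_of_node[nodes]
        idx = idx[idx >= 0]
        out[name] = r_bc[idx].sum(axis=0)
    total_reaction = r_bc.sum(axis=0)
    applied = f.reshape(-1, 3).sum(axis=0)
    out["_total_reaction"] = total_reaction
    out["_total_applied"] = applied
    out["_equilibrium_residual"] = float(
        np.linalg.norm(total_reaction + applied)
    )
    return out
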