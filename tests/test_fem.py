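"""FE core verification: patch test, beam benchmark, constraints, recovery."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from mandifix import fem
from mandifix.loading import BCSet, LoadCase, distribute_on_patch
from mandifix.materials import stiffness_voigt
from mandifix.mesh import structured_block

# degree-4 Keast rule on the reference tetrahedron (11 points), used as the
# independent quadrature oracle for the element stiffness
_KEAST11 = [
    (0.25, 0.25, 0.25, -0.013155555555555),
    (0.0714285714285714, 0.0714285714285714, 0.0714285714285714, 0.007622222222222),
    (0.785714285714286, 0.0714285714285714, 0.0714285714285714, 0.007622222222222),
    (0.0714285714285714, 0.785714285714286, 0.0714285714285714, 0.007622222222222),
    (0.0714285714285714, 0.0714285714285714, 0.785714285714286, 0.007622222222222),
    (0.399403576166799, 0.100596423833201, 0.100596423833201, 0.024888888888888),
    (0.100596423833201, 0.399403576166799, 0.100596423833201, 0.024888888888888),
    (0.100596423833201, 0.100596423833201, 0.399403576166799, 0.024888888888888),
    (0.399403576166799, 0.399403576166799, 0.100596423833201, 0.024888888888888),
    (0.399403576166799, 0.100596423833201, 0.399403576166799, 0.024888888888888),
    (0.100596423833201, 0.399403576166799, 0.399403576166799, 0.024888888888888),
]


def _stiffness_oracle(mesh, C):
    """Single-element stiffness via the independent 11-point rule."""
    x = mesh.corner_coords()[0]
    J = (x[1:] - x[:1]).T
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    DL = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    edges = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
    K = np.zeros((30, 30))
    for x1, x2, x3, w in _KEAST11:
        L = np.array([1 - x1 - x2 - x3, x1, x2, x3])
        G = np.zeros((10, 3))
        for i in range(4):
            G[i] = (4 * L[i] - 1) * DL[i]
        for k, (a, b) in enumerate(edges):
            G[4 + k] = 4 * (L[a] * DL[b] + L[b] * DL[a])
        G = G @ Jinv
        B = np.zeros((6, 30))
        for n in range(10):
            gx, gy, gz = G[n]
            B[0, 3 * n] = gx
            B[1, 3 * n + 1] = gy
            B[2, 3 * n + 2] = gz
            B[3, 3 * n], B[3, 3 * n + 1] = gy, gx
            B[4, 3 * n], B[4, 3 * n + 2] = gz, gx
            B[5, 3 * n + 1], B[5, 3 * n + 2] = gz, gy
        K += w * detJ * B.T @ C @ B
    return K


def _single_tet_mesh():
    from mandifix.mesh import LabeledMesh

    corners = np.array(
        [[0.0, 0, 0], [1.2, 0.1, 0], [0.3, 1.1, 0.05], [0.2, 0.3, 0.9]]
    )
    edges = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
    mids = np.array([(corners[a] + corners[b]) / 2 for a, b in edges])
    nodes = np.vstack([corners, mids])
    tets = np.arange(10)[None, :]
    return LabeledMesh(nodes=nodes, tets=tets,
                       region=np.array(["block"], dtype=object))


def test_element_stiffness_matches_higher_order_quadrature(cards):
    m = _single_tet_mesh()
    C = stiffness_voigt(cards["symphysis"])
    Ke = fem.element_stiffness(m, C[None])[0]
    Ko = _stiffness_oracle(m, C)
    assert np.abs(Ke - Ko).max() < 1e-8 * np.abs(Ko).max()


def test_unconstrained_element_has_six_rigid_modes(iso_card):
    m = _single_tet_mesh()
    C = np.broadcast_to(stiffness_voigt(iso_card), (1, 6, 6)).copy()
    K = fem.assemble(m, C).K_red.toarray()
    w = np.linalg.eigvalsh(K)
    assert np.abs(w[:6]).max() < 1e-9 * w[-1]
    assert w[6] > 1e-6 * w[-1]


def _patch_test(C6):
    m = structured_block((2.0, 1.5, 1.0), (2, 2, 2))
    C = np.broadcast_to(C6, (m.n_elems, 6, 6)).copy()
    A = np.array([[1.0, 0.4, -0.2], [0.4, -0.7, 0.3], [-0.2, 0.3, 0.5]]) * 1e-3
    u_exact = m.nodes @ A.T
    system = fem.assemble(m, C)
    K = system.K_red
    mask = np.zeros(3 * m.n_nodes, dtype=bool)
    surf = m.surface_nodes()
    mask[np.repeat(3 * surf, 3) + np.tile(np.arange(3), surf.size)] = True
    free = ~mask
    rhs = -K[:, mask] @ u_exact.ravel()[mask]
    u = u_exact.ravel().copy()
    u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs[free])
    grad, _ = fem.element_gradients(m)
    B = fem._b_matrices(grad)
    edof = (3 * m.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 30)
    strain = np.einsum("egij,ej->egi", B, u[edof])
    expected = np.array(
        [A[0, 0], A[1, 1], A[2, 2], 2 * A[0, 1], 2 * A[0, 2], 2 * A[1, 2]]
    )
    return np.abs(strain - expected).max()


def test_patch_test_passes_for_every_material_card(cards):
    """Quadratic elements reproduce any linear displacement field exactly."""
    for name, card in cards.items():
        err = _patch_test(stiffness_voigt(card))
        assert err < 1e-10, name


@pytest.fixture(scope="module")
def cantilever(iso_card):
    L, h, P = 20.0, 2.0, 10.0
    m = structured_block((L, h, h), (40, 4, 4))
    C = np.broadcast_to(stiffness_voigt(iso_card), (m.n_elems, 6, 6)).copy()
    fixed = np.nonzero(m.nodes[:, 0] < 1e-9)[0]
    m.node_sets["clamp"] = fixed
    bf = m.boundary_faces()
    fc = m.face_centroids(bf)
    tip = bf[fc[:, 0] > L - 1e-9]
    f = distribute_on_patch(m, tip, [0.0, 0.0, -P])
    bcs = BCSet(fixed_nodes=fixed, vertical_nodes=np.empty(0, dtype=int))
    system = fem.assemble(
        m, C, bcs=bcs, loads=LoadCase(nodal_forces=f, patch_resultants={})
    )
    sol = fem.solve(system)
    return m, sol, (L, h, P)


def test_cantilever_tip_deflection_matches_beam_theory(cantilever):
    m, sol, (L, h, P) = cantilever
    tip_nodes = np.nonzero(m.nodes[:, 0] > L - 1e-9)[0]
    w_fe = sol.u[tip_nodes, 2].mean()
    I = h**4 / 12.0
    w_beam = -P * L**3 / (3.0 * 15000.0 * I)
    assert abs(w_fe - w_beam) / abs(w_beam) < 0.02


def test_strain_energy_equals_half_external_work(cantilever):
    _, sol, _ = cantilever
    W = 0.5 * float(sol.system.f_red @ _reduced_u(sol))
    E = fem.strain_energy(sol)
    assert abs(E - W) / abs(W) < 1e-8


def _reduced_u(sol):
    if sol.system.T is None:
        return sol.u.ravel()
    is_slave = np.zeros(sol.mesh.n_nodes, dtype=bool)
    is_slave[sol.system.ties.slave_nodes] = True
    return sol.u.ravel()[np.repeat(~is_slave, 3)]


def test_reactions_balance_applied_load(cantilever):
    m, sol, (L, h, P) = cantilever
    r = fem.reaction_forces(sol)
    assert r["_equilibrium_residual"] < 1e-6
    assert np.allclose(r["clamp"], [0.0, 0.0, P], atol=1e-6)


def test_doubling_moduli_halves_displacements(iso_card):
    m = structured_block((4.0, 1.0, 1.0), (8, 2, 2))
    fixed = np.nonzero(m.nodes[:, 0] < 1e-9)[0]
    bcs = BCSet(fixed_nodes=fixed, vertical_nodes=np.empty(0, dtype=int))
    bf = m.boundary_faces()
    tip = bf[m.face_centroids(bf)[:, 0] > 4 - 1e-9]
    f = distribute_on_patch(m, tip, [1.0, 2.0, -3.0])
    lc = LoadCase(nodal_forces=f, patch_resultants={})
    C1 = np.broadcast_to(stiffness_voigt(iso_card), (m.n_elems, 6, 6)).copy()
    u1 = fem.solve(fem.assemble(m, C1, bcs=bcs, loads=lc)).u
    u2 = fem.solve(fem.assemble(m, 2.0 * C1, bcs=bcs, loads=lc)).u
    assert np.allclose(u2, 0.5 * u1, atol=1e-12 + 1e-6 * np.abs(u1).max())


def test_mirrored_problem_gives_mirrored_solution(iso_card):
    """Reflecting geometry and loads about x=0 reflects the solution."""
    from mandifix.mesh import LabeledMesh

    m = structured_block((3.0, 1.0, 1.0), (6, 2, 2))
    C = np.broadcast_to(stiffness_voigt(iso_card), (m.n_elems, 6, 6)).copy()
    fixed = np.nonzero(m.nodes[:, 0] < 1e-9)[0]
    bcs = BCSet(fixed_nodes=fixed, vertical_nodes=np.empty(0, dtype=int))
    rng = np.random.default_rng(3)
    f = np.zeros((m.n_nodes, 3))
    loaded = rng.choice(m.n_nodes, 20, replace=False)
    f[loaded] = rng.normal(size=(20, 3))
    u = fem.solve(
        fem.assemble(m, C, bcs=bcs, loads=LoadCase(f, {}))
    ).u

    mirror = np.array([-1.0, 1.0, 1.0])
    # restore positive orientation after reflection: swap corners 1<->2 and
    # permute the midside nodes accordingly
    reorient = [0, 2, 1, 3, 6, 5, 4, 7, 9, 8]
    m2 = LabeledMesh(
        nodes=m.nodes * mirror, tets=m.tets[:, reorient], region=m.region
    )
    f2 = f * mirror
    u2 = fem.solve(
        fem.assemble(m2, C, bcs=bcs, loads=LoadCase(f2, {}))
    ).u
    assert np.abs(u2 - u * mirror).max() < 1e-8 * np.abs(u).max()


def test_missing_boundary_conditions_raise(iso_card):
    m = structured_block((1.0, 1.0, 1.0), (2, 2, 2))
    C = np.broadcast_to(stiffness_voigt(iso_card), (m.n_elems, 6, 6)).copy()
    system = fem.assemble(m, C)
    with pytest.raises(fem.FEMError):
        fem.solve(system)


# ---- tie constraints -------------------------------------------------------


def _mesh_with_extra_nodes(points):
    from mandifix.mesh import LabeledMesh

    m = structured_block((2.0, 2.0, 2.0), (2, 2, 2))
    nodes = np.vstack([m.nodes, points])
    return LabeledMesh(nodes=nodes, tets=m.tets, region=m.region), m.n_nodes


def test_tie_weights_reproduce_slave_positions():
    rng = np.random.default_rng(11)
    pts = rng.uniform(0.05, 1.95, size=(15, 3))
    m, n0 = _mesh_with_extra_nodes(pts)
    ties = fem.build_ties(m, slave_nodes=np.arange(n0, n0 + 15))
    assert np.allclose(ties.weights.sum(axis=1), 1.0, atol=1e-12)
    interp = np.einsum("kn,knd->kd", ties.weights, m.nodes[ties.master_nodes])
    assert np.abs(interp - pts).max() < 1e-8


def test_tie_at_master_vertex_is_identity():
    m, n0 = _mesh_with_extra_nodes(np.array([[1.0, 1.0, 1.0]]))
    ties = fem.build_ties(m, slave_nodes=np.array([n0]))
    w = ties.weights[0]
    nz = np.nonzero(np.abs(w) > 1e-12)[0]
    assert len(nz) == 1 and np.isclose(w[nz[0]], 1.0)
    assert np.allclose(m.nodes[ties.master_nodes[0, nz[0]]], [1.0, 1.0, 1.0])


def test_far_slave_raises_projection_error():
    m, n0 = _mesh_with_extra_nodes(np.array([[10.0, 10.0, 10.0]]))
    with pytest.raises(fem.FEMError):
        fem.build_ties(m, slave_nodes=np.array([n0]))


def test_rigid_translation_through_ties_is_force_free(iso_card):
    """Tied systems transmit no internal force under rigid translation."""
    pts = np.array([[0.5, 0.5, 0.5], [1.3, 0.7, 1.1]])
    m, n0 = _mesh_with_extra_nodes(pts)
    C = np.broadcast_to(stiffness_voigt(iso_card), (m.n_elems, 6, 6)).copy()
    ties = fem.build_ties(m, slave_nodes=np.array([n0, n0 + 1]))
    system = fem.assemble(m, C, ties=ties)
    n_red = system.K_red.shape[0] // 3
    for comp in range(3):
        t = np.zeros((n_red, 3))
        t[:, comp] = 1.0
        force = system.K_red @ t.ravel()
        assert np.abs(force).max() < 1e-8 * abs(system.K_red).max()
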