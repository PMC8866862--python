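"""Material table, orthotropic stiffness, frame rotation."""

import numpy as np
import pytest

from mandifix.materials import (
    MaterialCard,
    MaterialError,
    assign_materials,
    compliance_voigt,
    load_material_table,
    local_frames,
    rotate_stiffness,
    stiffness_voigt,
    voigt_to_tensor,
)


def test_table_has_twelve_cards_with_printed_values(cards):
    assert len(cards) == 12
    sym = cards["symphysis"]
    assert (sym.E1, sym.nu12, sym.G12) == (20492.0, 0.34, 6908.0)
    gran = cards["granulation"]
    assert (gran.E1, gran.nu12, gran.G12) == (3.0, 0.4, 1.0)
    we = cards["WE43"]
    assert (we.E1, we.yield_strength) == (44200.0, 162.0)
    assert cards["Ti-6Al-4V"].yield_strength == 880.0
    assert cards["PLA"].yield_strength == 70.0


def test_cortical_moduli_ordered_and_admissible(cards):
    for name in ("symphysis", "body", "angle", "ramus", "condyle",
                 "coronoid_process"):
        c = cards[name]
        assert c.E1 >= c.E2 >= c.E3
        C = stiffness_voigt(c)  # raises if compliance not SPD
        assert np.abs(C - C.T).max() < 1e-10 * np.abs(C).max()


def test_isotropic_stiffness_matches_lame_closed_form(iso_card):
    C = stiffness_voigt(iso_card)
    E, nu = 15000.0, 0.3
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    assert np.isclose(C[0, 0], lam + 2 * mu)
    assert np.isclose(C[0, 1], lam)
    assert np.isclose(C[3, 3], mu)
    assert np.isclose(C[0, 0], 20192.3, atol=0.05)
    assert np.isclose(C[0, 1], 8653.8, atol=0.05)
    assert np.isclose(C[3, 3], 5769.2, atol=0.05)


def test_isotropic_closed_form_for_random_draws():
    rng = np.random.default_rng(42)
    for _ in range(20):
        E = rng.uniform(10.0, 2e5)
        nu = rng.uniform(0.05, 0.45)
        card = MaterialCard("r", E, E, E, nu, nu, nu, isotropic=True)
        C = stiffness_voigt(card)
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        ref = np.diag([2 * mu, 2 * mu, 2 * mu, mu, mu, mu]).astype(float)
        ref[:3, :3] += lam
        assert np.allclose(C, ref, rtol=1e-10)


def test_stiffness_is_inverse_of_compliance(cards):
    C = stiffness_voigt(cards["symphysis"])
    S = compliance_voigt(cards["symphysis"])
    assert np.abs(C @ S - np.eye(6)).max() < 1e-8


def test_rotation_identity_and_isotropy(cards, iso_card):
    C = stiffness_voigt(cards["body"])
    assert np.abs(rotate_stiffness(C, np.eye(3)) - C).max() < 1e-10
    Ci = stiffness_voigt(iso_card)
    th = 0.73
    R = np.array(
        [[np.cos(th), np.sin(th), 0], [-np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
    )
    assert np.abs(rotate_stiffness(Ci, R) - Ci).max() < 1e-8 * Ci.max()


def _rotate_tensor_oracle(C, Q):
    """Independent 4th-order tensor rotation with explicit loops."""
    T = voigt_to_tensor(C)
    out = np.zeros_like(T)
    for a in range(3):
        for b in range(3):
            for c in range(3):
                for d in range(3):
                    acc = 0.0
                    for i in range(3):
                        for j in range(3):
                            for k in range(3):
                                for l in range(3):
                                    acc += (
                                        Q[i, a] * Q[j, b] * Q[k, c] * Q[l, d]
                                        * T[i, j, k, l]
                                    )
                    out[a, b, c, d] = acc
    return out


def test_quarter_turn_swaps_longitudinal_and_tangential(cards):
    C = stiffness_voigt(cards["angle"])
    Rz = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    Cr = rotate_stiffness(C, Rz)
    assert np.isclose(Cr[0, 0], C[1, 1])
    assert np.isclose(Cr[1, 1], C[0, 0])
    oracle = _rotate_tensor_oracle(C, Rz)
    assert np.abs(voigt_to_tensor(Cr) - oracle).max() < 1e-8 * C.max()


def test_rotation_preserves_strain_energy(cards):
    """Energy density is frame invariant for any strain state."""
    C = stiffness_voigt(cards["ramus"])
    rng = np.random.default_rng(7)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    Cg = rotate_stiffness(C, Q)
    for _ in range(5):
        eps_t = rng.normal(size=(3, 3))
        eps_t = 0.5 * (eps_t + eps_t.T)
        # material-frame components of the same strain: e' = Q eps Q^T
        ep = Q @ eps_t @ Q.T

        def volt(e):
            return np.array(
                [e[0, 0], e[1, 1], e[2, 2], 2 * e[0, 1], 2 * e[0, 2], 2 * e[1, 2]]
            )

        w_local = volt(ep) @ C @ volt(ep)
        w_global = volt(eps_t) @ Cg @ volt(eps_t)
        assert np.isclose(w_local, w_global, rtol=1e-9)


def test_non_orthonormal_frame_rejected(cards):
    C = stiffness_voigt(cards["body"])
    with pytest.raises(MaterialError):
        rotate_stiffness(C, np.eye(3) * 1.1)


def test_inadmissible_card_rejected():
    with pytest.raises(MaterialError):
        MaterialCard("bad", 100.0, 100.0, 100.0, 0.6, 0.6, 0.6)
    with pytest.raises(MaterialError):
        # strongly coupled Poisson ratios -> indefinite compliance
        stiffness_voigt(MaterialCard("bad", 100.0, 10000.0, 100.0,
                                     0.45, 0.45, 0.45))


def test_assignment_labels_and_frames(coarse_mandible):
    card_of, C = assign_materials(coarse_mandible, "PLA")
    region = coarse_mandible.region
    teeth = np.nonzero(region == "teeth")[0]
    assert card_of[teeth[0]].E1 == 17600.0
    trab = np.nonzero(region == "trabecular")[0]
    assert card_of[trab[0]].E1 == 300.0
    # symphysis apex: axial direction tangent to the arch (here ~ +-x)
    frames = local_frames(coarse_mandible)
    s = coarse_mandible.elem_param[:, 0]
    apex = np.nonzero((region == "symphysis") & (np.abs(s - 0.5) < 0.03))[0]
    from mandifix.geometry import arch_tangent

    p = coarse_mandible.meta["params"]
    for e in apex[:5]:
        cosang = abs(frames[e, 0] @ arch_tangent(p, s[e]))
        assert cosang > np.cos(np.deg2rad(5.0))


def test_device_material_assignment(coarse_mandible, cards):
    from mandifix import FractureSpec, insert_fracture
    from mandifix.fixation import place_devices

    f = insert_fracture(coarse_mandible, FractureSpec("body"))
    _, merged = place_devices(f, "body", 1.0)
    card_of, C = assign_materials(merged, "PLA")
    dev = np.nonzero(np.isin(merged.region, ("plate", "screw")))[0]
    assert all(card_of[e].E1 == 3500.0 for e in dev[:20])
    gran = np.nonzero(merged.region == "granulation")[0]
    assert card_of[gran[0]].E1 == 3.0
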