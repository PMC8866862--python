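"""Elastic material cards and orthotropic stiffness construction.

The packaged table holds the bone-tissue, granulation and device materials:
six orthotropic cortical regions (direction 1 longitudinal/axial along the
mandibular axis, 2 tangential, 3 transverse), isotropic trabecular bone,
teeth, granulation tissue, and the three device materials (Ti-6Al-4V, WE43
magnesium, PLA) with their yield strengths (880 / 162 / 70 MPa).

Voigt convention used throughout the package: component order
(11, 22, 33, 12, 13, 23) with engineering shear strains.  With this
convention the stiffness matrix in Voigt form equals the corresponding
components of the fourth-order elasticity tensor, which makes the Bond
rotation a plain tensor rotation.

Minor Poisson ratios are derived from compliance symmetry (nu_ji = nu_ij *
Ej / Ei); every card is checked for thermodynamic admissibility (symmetric
positive-definite compliance) when its stiffness is built.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import geometry
from .geometry import MandibleParams, arch_radial, arch_tangent

DEVICE_MATERIALS = ("Ti-6Al-4V", "WE43", "PLA")

# Voigt pair order (11, 22, 33, 12, 13, 23)
VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


class MaterialError(ValueError):
    """Inadmissible or unknown material definition."""


@dataclass(frozen=True)
class MaterialCard:
    """Elastic constants of one tissue/device material (MPa, dimensionless)."""

    name: str
    E1: float
    E2: float
    E3: float
    nu12: float
    nu23: float
    nu13: float
    G12: float | None = None
    G23: float | None = None
    G13: float | None = None
    yield_strength: float | None = None
    isotropic: bool = False

    def __post_init__(self):
        if min(self.E1, self.E2, self.E3) <= 0:
            raise MaterialError(f"{self.name}: moduli must be positive")
        for nu in (self.nu12, self.nu23, self.nu13):
            if not (0.0 < nu < 0.5):
                raise MaterialError(f"{self.name}: Poisson ratio {nu} not in (0, 0.5)")
        if self.isotropic and not (
            self.E1 == self.E2 == self.E3
            and self.nu12 == self.nu23 == self.nu13
        ):
            raise MaterialError(f"{self.name}: isotropic card with unequal constants")

    def shear_moduli(self):
        """(G12, G13, G23); printed values win, otherwise E/(2(1+nu))."""

        def g(val, E, nu):
            return val if val is not None else E / (2.0 * (1.0 + nu))

        return (
            g(self.G12, self.E1, self.nu12),
            g(self.G13, self.E1, self.nu13),
            g(self.G23, self.E2, self.nu23),
        )


def load_material_table() -> dict[str, MaterialCard]:
    """Load the packaged material table (12 cards, values as printed)."""
    cards: dict[str, MaterialCard] = {}
    expected = {
        "name", "E1", "E2", "E3", "nu12", "nu23", "nu13",
        "G12", "G23", "G13", "yield_strength", "isotropic",
    }
    path = resources.files("mandifix.data").joinpath("materials_table1.csv")
    with path.open() as fh:
        reader = csv.DictReader(fh)
        if set(reader.fieldnames) != expected:
            raise MaterialError("material table schema mismatch")
        for row in reader:
            num = {
                k: (float(row[k]) if row[k] != "" else None)
                for k in expected - {"name", "isotropic"}
            }
            cards[row["name"]] = MaterialCard(
                name=row["name"],
                isotropic=row["isotropic"] == "1",
                **num,
            )
    if len(cards) != 12:
        raise MaterialError(f"expected 12 material cards, found {len(cards)}")
    for name in ("symphysis", "body", "angle", "ramus", "condyle", "coronoid_process"):
        c = cards[name]
        if not (c.E1 >= c.E2 >= c.E3):
            raise MaterialError(f"{name}: cortical moduli not ordered E1>=E2>=E3")
    return cards


def compliance_voigt(card: MaterialCard) -> np.ndarray:
    """Orthotropic compliance matrix in Voigt order (engineering shear)."""
    S = np.zeros((6, 6))
    E1, E2, E3 = card.E1, card.E2, card.E3
    S[0, 0], S[1, 1], S[2, 2] = 1 / E1, 1 / E2, 1 / E3
    S[0, 1] = S[1, 0] = -card.nu12 / E1
    S[0, 2] = S[2, 0] = -card.nu13 / E1
    S[1, 2] = S[2, 1] = -card.nu23 / E2
    G12, G13, G23 = card.shear_moduli()
    S[3, 3], S[4, 4], S[5, 5] = 1 / G12, 1 / G13, 1 / G23
    return S


def stiffness_voigt(card: MaterialCard) -> np.ndarray:
    """Stiffness = inverse compliance; symmetric positive definite (MPa)."""
    S = compliance_voigt(card)
    w = np.linalg.eigvalsh(S)
    if w.min() <= 0:
        raise MaterialError(f"{card.name}: compliance not positive definite")
    C = np.linalg.inv(S)
    return 0.5 * (C + C.T)


def voigt_to_tensor(C: np.ndarray) -> np.ndarray:
    """Unpack a Voigt stiffness into the full 3x3x3x3 elasticity tensor."""
    T = np.zeros((3, 3, 3, 3))
    for p, (i, j) in enumerate(VOIGT_PAIRS):
        for q, (k, l) in enumerate(VOIGT_PAIRS):
            T[i, j, k, l] = T[j, i, k, l] = T[i, j, l, k] = T[j, i, l, k] = C[p, q]
    return T


def tensor_to_voigt(T: np.ndarray) -> np.ndarray:
    C = np.empty(T.shape[:-4] + (6, 6))
    for p, (i, j) in enumerate(VOIGT_PAIRS):
        for q, (k, l) in enumerate(VOIGT_PAIRS):
            C[..., p, q] = T[..., i, j, k, l]
    return C


def check_frame(frame: np.ndarray, tol: float = 1e-10) -> None:
    frame = np.asarray(frame)
    if np.abs(frame @ frame.T - np.eye(3)).max() > tol:
        raise MaterialError("local frame is not orthonormal")
    if np.linalg.det(frame) < 0:
        raise MaterialError("local frame is not right-handed")


def rotate_stiffness(C: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """Rotate a Voigt stiffness from its local frame to global coordinates.

    `frame` rows are the material directions e1 (longitudinal), e2
    (tangential), e3 (transverse) expressed in global coordinates.
    """
    check_frame(frame)
    return rotate_stiffness_batch(C[None], frame[None])[0]


def rotate_stiffness_batch(C: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Vectorized Bond rotation: one shared or per-element (6,6) stiffness,
    (n, 3, 3) frames with rows e1/e2/e3 in global coordinates."""
    C = np.asarray(C)
    Q = frames  # Q[n, i, a]: global component a of material axis i
    if C.ndim == 2:
        T = voigt_to_tensor(C)
        T = np.einsum("nia,ijkl->najkl", Q, T)
    else:
        T = np.stack([voigt_to_tensor(c) for c in C])
        T = np.einsum("nia,nijkl->najkl", Q, T)
    T = np.einsum("njb,najkl->nabkl", Q, T)
    T = np.einsum("nkc,nabkl->nabcl", Q, T)
    T = np.einsum("nld,nabcl->nabcd", Q, T)
    return tensor_to_voigt(T)


def local_frames(mesh, params: MandibleParams | None = None) -> np.ndarray:
    """Per-element orthonormal frames (e1 axial, e2 tangential, e3 transverse).

    e1 follows the mandibular axis: the arch tangent in the body, vertical in
    the ramus and processes; e3 is the outward transverse direction.
    """
    params = params or mesh.meta["params"]
    n = mesh.n_elems
    s = mesh.elem_param[:, 0]
    v = mesh.elem_param[:, 2]
    e1 = arch_tangent(params, s)
    e3 = arch_radial(params, s)
    vertical = (geometry._mirror_fold(s) >= geometry.RAMUS_BAND[0]) & (
        v > params.body_height
    )
    e1[vertical] = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e3, e1)
    frames = np.stack([e1, e2, e3], axis=1)
    # guard against numerical drift
    err = np.abs(frames @ frames.transpose(0, 2, 1) - np.eye(3)).max()
    if err > 1e-10:
        raise MaterialError(f"element frames not orthonormal ({err:.2g})")
    return frames


def assign_materials(
    mesh,
    device_material: str = "Ti-6Al-4V",
    cards: dict[str, MaterialCard] | None = None,
    override: dict[str, MaterialCard] | None = None,
):
    """Per-element material cards and global-frame Voigt stiffnesses.

    Cortical elements receive their regional orthotropic card rotated into the
    element's local frame; trabecular/teeth/granulation are isotropic; plate
    and screw elements receive the chosen device card.

    Returns
    -------
    card_of_elem : (n,) object array of MaterialCard
    C_global : (n, 6, 6) stiffness in global coordinates, MPa
    """
    cards = dict(cards or load_material_table())
    if override:
        cards.update(override)
    if device_material not in cards:
        raise MaterialError(f"unknown device material {device_material!r}")

    labels = np.asarray(mesh.region, dtype=object)
    card_of_elem = np.empty(mesh.n_elems, dtype=object)
    C_global = np.empty((mesh.n_elems, 6, 6))
    frames = None

    for lab in np.unique(labels.astype(str)):
        idx = np.nonzero(labels == lab)[0]
        key = device_material if lab in ("plate", "screw") else lab
        if key not in cards:
            raise MaterialError(f"no material card for mesh label {lab!r}")
        card = cards[key]
        card_of_elem[idx] = card
        C_local = stiffness_voigt(card)
        if lab in ("plate", "screw") or card.isotropic:
            C_global[idx] = C_local
        else:
            if frames is None:
                frames = local_frames(mesh)
            C_global[idx] = rotate_stiffness_batch(C_local, frames[idx])
    return card_of_elem, C_global
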