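"""Post-operative unilateral-clenching loads and boundary conditions.

Seven mastication muscle groups act per side: superficial/deep masseter (SM,
DM), anterior/medial/posterior temporalis (AT, MT, PT), medial pterygoid
(MPt) and inferior lateral pterygoid (LPt).  Right unilateral clenching is
simulated: the right side is the working side, the left the balancing side.
Each patch resultant is

    F = (scale * max_force) * activation(side) * cosines(side)

with scale defaulting to 0.2 (post-operative reduction of the maximum muscle
forces).  Only the X direction cosine flips sign between right and left, as
tabulated.  Boundary conditions: both condylar head surfaces are fully
restrained (locked in the glenoid fossa; solid elements carry translational
DOFs only, so fixing the patch suppresses condylar rotation as well), and the
occlusal patch over the right first-molar/second-premolar group is restrained
vertically (Z), providing the bite-force reaction.

Patch resultants are turned into consistent nodal loads of a uniform traction
on the quadratic (6-node) boundary triangles: for a straight-edged quadratic
triangle each midside node carries one third of the face force and the corner
nodes carry none.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

MUSCLES = ("SM", "DM", "AT", "MT", "PT", "MPt", "LPt")


class LoadError(ValueError):
    pass


@dataclass(frozen=True)
class MuscleEntry:
    """One muscle group: forces in N, unit direction cosines per side."""

    name: str
    max_force: float
    postop_force: float
    cos_right: tuple
    cos_left: tuple
    activation_working: float
    activation_balancing: float

    def __post_init__(self):
        if abs(self.postop_force - 0.2 * self.max_force) > 5e-3:
            raise LoadError(
                f"{self.name}: post-operative force is not 20% of maximum"
            )
        for c in (self.cos_right, self.cos_left):
            if abs(np.linalg.norm(c) - 1.0) > 1e-3:
                raise LoadError(f"{self.name}: direction cosines not unit length")
        for a in (self.activation_working, self.activation_balancing):
            if not (0.0 <= a <= 1.0):
                raise LoadError(f"{self.name}: activation outside [0, 1]")

    def cosines(self, side: str) -> np.ndarray:
        return np.array(self.cos_right if side == "right" else self.cos_left)

    def activation(self, role: str) -> float:
        if role == "working":
            return self.activation_working
        if role == "balancing":
            return self.activation_balancing
        raise LoadError(f"unknown side role {role!r}")


def load_muscle_table() -> dict[str, MuscleEntry]:
    """Packaged muscle table: max/post-op forces, cosines, activations."""
    path = resources.files("mandifix.data").joinpath("muscles_table2.csv")
    entries = {}
    with path.open() as fh:
        for row in csv.DictReader(fh):
            cy, cz = float(row["cos_y"]), float(row["cos_z"])
            entries[row["name"]] = MuscleEntry(
                name=row["name"],
                max_force=float(row["max_force"]),
                postop_force=float(row["postop_force"]),
                cos_right=(float(row["cos_x_right"]), cy, cz),
                cos_left=(float(row["cos_x_left"]), cy, cz),
                activation_working=float(row["activation_working"]),
                activation_balancing=float(row["activation_balancing"]),
            )
    if set(entries) != set(MUSCLES):
        raise LoadError("muscle table does not contain the seven expected groups")
    return entries


def muscle_force_vector(
    entry: MuscleEntry, side_role: str, side: str | None = None, scale: float = 1.0
) -> np.ndarray:
    """Resultant force (N) of one muscle on one side.

    side_role is 'working' or 'balancing'; the anatomical side defaults to
    right for the working side (right unilateral clenching).
    """
    if side is None:
        side = "right" if side_role == "working" else "left"
    return (
        scale
        * entry.postop_force
        * entry.activation(side_role)
        * entry.cosines(side)
    )


def distribute_on_patch(mesh, faces: np.ndarray, resultant) -> np.ndarray:
    """Consistent nodal forces of a uniform traction with a given resultant.

    Returns an (n_nodes, 3) array; the nodal forces sum exactly to the
    resultant.  Corner nodes of quadratic triangles carry zero consistent
    load under uniform traction; each midside node carries A_face/3 weight.
    """
    if faces is None or len(faces) == 0:
        raise LoadError("empty load patch")
    resultant = np.asarray(resultant, dtype=float)
    areas, _ = mesh.face_areas_normals(faces)
    total = areas.sum()
    traction = resultant / total
    f = np.zeros((mesh.n_nodes, 3))
    w = np.repeat(areas / 3.0, 3)
    mids = faces[:, 3:].ravel()
    np.add.at(f, mids, w[:, None] * traction[None, :])
    return f


@dataclass
class BCSet:
    """Restrained DOFs: fixed node ids (all translations) and vertical-only."""

    fixed_nodes: np.ndarray
    vertical_nodes: np.ndarray

    def dof_mask(self, n_nodes: int) -> np.ndarray:
        mask = np.zeros((n_nodes, 3), dtype=bool)
        mask[self.fixed_nodes] = True
        mask[self.vertical_nodes, 2] = True
        return mask.ravel()


@dataclass
class LoadCase:
    """Nodal external forces (N) plus per-patch resultants for bookkeeping."""

    nodal_forces: np.ndarray
    patch_resultants: dict


def boundary_conditions(mesh) -> BCSet:
    fixed = np.union1d(
        mesh.node_sets["condyle_left"], mesh.node_sets["condyle_right"]
    )
    vertical = np.setdiff1d(mesh.node_sets["occlusal_right"], fixed)
    if fixed.size == 0 or vertical.size == 0:
        raise LoadError("empty boundary-condition node set")
    return BCSet(fixed_nodes=fixed, vertical_nodes=vertical)


def build_load_case(
    mesh, table: dict[str, MuscleEntry] | None = None, scale: float = 0.2
):
    """Full 14-patch unilateral-clenching load case plus boundary conditions.

    scale rescales the maximum muscle forces (0.2 = post-operative default);
    the patch resultant is scale * max_force * activation * cosines.
    """
    table = table or load_muscle_table()
    f = np.zeros((mesh.n_nodes, 3))
    resultants = {}
    for name, entry in table.items():
        for side, role in (("right", "working"), ("left", "balancing")):
            patch = f"muscle_{name}_{side}"
            if patch not in mesh.face_sets:
                raise LoadError(f"missing muscle patch {patch!r}")
            # scale acts on the maximum force; entry.postop_force = 0.2 * max
            R = (
                scale
                * entry.max_force
                * entry.activation(role)
                * entry.cosines(side)
            )
            resultants[patch] = R
            f += distribute_on_patch(mesh, mesh.face_sets[patch], R)
    return LoadCase(nodal_forces=f, patch_resultants=resultants), boundary_conditions(mesh)


def convergence_load_case(mesh, radius: float = 2.5):
    """Simplified verification load: (0, -50, +50) N spread over a masseter
    patch of the given radius around the right masseter centroid."""
    faces = mesh.face_sets["muscle_SM_right"]
    centers = mesh.face_centroids(faces)
    mid = centers.mean(axis=0)
    bf = mesh.boundary_faces()
    allc = mesh.face_centroids(bf)
    sel = np.linalg.norm(allc - mid, axis=1) <= radius
    patch = bf[sel]
    if len(patch) == 0:
        raise LoadError("empty convergence-mode masseter patch")
    R = np.array([0.0, -50.0, 50.0])
    f = distribute_on_patch(mesh, patch, R)
    return (
        LoadCase(nodal_forces=f, patch_resultants={"masseter_simplified": R}),
        boundary_conditions(mesh),
    )
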