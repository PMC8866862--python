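"""Parametric synthetic mandible: geometry, anatomical labels, and fracture gaps.

The mandible is modeled as a horseshoe-shaped swept solid: a rectangular
cross-section (body_width x body_height) is swept along a circular arch in the
transverse plane; at both posterior ends the section extends vertically into a
ramus topped by a condylar process (neck + head, posterior) and a coronoid
process (anterior), separated by a sigmoid notch.  The solid is meshed as a
structured lattice in the chart (s, u, v):

    s in [0, 1]   arc position, left posterior end -> symphysis (0.5) -> right
    u             transverse offset from the arch axis, mm (u > 0 is outward:
                  buccal/lateral on the body, anterior at the symphysis)
    v             height above the inferior border, mm

Coordinate frame (units mm): X mediolateral (+X = anatomical left, so the
right/working side lies at x < 0, matching the sign convention of the printed
muscle direction cosines), Y anteroposterior (+Y posterior), Z inferosuperior.
The mid-sagittal plane is x = 0.

Cortical bone is the shell of elements within `cortical_thickness` of the free
surface, subdivided into the six anatomical property regions (symphysis, body,
angle, ramus, condyle, coronoid process) by chart bands; the interior is
trabecular; a homogeneous teeth block occupies the crest over the tooth row.
A fracture is a thin slab of elements relabeled to granulation tissue: the
bone is deliberately not split topologically, so load transfer occurs through
the soft gap tissue and the fixation hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import LabeledMesh, MeshError, lattice_to_tet10

FRACTURE_SITES = ("symphysis", "body", "angle", "condylar_neck")

# chart bands (fractions of s, right half; the left half mirrors about 0.5)
RAMUS_BAND = (0.82, 1.0)
CORONOID_BAND = (0.82, 0.875)
NOTCH_BAND = (0.875, 0.92)
CONDYLE_BAND = (0.92, 1.0)
SYMPHYSIS_HALF = 0.07  # |s - 0.5| below this -> symphysis region
OCCLUSAL_BAND = (0.63, 0.70)  # right first-molar / second-premolar arc band

TOOTH_DEPTH = 1.5  # mm, crest band occupied by the teeth block
HEAD_HEIGHT = 2.5  # mm, condylar head above the neck
CORONOID_EXT = 2.5  # mm, coronoid process above the sigmoid-notch floor

# fracture plane anchors (arc fraction for arch sites; v offset for the neck)
FRACTURE_ARC_S = {"symphysis": 0.51, "body": 0.60, "angle": 0.80}
NECK_FRACTURE_V_FRAC = 0.4  # fraction of neck length above the ramus top


class ParameterError(ValueError):
    """Invalid or unresolvable geometric parameters."""


@dataclass(frozen=True)
class MandibleParams:
    """Desk-scale parametric mandible (all lengths in mm, angle in degrees)."""

    arch_radius: float = 9.0
    arch_span_angle: float = 220.0
    body_height: float = 7.0
    body_width: float = 5.5
    cortical_thickness: float = 0.95
    ramus_height: float = 6.0
    condyle_neck_length: float = 3.0
    tooth_row_extent: float = 0.45  # arc fraction, centered on the symphysis
    target_edge_length: float = 1.0
    seed: int = 0

    def __post_init__(self):
        dims = (
            self.arch_radius,
            self.arch_span_angle,
            self.body_height,
            self.body_width,
            self.cortical_thickness,
            self.ramus_height,
            self.condyle_neck_length,
            self.tooth_row_extent,
            self.target_edge_length,
        )
        if any(d <= 0 for d in dims):
            raise ParameterError("all dimensions must be positive")
        if self.cortical_thickness >= self.body_width / 2:
            raise ParameterError("cortical_thickness must be < body_width/2")
        if self.cortical_thickness >= self.body_height / 2:
            raise ParameterError("cortical_thickness must be < body_height/2")
        if self.tooth_row_extent >= 0.5:
            raise ParameterError("tooth_row_extent must be < 0.5")

    @property
    def span_rad(self) -> float:
        return np.deg2rad(self.arch_span_angle)

    @property
    def arc_length(self) -> float:
        return self.arch_radius * self.span_rad

    @property
    def total_height(self) -> float:
        return (
            self.body_height
            + self.ramus_height
            + self.condyle_neck_length
            + HEAD_HEIGHT
        )


@dataclass(frozen=True)
class FractureSpec:
    """Simple fracture: site and gap width of the granulation-filled slab."""

    site: str
    gap_width: float = 1.2

    def __post_init__(self):
        if self.site not in FRACTURE_SITES:
            raise ParameterError(f"unknown fracture site {self.site!r}")
        if not (1.0 <= self.gap_width <= 2.0):
            raise ParameterError("gap_width must lie in [1.0, 2.0] mm")


# ---- chart mapping ---------------------------------------------------------


def arch_theta(params: MandibleParams, s):
    return (np.asarray(s, dtype=float) - 0.5) * params.span_rad


def arch_point(params: MandibleParams, s, u=0.0, v=0.0):
    """Map chart coordinates (s, u, v) to Cartesian (x, y, z)."""
    th = arch_theta(params, s)
    r = params.arch_radius + np.asarray(u, dtype=float)
    x = -r * np.sin(th)
    y = -r * np.cos(th)
    z = np.broadcast_to(np.asarray(v, dtype=float), x.shape).copy()
    return np.stack([x, y, z], axis=-1)


def arch_tangent(params: MandibleParams, s):
    """Unit tangent of the arch axis (direction of increasing s)."""
    th = arch_theta(params, s)
    t = np.stack(
        [-np.cos(th), np.sin(th), np.zeros_like(th)], axis=-1
    )
    return t


def arch_radial(params: MandibleParams, s):
    """Outward (lateral/buccal) horizontal unit normal of the arch."""
    th = arch_theta(params, s)
    return np.stack([-np.sin(th), -np.cos(th), np.zeros_like(th)], axis=-1)


def condylar_neck_segment(params: MandibleParams, side: str = "right"):
    """Axis segment of the condylar neck: (anchor xy point, v range)."""
    m_center = 0.5 * (CONDYLE_BAND[0] + CONDYLE_BAND[1])
    s = m_center if side == "right" else 1.0 - m_center
    p = arch_point(params, s)
    v0 = params.body_height + params.ramus_height
    return p[:2], (v0, v0 + params.condyle_neck_length)


def _mirror_fold(s):
    """Fold s onto the right half: m in [0.5, 1]."""
    s = np.asarray(s, dtype=float)
    return np.maximum(s, 1.0 - s)


def _segmented_axis(edges, lengths_mm, h):
    """1D grid aligned to band edges, cell size ~h inside each segment."""
    pts = [np.array([edges[0]])]
    for a, b, L in zip(edges[:-1], edges[1:], lengths_mm):
        n = max(1, int(round(L / h)))
        pts.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(pts)


def _grids(params: MandibleParams):
    h = params.target_edge_length
    p = params
    # s-grid aligned to every chart band edge (kept mirror-symmetric)
    tr = p.tooth_row_extent / 2
    s_edges = sorted(
        {
            0.0,
            1.0,
            CONDYLE_BAND[0],
            1 - CONDYLE_BAND[0],
            NOTCH_BAND[0],
            1 - NOTCH_BAND[0],
            RAMUS_BAND[0],
            1 - RAMUS_BAND[0],
            0.5 - SYMPHYSIS_HALF,
            0.5 + SYMPHYSIS_HALF,
            0.5 - tr,
            0.5 + tr,
            OCCLUSAL_BAND[0],
            OCCLUSAL_BAND[1],
            1 - OCCLUSAL_BAND[0],
            1 - OCCLUSAL_BAND[1],
        }
    )
    seg_len = np.diff(s_edges) * p.arc_length
    s_grid = _segmented_axis(s_edges, seg_len, h)

    nu = 2 * int(np.ceil(p.body_width / (2 * h)))
    u_grid = np.linspace(-p.body_width / 2, p.body_width / 2, nu + 1)

    bh, rh, nk = p.body_height, p.ramus_height, p.condyle_neck_length
    v_edges = sorted(
        {
            0.0,
            bh - TOOTH_DEPTH,
            bh,
            bh + rh,
            bh + rh + CORONOID_EXT,
            bh + rh + nk,
            bh + rh + nk + 0.6 * HEAD_HEIGHT,
            bh + rh + nk + HEAD_HEIGHT,
        }
    )
    v_grid = _segmented_axis(v_edges, np.diff(v_edges), h)
    return s_grid, u_grid, v_grid


def _keep_mask(params: MandibleParams, s_c, v_c):
    """Solid indicator on cell centroids of the (s, v) chart."""
    p = params
    bh, rh = p.body_height, p.ramus_height
    m = _mirror_fold(s_c)
    keep = v_c <= bh
    in_ramus = m >= RAMUS_BAND[0]
    keep |= in_ramus & (v_c <= bh + rh)
    in_cond = m >= CONDYLE_BAND[0]
    keep |= in_cond & (v_c <= bh + rh + p.condyle_neck_length + HEAD_HEIGHT)
    in_cor = (m >= CORONOID_BAND[0]) & (m < CORONOID_BAND[1])
    keep |= in_cor & (v_c <= bh + rh + CORONOID_EXT)
    return keep


def _cortical_region(params: MandibleParams, m, v_c):
    """Anatomical cortical-region label from folded chart coordinates."""
    p = params
    bh, rh = p.body_height, p.ramus_height
    lab = np.full(m.shape, "body", dtype=object)
    lab[m < 0.5 + SYMPHYSIS_HALF] = "symphysis"
    ram = m >= RAMUS_BAND[0]
    lab[ram & (v_c <= bh)] = "angle"
    lab[ram & (v_c > bh)] = "ramus"
    cor = (m >= CORONOID_BAND[0]) & (m < CORONOID_BAND[1]) & (v_c > bh + rh)
    lab[cor] = "coronoid_process"
    cond = (m >= CONDYLE_BAND[0]) & (v_c > bh + rh)
    lab[cond] = "condyle"
    return lab


# ---- main builders ---------------------------------------------------------


def build_mandible(params: MandibleParams | None = None) -> LabeledMesh:
    """Generate the labeled TET10 mandible mesh.

    Returns a conforming quadratic-tet mesh with per-element region labels
    (six cortical regions, trabecular core, teeth block), named node sets
    (condyle_left/right), the occlusal face patch, and seven muscle attachment
    face patches per side.  Deterministic for fixed parameters.
    """
    params = params or MandibleParams()
    p = params
    s_grid, u_grid, v_grid = _grids(p)
    ns, nu, nv = len(s_grid) - 1, len(u_grid) - 1, len(v_grid) - 1

    # cortical classification threshold: nominal thickness, widened to half a
    # cell at coarse resolution so the outermost layer is always cortical
    du = u_grid[1] - u_grid[0]
    dvmax = np.diff(v_grid).max()
    t_eff = max(p.cortical_thickness, 0.51 * max(du, dvmax))
    if nu < 4 or t_eff >= min(p.body_width, p.body_height) / 2:
        raise ParameterError(
            "cortical shell cannot be resolved at target_edge_length "
            f"{p.target_edge_length} mm (cell size {max(du, dvmax):.2f} mm)"
        )

    S, U, V = np.meshgrid(s_grid, u_grid, v_grid, indexing="ij")
    verts = arch_point(p, S, U, V)
    vparam = np.stack([S, U, V], axis=-1)

    s_c = 0.5 * (s_grid[:-1] + s_grid[1:])
    u_c = 0.5 * (u_grid[:-1] + u_grid[1:])
    v_c = 0.5 * (v_grid[:-1] + v_grid[1:])
    Sc, Uc, Vc = np.meshgrid(s_c, u_c, v_c, indexing="ij")
    keep = _keep_mask(p, Sc, Vc)
    cell_param = np.stack([Sc, Uc, Vc], axis=-1)

    mesh = lattice_to_tet10(
        (ns, nu, nv), keep, verts, cell_param=cell_param, vertex_param=vparam
    )
    mesh.check_midside_nodes(tol=1e-9)

    es, ev = mesh.elem_param[:, 0], mesh.elem_param[:, 2]
    m = _mirror_fold(es)

    # cortical shell vs trabecular core: distance from element centroid to the
    # free surface (sampled at boundary-face centroids)
    bf = mesh.boundary_faces()
    tree = cKDTree(mesh.face_centroids(bf))
    dist, _ = tree.query(mesh.centroids(), k=1)
    cortical = dist < t_eff

    region = np.full(mesh.n_elems, "trabecular", dtype=object)
    region[cortical] = _cortical_region(p, m, ev)[cortical]

    # homogeneous teeth block fused to the crest over the tooth row
    tooth = (np.abs(es - 0.5) < p.tooth_row_extent / 2) & (
        ev > p.body_height - TOOTH_DEPTH
    )
    region[tooth] = "teeth"
    mesh.region = region

    _build_named_sets(mesh, p)
    mesh.meta["params"] = p
    mesh.meta["min_scaled_jacobian"] = mesh.min_scaled_jacobian()
    return mesh


def _build_named_sets(mesh: LabeledMesh, p: MandibleParams) -> None:
    bf = mesh.boundary_faces()
    belem = mesh.boundary_face_elements()
    fc = mesh.face_centroids(bf)
    _, fn = mesh.face_areas_normals(bf)

    es = mesh.elem_param[belem, 0]
    fv = fc[:, 2]
    m = _mirror_fold(es)
    right = es > 0.5

    # radial (outward) direction at each boundary face
    rad = fc[:, :2] / np.linalg.norm(fc[:, :2], axis=1, keepdims=True)
    dot_rad = (fn[:, :2] * rad).sum(axis=1)
    lateral = dot_rad > 0.5
    medial = dot_rad < -0.5

    bh, rh, nk = p.body_height, p.ramus_height, p.condyle_neck_length

    def add_faces(name, mask):
        if not mask.any():
            raise MeshError(f"named face set {name!r} is empty")
        mesh.face_sets[name] = bf[mask]
        mesh.meta.setdefault("face_set_elems", {})[name] = np.unique(
            belem[mask]
        )

    # occlusal patch: upward faces of teeth elements over the right
    # first-molar / second-premolar band
    up = fn[:, 2] > 0.7
    teeth = mesh.region[belem] == "teeth"
    occ = up & teeth & (es >= OCCLUSAL_BAND[0]) & (es <= OCCLUSAL_BAND[1])
    add_faces("occlusal_right", occ)
    mesh.node_sets["occlusal_right"] = np.unique(bf[occ])

    # condylar head surfaces (used as the glenoid-fossa restraint)
    head = (mesh.region[belem] == "condyle") & (fv > bh + rh + nk)
    for side, smask in (("right", right), ("left", ~right)):
        sel = head & smask
        if not sel.any():
            raise MeshError(f"condyle_{side} node set is empty")
        mesh.node_sets[f"condyle_{side}"] = np.unique(bf[sel])
        mesh.meta.setdefault("face_set_elems", {})[f"condyle_{side}"] = (
            np.unique(belem[sel])
        )
        mesh.face_sets[f"condyle_{side}"] = bf[sel]

    # muscle attachment patches (bands in the folded chart; X-side via s)
    ramus0, cor0, cor1, notch1 = (
        RAMUS_BAND[0],
        CORONOID_BAND[0],
        CORONOID_BAND[1],
        NOTCH_BAND[1],
    )
    defs = {
        "SM": lateral & (m >= notch1) & (fv >= 1.0) & (fv <= bh + 0.5 * rh),
        "DM": lateral & (m >= notch1) & (fv > bh + 0.5 * rh) & (fv <= bh + rh),
        "MPt": medial & (m >= notch1) & (fv >= 0.5) & (fv <= bh + 0.65 * rh),
        "MT": lateral & (m >= cor0) & (m < cor1) & (fv > bh + 0.6 * rh) & (fv <= bh + rh),
        "AT": (m >= cor0) & (m < cor1) & (fv > bh + rh),
        "PT": (m >= cor1) & (m < notch1 + 1e-12) & (fv > bh + 0.8 * rh),
        "LPt": (m >= CONDYLE_BAND[0])
        & (fv > bh + rh + nk)
        & (fv <= bh + rh + nk + 0.6 * HEAD_HEIGHT)
        & (dot_rad < 0.3),
    }
    for name, band in defs.items():
        for side, smask in (("right", right), ("left", ~right)):
            add_faces(f"muscle_{name}_{side}", band & smask)


def insert_fracture(mesh: LabeledMesh, spec: FractureSpec) -> LabeledMesh:
    """Relabel the gap slab at the fracture site to granulation tissue.

    The slab is the set of elements whose centroid lies within gap_width/2 of
    the site's cut plane (restricted to the local bone segment).  The mesh
    topology is unchanged: the healing region transfers load as a soft tissue
    volume, and the fixation device carries the remainder.  Idempotent.
    """
    p: MandibleParams = mesh.meta["params"]
    c = mesh.centroids()
    es, ev = mesh.elem_param[:, 0], mesh.elem_param[:, 2]
    half = spec.gap_width / 2

    if spec.site == "condylar_neck":
        v0 = (
            p.body_height
            + p.ramus_height
            + NECK_FRACTURE_V_FRAC * p.condyle_neck_length
        )
        d = c[:, 2] - v0
        m = _mirror_fold(es)
        restrict = (es > 0.5) & (m >= CONDYLE_BAND[0])
    else:
        s0 = FRACTURE_ARC_S[spec.site]
        p0 = arch_point(p, s0)
        t = arch_tangent(p, s0)
        d = (c - p0) @ t
        restrict = np.abs(es - s0) < 0.12
        if spec.site == "angle":
            # stay below the sigmoid notch: the coronoid process remains on
            # the posterior fragment instead of being clipped by the slab
            restrict &= ev <= p.body_height + p.ramus_height

    bone = ~np.isin(mesh.region, ("plate", "screw"))
    slab = (np.abs(d) < half) & restrict & bone
    if not slab.any():
        raise ParameterError(
            f"fracture plane at site {spec.site!r} does not intersect the solid"
        )

    slab_ids = np.nonzero(slab)[0]
    fse = mesh.meta.get("face_set_elems", {})
    protected = ["occlusal_right"] + [
        k for k in fse if k.startswith("muscle_")
    ]
    for name in protected:
        if np.intersect1d(slab_ids, fse[name]).size:
            raise ParameterError(
                f"fracture slab at {spec.site!r} intersects set {name!r}"
            )

    out = replace_region(mesh, slab_ids, "granulation")
    out.element_sets["healing_region"] = slab_ids
    out.node_sets["healing_region"] = np.unique(out.tets[slab_ids])
    out.meta["fracture"] = spec
    return out


def replace_region(mesh: LabeledMesh, elem_ids, label) -> LabeledMesh:
    """Copy of the mesh with the given elements relabeled."""
    region = mesh.region.copy()
    region[elem_ids] = label
    out = replace_dataclass(mesh, region)
    return out


def replace_dataclass(mesh: LabeledMesh, region) -> LabeledMesh:
    out = LabeledMesh(
        nodes=mesh.nodes,
        tets=mesh.tets,
        region=region,
        node_sets=dict(mesh.node_sets),
        face_sets=dict(mesh.face_sets),
        element_sets=dict(mesh.element_sets),
        elem_param=mesh.elem_param,
        node_param=mesh.node_param,
        meta=dict(mesh.meta),
    )
    return out
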