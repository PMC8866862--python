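"""Miniplate/screw osteosynthesis devices: geometry, placement, tie slaves.

Device configurations follow load-sharing miniplate fixation practice:

    symphysis, body   two parallel 4-hole miniplates
    angle             one 6-hole miniplate
    condylar neck     one 2-hole and one 4-hole miniplate, both with a
                      center space (longer central bridge)

Two plate profiles are studied (1.0 mm clinical vs 1.5 mm reinforced); their
midsurfaces coincide so that the screw positions are identical between
thickness variants and thickness is the only difference.  Screws are
simplified thread-less monocortical shanks fused into the plate at the hole
axes (one conforming device mesh, so the plate-screw bond is exact); the
screw-bone interface is a tie: every screw node at or below the bone surface
becomes a slave interpolated inside its containing bone element.

Plates are wrapped onto the bone surface: the device lattice is generated
directly in a surface chart (a = along the plate axis, b = across the width,
d = outward surface offset), so the plate follows the arch curvature.  All
dimensions are desk-scale, proportional to the synthetic mandible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import (
    FRACTURE_ARC_S,
    NECK_FRACTURE_V_FRAC,
    MandibleParams,
    ParameterError,
    arch_point,
    _keep_mask,
)
from .mesh import LabeledMesh, lattice_to_tet10, merge_meshes

PLATE_MIDSURFACE = 0.75  # mm above bone surface; = max(thickness)/2


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class PlateSpec:
    """One miniplate with its screws (desk-scale 2.0-system analogue)."""

    n_holes: int
    thickness: float
    center_space: bool = False
    hole_pitch: float = 2.4
    plate_width: float = 1.6
    screw_length: float = 2.0
    screw_diameter: float = 0.8
    end_margin: float = 0.7
    center_gap: float = 1.2
    device_edge: float = 0.4

    def __post_init__(self):
        if self.thickness not in (1.0, 1.5):
            raise ParameterError("plate thickness must be 1.0 or 1.5 mm")
        if self.n_holes % 2 or self.n_holes < 2:
            raise ParameterError("n_holes must be even and >= 2")
        if self.screw_diameter >= self.hole_pitch:
            raise ParameterError("screw holes overlap (diameter >= pitch)")

    def hole_positions(self) -> np.ndarray:
        a = self.hole_pitch * (np.arange(self.n_holes) - (self.n_holes - 1) / 2)
        if self.center_space:
            a += np.sign(a) * self.center_gap / 2
        return a

    @property
    def length(self) -> float:
        return (
            (self.n_holes - 1) * self.hole_pitch
            + (self.center_gap if self.center_space else 0.0)
            + 2 * self.end_margin
        )


@dataclass
class ScenarioFixation:
    """Placed devices of one fracture scenario."""

    site: str
    plates: list
    placements: list
    screw_axes: np.ndarray  # (n_screws, 3) world entry points at the surface
    n_screws: int = field(init=False)

    def __post_init__(self):
        self.n_screws = int(self.screw_axes.shape[0])


def _segmented(edges, h):
    pts = [np.array([edges[0]])]
    for a, b in zip(edges[:-1], edges[1:]):
        n = max(1, int(round((b - a) / h)))
        pts.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(pts)


def build_device_mesh(spec: PlateSpec, chart=None) -> LabeledMesh:
    """TET10 mesh of one plate with fused screws.

    Without a chart the device is built flat: a = plate axis (x), b = width
    (y), d = thickness direction (z), bone surface at d = 0 and the plate
    midsurface at d = PLATE_MIDSURFACE.  With a chart, (a, b, d) vertices are
    mapped onto the bone surface.
    """
    r = spec.screw_diameter / 2
    holes = spec.hole_positions()
    L2, w2 = spec.length / 2, spec.plate_width / 2
    d0 = PLATE_MIDSURFACE - spec.thickness / 2  # plate underside
    d1 = PLATE_MIDSURFACE + spec.thickness / 2

    a_edges = sorted(
        {-L2, L2}
        | {float(x) for h in holes for x in (h - r, h + r)}
    )
    b_edges = sorted({-w2, -r, r, w2})
    d_screw = np.linspace(
        -spec.screw_length,
        d0,
        max(2, int(round((spec.screw_length + d0) / spec.device_edge))) + 1,
    )
    d_plate = np.linspace(
        d0, d1, max(2, int(round(spec.thickness / spec.device_edge))) + 1
    )
    a_grid = _segmented(a_edges, spec.device_edge)
    b_grid = _segmented(b_edges, spec.device_edge)
    d_grid = np.concatenate([d_screw, d_plate[1:]])

    A, Bc, D = np.meshgrid(a_grid, b_grid, d_grid, indexing="ij")
    na, nb, nd = len(a_grid) - 1, len(b_grid) - 1, len(d_grid) - 1
    a_c = 0.5 * (a_grid[:-1] + a_grid[1:])
    b_c = 0.5 * (b_grid[:-1] + b_grid[1:])
    d_c = 0.5 * (d_grid[:-1] + d_grid[1:])
    Ac, Bcc, Dc = np.meshgrid(a_c, b_c, d_c, indexing="ij")

    in_plate = Dc > d0
    in_screw = np.zeros_like(in_plate)
    for h in holes:
        in_screw |= (
            (np.abs(Ac - h) < r + 1e-9)
            & (np.abs(Bcc) < r + 1e-9)
            & (Dc <= d0 + 1e-9)
        )
    keep = in_plate | in_screw

    param = np.stack([A, Bc, D], axis=-1)
    if chart is None:
        verts = param
    else:
        verts = chart(A, Bc, D)
    cellp = np.stack([Ac, Bcc, Dc], axis=-1)
    mesh = lattice_to_tet10((na, nb, nd), keep, verts, cell_param=cellp, vertex_param=param)
    mesh.region[:] = "plate"
    mesh.region[mesh.elem_param[:, 2] <= d0 + 1e-9] = "screw"
    mesh.meta["spec"] = spec

    # screw nodes at or below the bone surface become tie slaves
    screw_elems = np.nonzero(mesh.region == "screw")[0]
    screw_nodes = np.unique(mesh.tets[screw_elems])
    slaves = screw_nodes[mesh.node_param[screw_nodes, 2] <= 1e-9]
    mesh.node_sets["tie_slaves"] = slaves
    return mesh


# ---- scenario configurations ----------------------------------------------


def scenario_plates(site: str, thickness: float):
    """Plate specs and chart placements for one fracture site."""
    if site in ("symphysis", "body"):
        spec = PlateSpec(n_holes=4, thickness=thickness)
        s0 = FRACTURE_ARC_S[site]
        return [
            (spec, {"kind": "arch", "s0": s0, "v0": 2.2}),
            (spec, {"kind": "arch", "s0": s0, "v0": 4.6}),
        ]
    if site == "angle":
        spec = PlateSpec(n_holes=6, thickness=thickness, hole_pitch=1.8)
        return [(spec, {"kind": "arch", "s0": FRACTURE_ARC_S[site], "v0": 3.0})]
    if site == "condylar_neck":
        two = PlateSpec(
            n_holes=2, thickness=thickness, hole_pitch=1.6, center_space=True
        )
        four = PlateSpec(
            n_holes=4, thickness=thickness, hole_pitch=1.6, center_space=True
        )
        return [
            (two, {"kind": "neck", "s0": 0.942}),
            (four, {"kind": "neck", "s0": 0.980}),
        ]
    raise ParameterError(f"unknown fixation site {site!r}")


def _make_chart(params: MandibleParams, placement: dict):
    surf_r = params.arch_radius + params.body_width / 2
    arc = surf_r * params.span_rad  # surface arc length per unit s
    if placement["kind"] == "arch":
        s0, v0 = placement["s0"], placement["v0"]

        def chart(A, B, D):
            return arch_point(
                params, s0 + np.asarray(A) / arc,
                params.body_width / 2 + np.asarray(D), v0 + np.asarray(B),
            )

        def to_param(A, B, D):  # (s, u, v)
            return (
                s0 + np.asarray(A) / arc,
                params.body_width / 2 + np.asarray(D),
                v0 + np.asarray(B),
            )

    else:  # vertical chart on the condylar neck
        s0 = placement["s0"]
        v0 = (
            params.body_height
            + params.ramus_height
            + NECK_FRACTURE_V_FRAC * params.condyle_neck_length
        )

        def chart(A, B, D):
            return arch_point(
                params, s0 + np.asarray(B) / arc,
                params.body_width / 2 + np.asarray(D), v0 + np.asarray(A),
            )

        def to_param(A, B, D):
            return (
                s0 + np.asarray(B) / arc,
                params.body_width / 2 + np.asarray(D),
                v0 + np.asarray(A),
            )

    return chart, to_param


def place_devices(mesh: LabeledMesh, site: str, thickness: float = 1.0):
    """Wrap the scenario's plates onto the fractured mandible.

    Returns (ScenarioFixation, merged LabeledMesh).  The merged mesh appends
    the device meshes (non-conforming with the bone); the node set
    'tie_slaves' collects all screw nodes at or below the bone surface.
    Raises PlacementError if any screw leaves the bone volume.
    """
    params: MandibleParams = mesh.meta["params"]
    plates = scenario_plates(site, thickness)
    devices = []
    axes = []
    for spec, placement in plates:
        if spec.screw_length <= params.cortical_thickness:
            raise PlacementError("screws must engage beyond the cortical shell")
        chart, to_param = _make_chart(params, placement)
        dev = build_device_mesh(spec, chart=chart)

        # screws must stay inside the bone volume
        screw_nodes = dev.node_sets["tie_slaves"]
        a, b, d = (dev.node_param[screw_nodes, i] for i in range(3))
        s, u, v = to_param(a, b, d)
        ok = (
            (np.abs(u) <= params.body_width / 2 + 1e-9)
            & _keep_mask(params, s, np.maximum(v, 1e-9))
            & (v >= -1e-9)
        )
        if not ok.all():
            raise PlacementError(
                f"{int((~ok).sum())} screw nodes exit the bone at site {site!r}"
            )
        for h in spec.hole_positions():
            axes.append(np.asarray(chart(h, 0.0, 0.0)))
        devices.append(dev)

    merged = merge_meshes([mesh] + devices)
    slave_sets = []
    off = mesh.n_nodes
    for dev in devices:
        slave_sets.append(dev.node_sets["tie_slaves"] + off)
        off += dev.n_nodes
    merged.node_sets["tie_slaves"] = np.concatenate(slave_sets)
    merged.meta["params"] = params
    fix = ScenarioFixation(
        site=site,
        plates=[spec for spec, _ in plates],
        placements=[pl for _, pl in plates],
        screw_axes=np.array(axes),
    )
    merged.meta["fixation"] = fix
    return fix, merged
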