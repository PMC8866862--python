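"""Quadratic tetrahedral (TET10) mesh container and structured meshing utilities.

Meshes are generated by subdividing a structured hexahedral lattice into six
tetrahedra per cell (Freudenthal/Kuhn decomposition, which is conforming across
cells), then inserting midside nodes on every unique edge.  All elements are
straight-edged, so the geometric mapping of each TET10 is affine and the
Jacobian is constant per element.

Node ordering follows the C3D10 / VTK_QUADRATIC_TETRA convention:
vertices 0-3, then midside nodes on edges (0,1), (1,2), (0,2), (0,3), (1,3), (2,3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# midside node k (k=4..9) sits on edge TET10_EDGES[k-4]
TET10_EDGES = np.array([(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)])

# corner triangles of a tet, outward-oriented for a positively oriented tet
TET_FACES = np.array([(0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2)])

# midside node (local id) on each edge of each corner face, matching TET_FACES
_FACE_MIDSIDES = np.array([(6, 5, 4), (4, 8, 7), (5, 9, 8), (7, 9, 6)])

# Freudenthal 6-tet split of a hex whose vertices are indexed by the binary
# corner code (ix, iy, iz) -> ix + 2*iy + 4*iz.  Each tet is a monotone path
# from corner 000 to corner 111; ordering fixed up per-element for positive
# volume after mapping.
_HEX_TO_TETS = np.array(
    [
        (0, 1, 3, 7),
        (0, 3, 2, 7),
        (0, 2, 6, 7),
        (0, 6, 4, 7),
        (0, 4, 5, 7),
        (0, 5, 1, 7),
    ]
)


class MeshError(ValueError):
    """Raised for degenerate or inconsistent meshes."""


@dataclass
class LabeledMesh:
    """TET10 mesh with per-element region labels and named node/face sets.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, mm
    tets : (n_elems, 10) int array
    region : (n_elems,) array of region labels (str)
    node_sets : dict name -> int array of node ids
    face_sets : dict name -> (k, 6) int array of boundary faces
        (3 corner nodes + 3 midside nodes each)
    elem_param : optional (n_elems, 3) parametric centroid coordinates of each
        element in the generator's chart (used for region logic downstream)
    node_param : optional (n_nodes, 3) parametric node coordinates
    meta : free-form provenance dictionary
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    node_sets: dict = field(default_factory=dict)
    face_sets: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)
    elem_param: np.ndarray | None = None
    node_param: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.tets.shape[0]

    # ---- geometry ----------------------------------------------------------

    def corner_coords(self) -> np.ndarray:
        """(n_elems, 4, 3) coordinates of the tet vertices."""
        return self.nodes[self.tets[:, :4]]

    def jacobians(self) -> np.ndarray:
        """Signed constant Jacobian determinant of each (affine) element."""
        x = self.corner_coords()
        e = x[:, 1:] - x[:, :1]
        return np.linalg.det(e)

    def volumes(self) -> np.ndarray:
        return self.jacobians() / 6.0

    def centroids(self) -> np.ndarray:
        return self.corner_coords().mean(axis=1)

    def min_scaled_jacobian(self) -> float:
        """Minimum normalized shape quality 6*sqrt(2)*V / l_rms^3 in (0, 1]."""
        x = self.corner_coords()
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        l2 = np.stack(
            [((x[:, a] - x[:, b]) ** 2).sum(axis=1) for a, b in pairs], axis=1
        )
        lrms = np.sqrt(l2.mean(axis=1))
        q = 6.0 * np.sqrt(2.0) * np.abs(self.volumes()) / lrms**3
        return float(q.min())

    def check_positive_jacobians(self) -> None:
        j = self.jacobians()
        if (j <= 0).any():
            raise MeshError(
                f"{int((j <= 0).sum())} elements with non-positive Jacobian"
            )

    # ---- topology ----------------------------------------------------------

    def boundary_faces(self) -> np.ndarray:
        """(k, 6) boundary faces (outward oriented): 3 corners + 3 midsides."""
        if "_bfaces" in self.meta:
            return self.meta["_bfaces"]
        corners = self.tets[:, TET_FACES]  # (m, 4, 3)
        mids = self.tets[:, _FACE_MIDSIDES]  # (m, 4, 3)
        faces6 = np.concatenate([corners, mids], axis=2).reshape(-1, 6)
        key = np.sort(faces6[:, :3], axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        bmask = counts[inv] == 1
        out = faces6[bmask]
        self.meta["_bfaces"] = out
        self.meta["_bface_elem"] = np.repeat(
            np.arange(self.n_elems), 4
        )[bmask]
        return out

    def boundary_face_elements(self) -> np.ndarray:
        self.boundary_faces()
        return self.meta["_bface_elem"]

    def face_areas_normals(self, faces: np.ndarray):
        """Areas and outward unit normals of straight triangular faces."""
        p = self.nodes[faces[:, :3]]
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        nrm = np.linalg.norm(cr, axis=1)
        if (nrm <= 0).any():
            raise MeshError("degenerate boundary face")
        return 0.5 * nrm, cr / nrm[:, None]

    def face_centroids(self, faces: np.ndarray) -> np.ndarray:
        return self.nodes[faces[:, :3]].mean(axis=1)

    def surface_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_faces())

    def check_conforming(self) -> None:
        """Every interior face must be shared by exactly two elements."""
        corners = self.tets[:, TET_FACES].reshape(-1, 3)
        key = np.sort(corners, axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        if (counts > 2).any():
            raise MeshError("non-conforming mesh: face shared by >2 elements")

    def check_midside_nodes(self, tol: float = 1e-9) -> None:
        a = self.nodes[self.tets[:, TET10_EDGES[:, 0]]]
        b = self.nodes[self.tets[:, TET10_EDGES[:, 1]]]
        mid = self.nodes[self.tets[:, 4:]]
        err = np.abs(mid - 0.5 * (a + b)).max()
        if err > tol:
            raise MeshError(f"midside nodes off edge midpoints by {err:.3g} mm")


# ---- structured lattice meshing -------------------------------------------


def lattice_to_tet10(
    grid_shape,
    keep_mask: np.ndarray,
    vertex_coords: np.ndarray,
    cell_param: np.ndarray | None = None,
    vertex_param: np.ndarray | None = None,
):
    """Build a TET10 mesh from a structured hex lattice with a keep mask.

    Parameters
    ----------
    grid_shape : (ni, nj, nk) number of cells along each lattice direction.
    keep_mask : (ni, nj, nk) bool, cells to retain.
    vertex_coords : (ni+1, nj+1, nk+1, 3) physical vertex coordinates.
    cell_param, vertex_param : optional parametric coordinates carried through.

    Returns
    -------
    LabeledMesh (region label 'unset'), with elem_param/node_param filled and
    meta['hex_of_elem'] mapping each tet to its source kept-cell index.
    """
    ni, nj, nk = grid_shape
    keep = np.asarray(keep_mask, dtype=bool)
    if keep.shape != (ni, nj, nk):
        raise ValueError("keep_mask shape mismatch")
    if not keep.any():
        raise MeshError("no cells retained")

    # global vertex ids of the 8 corners of every kept cell
    vid = np.arange((ni + 1) * (nj + 1) * (nk + 1)).reshape(
        ni + 1, nj + 1, nk + 1
    )
    ci, cj, ck = np.nonzero(keep)
    corner = np.empty((ci.size, 8), dtype=np.int64)
    for code in range(8):
        dx, dy, dz = code & 1, (code >> 1) & 1, (code >> 2) & 1
        corner[:, code] = vid[ci + dx, cj + dy, ck + dz]

    tets4 = corner[:, _HEX_TO_TETS].reshape(-1, 4)
    hex_of_elem = np.repeat(np.arange(ci.size), 6)

    # compact vertex numbering
    used, tets4 = np.unique(tets4, return_inverse=True)
    tets4 = tets4.reshape(-1, 4)
    verts = vertex_coords.reshape(-1, 3)[used]

    # enforce positive orientation element-wise (swap two nodes if needed)
    e = verts[tets4[:, 1:]] - verts[tets4[:, :1]]
    neg = np.linalg.det(e) < 0
    tets4[neg, 1], tets4[neg, 2] = tets4[neg, 2].copy(), tets4[neg, 1].copy()

    # midside nodes on unique edges
    edges = tets4[:, TET10_EDGES].reshape(-1, 2)
    edges = np.sort(edges, axis=1)
    uedges, inv = np.unique(edges, axis=0, return_inverse=True)
    mid_ids = verts.shape[0] + inv.reshape(-1, 6)
    mid_coords = 0.5 * (verts[uedges[:, 0]] + verts[uedges[:, 1]])

    nodes = np.vstack([verts, mid_coords])
    tets = np.hstack([tets4, mid_ids])

    node_param = None
    if vertex_param is not None:
        vp = vertex_param.reshape(-1, vertex_param.shape[-1])[used]
        node_param = np.vstack(
            [vp, 0.5 * (vp[uedges[:, 0]] + vp[uedges[:, 1]])]
        )
    elem_param = None
    if cell_param is not None:
        elem_param = cell_param[keep][hex_of_elem]

    mesh = LabeledMesh(
        nodes=nodes,
        tets=tets,
        region=np.full(tets.shape[0], "unset", dtype=object),
        elem_param=elem_param,
        node_param=node_param,
    )
    mesh.meta["hex_of_elem"] = hex_of_elem
    mesh.check_positive_jacobians()
    return mesh


def structured_block(lengths, divisions) -> LabeledMesh:
    """Axis-aligned rectangular block meshed with TET10; origin at (0,0,0)."""
    lx, ly, lz = lengths
    ni, nj, nk = divisions
    x = np.linspace(0, lx, ni + 1)
    y = np.linspace(0, ly, nj + 1)
    z = np.linspace(0, lz, nk + 1)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    vc = np.stack([X, Y, Z], axis=-1)
    keep = np.ones((ni, nj, nk), dtype=bool)
    mesh = lattice_to_tet10((ni, nj, nk), keep, vc, vertex_param=vc)
    mesh.region[:] = "block"
    return mesh


def merge_meshes(meshes) -> LabeledMesh:
    """Concatenate independent meshes (no node welding across components)."""
    offs = np.cumsum([0] + [m.n_nodes for m in meshes])
    nodes = np.vstack([m.nodes for m in meshes])
    tets = np.vstack([m.tets + offs[i] for i, m in enumerate(meshes)])
    region = np.concatenate([m.region for m in meshes])
    out = LabeledMesh(nodes=nodes, tets=tets, region=region)
    if all(m.node_param is not None for m in meshes):
        out.node_param = np.vstack([m.node_param for m in meshes])
    if all(m.elem_param is not None for m in meshes):
        out.elem_param = np.vstack([m.elem_param for m in meshes])
    for i, m in enumerate(meshes):
        for name, ns in m.node_sets.items():
            out.node_sets[name] = ns + offs[i]
        for name, fs in m.face_sets.items():
            out.face_sets[name] = fs + offs[i]
    eoffs = np.cumsum([0] + [m.n_elems for m in meshes])
    for i, m in enumerate(meshes):
        for name, es in m.element_sets.items():
            out.element_sets[name] = es + eoffs[i]
    out.meta["component_of_node"] = np.concatenate(
        [np.full(m.n_nodes, i) for i, m in enumerate(meshes)]
    )
    out.meta["component_of_elem"] = np.concatenate(
        [np.full(m.n_elems, i) for i, m in enumerate(meshes)]
    )
    return out
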