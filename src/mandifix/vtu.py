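"""Minimal ASCII VTU (VTK XML UnstructuredGrid) writer for TET10 meshes.

Writes quadratic tetrahedra (VTK cell type 24) with optional point-data and
cell-data arrays.  ASCII encoding keeps exported files text-only and
diff-friendly; readable by ParaView/VTK and meshio.
"""

from __future__ import annotations

import numpy as np

VTK_QUADRATIC_TETRA = 24


def _fmt(arr: np.ndarray) -> str:
    a = np.asarray(arr)
    if a.dtype.kind in "iu":
        return "\n".join(" ".join(str(int(v)) for v in row) for row in np.atleast_2d(a))
    return "\n".join(" ".join(f"{v:.9g}" for v in row) for row in np.atleast_2d(a))


def _data_array(name: str, arr: np.ndarray) -> str:
    a = np.asarray(arr)
    if a.ndim == 1:
        a = a[:, None]
    vtk_type = "Int64" if a.dtype.kind in "iu" else "Float64"
    ncomp = a.shape[1]
    return (
        f'<DataArray type="{vtk_type}" Name="{name}" '
        f'NumberOfComponents="{ncomp}" format="ascii">\n'
        + _fmt(a)
        + "\n</DataArray>\n"
    )


def write_vtu(path, mesh, point_data=None, cell_data=None) -> None:
    """Write a LabeledMesh (plus optional fields) to an ASCII .vtu file.

    Region labels are always exported as an integer cell array ``region_id``
    with the label dictionary stored in the FieldData array comment; named
    node sets become 0/1 point arrays ``set_<name>``.
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})

    labels = sorted(set(mesh.region.tolist()))
    label_to_id = {lab: i for i, lab in enumerate(labels)}
    cell_data.setdefault(
        "region_id",
        np.array([label_to_id[r] for r in mesh.region], dtype=np.int64),
    )
    for name, ns in mesh.node_sets.items():
        flag = np.zeros(mesh.n_nodes, dtype=np.int64)
        flag[ns] = 1
        point_data.setdefault(f"set_{name}", flag)

    n_pts, n_cells = mesh.n_nodes, mesh.n_elems
    conn = mesh.tets.astype(np.int64)
    offsets = np.arange(1, n_cells + 1) * 10
    types = np.full(n_cells, VTK_QUADRATIC_TETRA, dtype=np.int64)

    parts = [
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        f"<!-- region_id legend: {label_to_id} -->\n"
        "<UnstructuredGrid>\n"
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">\n',
        "<Points>\n" + _data_array("Points", mesh.nodes) + "</Points>\n",
        "<Cells>\n"
        + _data_array("connectivity", conn.reshape(-1, 1))
        + _data_array("offsets", offsets[:, None])
        + _data_array("types", types[:, None])
        + "</Cells>\n",
    ]
    if point_data:
        parts.append(
            "<PointData>\n"
            + "".join(_data_array(k, v) for k, v in point_data.items())
            + "</PointData>\n"
        )
    if cell_data:
        parts.append(
            "<CellData>\n"
            + "".join(_data_array(k, v) for k, v in cell_data.items())
            + "</CellData>\n"
        )
    parts.append("</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))
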