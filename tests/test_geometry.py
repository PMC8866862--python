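"""Synthetic mandible: labels, named sets, symmetry, fractures."""

import numpy as np
import pytest

from mandifix import (
    FractureSpec,
    MandibleParams,
    build_mandible,
    insert_fracture,
)
from mandifix.geometry import (
    RAMUS_BAND,
    TOOTH_DEPTH,
    ParameterError,
    condylar_neck_segment,
)

BONE_LABELS = {
    "symphysis", "body", "angle", "ramus", "condyle", "coronoid_process",
    "trabecular", "teeth",
}
MUSCLES = ("SM", "DM", "AT", "MT", "PT", "MPt", "LPt")


def test_coarse_mesh_has_exactly_the_bone_labels(coarse_mandible):
    assert set(coarse_mandible.region.tolist()) == BONE_LABELS


def test_all_named_sets_nonempty(coarse_mandible):
    for side in ("left", "right"):
        assert coarse_mandible.node_sets[f"condyle_{side}"].size > 0
        for m in MUSCLES:
            assert len(coarse_mandible.face_sets[f"muscle_{m}_{side}"]) > 0
    assert coarse_mandible.node_sets["occlusal_right"].size > 0


def test_mesh_quality_and_conformity(coarse_mandible):
    coarse_mandible.check_positive_jacobians()
    coarse_mandible.check_conforming()
    coarse_mandible.check_midside_nodes()
    assert coarse_mandible.meta["min_scaled_jacobian"] > 0.05


def test_generation_is_deterministic():
    p = MandibleParams(target_edge_length=2.0)
    a, b = build_mandible(p), build_mandible(p)
    assert np.array_equal(a.nodes, b.nodes)
    assert np.array_equal(a.tets, b.tets)
    assert (a.region == b.region).all()


def test_vertex_lattice_mirror_symmetric(mandible):
    """Vertex positions are symmetric about the mid-sagittal plane x=0."""
    verts = np.unique(mandible.tets[:, :4])
    pts = mandible.nodes[verts]
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(mirrored)
    assert d.max() < 1e-9


def test_cortical_volume_matches_swept_shell_oracle(mandible):
    """Closed-form shell volume of the swept arch section within 10%."""
    p = mandible.meta["params"]
    t = p.cortical_thickness
    W, H, d = p.body_width, p.body_height, TOOTH_DEPTH
    arch = 1.0 - 2 * (1.0 - RAMUS_BAND[0])  # arc fraction outside the rami
    tooth = p.tooth_row_extent
    L_plain = (arch - tooth) * p.arc_length
    L_tooth = tooth * p.arc_length
    shell_plain = W * H - (W - 2 * t) * (H - 2 * t)
    # under the teeth block the crest lid is replaced by teeth material
    shell_tooth = W * (H - d) - (W - 2 * t) * (H - d - t)
    expected = L_plain * shell_plain + L_tooth * shell_tooth

    es = mandible.elem_param[:, 0]
    in_arch = np.abs(es - 0.5) <= (arch / 2)
    cortical = np.isin(
        mandible.region,
        ("symphysis", "body", "angle", "ramus", "condyle", "coronoid_process"),
    )
    measured = mandible.volumes()[in_arch & cortical].sum()
    assert abs(measured - expected) / expected < 0.10


def test_refinement_consistency():
    """Halving the edge length multiplies elements and keeps label fractions."""
    coarse = build_mandible(MandibleParams(target_edge_length=1.0))
    fine = build_mandible(MandibleParams(target_edge_length=0.5))
    assert fine.n_elems >= 2 * coarse.n_elems

    def fractions(m):
        v = m.volumes()
        tot = v.sum()
        return {lab: v[m.region == lab].sum() / tot
                for lab in np.unique(m.region.astype(str))}

    fc, ff = fractions(coarse), fractions(fine)
    assert set(fc) == set(ff)
    for lab in fc:
        assert abs(fc[lab] - ff[lab]) < 0.05, lab


@pytest.mark.parametrize("site", ["symphysis", "body", "angle", "condylar_neck"])
def test_fracture_relabels_slab_to_granulation(mandible, site):
    f = insert_fracture(mandible, FractureSpec(site))
    hr = f.element_sets["healing_region"]
    assert hr.size > 0
    assert (f.region[hr] == "granulation").all()
    assert (f.region != "granulation").sum() + hr.size == f.n_elems
    # topology untouched: same nodes and connectivity
    assert f.nodes is mandible.nodes
    assert f.tets is mandible.tets


def test_fracture_gap_thickness_close_to_spec(mandible):
    spec = FractureSpec("body", gap_width=1.2)
    f = insert_fracture(mandible, spec)
    hr = f.element_sets["healing_region"]
    from mandifix.geometry import FRACTURE_ARC_S, arch_point, arch_tangent

    p = mandible.meta["params"]
    s0 = FRACTURE_ARC_S["body"]
    d = (f.centroids()[hr] - arch_point(p, s0)) @ arch_tangent(p, s0)
    extent = d.max() - d.min()
    edge = p.target_edge_length
    assert extent <= spec.gap_width + edge


def test_neck_fracture_centroid_on_condylar_axis(mandible):
    f = insert_fracture(mandible, FractureSpec("condylar_neck"))
    hr = f.element_sets["healing_region"]
    cen = f.centroids()[hr].mean(axis=0)
    p = mandible.meta["params"]
    xy, (v0, v1) = condylar_neck_segment(p, side="right")
    assert np.linalg.norm(cen[:2] - xy) < 2 * p.target_edge_length
    assert v0 - p.target_edge_length < cen[2] < v1 + p.target_edge_length


def test_fracture_is_idempotent(mandible):
    spec = FractureSpec("angle")
    once = insert_fracture(mandible, spec)
    twice = insert_fracture(once, spec)
    assert np.array_equal(
        once.element_sets["healing_region"], twice.element_sets["healing_region"]
    )
    assert (once.region == twice.region).all()


def test_invalid_parameters_rejected():
    with pytest.raises(ParameterError):
        FractureSpec("body", gap_width=0.0)
    with pytest.raises(ParameterError):
        FractureSpec("mandible")
    with pytest.raises(ParameterError):
        MandibleParams(cortical_thickness=3.0)
    with pytest.raises(ParameterError):
        build_mandible(MandibleParams(target_edge_length=6.0))
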