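import numpy as np
import pytest

from hapi3d.ontology import (EmptyRegionError, Ontology, OntologyNode,
                             ontology_quantify, quantifications_to_frame,
                             region_load)
from hapi3d.volumes import Volume

VOX = (25.0, 25.0, 125.0)


def _two_leaf_ontology():
    return Ontology(OntologyNode("brain", "Br", children=[
        OntologyNode("left", "L", labels=[1]),
        OntologyNode("right", "R", labels=[2]),
    ]))


def _volumes(label_arr, stain_arr, valid=None):
    lab = Volume(label_arr.astype(np.int32), VOX, modality="label",
                 valid_planes=valid)
    seg = Volume(stain_arr.astype(np.uint8), VOX, modality="mask",
                 valid_planes=valid)
    return seg, lab


def test_ontology_validation_duplicate_labels():
    with pytest.raises(ValueError):
        Ontology(OntologyNode("root", children=[
            OntologyNode("a", labels=[1, 2]),
            OntologyNode("b", labels=[2]),
        ]))


def test_ontology_find_and_round_trip(tmp_path):
    onto = _two_leaf_ontology()
    assert onto.find("left").labels == [1]
    assert onto.find("R").name == "right"
    with pytest.raises(KeyError):
        onto.find("cerebellum")
    back = Ontology.load(onto.save(tmp_path / "o.json"))
    assert back.all_labels == {1, 2}
    assert back.find("right").acronym == "R"


def test_region_load_exact_arithmetic():
    lab = np.zeros((10, 10, 2), dtype=np.int32)
    lab[:5] = 1
    lab[5:] = 2
    seg = np.zeros_like(lab)
    seg[:5, :2, 0] = 1  # 10 stained voxels in region 1 (100 voxels)
    s, l = _volumes(lab, seg)
    q = region_load(s, l, [1])
    assert q.region_voxels == 100
    assert q.stained_voxels == 10
    assert q.load == pytest.approx(10.0)
    assert q.region_volume_mm3 == pytest.approx(100 * 25 * 25 * 125 * 1e-9)
    with pytest.raises(EmptyRegionError):
        region_load(s, l, [7])


def test_parent_load_is_volume_weighted_equal_volumes():
    # equal child volumes, loads 10% and 20% -> parent 15%
    lab = np.zeros((10, 10, 1), dtype=np.int32)
    lab[:5] = 1
    lab[5:] = 2
    seg = np.zeros_like(lab)
    seg[0, :5, 0] = 1          # 5 of 50 = 10% in region 1
    seg[5, :, 0] = 1           # 10 of 50 = 20% in region 2
    s, l = _volumes(lab, seg)
    quants = ontology_quantify(s, l, _two_leaf_ontology())
    root = quants[0]
    assert root.name == "brain"
    assert root.load == pytest.approx(15.0)


def test_parent_load_is_volume_weighted_unequal_volumes():
    # volumes 1:3 with loads 40% and 0% -> parent (0.4*V + 0)/(4V) = 10%
    lab = np.zeros((8, 10, 1), dtype=np.int32)
    lab[:2] = 1        # 20 voxels
    lab[2:] = 2        # 60 voxels
    seg = np.zeros_like(lab)
    seg[0, :8, 0] = 1  # 8 of 20 = 40% in region 1
    s, l = _volumes(lab, seg)
    quants = ontology_quantify(s, l, _two_leaf_ontology())
    by_name = {q.name: q for q in quants}
    assert by_name["left"].load == pytest.approx(40.0)
    assert by_name["right"].load == pytest.approx(0.0)
    assert by_name["brain"].load == pytest.approx(10.0)


def test_parent_volumes_equal_child_sums_exactly(phantom_small):
    ds = phantom_small
    seg = ds.truth_masks["abeta"]
    quants = ontology_quantify(seg, ds.labels, ds.ontology)
    by_path = {q.path: q for q in quants}
    for q in quants:
        node = ds.ontology.find(q.name)
        if not node.is_leaf:
            kids = [c for c in quants if c.path.startswith(q.path + "/")
                    and c.depth == q.depth + 1]
            assert q.region_voxels == sum(c.region_voxels for c in kids)
            assert q.stained_voxels == sum(c.stained_voxels for c in kids)
    # root load equals the whole-brain load computed directly
    root = quants[0]
    direct = region_load(seg, ds.labels, sorted(ds.ontology.all_labels))
    assert root.load == pytest.approx(direct.load, abs=1e-12)
    assert root.region_voxels == direct.region_voxels


def test_invalid_planes_excluded():
    lab = np.ones((4, 4, 3), dtype=np.int32)
    seg = np.zeros_like(lab)
    seg[:, :, 1] = 1  # stained only on the plane flagged invalid
    s, l = _volumes(lab, seg, valid=[True, False, True])
    q = region_load(s, l, [1])
    assert q.region_voxels == 32  # 2 valid planes x 16
    assert q.stained_voxels == 0


def test_orphan_labels_warn():
    lab = np.zeros((4, 4, 1), dtype=np.int32)
    lab[:2] = 1
    lab[2:] = 9  # not covered by the ontology
    seg = np.zeros_like(lab)
    seg[0, 0, 0] = 1
    s, l = _volumes(lab, seg)
    with pytest.warns(UserWarning):
        ontology_quantify(s, l, _two_leaf_ontology())


def test_truncated_flag():
    lab = np.zeros((6, 6, 2), dtype=np.int32)
    lab[0, :, :] = 1          # touches the x=0 face
    lab[2:4, 2:4, :] = 2      # interior only... still touches z faces
    seg = np.zeros_like(lab)
    seg[0, 0, 0] = 1
    s, l = _volumes(lab, seg)
    quants = {q.name: q for q in ontology_quantify(s, l, _two_leaf_ontology())}
    assert quants["left"].truncated
    assert quants["right"].truncated  # spans the full z range (2 planes)


def test_quantifications_frame_columns(phantom_small):
    ds = phantom_small
    quants = ontology_quantify(ds.truth_masks["abeta"], ds.labels, ds.ontology)
    frame = quantifications_to_frame(quants)
    assert {"name", "path", "load_percent", "region_volume_mm3"} <= set(frame.columns)
    assert len(frame) == len(quants)


def test_quantification_validation():
    from hapi3d.ontology import RegionQuantification
    with pytest.raises(ValueError):
        RegionQuantification("x", "x", 0, 10, 2, 1.0, 2.0, load=20.0)  # stained > region
    with pytest.raises(ValueError):
        RegionQuantification("x", "x", 0, 10, 2, 2.0, 1.0, load=120.0)
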