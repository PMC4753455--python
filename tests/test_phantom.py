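import numpy as np
import pytest

from hapi3d.ontology import region_load
from hapi3d.phantom import (PhantomSpec, RegionSpec, distort_section,
                            make_phantom, make_warped_copy, training_patches,
                            write_phantom)
from hapi3d.resample import resample_image


SMALL = dict(dims=(80, 60, 20))


def test_phantom_deterministic():
    a = make_phantom(PhantomSpec(**SMALL, seed=4))
    b = make_phantom(PhantomSpec(**SMALL, seed=4))
    assert np.array_equal(a.blockface.data, b.blockface.data)
    assert np.array_equal(a.truth_masks["abeta"].data, b.truth_masks["abeta"].data)
    for ia, ib in zip(a.series["cd68"].images, b.series["cd68"].images):
        assert np.array_equal(ia, ib)
    assert a.manifest == b.manifest


def test_phantom_seed_changes_data(phantom_small):
    other = make_phantom(PhantomSpec(**SMALL, seed=1))
    assert not np.array_equal(other.blockface.data, phantom_small.blockface.data)


def test_phantom_anatomy(phantom_small):
    ds = phantom_small
    labels = ds.labels.data
    assert set(np.unique(labels)) == set(range(7))  # background + 6 regions
    assert 0.05 < (labels > 0).mean() < 0.9
    assert ds.atlas_labels.shape == ds.blockface.shape
    assert np.array_equal(ds.atlas_labels.data, labels)
    assert ds.ontology.all_labels == {1, 2, 3, 4, 5, 6}


def test_true_loads_consistent_with_truth_masks(phantom_small):
    ds = phantom_small
    for marker in ("abeta", "cd68"):
        q = region_load(ds.truth_masks[marker], ds.labels, [1])
        assert q.load == pytest.approx(
            ds.true_region_loads[marker]["cerebral cortex"])


def test_marker_density_ordering(phantom_small):
    # the second marker is generated at 60% of the first marker's density
    a = phantom_small.true_region_loads["abeta"]["cerebral cortex"]
    c = phantom_small.true_region_loads["cd68"]["cerebral cortex"]
    assert 0.0 < c < a


def test_distort_section_bookkeeping(phantom_small):
    ds = phantom_small
    spec = ds.spec
    z = 10
    truth = ds.truth_masks["abeta"].data[:, :, z]
    img = np.asarray(ds.series["abeta"].images[z], dtype=float)
    mask_d = ds.distorted_masks["abeta"].data[:, :, z]
    tf = ds.true_section_transforms["abeta"][z]
    # undistorting the distorted mask through the recorded affine recovers
    # the generating mask; two stacked nearest-neighbor resamples shave the
    # rim of blobs only a few px across, so the overlap is high but not exact
    undist = resample_image(mask_d.astype(float), tf, spec.voxel_size[0],
                            mode="nearest") > 0.5
    t = truth.astype(bool)
    dice = 2 * (undist & t).sum() / max(undist.sum() + t.sum(), 1)
    assert dice > 0.8
    # stained area itself is conserved within the same rim tolerance
    assert abs(int(undist.sum()) - int(t.sum())) <= 0.2 * t.sum()
    # the sampled affine respects the declared ranges
    rot = np.rad2deg(np.arctan2(tf.matrix[1, 0], tf.matrix[0, 0]))
    assert abs(rot) <= spec.rotation_range_deg + 1e-6
    assert np.abs(tf.translation / spec.voxel_size[0]).max() \
        <= spec.translation_range_px + 1e-6


def test_distort_section_deterministic(phantom_small):
    spec = phantom_small.spec
    img = np.asarray(phantom_small.series["abeta"].images[5], dtype=float)
    truth = phantom_small.truth_masks["abeta"].data[:, :, 5]
    out1 = distort_section(img, truth, spec, seed=42)
    out2 = distort_section(img, truth, spec, seed=42)
    assert np.array_equal(out1[0], out2[0])
    assert np.array_equal(out1[1], out2[1])


def test_make_warped_copy_properties(phantom_small):
    vol = phantom_small.blockface
    warped, ffd = make_warped_copy(vol, amplitude_vox=2.0, seed=1,
                                   background=float(vol.data.min()))
    assert warped.shape == vol.shape
    assert not np.array_equal(warped.data, vol.data)
    grid = ffd.control_grid
    for a in range(3):
        sl = [slice(None)] * 4
        sl[a] = 0
        assert np.allclose(grid[tuple(sl)], 0.0)
        sl[a] = -1
        assert np.allclose(grid[tuple(sl)], 0.0)


def test_training_patches_consistent(phantom_small):
    patches = training_patches(phantom_small, "abeta", n_patches=6, seed=2)
    assert len(patches.patches) == 6
    for img, lab in patches.patches:
        assert img.shape[:2] == lab.shape
        assert set(np.unique(lab)) <= {1, 2, 3}
        stained = img[lab == 1]
        unstained = img[lab == 2]
        if len(stained) and len(unstained):
            # DAB-brown deposits are darker than the eosin tissue
            assert stained.mean() < unstained.mean()


def test_spec_validation():
    with pytest.raises(ValueError):
        RegionSpec(1.5)
    with pytest.raises(ValueError):
        RegionSpec(0.1, "sinusoid")
    with pytest.raises(ValueError):
        PhantomSpec(rotation_range_deg=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(blob_radius_um=(0.0, 10.0))


def test_write_phantom_layout(tmp_path):
    ds = make_phantom(PhantomSpec(dims=(48, 36, 8), seed=0))
    out = write_phantom(ds, tmp_path / "ph")
    assert (out / "blockface.nii.gz").exists()
    assert (out / "atlas_intensity.nii.gz").exists()
    assert (out / "ontology.json").exists()
    assert (out / "manifest.json").exists()
    for marker in ds.series:
        assert (out / f"sections_{marker}" / "series.json").exists()
        assert (out / f"truth_{marker}.nii.gz").exists()
        assert (out / f"true_transforms_{marker}" / "section_0000.json").exists()
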