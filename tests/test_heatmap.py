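import numpy as np
import pytest

from hapi3d.heatmap import (CorrelationResult, HeatMap, ResolutionError,
                            aggregate, correlate, correlation_matrix, smooth)
from hapi3d.volumes import Volume

VOX = (25.0, 25.0, 125.0)


def _mask_volume(data, valid=None):
    return Volume(data.astype(np.uint8), VOX, modality="mask",
                  valid_planes=valid)


def _heatmap_from(data, mask=None):
    vol = Volume(np.asarray(data, dtype=float), (125.0,) * 3, modality="heatmap")
    m = np.ones(vol.shape, dtype=bool) if mask is None else mask
    return HeatMap(vol, m)


def test_aggregate_exact_occupancy():
    # 10x10x2 at 25 um in-plane, 125 um target -> 2x2x2 heat map, 5x5x1 pools
    seg = np.zeros((10, 10, 2))
    seg[:5, :5, 0] = 1           # first pool fully stained on plane 0
    seg[5:, 5:, 1] = 1           # last pool fully stained on plane 1
    hm = aggregate(_mask_volume(seg), 125.0)
    assert hm.volume.shape == (2, 2, 2)
    assert hm.data[0, 0, 0] == pytest.approx(1.0)
    assert hm.data[1, 1, 1] == pytest.approx(1.0)
    assert hm.data[0, 1, 0] == pytest.approx(0.0)
    assert hm.brain_mask.all()


def test_aggregate_resolution_errors():
    seg = _mask_volume(np.zeros((10, 10, 2)))
    with pytest.raises(ResolutionError):
        aggregate(seg, 110.0)     # not a multiple of 25
    with pytest.raises(ResolutionError):
        aggregate(seg, 100.0)     # finer than the 125 um plane spacing
    with pytest.raises(ValueError):
        aggregate(Volume(np.zeros((10, 10, 2)), VOX), 125.0)  # not a mask


def test_aggregate_invalid_planes_excluded():
    seg = np.ones((5, 5, 2))
    hm = aggregate(_mask_volume(seg, valid=[True, False]), 125.0)
    # the invalid plane contributes neither coverage nor occupancy
    assert hm.data[0, 0, 0] == pytest.approx(1.0)
    assert hm.coverage[0, 0, 1] == pytest.approx(0.0)
    assert not hm.brain_mask[0, 0, 1]


def test_global_load_matches_segmentation_exactly(phantom_small):
    ds = phantom_small
    seg = ds.truth_masks["abeta"]
    tissue = Volume((ds.labels.data > 0).astype(np.uint8), VOX, modality="mask")
    hm = aggregate(seg, 125.0, tissue_mask=tissue)
    stained = (seg.data.astype(bool) & (ds.labels.data > 0)).sum()
    covered = (ds.labels.data > 0).sum()
    direct = 100.0 * stained / covered
    assert hm.global_load_percent() == pytest.approx(direct, abs=1e-9)


def test_smooth_preserves_constant_map():
    data = np.full((6, 6, 4), 0.4)
    hm = _heatmap_from(data)
    sm = smooth(hm)
    assert np.abs(sm.data - 0.4).max() < 1e-12
    assert sm.smoothed
    with pytest.raises(ValueError):
        smooth(sm)  # already smoothed


def test_smooth_preserves_masked_mean(rng):
    data = rng.uniform(0, 1, (8, 8, 6))
    mask = np.zeros((8, 8, 6), dtype=bool)
    mask[1:7, 1:7, 1:5] = True
    data[~mask] = 0.0
    hm = _heatmap_from(data, mask)
    sm = smooth(hm)
    m0 = hm.data[mask].mean()
    m1 = sm.data[mask].mean()
    assert abs(m1 - m0) / m0 < 0.005
    assert not sm.data[~mask].any()


def test_smooth_fwhm_is_gentler_than_sigma(rng):
    data = np.zeros((9, 9, 5))
    data[4, 4, 2] = 1.0
    peak_sigma = smooth(_heatmap_from(data.copy()), kernel="sigma").data[4, 4, 2]
    peak_fwhm = smooth(_heatmap_from(data.copy()), kernel="fwhm").data[4, 4, 2]
    assert peak_fwhm > peak_sigma  # FWHM=1 voxel is a narrower Gaussian


def test_spearman_exact_small_case():
    # paired values (1,2),(2,1),(3,3): rank correlation 0.5
    a = _heatmap_from(np.array([0.1, 0.2, 0.3]).reshape(3, 1, 1))
    b = _heatmap_from(np.array([0.2, 0.1, 0.3]).reshape(3, 1, 1))
    r = correlate(a, b)
    assert r.rho == pytest.approx(0.5)
    assert r.n_voxels == 3
    assert 0.0 <= r.p_value <= 1.0


def test_correlate_errors():
    a = _heatmap_from(np.full((3, 1, 1), 0.5))
    b = _heatmap_from(np.array([0.2, 0.1, 0.3]).reshape(3, 1, 1))
    with pytest.raises(ValueError):
        correlate(a, b)  # constant input
    c = _heatmap_from(np.zeros((4, 1, 1)))
    with pytest.raises(ValueError):
        correlate(b, c)  # grid mismatch
    with pytest.raises(ValueError):
        CorrelationResult(rho=1.5, p_value=0.0, n_voxels=10)
    with pytest.raises(ValueError):
        CorrelationResult(rho=0.5, p_value=0.0, n_voxels=2)


def test_correlation_matrix_symmetric(rng):
    hms = {"a": _heatmap_from(rng.uniform(0, 1, (4, 4, 4))),
           "b": _heatmap_from(rng.uniform(0, 1, (4, 4, 4)))}
    rho, p = correlation_matrix(hms)
    assert rho.loc["a", "b"] == rho.loc["b", "a"]
    assert rho.loc["a", "a"] == 1.0


def test_heatmap_validation():
    with pytest.raises(ValueError):
        HeatMap(Volume(np.zeros((2, 2, 2)), (125.0,) * 3), np.ones((2, 2, 2), bool))
    vol = Volume(np.full((2, 2, 2), 1.5), (125.0,) * 3, modality="heatmap")
    with pytest.raises(ValueError):
        HeatMap(vol, np.ones((2, 2, 2), dtype=bool))  # occupancy > 1
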