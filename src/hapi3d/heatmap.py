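"""Occupancy heat maps: quantitative low-resolution summaries of stainings.

High-resolution binary segmentations are aggregated in the coronal (x, y)
plane into low-resolution voxels (default 125 um isotropic, matching the
reconstructed section spacing) whose value is the *staining occupation
ratio* — the fraction of covered high-resolution voxels that are stained.
Heat maps preserve local quantitative information at a small fraction of
the memory, live on a common grid per subject, and support voxel-wise
cross-marker correlation (Spearman's rank rho).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .volumes import Volume

__all__ = ["HeatMap", "CorrelationResult", "aggregate", "smooth", "correlate",
           "ResolutionError"]


class ResolutionError(ValueError):
    """Target heat-map size is not an integer multiple of the voxel size."""


@dataclass
class HeatMap:
    """A low-resolution occupancy Volume plus its brain mask.

    ``volume.data`` holds occupancy fractions in [0, 1] (clipped to
    [0, 1+eps] after smoothing); ``brain_mask`` marks heat-map voxels with
    at least half their footprint inside tissue/valid planes, the voxels
    eligible for correlation analyses.
    """

    volume: Volume
    brain_mask: np.ndarray
    smoothed: bool = False
    coverage: np.ndarray | None = None  # fraction of footprint inside tissue

    def __post_init__(self):
        if self.volume.modality != "heatmap":
            raise ValueError("HeatMap volume must have modality 'heatmap'")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.volume.shape:
            raise ValueError("brain mask grid mismatch")
        tol = 1e-9 if not self.smoothed else 1e-6
        data = self.volume.data
        if data.min() < -tol or (not self.smoothed and data.max() > 1.0 + tol):
            raise ValueError("occupancy values must lie in [0, 1]")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    def masked_values(self) -> np.ndarray:
        return self.volume.data[self.brain_mask]

    def global_load_percent(self) -> float:
        """Whole-brain load (percent) from the heat map, coverage-weighted.

        Before smoothing this equals the voxelwise whole-brain load of
        the source segmentation exactly (occupancy is stained/covered
        per voxel; the coverage weights restore the global ratio).
        """
        w = self.coverage if self.coverage is not None else self.brain_mask.astype(float)
        tot = float((self.data * w).sum())
        cov = float(w.sum())
        return 100.0 * tot / cov if cov > 0 else 0.0


def _ratio(target: float, step: float) -> int:
    r = target / step
    if abs(r - round(r)) > 1e-6 or round(r) < 1:
        lower = int(np.floor(r)) * step
        upper = int(np.ceil(r)) * step
        raise ResolutionError(
            f"target {target} um is not an integer multiple of {step} um; "
            f"nearest valid targets are {lower:g} or {upper:g} um")
    return int(round(r))


def aggregate(seg: Volume, target_size: float = 125.0,
              tissue_mask: Volume | None = None,
              coverage_threshold: float = 0.5) -> HeatMap:
    """Aggregate a binary segmentation into an occupancy heat map.

    Each low-resolution voxel stores the fraction of its covered
    high-resolution voxels that are stained. In-plane (x, y) aggregation
    follows the integer size ratio; along z, planes are grouped by the
    dz ratio with invalid (missing-section) planes excluded from the
    denominator. Boundary voxels only partially covered by the grid use
    the covered-voxel denominator, and the returned ``brain_mask`` flags
    voxels with >= ``coverage_threshold`` tissue/valid coverage.

    Parameters
    ----------
    seg:
        Binary mask volume at histology resolution.
    target_size:
        Heat-map voxel size in um (default 125 um isotropic); must be an
        integer multiple of the in-plane voxel size.
    tissue_mask:
        Optional brain mask at ``seg`` resolution defining the tissue
        footprint (defaults to the full grid).
    """
    if seg.modality != "mask":
        raise ValueError("aggregate expects a binary mask volume")
    dx, dy, dz = seg.voxel_size
    fx, fy = _ratio(target_size, dx), _ratio(target_size, dy)
    if target_size < dz:
        raise ResolutionError(
            f"target {target_size} um is finer than the plane spacing {dz} um")
    fz = _ratio(target_size, dz)

    data = seg.data.astype(float)
    weight = np.ones(seg.shape)
    if tissue_mask is not None:
        weight *= tissue_mask.data.astype(float)
    weight[:, :, ~seg.valid_planes] = 0.0
    data = data * weight

    nx, ny, nz = seg.shape
    ox, oy, oz = -(-nx // fx), -(-ny // fy), -(-nz // fz)

    def pool(arr):
        padded = np.zeros((ox * fx, oy * fy, oz * fz))
        padded[:nx, :ny, :nz] = arr
        return padded.reshape(ox, fx, oy, fy, oz, fz).sum(axis=(1, 3, 5))

    stained = pool(data)
    covered = pool(weight)
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = np.where(covered > 0, stained / np.maximum(covered, 1e-300), 0.0)
    full = float(fx * fy * fz)
    brain_mask = covered / full >= coverage_threshold
    # voxels with any coverage participate in quantification sums
    brain_mask &= covered > 0
    vol = Volume(occ, (target_size,) * 3, modality="heatmap")
    return HeatMap(vol, brain_mask, smoothed=False, coverage=covered / full)


def smooth(hm: HeatMap, kernel: str = "sigma") -> HeatMap:
    """Gaussian smoothing with kernel size of one heat-map voxel per axis.

    ``kernel="sigma"`` (default) takes one voxel as the Gaussian sigma;
    ``kernel="fwhm"`` takes it as the full width at half maximum. The
    filter is renormalized inside the brain mask so no occupancy mass
    bleeds into (or from) the background.
    """
    if hm.smoothed:
        raise ValueError("heat map is already smoothed")
    sigma = 1.0 if kernel == "sigma" else 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    m = hm.brain_mask.astype(float)
    num = ndimage.gaussian_filter(hm.data * m, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(m, sigma=sigma, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(hm.brain_mask, num / np.maximum(den, 1e-300), 0.0)
    sm = np.clip(sm, 0.0, None)
    vol = Volume(sm, hm.volume.voxel_size, modality="heatmap")
    return HeatMap(vol, hm.brain_mask.copy(), smoothed=True,
                   coverage=None if hm.coverage is None else hm.coverage.copy())


@dataclass
class CorrelationResult:
    """Spearman's rank correlation between two heat maps over a mask."""

    rho: float
    p_value: float
    n_voxels: int

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.rho <= 1.0 + 1e-9:
            raise ValueError("rho out of range")
        if self.n_voxels < 3:
            raise ValueError("need at least 3 voxels")


def correlate(hm_a: HeatMap, hm_b: HeatMap,
              mask: np.ndarray | None = None) -> CorrelationResult:
    """Voxel-wise Spearman rank correlation of two heat maps.

    Uses average ranks for ties and a two-sided p value, over the voxels
    of ``mask`` (default: the intersection of the two brain masks).
    Raises when either input is constant over the mask.
    """
    if hm_a.volume.shape != hm_b.volume.shape:
        raise ValueError("heat maps must share a grid")
    if mask is None:
        mask = hm_a.brain_mask & hm_b.brain_mask
    mask = np.asarray(mask, dtype=bool)
    a = hm_a.data[mask]
    b = hm_b.data[mask]
    if a.size < 3:
        raise ValueError("mask selects fewer than 3 voxels")
    if np.ptp(a) < 1e-15 or np.ptp(b) < 1e-15:
        raise ValueError("constant heat map: rank correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return CorrelationResult(float(rho), float(p), int(a.size))


def correlation_matrix(heatmaps: dict[str, HeatMap],
                       mask: np.ndarray | None = None):
    """Pairwise Spearman rho and p for a set of markers on one grid.

    Returns two pandas DataFrames (rho, p) indexed by marker name.
    """
    import pandas as pd
    names = list(heatmaps)
    rho = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            res = correlate(heatmaps[a], heatmaps[b], mask)
            rho.loc[a, b] = rho.loc[b, a] = res.rho
            pval.loc[a, b] = pval.loc[b, a] = res.p_value
    return rho, pval
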