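"""Section-sampling simulation: how much does a 2D protocol deviate from 3D?

Conventional histopathology quantifies a marker on a handful of sections
per region; full 3D reconstruction uses all of them. To measure the cost
of sparse sampling, equidistant section subsets are enumerated at each
spacing ``k`` (one subset per phase offset), the load of each subset is
recomputed, and the relative error against the all-sections reference is
reported. Subset loads pool stained and ROI voxel counts over the
subset's sections (as 2D protocols pool outlined areas), not a per-
section average. Rostro-caudal load dispersion within an ROI is
summarized by the coefficient of variation of per-section loads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import Volume

__all__ = [
    "ProfileStats",
    "SamplingSimulationResult",
    "rostrocaudal_profile",
    "enumerate_subsets",
    "relative_error",
    "sampling_simulation",
    "compare_groups",
    "simulation_to_frame",
    "EmptyProfileError",
]


class EmptyProfileError(ValueError):
    """The ROI is absent from every valid section."""


@dataclass
class ProfileStats:
    """Per-section loads of an ROI along the rostro-caudal (z) axis.

    ``cv`` is 100 x sd / mean with the sample (n-1) standard deviation;
    it is undefined (error at construction) when the mean load is zero.
    """

    z_indices: np.ndarray
    loads: np.ndarray  # percent, one per section where the ROI is present
    mean: float = field(init=False)
    sd: float = field(init=False)
    cv: float = field(init=False)

    def __post_init__(self):
        self.z_indices = np.asarray(self.z_indices, dtype=int)
        self.loads = np.asarray(self.loads, dtype=float)
        if self.loads.size == 0:
            raise EmptyProfileError("no sections carry the ROI")
        self.mean = float(self.loads.mean())
        self.sd = float(self.loads.std(ddof=1)) if self.loads.size > 1 else 0.0
        if self.mean == 0.0:
            raise ValueError("CV undefined: mean load is zero")
        self.cv = 100.0 * self.sd / self.mean


def _per_section_counts(seg: Volume, labels: Volume, roi_labels):
    if seg.shape != labels.shape:
        raise ValueError("segmentation and label volumes must share a grid")
    roi = list({int(v) for v in (roi_labels if hasattr(roi_labels, "__iter__") else [roi_labels])})
    in_roi = np.isin(labels.data, roi)
    stained = seg.data.astype(bool) & in_roi
    valid = seg.valid_planes & labels.valid_planes
    roi_per_z = in_roi.sum(axis=(0, 1)).astype(float)
    st_per_z = stained.sum(axis=(0, 1)).astype(float)
    roi_per_z[~valid] = 0.0
    st_per_z[~valid] = 0.0
    return roi_per_z, st_per_z


def rostrocaudal_profile(seg: Volume, labels: Volume, roi_labels) -> ProfileStats:
    """Per-section load profile of an ROI along the rostro-caudal axis.

    Sections where the ROI is absent (or flagged invalid) are excluded —
    not counted as zero — so the profile reflects load where the region
    exists.
    """
    roi_per_z, st_per_z = _per_section_counts(seg, labels, roi_labels)
    present = roi_per_z > 0
    if not present.any():
        raise EmptyProfileError("ROI absent from every valid section")
    z = np.nonzero(present)[0]
    loads = 100.0 * st_per_z[present] / roi_per_z[present]
    return ProfileStats(z, loads)


def enumerate_subsets(valid_sections, step_k: int) -> list[list[int]]:
    """All equidistant subsets at spacing ``step_k`` of an ordered section list.

    One subset per phase offset ``o`` in ``0..k-1``: the sections at
    positions ``o, o+k, o+2k, ...`` of the valid list. Empty subsets are
    dropped, so ``k > n`` yields ``n`` singleton subsets. The subsets at
    any ``k`` are pairwise disjoint and their union is the full list.
    """
    if step_k < 1:
        raise ValueError("step_k must be >= 1")
    sections = list(valid_sections)
    subsets = [sections[o::step_k] for o in range(step_k)]
    return [s for s in subsets if s]


def relative_error(l_subset: float, l_full: float) -> float:
    """Relative deviation (percent) of a subset load from the full-stack load.

    ``100 * |L_subset - L_full| / L_full``; undefined for a zero
    reference load.
    """
    if l_full <= 0:
        raise ValueError("reference load must be > 0")
    return 100.0 * abs(l_subset - l_full) / l_full


@dataclass
class SamplingSimulationResult:
    """Relative-error distribution at one inter-section spacing ``k``."""

    step_k: int
    spacing_mm: float
    offsets: list[int]
    subset_loads: list[float]
    reference_load: float
    relative_errors: list[float]
    median_re: float = field(init=False)
    q1_re: float = field(init=False)
    q3_re: float = field(init=False)

    def __post_init__(self):
        re = np.asarray(self.relative_errors, dtype=float)
        self.median_re = float(np.median(re))
        self.q1_re = float(np.percentile(re, 25))
        self.q3_re = float(np.percentile(re, 75))


def sampling_simulation(seg: Volume, labels: Volume, roi_labels,
                        steps=(1, 5, 10, 15)) -> list[SamplingSimulationResult]:
    """Simulate sparse equidistant section sampling of an ROI.

    For every spacing ``k`` all phase-offset subsets of the valid
    sections carrying the ROI are enumerated; each subset load pools
    stained and ROI voxel counts over its sections, and the relative
    error against the all-sections reference load is recorded. Spacing is
    also reported in mm as ``k x dz``.
    """
    roi_per_z, st_per_z = _per_section_counts(seg, labels, roi_labels)
    present = np.nonzero(roi_per_z > 0)[0]
    if present.size == 0:
        raise EmptyProfileError("ROI absent from every valid section")
    ref_roi = roi_per_z[present].sum()
    ref_st = st_per_z[present].sum()
    ref_load = 100.0 * ref_st / ref_roi
    if ref_load <= 0:
        raise ValueError("reference load is zero: relative error undefined")
    dz_mm = seg.voxel_size[2] * 1e-3
    results = []
    for k in steps:
        subset_loads, res, offsets = [], [], []
        for o, subset in enumerate(enumerate_subsets(list(present), int(k))):
            idx = np.asarray(subset)
            roi_n = roi_per_z[idx].sum()
            if roi_n == 0:
                continue
            load = 100.0 * st_per_z[idx].sum() / roi_n
            subset_loads.append(float(load))
            res.append(relative_error(load, ref_load))
            offsets.append(o)
        results.append(SamplingSimulationResult(
            step_k=int(k), spacing_mm=float(k * dz_mm), offsets=offsets,
            subset_loads=subset_loads, reference_load=float(ref_load),
            relative_errors=res))
    return results


def simulation_to_frame(results: list[SamplingSimulationResult],
                        roi: str = "", animal: str = "") -> pd.DataFrame:
    """Tidy (animal, roi, k, offset, L_subset, RE) table, box-plot ready."""
    rows = []
    for r in results:
        for o, load, re in zip(r.offsets, r.subset_loads, r.relative_errors):
            rows.append({"animal": animal, "roi": roi, "k": r.step_k,
                         "spacing_mm": r.spacing_mm, "offset": o,
                         "L_subset": load, "L_full": r.reference_load,
                         "RE": re})
    return pd.DataFrame(rows)


def compare_groups(loads_a, loads_b):
    """Two-sided Mann-Whitney U test between two groups of loads.

    Ties are handled by average ranks. Returns ``(U, p)`` with U the
    statistic of the first group.
    """
    a = np.asarray(list(loads_a), dtype=float)
    b = np.asarray(list(loads_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
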