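"""Image similarity metrics used as registration criteria.

Two metrics drive all registrations: the Pearson correlation coefficient
(monomodal: histology section vs. block-face photograph) and mutual
information of the joint intensity histogram (multimodal: block-face vs.
MRI-like atlas).

:func:`mutual_information` is the reporting metric (hard-binned, bits).
:func:`mi_soft` is the internal optimization criterion: the floating
intensity axis is soft-binned with linear (hat) windows, which makes the
metric piecewise-smooth in the transform parameters and yields an
analytic derivative with respect to each warped sample intensity — the
quantity the quasi-Newton elastic registration chains through the image
gradient to the control lattice.
"""

from __future__ import annotations

import numpy as np

__all__ = ["correlation_coefficient", "mutual_information", "mi_soft",
           "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    """Raised when a similarity metric is undefined for the given inputs."""


def _masked_pair(a, b, mask):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape mismatch")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    return a, b


def correlation_coefficient(a, b, mask=None) -> float:
    """Pearson correlation of the (masked) overlapping intensities.

    Raises
    ------
    UndefinedMetricError
        Fewer than 2 samples, or zero variance in either input.
    """
    a, b = _masked_pair(a, b, mask)
    if a.size < 2:
        raise UndefinedMetricError("need at least 2 overlapping samples")
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        raise UndefinedMetricError("zero variance: correlation undefined")
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return float(np.clip(r, -1.0, 1.0))


def mutual_information(a, b, n_bins: int = 64, mask=None) -> float:
    """Mutual information of the joint intensity histogram, in **bits**.

    Each image is binned over its own (masked) intensity range into
    ``n_bins`` equal-width bins; MI is computed from the joint frequency
    table. Invariant under any per-image bijective intensity remap that
    preserves bin occupancy (e.g. ``255 - a``).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a, b = _masked_pair(a, b, mask)
    if a.size == 0:
        raise UndefinedMetricError("empty overlap")
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


def mi_soft(ref_vals: np.ndarray, flo_vals: np.ndarray, n_bins: int = 32,
            ref_range: tuple[float, float] | None = None,
            flo_range: tuple[float, float] | None = None,
            with_gradient: bool = False):
    """Soft-binned mutual information (nats) with optional sample gradient.

    The reference axis is hard-binned; the floating axis uses linear hat
    windows so each sample contributes to two adjacent bins. When
    ``with_gradient`` is true the derivative of MI with respect to each
    floating sample value is returned alongside.
    """
    ref_vals = np.asarray(ref_vals, dtype=float).ravel()
    flo_vals = np.asarray(flo_vals, dtype=float).ravel()
    n = ref_vals.size
    if n == 0:
        raise UndefinedMetricError("empty overlap")
    rlo, rhi = ref_range if ref_range is not None else (ref_vals.min(), ref_vals.max())
    flo_lo, flo_hi = flo_range if flo_range is not None else (flo_vals.min(), flo_vals.max())
    if rhi - rlo < 1e-12 or flo_hi - flo_lo < 1e-12:
        raise UndefinedMetricError("constant input: MI undefined")
    ri = np.clip(((ref_vals - rlo) / (rhi - rlo) * n_bins).astype(int), 0, n_bins - 1)
    t = np.clip((flo_vals - flo_lo) / (flo_hi - flo_lo), 0.0, 1.0) * (n_bins - 1)
    j0 = np.minimum(t.astype(int), n_bins - 2)
    w1 = t - j0

    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (ri, j0), 1.0 - w1)
    np.add.at(joint, (ri, j0 + 1), w1)
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    eps = 1e-12
    log_ratio = np.log((p + eps) / (np.outer(px, py) + eps))
    mi = float((p * log_ratio).sum())
    if not with_gradient:
        return mi
    # dMI/dflo_k = (L[i, j0+1] - L[i, j0]) / N * dt/dv
    dt_dv = (n_bins - 1) / (flo_hi - flo_lo)
    grad = (log_ratio[ri, j0 + 1] - log_ratio[ri, j0]) * (dt_dv / n)
    # clamped samples have zero derivative
    grad[(t <= 0.0) | (t >= n_bins - 1)] = 0.0
    return mi, grad
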