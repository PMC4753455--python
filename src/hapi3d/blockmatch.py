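"""Block-matching transform estimation.

The reference image/volume is partitioned into non-overlapping blocks;
each block with sufficient intensity variance is matched to the
displacement (within a search radius) that maximizes the correlation
coefficient against the floating image. A global transform (2D affine,
3D rigid or 3D affine) is then fitted to the block correspondences by a
trimmed least-squares loop, which makes the estimate robust to tears,
folds and local staining artifacts that corrupt individual blocks.
The match-and-fit cycle is iterated, resampling the floating image
through the current estimate, until the parameter update is negligible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .resample import resample_image, affine_world_to_voxel
from .transforms import Affine2D, Affine3D, Rigid3D
from scipy import ndimage

__all__ = ["block_matching", "BlockMatchConfig", "InsufficientDataError"]


class InsufficientDataError(ValueError):
    """Too few valid blocks to estimate a transform."""


@dataclass
class BlockMatchConfig:
    """Tunables of the block-matching estimator.

    block_size:
        Edge length of the (square/cubic) blocks, in pixels/voxels.
    search_radius:
        Maximum displacement searched per axis, in pixels/voxels.
    variance_quantile:
        Blocks below this quantile of per-block variance are discarded
        (flat background carries no matching information).
    trim_fraction:
        Fraction of correspondences kept in each robust refit.
    mask_coverage:
        Minimum tissue-mask fraction for a block to participate.
    """

    block_size: int = 21
    search_radius: int = 10
    variance_quantile: float = 0.5
    trim_fraction: float = 0.5
    mask_coverage: float = 0.5
    min_blocks: int = 10
    max_outer_iters: int = 5
    tol: float = 1e-3
    robust_iters: int = 4


def _block_reduce_sum(arr: np.ndarray, b: int) -> np.ndarray:
    """Sum over non-overlapping b^nd blocks (array pre-cropped to multiples)."""
    nd = arr.ndim
    shape = []
    for n in arr.shape:
        shape.extend([n // b, b])
    view = arr.reshape(shape)
    return view.sum(axis=tuple(range(1, 2 * nd, 2)))


def _match_blocks(ref: np.ndarray, flo: np.ndarray, cfg: BlockMatchConfig,
                  ref_mask: np.ndarray | None):
    """One match pass: returns (ref block centers, matched positions) in px."""
    nd = ref.ndim
    b, r = cfg.block_size, cfg.search_radius
    nb = [(s - 2 * r) // b for s in ref.shape]
    if min(nb) < 1:
        raise InsufficientDataError("image too small for block size + search radius")
    crop = tuple(slice(r, r + n * b) for n in nb)
    ref_sub = ref[crop].astype(float)
    n_px = b ** nd

    ref_s1 = _block_reduce_sum(ref_sub, b)
    ref_s2 = _block_reduce_sum(ref_sub ** 2, b)
    ref_var = ref_s2 - ref_s1 ** 2 / n_px
    valid = ref_var > 1e-9
    if ref_mask is not None:
        cover = _block_reduce_sum(ref_mask[crop].astype(float), b) / n_px
        valid &= cover >= cfg.mask_coverage
    if valid.any():
        floor = np.quantile(ref_var[valid], cfg.variance_quantile)
        filtered = valid & (ref_var >= floor)
        if filtered.sum() >= cfg.min_blocks:
            valid = filtered
    if valid.sum() < cfg.min_blocks:
        raise InsufficientDataError(
            f"only {int(valid.sum())} valid blocks (need >= {cfg.min_blocks})")

    offsets = list(itertools.product(range(-r, r + 1), repeat=nd))
    n_disp = len(offsets)
    cc = np.full((n_disp,) + tuple(nb), -np.inf)
    for di, d in enumerate(offsets):
        sl = tuple(slice(r + dd, r + dd + n * b) for dd, n in zip(d, nb))
        flo_sub = flo[sl].astype(float)
        f1 = _block_reduce_sum(flo_sub, b)
        f2 = _block_reduce_sum(flo_sub ** 2, b)
        rf = _block_reduce_sum(ref_sub * flo_sub, b)
        cov = rf - ref_s1 * f1 / n_px
        var = ref_var * (f2 - f1 ** 2 / n_px)
        cc[di] = np.where(var > 1e-9, cov / np.sqrt(np.maximum(var, 1e-12)), -np.inf)

    cc_flat = cc.reshape(n_disp, -1)
    valid_flat = valid.ravel()
    best = np.argmax(cc_flat, axis=0)

    # parabolic sub-pixel refinement per displacement axis
    disp_shape = (2 * r + 1,) * nd
    best_idx = np.array(np.unravel_index(best, disp_shape))  # (nd, nblocks)
    cc_grid = cc.reshape(disp_shape + (-1,))
    nblocks = cc_flat.shape[1]
    block_ids = np.arange(nblocks)
    c0 = cc_flat[best, block_ids]
    delta = np.zeros((nd, nblocks))
    for a in range(nd):
        interior = (best_idx[a] > 0) & (best_idx[a] < 2 * r)
        if not interior.any():
            continue
        idx_m = best_idx.copy(); idx_m[a] -= 1
        idx_p = best_idx.copy(); idx_p[a] += 1
        idx_m[a] = np.clip(idx_m[a], 0, 2 * r)
        idx_p[a] = np.clip(idx_p[a], 0, 2 * r)
        cm = cc_grid[tuple(idx_m) + (block_ids,)]
        cp = cc_grid[tuple(idx_p) + (block_ids,)]
        denom = cm - 2 * c0 + cp
        ok = interior & np.isfinite(cm) & np.isfinite(cp) & (denom < -1e-12)
        d_sub = np.zeros(nblocks)
        d_sub[ok] = 0.5 * (cm[ok] - cp[ok]) / denom[ok]
        delta[a] = np.clip(d_sub, -0.5, 0.5)

    disp = best_idx - r + delta  # (nd, nblocks)
    keep = valid_flat & np.isfinite(c0)
    centers = np.stack(np.meshgrid(
        *[r + np.arange(n) * b + (b - 1) / 2.0 for n in nb], indexing="ij"),
        axis=0).reshape(nd, -1)
    return centers[:, keep].T, (centers + disp)[:, keep].T


def _fit_affine(src: np.ndarray, dst: np.ndarray):
    """Least-squares affine dst ~= A src + t; returns (A, t)."""
    nd = src.shape[1]
    design = np.hstack([src, np.ones((src.shape[0], 1))])
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return sol[:nd].T, sol[nd]


def _fit_rigid(src: np.ndarray, dst: np.ndarray):
    """Kabsch best-fit rotation + translation, dst ~= R src + t."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0] * (src.shape[1] - 1) + [d])
    rot = vt.T @ corr @ u.T
    t = cd - rot @ cs
    return rot, t


def _euler_zyx_from_matrix(rot: np.ndarray) -> np.ndarray:
    ay = -np.arcsin(np.clip(rot[2, 0], -1, 1))
    az = np.arctan2(rot[1, 0], rot[0, 0])
    ax = np.arctan2(rot[2, 1], rot[2, 2])
    return np.rad2deg(np.array([az, ay, ax]))


def _fit_model(src, dst, model: str, cfg: BlockMatchConfig):
    """Trimmed least-squares fit of the requested transform model."""
    keep = np.ones(len(src), dtype=bool)
    fit = _fit_rigid if model == "rigid3d" else _fit_affine
    a = t = None
    for _ in range(cfg.robust_iters):
        a, t = fit(src[keep], dst[keep])
        resid = np.linalg.norm(dst - (src @ a.T + t), axis=1)
        n_keep = max(int(np.ceil(cfg.trim_fraction * len(src))), src.shape[1] + 1)
        keep = np.zeros(len(src), dtype=bool)
        keep[np.argsort(resid)[:n_keep]] = True
    if model == "affine2d":
        return Affine2D(a, t)
    if model == "affine3d":
        return Affine3D(a, t)
    if model == "rigid3d":
        return Rigid3D(_euler_zyx_from_matrix(a), t)
    raise ValueError(f"unknown model {model!r}")


def _resample_nd(arr, transform, voxel_size, background):
    if arr.ndim == 2:
        return resample_image(arr, transform, voxel_size, mode="linear",
                              background=background)
    m, o = affine_world_to_voxel(transform, voxel_size, voxel_size)
    return ndimage.affine_transform(arr.astype(float), m, o, order=1,
                                    mode="constant", cval=background)


def _param_norm(t) -> float:
    """Deviation from identity in px/degrees (convergence criterion)."""
    if isinstance(t, Rigid3D):
        return float(np.abs(t.rotation_deg).max() + np.abs(t.translation).max())
    return float(np.abs(t.matrix - np.eye(t.matrix.shape[0])).max() * 100
                 + np.abs(t.translation).max())


def block_matching(ref: np.ndarray, flo: np.ndarray, block_size: int | None = None,
                   search_radius: int | None = None, model: str = "affine2d",
                   voxel_size=1.0, ref_mask: np.ndarray | None = None,
                   background: float = 0.0,
                   config: BlockMatchConfig | None = None):
    """Estimate a transform aligning ``flo`` onto ``ref`` by block matching.

    Parameters
    ----------
    ref, flo:
        Same-shape 2D images or 3D volumes (scalar intensities).
    model:
        ``affine2d``, ``rigid3d`` or ``affine3d``.
    voxel_size:
        Physical pixel/voxel size (um), scalar or per-axis; the returned
        transform lives in world coordinates.
    ref_mask:
        Optional tissue mask on the reference; blocks mostly outside the
        mask are excluded.

    Returns
    -------
    Transform
        World-coordinate transform mapping reference coordinates to
        floating coordinates (pull-back convention).

    Raises
    ------
    InsufficientDataError
        Fewer than ``config.min_blocks`` valid blocks.
    """
    if ref.shape != flo.shape:
        raise ValueError("ref and flo must have the same shape")
    nd = ref.ndim
    if model.endswith("2d") != (nd == 2):
        raise ValueError(f"model {model!r} incompatible with {nd}D input")
    cfg = config or BlockMatchConfig(
        block_size=21 if nd == 2 else 7,
        search_radius=10 if nd == 2 else 4)
    if block_size is not None:
        cfg.block_size = block_size
    if search_radius is not None:
        cfg.search_radius = search_radius
    vox = np.broadcast_to(np.asarray(voxel_size, dtype=float), (nd,)).copy()

    identity = Affine2D.identity() if nd == 2 else Affine3D.identity()
    total = identity
    current = flo.astype(float)
    for _ in range(cfg.max_outer_iters):
        src_px, dst_px = _match_blocks(ref, current, cfg, ref_mask)
        t_step = _fit_model(src_px * vox, dst_px * vox, model, cfg)
        # compose in world coords: new total = total o step
        step_affine = t_step.as_affine() if isinstance(t_step, Rigid3D) else t_step
        total = total.compose(step_affine)
        if _param_norm(t_step) < cfg.tol:
            break
        current = _resample_nd(flo, total, vox, background)

    if model == "rigid3d":
        rot = _euler_zyx_from_matrix(total.matrix)
        return Rigid3D(rot, total.translation + (np.eye(3) - total.matrix) @ total.center)
    return total
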