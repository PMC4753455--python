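"""High-level registration estimators.

The reconstruction and atlas-matching strategy is hierarchical:

* 2D histology sections are aligned to their block-face photographs by
  block matching at three resolution levels, maximizing the correlation
  coefficient (:func:`register_section`);
* 3D anatomical volumes (block-face vs. MRI-like atlas) are matched by a
  rigid transform maximizing mutual information with a derivative-free
  direction-set (Powell) optimizer (:func:`register_rigid_3d`), refined
  by an affine estimated with 3D block matching
  (:func:`register_affine_3d`), and finally by a free-form deformation
  on a 10x10x10 control lattice maximizing mutual information by
  quasi-Newton ascent (:func:`register_ffd`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.transform import downscale_local_mean

from .blockmatch import BlockMatchConfig, block_matching
from .metrics import correlation_coefficient, mi_soft
from .resample import affine_world_to_voxel, resample, resample_image
from .transforms import Affine2D, Affine3D, FFD3D, Rigid3D, bspline_basis_matrix
from .volumes import Volume

__all__ = [
    "RegistrationReport",
    "register_section",
    "register_rigid_3d",
    "register_affine_3d",
    "register_ffd",
]


@dataclass
class RegistrationReport:
    """Scalar summary of one registration run (similarity before/after)."""

    metric_name: str
    metric_initial: float
    metric_final: float
    n_levels: int = 1
    converged: bool = True

    def to_dict(self) -> dict:
        return {"metric_name": self.metric_name,
                "metric_initial": self.metric_initial,
                "metric_final": self.metric_final,
                "n_levels": self.n_levels,
                "converged": self.converged}


def _to_gray(img: np.ndarray) -> np.ndarray:
    return img.mean(axis=-1) if img.ndim == 3 else img.astype(float)


def register_section(ref_photo: np.ndarray, flo_section: np.ndarray,
                     resolution: float = 1.0, n_levels: int = 3,
                     ref_mask: np.ndarray | None = None,
                     background: float = 0.0,
                     config: BlockMatchConfig | None = None
                     ) -> tuple[Affine2D, RegistrationReport]:
    """Align a 2D histology section onto its block-face photograph.

    Block matching maximizing the correlation coefficient is run on a
    coarse-to-fine pyramid (default 3 levels, each a x2 downsample) to
    correct the section deformations introduced by cutting, mounting and
    staining. The returned transform maps block-face world coordinates to
    section coordinates (pull-back), so resampling the section through it
    reconstructs it in block-face geometry.
    """
    ref = _to_gray(ref_photo)
    flo = _to_gray(flo_section)
    cc0 = correlation_coefficient(ref, flo)
    total = Affine2D.identity()
    for level in range(n_levels - 1, -1, -1):
        f = 2 ** level
        if f > 1:
            ref_l = downscale_local_mean(ref, (f, f))
            flo_l = downscale_local_mean(flo, (f, f))
            mask_l = (downscale_local_mean(ref_mask.astype(float), (f, f)) > 0.5
                      if ref_mask is not None else None)
        else:
            ref_l, flo_l, mask_l = ref, flo, ref_mask
        res_l = resolution * f
        cur = (flo_l if level == n_levels - 1 else
               resample_image(flo_l, total, res_l, background=background))
        cfg_l = BlockMatchConfig(**vars(config)) if config is not None else \
            BlockMatchConfig(block_size=21, search_radius=10)
        # shrink blocks/search so every level keeps a dense correspondence set
        short = min(ref_l.shape)
        cfg_l.block_size = max(5, min(cfg_l.block_size, short // 10))
        cfg_l.search_radius = max(2, min(cfg_l.search_radius,
                                         (short - cfg_l.block_size) // 4))
        try:
            step = block_matching(ref_l, cur, model="affine2d", voxel_size=res_l,
                                  ref_mask=mask_l, background=background,
                                  config=cfg_l)
        except Exception:
            if level > 0:
                continue  # coarse level too small/flat: defer to finer levels
            if not np.allclose(total.matrix, np.eye(2)):
                break  # keep the coarse estimate if the fine level degenerates
            raise
        total = total.compose(step)
    warped = resample_image(flo, total, resolution, background=background)
    cc1 = correlation_coefficient(ref, warped)
    if cc1 < cc0:  # never degrade the criterion: fall back to identity
        return Affine2D.identity(), RegistrationReport(
            "correlation_coefficient", cc0, cc0, n_levels, converged=False)
    return total, RegistrationReport("correlation_coefficient", cc0, cc1, n_levels)


# ---------------------------------------------------------------------------
# 3D rigid (mutual information + Powell)
# ---------------------------------------------------------------------------

def _warp_affine_volume(flo: Volume, transform, ref: Volume,
                        background: float = 0.0, order: int = 1) -> np.ndarray:
    m, o = affine_world_to_voxel(transform, flo.voxel_size, ref.voxel_size)
    return ndimage.affine_transform(flo.data.astype(float), m, o,
                                    output_shape=ref.shape, order=order,
                                    mode="constant", cval=background)


def register_rigid_3d(ref: Volume, flo: Volume, n_bins: int = 32,
                      mask: np.ndarray | None = None,
                      max_angle: float = 20.0, max_shift_voxels: float = 10.0,
                      xtol: float = 1e-3
                      ) -> tuple[Rigid3D, RegistrationReport]:
    """Estimate a 6-parameter rigid motion maximizing mutual information.

    Rotation is about the reference volume center. The optimizer is the
    derivative-free direction-set (Powell) method on the soft-binned MI;
    non-convergence is flagged in the report and the best-so-far
    parameters are returned.
    """
    center = ref.world_extent() / 2.0
    ref_vals_full = ref.data.astype(float)
    sel = np.ones(ref.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    ref_vals = ref_vals_full[sel]
    ref_range = (float(ref_vals.min()), float(ref_vals.max()))
    flo_range = (float(flo.data.min()), float(flo.data.max()))
    tscale = float(min(ref.voxel_size))  # translations optimized in voxel units

    def transform_of(p):
        return Rigid3D(p[:3], np.asarray(p[3:]) * tscale, center)

    def neg_mi(p):
        warped = _warp_affine_volume(flo, transform_of(p), ref,
                                     background=flo_range[0])
        try:
            return -mi_soft(ref_vals, warped[sel], n_bins, ref_range, flo_range)
        except Exception:
            return 0.0

    p0 = np.zeros(6)
    mi0 = -neg_mi(p0)
    bounds = ([(-max_angle, max_angle)] * 3
              + [(-max_shift_voxels * 2, max_shift_voxels * 2)] * 3)
    res = optimize.minimize(neg_mi, p0, method="Powell", bounds=bounds,
                            options={"xtol": xtol, "ftol": 1e-7, "maxiter": 200})
    p_best = res.x if -res.fun >= mi0 else p0
    mi1 = max(-res.fun, mi0)
    report = RegistrationReport("mutual_information", mi0, mi1,
                                n_levels=1, converged=bool(res.success))
    return transform_of(p_best), report


def register_affine_3d(ref: Volume, flo: Volume, init: Rigid3D | Affine3D,
                       config: BlockMatchConfig | None = None,
                       mask: np.ndarray | None = None,
                       background: float = 0.0
                       ) -> tuple[Affine3D, RegistrationReport]:
    """Affine refinement of a rigid initialization by 3D block matching.

    The floating volume is first resampled through ``init`` onto the
    reference grid; the residual affine is estimated by block matching
    maximizing the correlation coefficient and composed with ``init``.
    """
    init_aff = init.as_affine() if isinstance(init, Rigid3D) else init
    flo_init = _warp_affine_volume(flo, init_aff, ref, background=background)
    cc0 = correlation_coefficient(ref.data.astype(float), flo_init, mask)
    step = block_matching(ref.data.astype(float), flo_init, model="affine3d",
                          voxel_size=ref.voxel_size, ref_mask=mask,
                          background=background, config=config)
    total = init_aff.compose(step)
    warped = _warp_affine_volume(flo, total, ref, background=background)
    cc1 = correlation_coefficient(ref.data.astype(float), warped, mask)
    if cc1 < cc0:
        return init_aff, RegistrationReport("correlation_coefficient", cc0, cc0,
                                            converged=False)
    return total, RegistrationReport("correlation_coefficient", cc0, cc1)


# ---------------------------------------------------------------------------
# Free-form deformation (mutual information + quasi-Newton)
# ---------------------------------------------------------------------------

def register_ffd(ref: Volume, flo: Volume, init: Affine3D | Rigid3D | None = None,
                 grid_shape: tuple[int, int, int] = (10, 10, 10),
                 n_bins: int = 32, maxiter: int = 100,
                 mask: np.ndarray | None = None,
                 reg_weight: float = 1e-3, background: float | None = None
                 ) -> tuple[FFD3D, RegistrationReport]:
    """Elastic registration: B-spline FFD maximizing mutual information.

    The control-point displacements of a regular lattice (default
    10x10x10) are optimized by quasi-Newton (L-BFGS) ascent of the
    soft-binned mutual information, using the analytic gradient obtained
    by chaining the per-sample MI derivative through the trilinear image
    gradient and the B-spline basis. A small L2 penalty on the control
    displacements regularizes the field. Non-convergence is flagged; the
    best-so-far lattice is returned.
    """
    init_aff = (Affine3D.identity() if init is None
                else (init.as_affine() if isinstance(init, Rigid3D) else init))
    bg = float(flo.data.min()) if background is None else background
    flo_b = _warp_affine_volume(flo, init_aff, ref, background=bg)

    shape = ref.shape
    vox = np.asarray(ref.voxel_size, dtype=float)
    sel = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    ref_vals = ref.data.astype(float)[sel]
    ref_range = (float(ref_vals.min()), float(ref_vals.max()))
    flo_range = (float(flo_b.min()), float(flo_b.max()))

    # per-axis B-spline basis at voxel centers, and base voxel coordinates
    extent = ref.world_extent()
    bases = [bspline_basis_matrix((np.arange(shape[a]) + 0.5) * vox[a],
                                  extent[a], grid_shape[a]) for a in range(3)]
    base_coords = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                       indexing="ij"), axis=0)
    grads = np.gradient(flo_b)  # d(intensity)/d(voxel index), per axis

    n_ctrl = int(np.prod(grid_shape))

    def field_from(vflat):
        grid = vflat.reshape(grid_shape + (3,))
        u = np.tensordot(bases[0], grid, axes=(1, 0))
        u = np.tensordot(bases[1], u, axes=(1, 1)).transpose(1, 0, 2, 3)
        u = np.tensordot(bases[2], u, axes=(1, 2)).transpose(1, 2, 0, 3)
        return u  # (nx, ny, nz, 3) in voxel units

    def scatter_to_ctrl(gvox):
        # transpose of field_from: (nx,ny,nz,3) voxel-gradients -> lattice
        g = np.tensordot(bases[0].T, gvox, axes=(1, 0))
        g = np.tensordot(bases[1].T, g, axes=(1, 1)).transpose(1, 0, 2, 3)
        g = np.tensordot(bases[2].T, g, axes=(1, 2)).transpose(1, 2, 0, 3)
        return g

    def objective(vflat):
        u = field_from(vflat)
        coords = base_coords + np.moveaxis(u, -1, 0)
        flat = coords.reshape(3, -1)
        warped = ndimage.map_coordinates(flo_b, flat, order=1, mode="constant",
                                         cval=bg).reshape(shape)
        mi, dmi = mi_soft(ref_vals, warped[sel], n_bins, ref_range, flo_range,
                          with_gradient=True)
        gvox = np.zeros(shape + (3,))
        for a in range(3):
            ga = ndimage.map_coordinates(grads[a], flat, order=1,
                                         mode="constant", cval=0.0).reshape(shape)
            gv = np.zeros(shape)
            gv[sel] = dmi * ga[sel]
            gvox[..., a] = gv
        grad_ctrl = scatter_to_ctrl(gvox)
        f = -mi + reg_weight * float(vflat @ vflat) / n_ctrl
        g = -grad_ctrl.ravel() + 2.0 * reg_weight * vflat / n_ctrl
        return f, g

    v0 = np.zeros(n_ctrl * 3)
    mi0 = -objective(v0)[0]
    res = optimize.minimize(objective, v0, jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-9,
                                     "gtol": 1e-8})
    mi_final = -objective(res.x)[0]
    if mi_final < mi0:
        res_x, mi_final = v0, mi0
    else:
        res_x = res.x
    ctrl_vox = res_x.reshape(grid_shape + (3,))
    # voxel -> world displacements, then fold the bulk linear part in:
    # sampling flo_b at x+u equals sampling flo at bulk(x) + M u.
    ctrl_world = ctrl_vox * vox[None, None, None, :]
    ctrl_world = ctrl_world @ init_aff.matrix.T
    ffd = FFD3D(ctrl_world, extent, bulk_transform=init_aff)
    report = RegistrationReport("mutual_information", mi0, mi_final,
                                converged=bool(res.success))
    return ffd, report
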