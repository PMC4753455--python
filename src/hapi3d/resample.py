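"""Pull-back resampling of images and volumes through spatial transforms.

Every transform maps reference world coordinates to floating world
coordinates, so resampling evaluates the floating image at the
transformed positions of the target grid's voxel centers. Intensity
data uses linear interpolation; label and mask data must use nearest
neighbor so no new label values are ever created.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .transforms import Affine2D, Affine3D, FFD3D, Rigid3D, CompositeTransform
from .volumes import Volume

__all__ = ["resample", "resample_image", "affine_world_to_voxel"]


def affine_world_to_voxel(transform, src_voxel_size, dst_voxel_size):
    """Convert a world-coordinate affine to the voxel-index map (M, o).

    Returns matrix ``M`` and offset ``o`` such that for a target voxel
    index ``i``, the source voxel index is ``M @ i + o`` (the form
    consumed by :func:`scipy.ndimage.affine_transform`).
    """
    if isinstance(transform, Rigid3D):
        transform = transform.as_affine()
    a, t = transform._homogeneous()
    sd = np.asarray(dst_voxel_size, dtype=float)
    ss = np.asarray(src_voxel_size, dtype=float)
    m = a * sd[None, :] / ss[:, None]
    o = (a @ (0.5 * sd) + t) / ss - 0.5
    return m, o


def _grid_world_coords(shape, voxel_size):
    axes = [(np.arange(n) + 0.5) * d for n, d in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij")


def resample_image(img: np.ndarray, transform: Affine2D, resolution: float | tuple = 1.0,
                   target_shape=None, mode: str = "linear", background: float = 0.0) -> np.ndarray:
    """Resample a 2D section image through a world-coordinate 2D affine.

    ``resolution`` is um/pixel of both images (scalar or per-axis pair).
    RGB images are resampled channel-wise.
    """
    res = np.broadcast_to(np.asarray(resolution, dtype=float), (2,))
    shape = tuple(target_shape) if target_shape is not None else img.shape[:2]
    m, o = affine_world_to_voxel(transform, res, res)
    order = 1 if mode == "linear" else 0
    if img.ndim == 3:
        return np.stack(
            [ndimage.affine_transform(img[..., c].astype(float), m, o, output_shape=shape,
                                      order=order, mode="constant", cval=background)
             for c in range(img.shape[2])], axis=-1)
    return ndimage.affine_transform(img.astype(float), m, o, output_shape=shape,
                                    order=order, mode="constant", cval=background)


def _warped_voxel_coords(transform, target_shape, target_voxel, src_voxel):
    """Source voxel coordinates for each target voxel center (3, nvox)."""
    if isinstance(transform, FFD3D):
        # separable evaluation of the lattice keeps memory bounded
        bulk_m, bulk_o = transform.bulk_transform._homogeneous()
        gx, gy, gz = _grid_world_coords(target_shape, target_voxel)
        pts = np.stack([gx, gy, gz], axis=-1)
        warped = pts @ bulk_m.T + bulk_o
        warped += transform.displacement_on_grid(target_shape, target_voxel)
        coords = warped.reshape(-1, 3).T / np.asarray(src_voxel)[:, None] - 0.5
        return coords
    if isinstance(transform, CompositeTransform):
        gx, gy, gz = _grid_world_coords(target_shape, target_voxel)
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=-1)
        out = np.empty_like(pts)
        # chunk to bound the memory of FFD basis evaluation on point sets
        for sl in range(0, pts.shape[0], 16384):
            out[sl:sl + 16384] = transform.apply(pts[sl:sl + 16384])
        return out.T / np.asarray(src_voxel)[:, None] - 0.5
    raise TypeError(f"unsupported transform {type(transform).__name__}")


def resample(vol: Volume, transform, target_grid: Volume | tuple | None = None,
             mode: str = "linear", background: float = 0.0) -> Volume:
    """Resample a volume through a transform onto a target grid.

    Parameters
    ----------
    vol:
        Floating volume to be pulled back.
    transform:
        Maps target world coordinates into ``vol``'s world space
        (:class:`Rigid3D`, :class:`Affine3D`, :class:`FFD3D` or a
        composite).
    target_grid:
        A template :class:`Volume`, a ``(shape, voxel_size)`` pair, or
        ``None`` to reuse ``vol``'s own grid.
    mode:
        ``linear`` for intensities and heat maps, ``nearest`` for label
        and mask volumes (never creates new label values).
    background:
        Fill value for voxels mapped outside the floating field of view.
    """
    if target_grid is None:
        shape, tvox, valid = vol.shape, vol.voxel_size, vol.valid_planes
    elif isinstance(target_grid, Volume):
        shape, tvox, valid = target_grid.shape, target_grid.voxel_size, None
    else:
        (shape, tvox), valid = target_grid, None
    order = 1 if mode == "linear" else 0
    if mode == "nearest" and vol.modality in ("label", "mask"):
        background = int(background)

    def _one(channel: np.ndarray) -> np.ndarray:
        if isinstance(transform, (Affine3D, Rigid3D)):
            m, o = affine_world_to_voxel(transform, vol.voxel_size, tvox)
            return ndimage.affine_transform(channel, m, o, output_shape=tuple(shape),
                                            order=order, mode="constant", cval=background)
        coords = _warped_voxel_coords(transform, shape, tvox, vol.voxel_size)
        out = ndimage.map_coordinates(channel, coords, order=order,
                                      mode="constant", cval=background)
        return out.reshape(tuple(shape))

    if vol.data.ndim == 4:
        data = np.stack([_one(vol.data[..., c].astype(float)) for c in range(3)], axis=-1)
    else:
        src = vol.data.astype(float) if order == 1 else vol.data
        data = _one(src)
    if vol.modality == "label":
        data = np.rint(data).astype(vol.data.dtype)
    elif vol.modality == "mask":
        data = np.rint(data).astype(np.uint8)
    return Volume(data, tuple(tvox), modality=vol.modality, valid_planes=valid)
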