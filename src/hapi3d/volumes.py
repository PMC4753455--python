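"""Voxel volume data model and serial-section stacking.

A :class:`Volume` is the universal carrier of 3D data throughout the
pipeline: block-face photographic reference stacks, reconstructed
histology, atlas label volumes, binary stain masks and low-resolution
heat maps all share the same representation.

Axes convention
---------------
``data[x, y, z]`` with x = medio-lateral, y = dorso-ventral and
z = rostro-caudal, so a coronal section is the in-plane ``data[:, :, k]``.
RGB data carries a trailing color axis (``data[x, y, z, 3]``).
Voxel sizes are in micrometres; voxel ``i`` is centred at world
coordinate ``(i + 0.5) * d`` with the world origin at the grid corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import resize

__all__ = [
    "Volume",
    "SectionSeries",
    "stack_sections",
    "auto_mask_blockface",
    "DegenerateThresholdError",
]

MODALITIES = ("blockface", "histology", "label", "heatmap", "mask", "mri")


class DegenerateThresholdError(ValueError):
    """Raised when no meaningful foreground/background threshold exists."""


@dataclass
class Volume:
    """A rank-3 (or rank-4 RGB) voxel grid with physical voxel sizes.

    Parameters
    ----------
    data:
        ``(nx, ny, nz)`` array, or ``(nx, ny, nz, 3)`` for color data.
    voxel_size:
        ``(dx, dy, dz)`` in micrometres, all strictly positive.
    modality:
        One of ``blockface, histology, label, heatmap, mask, mri``.
    valid_planes:
        Boolean flag per z plane; ``False`` marks missing/damaged sections
        that are excluded from every quantification. Defaults to all valid.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    modality: str = "histology"
    valid_planes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected rank-3/4 data, got rank {self.data.ndim}")
        if self.data.ndim == 4 and self.data.shape[-1] != 3:
            raise ValueError("rank-4 volumes must have a trailing color axis of size 3")
        if min(self.data.shape[:3]) < 1:
            raise ValueError("all spatial dims must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be 3 strictly positive values, got {self.voxel_size}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "label":
            if not np.issubdtype(self.data.dtype, np.integer) or self.data.min() < 0:
                raise ValueError("label volumes must contain non-negative integers")
        if self.modality == "mask":
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask volumes must contain only {0, 1}")
        if self.valid_planes is None:
            self.valid_planes = np.ones(self.data.shape[2], dtype=bool)
        else:
            self.valid_planes = np.asarray(self.valid_planes, dtype=bool)
            if self.valid_planes.shape != (self.data.shape[2],):
                raise ValueError("valid_planes must have one flag per z plane")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz * 1e-9  # um^3 -> mm^3

    def world_extent(self) -> np.ndarray:
        """Physical size (um) of the grid along each axis."""
        return np.asarray(self.shape, dtype=float) * np.asarray(self.voxel_size)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world um coordinates."""
        idx = np.asarray(idx, dtype=float)
        return (idx + 0.5) * np.asarray(self.voxel_size)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts / np.asarray(self.voxel_size) - 0.5

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "Volume":
        return replace(self, data=data, modality=modality or self.modality)

    def plane(self, k: int) -> np.ndarray:
        """Coronal (x-y) plane at z index ``k``."""
        return self.data[:, :, k]


@dataclass
class SectionSeries:
    """An ordered series of 2D section images referenced to block-face planes.

    ``z_indices[i]`` is the block-face plane index to which ``images[i]``
    belongs; gaps are allowed (damaged/missing sections). ``interleave`` is
    the physical-section sampling period of the series (e.g. every 5th
    25-um section gives an effective plane spacing of 125 um).
    """

    images: list[np.ndarray]
    z_indices: Sequence[int]
    in_plane_resolution: float
    section_thickness: float
    interleave: int = 1
    stain: str = "unspecified"

    def __post_init__(self) -> None:
        self.z_indices = [int(z) for z in self.z_indices]
        if len(self.images) != len(self.z_indices):
            raise ValueError("images and z_indices must have equal length")
        if any(b <= a for a, b in zip(self.z_indices, self.z_indices[1:])):
            raise ValueError("z_indices must be strictly increasing")
        if self.interleave < 1:
            raise ValueError("interleave must be >= 1")
        if self.in_plane_resolution <= 0 or self.section_thickness <= 0:
            raise ValueError("resolutions must be positive")

    @property
    def plane_spacing(self) -> float:
        """Effective rostro-caudal spacing (um) between consecutive planes."""
        return self.section_thickness * self.interleave

    def __len__(self) -> int:
        return len(self.images)


def _rescale_image(img: np.ndarray, current: float, target: float) -> np.ndarray:
    if abs(current - target) < 1e-12:
        return img
    factor = current / target
    out_shape = tuple(max(1, int(round(s * factor))) for s in img.shape[:2])
    if img.ndim == 3:
        out_shape = out_shape + (img.shape[2],)
    out = resize(img.astype(float), out_shape, order=1, mode="edge",
                 anti_aliasing=factor < 1, preserve_range=True)
    return out


def stack_sections(series: SectionSeries, target_xy_resolution: float | None = None) -> Volume:
    """Stack a section series into a 3D histology volume.

    Planes absent from ``series.z_indices`` (damaged or unstained sections)
    are zero-filled and flagged invalid rather than interpolated, so they
    never contribute fabricated signal to downstream quantification.

    Parameters
    ----------
    series:
        The ordered section images with their block-face plane indices.
    target_xy_resolution:
        If given, images are uniformly rescaled to this in-plane
        resolution (um/pixel) before stacking.

    Returns
    -------
    Volume
        Histology volume with ``dz = section_thickness * interleave``.
    """
    if len(series) == 0:
        raise ValueError("cannot stack an empty section series")
    res = series.in_plane_resolution
    target = target_xy_resolution if target_xy_resolution is not None else res
    images = [_rescale_image(np.asarray(im), res, target) for im in series.images]
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent section image shapes after rescale: {sorted(shapes)}")
    first = images[0]
    z0 = series.z_indices[0]
    nz = series.z_indices[-1] - z0 + 1
    shape = first.shape[:2] + (nz,) + (first.shape[2:] if first.ndim == 3 else ())
    data = np.zeros(shape, dtype=float)
    valid = np.zeros(nz, dtype=bool)
    for img, z in zip(images, series.z_indices):
        data[:, :, z - z0] = img
        valid[z - z0] = True
    return Volume(
        data=data,
        voxel_size=(target, target, series.plane_spacing),
        modality="histology",
        valid_planes=valid,
    )


def auto_mask_blockface(vol: Volume, channel: str = "luminance") -> Volume:
    """Segment tissue from background on a block-face volume.

    Uses Otsu's automatic threshold on the intensity histogram. Colored
    block-face photographs (e.g. tissue embedded in a green matrix) are
    first reduced to a scalar channel; by default luminance, which can be
    overridden with the channel of maximal tissue/background contrast.

    Parameters
    ----------
    vol:
        Block-face volume (grayscale rank-3 or RGB rank-4).
    channel:
        ``luminance`` or one of ``r``/``g``/``b`` for RGB input.

    Returns
    -------
    Volume
        Binary mask volume (1 = tissue) on the same grid.

    Raises
    ------
    DegenerateThresholdError
        If the volume is (near-)constant so no threshold separates
        foreground from background.
    """
    if vol.modality != "blockface":
        raise ValueError("auto_mask_blockface expects a blockface volume")
    data = vol.data.astype(float)
    if data.ndim == 4:
        if channel == "luminance":
            scalar = data.mean(axis=-1)
        else:
            scalar = data[..., "rgb".index(channel)]
    else:
        scalar = data
    lo, hi = float(scalar.min()), float(scalar.max())
    if hi - lo < 1e-9:
        raise DegenerateThresholdError("constant-intensity volume: no tissue/background separation")
    thr = threshold_otsu(scalar)
    mask = (scalar > thr).astype(np.uint8)
    if mask.all() or not mask.any():
        raise DegenerateThresholdError("threshold did not separate two intensity populations")
    return Volume(mask, vol.voxel_size, modality="mask", valid_planes=vol.valid_planes.copy())


def apply_mask(vol: Volume, mask: Volume, background: float = 0.0) -> Volume:
    """Zero out (or fill) background voxels of ``vol`` using a tissue mask."""
    if mask.shape != vol.shape:
        raise ValueError("mask and volume grids differ")
    m = mask.data.astype(bool)
    if vol.data.ndim == 4:
        m = m[..., None]
    data = np.where(m, vol.data, background)
    return vol.with_data(data)
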