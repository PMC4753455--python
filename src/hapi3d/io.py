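"""Standard-format readers and writers.

Volumes travel as NIfTI-1 (voxel sizes stored in the header in mm, i.e.
um x 1e-3, with a sidecar JSON recording the original units and
modality). 2D sections travel as PNG or multi-page TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .volumes import SectionSeries, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_section_series",
    "write_section_series",
    "read_training_patches",
    "write_training_patches",
]

_UM_PER_MM = 1000.0


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a Volume as NIfTI-1 plus a JSON sidecar with units/modality."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if vol.modality in ("label", "mask"):
        data = data.astype(np.int32)
    affine = np.diag([vol.voxel_size[0] / _UM_PER_MM,
                      vol.voxel_size[1] / _UM_PER_MM,
                      vol.voxel_size[2] / _UM_PER_MM, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(v / _UM_PER_MM for v in vol.voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    sidecar = {
        "units": "um",
        "voxel_size_um": list(vol.voxel_size),
        "modality": vol.modality,
        "valid_planes": vol.valid_planes.astype(int).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> Volume:
    """Read a Volume written by :func:`write_volume` (or any NIfTI-1)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    voxel_size = tuple(float(z) * _UM_PER_MM for z in zooms)
    modality = "histology"
    valid = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size = tuple(meta.get("voxel_size_um", voxel_size))
        modality = meta.get("modality", modality)
        if "valid_planes" in meta:
            valid = np.asarray(meta["valid_planes"], dtype=bool)
    if modality in ("label", "mask"):
        data = np.rint(data).astype(np.int64 if modality == "label" else np.uint8)
    return Volume(data, voxel_size, modality=modality, valid_planes=valid)


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def write_section_series(series: SectionSeries, directory: str | Path,
                         fmt: str = "png") -> Path:
    """Write each section image plus a manifest JSON into ``directory``.

    ``fmt`` is ``png`` (one file per section) or ``tiff`` (one multi-page
    file ``sections.tif``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    if fmt == "tiff":
        stackfile = directory / "sections.tif"
        tifffile.imwrite(str(stackfile), np.stack([_to_uint8(im) for im in series.images]))
        files = [stackfile.name]
    elif fmt == "png":
        for i, (img, z) in enumerate(zip(series.images, series.z_indices)):
            f = directory / f"section_{z:04d}.png"
            iio.imwrite(f, _to_uint8(img))
            files.append(f.name)
    else:
        raise ValueError(f"unknown section format {fmt!r}")
    manifest = {
        "format": fmt,
        "files": files,
        "z_indices": list(series.z_indices),
        "in_plane_resolution_um": series.in_plane_resolution,
        "section_thickness_um": series.section_thickness,
        "interleave": series.interleave,
        "stain": series.stain,
    }
    (directory / "series.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_section_series(directory: str | Path) -> SectionSeries:
    """Read a section series written by :func:`write_section_series`."""
    directory = Path(directory)
    manifest = json.loads((directory / "series.json").read_text())
    if manifest["format"] == "tiff":
        stack = tifffile.imread(str(directory / manifest["files"][0]))
        images = [np.asarray(stack[i]) for i in range(stack.shape[0])]
    else:
        images = [np.asarray(iio.imread(directory / f)) for f in manifest["files"]]
    return SectionSeries(
        images=images,
        z_indices=manifest["z_indices"],
        in_plane_resolution=manifest["in_plane_resolution_um"],
        section_thickness=manifest["section_thickness_um"],
        interleave=manifest["interleave"],
        stain=manifest.get("stain", "unspecified"),
    )


def write_training_patches(patches, directory: str | Path) -> Path:
    """Write (RGB image, label image) patch pairs as paired PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (img, lab) in enumerate(patches.patches):
        iio.imwrite(directory / f"patch_{i:04d}_image.png", _to_uint8(np.asarray(img)))
        iio.imwrite(directory / f"patch_{i:04d}_labels.png",
                    np.asarray(lab).astype(np.uint8))
        names.append(f"patch_{i:04d}")
    (directory / "patches.json").write_text(json.dumps({"patches": names}))
    return directory


def read_training_patches(directory: str | Path):
    """Read patch pairs written by :func:`write_training_patches`."""
    from .biovision import GroundTruthPatchSet

    directory = Path(directory)
    manifest = json.loads((directory / "patches.json").read_text())
    pairs = []
    for name in manifest["patches"]:
        img = np.asarray(iio.imread(directory / f"{name}_image.png"))
        lab = np.asarray(iio.imread(directory / f"{name}_labels.png"))
        pairs.append((img, lab))
    return GroundTruthPatchSet(pairs)
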