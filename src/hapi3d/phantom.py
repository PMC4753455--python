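"""Synthetic phantom brain: a complete fake study with full ground truth.

The phantom emulates the data layout of a serial-section study of an
amyloid-bearing mouse brain: an ellipsoidal "brain" with nested labeled
regions, a block-face photographic volume with smooth intensity texture,
an MRI-like atlas (intensity + labels) with a small hierarchical
ontology, and per-marker stained RGB section series rendered in a
DAB-like palette (brown deposits on pink tissue, white slide background).
Stain "plaques" are non-overlapping disks seeded per region at a target
density with a rostro-caudal profile (uniform, gradient or hotspot), so
regional loads, per-section transforms and elastic warps all have exact
ground truth for testing every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy import ndimage

from .ontology import Ontology, OntologyNode
from .resample import resample_image
from .transforms import Affine2D, FFD3D
from .volumes import SectionSeries, Volume

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "PhantomDataset",
    "make_phantom",
    "distort_section",
    "make_warped_copy",
    "training_patches",
]

REGION_NAMES = {
    1: "cerebral cortex",
    2: "striatum",
    3: "hippocampal region",
    4: "thalamus",
    5: "white matter",
    6: "basal region",
}

# DAB-like rendering palette (fixed so training patches can be auto-generated)
TISSUE_RGB = np.array([205.0, 160.0, 175.0])   # eosin-like pink
STAIN_RGB = np.array([110.0, 75.0, 45.0])      # DAB brown
BACKGROUND_RGB = np.array([246.0, 246.0, 246.0])
BLOCKFACE_BACKGROUND = 15.0
REGION_BASE_INTENSITY = {1: 170.0, 2: 140.0, 3: 155.0, 4: 130.0, 5: 215.0, 6: 185.0}


@dataclass
class RegionSpec:
    """Stain parameters of one phantom region."""

    density: float          # target stained area fraction in [0, 1]
    z_profile: str = "uniform"   # uniform | gradient | hotspot

    def __post_init__(self):
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        if self.z_profile not in ("uniform", "gradient", "hotspot"):
            raise ValueError(f"unknown z profile {self.z_profile!r}")


def _default_markers() -> dict[str, dict[int, RegionSpec]]:
    # Amyloid-like marker: heavy cortical/hippocampal load, caudal hotspot
    # in the thalamus (the heterogeneous ROI of the sampling analysis),
    # near-absence in white matter; phagocytic-cell-like marker follows the
    # same regional pattern at ~60% density, giving a strong positive
    # regional coupling between the two markers.
    abeta = {
        1: RegionSpec(0.08, "uniform"),
        2: RegionSpec(0.05, "uniform"),
        3: RegionSpec(0.10, "gradient"),
        4: RegionSpec(0.05, "hotspot"),
        5: RegionSpec(0.005, "uniform"),
        6: RegionSpec(0.02, "uniform"),
    }
    cd68 = {k: RegionSpec(round(v.density * 0.6, 4), v.z_profile)
            for k, v in abeta.items()}
    return {"abeta": abeta, "cd68": cd68}


@dataclass
class PhantomSpec:
    """Generator parameters; the defaults define the study conditions.

    Grid 128 x 96 x 60 voxels at 25 x 25 x 125 um mirrors 25-um serial
    sections with block-face photographs every 5th section. Distortion
    ranges emulate the affine component of cutting/mounting deformations.
    """

    dims: tuple[int, int, int] = (128, 96, 60)
    voxel_size: tuple[float, float, float] = (25.0, 25.0, 125.0)
    markers: dict[str, dict[int, RegionSpec]] = field(default_factory=_default_markers)
    blob_radius_um: tuple[float, float] = (40.0, 90.0)
    rotation_range_deg: float = 4.0
    shear_range: float = 0.05
    translation_range_px: float = 12.0
    elastic_amplitude_px: float = 0.0
    elastic_wavelength_px: float = 48.0
    noise_sigma: float = 8.0
    blockface_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for marker in self.markers.values():
            for r in marker.values():
                if not isinstance(r, RegionSpec):
                    raise TypeError("marker regions must be RegionSpec")
        if min(self.blob_radius_um) <= 0:
            raise ValueError("blob radii must be positive")
        for rng_val in (self.rotation_range_deg, self.shear_range,
                        self.translation_range_px, self.elastic_amplitude_px):
            if rng_val < 0:
                raise ValueError("distortion ranges must be non-negative")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _label_volume(dims) -> np.ndarray:
    nx, ny, nz = dims
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.46 * nx, 0.43 * ny, 0.47 * nz

    def rho(ctr, axes):
        return np.sqrt(((x - ctr[0]) / axes[0]) ** 2 + ((y - ctr[1]) / axes[1]) ** 2
                       + ((z - ctr[2]) / axes[2]) ** 2)

    r_brain = rho((cx, cy, cz), (ax, ay, az))
    labels = np.zeros(dims, dtype=np.int32)
    labels[r_brain <= 1.0] = 1                       # cortex (outer shell)
    labels[r_brain <= 0.82] = 5                      # white matter shell
    labels[r_brain <= 0.72] = 6                      # basal interior
    interior = labels == 6
    thal = rho((cx, 0.56 * ny, 0.70 * nz), (0.20 * nx, 0.19 * ny, 0.15 * nz)) <= 1.0
    hipp = rho((cx, 0.40 * ny, 0.52 * nz), (0.25 * nx, 0.17 * ny, 0.16 * nz)) <= 1.0
    stri = rho((cx, 0.46 * ny, 0.28 * nz), (0.23 * nx, 0.21 * ny, 0.19 * nz)) <= 1.0
    labels[interior & thal] = 4
    labels[interior & hipp & ~thal] = 3
    labels[interior & stri & ~thal & ~hipp] = 2
    return labels


def _smooth_texture(dims, rng, sigma_vox=(4.0, 4.0, 1.5), amplitude=25.0) -> np.ndarray:
    field = rng.standard_normal(dims)
    field = ndimage.gaussian_filter(field, sigma_vox)
    field /= max(field.std(), 1e-9)
    return amplitude * field


def _profile_weight(profile: str, z: int, nz: int) -> float:
    if profile == "uniform":
        return 1.0
    if profile == "gradient":
        return 2.0 * (z + 0.5) / nz          # rostral->caudal ramp, mean 1
    # hotspot: narrow caudal bump (near-zero elsewhere)
    center, width = 0.78 * nz, 0.06 * nz
    return float(np.exp(-0.5 * ((z - center) / width) ** 2)) * 6.0


def _place_disks(region2d: np.ndarray, target_fraction: float,
                 radii_px: tuple[float, float], rng) -> tuple[np.ndarray, float]:
    """Seed non-overlapping disks clipped to a 2D region mask.

    Returns the stained mask and the analytic (un-clipped) disk area sum.
    """
    stained = np.zeros_like(region2d, dtype=bool)
    area = int(region2d.sum())
    target = target_fraction * area
    if target < 1 or area == 0:
        return stained, 0.0
    idx = np.argwhere(region2d)
    h, w = region2d.shape
    yy, xx = np.mgrid[0:h, 0:w]
    placed = 0.0
    analytic = 0.0
    tries = 0
    max_tries = 200 + int(20 * target)
    while placed < target and tries < max_tries:
        tries += 1
        cy, cx = idx[rng.integers(len(idx))]
        r = rng.uniform(*radii_px)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        disk &= region2d
        if (disk & stained).any():
            continue
        stained |= disk
        placed += disk.sum()
        analytic += np.pi * r ** 2
    return stained, analytic


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _anatomy(labels: np.ndarray, texture: np.ndarray) -> np.ndarray:
    """Noise-free anatomical intensity: region base levels + smooth texture."""
    base = np.full(labels.shape, BLOCKFACE_BACKGROUND)
    for lab, inten in REGION_BASE_INTENSITY.items():
        base[labels == lab] = inten
    tissue = labels > 0
    return np.clip(base + np.where(tissue, texture, 0.0), 0, 255)


def _render_section(labels2d: np.ndarray, stain2d: np.ndarray,
                    anat2d: np.ndarray, rng, noise_sigma: float) -> np.ndarray:
    """Render one RGB histology section from the anatomical underlay.

    ``anat2d`` is the noise-free block-face intensity (region contrast +
    texture); the eosin shade darkens where the underlay brightens, so
    inverted histology luminance correlates with the block-face — the
    monomodal assumption of the section-to-photo registration.
    """
    h, w = labels2d.shape
    img = np.empty((h, w, 3))
    img[:] = BACKGROUND_RGB
    tissue = labels2d > 0
    shade = 1.0 - (anat2d - 170.0) / 255.0 * 0.8
    for c in range(3):
        channel = img[..., c]
        channel[tissue] = np.clip(TISSUE_RGB[c] * shade[tissue], 0, 255)
        channel[stain2d] = STAIN_RGB[c]
    img += rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0, 255)


# ---------------------------------------------------------------------------
# distortion
# ---------------------------------------------------------------------------

def distort_section(image: np.ndarray, truth_mask: np.ndarray, spec: PhantomSpec,
                    seed: int):
    """Apply a sampled affine (+ optional elastic) distortion to a section.

    The same geometric transform is applied to the RGB image and its
    ground-truth stain mask. Returns
    ``(image', mask', affine_true, elastic_field_true)`` where
    ``affine_true`` maps undistorted (reference) world coordinates into
    the distorted image — exactly the transform a section-to-block-face
    registration must recover — and ``elastic_field_true`` is the
    additional displacement field (px), zero when the elastic amplitude
    is zero.
    """
    rng = np.random.default_rng(seed)
    res = spec.voxel_size[0]
    rot = np.deg2rad(rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg))
    shear = rng.uniform(-spec.shear_range, spec.shear_range)
    trans = rng.uniform(-spec.translation_range_px, spec.translation_range_px, 2)
    c, s = np.cos(rot), np.sin(rot)
    mat = np.array([[c, -s], [s, c]]) @ np.array([[1.0, shear], [0.0, 1.0]])
    center = 0.5 * np.asarray(image.shape[:2], dtype=float) * res
    affine_true = Affine2D(mat, trans * res, center=center)
    inv = affine_true.inverse()

    if spec.elastic_amplitude_px > 0:
        h, w = image.shape[:2]
        i0, i1 = np.mgrid[0:h, 0:w].astype(float)
        k = 2 * np.pi / spec.elastic_wavelength_px
        phase = rng.uniform(0, 2 * np.pi, 4)
        e0 = spec.elastic_amplitude_px * np.sin(k * i1 + phase[0]) * np.cos(k * i0 + phase[1])
        e1 = spec.elastic_amplitude_px * np.sin(k * i0 + phase[2]) * np.cos(k * i1 + phase[3])
        elastic = np.stack([e0, e1], axis=-1)

        def warp(img2d, order):
            # distorted(y) = original at inv(y) + elastic(y), in pixel units
            pts = (np.stack([i0.ravel(), i1.ravel()], axis=-1) + 0.5) * res
            src = inv.apply(pts) / res - 0.5
            src = src + elastic.reshape(-1, 2)
            out = ndimage.map_coordinates(img2d.astype(float), src.T, order=order,
                                          mode="constant", cval=0.0)
            return out.reshape(h, w)
    else:
        elastic = np.zeros(image.shape[:2] + (2,))

        def warp(img2d, order):
            return resample_image(img2d, inv, res,
                                  mode="linear" if order else "nearest",
                                  background=0.0)

    if image.ndim == 3:
        img_out = np.stack([warp(image[..., ch], 1) for ch in range(3)], axis=-1)
        # out-of-field pixels take the slide background color
        off = warp(np.ones(image.shape[:2]), 1) < 0.5
        img_out[off] = BACKGROUND_RGB
    else:
        img_out = warp(image, 1)
    mask_out = warp(truth_mask.astype(float), 0) > 0.5
    return img_out, mask_out.astype(np.uint8), affine_true, elastic


def make_warped_copy(vol: Volume, amplitude_vox: float = 3.0,
                     grid_shape=(6, 6, 6), seed: int = 0,
                     background: float = 0.0) -> tuple[Volume, FFD3D]:
    """Warp a volume with a known smooth random FFD (for recovery tests).

    Returns the warped volume and the true transform mapping the warped
    (reference) space into the original volume — the transform a
    registration of ``vol`` onto the warped copy should recover.
    """
    rng = np.random.default_rng(seed)
    vox = np.asarray(vol.voxel_size)
    ctrl = rng.uniform(-amplitude_vox, amplitude_vox, tuple(grid_shape) + (3,))
    ctrl = ndimage.gaussian_filter(ctrl, sigma=(1.0, 1.0, 1.0, 0.0))
    # zero displacement at the lattice border keeps the warp inside the FOV
    for a in range(3):
        sl = [slice(None)] * 4
        sl[a] = 0
        ctrl[tuple(sl)] = 0.0
        sl[a] = -1
        ctrl[tuple(sl)] = 0.0
    ctrl_world = ctrl * vox[None, None, None, :]
    ffd = FFD3D(ctrl_world, vol.world_extent())
    from .resample import resample
    mode = "nearest" if vol.modality in ("label", "mask") else "linear"
    warped = resample(vol, ffd, mode=mode, background=background)
    warped.valid_planes = vol.valid_planes.copy()
    return warped, ffd


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _default_ontology() -> Ontology:
    root = OntologyNode("brain", "Br", children=[
        OntologyNode("telencephalon", "Tel", children=[
            OntologyNode("cerebral cortex", "Cx", labels=[1]),
            OntologyNode("striatum", "Str", labels=[2]),
            OntologyNode("hippocampal region", "HiR", labels=[3]),
            OntologyNode("white matter", "WM", labels=[5]),
        ]),
        OntologyNode("diencephalon", "Die", children=[
            OntologyNode("thalamus", "Thal", labels=[4]),
            OntologyNode("basal region", "Bas", labels=[6]),
        ]),
    ])
    return Ontology(root)


@dataclass
class PhantomDataset:
    """All phantom outputs plus serialized ground truth."""

    spec: PhantomSpec
    blockface: Volume
    atlas_intensity: Volume
    atlas_labels: Volume
    labels: Volume               # true parcellation on the block-face grid
    ontology: Ontology
    series: dict[str, SectionSeries]
    truth_masks: dict[str, Volume]            # undistorted, block-face grid
    distorted_masks: dict[str, Volume]        # aligned with distorted sections
    true_section_transforms: dict[str, list[Affine2D]]
    true_region_loads: dict[str, dict[str, float]]
    analytic_region_loads: dict[str, dict[str, float]]
    manifest: dict


def make_phantom(spec: PhantomSpec | None = None) -> PhantomDataset:
    """Build the full synthetic study (deterministic given ``spec.seed``)."""
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.dims
    labels_arr = _label_volume(spec.dims)
    brain_fraction = (labels_arr > 0).mean()
    if brain_fraction < 0.05:
        raise ValueError("phantom regions exceed/escape the brain volume")
    rng = np.random.default_rng(spec.seed)

    texture = _smooth_texture(spec.dims, rng)
    anat = _anatomy(labels_arr, texture)
    blockface = Volume(
        np.clip(anat + rng.normal(0.0, spec.blockface_noise_sigma, spec.dims), 0, 255),
        spec.voxel_size, modality="blockface")
    labels = Volume(labels_arr, spec.voxel_size, modality="label")

    # MRI-like atlas: same anatomy, remapped intensities (multimodal pair)
    mri = 255.0 * (anat / 255.0) ** 0.5
    mri = ndimage.gaussian_filter(mri, (1.0, 1.0, 0.3))
    atlas_intensity = Volume(mri, spec.voxel_size, modality="mri")
    atlas_labels = Volume(labels_arr.copy(), spec.voxel_size, modality="label")

    radii_px = tuple(r / spec.voxel_size[0] for r in spec.blob_radius_um)
    ontology = _default_ontology()

    series: dict[str, SectionSeries] = {}
    truth_masks: dict[str, Volume] = {}
    distorted_masks: dict[str, Volume] = {}
    true_tf: dict[str, list[Affine2D]] = {}
    true_loads: dict[str, dict[str, float]] = {}
    analytic_loads: dict[str, dict[str, float]] = {}

    for marker, regions in spec.markers.items():
        stain3d = np.zeros(spec.dims, dtype=np.uint8)
        analytic_area = {lab: 0.0 for lab in regions}
        for z in range(nz):
            lab2d = labels_arr[:, :, z]
            for lab, rs in regions.items():
                w = _profile_weight(rs.z_profile, z, nz)
                frac = min(rs.density * w, 0.9)
                if frac <= 0:
                    continue
                region2d = lab2d == lab
                if not region2d.any():
                    continue
                disks, analytic = _place_disks(region2d, frac, radii_px, rng)
                stain3d[:, :, z] |= disks.astype(np.uint8)
                analytic_area[lab] += analytic
        truth_masks[marker] = Volume(stain3d, spec.voxel_size, modality="mask")

        loads = {}
        ana = {}
        for lab, name in REGION_NAMES.items():
            region = labels_arr == lab
            n_region = int(region.sum())
            n_st = int((stain3d.astype(bool) & region).sum())
            loads[name] = 100.0 * n_st / n_region if n_region else 0.0
            ana[name] = 100.0 * analytic_area[lab] / n_region if n_region else 0.0
        true_loads[marker] = loads
        analytic_loads[marker] = ana

        images, masks_d, tfs = [], [], []
        dist3d = np.zeros(spec.dims, dtype=np.uint8)
        for z in range(nz):
            img = _render_section(labels_arr[:, :, z], stain3d[:, :, z].astype(bool),
                                  anat[:, :, z], rng, spec.noise_sigma)
            sec_seed = int(rng.integers(0, 2 ** 31 - 1))
            img_d, mask_d, tf, _ = distort_section(img, stain3d[:, :, z], spec, sec_seed)
            images.append(img_d)
            masks_d.append(mask_d)
            tfs.append(tf)
            dist3d[:, :, z] = mask_d
        series[marker] = SectionSeries(images, list(range(nz)),
                                       in_plane_resolution=spec.voxel_size[0],
                                       section_thickness=spec.voxel_size[2] / 5.0,
                                       interleave=5, stain=marker)
        distorted_masks[marker] = Volume(dist3d, spec.voxel_size, modality="mask")
        true_tf[marker] = tfs

    manifest = {
        "seed": spec.seed,
        "dims": list(spec.dims),
        "voxel_size_um": list(spec.voxel_size),
        "markers": list(spec.markers),
        "brain_fraction": float(brain_fraction),
        "true_region_loads_percent": true_loads,
        "distortion_ranges": {
            "rotation_deg": spec.rotation_range_deg,
            "shear": spec.shear_range,
            "translation_px": spec.translation_range_px,
            "elastic_px": spec.elastic_amplitude_px,
        },
        "noise_sigma": spec.noise_sigma,
    }
    return PhantomDataset(spec, blockface, atlas_intensity, atlas_labels, labels,
                          ontology, series, truth_masks, distorted_masks,
                          true_tf, true_loads, analytic_loads, manifest)


def training_patches(dataset: PhantomDataset, marker: str, n_patches: int = 12,
                     patch_size: int = 48, seed: int = 0):
    """Auto-generate expert-like annotated patches from undistorted sections.

    Labels derive from the generator's ground truth: stained where the
    truth mask is set, unstained elsewhere in tissue, background outside.
    Returns a :class:`~hapi3d.biovision.GroundTruthPatchSet`.
    """
    from .biovision import GroundTruthPatchSet

    rng = np.random.default_rng(seed)
    spec = dataset.spec
    labels_arr = dataset.labels.data
    stain = dataset.truth_masks[marker].data.astype(bool)
    nz = spec.dims[2]
    # re-render sections undistorted with an independent noise stream
    tex_rng = np.random.default_rng(spec.seed + 10_000)
    anat = _anatomy(labels_arr, _smooth_texture(spec.dims, tex_rng))
    patches = []
    for _ in range(n_patches):
        z = int(rng.integers(nz // 4, 3 * nz // 4))
        img = _render_section(labels_arr[:, :, z], stain[:, :, z],
                              anat[:, :, z], rng, spec.noise_sigma)
        h, w = img.shape[:2]
        x0 = int(rng.integers(0, max(h - patch_size, 1)))
        y0 = int(rng.integers(0, max(w - patch_size, 1)))
        sub = img[x0:x0 + patch_size, y0:y0 + patch_size]
        lab2d = labels_arr[x0:x0 + patch_size, y0:y0 + patch_size, z]
        st2d = stain[x0:x0 + patch_size, y0:y0 + patch_size, z]
        lab = np.full(sub.shape[:2], 2, dtype=np.uint8)   # unstained tissue
        lab[lab2d == 0] = 3                               # background
        lab[st2d] = 1                                     # stained
        patches.append((sub, lab))
    return GroundTruthPatchSet(patches)


def write_phantom(dataset: PhantomDataset, out_dir: str | Path) -> Path:
    """Serialize the full phantom dataset + ground-truth manifest to disk."""
    from . import io as hio
    from .transforms import save_transform

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_volume(dataset.blockface, out / "blockface.nii.gz")
    hio.write_volume(dataset.atlas_intensity, out / "atlas_intensity.nii.gz")
    hio.write_volume(dataset.atlas_labels, out / "atlas_labels.nii.gz")
    hio.write_volume(dataset.labels, out / "labels.nii.gz")
    dataset.ontology.save(out / "ontology.json")
    for marker, ser in dataset.series.items():
        hio.write_section_series(ser, out / f"sections_{marker}")
        hio.write_volume(dataset.truth_masks[marker], out / f"truth_{marker}.nii.gz")
        tdir = out / f"true_transforms_{marker}"
        tdir.mkdir(exist_ok=True)
        for i, tf in enumerate(dataset.true_section_transforms[marker]):
            save_transform(tf, tdir / f"section_{i:04d}.json")
    (out / "manifest.json").write_text(json.dumps(dataset.manifest, indent=1))
    return out
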