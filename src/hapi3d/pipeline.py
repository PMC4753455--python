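"""End-to-end 3D histopathology pipeline.

Chains the full workflow on one animal: stack and register the stained
serial sections onto the block-face reference, segment the stainings
with a trained pixel classifier, parcellate the brain by atlas
registration, quantify marker load over the anatomical hierarchy, build
and smooth occupancy heat maps, correlate markers voxel-wise, and
simulate sparse 2D section sampling. Every run emits a JSON-serializable
manifest recording the configuration, per-stage reports and SHA-256
digests of all derived volumes, so two runs from the same inputs and
seed can be compared bit-for-bit.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .biovision import BioVisionModel
from .heatmap import HeatMap, aggregate, correlate, smooth
from .ontology import Ontology, ontology_quantify, parcellate, quantifications_to_frame
from .blockmatch import InsufficientDataError
from .register import register_section
from .resample import resample_image
from .sampling import sampling_simulation, simulation_to_frame
from .transforms import Affine2D
from .volumes import SectionSeries, Volume, auto_mask_blockface

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError",
           "reconstruct_series", "segment_series", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run parameters (all lengths in micrometres).

    section_levels:
        Resolution levels of the 2D section-to-block-face pyramid.
    ffd_grid / ffd_maxiter:
        Control lattice and iteration cap of the elastic atlas match.
    gmm_components:
        Gaussian mixture components per pixel class (recorded for the
        manifest; training itself happens before the pipeline runs).
    heatmap_voxel_um:
        Isotropic edge length of the occupancy heat-map voxels.
    smoothing_kernel:
        ``sigma`` (one heat-map voxel as Gaussian sigma) or ``fwhm``.
    sampling_steps:
        Inter-section spacings ``k`` simulated for the 2D-sampling error.
    section_background:
        Fill intensity for reconstructed pixels outside the section
        (bright, like an empty slide).
    seed:
        Recorded in the manifest; the pipeline itself is deterministic
        given its inputs, the seed identifies the upstream data/training
        stream.
    """

    section_levels: int = 3
    ffd_grid: tuple[int, int, int] = (10, 10, 10)
    ffd_maxiter: int = 60
    gmm_components: int = 3
    heatmap_voxel_um: float = 125.0
    smoothing_kernel: str = "sigma"
    sampling_steps: tuple[int, ...] = (1, 5, 10, 15)
    section_background: float = 255.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {"section_levels": self.section_levels,
                "ffd_grid": list(self.ffd_grid),
                "ffd_maxiter": self.ffd_maxiter,
                "gmm_components": self.gmm_components,
                "heatmap_voxel_um": self.heatmap_voxel_um,
                "smoothing_kernel": self.smoothing_kernel,
                "sampling_steps": list(self.sampling_steps),
                "section_background": self.section_background,
                "seed": self.seed}


@dataclass
class PipelineResult:
    """All pipeline outputs plus the run manifest."""

    reconstructed: dict[str, Volume]
    section_transforms: dict[str, list[Affine2D]]
    segmentations: dict[str, Volume]
    labels: Volume
    quantifications: dict[str, list]
    heatmaps: dict[str, HeatMap]
    correlations: dict[str, dict]
    sampling: dict[str, list]
    manifest: dict = field(default_factory=dict)


def _sha256(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(arr)
    return hashlib.sha256(a.tobytes()).hexdigest()


def _section_gray(img: np.ndarray) -> np.ndarray:
    """Inverted luminance: tissue bright, slide dark, like the block-face."""
    lum = img.mean(axis=-1) if img.ndim == 3 else img.astype(float)
    return 255.0 - lum


def reconstruct_series(blockface: Volume, series: SectionSeries,
                       mask: Volume | None = None, n_levels: int = 3,
                       background: float = 255.0
                       ) -> tuple[Volume, list[Affine2D], list[dict]]:
    """Register every section to its block-face plane and stack the result.

    Each section's inverted luminance is block-matched against the
    corresponding block-face photograph on a coarse-to-fine pyramid; the
    RGB image is then resampled through the recovered affine onto the
    block-face grid. Planes without a section are flagged invalid and
    filled with ``background``.

    Returns the reconstructed RGB volume (block-face geometry), the
    per-section transforms (block-face world -> section world) and the
    per-section registration reports.
    """
    nx, ny, nz = blockface.shape[:3]
    res = float(series.in_plane_resolution)
    if not np.allclose((blockface.voxel_size[0], blockface.voxel_size[1]),
                       (res, res)):
        raise ValueError("section resolution differs from the block-face "
                         "in-plane resolution; rescale the series first")
    data = np.full((nx, ny, nz, 3), background, dtype=float)
    valid = np.zeros(nz, dtype=bool)
    transforms: list[Affine2D] = []
    reports: list[dict] = []
    for img, z in zip(series.images, series.z_indices):
        if not (0 <= z < nz):
            raise ValueError(f"section plane index {z} outside block-face stack")
        ref = blockface.plane(int(z)).astype(float)
        ref_mask = mask.plane(int(z)).astype(bool) if mask is not None else None
        try:
            tf, rep = register_section(ref, _section_gray(img), resolution=res,
                                       n_levels=n_levels, ref_mask=ref_mask)
            rep_d = rep.to_dict()
        except InsufficientDataError:
            # near-empty plane (tip of the brain): keep the section as-is
            tf = Affine2D.identity()
            rep_d = {"metric_name": "correlation_coefficient",
                     "converged": False, "fallback": "identity"}
        warped = resample_image(np.asarray(img, dtype=float), tf, res,
                                target_shape=(nx, ny), background=background)
        if warped.ndim == 2:
            warped = np.stack([warped] * 3, axis=-1)
        data[:, :, int(z)] = warped
        valid[int(z)] = True
        transforms.append(tf)
        reports.append(rep_d)
    vol = Volume(np.clip(data, 0, 255), blockface.voxel_size,
                 modality="histology", valid_planes=valid)
    return vol, transforms, reports


def segment_series(series: SectionSeries, transforms: list[Affine2D],
                   model: BioVisionModel, blockface: Volume) -> Volume:
    """Classify each section in native geometry, then warp the stain masks.

    Pixel classification runs on the original section images (so the
    classifier never sees interpolated colors, which blur small stained
    objects below the decision boundary); the resulting binary masks are
    pulled onto the block-face grid with nearest-neighbor resampling.
    """
    from .biovision import classify

    nx, ny, nz = blockface.shape[:3]
    res = float(series.in_plane_resolution)
    data = np.zeros((nx, ny, nz), dtype=np.uint8)
    valid = np.zeros(nz, dtype=bool)
    for img, z, tf in zip(series.images, series.z_indices, transforms):
        pred = (classify(np.asarray(img, dtype=float), model) == 1).astype(float)
        warped = resample_image(pred, tf, res, target_shape=(nx, ny),
                                mode="nearest", background=0.0)
        data[:, :, int(z)] = warped > 0.5
        valid[int(z)] = True
    return Volume(data, blockface.voxel_size, modality="mask", valid_planes=valid)


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with the stage name."""
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False
    return _Guard()


def run_pipeline(blockface: Volume,
                 series: dict[str, SectionSeries],
                 atlas_intensity: Volume,
                 atlas_labels: Volume,
                 ontology: Ontology,
                 models: dict[str, BioVisionModel],
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full reconstruction-to-quantification pipeline on one animal.

    ``series`` and ``models`` are keyed by marker name (one trained
    classifier per staining). When ``out_dir`` is given, all derived
    volumes, tables and ``manifest.json`` are written there.

    Raises
    ------
    PipelineError
        Any stage failure, tagged with the stage name.
    """
    cfg = config or PipelineConfig()
    markers = sorted(series)
    missing = [m for m in markers if m not in models]
    if missing:
        raise PipelineError("segment", f"no classifier for markers {missing}")

    manifest: dict = {"version": __version__, "config": cfg.to_dict(),
                      "markers": markers, "stages": {}}

    with _stage("mask"):
        mask = auto_mask_blockface(blockface)
        manifest["stages"]["mask"] = {
            "tissue_voxels": int(mask.data.sum()),
            "sha256": _sha256(mask.data)}

    reconstructed, section_tf, seg_vols = {}, {}, {}
    with _stage("reconstruct"):
        recon_info = {}
        for m in markers:
            vol, tfs, reps = reconstruct_series(
                blockface, series[m], mask=mask, n_levels=cfg.section_levels,
                background=cfg.section_background)
            reconstructed[m] = vol
            section_tf[m] = tfs
            recon_info[m] = {
                "n_sections": len(tfs),
                "section_reports": reps,
                "sha256": _sha256(vol.data)}
        manifest["stages"]["reconstruct"] = recon_info

    with _stage("segment"):
        seg_info = {}
        for m in markers:
            seg = segment_series(series[m], section_tf[m], models[m], blockface)
            seg_vols[m] = seg
            seg_info[m] = {"stained_voxels": int(seg.data.sum()),
                           "sha256": _sha256(seg.data)}
        manifest["stages"]["segment"] = seg_info

    with _stage("parcellate"):
        labels_bf = parcellate(atlas_intensity, atlas_labels, blockface,
                               mask=mask.data.astype(bool),
                               ffd_grid=cfg.ffd_grid,
                               ffd_maxiter=cfg.ffd_maxiter)
        manifest["stages"]["parcellate"] = {
            "labels_present": [int(v) for v in np.unique(labels_bf.data) if v > 0],
            "sha256": _sha256(labels_bf.data)}

    quants = {}
    with _stage("quantify"):
        q_info = {}
        for m in markers:
            # align the segmentation's valid planes with the label volume
            seg_vols[m].valid_planes &= labels_bf.valid_planes
            qs = ontology_quantify(seg_vols[m], labels_bf, ontology,
                                   warn_orphans=False)
            quants[m] = qs
            q_info[m] = {q.path: {"load_percent": q.load,
                                  "region_voxels": q.region_voxels,
                                  "stained_voxels": q.stained_voxels}
                         for q in qs}
        manifest["stages"]["quantify"] = q_info

    heatmaps = {}
    with _stage("heatmap"):
        hm_info = {}
        for m in markers:
            hm = smooth(aggregate(seg_vols[m], cfg.heatmap_voxel_um,
                                  tissue_mask=mask),
                        kernel=cfg.smoothing_kernel)
            heatmaps[m] = hm
            hm_info[m] = {"global_load_percent": hm.global_load_percent(),
                          "shape": list(hm.volume.shape),
                          "sha256": _sha256(hm.data)}
        manifest["stages"]["heatmap"] = hm_info

    correlations: dict[str, dict] = {}
    with _stage("correlate"):
        for a, b in itertools.combinations(markers, 2):
            r = correlate(heatmaps[a], heatmaps[b])
            correlations[f"{a}|{b}"] = {"rho": r.rho, "p_value": r.p_value,
                                        "n_voxels": r.n_voxels}
        manifest["stages"]["correlate"] = correlations

    sampling = {}
    with _stage("sampling"):
        s_info = {}
        roi_all = sorted(ontology.all_labels)
        for m in markers:
            res = sampling_simulation(seg_vols[m], labels_bf, roi_all,
                                      steps=cfg.sampling_steps)
            sampling[m] = res
            s_info[m] = [{"k": r.step_k, "spacing_mm": r.spacing_mm,
                          "n_subsets": len(r.subset_loads),
                          "reference_load": r.reference_load,
                          "median_re": r.median_re} for r in res]
        manifest["stages"]["sampling"] = s_info

    result = PipelineResult(reconstructed, section_tf, seg_vols, labels_bf,
                            quants, heatmaps, correlations, sampling, manifest)
    if out_dir is not None:
        _write_outputs(result, blockface, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, blockface: Volume, out: Path) -> None:
    from . import io as hio

    out.mkdir(parents=True, exist_ok=True)
    hio.write_volume(blockface, out / "blockface.nii.gz")
    hio.write_volume(result.labels, out / "labels.nii.gz")
    for m in sorted(result.reconstructed):
        hio.write_volume(result.reconstructed[m], out / f"{m}_reconstructed.nii.gz")
        hio.write_volume(result.segmentations[m], out / f"{m}_segmentation.nii.gz")
        hm = result.heatmaps[m]
        hio.write_volume(hm.volume, out / f"{m}_heatmap.nii.gz")
        quantifications_to_frame(result.quantifications[m]).to_csv(
            out / f"{m}_quantification.csv", index=False)
        simulation_to_frame(result.sampling[m], roi="brain", animal="").to_csv(
            out / f"{m}_sampling.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
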