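# hapi3d

3D whole-brain quantitative histopathology for rodent brains.

`hapi3d` reconstructs a stack of serially sectioned, stained histology
images into the 3D space of a block-face photograph volume, registers a
labeled reference atlas onto it, segments the stained pixels with a
trainable Gaussian-mixture color/texture classifier, and derives
quantitative read-outs: per-region stain loads over an anatomical
ontology, low-resolution 3D occupancy heat maps, inter-marker spatial
correlations, and simulations of how sparse section sampling degrades
load estimates. A fully synthetic phantom with known ground truth
(anatomy, stain masks, per-section distortions) exercises every stage,
so the whole pipeline can be validated quantitatively without any image
data.

## Quick start

```python
from hapi3d.phantom import PhantomSpec, make_phantom, training_patches
from hapi3d.biovision import fit_model
from hapi3d.pipeline import PipelineConfig, run_pipeline

ds = make_phantom(PhantomSpec(seed=0))        # 128x96x60 @ 25x25x125 um
models = {
    m: fit_model(training_patches(ds, m, n_patches=12, seed=1), seed=0)
    for m in ("abeta", "cd68")
}
result = run_pipeline(ds.blockface, ds.series, ds.atlas_intensity,
                      ds.atlas_labels, ds.ontology, models,
                      config=PipelineConfig(seed=0))
print(result.quantifications["abeta"][0])     # whole-brain amyloid load
print(result.correlations["abeta|cd68"])     # marker co-localization
```

The same workflow is available on the command line:

```bash
hapi3d phantom --out data --seed 0
hapi3d train --patches data/patches_abeta --out model.json
hapi3d run --data data --out results --seed 0
```

## What the numbers look like

On the default phantom (seed 0, section noise σ = 8 gray levels,
per-section distortions up to 4° rotation, 5% shear, 12 px translation):

- 2D section-to-blockface registration recovers the known affine
  distortions with a mean landmark error of **0.74 px** over 54 sections;
- a known 3D rigid motion (3°, −2°, 1.5°; 40, −30, 60 µm) is recovered
  within **0.07°** and **0.005 voxel**;
- a known smooth deformation (4-voxel sinusoidal field) is recovered with
  **93%** residual reduction;
- the stained-pixel classifier reaches **F1 = 1.00** against the
  generating masks on held-out noisy sections;
- ontology roll-ups conserve voxel counts exactly, and the unsmoothed
  heat map's coverage-weighted mean reproduces the whole-brain load to
  < 1e-9 percent;
- sampling simulation: a z-uniform stain keeps the median load error
  < 0.1% for every 1-in-k section scheme up to k = n/3, while a caudal
  hotspot degrades to a 73% median error at k = 15 — quantifying why
  sparse sampling fails for focal pathology;
- two pipeline runs with the same seed produce bit-identical manifests
  (sha256 of every derived volume).

## Package layout

| Module | Contents |
|---|---|
| `hapi3d.volumes` | `Volume`, `SectionSeries`, stacking, block-face auto-masking |
| `hapi3d.transforms` | 2D/3D affine, rigid, B-spline FFD, composition, (de)serialization |
| `hapi3d.metrics` | correlation coefficient, mutual information (hard and soft-binned) |
| `hapi3d.blockmatch` | multi-scale block matching with trimmed least-squares model fits |
| `hapi3d.register` | 2D section, 3D rigid/affine, and FFD registration drivers |
| `hapi3d.resample` | world-coordinate resampling of images and volumes |
| `hapi3d.biovision` | GMM color/texture pixel classifier, F1 evaluation |
| `hapi3d.ontology` | hierarchical region ontology, load quantification, parcellation |
| `hapi3d.heatmap` | occupancy heat maps, masked smoothing, Spearman correlation |
| `hapi3d.sampling` | rostrocaudal profiles, subset enumeration, sampling simulation, group tests |
| `hapi3d.phantom` | synthetic ground-truth dataset generator |
| `hapi3d.pipeline` | end-to-end orchestration with stage-named errors and manifests |
| `hapi3d.cli` | `hapi3d` command-line interface |

See `docs/methods.md` for the underlying models, conventions and
parameter choices.
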