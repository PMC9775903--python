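# voxenc

Voxel-wise fMRI visual encoding with a **mixed large/small-kernel
convolutional feature space**.

Visual encoding models predict brain responses (fMRI voxels) to image
stimuli. The standard two-step recipe extracts image features with a
pretrained convolutional network and maps them to each voxel with a linear
model. Small-kernel networks such as VGG16 have effective receptive fields
(ERFs) that stay small even at depth, while population receptive fields in
higher visual cortex are several times larger than in V1–V3. `voxenc`
implements an encoding model whose feature space mixes a small-kernel
VGG16-style backbone with a large-kernel RepLKNet-style backbone (depthwise
kernels up to 31×31 with structural reparameterization), so the feature
space carries receptive fields of many sizes at once.

It is aimed at computational neuroscientists who want to run, test, or
extend this class of encoding model at desk scale — everything works with
seeded random weights and synthetic data; pretrained weights and real fMRI
datasets can be plugged in through the same containers.

## Model

For each voxel, responses are modeled as a sparse linear function of image
features:

```
v = F w + b,          Pcc = cor(v, v̂)
```

where `F` is the m×n feature matrix (m stimuli, n features, typically
n ≫ m). The pipeline is:

1. **V features** — six layers from the VGG16-style backbone (the five
   block outputs and the final pooled output:
   64×224×224 … 512×7×7 for a 224×224 input).
2. **R features** — five layers from the RepLKNet-style backbone (four
   stage outputs, 128×56×56 … 1024×7×7, plus an L2-normalized copy of the
   deepest stage).
3. **M features** — per-image concatenation [V ‖ R] with equal weighting.
4. **PCA** to at most m−1 components (lossless on the training set).
5. **ROMP** (regularized orthogonal matching pursuit) per voxel: greedy
   selection of comparable-magnitude correlated components, least-squares
   re-solves on the growing support.
6. **Evaluation** — per-voxel Pearson correlation on repeat-averaged test
   responses; voxels with Pcc > 0.41 count as validly predicted; ROIs
   (V1–V4, LOC, FFA, PPA, and the LVC/HVC/VC groups) are summarized by
   their top-100 mean Pcc.

The `erf` module quantifies effective receptive fields by backpropagating
from the central unit of the deepest feature tap to the input pixels and
summarizing the contribution-score heatmap by the smallest centered square
holding 95% of its mass.

## Worked example

Generate a desk-scale synthetic fixture (120 training images at 32×32 in 30
Gabor-texture categories, 10 test images shown 35 times, 14 voxels across 7
ROIs, noise σ = 0.5) and run the full pipeline:

```bash
voxenc simulate --preset reduced --seed 3 --out fixture/
voxenc run --fixture fixture/ --out results/ --seed 3
```

The run prints a manifest like:

```json
{
  "seed": 3,
  "pca_components": 119,
  "n_voxels": 14,
  "n_valid": 6,
  "mean_pcc": 0.381,
  "min_pcc": -0.131,
  "stage_seconds": {"features": 0.005, "pca": 0.026, "fit": 0.046, "evaluate": 0.008}
}
```

Six of the 14 voxels clear the 0.41 validity rule here: with only 119
principal components and a support budget of 40, the fit captures part of
each voxel's sparse signal, and trial noise (σ = 0.5) caps attainable
correlations. `results/summary.csv` holds the per-ROI top-n mean Pcc table
and `results/results.csv` the per-voxel correlations, validity flags and
ROI labels. In the noiseless well-posed regime (`--preset wellposed`,
where training samples outnumber features) every voxel is recovered with
Pcc ≈ 1.0.

Effective receptive fields:

```bash
voxenc erf --backbone replknet --variant reduced --probes 8 --out erf/
# {"backbone": "replknet-reduced", "erf_size": 31}
```

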