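# Methods

This note documents the model, the numerical choices, and the synthetic
test bed behind `voxenc`, in the spirit of a package methods appendix.

## Backbones

Two convolutional feature extractors are built as explicit layer graphs
with named tap points.

**VGG16-style (small kernels).** Thirteen 3×3 same-padding convolutions in
five blocks (2×64, 2×128, 3×256, 3×512, 3×512 channels), ReLU after every
convolution, 2×2 max-pooling between blocks. Six taps: each block output
plus the output of the last block after the final pool. For a 3×224×224
input the tap shapes are 64×224×224, 128×112×112, 256×56×56, 512×28×28,
512×14×14 and 512×7×7. The classifier's fully connected layers play no
role in feature extraction and are not part of the graph.

**RepLKNet-style (large kernels).** One stem (stride-4 total: a 3×3
stride-2 convolution, a depthwise 3×3, a 1×1 mixer, a depthwise 3×3
stride-2), four stages with channels 128/256/512/1024 (the 31B-style
ladder), and transition blocks (1×1 channel doubling + depthwise 3×3
stride-2) between stages. Each stage block is a residual unit:
BN → depthwise large-kernel convolution (stage kernels 31/29/27/13) with a
parallel depthwise 5×5 branch, each branch batch-normalized → ReLU → 1×1
mixer. Taps at the four stage outputs give 56/28/14/7 spatial sizes for a
224×224 input. Two blocks per stage are used by default; the published
reference model stacks more blocks (and interleaves ConvFFN units), but
block count does not change tap geometry, kernel structure, or any
property this package measures, and two keeps desk-scale runtimes. Source
descriptions of this architecture print the first-stage width as "125" and
one spatial size as "28V28"; these are treated as typographical artifacts
of 128 and 28×28 (the only values consistent with the stated channel
ladder and downsampling), and the fifth R-feature layer printed once as
1027×7×7 is implemented as 1024×7×7 — a normalization layer cannot add
channels.

**Structural reparameterization.** The two depthwise branches are
algebraically fused for inference: batch normalization is folded into each
kernel (`w ← w·γ/√(σ²+ε)`, `b ← β − μ·γ/√(σ²+ε)`), the small kernel is
zero-padded symmetrically to the large kernel size, and kernels and biases
are summed. Fused and two-branch forwards agree to ~1e−15 relative; the
contract is 1e−4.

**Engine.** Both graphs run on a small inference-only NumPy convolution
engine (float64): im2col + BLAS matmul for dense/grouped convolutions,
shift-and-accumulate for depthwise kernels (O(output) memory even at
31×31), frozen batch normalization, non-overlapping max pooling, residual
units. Every layer implements the input-side vector-Jacobian product, which
the ERF probe consumes. Weight initialization is seeded He/fan-in normal —
the standard choice for ReLU networks and reproducible in tests. Input
images in [0,1] are standardized per channel with the customary ImageNet
statistics. Pretrained weights can be loaded from a flat HDF5 container
(`layer/weight`, `layer/bias`, `layer/bn_*`), with all shapes validated
before any assignment; no training code exists in the package, and the
published training hyperparameters of the large-kernel backbone are kept
only as documentation constants.

## Feature space

V features are the six VGG taps; R features are the four stage taps plus a
fifth layer: the deepest stage activation L2-normalized per image over all
channel×spatial elements. The "regularization layer" that produces this
fifth entry is not defined precisely in the source description; global L2
normalization was chosen because it is parameter-free, shape-preserving,
maps zero to zero, and is trivially testable. Merging concatenates the
flattened V layers (shallow→deep) followed by the flattened R layers, with
no rescaling between sources — the merge is deliberately unweighted.
Flattening is row-major with shape metadata retained, so it is invertible
and serialized models are portable.

## Mapping

The per-voxel linear system `v = Fw + b` is fit in two steps.

**PCA.** Thin SVD of the centered training features; components with
singular values below 1e−10 of the largest are treated as noise, and
k = min(m−1, rank) components are retained (all of them — no
variance-based dropping). With n ≫ m this is lossless on the training
samples. The PCA is fit once per feature space on training data only; test
data are transformed with the training model (fingerprints guard against
mixing).

**ROMP.** Regularized orthogonal matching pursuit per voxel on centered
data: each iteration correlates the residual with all columns, takes the K
largest-magnitude correlations, selects among them the maximal-energy
subset whose magnitudes are within a factor of two of each other (ties go
to the subset containing the largest coordinate), adds it to the support,
and re-solves least squares on the support. Stopping: residual norm below
`tol·‖y_centered‖` (default 1e−6), support size 2K, a hard iteration cap
(default 50), or no addable coordinate. The least-squares re-solves use an
incrementally grown orthonormal basis (modified Gram–Schmidt with one
reorthogonalization pass); numerically dependent candidates are excluded
from the support, and candidate blocks are truncated to keep the support
within the algorithm's 2K bound. The intercept is handled by centering —
numerically equivalent to an explicit ones-column and it keeps the PCA
well-defined.

Defaults K=20, tol=1e−6, 50 iterations follow common sparse-encoding
practice; no values are prescribed by the source description. For
noiseless-recovery configurations the pipeline can derive K from the
fitted PCA dimension (K = ⌈k/2⌉, `sparsity=None`): an exact fit requires
the 2K support budget to cover every retained component, and the retained
rank varies with the data.

## Evaluation

Prediction accuracy is the sample Pearson correlation per voxel, computed
on test responses averaged across the repeated presentations of each test
image (averaging is the standard protocol for repeat-presentation designs
and is exposed as a flag). A zero-variance vector makes the correlation
undefined; undefined propagates as invalid, never as 0. The validity rule
is strict: Pcc > 0.41. ROI summaries average the top-n (default 100) voxel
correlations per ROI, with deterministic tie-breaking by voxel index; the
derived groups are LVC = V1∪V2∪V3, HVC = LOC∪FFA∪PPA, VC = LVC∪V4∪HVC.
Model comparison categorizes voxels as red (second model better), blue
(first better), black (neither valid) or tie (exactly equal with at least
one valid) — exact ties get their own category rather than an arbitrary
color.

## Effective receptive fields

The ERF of a backbone is measured from the gradient of the central spatial
unit of the deepest tap (summed over channels) with respect to the input:
for each seeded standard-normal probe image (default 32 probes), absolute
input-gradients are summed over input channels, averaged over probes, and
peak-normalized. Probing keeps nonlinearities active, matching the network
as deployed; a linear mode (ReLU treated as identity) exists for analytic
checks, where the nonzero support equals the theoretical receptive field
from kernel/stride/padding arithmetic. The scalar summary is the side
length of the smallest centered square window holding 95% of the score
mass (the fraction is a flag). Which probe images or weights produced the
published heatmaps is not stated anywhere; random weights and probes are
the documented default, which is sufficient for the size *comparisons* the
package makes (single large-kernel layers beat small-kernel layers;
matched-depth large-kernel stacks are at least as wide as small-kernel
stacks).

## Synthetic data

The generator emulates the structure of the image-presentation experiment
the pipeline assumes: 1200 training images in 150 categories of 8; 50 test
images from held-out categories, each presented 35 times; 3×224×224
stimuli; 7 base ROIs. Images are seeded mixtures of category-specific
Gabor atoms (orientation, frequency, phase, envelope, per-channel color
weights) with per-image amplitude jitter and light pixel noise, squashed
into (0,1) — so categories are discriminable by convolutional features and
within-category images correlate more than between-category ones. Voxel
responses are sparse linear functions of the merged features: each voxel
gets a support of 10 features drawn among columns that vary across
training images, coefficients two-sided uniform in ±[0.5, 2], rescaled so
the noiseless training signal has unit standard deviation — which makes
the noise σ directly a noise-to-signal ratio (default 0.5). Test trials
replicate each test image with independent Gaussian noise per trial. All
randomness flows through one seeded generator.

Two desk-scale presets:

- `reduced_spec`: 30 categories × 4 images at 32×32, 10 test images × 35
  repeats, 2 voxels per ROI. Used for smoke tests and the noise sweep.
- `wellposed_spec`: 400 categories × 4 images, otherwise as above. The
  reduced backbones at 32×32 produce 1537 merged features (the VGG
  topology needs input ≥ 32 for its five poolings, and its first tap alone
  is 32×32 per channel, so this is close to the floor); 1600 training
  samples put PCA in the regime where its components span the entire
  feature space, making noiseless responses exactly recoverable
  end-to-end. This preset, with σ=0 and PCA-derived K, is the
  exact-recovery test bed.

What passing these tests shows — and what it does not: the pipeline's
algebra and algorithms are correct (exact recovery where recovery is
well-posed; graceful, monotone degradation with noise; architecture and
fusion fidelity). Synthetic Gabor stimuli and linear responses do not
emulate the statistics of natural images, fMRI noise structure,
retinotopy, or hemodynamics, so passing says nothing about absolute
encoding performance on real cortex; reproducing published ROI-level
correlations would require the external dataset and pretrained weights,
which are deliberately out of scope.

## Numerical choices and degenerate inputs

- Engine dtype float64 throughout; feature containers store float32 on
  disk (relative rounding ~1e−7, negligible against all contracts).
- PCA rank threshold 1e−10 of the largest singular value; an all-constant
  feature matrix yields k=0 with a warning.
- Zero-variance voxels fit a constant model with a warning, never fail.
- Zero activations normalize to zero; non-finite activations are rejected
  at extraction.
- MaxPool gradient routes to the argmax (first index on exact ties).
- ERF window sides grow symmetrically around the pixel aligned with the
  probed unit (index size//2 per axis).
- Problem sizes in the test suite (1600×1537 features for the recovery
  check, 100-instance batteries elsewhere) were chosen so the whole suite
  and the acceptance script each run in a few minutes on one CPU.

## Known limitations

- No training of backbones (inference only); pretrained-weight workflows
  require externally produced weight files in the documented container.
- The block counts of the large-kernel backbone are reduced relative to
  the published reference model (see above).
- ROMP hyperparameters are not tuned per dataset; no cross-validation is
  provided.
- A single-channel reduced VGG (the fixture configuration) can have a dead
  ReLU path, which zeroes ERF maps; ERF probing should use the widened
  reduced channels the CLI selects.
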