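# Methods

## Problem and model

The package segments the three nested BraTS tumor regions — whole tumor
(WT), tumor core (TC) and enhancing tumor (ET) — from four co-registered
MRI modalities.  Because the regions overlap (ET ⊆ TC ⊆ WT), the network
head is a per-channel sigmoid over three output channels rather than an
exclusive softmax, and predictions may optionally be re-nested after
thresholding (et ← et ∧ tc ∧ wt).

Three network variants share one skeleton and differ in two orthogonal
choices:

| variant      | encoder stage        | normalization + activation |
|--------------|----------------------|----------------------------|
| `unet3p`     | plain double conv    | BatchNorm + ReLU           |
| `frn_unet3p` | plain double conv    | FRN + TLU                  |
| `iresunet3p` | stage residual       | FRN + TLU                  |

The FRN/TLU replacement is applied globally — encoder, decoder branches
and fusion convolutions — not only in the encoder.

### Stage-residual encoder wiring

The stage groups a start residual block, `n_middle` middle blocks
(default 0) and an end residual block; the summed stage output is then
normalized and activated, so the main signal path has exactly one
activation however deep the stage is.  The block interior is not uniquely
determined by the design's published description, so it is a configuration
enum (`StageLayout`):

* `convs_per_block` (default 1): 3×3(×3) convolutions on the residual
  branch of the start and end blocks.  The default keeps two 3×3
  convolutions per stage, matching the benchmark U-Net3+ encoder's conv
  count.  Middle blocks always carry two convolutions (pre-activation
  double conv).
* `shortcut_kernel` (default 3): projection shortcut used when the channel
  count changes — pointwise (1) or full-kernel (3).

With the defaults, the parameter counts of the constructed models are
26.96 M (2D U-Net3+), 5.06 M (3D U-Net3+ and 3D FRN_U-Net3+, which differ
only by the learnable TLU thresholds) and 6.24 M (3D IResUnet3+).  The
enumerable alternatives give 5.10 M (pointwise shortcuts), 7.46 M
(two-conv start block) and 8.29 M (two convs in both blocks) for the 3D
IResUnet3+; the full-kernel projection is the default wiring.

### FRN + TLU

ν² is the mean of x² over the spatial grid, per sample and per channel —
never across the batch, which is the entire point of FRN.  The mean is
accumulated in float64 and cast back to float32.  ε is fixed at 1e-6 (not
learnable); γ, β, τ initialize to 1, 0, 0 so the layer starts
identity-like.  TLU is z = max(y, τ); its dual form relu(y − τ) + τ is an
exact algebraic identity (and bit-exact on dyadic inputs, which is how the
test asserts it).

### Decoder

Scale unification uses max pooling downward and linear interpolation
(bilinear / trilinear, half-pixel convention with edge clamping) upward.
Each of the five branches is conv(3) → norm → act to the aggregation
width; concatenation gives 5× that; one fusion conv(3) → norm → act
produces the node.  The 3D aggregation width follows the 2D convention
(first-stage width, 16), which reproduces the 5 M baseline count.
Convolutions before a norm carry no bias; the 1×1 output head has a bias.

## Loss

L_all = α·L_bce + β·L_dice, α = 0.5, β = 1.0.  L_bce is the mean binary
cross-entropy over voxels and channels, with predictions clipped to
[1e-7, 1−1e-7].  L_dice is the generalized Dice loss with per-channel
weights w_c = 1/(Σ g_c)² and smoothing constant 1e-5 in numerator and
denominator; channel sums pool over the whole batch.  A plain per-channel
mean soft Dice is available via `dice_weighting="mean"`.

## Preprocessing

* **Standardization**: per modality, per case, zero mean / unit SD
  (population convention) over the nonzero support; background stays
  exactly zero.  Constant or empty supports return zeros with a warning.
* **Regions**: WT = NET∪ED∪ET, TC = NET∪ET, ET = ET, with the BraTS codes
  NET=1, ED=2, ET=4 (configurable).
* **Geometry**: depth padding to 160 splits the deficit front-heavy
  (155 → (3, 2)); center crops put the extra voxel of odd remainders at
  the far end; blocks are half-open z ranges at 0-based offsets.  Every
  step records its inverse (pad record, crop offsets, block offsets) in a
  JSON sidecar, so block-wise predictions map back to native geometry
  exactly; overlapping blocks are averaged with equal weights.
* **2D path**: slices become (4, H, W) patches after the same
  standardize/region/crop steps; an off-by-default flag drops slices with
  no brain support.

## Evaluation

Dice = 2TP/(2TP+FN+FP) and SEN = TP/(TP+FN) on voxel counts.  Empty-mask
conventions: both masks empty → Dice 1, SEN 1; prediction empty with
nonempty reference → 0.  The Hausdorff distance is the symmetric maximum
(or a percentile, e.g. HD95) of Euclidean nearest-surface distances;
surfaces are the face-connected mask boundaries (erosion difference);
cases with an empty mask are excluded from HD aggregation and counted.
Summaries report sample SD (ddof 1), median and quartiles with the
linear-interpolation quantile convention.

## Phantoms

A phantom is an ellipsoidal brain with a concentric three-shell tumor
(ET core, NET shell, ED rim) — the simplest geometry satisfying region
nesting — with piecewise-constant modality intensities per tissue class
and additive Gaussian noise (default SD 0.05 against tissue contrasts of
order 0.1–0.9); `lumpiness` adds a smooth radial perturbation for
irregular shapes.  Phantoms emulate the *structure* of BraTS cases
(modalities, codes, nesting, background zeros), not MRI physics: no bias
fields, partial-volume effects, anisotropic spacing, or realistic texture.
Tests passing on phantoms therefore validate the pipeline's mechanics and
the learnability of well-separated contrasts, not clinical accuracy.
The default split fraction mirrors the 285:66 train/validation case split
of BraTS2018.

## Desk-scale experiments

`experiments.desk_training_run` trains the 3D `iresunet3p` variant with
channel plan [2,4,8,16,32] on six noise-free (32,64,64) phantoms (two held
out), using depth-16 blocks over a (32,32,32) crop with the method-B
step:depth ratio (stride 4), Adam at the standard learning rate 0.03,
batch size 2, 12 epochs.  These sizes exercise all five network scales
while keeping a run to a few CPU-minutes.
`experiments.block_method_comparison` trains identical models for an equal
epoch budget on method-A (stride = block depth) and method-B (stride =
quarter block) data; B sees more, overlapping blocks per epoch and reaches
a lower training loss.

## Numerical choices and limitations

* All learnable tensors and activations are float32; reductions that need
  it (FRN statistics, loss sums) accumulate in float64.
* Max-pool gradients split ties evenly among tied voxels; TLU/elementwise
  max uses the same convention at exact ties.
* Probability threshold for hard masks: 0.5.
* The autodiff core implements only stride-1 same-padding convolutions
  with odd kernels; encoder downsampling is explicit 2× max pooling.
* Early stopping monitors mean validation Dice over the three regions
  (patience 10 by default); validation loss is logged alongside.
* Training on one CPU in numpy is orders of magnitude slower than a GPU
  framework; the full-resolution published configuration builds and runs
  forward, but training it end to end is out of desk scope.
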