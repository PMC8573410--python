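# Methods

This note documents the models, parameters, numerical choices and design
decisions behind `chiasmseg`, and what the synthetic experiments do and do
not establish.

## Problem and approach

The optic chiasm is the X-shaped midline crossing of the optic nerves. In
congenital conditions such as albinism its geometry changes: narrower
chiasm and optic nerves, wider angle between the optic tracts. The package
implements a detection-by-failure approach: a convolutional segmenter is
trained exclusively on normal chiasms, and the quality of its prediction on
a new subject — Dice similarity against a manually delineated reference —
acts as a normality score. A segmenter that has only ever seen normal
anatomy reproduces normal chiasms well and malformed ones poorly, so a low
Dice score flags malformation.

## Data model and conventions

All volumes are 3D scalar grids with per-axis voxel spacing. On NIfTI load
every image is reoriented to a canonical axis order (axis 0 left→right,
axis 1 posterior→anterior, axis 2 inferior→superior), so "axial slice"
always means a fixed index along axis 2; indexing is 0-based. Masks are
strict {0,1} grids; two-valued files such as {0,255} are normalized with a
warning, anything else is rejected. Masks are written as unsigned 8-bit.

Degenerate-case policy: Dice of two empty masks raises (the comparison is
undefined and silent defaults hide bugs upstream); in slice-restricted
evaluation, where restriction can legitimately empty the candidate, a
one-sided empty comparison scores 0.

## Atlas-mask correction

Steps, given a T1w volume and a noisy initial chiasm mask:

1. collect the intensities of the volume at initial-mask voxels;
2. 98th percentile of that distribution → upper threshold (separates
   hyperintense voxels with blood-vessel contributions);
3. 66th percentile → lower threshold (separates white matter from
   partial-volume and surrounding tissue);
4. binarize the whole volume to the inclusive band [lower, upper];
5. restrict to the axis-aligned bounding box of the initial mask extended
   by 5 voxels along left–right and posterior–anterior only (the
   inferior–superior extent is deliberately not extended, which keeps
   out-of-plane white-matter structures away from step 6);
6. keep the biggest connected cluster;
7. dilate it by one voxel to re-include the partial-volume surface.

Defaults and open choices: percentiles 66/98 (tuned for HCP-like intensity
profiles; exposed because their transfer to other acquisitions is poor),
margin 5 voxels, component connectivity 26 (the common neuroimaging cluster
convention; the choice is not dictated by the algorithm and is
configurable), dilation element the 6-neighbour cross (a literal "one voxel
in each direction"; the 26-cube is available). Band thresholds are
inclusive at both ends. Percentiles use linear interpolation between order
statistics. Equal-size cluster ties are broken toward the component
containing the smallest row-major linear index, which is deterministic and
stable under the canonical orientation. Step 4 binarizes the entire volume
before the box restriction, matching the algorithm's stated order; a
`fast=True` path restricts first and is tested to produce identical output.
If the selected cluster does not overlap the initial mask the algorithm
proceeds with a warning — the analogous CNN postprocessing shows that
non-overlapping biggest clusters are a real outcome, not an error.

## Network

A volumetric U-Net with five resolution levels: four encoder levels and a
bottleneck, channel widths 10, 20, 40, 80, 160 (doubling per level). Each
block is two 3×3×3 convolutions, each followed by batch normalization and
ReLU; 2×2×2 max-pooling (stride 2) between encoder levels; 2×2×2
up-convolutions (stride 2) followed by concatenation with the matching
encoder feature maps and a decoder block; a 1×1×1 convolution to two
channels and a voxelwise softmax. Block convolutions carry no bias (the
normalization shift subsumes it); up-convolutions and the head do; each
normalization layer contributes two learnable vectors (scale, shift), and
running statistics are not parameters. Under these conventions the default
network has exactly 2,206,482 trainable parameters — this identity pins the
architecture, and the closed-form sum

    Σ_blocks 27·Cin·Cout  +  Σ_norms 2·C  +  Σ_upconvs (8·Cin·Cout + Cout)
    +  (10·2 + 2)

is kept in the code as an independent oracle. Among standard U-Net
variants this bias/width policy is the one consistent with both the stated
block structure and the parameter total; alternatives (biased block convs,
different base width) miss the total.

The whole stack — convolutions, batch norm, pooling, transposed
convolutions, softmax, soft-Dice loss, Adam, and backpropagation — is
implemented in NumPy (float32, with a float64 path used by the gradient
checks). Convolutions are evaluated as 27 accumulated GEMMs over spatially
shifted views, which keeps peak memory bounded and is the fastest pure-BLAS
formulation we measured on one CPU. Gradients of every layer are verified
against central finite differences in float64 (relative error < 1e−4).
Weight initialization is He-uniform for convolutions, ones/zeros for
normalization scale/shift, fixed by a seed.

Inputs must have sides divisible by 2^(levels−1) = 16; inference pads to
the next multiple and crops the output back.

## Loss, training, inference

Soft-Dice loss on the foreground channel, `1 − (2Σpg + s)/(Σp + Σg + s)`
with smoothing s = 1e−5 (which also defines the empty/empty limit as 0).
Training uses mini-batches of 2 and Adam. The historical hyperparameter
grid pairs maximal epochs (13, 15, 30, 40, 100) with learning rates
(0.0025, 0.0030, 0.0025, 0.0015, 0.0005); the best-reported combination is
30 epochs at 0.0025 with prediction threshold 1.0. There is no early
stopping: the model after the final epoch is the model. Splits are a
seeded shuffle followed by contiguous partition; the historical cohort of
1049 was split 932/107/10 (the printed percentages 87.5/10/2.5 are
inconsistent with those counts; the counts are authoritative here).

Augmentation order follows its listing: normalize (max → 1), flip each
axis independently with p = 0.5, random crop (zero-padded when the input
is smaller), random rigid affine with per-axis rotation and translation
drawn uniformly within bounds, b-spline (order 3) for the image and
nearest neighbour for the mask, zero fill outside the field. Image and
mask always share one transform.

Inference thresholds the foreground probability at τ − ε with ε = 1e−6
(τ = 1.0 would otherwise compare floats for exact equality against a
saturated softmax) and keeps the biggest suprathreshold cluster wherever it
lies; an empty result is returned as an empty mask with a warning, because
"the biggest cluster is somewhere else entirely" is a meaningful failure
mode, not an exception.

## Evaluation statistics

Candidate masks are scored against the manual reference restricted to
axial slices where the reference is present (excess voxels on other slices
are cropped first), so neighbouring structures like nerves and tracts do
not contaminate the score. Group results are mean ± SEM (sample sd, n−1).

Each two-sample comparison runs the D'Agostino–Pearson normality test on
both samples at α = 0.05; only if neither rejects is the two-tailed
pooled-variance Student t-test used, otherwise the two-sided Wilcoxon
rank-sum test. The pooled (not Welch) variant is the default and is
configurable. Samples below n = 8 are under the normality test's validity
floor; callers must then select a path explicitly (the cohort evaluator
defaults such cells to rank-sum). All p-values of the comparison plan are
Bonferroni-corrected together as one family (corrected p = min(1, raw·m)),
not per sub-family.

The plan for the full study configuration (three groups: two control
cohorts and one patient cohort; three mask kinds: atlas-initial,
atlas-corrected, CNN) contains exactly ten tests: (a) four comparing
atlas-initial vs atlas-corrected quality within and across the two control
groups, (b) three comparing atlas-corrected vs CNN within each group,
(c) three comparing CNN masks across the three group pairs.

## Classification

A C-SVC with polynomial kernel on the single DSC feature, malformed as the
positive class. Hyperparameters are the common library defaults (degree 3,
C = 1, variance-scaled kernel coefficient, zero independent term) since
nothing in the protocol pins them; all are exposed. Training and
evaluation use the same data on purpose — the metrics quantify group
overlap, not generalization — and every report carries an `in_sample`
flag; a leave-one-out mode exists as an opt-in extension. Accuracy,
precision, recall and specificity are computed from integer confusion
counts; a zero denominator yields an explicitly flagged undefined metric.

## Synthetic phantoms

Each phantom is two straight tubular limbs crossing at the grid centre in
an axial band: the simplest geometry carrying the discriminative features
(widths, tract angle). The limb radius tapers from chiasm_width/2 at the
centre to nerve_width/2 distally (Gaussian taper, scale ≈ 0.18 of the grid
side). Defaults: 64³ grid (160³ supported), chiasm width 7 voxels, nerve
width 4.5, tract angle 90°, white matter 0.7, background 0.35, vessels 1.0
(the T1w ordering vessel > WM > background), blur σ 0.7 voxels emulating
partial volume, Gaussian noise σ 0.02. The ground-truth mask is the
voxels with pre-degradation white-matter fraction > 0.5 — a stand-in for a
rater labelling majority-WM voxels — and is always one 26-connected
component. One to three vessel blobs touch the surface from outside.
The malformed preset multiplies chiasm width by 0.5, nerve width by 0.7 and
adds 30° to the tract angle; the directions come from reported group
differences, the magnitudes are free choices exposed as configuration, and
the intensity model never changes, so downstream segmentation failure is
attributable to shape alone.

The atlas-like corrupted mask applies, under one seed: per-voxel flips
within a two-voxel shell of the boundary (p = 0.20·severity), one global
one-voxel dilation or erosion (applied with probability min(1, 2·severity),
so corruption vanishes as severity → 0), and one contiguous
false-positive blob of background/partial-volume voxels grown against the
mask. The flip rate and blob size were calibrated once so that at the
default severity 0.5 the mean DSC against ground truth over 50 seeds is
≈ 0.57 (within [0.45, 0.65]) on control phantoms — the quality regime of
raw atlas chiasm segmentations. Corruption severity is monotone in
expectation. Per-sample seeds derive from `SeedSequence((master_seed,
index))`, fixed and platform-stable.

What the phantoms do **not** emulate: MR physics (bias fields, k-space
artifacts, acquisition-dependent contrast), anatomical variability beyond
width/angle, gray-matter structures, and real malformation anatomy.
Passing phantom tests therefore demonstrates that the algorithms behave as
designed on data with the stated structure — not that real-data Dice
magnitudes are reproduced. Desk-scale experiments check directions
(correction improves atlas masks; control-trained segmenters score normal
anatomy higher than malformed), never the published real-data values.

## Desk-scale experiment sizes

The repository's experiments are sized for a single CPU: 64³ phantom
grids, a base-width-4 network for end-to-end runs (the full base-width-10
architecture is instantiated and verified exactly, and its 160³ forward
pass is tested), 40 training phantoms with batch 2, 15 epochs at learning
rate 0.02 (chosen for convergence at that step count), flip-and-crop
augmentation only, and 10 + 10 held-out normal/malformed test phantoms.
The correction study uses 50 seeds. These sizes are stated here as the
package's own reproducible configuration. At this scale the held-out
malformed scores are bimodal — thin structures either collapse below the
saturated threshold or are segmented via their preserved intensity band —
so the group contrast is assessed with the rank-sum test rather than a
mean difference alone.

## Known limitations

- The NumPy network trains at desk scale only; the full-resolution
  160³/base-10 configuration is supported for inference and parameter
  audit but would be impractically slow to train without a GPU framework.
- Batch normalization with batch size 2 has noisy statistics; running
  statistics are used at inference.
- The correction algorithm's percentile defaults are acquisition-specific
  by construction; on data with different intensity profiles they are
  expected to fail (this transfer failure is documented behaviour, not a
  bug, and the thresholds are configurable).
- The SVC metrics are in-sample by protocol and say nothing about
  out-of-sample diagnostic accuracy; no decision threshold on DSC is
  proposed.
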