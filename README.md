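# chiasmseg

Detection of malformed optic chiasms from T1-weighted MRI via
**segmentation failure**: a 3D U-Net trained to segment *normal* chiasms
produces poor masks on malformed ones (e.g. the optic-nerve misrouting
typical of albinism), and that quality drop — measured with the Dice
similarity coefficient — is the diagnostic signal.

The package is aimed at neuroimaging researchers who want to reproduce or
extend the pipeline without access to the original cohorts: every stage is
runnable end-to-end on seeded synthetic phantoms.

## What is inside

1. **Atlas-mask correction** (`chiasmseg.correction`) — a seven-step
   algorithm refining a noisy atlas-based chiasm mask using the intensity
   distribution of the T1w image inside the mask: keep voxels in the
   66th–98th in-mask percentile band, restrict to the initial mask's
   bounding box extended by 5 voxels along the left–right and
   posterior–anterior axes, keep the biggest cluster, dilate by one voxel.
2. **3D U-Net** (`chiasmseg.nn`) — five resolution levels with channel
   widths 10→20→40→80→160, two 3×3×3 convolutions per block (each followed
   by batch normalization and ReLU), 2×2×2 max-pooling, 2×2×2
   up-convolutions with encoder skip concatenation, and a 1×1×1 two-channel
   voxelwise-softmax head. The default network has exactly **2,206,482**
   trainable parameters, verified against an independent closed-form count.
   The network, soft-Dice loss `1 − (2Σpg + s)/(Σp + Σg + s)`, Adam
   optimizer and backpropagation are implemented in NumPy; no GPU framework
   is required.
3. **Augmentation** (`chiasmseg.augment`) — max-intensity normalization,
   random flips, random crop (default 160³), random rigid affine (rotation
   ≤ 15°, translation ≤ 20 voxels, b-spline image / nearest-neighbour mask
   interpolation), applied jointly to image and target.
4. **Training & inference** (`chiasmseg.training`) — seeded splits,
   mini-batches of 2, the historical hyperparameter grid
   (13, 15, 30, 40, 100 epochs × matched learning rates, best 30 @ 0.0025),
   and CNN-mask extraction: threshold the foreground-probability map
   (default τ = 1.0, read as p ≥ τ − 1e−6) and keep the biggest cluster.
5. **Statistics** (`chiasmseg.stats`) — slice-restricted DSC against the
   manual ground truth, mean ± SEM summaries, D'Agostino–Pearson-gated
   choice between the pooled two-sample t-test and the Wilcoxon rank-sum
   test, Bonferroni familywise correction, and the ten-test comparison plan
   over three groups × three mask provenances.
6. **Classification** (`chiasmseg.classify`) — polynomial-kernel C-SVC on
   the one-dimensional DSC feature with accuracy / precision / recall /
   specificity, explicitly flagged as in-sample.
7. **Phantoms** (`chiasmseg.phantom`) — seeded synthetic T1w-like volumes
   with an X-shaped white-matter structure, partial-volume blur, vessel-like
   hyperintense blobs, ground-truth masks, and calibrated atlas-like
   corrupted masks; malformed variants narrow the chiasm/nerves and widen
   the tract angle without touching the intensity model.

## Worked example

`examples/correct_atlas_mask.py` generates one phantom, corrupts its mask
to atlas quality, and runs the correction:

```
intensity band kept by the correction: [0.600, 0.721]
DSC(initial,   manual) = 0.647
DSC(corrected, manual) = 0.886
```

The band excludes hyperintense vessel voxels above the 98th in-mask
percentile and dark partial-volume voxels below the 66th, so the corrected
mask recovers the white-matter core; the final dilation restores the
surface voxels the conservative thresholds removed. Across 50 seeded
phantoms the mean initial-mask quality is calibrated to ≈ 0.57 DSC and the
correction raises it (≈ 0.77, improving every seed), mirroring the
direction of the real-data improvement this algorithm was designed for.

The other scripts in `examples/` walk through cohort generation, desk-scale
training plus the normal/malformed contrast, the statistical table, and the
SVC report; each prints a short interpretation of its numbers.

A thin CLI mirrors the library: `chiasmseg generate-phantoms | correct-masks
| train | predict | evaluate | classify` (see `chiasmseg --help`).

## Limitations

Phantoms are geometric stand-ins, not MR simulations: no bias field,
no k-space artifacts, no real anatomical variability. Real-data Dice
magnitudes are not reproduced here — only directions and mechanisms.
See `docs/methods.md` for the full methodological account.
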