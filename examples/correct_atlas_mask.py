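"""Refine a noisy atlas mask with the seven-step percentile correction.

Generates one phantom with a corrupted initial mask, runs the correction
(66th/98th in-mask intensity percentiles -> whole-volume band threshold ->
extended bounding box -> biggest cluster -> one-voxel dilation), and compares
mask quality before and after.
"""

from chiasmseg import (
    PhantomParams,
    correct_mask,
    corrupt_to_initial,
    dsc,
    make_phantom,
)
from chiasmseg.correction import CorrectionParams, mask_intensity_thresholds

sample = make_phantom(PhantomParams(seed=7))
initial = corrupt_to_initial(sample, corruption_seed=8)

t_lo, t_hi = mask_intensity_thresholds(sample.volume, initial, CorrectionParams())
corrected = correct_mask(sample.volume, initial)

print(f"intensity band kept by the correction: [{t_lo:.3f}, {t_hi:.3f}]")
print(f"DSC(initial,   manual) = {dsc(initial, sample.manual_mask):.3f}")
print(f"DSC(corrected, manual) = {dsc(corrected, sample.manual_mask):.3f}")
print("The band excludes hyperintense vessel voxels (above the 98th in-mask")
print("percentile) and dark partial-volume/background voxels (below the 66th),")
print("so the corrected mask recovers the white-matter core plus one surface voxel.")
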