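"""Generate a small synthetic cohort of chiasm phantoms and inspect its quality.

Builds 8 control and 9 malformed phantoms (the test-cohort proportions of the
clinical dataset the package emulates), each with a ground-truth mask and a
corrupted atlas-like initial mask, and prints the initial-mask quality.
"""

import numpy as np

from chiasmseg import dsc, make_cohort

samples = make_cohort(n_control=8, n_malformed=9, master_seed=42)

print(f"{'id':8s} {'label':10s} {'mask voxels':>11s} {'DSC(initial)':>12s}")
for s in samples:
    d = dsc(s.initial_mask, s.manual_mask)
    print(f"{s.sample_id:8s} {s.label:10s} {s.manual_mask.count():11d} {d:12.3f}")

ctrl = [dsc(s.initial_mask, s.manual_mask) for s in samples if s.label == "control"]
mal = [dsc(s.initial_mask, s.manual_mask) for s in samples if s.label == "malformed"]
print(f"\nmean initial-mask DSC: controls {np.mean(ctrl):.3f}, malformed {np.mean(mal):.3f}")
print("Malformed phantoms have fewer mask voxels (narrower chiasm and nerves).")
print("Control initial masks sit near the ~0.55 quality typical of raw atlas")
print("chiasm segmentations; the same corruption damages thin malformed")
print("structures proportionally more.")
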