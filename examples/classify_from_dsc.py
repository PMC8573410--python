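"""Classify malformation from the one-dimensional CNN-mask DSC feature.

Fits the polynomial-kernel C-SVC on per-subject Dice scores (malformed =
positive class) and prints the four confusion metrics.  Evaluation is
in-sample by design - the point is to quantify group overlap, not to claim
generalization - and the report says so explicitly.
"""

import numpy as np

from chiasmseg import fit_svc

rng = np.random.default_rng(1)
dsc_controls = np.clip(rng.normal(0.75, 0.08, size=8), 0, 1)
dsc_malformed = np.clip(rng.normal(0.44, 0.15, size=9), 0, 1)

values = np.concatenate([dsc_controls, dsc_malformed]).tolist()
labels = ["control"] * 8 + ["malformed"] * 9

report = fit_svc(values, labels)
print(report.boundary)
m = report.metrics
print(f"accuracy    {m.accuracy:.2f}")
print(f"precision   {m.precision:.2f}")
print(f"recall      {m.recall:.2f}")
print(f"specificity {m.specificity:.2f}")
print(f"in-sample evaluation: {report.in_sample}")
print("Low-DSC subjects fall on the positive (malformed) side of the margin;")
print("overlap between the groups shows up as false positives/negatives.")
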