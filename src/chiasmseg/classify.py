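"""DSC-based malformation classification with a polynomial-kernel C-SVC.

The single feature per subject is the Dice score of the CNN mask against the
manual ground truth; malformed subjects are the positive class.  The
classifier is deliberately fitted and evaluated on the same data — the point
is a quantitative expression of inter-group overlap of the DSC values, not a
generalization claim — so every report carries an explicit in-sample flag.
An optional leave-one-out evaluation is available for exploration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "SvcParams",
    "ConfusionCounts",
    "Metrics",
    "ClassifierReport",
    "confusion_metrics",
    "fit_svc",
]

POSITIVE_LABEL = "malformed"


@dataclass
class SvcParams:
    """Polynomial-kernel C-SVC hyperparameters (library defaults)."""

    degree: int = 3
    C: float = 1.0
    gamma: str | float = "scale"
    coef0: float = 0.0


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.tn, self.fp, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("at least one observation is required")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    undefined: list[str] = field(default_factory=list)


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall (sensitivity), specificity from counts.

    A metric with a zero denominator is reported as None and flagged in
    ``undefined`` rather than silently zeroed.
    """
    undefined: list[str] = []

    def safe(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    return Metrics(
        accuracy=safe(c.tp + c.tn, c.total, "accuracy"),
        precision=safe(c.tp, c.tp + c.fp, "precision"),
        recall=safe(c.tp, c.tp + c.fn, "recall"),
        specificity=safe(c.tn, c.tn + c.fp, "specificity"),
        undefined=undefined,
    )


@dataclass
class ClassifierReport:
    boundary: str
    predicted: list[str]
    counts: ConfusionCounts
    metrics: Metrics
    in_sample: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _describe_boundary(model: SVC, lo: float, hi: float) -> str:
    """Locate sign changes of the decision function on a fine 1-D grid."""
    pad = 0.05 * (hi - lo) if hi > lo else 0.05
    grid = np.linspace(lo - pad, hi + pad, 2001)
    vals = model.decision_function(grid[:, None])
    signs = np.sign(vals)
    crossings = grid[:-1][signs[:-1] * signs[1:] < 0]
    if crossings.size == 0:
        side = POSITIVE_LABEL if vals.mean() > 0 else "control"
        return f"no decision boundary in data range (all {side})"
    return "decision boundary at DSC ~= " + ", ".join(f"{c:.3f}" for c in crossings)


def fit_svc(
    dsc_values,
    labels,
    params: SvcParams | None = None,
    leave_one_out: bool = False,
) -> ClassifierReport:
    """Fit the 1-D polynomial C-SVC and report in-sample confusion metrics.

    ``labels`` use "malformed" (or any case label) as positives and
    "control" as negatives; both classes must be present.
    """
    params = params or SvcParams()
    x = np.asarray(dsc_values, dtype=float)[:, None]
    y = np.asarray([1 if lab != "control" else 0 for lab in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    model = SVC(kernel="poly", degree=params.degree, C=params.C,
                gamma=params.gamma, coef0=params.coef0)
    model.fit(x, y)

    if leave_one_out:
        pred = np.empty_like(y)
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            m_i = SVC(kernel="poly", degree=params.degree, C=params.C,
                      gamma=params.gamma, coef0=params.coef0)
            m_i.fit(x[keep], y[keep])
            pred[i] = m_i.predict(x[i:i + 1])[0]
        in_sample = False
    else:
        pred = model.predict(x)
        in_sample = True

    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )
    return ClassifierReport(
        boundary=_describe_boundary(model, float(x.min()), float(x.max())),
        predicted=[POSITIVE_LABEL if p == 1 else "control" for p in pred],
        counts=counts,
        metrics=confusion_metrics(counts),
        in_sample=in_sample,
    )
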