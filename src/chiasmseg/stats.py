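"""Cohort evaluation: slice-restricted DSC, group summaries, and the
normality-gated two-sample testing scheme with Bonferroni FWE control.

Mask quality is always judged against the manually delineated ground truth,
restricted to the axial slices where the manual mask is present so that
neighbouring white-matter structures (optic nerves/tracts running out of
plane) do not perturb the score.  Group results are reported as mean +/- SEM.

Each two-sample comparison first checks both samples for normality with the
D'Agostino-Pearson test; if neither rejects at alpha the comparison uses a
two-tailed pooled-variance two-sample t-test, otherwise the two-sided
Wilcoxon rank-sum test.  All p-values of a comparison family are corrected
together with Bonferroni's method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .volgrid import BinaryMask, dsc

__all__ = [
    "MASK_KINDS",
    "STUDY_GROUPS",
    "STUDY_CONTROL_GROUPS",
    "DscRecord",
    "TestResult",
    "Comparison",
    "slice_restricted_dsc",
    "group_summary",
    "compare_groups",
    "bonferroni",
    "comparison_plan",
    "evaluate_cohort",
]

MASK_KINDS = ("atlas_initial", "atlas_corrected", "cnn")
STUDY_GROUPS = ("hcp_test_control", "chiasm_control", "chiasm_albinism")
STUDY_CONTROL_GROUPS = ("hcp_test_control", "chiasm_control")

#: substrings identifying case (non-control) groups when not stated explicitly
_CASE_MARKERS = ("albinism", "malformed", "pwa", "patient")


@dataclass
class DscRecord:
    subject: str
    group: str
    kind: str
    dsc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dsc <= 1.0:
            raise ValueError(f"dsc must lie in [0,1], got {self.dsc}")


@dataclass
class TestResult:
    label: str
    test_used: str  # "t_test" | "rank_sum"
    statistic: float
    p_raw: float
    p_corrected: float | None = None
    family_size: int | None = None


@dataclass(frozen=True)
class Comparison:
    label: str
    family: str  # "a" | "b" | "c"
    side_a: tuple[str, str]  # (group, kind)
    side_b: tuple[str, str]


def slice_restricted_dsc(candidate: BinaryMask, manual: BinaryMask) -> float:
    """DSC after cropping the candidate to axial slices where the manual mask exists.

    Candidate voxels on manual-free slices are excessive by construction and
    removed before scoring.  If restriction empties the candidate the score
    is 0 (one-sided emptiness counts as complete lack of overlap).
    """
    if candidate.shape != manual.shape:
        raise ValueError(f"shape mismatch: {candidate.shape} vs {manual.shape}")
    man = manual.astype_bool()
    if not man.any():
        raise ValueError("manual mask is empty")
    keep_z = man.any(axis=(0, 1))
    restricted = candidate.data * keep_z[None, None, :]
    if not restricted.any():
        return 0.0
    return dsc(BinaryMask(restricted.astype(np.uint8)), manual)


def group_summary(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample sd, n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("group summary requires n >= 2")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


def compare_groups(
    a, b, alpha: float = 0.05, label: str = "", force: str | None = None
) -> TestResult:
    """Two-sample comparison with a normality gate.

    Pooled-variance two-tailed t-test if the D'Agostino-Pearson test rejects
    normality for neither sample at ``alpha``; two-sided Wilcoxon rank-sum
    otherwise.  ``force`` ("t_test" or "rank_sum") bypasses the gate, which
    is required for samples below the normality test's validity floor (n<8).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if force is None:
        if len(a) < 8 or len(b) < 8:
            raise ValueError(
                "normality gate requires n >= 8 per sample; pass force= to "
                "select a test path explicitly"
            )
        both_normalish = (
            sps.normaltest(a).pvalue > alpha and sps.normaltest(b).pvalue > alpha
        )
        path = "t_test" if both_normalish else "rank_sum"
    elif force in ("t_test", "rank_sum"):
        path = force
    else:
        raise ValueError(f"unknown force path {force!r}")

    if path == "t_test":
        res = sps.ttest_ind(a, b, equal_var=True)
    else:
        res = sps.ranksums(a, b)
    return TestResult(
        label=label,
        test_used=path,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
    )


def bonferroni(raw_ps, m: int) -> list[float]:
    """Familywise-error control: each corrected p = min(1, raw * m)."""
    ps = list(np.asarray(raw_ps, dtype=float))
    if m < len(ps):
        raise ValueError("family size m must be >= number of p-values")
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("raw p-values must lie in [0,1]")
    return [min(1.0, p * m) for p in ps]


def comparison_plan(
    mask_kinds=MASK_KINDS,
    groups=STUDY_GROUPS,
    control_groups: tuple[str, ...] | None = None,
) -> list[Comparison]:
    """The family-structured plan of group comparisons.

    Family a: atlas-initial vs atlas-corrected quality within each control
    group, plus cross-control-group comparisons of each of the two atlas
    kinds.  Family b: atlas-corrected vs CNN within every group.  Family c:
    cross-group comparisons of the CNN masks for every pair of groups.  For
    the full three-group, three-kind study configuration this yields exactly
    ten tests (4 + 3 + 3).
    """
    kinds = list(mask_kinds)
    groups = list(groups)
    unknown = [k for k in kinds if k not in MASK_KINDS]
    if unknown:
        raise ValueError(f"unknown mask kinds {unknown}")
    if control_groups is None:
        control_groups = tuple(
            g for g in groups if not any(mark in g.lower() for mark in _CASE_MARKERS)
        )
    controls = [g for g in groups if g in control_groups]

    plan: list[Comparison] = []

    def lbl(s1, s2):
        return f"{s1[0]}:{s1[1]} vs {s2[0]}:{s2[1]}"

    if "atlas_initial" in kinds and "atlas_corrected" in kinds:
        for g in controls:
            s1, s2 = (g, "atlas_initial"), (g, "atlas_corrected")
            plan.append(Comparison(lbl(s1, s2), "a", s1, s2))
        for i in range(len(controls)):
            for j in range(i + 1, len(controls)):
                for kind in ("atlas_initial", "atlas_corrected"):
                    s1, s2 = (controls[i], kind), (controls[j], kind)
                    plan.append(Comparison(lbl(s1, s2), "a", s1, s2))
    if "atlas_corrected" in kinds and "cnn" in kinds:
        for g in groups:
            s1, s2 = (g, "atlas_corrected"), (g, "cnn")
            plan.append(Comparison(lbl(s1, s2), "b", s1, s2))
    if "cnn" in kinds:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                s1, s2 = (groups[i], "cnn"), (groups[j], "cnn")
                plan.append(Comparison(lbl(s1, s2), "c", s1, s2))

    labels = [c.label for c in plan]
    assert len(labels) == len(set(labels))
    return plan


def evaluate_cohort(
    records: list[DscRecord],
    control_groups: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    small_sample_path: str = "rank_sum",
) -> tuple[pd.DataFrame, list[TestResult]]:
    """Summaries and corrected comparisons for a cohort of DSC records.

    Returns a square table indexed by (group, kind): the diagonal holds
    ``mean +/- SEM`` strings, off-diagonal cells the Bonferroni-corrected
    p-values of the planned comparisons (blank where no test is planned),
    plus the list of test results.  Samples below the normality-gate floor
    (n < 8) take the ``small_sample_path`` test directly.
    """
    df = pd.DataFrame(
        [(r.subject, r.group, r.kind, r.dsc) for r in records],
        columns=["subject", "group", "kind", "dsc"],
    )
    if df.duplicated(["subject", "kind"]).any():
        raise ValueError("multiple records for the same (subject, kind)")
    groups = [g for g in STUDY_GROUPS if g in set(df["group"])]
    groups += [g for g in df["group"].unique() if g not in groups]
    kinds = [k for k in MASK_KINDS if k in set(df["kind"])]
    cells: dict[tuple[str, str], np.ndarray] = {}
    for g in groups:
        for k in kinds:
            vals = df.loc[(df["group"] == g) & (df["kind"] == k), "dsc"].to_numpy()
            if len(vals) < 2:
                raise ValueError(f"cell ({g}, {k}) has n={len(vals)} < 2")
            cells[(g, k)] = vals

    plan = comparison_plan(tuple(kinds), tuple(groups), control_groups)
    results: list[TestResult] = []
    for comp in plan:
        a, b = cells[comp.side_a], cells[comp.side_b]
        force = small_sample_path if (len(a) < 8 or len(b) < 8) else None
        results.append(compare_groups(a, b, alpha=alpha, label=comp.label, force=force))
    m = len(plan)
    corrected = bonferroni([r.p_raw for r in results], m)
    for r, pc in zip(results, corrected):
        r.p_corrected = pc
        r.family_size = m

    index = pd.MultiIndex.from_tuples(
        [(g, k) for g in groups for k in kinds], names=["group", "kind"]
    )
    table = pd.DataFrame("", index=index, columns=index)
    for (g, k), vals in cells.items():
        mean, sem = group_summary(vals)
        table.loc[(g, k), (g, k)] = f"{mean:.3f} +/- {sem:.3f}"
    for comp, r in zip(plan, results):
        table.loc[comp.side_a, comp.side_b] = f"{r.p_corrected:.4g}"
        table.loc[comp.side_b, comp.side_a] = f"{r.p_corrected:.4g}"
    return table, results
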