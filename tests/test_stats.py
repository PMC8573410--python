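"""Evaluation statistics: restricted DSC, summaries, test gating, Bonferroni, plan."""

import numpy as np
import pytest

from chiasmseg.stats import (
    DscRecord,
    bonferroni,
    compare_groups,
    comparison_plan,
    evaluate_cohort,
    group_summary,
    slice_restricted_dsc,
)
from chiasmseg.volgrid import BinaryMask, dsc


def _box_mask(shape, sl):
    m = np.zeros(shape, dtype=np.uint8)
    m[sl] = 1
    return BinaryMask(m)


class TestSliceRestrictedDsc:
    def test_out_of_range_voxels_cropped(self):
        shape = (10, 10, 10)
        manual = _box_mask(shape, (slice(3, 6), slice(3, 6), slice(3, 6)))
        cand = manual.data.copy()
        cand[0:5, 0:2, 8] = 1  # 10 voxels on a manual-free axial slice
        assert cand.sum() == manual.count() + 10
        assert slice_restricted_dsc(BinaryMask(cand), manual) == 1.0

    def test_identity(self):
        m = _box_mask((6, 6, 6), (slice(1, 3), slice(2, 4), slice(2, 5)))
        assert slice_restricted_dsc(m, m) == 1.0

    def test_candidate_entirely_out_of_range_scores_zero(self):
        shape = (8, 8, 8)
        manual = _box_mask(shape, (slice(2, 5), slice(2, 5), slice(2, 4)))
        cand = _box_mask(shape, (slice(2, 5), slice(2, 5), slice(6, 8)))
        assert slice_restricted_dsc(cand, manual) == 0.0

    def test_restriction_never_lowers_dsc(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            manual = BinaryMask((rng.random((8, 8, 8)) < 0.2).astype(np.uint8))
            cand = BinaryMask((rng.random((8, 8, 8)) < 0.2).astype(np.uint8))
            if manual.count() == 0 or cand.count() == 0:
                continue
            assert slice_restricted_dsc(cand, manual) >= dsc(cand, manual) - 1e-12

    def test_empty_manual_raises(self):
        z = BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8))
        m = _box_mask((4, 4, 4), (slice(0, 2), slice(0, 2), slice(0, 2)))
        with pytest.raises(ValueError, match="empty"):
            slice_restricted_dsc(m, z)


class TestGroupSummary:
    def test_mean_and_sem(self):
        mean, sem = group_summary([1, 2, 3])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1 / np.sqrt(3))

    def test_constant_sample(self):
        assert group_summary([4.2] * 5) == (pytest.approx(4.2), 0.0)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(3)
        vals = rng.random(12)
        m1, s1 = group_summary(vals)
        m2, s2 = group_summary(vals * 7.0)
        assert m2 == pytest.approx(7 * m1)
        assert s2 == pytest.approx(7 * s1)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            group_summary([1.0])


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        res = compare_groups(a, a.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_separated_gaussians_take_t_path(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 10)
        b = rng.normal(5, 1, 10)
        res = compare_groups(a, b)
        assert res.test_used == "t_test"
        assert res.p_raw < 1e-3

    def test_non_normal_sample_takes_rank_sum_path(self):
        # heavy-tailed mixture that decisively fails the normality test
        rng = np.random.default_rng(7)
        a = np.concatenate([rng.normal(0, 0.05, 17), rng.normal(40, 0.05, 3)])
        b = rng.normal(0, 1, 20)
        from scipy import stats as sps

        assert sps.normaltest(a).pvalue < 0.05  # construction sanity
        res = compare_groups(a, b)
        assert res.test_used == "rank_sum"

    def test_small_samples_require_forced_path(self):
        with pytest.raises(ValueError, match="force"):
            compare_groups([1, 2, 3], [4, 5, 6])
        res = compare_groups([1, 2, 3], [4, 5, 6], force="rank_sum")
        assert res.test_used == "rank_sum"

    def test_null_type_one_error_rate_of_t_path(self):
        """Both groups from one Gaussian: raw rejections at 5% stay near 5%."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_t = 0
        for _ in range(1000):
            a, b = rng.normal(size=10), rng.normal(size=10)
            res = compare_groups(a, b)
            if res.test_used == "t_test":
                n_t += 1
                rejections += res.p_raw < 0.05
        assert n_t > 800  # gate rarely rejects normality for Gaussian data
        assert 0.035 <= rejections / n_t <= 0.065


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni([0.0025], 10) == [pytest.approx(0.025)]
        assert bonferroni([0.5], 10) == [1.0]
        assert bonferroni([0.3, 0.01], 1 + 1) == [pytest.approx(0.6), pytest.approx(0.02)]

    def test_identity_for_single_test(self):
        assert bonferroni([0.123], 1) == [pytest.approx(0.123)]

    def test_monotone_order_preserving(self):
        rng = np.random.default_rng(5)
        ps = np.sort(rng.random(8))
        out = bonferroni(ps, 10)
        assert all(a <= b for a, b in zip(out, out[1:]))
        assert all(c >= r for c, r in zip(out, ps))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)


class TestComparisonPlan:
    def test_study_configuration_has_ten_tests_in_three_families(self):
        plan = comparison_plan()
        fams = {f: [c for c in plan if c.family == f] for f in "abc"}
        assert len(plan) == 10
        assert len(fams["a"]) == 4
        assert len(fams["b"]) == 3
        assert len(fams["c"]) == 3
        # family a touches only the two control groups and the atlas kinds
        for c in fams["a"]:
            for g, k in (c.side_a, c.side_b):
                assert g in ("hcp_test_control", "chiasm_control")
                assert k in ("atlas_initial", "atlas_corrected")
        # family b: corrected vs cnn within each group
        assert {c.side_a[0] for c in fams["b"]} == {
            "hcp_test_control", "chiasm_control", "chiasm_albinism"
        }
        # family c: cnn between every group pair
        assert all(c.side_a[1] == c.side_b[1] == "cnn" for c in fams["c"])

    def test_single_group_single_kind_empty(self):
        assert comparison_plan(("cnn",), ("chiasm_control",)) == []

    def test_labels_unique_and_two_sided(self):
        plan = comparison_plan()
        labels = [c.label for c in plan]
        assert len(set(labels)) == 10
        for c in plan:
            assert f"{c.side_a[0]}:{c.side_a[1]}" in c.label
            assert f"{c.side_b[0]}:{c.side_b[1]}" in c.label

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            comparison_plan(("freehand",), ("chiasm_control",))


class TestEvaluateCohort:
    @staticmethod
    def _records(rng, n_control=8, n_malformed=9):
        recs = []
        for i in range(n_control):
            for kind, mu in (("atlas_initial", 0.55), ("atlas_corrected", 0.75), ("cnn", 0.8)):
                recs.append(DscRecord(f"c{i}", "control", kind, np.clip(mu + rng.normal(0, 0.04), 0, 1)))
        for i in range(n_malformed):
            for kind, mu in (("atlas_initial", 0.5), ("atlas_corrected", 0.6), ("cnn", 0.4)):
                recs.append(DscRecord(f"m{i}", "malformed", kind, np.clip(mu + rng.normal(0, 0.06), 0, 1)))
        return recs

    def test_full_table_populated(self):
        rng = np.random.default_rng(0)
        table, results = evaluate_cohort(self._records(rng))
        # diagonal summaries for every (group, kind) cell
        for idx in table.index:
            assert "+/-" in table.loc[idx, idx]
        assert all(r.p_corrected is not None for r in results)
        assert all(r.family_size == len(results) for r in results)

    def test_identical_values_give_p_one(self):
        recs = []
        for g in ("control", "malformed"):
            for i in range(8):
                for kind in ("atlas_initial", "atlas_corrected", "cnn"):
                    recs.append(DscRecord(f"{g}{i}", g, kind, 0.5))
        _, results = evaluate_cohort(recs)
        assert all(r.p_corrected == pytest.approx(1.0) for r in results)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        recs = self._records(rng)
        table1, _ = evaluate_cohort(recs)
        perm = [recs[i] for i in np.random.default_rng(2).permutation(len(recs))]
        table2, _ = evaluate_cohort(perm)
        assert table1.equals(table2)

    def test_missing_cell_rejected(self):
        recs = [DscRecord("a", "control", "cnn", 0.5), DscRecord("b", "control", "cnn", 0.6),
                DscRecord("a2", "malformed", "cnn", 0.1)]
        with pytest.raises(ValueError, match="n=1"):
            evaluate_cohort(recs)
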