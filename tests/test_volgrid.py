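"""Core grid primitives: I/O round trips, DSC, components, dilation, percentiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chiasmseg.volgrid import (
    BinaryMask,
    Volume,
    binarize_band,
    dilate,
    dsc,
    largest_component,
    percentile,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)

from conftest import flood_fill_components, random_mask


class TestIO:
    def test_volume_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        v = Volume(rng.random((16, 16, 16)), spacing=(1.25, 1.25, 1.25))
        p = tmp_path / "vol.nii.gz"
        write_volume(v, p)
        back = read_volume(p)
        np.testing.assert_array_equal(back.data, v.data)
        assert back.spacing == v.spacing

    def test_mask_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        m = random_mask(rng, (12, 10, 8))
        p = tmp_path / "mask.nii.gz"
        write_mask(m, p)
        back = read_mask(p)
        np.testing.assert_array_equal(back.data, m.data)

    def test_two_valued_mask_normalized_with_warning(self, tmp_path):
        import nibabel as nib

        data = np.zeros((6, 6, 6), dtype=np.uint8)
        data[2:4, 2:4, 2:4] = 255
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "m255.nii.gz"))
        with pytest.warns(UserWarning, match="normalized"):
            m = read_mask(tmp_path / "m255.nii.gz")
        assert set(np.unique(m.data)) == {0, 1}
        assert m.count() == 8

    def test_4d_input_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(np.zeros((4, 4, 4, 3)), np.eye(4)),
            str(tmp_path / "4d.nii.gz"),
        )
        with pytest.raises(ValueError, match="expected 3D"):
            read_volume(tmp_path / "4d.nii.gz")

    def test_mask_with_many_values_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(np.arange(27.0).reshape(3, 3, 3), np.eye(4)),
            str(tmp_path / "many.nii.gz"),
        )
        with pytest.raises(ValueError, match="distinct values"):
            read_mask(tmp_path / "many.nii.gz")


class TestDsc:
    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b = np.zeros_like(a)
        b[3, 3, 3] = 1
        assert dsc(BinaryMask(a), BinaryMask(a)) == 1.0
        assert dsc(BinaryMask(a), BinaryMask(b)) == 0.0

    def test_half_overlap_blocks(self):
        # |A| = |B| = 4, |A ∩ B| = 2 -> 2*2/8 = 0.5
        a = np.zeros((3, 2, 2), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0:2, :, 0] = 1  # voxels at x in {0,1}
        b[1:3, :, 0] = 1  # voxels at x in {1,2}
        assert dsc(BinaryMask(a), BinaryMask(b)) == 0.5

    def test_both_empty_raises(self):
        z = BinaryMask(np.zeros((3, 3, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            dsc(z, z)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dsc(
                BinaryMask(np.ones((2, 2, 2), dtype=np.uint8)),
                BinaryMask(np.ones((3, 3, 3), dtype=np.uint8)),
            )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask(rng), random_mask(rng)
        if not (a.count() or b.count()):
            return
        assert dsc(a, b) == pytest.approx(dsc(b, a))


class TestLargestComponent:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        """Output equals the max-size flood-fill component on 200 random 8^3 masks."""
        for seed in range(200):
            rng = np.random.default_rng(seed)
            m = random_mask(rng, p=0.25)
            if m.count() == 0:
                continue
            comps = flood_fill_components(m.data, connectivity)
            best_size = max(len(c) for c in comps)
            tied = [c for c in comps if len(c) == best_size]
            # tie-break: component containing the smallest linear index
            expected = min(tied, key=min)
            got = largest_component(m, connectivity=connectivity)
            got_idx = set(np.flatnonzero(got.data.ravel()).tolist())
            assert got_idx == expected, f"seed {seed}"

    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        m[1, 1, 1] = 1
        out = largest_component(BinaryMask(m))
        np.testing.assert_array_equal(out.data, m)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            largest_component(BinaryMask(np.zeros((3, 3, 3), dtype=np.uint8)))


class TestDilate:
    def test_empty_stays_empty(self):
        z = BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8))
        assert dilate(z).count() == 0

    def test_interior_voxel_cross(self):
        m = np.zeros((5, 5, 5), dtype=np.uint8)
        m[2, 2, 2] = 1
        out = dilate(BinaryMask(m), element="cross6")
        assert out.count() == 7

    def test_corner_voxel_cube_clipped(self):
        m = np.zeros((5, 5, 5), dtype=np.uint8)
        m[0, 0, 0] = 1
        out = dilate(BinaryMask(m), element="cube26")
        assert out.count() == 8
        assert out.data[:2, :2, :2].sum() == 8

    @given(seed=st.integers(0, 10_000), element=st.sampled_from(["cross6", "cube26"]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_extensive_and_monotone(self, seed, element):
        rng = np.random.default_rng(seed)
        m2 = random_mask(rng, p=0.3)
        sub = BinaryMask(m2.data * random_mask(rng, p=0.7).data)
        d_sub, d_m2 = dilate(sub, element), dilate(m2, element)
        assert np.all(d_m2.data >= m2.data)  # extensive
        assert np.all(d_sub.data <= d_m2.data)  # monotone


class TestPercentile:
    @pytest.mark.parametrize(
        "values,q,expected",
        [
            ([1, 2, 3], 50, 2.0),
            ([5, 5, 5, 5], 37.2, 5.0),
            ([10, 20, 30, 40], 66, 29.8),  # idx = 3*0.66 = 1.98
            ([10, 20, 30, 40], 0, 10.0),
            ([10, 20, 30, 40], 100, 40.0),
        ],
    )
    def test_linear_interpolation(self, values, q, expected):
        assert percentile(values, q) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            percentile([], 50)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_q_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=rng.integers(1, 30))
        qs = sorted(rng.uniform(0, 100, size=4))
        ps = [percentile(vals, q) for q in qs]
        assert all(a <= b + 1e-12 for a, b in zip(ps, ps[1:]))
        assert percentile(rng.permutation(vals), qs[0]) == pytest.approx(ps[0])


class TestBinarizeBand:
    def test_full_range_all_ones(self):
        v = Volume(np.arange(27.0).reshape(3, 3, 3))
        assert binarize_band(v, 0, 26).count() == 27

    def test_point_band(self):
        v = Volume(np.arange(27.0).reshape(3, 3, 3))
        out = binarize_band(v, 13, 13)
        assert out.count() == 1
        assert out.data.ravel()[13] == 1

    def test_integer_band_inclusive(self):
        v = Volume(np.arange(1.0, 28.0).reshape(3, 3, 3))
        assert binarize_band(v, 10, 20).count() == 11

    def test_inverted_band_raises(self):
        with pytest.raises(ValueError):
            binarize_band(Volume(np.zeros((2, 2, 2))), 5, 1)
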