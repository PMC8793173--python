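"""Standardization, region mapping, pad/crop/block geometry and I/O."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iresunet3p.preprocessing import (BlockSpec, CaseRecord, PreprocessingError,
                                      blockify, center_crop, deblockify,
                                      labels_to_regions, make_2d_patches,
                                      pad_depth, preprocess_case_3d,
                                      read_arrays, read_case,
                                      reassemble_case_3d, standardize,
                                      uncrop, unpad_depth, write_arrays,
                                      write_case)


class TestStandardize:
    def test_two_value_hand_arithmetic(self):
        """Nonzero voxels {2, 4}: mean 3, population SD 1 -> {-1, +1}."""
        v = np.zeros((1, 2, 2))
        v[0, 0, 0] = 2.0
        v[0, 1, 1] = 4.0
        out = standardize(v)
        assert out[0, 0, 0] == pytest.approx(-1.0)
        assert out[0, 1, 1] == pytest.approx(1.0)
        assert out[0, 0, 1] == 0.0 and out[0, 1, 0] == 0.0

    def test_idempotent_on_support(self, rng):
        v = rng.normal(2.0, 3.0, size=(4, 5, 6))
        v[v == 0] = 1.0  # ensure full support
        once = standardize(v)
        twice = standardize(once)
        np.testing.assert_allclose(twice, once, atol=1e-6)

    def test_degenerate_volumes_warn_and_zero(self):
        with pytest.warns(UserWarning):
            out = standardize(np.zeros((3, 3, 3)))
        assert not out.any()
        const = np.full((2, 2, 2), 5.0)
        with pytest.warns(UserWarning):
            out = standardize(const)
        assert not out.any()


class TestRegions:
    def test_single_voxel_memberships(self):
        labels = np.zeros((1, 1, 3), dtype=int)
        labels[0, 0, 0] = 4  # ET
        labels[0, 0, 1] = 2  # ED
        labels[0, 0, 2] = 1  # NET
        m = labels_to_regions(labels)
        # ET voxel belongs to all three nested regions
        assert (m.wt[0, 0, 0], m.tc[0, 0, 0], m.et[0, 0, 0]) == (1, 1, 1)
        # ED voxel belongs only to the whole tumor
        assert (m.wt[0, 0, 1], m.tc[0, 0, 1], m.et[0, 0, 1]) == (1, 0, 0)
        # NET voxel belongs to WT and TC
        assert (m.wt[0, 0, 2], m.tc[0, 0, 2], m.et[0, 0, 2]) == (1, 1, 0)

    def test_all_background(self):
        m = labels_to_regions(np.zeros((2, 2, 2), dtype=int))
        assert not (m.wt.any() or m.tc.any() or m.et.any())

    def test_unknown_code_listed(self):
        labels = np.zeros((2, 2, 2), dtype=int)
        labels[0, 0, 0] = 7
        with pytest.raises(PreprocessingError, match="7"):
            labels_to_regions(labels)

    def test_nesting_invariant(self, small_case):
        m = labels_to_regions(small_case.labels)
        assert m.nested()


class TestPadCrop:
    def test_155_to_160_gives_3_2(self):
        v = np.ones((155, 4, 4))
        padded, rec = pad_depth(v, 160)
        assert padded.shape[0] == 160 and rec == (3, 2)
        assert not padded[:3].any() and not padded[-2:].any()

    def test_identity_and_roundtrip(self, rng):
        v = rng.normal(size=(160, 3, 3))
        padded, rec = pad_depth(v, 160)
        assert rec == (0, 0)
        np.testing.assert_array_equal(padded, v)
        v2 = rng.normal(size=(150, 3, 3))
        padded, rec = pad_depth(v2, 160)
        np.testing.assert_array_equal(unpad_depth(padded, rec), v2)

    def test_depth_exceeding_target_raises(self):
        with pytest.raises(PreprocessingError):
            pad_depth(np.zeros((161, 2, 2)), 160)

    def test_center_crop_240_to_160(self):
        v = np.zeros((160, 240, 240))
        out, offs = center_crop(v, (160, 160, 160))
        assert out.shape == (160, 160, 160)
        assert offs == (0, 40, 40)

    def test_center_crop_odd_remainder_floor_front(self):
        v = np.arange(7)[:, None] * np.ones((7, 2))
        out, offs = center_crop(v, (4, 2))
        assert offs == (1, 0)  # (7-4)//2 = 1: one removed in front, two behind
        np.testing.assert_array_equal(out[:, 0], [1, 2, 3, 4])

    def test_uncrop_inverts(self, rng):
        v = rng.normal(size=(8, 10, 12))
        out, offs = center_crop(v, (4, 6, 8))
        restored = uncrop(out, offs, v.shape)
        np.testing.assert_array_equal(
            restored[offs[0]:offs[0] + 4, offs[1]:offs[1] + 6,
                     offs[2]:offs[2] + 8], out)


class TestBlocks:
    def test_method_a_five_blocks(self):
        blocks, offs = blockify(np.zeros((160, 4, 4)), BlockSpec(z_step=32))
        assert len(blocks) == 5
        assert offs == [0, 32, 64, 96, 128]

    def test_method_b_seventeen_blocks(self):
        blocks, offs = blockify(np.zeros((160, 4, 4)), BlockSpec(z_step=8))
        assert len(blocks) == 17
        assert np.all(np.diff(offs) == 8)

    def test_single_block(self):
        spec = BlockSpec(block_depth=32, z_step=8)
        blocks, offs = blockify(np.zeros((32, 2, 2)), spec)
        assert len(blocks) == 1 and offs == [0]

    def test_indivisible_step_raises(self):
        with pytest.raises(PreprocessingError, match="step"):
            blockify(np.zeros((150, 2, 2)), BlockSpec(z_step=32))

    @pytest.mark.parametrize("step", [8, 32])
    def test_roundtrip_exact(self, step, rng):
        v = rng.normal(size=(160, 3, 3)).astype(np.float64)
        spec = BlockSpec(z_step=step)
        blocks, offs = blockify(v, spec)
        out = deblockify(blocks, offs, 160)
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_constant_volume_survives_overlap_averaging(self):
        v = np.ones((64, 2, 2))
        spec = BlockSpec(block_depth=32, z_step=8)
        blocks, offs = blockify(v, spec)
        np.testing.assert_array_equal(deblockify(blocks, offs, 64), v)

    def test_coverage_gap_raises(self):
        with pytest.raises(PreprocessingError, match="gap"):
            deblockify([np.ones((4, 2, 2))], [0], 10)

    def test_method_a_partitions_method_b_covers(self):
        depth = 160
        for step, max_cover in ((32, 1), (8, 4)):
            spec = BlockSpec(z_step=step)
            _, offs = blockify(np.zeros((depth, 1, 1)), spec)
            cover = np.zeros(depth, dtype=int)
            for z in offs:
                cover[z:z + 32] += 1
            assert cover.min() >= 1
            assert cover.max() == max_cover

    @given(depth=st.sampled_from([32, 64, 96, 160]),
           step=st.sampled_from([8, 16, 32]))
    @settings(max_examples=12, deadline=None, derandomize=True)
    def test_block_count_formula(self, depth, step):
        spec = BlockSpec(block_depth=32, z_step=step)
        blocks, _ = blockify(np.zeros((depth, 1, 1)), spec)
        assert len(blocks) == (depth - 32) // step + 1


class TestPatchesAndPipeline:
    def test_patch_count_and_shapes(self, small_case):
        imgs, regs = make_2d_patches(small_case, patch_hw=48)
        assert imgs.shape == (32, 4, 48, 48)
        assert regs.shape == (32, 3, 48, 48)

    def test_empty_slice_filter_monotone(self, small_case):
        full, _ = make_2d_patches(small_case, patch_hw=48)
        kept, _ = make_2d_patches(small_case, patch_hw=48, filter_empty=True)
        assert kept.shape[0] <= full.shape[0]

    def test_nesting_preserved_through_pipeline(self, small_case,
                                                small_block_spec):
        _, region_blocks, _ = preprocess_case_3d(small_case, small_block_spec)
        for rb in region_blocks:
            wt, tc, et = rb[0] > 0.5, rb[1] > 0.5, rb[2] > 0.5
            assert np.all(et <= tc) and np.all(tc <= wt)

    def test_geometry_roundtrip_recovers_regions(self, small_case,
                                                 small_block_spec):
        """Feeding the true region blocks back through the inverse geometry
        reproduces the ground truth inside the crop window exactly."""
        _, region_blocks, sidecar = preprocess_case_3d(small_case,
                                                       small_block_spec)
        restored = reassemble_case_3d(region_blocks, sidecar)
        m = labels_to_regions(small_case.labels)
        truth = m.stack()
        offs = sidecar["crop_offsets"]
        ch, cw = small_block_spec.crop_shape[1:]
        window = (slice(None), slice(None),
                  slice(offs[1], offs[1] + ch), slice(offs[2], offs[2] + cw))
        np.testing.assert_allclose(restored[window], truth[window], atol=1e-6)


class TestIO:
    def test_nifti_roundtrip(self, small_case, tmp_path):
        case_dir = write_case(small_case, tmp_path)
        back = read_case(case_dir)
        np.testing.assert_allclose(back.modalities, small_case.modalities,
                                   atol=1e-6)
        np.testing.assert_array_equal(back.labels, small_case.labels)
        assert back.case_id == small_case.case_id

    def test_missing_modality_listed(self, small_case, tmp_path):
        case_dir = write_case(small_case, tmp_path)
        (case_dir / f"{small_case.case_id}_flair.nii.gz").unlink()
        with pytest.raises(PreprocessingError, match="flair"):
            read_case(case_dir)

    def test_npy_roundtrip_bit_exact(self, rng, tmp_path):
        arrays = {"blocks": rng.normal(size=(2, 4, 8, 8)).astype(np.float32)}
        sidecar = {"pad_record": [3, 2]}
        write_arrays(arrays, tmp_path / "case", sidecar)
        back, side = read_arrays(tmp_path / "case")
        np.testing.assert_array_equal(back["blocks"], arrays["blocks"])
        assert side == sidecar

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(PreprocessingError):
            CaseRecord(modalities=np.zeros((4, 8, 8, 8)),
                       labels=np.zeros((8, 8, 7), dtype=int),
                       case_id="bad")
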