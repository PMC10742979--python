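"""Stack I/O, frame handling, patching, normalisation and ROI splitting."""

import numpy as np
import pytest
import tifffile
import yaml
from hypothesis import given, settings, strategies as st

from wunet.stack_io import (DataError, DatasetSplit, NormalizationParams,
                            StackFormatError, StackStructureError,
                            TissueStack, denormalize, frame_average,
                            patch_2x2, percentile_normalize, read_stack,
                            select_input_frame, split_by_roi, stitch_2x2,
                            write_stack)


def _stack(voxels, provenance="raw_frames", **kw):
    return TissueStack(channel="NADPH", voxels=voxels,
                       provenance=provenance, **kw)


class TestTissueStack:
    def test_invariants(self, rng):
        with pytest.raises(ValueError):
            _stack(rng.random((2, 3, 4, 4)), provenance="raw_single")
        with pytest.raises(DataError):
            _stack(-np.ones((2, 1, 4, 4)), provenance="clean")
        with pytest.raises(DataError):
            _stack(np.full((2, 1, 4, 4), np.nan))
        # denoised output may go slightly negative
        _stack(-0.1 * np.ones((2, 1, 4, 4)), provenance="denoised")


class TestDiskRoundTrip:
    def test_round_trip_is_exact(self, tmp_path, rng):
        stack = _stack(rng.random((3, 2, 16, 16)), roi_id="r1",
                       patient_id="p1")
        path = write_stack(stack, tmp_path / "s.tif")
        back = read_stack(path)
        np.testing.assert_array_equal(back.voxels, stack.voxels)
        assert back.roi_id == "r1" and back.channel == "NADPH"
        assert back.frames_per_depth == 2 and back.n_depths == 3

    def test_page_layout_declared_in_sidecar(self, tmp_path, rng):
        # 30 pages at 6 frames/depth -> 5 depths
        pages = rng.random((30, 8, 8)).astype(np.float32)
        tifffile.imwrite(tmp_path / "s.tif", pages)
        header = {"frames_per_depth": 6, "channel": "FAD",
                  "provenance": "raw_frames"}
        (tmp_path / "s.tif.yaml").write_text(yaml.safe_dump(header))
        stack = read_stack(tmp_path / "s.tif")
        assert stack.n_depths == 5 and stack.frames_per_depth == 6

    def test_indivisible_page_count_is_structural_error(self, tmp_path, rng):
        tifffile.imwrite(tmp_path / "s.tif",
                         rng.random((31, 8, 8)).astype(np.float32))
        (tmp_path / "s.tif.yaml").write_text(yaml.safe_dump(
            {"frames_per_depth": 6, "channel": "FAD",
             "provenance": "raw_frames"}))
        with pytest.raises(StackStructureError):
            read_stack(tmp_path / "s.tif")

    def test_color_pages_are_format_error(self, tmp_path, rng):
        tifffile.imwrite(tmp_path / "s.tif",
                         (rng.random((4, 8, 8, 3)) * 255).astype(np.uint8))
        (tmp_path / "s.tif.yaml").write_text(yaml.safe_dump(
            {"frames_per_depth": 2, "channel": "FAD",
             "provenance": "raw_frames"}))
        with pytest.raises(StackFormatError):
            read_stack(tmp_path / "s.tif")


class TestFrameAverage:
    def test_mean_of_constant_frames(self):
        stack = _stack(np.full((2, 6, 8, 8), 3.5))
        out = frame_average(stack)
        assert out.provenance == "gt_average"
        np.testing.assert_allclose(out.voxels, 3.5)

    def test_mean_of_two_frames(self):
        vox = np.zeros((1, 2, 4, 4))
        vox[0, 1] = 2.0
        np.testing.assert_allclose(frame_average(_stack(vox), 2).voxels, 1.0)

    def test_variance_reduction_law(self, rng):
        # clean + i.i.d. N(0,1) noise, n=6 -> residual variance ~ 1/6
        clean = np.full((512, 512), 10.0)
        vox = clean[None, None] + rng.standard_normal((1, 6, 512, 512))
        avg = frame_average(_stack(vox), 6)
        resid_var = np.var(avg.voxels[0, 0] - clean)
        assert abs(resid_var - 1 / 6) < 0.1 / 6

    def test_too_many_frames_requested(self):
        with pytest.raises(ValueError):
            frame_average(_stack(np.ones((1, 3, 4, 4))), 6)


class TestSelectInputFrame:
    def test_single_frame_returned_unchanged(self):
        stack = _stack(np.ones((2, 1, 4, 4)))
        out = select_input_frame(stack, seed=0)
        np.testing.assert_array_equal(out.voxels, stack.voxels)
        assert out.provenance == "raw_single"

    def test_deterministic_given_seed(self, rng):
        stack = _stack(rng.random((4, 6, 8, 8)))
        a = select_input_frame(stack, seed=5)
        b = select_input_frame(stack, seed=5)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_all_frames_eventually_selected(self):
        # frames are distinct constants; many seeds must cover all six
        vox = np.tile(np.arange(6.0)[None, :, None, None], (1, 1, 4, 4))
        stack = _stack(vox)
        seen = {float(select_input_frame(stack, seed=s).voxels[0, 0, 0, 0])
                for s in range(1000)}
        assert seen == {0.0, 1.0, 2.0, 3.0, 4.0, 5.0}

    def test_whole_stack_mode_uses_one_index(self, rng):
        vox = np.tile(np.arange(6.0)[None, :, None, None], (5, 1, 4, 4))
        out = select_input_frame(_stack(vox), seed=3, per_depth=False)
        assert len(np.unique(out.voxels)) == 1


class TestPatching:
    def test_512_splits_into_four_256(self, rng):
        patches = patch_2x2(rng.random((512, 512)))
        assert patches.shape == (4, 256, 256)

    def test_stitch_inverts_patch(self, rng):
        x = rng.random((64, 48))
        np.testing.assert_array_equal(stitch_2x2(patch_2x2(x)), x)

    def test_checkerboard_reassembly_order(self):
        quads = np.stack([np.full((2, 2), v) for v in (1.0, 2.0, 3.0, 4.0)])
        out = stitch_2x2(quads)
        assert out[0, 0] == 1 and out[0, 3] == 2
        assert out[3, 0] == 3 and out[3, 3] == 4

    def test_single_pixel_quadrants(self):
        out = stitch_2x2(np.arange(4.0).reshape(4, 1, 1))
        np.testing.assert_array_equal(out, [[0, 1], [2, 3]])

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            patch_2x2(rng.random((5, 4)))
        with pytest.raises(ValueError):
            stitch_2x2(np.ones((4, 2, 2)), indices=(0, 1, 2, 2))


class TestPercentileNormalize:
    def test_full_range_is_linear_map(self):
        x = np.linspace(0, 100, 256).reshape(16, 16)
        norm, params = percentile_normalize(x, 0, 100)
        np.testing.assert_allclose(norm.min(), 0, atol=1e-12)
        np.testing.assert_allclose(norm.max(), 1, atol=1e-12)

    def test_constant_input_is_degenerate(self):
        norm, params = percentile_normalize(np.full((8, 8), 7.0))
        assert params.degenerate
        np.testing.assert_array_equal(norm, 0)
        np.testing.assert_allclose(denormalize(norm, params), 7.0)

    def test_inverse_pair(self, rng):
        x = 50 + 10 * rng.standard_normal((32, 32))
        norm, params = percentile_normalize(x)
        np.testing.assert_allclose(denormalize(norm, params), x,
                                   rtol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            percentile_normalize(np.array([[1.0, np.inf]]))


class TestSplitByRoi:
    def test_proportions(self):
        s = split_by_roi([f"r{i}" for i in range(100)], (0.75, 0.25), 0)
        assert len(s.train_rois) == 75 and len(s.val_rois) == 25
        assert len(s.test_rois) == 0

    def test_same_seed_same_split(self):
        rois = list("abcdefghij")
        assert split_by_roi(rois, seed=9) == split_by_roi(rois, seed=9)

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(4, 60), seed=st.integers(0, 2 ** 20),
           f_train=st.floats(0.3, 0.7))
    def test_partition_property(self, n, seed, f_train):
        rois = [f"roi{i}" for i in range(n)]
        s = split_by_roi(rois, (f_train, 0.25), seed)
        groups = [s.train_rois, s.val_rois, s.test_rois]
        union = set().union(*groups)
        assert union == set(rois)
        assert sum(len(g) for g in groups) == n  # pairwise disjoint

    def test_too_few_rois(self):
        with pytest.raises(ValueError):
            split_by_roi(["a"], (0.75, 0.25), 0)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            DatasetSplit(frozenset("ab"), frozenset("bc"), frozenset(), 0)
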