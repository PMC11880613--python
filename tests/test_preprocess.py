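"""ROI preprocessing: bounding box, depth crop, resize, normalization."""

import numpy as np
import pytest

from xaimri.errors import BoundsError, NoForegroundError, ValidationError
from xaimri.preprocess import (
    PreprocessConfig,
    RoiBox,
    RoiPreprocessor,
    apply_roi,
    compute_roi_box,
    crop_depth,
    normalize_intensity,
    preprocess_subject,
    resize_inplane,
)


def brute_force_box(slice2d, threshold=0.0):
    """Exhaustive index-scan oracle for the tight bounding box."""
    xs, ys = [], []
    for i in range(slice2d.shape[0]):
        for j in range(slice2d.shape[1]):
            if slice2d[i, j] > threshold:
                xs.append(i)
                ys.append(j)
    return min(xs), max(xs) + 1, min(ys), max(ys) + 1


class TestComputeRoiBox:
    def test_default_reference_slice_is_77(self):
        assert PreprocessConfig().reference_slice == 77

    def test_single_pixel_degenerate_box(self):
        vol = np.zeros((32, 32, 5), dtype=np.float32)
        vol[10, 20, 2] = 1.0
        cfg = PreprocessConfig(reference_slice=2, depth_range=(0, 5), target_inplane=8)
        box = compute_roi_box(vol, cfg)
        assert (box.x1, box.x2, box.y1, box.y2) == (10, 11, 20, 21)

    def test_filled_ellipse_matches_exhaustive_scan(self, rng):
        ii, jj = np.mgrid[0:40, 0:40]
        vol = np.zeros((40, 40, 3), dtype=np.float32)
        vol[:, :, 1] = (((ii - 22) / 9.0) ** 2 + ((jj - 17) / 13.0) ** 2 <= 1).astype(np.float32)
        cfg = PreprocessConfig(reference_slice=1, depth_range=(0, 3), target_inplane=8)
        box = compute_roi_box(vol, cfg)
        assert (box.x1, box.x2, box.y1, box.y2) == brute_force_box(vol[:, :, 1])

    def test_random_slices_match_oracle(self, rng):
        cfg = PreprocessConfig(reference_slice=0, depth_range=(0, 1), target_inplane=8)
        for _ in range(200):
            sl = (rng.random((16, 16)) < 0.1).astype(np.float32)
            if not sl.any():
                continue
            box = compute_roi_box(sl[:, :, None], cfg)
            assert (box.x1, box.x2, box.y1, box.y2) == brute_force_box(sl)

    def test_no_foreground_never_returns_full_frame(self):
        cfg = PreprocessConfig(reference_slice=0, depth_range=(0, 1), target_inplane=8)
        with pytest.raises(NoForegroundError):
            compute_roi_box(np.zeros((8, 8, 1), dtype=np.float32), cfg)


class TestCropDepth:
    def test_default_range_keeps_128_of_155(self):
        vol = np.zeros((4, 4, 155), dtype=np.float32)
        assert crop_depth(vol, (13, 141)).shape[2] == 128

    def test_full_range_is_identity(self, rng):
        vol = rng.random((4, 4, 9)).astype(np.float32)
        assert np.array_equal(crop_depth(vol, (0, 9)), vol)

    @pytest.mark.parametrize("bad", [(141, 13), (0, 200), (-1, 5)])
    def test_invalid_ranges_rejected(self, bad):
        with pytest.raises(BoundsError):
            crop_depth(np.zeros((4, 4, 155)), bad)


class TestApplyRoi:
    def test_full_frame_box_is_identity(self, rng):
        vol = rng.random((8, 8, 4)).astype(np.float32)
        box = RoiBox(0, 8, 0, 8, reference_slice=0, depth_range=(0, 4))
        assert np.array_equal(apply_roi(vol, box), vol)

    def test_crop_is_pure_slicing(self, rng):
        vol = rng.random((12, 10, 4)).astype(np.float32)
        box = RoiBox(2, 9, 1, 8, reference_slice=0, depth_range=(0, 4))
        out = apply_roi(vol, box)
        assert np.array_equal(out, vol[2:9, 1:8, :])

    def test_same_box_gives_same_inplane_shape_for_all_five_arrays(self, small_subject):
        cfg = PreprocessConfig.scaled(small_subject.grid_shape, 16)
        box = compute_roi_box(small_subject.volumes["T1"], cfg)
        shapes = {
            apply_roi(small_subject.volumes[m], box).shape[:2]
            for m in small_subject.volumes
        }
        shapes.add(apply_roi(small_subject.labels, box).shape[:2])
        assert len(shapes) == 1

    def test_box_beyond_extents_rejected(self):
        box = RoiBox(0, 30, 0, 30, reference_slice=0, depth_range=(0, 2))
        with pytest.raises(BoundsError):
            apply_roi(np.zeros((8, 8, 2)), box)


class TestResizeInplane:
    def test_identity_when_already_target_size(self, rng):
        labels = rng.integers(0, 4, size=(16, 16, 4))
        assert np.array_equal(resize_inplane(labels, 16, is_label=True), labels)

    def test_nearest_upsampling_replicates_2x2_blocks(self):
        sl = np.array([[1, 2], [3, 4]], dtype=np.int16)[:, :, None]
        out = resize_inplane(sl, 4, is_label=True)[:, :, 0]
        expected = np.array([
            [1, 1, 2, 2],
            [1, 1, 2, 2],
            [3, 3, 4, 4],
            [3, 3, 4, 4],
        ])
        assert np.array_equal(out, expected)

    def test_label_resize_never_invents_values(self, rng):
        for _ in range(100):
            labels = rng.choice([0, 1, 2, 3], size=(11, 13, 2), p=[0.7, 0.1, 0.1, 0.1])
            out = resize_inplane(labels, 8, is_label=True)
            assert set(np.unique(out)) <= set(np.unique(labels))
            assert out.dtype == labels.dtype

    def test_target_shape_and_validation(self, rng):
        vol = rng.random((40, 30, 3)).astype(np.float32)
        assert resize_inplane(vol, 128).shape == (128, 128, 3)
        with pytest.raises(ValidationError):
            resize_inplane(vol, 0)


class TestNormalizeIntensity:
    def test_constant_volume_maps_to_zero(self):
        assert not normalize_intensity(np.full((4, 4, 2), 7.0)).any()

    def test_endpoint_mapping(self):
        vol = np.zeros((2, 2, 1), dtype=np.float32)
        vol[0, 0, 0] = 10.0
        vol[0, 1, 0] = 2.0
        out = normalize_intensity(vol)
        assert out[0, 0, 0] == pytest.approx(1.0)

    def test_minmax_by_brute_force_scan(self, rng):
        vol = rng.random((10, 10, 5)).astype(np.float32) + 0.1
        out = normalize_intensity(vol)
        assert out.min() == pytest.approx(0.0, abs=1e-7)
        assert out.max() == pytest.approx(1.0, abs=1e-7)


class TestPreprocessSubject:
    def test_output_cube_shape(self, preprocessed_subject):
        assert preprocessed_subject.shape == (32, 32, 32)
        assert preprocessed_subject.mask.shape == (32, 32, 32)

    def test_deterministic(self, small_subject):
        cfg = PreprocessConfig.scaled(small_subject.grid_shape, 16)
        a = preprocess_subject(small_subject, cfg)
        b = preprocess_subject(small_subject, cfg)
        for m in a.volumes:
            assert np.array_equal(a.volumes[m], b.volumes[m])
        assert np.array_equal(a.mask, b.mask)

    def test_mask_label_set_is_remapped_subset(self, small_subject, preprocessed_subject):
        raw = set(np.unique(small_subject.labels))
        remapped = {{0: 0, 1: 1, 2: 2, 4: 3}[v] for v in raw}
        assert set(np.unique(preprocessed_subject.mask)) <= remapped

    def test_standard_geometry_yields_128_cube(self):
        # full-size geometry through the default config; noise-free
        # keeps the phantom cheap to render
        from xaimri.phantom import PhantomSpec, generate_subject

        spec = PhantomSpec(noise_sigma=0.0, seed=11)
        subject = generate_subject(spec, "full")
        pre = preprocess_subject(subject, PreprocessConfig())
        assert pre.shape == (128, 128, 128)
        assert pre.roi_box.reference_slice == 77

    def test_shape_mismatch_across_modalities_rejected(self, small_subject):
        volumes = dict(small_subject.volumes)
        volumes["T2"] = volumes["T2"][:-2]
        with pytest.raises(ValidationError, match="disagree"):
            preprocess_subject((volumes, small_subject.labels),
                               PreprocessConfig.scaled(small_subject.grid_shape, 16))


class TestRoiPreprocessorEstimator:
    def test_transform_matches_function_path(self, small_cohort):
        cfg = PreprocessConfig.scaled(small_cohort[0].grid_shape, 16)
        est = RoiPreprocessor(cfg).fit(small_cohort[:2])
        outs = est.transform(small_cohort[:2])
        direct = preprocess_subject(small_cohort[0], cfg)
        assert np.array_equal(outs[0].mask, direct.mask)
        assert est.get_params()["config"] is cfg
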