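"""Otsu thresholding, labeling, size filtering and colocalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osteoquant import (
    DegenerateImageError,
    binarize_and_label,
    colocalize,
    dilated_bone_mask,
    filter_by_volume,
    otsu_threshold,
    render_stack,
    unmix,
)


def brute_force_otsu(image, nbins=256):
    """Independent oracle: scan every histogram cut, accumulate class
    weights and means with plain Python loops."""
    lo, hi = float(image.min()), float(image.max())
    counts, edges = np.histogram(np.asarray(image).ravel(), bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    sigmas = []
    for cut in range(nbins - 1):  # cut after bin `cut`; both classes non-trivial
        w0 = counts[: cut + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            sigmas.append(-1.0)
            continue
        mu0 = (counts[: cut + 1] * centers[: cut + 1]).sum() / w0
        mu1 = (counts[cut + 1 :] * centers[cut + 1 :]).sum() / w1
        sigmas.append(w0 * w1 * (mu0 - mu1) ** 2)
    sigmas = np.array(sigmas)
    peak = sigmas.max()
    # lowest threshold among (near-)maximizers, matching the tie-break rule
    return centers[np.flatnonzero(sigmas >= peak - 1e-12 * abs(peak))[0]]


class TestOtsu:
    def test_two_delta_histogram(self):
        image = np.array([10.0] * 50 + [200.0] * 50)
        t = otsu_threshold(image)
        assert 10.0 < t < 200.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            image = rng.gamma(2.0, 30.0, size=500) + rng.normal(0, 5, 500)
            assert otsu_threshold(image) == pytest.approx(brute_force_otsu(image))

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 3.0))


class TestLabeling:
    def test_two_squares_counted_exactly(self):
        img = np.zeros((20, 20))
        img[2:6, 2:6] = 1.0  # 16 px
        img[10:15, 10:16] = 1.0  # 30 px
        labels = binarize_and_label(img, 0.5, pixel_size_um=2.0)
        assert labels.n_objects == 2
        assert sorted(labels.table["pixels"]) == [16, 30]
        # physical area = count x pixel_area exactly
        assert sorted(labels.table["area_um2"]) == [16 * 4.0, 30 * 4.0]

    def test_connectivity_semantics(self):
        img = np.zeros((4, 4))
        img[0, 0] = img[1, 1] = 1.0  # diagonal touch
        assert binarize_and_label(img, 0.5, 1.0, connectivity=2).n_objects == 1
        assert binarize_and_label(img, 0.5, 1.0, connectivity=1).n_objects == 2

    def test_label_conservation(self, rng):
        img = (rng.uniform(0, 1, (40, 40)) > 0.6).astype(float)
        labels = binarize_and_label(img, 0.5, 1.0)
        assert labels.table["pixels"].sum() == labels.mask().sum()
        assert labels.n_objects == labels.label_image.max()
        assert list(labels.table["label"]) == list(range(1, labels.n_objects + 1))

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_and_label(np.zeros((4, 4)), 1.5, 1.0)

    def test_recovers_synthetic_osteoclast_footprints(self, small_scene, library):
        """Labeled objects overlap the ground-truth footprints (IoU >= 0.7)."""
        scene = small_scene
        stack = render_stack(scene)
        unmixed = unmix(stack, library)
        td = unmixed.channel("tdTomato")[0].max(axis=0)
        labels = binarize_and_label(td, otsu_threshold(td), stack.pixel_size_um)
        shape = scene.config.field_size_px
        matched = 0
        for cell in scene.cells_of("osteoclast"):
            truth = cell.footprint_mask(0, shape)
            best = 0.0
            for lab in range(1, labels.n_objects + 1):
                obj = labels.label_image == lab
                iou = (obj & truth).sum() / (obj | truth).sum()
                best = max(best, iou)
            if best >= 0.7:
                matched += 1
        assert matched == len(scene.cells_of("osteoclast"))


class TestVolumeFilter:
    def _labels_with_volumes(self, voxels):
        """Distinct blobs with the given voxel counts; 1 µm³ voxels."""
        depth = 4
        img = np.zeros((depth, 12, 10 * len(voxels)))
        for i, v in enumerate(voxels):
            per_slice = int(np.ceil(v / depth))
            left = v
            for z in range(depth):
                take = min(per_slice, left)
                img[z, 0, 10 * i : 10 * i + 1] = 0  # noop, keep shape clear
                ys, xs = np.unravel_index(np.arange(take), (12, 8))
                img[z, ys, xs + 10 * i] = 1.0
                left -= take
        return binarize_and_label(img, 0.5, pixel_size_um=1.0, z_step_um=1.0)

    def test_exclusive_survival_rule(self):
        labels = self._labels_with_volumes([30, 50, 51])
        out = filter_by_volume(labels, 50.0)
        assert out.n_objects == 1
        assert out.table["volume_um3"].iloc[0] == 51.0
        assert out.table["label"].iloc[0] == 1  # renumbered consecutively

    def test_idempotent(self):
        labels = self._labels_with_volumes([30, 50, 51, 120])
        once = filter_by_volume(labels, 50.0)
        twice = filter_by_volume(once, 50.0)
        np.testing.assert_array_equal(once.label_image, twice.label_image)
        assert once.table.equals(twice.table)

    def test_zero_bound_is_identity(self):
        labels = self._labels_with_volumes([30, 51])
        out = filter_by_volume(labels, 0.0)
        assert out.n_objects == 2

    def test_empty_labeling_passes_through(self):
        img = np.zeros((3, 6, 6))
        img[1, 3, 3] = 1.0  # one tiny object, removed by the filter
        labels = binarize_and_label(img, 0.5, 1.0, z_step_um=1.0)
        empty = filter_by_volume(labels, 50.0)
        assert empty.n_objects == 0
        again = filter_by_volume(empty, 50.0)  # empty input, no error
        assert again.n_objects == 0 and not again.label_image.any()

    def test_2d_input_rejected(self):
        labels = binarize_and_label(np.eye(4), 0.5, 1.0)
        with pytest.raises(ValueError, match="area"):
            filter_by_volume(labels, 50.0)


class TestColocalize:
    def test_disjoint_masks(self):
        a = np.zeros((2, 4, 4), bool)
        b = np.zeros((2, 4, 4), bool)
        a[0, :2] = True
        b[1, 2:] = True
        mask, measure = colocalize(a, b, 1.0, z_step_um=1.0)
        assert not mask.any() and measure == 0.0

    def test_subset_masks(self, rng):
        b = rng.uniform(0, 1, (3, 8, 8)) > 0.4
        a = b & (rng.uniform(0, 1, (3, 8, 8)) > 0.5)
        mask, measure = colocalize(a, b, 0.5, z_step_um=2.0)
        np.testing.assert_array_equal(mask, a)
        assert measure == pytest.approx(a.sum() * 0.25 * 2.0)

    @given(seed=st.integers(0, 10_000))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a = r.uniform(0, 1, (4, 6, 6)) > 0.5
        b = r.uniform(0, 1, (4, 6, 6)) > 0.5
        ma, va = colocalize(a, b, 1.0, z_step_um=1.0)
        mb, vb = colocalize(b, a, 1.0, z_step_um=1.0)
        np.testing.assert_array_equal(ma, mb)
        assert va == vb

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            colocalize(np.zeros((2, 2), bool), np.zeros((3, 3), bool), 1.0)

    def test_bone_dilation_expands_by_radius(self):
        bone = np.zeros((3, 5, 5), bool)
        bone[0] = True
        out = dilated_bone_mask(bone, radius_vox=1)
        assert out[1].all() and not out[2].any()
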