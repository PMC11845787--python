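"""Feature stack, random-forest classifier, thresholding, background
subtraction, components, and the subcellular volume filter."""

import numpy as np
import pytest
from scipy import ndimage

from qlsm import segmentation as seg
from qlsm.grids import VoxelGrid

SPACING = (2.5, 1.3, 1.3)


def _grid(data, spacing=SPACING):
    return VoxelGrid(np.asarray(data, dtype=np.float32), spacing)


class TestFeatures:
    def test_constant_image_has_zero_derivatives(self):
        fs = seg.extract_features(_grid(np.full((8, 12, 12), 7.0)), scales=(1.0,))
        for name, feat in zip(fs.names, fs.data):
            if name.startswith("gaussian"):
                assert np.allclose(feat, 7.0, atol=1e-4)
            elif name.startswith(("gradient", "laplacian", "hessian")):
                assert np.allclose(feat, 0.0, atol=1e-3)

    def test_single_voxel_matches_discrete_kernel(self):
        # smoothing an impulse reproduces the (normalized, truncated)
        # discrete Gaussian kernel product at the center
        img = np.zeros((9, 21, 21), dtype=np.float32)
        img[4, 10, 10] = 1.0
        fs = seg.extract_features(_grid(img, (1.3, 1.3, 1.3)), scales=(1.0,), kinds=("gaussian",))
        got = fs.data[0][4, 10, 10]

        def kernel_center(sigma, truncate=4.0):
            r = int(truncate * sigma + 0.5)
            x = np.arange(-r, r + 1)
            k = np.exp(-(x**2) / (2 * sigma**2))
            return k[r] / k.sum()

        expect = kernel_center(1.0) ** 3
        assert got == pytest.approx(expect, abs=1e-6)

    def test_scale_list_extension_is_prefix(self):
        img = np.random.default_rng(0).normal(size=(6, 10, 10)).astype(np.float32)
        one = seg.extract_features(_grid(img), scales=(1.0,))
        two = seg.extract_features(_grid(img), scales=(1.0, 2.0))
        assert two.names[: one.n_features] == one.names
        np.testing.assert_array_equal(two.data[: one.n_features], one.data)

    def test_non_finite_input_rejected(self):
        img = np.ones((4, 4, 4), dtype=np.float32)
        img[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            seg.extract_features(_grid(img))

    def test_analytic_eigvals_match_lapack(self):
        rng = np.random.default_rng(1)
        elems = [rng.normal(size=(5, 6, 7)) for _ in range(6)]
        mine = seg._sym3_eigvals(elems)
        a11, a12, a13, a22, a23, a33 = elems
        M = np.stack(
            [np.stack([a11, a12, a13], -1), np.stack([a12, a22, a23], -1), np.stack([a13, a23, a33], -1)], -2
        )
        ref = np.linalg.eigvalsh(M)[..., ::-1]
        for k in range(3):
            np.testing.assert_allclose(mine[k], ref[..., k], atol=1e-5)


def _two_blob_volume():
    rng = np.random.default_rng(0)
    img = rng.normal(10, 1, size=(10, 30, 30)).astype(np.float32)
    truth = np.zeros(img.shape, dtype=bool)
    truth[3:7, 5:12, 5:12] = True
    truth[3:7, 18:25, 18:25] = True
    img[truth] += 100
    labels = np.zeros(img.shape, dtype=np.uint8)
    fg = np.argwhere(truth)
    bg = np.argwhere(~truth)
    labels[tuple(fg[rng.choice(len(fg), 120, replace=False)].T)] = 1
    labels[tuple(bg[rng.choice(len(bg), 120, replace=False)].T)] = 2
    return img, truth, labels


class TestClassifier:
    def test_separable_blobs_perfect_holdout(self):
        img, truth, labels = _two_blob_volume()
        fs = seg.extract_features(_grid(img), scales=(1.0,))
        model = seg.train_pixel_classifier(fs, labels, seed=0)
        assert model.holdout_accuracy == 1.0
        _, mask = seg.predict_mask(model, _grid(img), features=fs)
        # interior agreement (partial-volume boundary tolerated)
        core = ndimage.binary_erosion(truth)
        assert mask[core].mean() > 0.99

    def test_single_class_labels_rejected(self):
        img, _, labels = _two_blob_volume()
        labels[labels == 2] = 0
        fs = seg.extract_features(_grid(img), scales=(1.0,))
        with pytest.raises(ValueError, match="both"):
            seg.train_pixel_classifier(fs, labels, seed=0)

    def test_same_seed_identical_predictions(self):
        img, _, labels = _two_blob_volume()
        fs = seg.extract_features(_grid(img), scales=(1.0,))
        m1 = seg.train_pixel_classifier(fs, labels, seed=3)
        m2 = seg.train_pixel_classifier(fs, labels, seed=3)
        p1, _ = seg.predict_mask(m1, _grid(img), features=fs)
        p2, _ = seg.predict_mask(m2, _grid(img), features=fs)
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_model_roundtrip_reproduces_predictions(self, tmp_path):
        img, _, labels = _two_blob_volume()
        fs = seg.extract_features(_grid(img), scales=(1.0,))
        model = seg.train_pixel_classifier(fs, labels, seed=0)
        model.save(tmp_path / "model.pkl")
        back = seg.PixelClassifierModel.load(tmp_path / "model.pkl")
        p1, _ = seg.predict_mask(model, _grid(img))
        p2, _ = seg.predict_mask(back, _grid(img))
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_spacing_mismatch_rejected(self):
        img, _, labels = _two_blob_volume()
        fs = seg.extract_features(_grid(img), scales=(1.0,))
        model = seg.train_pixel_classifier(fs, labels, seed=0)
        with pytest.raises(ValueError, match="spacing"):
            seg.predict_mask(model, _grid(img, spacing=(1.0, 1.0, 1.0)))

    def test_probability_bounded(self):
        img, _, labels = _two_blob_volume()
        fs = seg.extract_features(_grid(img), scales=(1.0,))
        model = seg.train_pixel_classifier(fs, labels, seed=0)
        prob, _ = seg.predict_mask(model, _grid(img), features=fs)
        assert prob.data.min() >= 0.0 and prob.data.max() <= 1.0

    def test_nerve_channel_dice_on_noise_free_phantom(self, small_phantom_noise_free):
        spec, channels, gt = small_phantom_noise_free
        rng = np.random.default_rng(0)
        labels = seg.sample_training_labels(gt.nerve_label, 200, rng)
        fs = seg.extract_features(channels["nerve"], scales=(0.7, 1.0, 1.6, 3.5))
        model = seg.train_pixel_classifier(fs, labels, seed=0)
        _, mask = seg.predict_mask(model, channels["nerve"], features=fs)
        dice = 2 * (mask & gt.nerve_label).sum() / (mask.sum() + gt.nerve_label.sum())
        assert dice >= 0.90


class TestThresholdAndBackground:
    def test_threshold_extremes(self):
        img = _grid(np.arange(27, dtype=np.float32).reshape(3, 3, 3))
        assert not seg.threshold_absolute(img, 27.0).any()
        assert seg.threshold_absolute(img, 0.0).all()

    def test_constant_image_fully_subtracted(self):
        out = seg.subtract_background(_grid(np.full((8, 20, 20), 55.0)))
        assert np.allclose(out.data, 0.0)

    def test_thin_tube_peak_preserved(self):
        # 6 um tube on a flat background: peak survives within 10%
        img = np.full((15, 40, 40), 10.0, dtype=np.float32)
        z = (np.arange(15) - 7)[:, None] * SPACING[0]
        x = (np.arange(40) - 20)[None, :] * SPACING[2]
        tube = (z**2 + x**2) <= 3.0**2
        img[:, :, :] += 0.0
        img[np.broadcast_to(tube[:, None, :], img.shape)] = 200.0
        out = seg.subtract_background(_grid(img), radius_um=10.0)
        assert out.data.max() >= 0.9 * 190.0

    def test_smooth_gradient_removed(self):
        # gentle diffuse gradient at the scale the cleared-bone background
        # shows (tens of units across hundreds of um)
        img = np.tile(np.linspace(0, 50, 256, dtype=np.float32), (8, 32, 1))
        out = seg.subtract_background(_grid(img), radius_um=10.0)
        assert out.data.max() < 0.05 * img.max()

    def test_idempotent_on_flat_background(self):
        img = np.full((8, 30, 30), 20.0, dtype=np.float32)
        img[4, 15, 15] = 220.0
        once = seg.subtract_background(_grid(img))
        twice = seg.subtract_background(once)
        assert np.allclose(once.data, twice.data, atol=1e-6)

    def test_subvoxel_radius_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="clamping"):
            seg.subtract_background(_grid(np.zeros((4, 4, 4), np.float32)), radius_um=0.5)


def _flood_fill_labels(mask):
    """Brute-force 26-connectivity flood fill (independent oracle)."""
    mask = np.asarray(mask, bool)
    out = np.zeros(mask.shape, dtype=int)
    nxt = 0
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(mask)):
        if out[start]:
            continue
        nxt += 1
        stack = [start]
        out[start] = nxt
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offs:
                q = (z + dz, y + dy, x + dx)
                if all(0 <= q[i] < mask.shape[i] for i in range(3)) and mask[q] and not out[q]:
                    out[q] = nxt
                    stack.append(q)
    return out, nxt


class TestComponents:
    def test_two_cubes_volume_arithmetic(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[1:4, 1:4, 1:4] = True
        mask[6:9, 6:9, 6:9] = True
        lv, table = seg.label_components(mask, SPACING)
        assert len(table) == 2
        assert np.allclose(table.volume_um3, 27 * 4.225)

    def test_empty_mask(self):
        _, table = seg.label_components(np.zeros((5, 5, 5), bool), SPACING)
        assert len(table) == 0

    def test_full_volume_single_object(self):
        _, table = seg.label_components(np.ones((4, 4, 4), bool), SPACING)
        assert len(table) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12, 12)) < 0.25
        lv, table = seg.label_components(mask, SPACING)
        oracle, n = _flood_fill_labels(mask)
        assert lv.n_objects == n
        # same partition up to label names
        for lab in range(1, n + 1):
            ours = lv.labels[oracle == lab]
            assert ours.min() == ours.max()

    def test_centroid_physical_units(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 3, 4] = True
        _, table = seg.label_components(mask, SPACING)
        assert table.iloc[0].centroid_z_um == pytest.approx(2 * 2.5)
        assert table.iloc[0].centroid_x_um == pytest.approx(4 * 1.3)


class TestVolumeFilter:
    def test_threshold_boundary_voxel_counts(self):
        # voxel volume 4.225 um^3: 2366 voxels = 9996.35 (removed),
        # 2367 voxels = 10000.575 (retained, inclusive threshold)
        mask = np.zeros((40, 40, 40), bool)
        flat = mask.reshape(-1)
        flat[:2366] = True
        _, t1 = seg.label_components(mask, SPACING)
        mask2 = np.zeros((40, 40, 40), bool)
        mask2.reshape(-1)[:2367] = True
        _, t2 = seg.label_components(mask2, SPACING)
        assert len(seg.filter_by_volume(t1)) == 0
        assert len(seg.filter_by_volume(t2)) == 1

    def test_empty_table_passthrough(self):
        _, table = seg.label_components(np.zeros((3, 3, 3), bool), SPACING)
        assert len(seg.filter_by_volume(table)) == 0

    def test_zero_threshold_is_identity(self):
        mask = np.random.default_rng(0).random((8, 8, 8)) < 0.3
        _, table = seg.label_components(mask, SPACING)
        assert len(seg.filter_by_volume(table, 0.0)) == len(table)

    def test_no_retained_object_below_threshold(self):
        rng = np.random.default_rng(1)
        mask = rng.random((15, 30, 30)) < 0.3
        _, table = seg.label_components(mask, SPACING)
        kept = seg.filter_by_volume(table, 500.0)
        assert (kept.volume_um3 >= 500.0).all()
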