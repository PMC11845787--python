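"""Down-sampling, watershed splitting, CD31/Emcn phenotype logic."""

import numpy as np
import pytest
from scipy import ndimage

from qlsm import vessel_phenotyping as vp
from qlsm.grids import LabelVolume

SPACING = (2.5, 1.3, 1.3)
DS_SPACING = (5.0, 2.6, 2.6)


class TestDownsample:
    def test_shape_and_spacing_arithmetic(self):
        out = vp.downsample(np.zeros((100, 512, 512), np.float32), 2)
        assert out.shape == (50, 256, 256)

    def test_ceil_shape_for_odd_sizes(self):
        out = vp.downsample(np.zeros((5, 7, 9), np.float32), 2)
        assert out.shape == (3, 4, 5)

    def test_constant_preserved(self):
        out = vp.downsample(np.full((8, 8, 8), 3.5, np.float32), 2)
        assert np.allclose(out, 3.5)

    def test_checkerboard_averages_to_half(self):
        idx = np.indices((8, 8, 8)).sum(axis=0)
        out = vp.downsample((idx % 2).astype(np.float32), 2)
        assert np.allclose(out, 0.5)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            vp.downsample(np.zeros((4, 4, 4)), 0)


def _tube_mask(length_um=100.0, radius_um=4.0, spacing=DS_SPACING):
    nz, ny, nx = 9, int(length_um / spacing[1]) + 8, 9
    z = (np.arange(nz) - nz // 2)[:, None, None] * spacing[0]
    x = (np.arange(nx) - nx // 2)[None, None, :] * spacing[2]
    y = np.arange(ny)[None, :, None] * spacing[1]
    in_y = (y >= 4 * spacing[1]) & (y <= 4 * spacing[1] + length_um)
    return np.broadcast_to((z**2 + x**2) <= radius_um**2, (nz, ny, nx)) & in_y


class TestSplitObjects:
    def test_small_sphere_is_one_object(self):
        # sphere of diameter 8 um: below the 10 um seed spacing
        nz = ny = nx = 9
        z = (np.arange(nz) - 4)[:, None, None] * DS_SPACING[0]
        y = (np.arange(ny) - 4)[None, :, None] * DS_SPACING[1]
        x = (np.arange(nx) - 4)[None, None, :] * DS_SPACING[2]
        mask = z**2 + y**2 + x**2 <= 4.0**2
        lv = vp.split_objects(mask, DS_SPACING)
        assert lv.n_objects == 1

    def test_straight_tube_splits_into_ten_micron_pieces(self):
        mask = _tube_mask(100.0)
        lv = vp.split_objects(mask, DS_SPACING, 10.0)
        assert 8 <= lv.n_objects <= 13
        # each piece spans roughly 7-13 um along the axis
        for lab in range(1, lv.n_objects + 1):
            ys = np.nonzero(lv.labels == lab)[1]
            extent = (ys.max() - ys.min() + 1) * DS_SPACING[1]
            assert 5.0 <= extent <= 16.0

    def test_empty_mask(self):
        lv = vp.split_objects(np.zeros((4, 4, 4), bool), DS_SPACING)
        assert lv.n_objects == 0

    def test_union_of_labels_equals_mask_exactly(self):
        rng = np.random.default_rng(0)
        blob = ndimage.binary_dilation(rng.random((10, 20, 20)) < 0.05, iterations=2)
        lv = vp.split_objects(blob, DS_SPACING)
        np.testing.assert_array_equal(lv.labels > 0, blob)

    def test_deterministic(self):
        mask = _tube_mask(60.0)
        a = vp.split_objects(mask, DS_SPACING)
        b = vp.split_objects(mask, DS_SPACING)
        np.testing.assert_array_equal(a.labels, b.labels)


def _vessel_scene():
    """Three tubes: one CD31-only, one CD31+Emcn, one Emcn-only."""
    shape = (8, 40, 40)
    cd31 = np.zeros(shape, bool)
    emcn = np.zeros(shape, bool)
    cd31[2:6, 5:35, 4:8] = True  # P1
    cd31[2:6, 5:35, 18:22] = True  # P2 (Emcn overlaps)
    emcn[2:6, 5:35, 18:22] = True
    emcn[2:6, 5:35, 32:36] = True  # P3
    return cd31, emcn


class TestClassifyPhenotype:
    def test_presence_absence_rules(self):
        cd31, emcn = _vessel_scene()
        cs = vp.split_objects(cd31, DS_SPACING)
        es = vp.split_objects(emcn, DS_SPACING)
        table, phen = vp.classify_phenotype(cs, es)
        # the P1 tube (x 4-8) carries no Emcn -> P1 everywhere
        assert set(np.unique(phen[:, :, 4:8])) <= {0, 1}
        # the overlapping tube is P2
        assert set(np.unique(phen[:, :, 18:22])) <= {0, 2}
        # the Emcn-only tube is P3
        assert set(np.unique(phen[:, :, 32:36])) <= {0, 3}
        # colocalized Emcn objects are not emitted as P3 rows
        assert not ((table.source == "emcn") & (table.phenotype != "P3")).any()

    def test_phenotype_map_partitions_union(self):
        cd31, emcn = _vessel_scene()
        cs = vp.split_objects(cd31, DS_SPACING)
        es = vp.split_objects(emcn, DS_SPACING)
        _, phen = vp.classify_phenotype(cs, es)
        np.testing.assert_array_equal(phen > 0, cd31 | emcn)

    def test_geometry_mismatch_rejected(self):
        cd31, emcn = _vessel_scene()
        cs = vp.split_objects(cd31, DS_SPACING)
        es = vp.split_objects(emcn[:, :20], DS_SPACING)
        with pytest.raises(ValueError, match="shape"):
            vp.classify_phenotype(cs, es)

    def test_invariant_to_label_order(self):
        cd31, emcn = _vessel_scene()
        cs = vp.split_objects(cd31, DS_SPACING)
        es = vp.split_objects(emcn, DS_SPACING)
        _, phen1 = vp.classify_phenotype(cs, es)
        # permute CD31 object ids
        perm = np.concatenate([[0], np.random.default_rng(0).permutation(cs.n_objects) + 1])
        cs2 = LabelVolume(perm[cs.labels].astype(np.int32), DS_SPACING)
        _, phen2 = vp.classify_phenotype(cs2, es)
        np.testing.assert_array_equal(phen1, phen2)

    def test_phenotype_recovery_on_noise_free_phantom(self, small_phantom_noise_free):
        """>= 95% of split vessel objects receive their true phenotype."""
        _, _, gt = small_phantom_noise_free
        cd31 = (gt.occupancy["P1"] >= 0.5) | (gt.occupancy["P2"] >= 0.5)
        emcn = (gt.occupancy["P2"] >= 0.5) | (gt.occupancy["P3"] >= 0.5)
        f = 2
        cs = vp.split_objects(vp.downsample_mask(cd31, f), DS_SPACING)
        es = vp.split_objects(vp.downsample_mask(emcn, f), DS_SPACING)
        table, phen = vp.classify_phenotype(cs, es)
        # down-sampled majority-vote truth phenotype per voxel
        votes = np.stack([vp.downsample(gt.vessel_label == k, f) for k in (1, 2, 3)])
        truth_ds = np.where(votes.max(axis=0) > 0, votes.argmax(axis=0) + 1, 0).astype(np.uint8)
        ok = total = 0
        code = {"P1": 1, "P2": 2, "P3": 3}
        for _, row in table.iterrows():
            sel = (cs.labels == row.label) if row.source == "cd31" else (es.labels == row.label)
            truth_votes = truth_ds[sel]
            truth_votes = truth_votes[truth_votes > 0]
            if truth_votes.size == 0:
                continue
            total += 1
            ok += int(np.bincount(truth_votes).argmax() == code[row.phenotype])
        assert total > 10
        assert ok / total >= 0.95


class TestPhenotypeFractions:
    def test_all_p2(self):
        phen = np.zeros((4, 4, 4), np.uint8)
        phen[1:3, 1:3, 1:3] = 2
        fr = vp.phenotype_fractions(phen, DS_SPACING)
        assert (fr["P1"], fr["P2"], fr["P3"]) == (0.0, 1.0, 0.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        phen = rng.integers(0, 4, size=(6, 6, 6)).astype(np.uint8)
        fr = vp.phenotype_fractions(phen, DS_SPACING)
        assert fr["P1"] + fr["P2"] + fr["P3"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_vessel_volume_flagged(self):
        with pytest.raises(ValueError, match="zero"):
            vp.phenotype_fractions(np.zeros((3, 3, 3), np.uint8), DS_SPACING)

    def test_equal_true_volumes_near_thirds(self, small_phantom_noise_free):
        _, _, gt = small_phantom_noise_free
        cd31 = (gt.occupancy["P1"] >= 0.5) | (gt.occupancy["P2"] >= 0.5)
        emcn = (gt.occupancy["P2"] >= 0.5) | (gt.occupancy["P3"] >= 0.5)
        cs = vp.split_objects(vp.downsample_mask(cd31, 2), DS_SPACING)
        es = vp.split_objects(vp.downsample_mask(emcn, 2), DS_SPACING)
        _, phen = vp.classify_phenotype(cs, es)
        fr = vp.phenotype_fractions(phen, DS_SPACING)
        vols = gt.true_densities["structure_volume_um3"]
        tot = vols["P1"] + vols["P2"] + vols["P3"]
        for p in ("P1", "P2", "P3"):
            assert fr[p] == pytest.approx(vols[p] / tot, abs=0.08)
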