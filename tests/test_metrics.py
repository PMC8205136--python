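"""Grey-mass Dice/IOU metrics, class grey models, and histogram extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echoseg import metrics


class TestClassModels:
    def test_benign_constants(self):
        m = metrics.BENIGN_MODEL
        assert m.alpha == pytest.approx(2 / 3, abs=1e-3)
        assert m.delta == 5.0
        assert m.band == (80.0, 90.0)
        assert m.truth_grey == 127.5
        # the band is the per-pixel tolerance around the expected grey 85
        assert (m.alpha * m.truth_grey - m.delta,
                m.alpha * m.truth_grey + m.delta) == m.band

    def test_malignant_constants(self):
        m = metrics.MALIGNANT_MODEL
        assert m.alpha == 1.0 and m.delta == 85.0
        assert m.band == (170.0, 255.0)
        assert m.truth_grey - m.delta == m.band[0]

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            metrics.ClassGreyModel(1, "x", alpha=0.0, delta=5, band=(80, 90))
        with pytest.raises(ValueError):
            metrics.ClassGreyModel(1, "x", alpha=1.0, delta=5, band=(90, 80))


class TestGreyHistogram:
    def test_delta_histogram(self):
        h = metrics.grey_histogram(np.full((10, 10), 85.0))
        assert h[85] == 100 and h.sum() == 100

    def test_two_level_image(self):
        img = np.zeros((10, 10))
        img.ravel()[:60] = 255.0
        h = metrics.grey_histogram(img)
        assert h[0] == 40 and h[255] == 60

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics.grey_histogram(np.zeros((0, 0)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            metrics.grey_histogram(np.full((2, 2), 300.0))


class TestExtractClassRegion:
    def test_benign_patch_mass(self):
        img = np.zeros((8, 8))
        img.ravel()[:10] = 85.0
        mask, x_p = metrics.extract_class_region(img, metrics.BENIGN_MODEL)
        assert mask.sum() == 10 and x_p == 850.0

    def test_out_of_band_grey_excluded(self):
        assert metrics.extract_class_region(
            np.full((4, 4), 50.0), metrics.BENIGN_MODEL)[1] == 0.0
        assert metrics.extract_class_region(
            np.full((4, 4), 200.0), metrics.BENIGN_MODEL)[1] == 0.0

    def test_truth_grey_levels_fall_in_their_bands(self):
        # malignant ground-truth grey 255 is inside (170, 255]
        assert metrics.extract_class_region(
            np.full((2, 2), 255.0), metrics.MALIGNANT_MODEL)[1] == 4 * 255.0


class TestMassDiceIou:
    def test_hand_computed_example(self):
        dice, iou = metrics.mass_dice_iou(1000.0, 900.0)
        assert dice == pytest.approx(2 * 900 / 1900)   # ~0.947
        assert iou == pytest.approx(0.9)

    def test_perfect_match(self):
        assert metrics.mass_dice_iou(123.0, 123.0) == (1.0, 1.0)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6))
    def test_dice_iou_identity_and_symmetry(self, a, b):
        dice, iou = metrics.mass_dice_iou(a, b)
        assert 0.0 <= iou <= 1.0 and 0.0 <= dice <= 1.0
        assert dice == pytest.approx(2 * iou / (1 + iou), rel=1e-9)
        assert metrics.mass_dice_iou(b, a) == pytest.approx((dice, iou))

    def test_monotone_decrease_away_from_match(self):
        scores = [metrics.mass_dice_iou(1000.0, x_p)
                  for x_p in (1000.0, 800.0, 600.0, 400.0, 200.0)]
        dices = [s[0] for s in scores]
        ious = [s[1] for s in scores]
        assert dices == sorted(dices, reverse=True)
        assert ious == sorted(ious, reverse=True)


class TestGreyDiceIou:
    def _mask(self, class_id, n, shape=(16, 16)):
        m = np.zeros(shape, dtype=int)
        m.ravel()[:n] = class_id
        return m

    def test_perfect_expected_rendering_scores_one(self):
        for class_id in (1, 2):
            mask = self._mask(class_id, 30)
            grey = metrics.render_expected_grey(mask)
            rep = metrics.grey_dice_iou(mask, grey, metrics.CLASS_MODELS[class_id])
            assert rep.dice == pytest.approx(1.0)
            assert rep.iou == pytest.approx(1.0)
            assert rep.delta_x == pytest.approx(0.0)
            assert rep.within_tolerance

    def test_total_miss_scores_zero(self):
        mask = self._mask(2, 20)
        rep = metrics.grey_dice_iou(mask, np.zeros((16, 16)),
                                    metrics.MALIGNANT_MODEL)
        assert rep.dice == 0.0 and rep.iou == 0.0
        assert rep.x_t == 20 * 255.0 and rep.x_p == 0.0

    def test_malignant_arithmetic(self):
        # 4 malignant pixels -> x_t = 1020; prediction holds grey 180 on 5 px
        mask = self._mask(2, 4)
        grey = np.zeros((16, 16))
        grey.ravel()[:5] = 180.0
        rep = metrics.grey_dice_iou(mask, grey, metrics.MALIGNANT_MODEL)
        assert rep.x_p == 900.0
        assert rep.delta_x == pytest.approx(1020.0 - 900.0)
        assert rep.dice == pytest.approx(2 * 900 / 1920)
        assert rep.iou == pytest.approx(900 / 1020)

    def test_no_tumour_degenerate_contract_warns(self):
        mask = np.zeros((8, 8), dtype=int)
        with pytest.warns(UserWarning, match="degenerate"):
            rep = metrics.grey_dice_iou(mask, np.zeros((8, 8)),
                                        metrics.BENIGN_MODEL)
        assert rep.dice == 1.0 and rep.iou == 1.0
        grey = np.full((8, 8), 85.0)
        with pytest.warns(UserWarning):
            rep = metrics.grey_dice_iou(mask, grey, metrics.BENIGN_MODEL)
        assert rep.dice == 0.0 and rep.iou == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            metrics.grey_dice_iou(np.zeros((4, 4), dtype=int),
                                  np.zeros((5, 5)), metrics.BENIGN_MODEL)

    def test_binary_map_with_full_band_matches_mass_ratio(self, rng):
        """On 0/255 maps with alpha = 1 and a full band, the grey scores are
        the plain mass-ratio scores of the two pixel sets."""
        full = metrics.ClassGreyModel(2, "binary", alpha=1.0, delta=255.0,
                                      band=(0.0, 255.0))
        mask = (rng.random((16, 16)) < 0.3).astype(int) * 2
        pred = (rng.random((16, 16)) < 0.3) * 255.0
        rep = metrics.grey_dice_iou(mask, pred, full)
        a = (mask == 2).sum() * 255.0
        b = pred.sum()
        assert (rep.dice, rep.iou) == pytest.approx(metrics.mass_dice_iou(a, b))


class TestClassicalDiceIou:
    def test_identity_disjoint_and_half_overlap(self):
        a = np.zeros((20, 20), dtype=bool)
        a.ravel()[:100] = True
        assert metrics.classical_dice_iou(a, a) == (1.0, 1.0)
        b = np.zeros_like(a)
        b.ravel()[100:200] = True
        assert metrics.classical_dice_iou(a, b) == (0.0, 0.0)
        c = np.zeros_like(a)
        c.ravel()[50:150] = True  # |A|=|B|=100, overlap 50
        dice, iou = metrics.classical_dice_iou(a, c)
        assert dice == pytest.approx(0.5)
        assert iou == pytest.approx(1 / 3)

    def test_both_empty_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="empty"):
            assert metrics.classical_dice_iou(
                np.zeros((3, 3)), np.zeros((3, 3))) == (1.0, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2 ** 16 - 1), st.integers(1, 2 ** 16 - 1))
    def test_dice_iou_identity_on_random_masks(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], dtype=bool)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], dtype=bool)
        dice, iou = metrics.classical_dice_iou(a, b)
        assert dice == pytest.approx(2 * iou / (1 + iou), rel=1e-9)
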