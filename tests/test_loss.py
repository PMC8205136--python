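"""Expanded cross-entropy: entropy terms, case analysis, minima, 3x ratio."""

import numpy as np
import pytest

from echoseg import loss

LN2 = np.log(2.0)


class TestPixelEntropyTerms:
    def test_confident_malignant_pixel(self):
        e, ep = loss.pixel_entropy_terms([1, 1, 1], [1 - 1e-7] * 3)
        assert abs(e) < 1e-5
        assert ep == 0.0  # (1 - y) weights vanish exactly

    def test_confident_normal_pixel(self):
        e, ep = loss.pixel_entropy_terms([0, 0, 0], [1e-7] * 3)
        assert e == 0.0
        assert abs(ep) < 1e-5

    def test_benign_pixel_at_half(self):
        e, ep = loss.pixel_entropy_terms([0.5] * 3, [0.5] * 3)
        expected = 3 * 0.5 * np.log(0.5)  # = -1.0397...
        assert e == pytest.approx(expected, abs=1e-12)
        assert ep == pytest.approx(expected, abs=1e-12)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="3 channels"):
            loss.pixel_entropy_terms([1, 0], [0.5, 0.5])


class TestExpandedCrossEntropy:
    def test_perfect_normal_prediction_vanishes(self):
        value = loss.expanded_cross_entropy([0.0] * 3, [1e-7] * 3)
        assert 0.0 <= value < 1e-5

    def test_benign_pixel_value(self):
        value = loss.expanded_cross_entropy([0.5] * 3, [0.5] * 3)
        assert value == pytest.approx(3 * LN2, rel=1e-12)  # ~2.079

    def test_nonnegative_on_random_batches(self, rng):
        y = rng.choice([0.0, 0.5, 1.0], size=(4, 6, 6, 3))
        p = rng.uniform(0.01, 0.99, size=(4, 6, 6, 3))
        assert loss.expanded_cross_entropy(y, p) >= 0.0

    def test_matches_pointwise_case_loss(self, rng):
        """Batch ECE equals the mean over pixels of the per-channel case losses."""
        y = np.repeat(rng.choice([0.0, 0.5, 1.0], size=(3, 4, 5, 1)), 3, axis=-1)
        p = rng.uniform(0.05, 0.95, size=(3, 4, 5, 3))
        oracle = np.mean([
            sum(loss.per_pixel_case_loss(y[n, i, j, k], p[n, i, j, k])
                for k in range(3))
            for n in range(3) for i in range(4) for j in range(5)])
        assert loss.expanded_cross_entropy(y, p) == pytest.approx(oracle, rel=1e-12)

    def test_shape_mismatch_and_nan_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            loss.expanded_cross_entropy(np.zeros((2, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="NaN"):
            loss.expanded_cross_entropy([0.0, 0.0, np.nan], [0.5] * 3)

    def test_gradient_matches_finite_differences(self, rng):
        y = rng.choice([0.0, 0.5, 1.0], size=(2, 3, 3, 3))
        p = rng.uniform(0.1, 0.9, size=(2, 3, 3, 3))
        g = loss.expanded_cross_entropy_grad(y, p)
        eps = 1e-7
        for ix in [(0, 1, 2, 0), (1, 0, 0, 2), (1, 2, 1, 1)]:
            p1, p2 = p.copy(), p.copy()
            p1[ix] += eps
            p2[ix] -= eps
            num = (loss.expanded_cross_entropy(y, p1)
                   - loss.expanded_cross_entropy(y, p2)) / (2 * eps)
            assert g[ix] == pytest.approx(num, rel=1e-5)


class TestCaseLoss:
    @pytest.mark.parametrize("y", [0.0, 0.5, 1.0])
    def test_agrees_with_direct_binary_form(self, y, rng):
        """The three-case form equals -y log p - (1-y) log(1-p) exactly."""
        for p in rng.uniform(1e-6, 1 - 1e-6, size=50):
            direct = -y * np.log(p) - (1 - y) * np.log(1 - p)
            assert loss.per_pixel_case_loss(y, p) == pytest.approx(
                direct, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("y, argmin_target, min_value", [
        (1.0, 1.0, 0.0),          # loss -> 0 as p -> 1
        (0.5, 0.5, LN2),          # minimum -0.5 ln(1/4) = ln 2 at p = 0.5
        (0.0, 0.0, 0.0),          # loss -> 0 as p -> 0
    ])
    def test_minima_by_grid_search(self, y, argmin_target, min_value):
        """Brute-force grid search reproduces the analytic case minima."""
        grid = np.linspace(1e-6, 1 - 1e-6, 999_999)  # includes 0.5 exactly
        values = -y * np.log(grid) - (1 - y) * np.log1p(-grid)  # direct oracle
        argmin = grid[np.argmin(values)]
        assert argmin == pytest.approx(argmin_target, abs=2e-6)
        assert loss.per_pixel_case_loss(y, argmin) == pytest.approx(
            min_value, abs=1e-5)

    def test_benign_case_symmetric_in_p(self, rng):
        for p in rng.uniform(0.01, 0.99, size=20):
            assert loss.per_pixel_case_loss(0.5, p) == pytest.approx(
                loss.per_pixel_case_loss(0.5, 1 - p), rel=1e-12)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError, match="0.3"):
            loss.per_pixel_case_loss(0.3, 0.5)


class TestUpdateRateRatio:
    def test_three_for_values_and_gradients(self, rng):
        """3-channel ECE is exactly 3x the 1-channel BCE, loss and gradient."""
        for _ in range(25):
            y = float(rng.choice([0.0, 0.5, 1.0]))
            p = float(rng.uniform(0.05, 0.95))
            if abs(p - y) < 1e-3:
                p += 0.01  # keep the gradient away from zero
            lr, gr = loss.update_rate_ratio(y, p)
            assert lr == pytest.approx(3.0, rel=1e-12)
            assert gr == pytest.approx(3.0, rel=1e-12)

    def test_gradient_ratio_against_finite_differences(self):
        y, p, eps = 0.5, 0.7, 1e-7
        num3 = (loss.expanded_cross_entropy([y] * 3, [p + eps] * 3)
                - loss.expanded_cross_entropy([y] * 3, [p - eps] * 3)) / (2 * eps)
        num1 = (loss.binary_cross_entropy(y, p + eps)
                - loss.binary_cross_entropy(y, p - eps)) / (2 * eps)
        assert num3 / num1 == pytest.approx(3.0, rel=1e-6)


class TestConstrainedBenignMinimum:
    def test_uniform_optimum_grey_and_alpha(self):
        opt = loss.constrained_benign_minimum()
        assert np.allclose(opt.p, 1 / 3, atol=1e-6)
        assert opt.grey == pytest.approx(85.0, abs=1e-3)
        assert opt.alpha == pytest.approx(2 / 3, abs=1e-5)

    def test_against_projected_gradient_oracle(self):
        """An independent projected-gradient descent lands on the same point."""
        p = np.array([0.6, 0.3, 0.1])
        for _ in range(5000):
            g = -0.5 / p + 0.5 / (1 - p)
            g -= g.mean()  # project the gradient onto the simplex tangent
            p = np.clip(p - 1e-3 * g, 1e-6, 1 - 1e-6)
            p /= p.sum()
        opt = loss.constrained_benign_minimum()
        assert np.allclose(opt.p, p, atol=1e-4)
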