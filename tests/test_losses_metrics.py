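"""Loss and metric tests: identities, hand-computed values, gradient checks."""

import numpy as np
import pytest

from polyreg import (
    AgreementStats,
    HybridLossConfig,
    ParameterRanges,
    RegressionReport,
    SSIMConstants,
    bland_altman,
    cosine_similarity,
    hybrid_loss,
    msle,
    ncc,
    ncc_loss,
    pearson_r,
    pooled_regression_report,
    ssim,
)
from polyreg.losses_metrics import hybrid_loss_and_grad, ncc_and_grad

E_MINUS_1 = np.e - 1.0


class TestMsle:
    def test_zero_iff_equal(self, rng):
        v = rng.uniform(0, 1, 12)
        assert msle(v, v) == 0.0
        assert msle(v, v + 0.1) > 0.0

    def test_hand_computed_unit_value(self):
        # (log e - log 1)^2 = 1
        assert msle([E_MINUS_1], [0.0]) == pytest.approx(1.0, abs=1e-12)

    def test_mean_over_entries(self):
        assert msle([0.0, 0.0], [E_MINUS_1, E_MINUS_1]) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self, rng):
        a, b = rng.uniform(0, 1, 5), rng.uniform(0, 1, 5)
        assert msle(a, b) == pytest.approx(msle(b, a))

    def test_log_domain_guard(self):
        with pytest.raises(ValueError, match="normalize"):
            msle([-1.5], [0.0])


class TestCosineSimilarity:
    @pytest.mark.parametrize("a, b, expected", [
        ([1.0, 2.0], [1.0, 2.0], 1.0),
        ([1.0, 0.0], [0.0, 1.0], 0.0),
        ([1.0, 2.0], [-1.0, -2.0], -1.0),
    ])
    def test_reference_angles(self, a, b, expected):
        assert cosine_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity([0.0, 0.0], [1.0, 2.0])


class TestHybridLoss:
    def test_zero_at_equality(self, rng):
        v = rng.uniform(0.1, 1, 12)
        assert hybrid_loss(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_omega_endpoints_reduce_to_components(self, rng):
        t, p = rng.uniform(0.1, 1, 6), rng.uniform(0.1, 1, 6)
        assert hybrid_loss(t, p, HybridLossConfig(omega=1.0)) == pytest.approx(msle(t, p))
        assert hybrid_loss(t, p, HybridLossConfig(omega=0.0)) == pytest.approx(
            1.0 - cosine_similarity(t, p))

    def test_zero_vector_prediction_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            hybrid_loss([E_MINUS_1, E_MINUS_1], [0.0, 0.0])

    def test_invalid_omega_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            HybridLossConfig(omega=1.5)

    def test_batched_version_matches_scalar_path(self, rng):
        t = rng.uniform(0.05, 0.95, (4, 12))
        p = rng.uniform(0.05, 0.95, (4, 12))
        loss, _ = hybrid_loss_and_grad(t, p)
        per_sample = [hybrid_loss(t[i], p[i]) for i in range(4)]
        assert loss == pytest.approx(np.mean(per_sample), rel=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        t = rng.uniform(0.1, 0.9, (3, 12))
        p = rng.uniform(0.1, 0.9, (3, 12))
        _, grad = hybrid_loss_and_grad(t, p)
        eps = 1e-6
        for i in [0, 2]:
            for j in [0, 5, 11]:
                dp = p.copy()
                dp[i, j] += eps
                lp, _ = hybrid_loss_and_grad(t, dp)
                dp[i, j] -= 2 * eps
                lm, _ = hybrid_loss_and_grad(t, dp)
                assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


class TestNcc:
    def test_self_correlation_is_one(self, random_image):
        assert ncc(random_image, random_image) == pytest.approx(1.0)
        assert ncc_loss(random_image, random_image) == pytest.approx(0.0, abs=1e-12)

    def test_affine_gain_invariance(self, random_image):
        assert ncc(random_image, 2.0 * random_image + 10.0) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, random_image):
        assert ncc(random_image, -random_image) == pytest.approx(-1.0)
        assert ncc_loss(random_image, -random_image) == pytest.approx(2.0)

    def test_symmetric(self, rng):
        a, b = rng.uniform(0, 1, (8, 8)), rng.uniform(0, 1, (8, 8))
        assert ncc(a, b) == pytest.approx(ncc(b, a), rel=1e-12)

    def test_constant_image_rejected(self, random_image):
        with pytest.raises(ValueError, match="constant"):
            ncc(np.full((8, 8), 3.0), np.full((8, 8), 3.0))

    def test_mask_restricts_region(self, rng):
        a, b = rng.uniform(0, 1, (8, 8)), rng.uniform(0, 1, (8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True
        assert ncc(a, b, mask=mask) == pytest.approx(
            np.corrcoef(a[:4].ravel(), b[:4].ravel())[0, 1])

    def test_gradient_matches_finite_differences(self, rng):
        f = rng.uniform(0, 1, (6, 6))
        w = rng.uniform(0, 1, (6, 6))
        _, grad = ncc_and_grad(f, w)
        eps = 1e-7
        for idx in [(0, 0), (3, 2), (5, 5)]:
            wp = w.copy()
            wp[idx] += eps
            vp, _ = ncc_and_grad(f, wp)
            wp[idx] -= 2 * eps
            vm, _ = ncc_and_grad(f, wp)
            assert grad[idx] == pytest.approx((vp - vm) / (2 * eps), abs=1e-6)


class TestSsim:
    def test_identical_images_give_one(self, random_image):
        assert ssim(random_image, random_image) == pytest.approx(1.0)

    def test_constant_zero_pair_gives_one(self):
        z = np.zeros((16, 16))
        assert ssim(z, z) == pytest.approx(1.0)

    def test_negation_is_negative(self, rng):
        a = rng.uniform(0, 255, (32, 32))
        assert ssim(a, 255.0 - a) < 0.0

    def test_symmetric(self, rng):
        a, b = rng.uniform(0, 255, (16, 16)), rng.uniform(0, 255, (16, 16))
        assert ssim(a, b) == pytest.approx(ssim(b, a), rel=1e-12)

    def test_matches_directly_evaluated_formula(self, rng):
        a, b = rng.uniform(0, 255, (20, 20)), rng.uniform(0, 255, (20, 20))
        C1, C2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
        mu_a, mu_b = a.mean(), b.mean()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        expected = ((2 * mu_a * mu_b + C1) * (2 * cov + C2)) / (
            (mu_a**2 + mu_b**2 + C1) * (a.var() + b.var() + C2))
        assert ssim(a, b) == pytest.approx(expected, rel=1e-12)

    def test_windowed_variant_available(self, rng):
        a = rng.uniform(0, 255, (32, 32))
        b = np.clip(a + rng.normal(0, 5, a.shape), 0, 255)
        w = ssim(a, b, windowed=True)
        assert -1.0 <= w <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ssim(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_invalid_dynamic_range_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            SSIMConstants(L=0.0)


class TestPearson:
    def test_exact_linear_relations(self):
        r, p = pearson_r([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        r, _ = pearson_r([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_point_eight(self):
        r, _ = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_agrees_with_covariance_oracle(self, rng):
        x, y = rng.normal(size=200), rng.normal(size=200)
        r, _ = pearson_r(x, y)
        oracle = (np.mean((x - x.mean()) * (y - y.mean()))
                  / (x.std() * y.std()))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_measurements(self, rng):
        x = rng.uniform(0, 1, 10)
        stats = bland_altman(x, x.copy())
        assert stats.mean_difference == 0.0
        assert stats.lower_limit == 0.0
        assert stats.upper_limit == 0.0

    def test_hand_computed_limits(self):
        # diffs (-1, 0, 1): sample SD = 1, limits = +-1.96
        stats = bland_altman([0.0, 1.0, 3.0], [1.0, 1.0, 2.0])
        assert stats.mean_difference == pytest.approx(0.0)
        assert stats.lower_limit == pytest.approx(-1.96)
        assert stats.upper_limit == pytest.approx(1.96)

    def test_constant_offset(self, rng):
        y = rng.uniform(0, 1, 8)
        stats = bland_altman(y + 5.0, y)
        assert stats.mean_difference == pytest.approx(5.0)
        assert stats.lower_limit == pytest.approx(5.0)
        assert stats.upper_limit == pytest.approx(5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bland_altman([1, 2], [1, 2, 3])


class TestRegressionReport:
    @pytest.fixture
    def ranges(self):
        return ParameterRanges.default(64)

    @pytest.fixture
    def target_params(self, ranges, rng):
        z = rng.uniform(0.2, 0.8, (20, 12))
        return ranges.mins + z * (ranges.maxs - ranges.mins)

    def test_perfect_predictions(self, ranges, target_params):
        report = pooled_regression_report(target_params, target_params, ranges)
        assert report.pooled_r == pytest.approx(1.0)
        for stats in report.per_parameter.values():
            assert stats.mean_difference == pytest.approx(0.0, abs=1e-12)

    def test_constant_normalized_offset(self, ranges, target_params):
        width = ranges.maxs - ranges.mins
        preds = target_params + 0.1 * width
        report = pooled_regression_report(preds, target_params, ranges)
        assert report.pooled_r == pytest.approx(1.0, abs=1e-9)
        for stats in report.per_parameter.values():
            assert stats.mean_difference == pytest.approx(0.1, abs=1e-9)

    def test_image_level_metrics_filled(self, ranges, target_params, rng):
        f = rng.uniform(0, 255, (16, 16))
        triples = [(f, 0.5 * f + 3, f.copy())]
        report = pooled_regression_report(target_params, target_params, ranges,
                                          image_pairs_before_after=triples)
        assert report.ssim_after == pytest.approx(1.0)
        assert report.ncc_after == pytest.approx(1.0)
        assert report.ncc_before == pytest.approx(1.0)  # affine gain invariance
        assert report.ssim_before < report.ssim_after

    def test_json_round_trip_lossless(self, ranges, target_params, rng):
        preds = target_params + rng.normal(0, 1e-5, target_params.shape)
        report = pooled_regression_report(preds, target_params, ranges)
        back = RegressionReport.from_json(report.to_json())
        assert back.pooled_r == report.pooled_r
        for name, stats in report.per_parameter.items():
            assert back.per_parameter[name].to_dict() == stats.to_dict()

    def test_frame_has_one_row_per_parameter(self, ranges, target_params):
        report = pooled_regression_report(target_params, target_params, ranges)
        frame = report.to_frame()
        assert len(frame) == 12
        assert "mean_difference" in frame.columns
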