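import numpy as np
import pandas as pd
import pytest

from seedsynth import morpho
from seedsynth.morpho import (
    Contour,
    EFDCoefficients,
    compute_descriptors,
    efd_coefficients,
    efd_features,
    efd_from_mask,
    efd_reconstruct,
    extract_contour,
    features_to_coeffs,
    latent_axis_contours,
    mean_contour,
    pca_fit,
)

from conftest import polygon_circle, polygon_ellipse


def brute_force_efd(points, harmonics):
    """Independent oracle: direct numerical Fourier integrals of x(s), y(s).

    The per-harmonic quadruple (a_n, b_n, c_n, d_n) is just the Fourier
    series of the chord-length traversal, so a_n = (2/T) int x(s) cos(2 pi n
    s / T) ds etc.  Each polygon segment is subdivided into vertex-aligned
    substeps and the integrals taken by the trapezoid rule — a different
    route than the closed-form derivative sums under test.
    """
    pts = np.vstack([points, points[:1]])
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    t = np.concatenate([[0], np.cumsum(seglen)])
    T = t[-1]
    h = T / 400_000
    s_parts = [
        np.linspace(t[i], t[i + 1], max(2, int(np.ceil(seglen[i] / h)) + 1))
        for i in range(len(seglen))
    ]
    s = np.unique(np.concatenate(s_parts))
    x = np.interp(s, t, pts[:, 0])
    y = np.interp(s, t, pts[:, 1])
    out = np.zeros((harmonics, 4))
    for n in range(1, harmonics + 1):
        w = 2 * np.pi * n / T
        out[n - 1, 0] = (2 / T) * np.trapezoid(x * np.cos(w * s), s)
        out[n - 1, 1] = (2 / T) * np.trapezoid(x * np.sin(w * s), s)
        out[n - 1, 2] = (2 / T) * np.trapezoid(y * np.cos(w * s), s)
        out[n - 1, 3] = (2 / T) * np.trapezoid(y * np.sin(w * s), s)
    return out


class TestExtractContour:
    def test_disc_arc_length(self, disc_mask):
        c = extract_contour(disc_mask)
        assert c.arc_length == pytest.approx(2 * np.pi * 100, rel=0.02)
        assert c.signed_area > 0  # counter-clockwise in (x, y)

    def test_border_touching_mask_still_closed(self):
        mask = np.zeros((50, 50), bool)
        mask[0:30, 0:30] = True  # touches two raster borders
        c = extract_contour(mask)
        assert abs(c.signed_area) == pytest.approx(900, rel=0.1)

    def test_hole_ignored_outer_returned(self, disc_mask):
        holed = disc_mask.copy()
        holed[109:111, 109:111] = False
        c_full = extract_contour(disc_mask)
        c_holed = extract_contour(holed)
        assert c_holed.signed_area == pytest.approx(c_full.signed_area, rel=0.01)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_contour(np.zeros((10, 10), bool))


class TestDescriptors:
    def test_disc_values(self, disc_mask):
        r = compute_descriptors(disc_mask)
        assert r.area == pytest.approx(np.pi * 100**2, rel=0.01)
        assert r.eccentricity < 0.05
        assert r.solidity > 0.98
        assert 0.98 <= r.circularity <= 1.02

    def test_ellipse_values(self, ellipse_mask):
        r = compute_descriptors(ellipse_mask)
        assert r.length == pytest.approx(120, rel=0.02)
        assert r.width == pytest.approx(60, rel=0.02)
        assert r.lwr == pytest.approx(2.0, rel=0.02)
        assert r.eccentricity == pytest.approx(np.sqrt(1 - 0.25), abs=0.01)

    def test_square_solidity_exact(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        assert compute_descriptors(mask).solidity == 1.0

    def test_scaling_behavior(self):
        yy, xx = np.mgrid[0:90, 0:150]
        small = ((xx - 75) / 30.0) ** 2 + ((yy - 45) / 15.0) ** 2 <= 1
        yy, xx = np.mgrid[0:180, 0:300]
        big = ((xx - 150) / 60.0) ** 2 + ((yy - 90) / 30.0) ** 2 <= 1
        a, b = compute_descriptors(small), compute_descriptors(big)
        assert b.area / a.area == pytest.approx(4, rel=0.02)
        assert b.length / a.length == pytest.approx(2, rel=0.02)
        assert b.perimeter / a.perimeter == pytest.approx(2, rel=0.02)
        for f in ("lwr", "eccentricity", "solidity", "circularity"):
            assert getattr(b, f) == pytest.approx(getattr(a, f), rel=0.02)

    def test_multi_component_rejected(self):
        mask = np.zeros((30, 30), bool)
        mask[2:8, 2:8] = True
        mask[20:26, 20:26] = True
        with pytest.raises(ValueError, match="components"):
            compute_descriptors(mask)

    def test_dpi_converts_units(self, disc_mask):
        px = compute_descriptors(disc_mask)
        mm = compute_descriptors(disc_mask, dpi=600)
        scale = 25.4 / 600
        assert mm.length == pytest.approx(px.length * scale)
        assert mm.area == pytest.approx(px.area * scale**2)
        assert mm.circularity == pytest.approx(px.circularity)


class TestEFD:
    def test_circle_coefficients(self, circle_contour):
        c = efd_coefficients(circle_contour, harmonics=20, normalize=True)
        a1, b1, c1, d1 = c.coeffs[0]
        assert a1 == pytest.approx(1.0, abs=1e-6)
        assert abs(b1) < 1e-6 and abs(c1) < 1e-6
        assert d1 == pytest.approx(1.0, abs=0.01)
        assert np.abs(c.coeffs[1:]).max() < 0.01

    def test_ellipse_first_harmonic_matches_integral_oracle(self, ellipse_contour):
        # chord-length parameterization of a 2:1 ellipse gives d1 ~ 0.587
        # (not the axis ratio 0.5): the oracle integral fixes the value
        oracle = brute_force_efd(ellipse_contour.points, 1)
        ours = efd_coefficients(ellipse_contour, harmonics=1, normalize=False)
        np.testing.assert_allclose(ours.coeffs, oracle, atol=1e-6)
        norm = efd_coefficients(ellipse_contour, harmonics=20, normalize=True)
        expected_d1 = abs(oracle[0, 3]) / abs(oracle[0, 0])
        assert norm.coeffs[0, 3] == pytest.approx(expected_d1, abs=1e-3)

    def test_oracle_equivalence_on_random_polygons(self):
        """Closed-form coefficients match dense numerical integration."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(12, 64))
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(20, 60, n)
            pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
            ours = efd_coefficients(Contour(pts), harmonics=8, normalize=False)
            oracle = brute_force_efd(pts, 8)
            np.testing.assert_allclose(ours.coeffs, oracle, atol=1e-6)

    def test_similarity_invariance(self, ellipse_contour):
        base = efd_coefficients(ellipse_contour, 20, normalize=True)
        th = np.deg2rad(40)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = (ellipse_contour.points * 3) @ R.T + [17.0, -4.0]
        pts = np.roll(pts, 57, axis=0)  # starting-point shift
        other = efd_coefficients(Contour(pts), 20, normalize=True)
        np.testing.assert_allclose(other.coeffs, base.coeffs, atol=1e-4)

    def test_degenerate_contour_raises(self):
        pts = np.tile([[1.0, 1.0]], (10, 1))
        with pytest.raises(ValueError):
            efd_coefficients(Contour(pts), 5)


class TestEFDFeatures:
    def test_length_and_circle_content(self, circle_contour):
        c = efd_coefficients(circle_contour, 20, normalize=True)
        v = efd_features(c)
        assert v.shape == (77,)
        assert v[0] == pytest.approx(1.0, abs=0.01)  # d1
        assert np.abs(v[1:]).max() < 0.01

    def test_unnormalized_rejected(self, circle_contour):
        c = efd_coefficients(circle_contour, 20, normalize=False)
        with pytest.raises(ValueError):
            efd_features(c)

    def test_rotation_invariant_features(self, ellipse_contour):
        v1 = efd_features(efd_coefficients(ellipse_contour, 20, normalize=True))
        th = np.deg2rad(111)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        v2 = efd_features(
            efd_coefficients(Contour(ellipse_contour.points @ R.T), 20, normalize=True)
        )
        np.testing.assert_allclose(v1, v2, atol=1e-4)

    def test_features_to_coeffs_inverse(self, ellipse_contour):
        c = efd_coefficients(ellipse_contour, 20, normalize=True)
        back = features_to_coeffs(efd_features(c))
        np.testing.assert_allclose(back.coeffs[0, :3], [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(back.coeffs.ravel()[3:], c.coeffs.ravel()[3:])


class TestReconstruction:
    def test_self_reconstruction_close(self, small_pool):
        sprite = small_pool.sprites[0]
        mask = sprite.alpha > 0.5
        contour = extract_contour(mask)
        coeffs = efd_coefficients(contour, 20, normalize=False)
        rec = efd_reconstruct(coeffs, n_points=400)
        # mean distance from reconstructed points to the original polygon
        d = np.min(
            np.linalg.norm(rec.points[:, None, :] - contour.points[None, :, :], axis=2), axis=1
        )
        assert d.mean() < 0.015 * max(np.ptp(contour.points[:, 0]), np.ptp(contour.points[:, 1]))

    def test_circle_radius_uniform(self, circle_contour):
        coeffs = efd_coefficients(circle_contour, 20, normalize=False)
        rec = efd_reconstruct(coeffs, n_points=200)
        r = np.linalg.norm(rec.points - rec.points.mean(axis=0), axis=1)
        assert r.std() / r.mean() < 0.01

    def test_error_decreases_with_harmonics(self, small_pool):
        mask = small_pool.sprites[3].alpha > 0.5
        contour = extract_contour(mask)
        errs = []
        for h in (2, 5, 10, 20):
            rec = efd_reconstruct(efd_coefficients(contour, h, normalize=False), n_points=3 * 20 * 2)
            d = np.min(
                np.linalg.norm(rec.points[:, None, :] - contour.points[None, :, :], axis=2),
                axis=1,
            )
            errs.append(d.mean())
        assert errs[-1] <= errs[0]
        assert all(b <= a * 1.05 for a, b in zip(errs, errs[1:]))  # non-increasing on average

    def test_too_few_points_rejected(self, circle_contour):
        coeffs = efd_coefficients(circle_contour, 20)
        with pytest.raises(ValueError):
            efd_reconstruct(coeffs, n_points=10)


class TestMeanContour:
    def test_mean_of_one_is_member(self, ellipse_contour):
        c = efd_coefficients(ellipse_contour, 20, normalize=True)
        m = mean_contour([c], n_points=120)
        r = efd_reconstruct(c, n_points=120)
        np.testing.assert_allclose(m.points, r.points)

    def test_identical_group(self, ellipse_contour):
        c = efd_coefficients(ellipse_contour, 20, normalize=True)
        m = mean_contour([c, c, c], n_points=120)
        np.testing.assert_allclose(m.points, efd_reconstruct(c, 120).points, atol=1e-12)

    def test_mean_of_mirror_perturbations_recovers_base(self, ellipse_contour):
        base = efd_coefficients(ellipse_contour, 20, normalize=True)
        delta = np.zeros_like(base.coeffs)
        delta[4, 3] = 0.05  # perturb one higher harmonic
        plus = EFDCoefficients(base.coeffs + delta, normalized=True)
        minus = EFDCoefficients(base.coeffs - delta, normalized=True)
        m = mean_contour([plus, minus], n_points=120)
        ref = efd_reconstruct(base, 120)
        dist_mean = np.abs(m.points - ref.points).max()
        dist_member = np.abs(efd_reconstruct(plus, 120).points - ref.points).max()
        assert dist_mean < dist_member
        np.testing.assert_allclose(m.points, ref.points, atol=1e-10)

    def test_mixed_harmonics_rejected(self, ellipse_contour):
        c20 = efd_coefficients(ellipse_contour, 20, normalize=True)
        c10 = efd_coefficients(ellipse_contour, 10, normalize=True)
        with pytest.raises(ValueError):
            mean_contour([c20, c10])


class TestPCA:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([t, 2 * t + 1])
        res = pca_fit(X)
        assert res.explained_ratio[0] == pytest.approx(1.0)
        assert res.explained_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_eigenvalue_recovery(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20000, 2)) * [2.0, 1.0]  # covariance diag(4, 1)
        res = pca_fit(X, standardize=False)
        assert res.explained_ratio[0] == pytest.approx(0.8, abs=0.02)
        assert res.explained_ratio[1] == pytest.approx(0.2, abs=0.02)

    def test_ratios_sum_to_one_full_rank(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 5))
        res = pca_fit(X)
        assert res.explained_ratio.sum() == pytest.approx(1.0)
        # loadings orthonormal
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-10)

    def test_zero_variance_column_named(self):
        X = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            pca_fit(X, standardize=True)

    def test_full_reconstruction_identity(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))
        res = pca_fit(X, standardize=True)
        back = res.inverse_transform(res.scores)
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 3))
        res = pca_fit(X)
        for k in range(res.loadings.shape[1]):
            j = np.argmax(np.abs(res.loadings[:, k]))
            assert res.loadings[j, k] > 0


class TestLatentAxisContours:
    @staticmethod
    def elongation_features(n=60, seed=9):
        """EFD features of ellipses with smoothly varying aspect ratio."""
        rng = np.random.default_rng(seed)
        feats = []
        aspects = np.linspace(1.2, 3.5, n)
        for a in aspects:
            c = polygon_ellipse(a=30 * a, b=30.0, n=200)
            pts = c.points + rng.normal(0, 0.05, c.points.shape)
            feats.append(efd_features(efd_coefficients(Contour(pts), 20, normalize=True)))
        return np.array(feats)

    def test_position_zero_is_mean_shape(self):
        X = self.elongation_features()
        res = pca_fit(X, standardize=False)
        (c0,) = latent_axis_contours(res, axis=0, positions=[0.0])
        ref = efd_reconstruct(features_to_coeffs(res.mean), 300)
        np.testing.assert_allclose(c0.points, ref.points, atol=1e-10)

    def test_aspect_monotone_along_pc1(self):
        X = self.elongation_features()
        res = pca_fit(X, standardize=False)
        sd = res.scores[:, 0].std()
        contours = latent_axis_contours(res, 0, [-2 * sd, 0.0, 2 * sd])
        def aspect(c):
            w = np.ptp(c.points[:, 0])
            h = np.ptp(c.points[:, 1])
            return max(w, h) / min(w, h)
        aspects = [aspect(c) for c in contours]
        assert aspects == sorted(aspects) or aspects == sorted(aspects, reverse=True)
        assert aspects[0] != pytest.approx(aspects[-1], rel=0.05)

    def test_score_feature_roundtrip(self):
        X = self.elongation_features(n=20)
        res = pca_fit(X, standardize=False)
        back = (res.inverse_transform(res.scores) - res.mean) / res.scale @ res.loadings
        np.testing.assert_allclose(back, res.scores, atol=1e-8)

    def test_axis_out_of_range(self):
        X = self.elongation_features(n=10)
        res = pca_fit(X, standardize=False)
        with pytest.raises(ValueError):
            latent_axis_contours(res, axis=99, positions=[0.0])
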