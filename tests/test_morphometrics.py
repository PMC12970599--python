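"""EFA, shape PCA, mask registration, sweeps, and k-means diagnostics.

Independent oracles: EFA coefficients are cross-checked by direct Fourier
integration (rectangle rule on a densely arc-length-resampled contour,
spectrally accurate for periodic signals); PCA is cross-checked by an
eigendecomposition of the covariance matrix.
"""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fruitmorph._geometry import resample_closed
from fruitmorph.morphometrics import (
    EFACoefficients,
    efa_forward,
    efa_inverse,
    harmonic_power,
    kmeans_sweep,
    pc_shape_sweep,
    pca_fit,
    register_mask,
)
from fruitmorph.synthetic import SeedShapeParams, generate_shape


def ellipse(a=50.0, b=25.0, n=400, phase=0.0, rot=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    if rot:
        c, s = np.cos(rot), np.sin(rot)
        pts = pts @ np.array([[c, -s], [s, c]]).T
    return pts


def blob(n=400, seed=0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rng = np.random.default_rng(seed)
    r = 30 + 5 * np.sin(3 * t + rng.uniform(0, np.pi)) + 3 * np.cos(5 * t)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def efa_oracle(contour, harmonics, dense=8192):
    """Direct Fourier integration of the arc-length parameterized contour."""
    pts = resample_closed(contour, dense)  # uniform in arc length
    x, y = pts[:, 0], pts[:, 1]
    t = np.arange(dense) / dense
    coeffs = np.empty((harmonics, 4))
    for i, n in enumerate(range(1, harmonics + 1)):
        cos = np.cos(2 * np.pi * n * t)
        sin = np.sin(2 * np.pi * n * t)
        coeffs[i] = [
            2 * np.mean(x * cos),
            2 * np.mean(x * sin),
            2 * np.mean(y * cos),
            2 * np.mean(y * sin),
        ]
    return coeffs, float(np.mean(x)), float(np.mean(y))


def roundtrip_error(contour, harmonics):
    rec = efa_inverse(efa_forward(contour, harmonics), 600)
    return float(cKDTree(contour).query(rec)[0].mean())


class TestEFA:
    def test_ellipse_is_pure_first_harmonic_under_index_param(self):
        co = efa_forward(ellipse(), harmonics=6, parameterization="index")
        np.testing.assert_allclose(co.coeffs[0], [50, 0, 0, 25], atol=1e-3 * 50)
        assert np.abs(co.coeffs[1:]).max() < 1e-3 * 50

    def test_circle_first_harmonic_radius(self):
        co = efa_forward(ellipse(30, 30), harmonics=4)
        assert co.coeffs[0, 0] == pytest.approx(30, rel=1e-3)
        assert co.coeffs[0, 3] == pytest.approx(30, rel=1e-3)
        assert np.abs(co.coeffs[1:]).max() < 1e-3 * 30

    def test_chain_summation_matches_integration_oracle(self):
        for seed in range(3):
            contour = blob(seed=seed)
            mine = efa_forward(contour, 8)
            oracle_coeffs, a0, c0 = efa_oracle(contour, 8)
            np.testing.assert_allclose(mine.coeffs, oracle_coeffs, atol=5e-3 * 30)
            assert mine.a0 == pytest.approx(a0, abs=0.05)
            assert mine.c0 == pytest.approx(c0, abs=0.05)

    def test_harmonic1_inverse_is_parametric_ellipse(self):
        co = EFACoefficients(np.array([[40.0, 0.0, 0.0, 20.0]]), 5.0, -3.0)
        rec = efa_inverse(co, 128)
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        np.testing.assert_allclose(rec[:, 0], 5 + 40 * np.cos(t), atol=1e-6)
        np.testing.assert_allclose(rec[:, 1], -3 + 20 * np.sin(t), atol=1e-6)

    def test_roundtrip_below_half_pixel_at_h40(self):
        for seed in range(3):
            assert roundtrip_error(blob(seed=seed), 40) < 0.5

    def test_reconstruction_improves_with_harmonics(self):
        contour = blob(seed=5)
        errs = [roundtrip_error(contour, h) for h in (1, 3, 10, 40)]
        assert all(b <= a for a, b in zip(errs, errs[1:]))

    def test_sampling_density_does_not_change_shape(self):
        co = efa_forward(blob(seed=2), 10)
        rec1 = efa_inverse(co, 200)
        rec2 = efa_inverse(co, 400)
        d = cKDTree(rec2).query(rec1)[0].max()
        assert d < 1.0

    def test_normalization_invariants_and_stability(self):
        base = ellipse(40, 18)
        variants = [
            np.roll(base, 91, axis=0),  # starting point shift
            ellipse(40, 18, rot=np.deg2rad(55)),  # rigid rotation
        ]
        ref = efa_forward(base, 6, normalize=True)
        assert ref.coeffs[0, 0] > 0
        assert abs(ref.coeffs[0, 1]) < 1e-9 and abs(ref.coeffs[0, 2]) < 1e-9
        for v in variants:
            other = efa_forward(v, 6, normalize=True)
            np.testing.assert_allclose(other.coeffs, ref.coeffs, atol=1e-3)

    def test_open_contour_rejected(self):
        with pytest.raises(ValueError):
            efa_forward(np.array([[0.0, 0.0], [1.0, 1.0]]), 2)


class TestHarmonicPower:
    def test_pure_ellipse_all_power_in_first(self):
        co = efa_forward(ellipse(), 6, parameterization="index")
        power = harmonic_power(co)
        assert power["cumulative_fraction"][0] > 0.999999

    def test_cumulative_curve_monotone_bounded(self):
        power = harmonic_power([efa_forward(blob(seed=s), 12) for s in range(4)])
        cf = power["cumulative_fraction"]
        assert np.all(np.diff(cf) >= 0) and cf[-1] == pytest.approx(1.0)

    def test_harmonics_to_99pct_match_bruteforce(self):
        coeffs = [efa_forward(blob(seed=s), 20) for s in range(4)]
        cf = harmonic_power(coeffs)["cumulative_fraction"]
        by_curve = 1 + int(np.argmax(cf >= 0.99))
        powers = np.mean([np.sum(c.coeffs**2, axis=1) / 2 for c in coeffs], axis=0)
        total = powers.sum()
        running = 0.0
        for h, p in enumerate(powers, start=1):  # brute-force scan
            running += p
            if running / total >= 0.99:
                break
        assert by_curve == h


class TestPCA:
    def test_points_on_line_single_component(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([2 * t, -3 * t])
        model = pca_fit(X, basis="efa")
        assert model.explained_variance_fractions[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(50, 20))
            model = pca_fit(X, basis="efa")
            cov = np.cov(X, rowvar=False)
            evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
            fractions = evals / evals.sum()
            np.testing.assert_allclose(
                model.explained_variance_fractions, fractions, atol=1e-8
            )
            # scores agree with projections up to component sign
            centered = X - X.mean(axis=0)
            _, vecs = np.linalg.eigh(cov)
            proj = centered @ vecs[:, ::-1]
            np.testing.assert_allclose(
                np.abs(model.scores), np.abs(proj), atol=1e-8
            )

    def test_scores_zero_mean_and_retention_rule(self, rng):
        # construct data with known variance fractions: 0.70 / 0.29 / 0.005 ...
        n = 2000
        sds = np.sqrt(np.array([0.70, 0.29, 0.005, 0.005]))
        X = rng.normal(size=(n, 4)) * sds
        model = pca_fit(X, basis="efa")
        np.testing.assert_allclose(model.scores.mean(axis=0), 0, atol=1e-10)
        expected = int(np.sum(model.explained_variance_fractions >= 0.01))
        assert model.retained == expected == 2

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_fit(np.ones((10, 5)), basis="efa")


class TestRegisterMask:
    def test_vector_length(self, ellipse_shape):
        vec = register_mask(ellipse_shape.mask, (128, 128))
        assert vec.shape == (16384,)

    def test_scale_invariance(self):
        p = SeedShapeParams(24, 13, 0.8, 0.1, 0.02)
        v4 = register_mask(generate_shape(p, 4.0).mask)
        v8 = register_mask(generate_shape(p, 8.0).mask)
        assert np.mean(v4 != v8) <= 0.01

    def test_mirrored_shape_same_after_alignment(self):
        from fruitmorph.morphology import align

        shape = generate_shape(SeedShapeParams(26, 14, 0.8, 0.15, 0.05), 6.0)
        a1 = align(shape.mask)
        a2 = align(shape.mask[:, ::-1].copy())
        assert np.array_equal(register_mask(a1.mask), register_mask(a2.mask))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            register_mask(np.zeros((10, 10), bool))


def elongation_family(n=30, px=5.0):
    return [
        generate_shape(SeedShapeParams(L, 12.0, 0.9), px)
        for L in np.linspace(20, 32, n)
    ]


class TestSweepAndClusters:
    def test_sweep_multiple_zero_is_mean(self, rng):
        X = rng.normal(size=(40, 12))  # 3 harmonics x 4 coefficients
        model = pca_fit(X, basis="efa")
        shapes = pc_shape_sweep(model, 0, multiples=(0,), n_points=100)
        # efa basis: back-projection of the mean reshaped through inverse
        co = EFACoefficients(model.mean.reshape(-1, 4), 0.0, 0.0)
        np.testing.assert_allclose(shapes[0], efa_inverse(co, 100))

    def test_sweep_symmetry_through_mean(self, rng):
        X = rng.normal(size=(30, 8))
        model = pca_fit(X, basis="efa")
        sm, s0, sp = pc_shape_sweep(model, 1, multiples=(-2, 0, 2), n_points=50)
        np.testing.assert_allclose((sm + sp) / 2, s0, atol=1e-9)

    def test_elongation_family_pc1_monotone_aspect(self):
        shapes = elongation_family()
        X = np.asarray([register_mask(s.mask) for s in shapes])
        model = pca_fit(X, basis="pixel", feature_shape=(128, 128))
        # PC1 dominates and orders the family by its single varying parameter
        f = model.explained_variance_fractions
        assert f[0] > 0.5 and f[0] > 3 * f[1]
        scores = model.scores[:, 0]
        assert np.all(np.diff(scores) > 0) or np.all(np.diff(scores) < 0)
        masks = pc_shape_sweep(model, 0, multiples=(-3, 0, 3))
        aspects = [m.sum(axis=1).max() and (m.any(axis=1).sum() / m.any(axis=0).sum()) for m in masks]
        assert (aspects[0] - aspects[1]) * (aspects[1] - aspects[2]) > 0  # monotone

    def test_efa_basis_family_concentrates_variance(self):
        shapes = elongation_family()
        from fruitmorph._geometry import outer_contour

        X = []
        for s in shapes:
            c = resample_closed(outer_contour(s.mask), 300)[:, ::-1]
            X.append(efa_forward(c - c.mean(axis=0), 10).flatten())
        model = pca_fit(np.asarray(X), basis="efa", harmonics=10)
        assert model.explained_variance_fractions[0] >= 0.9

    def test_kmeans_k1_wss_is_total_ss(self, rng):
        X = rng.normal(size=(60, 3))
        results, wss = kmeans_sweep(X, k_range=range(1, 4), seed=0)
        total_ss = np.sum((X - X.mean(axis=0)) ** 2)
        assert wss[0] == pytest.approx(total_ss, rel=1e-9)

    def test_kmeans_recovers_separated_blobs(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([rng.normal(c, 0.5, size=(40, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 40)
        results, wss = kmeans_sweep(X, k_range=range(1, 6), seed=1)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, results[2].assignments) >= 0.99
        assert all(b <= a + 1e-9 for a, b in zip(wss, wss[1:]))

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_sweep(rng.normal(size=(4, 2)), k_range=range(1, 6), seed=0)
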