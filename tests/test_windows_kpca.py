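"""Windowing, PCA and Gaussian-kernel KPCA against dense eigensolver oracles."""

import numpy as np
import pytest

from emgforce.kpca import (KpcaModel, contribution_rates, cumulative_contribution,
                           gaussian_kernel, kpca_fit, kpca_project, load_kpca,
                           median_heuristic_gamma, pca_fit, pca_project, save_kpca)
from emgforce.synth import Recording
from emgforce.windows import WindowSpec, build_windows


class TestBuildWindows:
    def _rec(self, T=1000, C=2):
        rng = np.random.default_rng(0)
        return Recording(signals=rng.standard_normal((T, C)),
                         force=np.linspace(0.0, 1.0, T), fs=1000.0,
                         labels=tuple(f"ch{i}" for i in range(C)))

    def test_window_count(self):
        ds = build_windows(self._rec(1000), WindowSpec(window_len=200, stride=100))
        assert len(ds) == 9

    def test_non_overlapping_partition(self):
        rec = self._rec(1000)
        ds = build_windows(rec, WindowSpec(window_len=200, stride=200))
        assert len(ds) == 5
        np.testing.assert_array_equal(ds.X.ravel(), rec.signals[:, 0])

    def test_constant_force_targets(self):
        rec = self._rec(600)
        rec.force[:] = 3.5
        ds = build_windows(rec, WindowSpec())
        np.testing.assert_allclose(ds.y, 3.5)

    def test_stacked_mode_concatenates_channels(self):
        rec = self._rec(400, C=3)
        ds = build_windows(rec, WindowSpec(window_len=100, stride=100,
                                           channel_mode="stacked"))
        assert ds.X.shape == (4, 300)
        np.testing.assert_array_equal(ds.X[0, :100], rec.signals[:100, 0])
        np.testing.assert_array_equal(ds.X[0, 100:200], rec.signals[:100, 1])

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="window_len"):
            build_windows(self._rec(100), WindowSpec(window_len=200, stride=100))

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(window_len=100, stride=0)
        with pytest.raises(ValueError):
            WindowSpec(window_len=100, stride=200)


class TestPca:
    def test_line_through_centroid_one_component(self):
        t = np.linspace(-1, 1, 30)
        X = np.outer(t, [1.0, 2.0, -1.0]) + 5.0
        m = pca_fit(X, k=3)
        cont = contribution_rates(m.eigenvalues)
        assert cont[0] > 1.0 - 1e-12

    def test_matches_dense_eigensolver_oracle(self, rng):
        X = rng.standard_normal((25, 6))
        m = pca_fit(X, k=6)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / len(X))
        order = np.argsort(evals)[::-1]
        np.testing.assert_allclose(m.eigenvalues, evals[order], atol=1e-10)
        proj = pca_project(m, X)
        oracle = Xc @ evecs[:, order]
        np.testing.assert_allclose(np.abs(proj), np.abs(oracle), atol=1e-8)

    def test_mean_sample_projects_to_zero(self, rng):
        X = rng.standard_normal((10, 4))
        m = pca_fit(X, k=2)
        np.testing.assert_allclose(pca_project(m, X.mean(axis=0)),
                                   np.zeros(2), atol=1e-12)

    def test_axes_orthonormal(self, rng):
        m = pca_fit(rng.standard_normal((15, 5)), k=4)
        np.testing.assert_allclose(m.axes @ m.axes.T, np.eye(4), atol=1e-10)

    def test_invalid_k_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            pca_fit(X, k=0)
        with pytest.raises(ValueError):
            pca_fit(X, k=5)


class TestGaussianKernel:
    def test_closed_form_values(self):
        assert gaussian_kernel(np.ones(3), np.ones(3), gamma=2.0) == 1.0
        x, y = np.array([0.0, 0.0]), np.array([1.0, 1.0])   # ||x-y||^2 = 2
        assert gaussian_kernel(x, y, gamma=0.5) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_kernel_matrix_symmetric_psd(self, rng):
        X = rng.standard_normal((10, 3))
        K = gaussian_kernel(X, X, gamma=0.7)
        np.testing.assert_allclose(K, K.T, atol=1e-14)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.ones(2), np.ones(2), gamma=0.0)
        with pytest.raises(ValueError):
            gaussian_kernel(np.ones(2), np.ones(3), gamma=1.0)


class TestKpca:
    def test_linear_kernel_matches_pca_oracle(self, rng):
        """Inner-product-kernel KPCA projections equal PCA scores up to sign."""
        X = rng.standard_normal((20, 8))
        k = kpca_fit(X, xi_threshold=1.0, linear=True)
        pca = pca_fit(X, k=8)
        H = kpca_project(k, X, n_components=5)
        Y = pca_project(pca, X)[:, :5]
        np.testing.assert_allclose(np.abs(H), np.abs(Y), atol=1e-8)

    def test_eigenvalues_sorted_nonnegative(self, windowed_channel):
        m = kpca_fit(windowed_channel.X[:80])
        assert np.all(np.diff(m.eigenvalues) <= 1e-9)
        assert m.eigenvalues.min() >= 0.0

    def test_xi_one_retains_all_nonzero(self, rng):
        X = rng.standard_normal((12, 4))
        m = kpca_fit(X, gamma=0.5, xi_threshold=1.0)
        assert m.P == len(m.eigenvalues)
        assert contribution_rates(m.eigenvalues).sum() == pytest.approx(1.0)

    def test_training_scores_zero_mean_and_consistent(self, rng):
        X = rng.standard_normal((15, 5))
        m = kpca_fit(X, gamma=0.3, xi_threshold=1.0)
        H = kpca_project(m, X)
        np.testing.assert_allclose(H.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(kpca_project(m, X[3]), H[3], atol=1e-10)

    def test_projection_invariant_to_constant_shift(self, rng):
        X = rng.standard_normal((12, 4))
        shift = 7.3 * np.ones(4)
        m1 = kpca_fit(X, gamma=0.4, xi_threshold=1.0)
        m2 = kpca_fit(X + shift, gamma=0.4, xi_threshold=1.0)
        x = rng.standard_normal(4)
        h1 = kpca_project(m1, x)
        h2 = kpca_project(m2, x + shift)
        np.testing.assert_allclose(np.abs(h1), np.abs(h2), atol=1e-7)

    def test_degenerate_identical_samples_rejected(self):
        X = np.ones((6, 3))
        with pytest.raises(ValueError, match="degenerate|identical"):
            kpca_fit(X, gamma=1.0)

    def test_median_heuristic_positive(self, rng):
        X = rng.standard_normal((30, 4))
        g = median_heuristic_gamma(X)
        assert g > 0

    def test_matches_sklearn_kernel_pca_oracle(self, rng):
        """Training scores agree with an independent KPCA implementation."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = rng.standard_normal((30, 5))
        gamma = 0.2
        m = kpca_fit(X, gamma=gamma, xi_threshold=1.0)
        H = kpca_project(m, X, n_components=4)
        ref = sklearn.KernelPCA(n_components=4, kernel="rbf", gamma=gamma)
        R = ref.fit_transform(X)
        np.testing.assert_allclose(np.abs(H), np.abs(R), atol=1e-8)
        np.testing.assert_allclose(m.eigenvalues[:4], ref.eigenvalues_, atol=1e-8)

    def test_save_load_project_bit_identical(self, tmp_path, rng):
        X = rng.standard_normal((20, 6))
        m = kpca_fit(X, xi_threshold=0.9)
        path = tmp_path / "kpca.npz"
        save_kpca(m, path)
        m2 = load_kpca(path)
        x = rng.standard_normal((5, 6))
        np.testing.assert_array_equal(kpca_project(m, x), kpca_project(m2, x))


class TestContributionRates:
    def test_simple_shares(self):
        np.testing.assert_allclose(contribution_rates([3.0, 1.0]), [0.75, 0.25])

    def test_equal_eigenvalues_uniform(self):
        np.testing.assert_allclose(contribution_rates(np.ones(5)), np.full(5, 0.2))

    def test_cumulative_full_is_one(self):
        lam = np.array([4.0, 2.0, 1.0])
        assert cumulative_contribution(lam, 3) == pytest.approx(1.0)
        assert cumulative_contribution(lam, 1) == pytest.approx(4.0 / 7.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            contribution_rates([0.0, 0.0])
        with pytest.raises(ValueError):
            contribution_rates([-1.0, 2.0])
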