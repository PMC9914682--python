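import numpy as np
import pytest
from scipy import stats

from specerr.screening import SpectralPCA, flag_outliers


def _plane_data(n=40, p=8, k=2, noise=0.0, seed=0):
    """Data on a random k-dim plane through a random center, plus iid noise."""
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((p, k)))
    scores = rng.standard_normal((n, k)) * np.array([5.0, 2.0])[:k]
    X = 10.0 + scores @ basis.T
    if noise:
        X = X + noise * rng.standard_normal((n, p))
    return X, basis


class TestFit:
    def test_line_data_single_component_explains_all(self):
        X, _ = _plane_data(k=1)
        res = SpectralPCA(X, 1).fit()
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_two_cluster_scores_opposite_signs(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.1, (10, 4)), rng.normal(5, 0.1, (10, 4))])
        scores = SpectralPCA(X, 1).fit().transform()[:, 0]
        assert set(np.sign(scores[:10])) != set(np.sign(scores[10:]))

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 6))
        res = SpectralPCA(X, min(9, 6)).fit()
        recon = res.transform() @ res.loadings.T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-10)

    def test_sign_convention_deterministic(self):
        X, _ = _plane_data()
        a = SpectralPCA(X, 2).fit().loadings
        b = SpectralPCA(X.copy(), 2).fit().loadings
        np.testing.assert_array_equal(a, b)
        assert (a[np.argmax(np.abs(a), axis=0), np.arange(2)] > 0).all()

    def test_k_out_of_range(self):
        X, _ = _plane_data(n=5, p=3)
        with pytest.raises(ValueError):
            SpectralPCA(X, 5)


class TestStatistics:
    def test_center_sample_zero_t2_and_contributions(self):
        X, _ = _plane_data()
        res = SpectralPCA(X, 2).fit()
        center = res.center
        assert res.t2_statistic(center[None, :])[0] == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(res.t2_contributions(center), 0.0, atol=1e-18)
        np.testing.assert_allclose(res.q_contributions(center), 0.0, atol=1e-18)

    def test_t2_single_component_definition(self):
        X, _ = _plane_data(k=1)
        res = SpectralPCA(X, 1).fit()
        t = res.transform()[:, 0]
        np.testing.assert_allclose(res.t2_statistic(), t**2 / res.eigenvalues[0])

    def test_q_zero_in_subspace_and_full_rank(self):
        X, _ = _plane_data(k=2)
        res = SpectralPCA(X, 2).fit()
        np.testing.assert_allclose(res.q_statistic(), 0.0, atol=1e-18)
        noisy, _ = _plane_data(k=2, noise=0.3)
        full = SpectralPCA(noisy, min(noisy.shape[0] - 1, noisy.shape[1])).fit()
        np.testing.assert_allclose(full.q_statistic(), 0.0, atol=1e-16)

    def test_q_equals_squared_residual_norm(self):
        X, _ = _plane_data(k=2, noise=0.5)
        res = SpectralPCA(X, 1).fit()
        r = res.residuals()
        np.testing.assert_allclose(res.q_statistic(), np.sum(r**2, axis=1))

    def test_contributions_sum_to_statistics(self):
        X, _ = _plane_data(noise=0.4, seed=9)
        res = SpectralPCA(X, 2).fit()
        x = X[3]
        assert res.q_contributions(x).sum() == pytest.approx(
            res.q_statistic(x[None, :])[0]
        )
        assert res.t2_contributions(x).sum() == pytest.approx(
            res.t2_statistic(x[None, :])[0]
        )

    def test_spike_dominates_q_contributions(self):
        X, _ = _plane_data(noise=0.05, seed=2)
        res = SpectralPCA(X, 2).fit()
        x = X[0].copy()
        x[5] += 4.0
        assert np.argmax(res.q_contributions(x)) == 5


class TestLimits:
    def test_t2_limit_matches_chi2_asymptote(self):
        X = np.random.default_rng(0).standard_normal((100_000, 3))
        res = SpectralPCA(X, 1).fit()
        assert res.t2_limit(0.05) == pytest.approx(stats.chi2.ppf(0.95, 1), rel=1e-3)

    def test_limits_vanish_as_alpha_approaches_one(self):
        X, _ = _plane_data(noise=0.3)
        res = SpectralPCA(X, 2).fit()
        assert res.t2_limit(0.9999) < 1e-3
        assert res.q_limit(0.9999) < res.q_limit(0.05)

    def test_component_count_capped_below_sample_count(self):
        X = np.random.default_rng(1).standard_normal((4, 10))
        with pytest.raises(ValueError):
            SpectralPCA(X, 4)  # k = n leaves no dof for the T² limit

    def test_exceedance_rates_near_alpha(self):
        """On 500 Gaussian samples from a 2-component model, both 95% limits
        are exceeded by about 5% of the training set."""
        X, _ = _plane_data(n=500, p=30, k=2, noise=0.1, seed=42)
        screen = SpectralPCA(X, 2).fit().screen(alpha=0.05)
        assert 0.03 <= screen.exceeds_t2.mean() <= 0.07
        assert 0.03 <= screen.exceeds_q.mean() <= 0.07


class TestFlagging:
    def test_rules(self):
        X, _ = _plane_data(n=100, p=10, noise=0.2, seed=6)
        res = SpectralPCA(X, 2).fit()
        screen = res.screen(alpha=0.05)
        only_q = screen.exceeds_q & ~screen.exceeds_t2
        if only_q.any():
            assert not flag_outliers(screen, "both")[only_q].any()
            assert flag_outliers(screen, "either")[only_q].all()
        both = screen.exceeds_q & screen.exceeds_t2
        np.testing.assert_array_equal(flag_outliers(screen, "both"), both)
        with pytest.raises(ValueError):
            flag_outliers(screen, "any")

    def test_shifted_replicate_flagged_on_both(self):
        from specerr.simulate import DesignSpec, NoiseModel, NEOSPECTRA_LIKE, simulate_dataset

        ds = simulate_dataset(
            DesignSpec(samples=("s",), instrument=NEOSPECTRA_LIKE),
            NoiseModel(seed=8),
        )
        # a gross outlier needs in-plane *and* off-plane anomaly: a level
        # shift of several error-SDs plus a channel-wise shape perturbation
        sd = ds.X.std(axis=0, ddof=1).mean()
        rng = np.random.default_rng(0)
        X = ds.X.copy()
        X[17] += 5.0 * sd + rng.standard_normal(X.shape[1])
        screen = SpectralPCA(X, 2).fit().screen(alpha=0.05)
        flags = flag_outliers(screen, "both")
        assert flags[17] and flags.sum() == 1

    def test_pure_offset_shift_is_t2_only(self):
        """A constant 10σ shift lies (nearly) inside the retained subspace of
        offset-dominated spectra: a T² detection, not a Q one."""
        from specerr.simulate import DesignSpec, NoiseModel, NEOSPECTRA_LIKE, simulate_dataset

        ds = simulate_dataset(
            DesignSpec(samples=("s",), instrument=NEOSPECTRA_LIKE),
            NoiseModel(seed=8),
        )
        sd = ds.X.std(axis=0, ddof=1).mean()
        X = ds.X.copy()
        X[17] += 10.0 * sd
        screen = SpectralPCA(X, 2).fit().screen(alpha=0.05)
        assert screen.exceeds_t2[17]
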