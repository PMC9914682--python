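import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from specerr.dataset import ReplicateGrouping
from specerr.error_structure import (
    ErrorMatrix,
    error_correlation,
    error_covariance,
    error_matrix,
    residual_matrix,
)
from specerr.simulate import (
    DesignSpec,
    NEOSPECTRA_LIKE,
    NoiseModel,
    base_spectrum,
    simulate_dataset,
)

from conftest import make_dataset


def _sim(noise, n=200, seed=0, profile=NEOSPECTRA_LIKE):
    design = DesignSpec(samples=("s",), sessions_per_mode=1,
                        replicates_per_session=n // 2, instrument=profile)
    return simulate_dataset(design, noise, seed=seed)


class TestErrorMatrix:
    def test_two_point_symmetry(self):
        ds = make_dataset([[1.0, 5.0], [3.0, 1.0]])
        em = error_matrix(ds, "all")
        np.testing.assert_allclose(em.E, [[-1.0, 2.0], [1.0, -2.0]])

    def test_zero_noise_gives_zero(self):
        ds = _sim(NoiseModel(0, 0, 0, 0, 0, 0), n=10)
        assert np.abs(error_matrix(ds, "per_session").E).max() < 1e-12

    def test_group_columns_sum_to_zero(self, emulated_design):
        em = error_matrix(emulated_design, "per_session")
        for label in set(em.group_labels):
            idx = em.group_labels == label
            np.testing.assert_allclose(em.E[idx].sum(axis=0), 0.0, atol=1e-9)

    def test_grouping_all_single_sample_equals_residuals(self, emulated_design):
        sub = emulated_design.subset(sample_id="sugar_lump")
        np.testing.assert_allclose(
            error_matrix(sub, "all").E, residual_matrix(sub).E
        )

    def test_singleton_group_named(self):
        ds = make_dataset(np.ones((3, 2)))
        ds.meta.loc[2, "session_id"] = "2A"
        with pytest.raises(ValueError, match="2A"):
            error_matrix(ds, "per_session")


class TestResidualMatrix:
    def test_identical_rows_zero(self):
        assert np.abs(residual_matrix(make_dataset([[2.0, 3.0]] * 2)).E).max() == 0

    def test_grouped_vs_grand_difference_is_group_mean_offset(self):
        ds = make_dataset(np.vstack([np.zeros((3, 2)), np.full((3, 2), 10.0)])
                          + np.random.default_rng(0).normal(0, 0.1, (6, 2)))
        ds.meta.loc[3:, "session_id"] = "2A"
        E = error_matrix(ds, "per_session")
        Ehat = residual_matrix(ds)
        diff = Ehat.E - E.E
        grand = ds.X.mean(axis=0)
        for label in set(E.group_labels):
            idx = E.group_labels == label
            offset = ds.X[idx].mean(axis=0) - grand
            np.testing.assert_allclose(diff[idx], np.tile(offset, (idx.sum(), 1)),
                                       atol=1e-12)


class TestCovariance:
    def test_hand_computed(self):
        em = ErrorMatrix(np.array([[1.0, 1.0], [-1.0, -1.0]]),
                         np.array(["g", "g"], dtype=object), "replicate_error")
        cov = error_covariance(em)
        assert cov.n_effective == 1
        np.testing.assert_allclose(cov.Sigma, [[2.0, 2.0], [2.0, 2.0]])

    def test_zero_error_gives_zero(self):
        em = ErrorMatrix(np.zeros((4, 3)), np.array(["g"] * 4, dtype=object),
                         "replicate_error")
        np.testing.assert_array_equal(error_covariance(em).Sigma, 0.0)

    def test_offset_only_approaches_constant_matrix(self):
        sigma_o = 0.5
        ds = _sim(NoiseModel(sigma_o, 0, 0, 0, 0, 0), n=1000, seed=3)
        cov = error_covariance(error_matrix(ds, "per_session"))
        np.testing.assert_allclose(cov.Sigma, sigma_o**2, rtol=0.35)
        assert abs(cov.Sigma.mean() - sigma_o**2) / sigma_o**2 < 0.15

    def test_no_degrees_of_freedom(self):
        em = ErrorMatrix(np.zeros((2, 2)),
                         np.array(["a", "b"], dtype=object), "replicate_error")
        with pytest.raises(ValueError):
            error_covariance(em)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    arrays(np.float64, st.tuples(st.integers(3, 10), st.integers(2, 8)),
           elements=st.floats(-30, 30, allow_nan=False, width=32))
)
def test_sigma_always_psd(X):
    ds = make_dataset(X)
    cov = error_covariance(error_matrix(ds, "all"))
    assert np.linalg.eigvalsh(cov.Sigma).min() >= -1e-8 * max(
        1.0, np.abs(cov.Sigma).max()
    )


class TestCorrelation:
    def test_hand_computed(self):
        corr = error_correlation(np.array([[2.0, 2.0], [2.0, 2.0]]))
        np.testing.assert_allclose(corr.R, 1.0)

    def test_diagonal_sigma_gives_identity(self):
        corr = error_correlation(np.diag([1.0, 4.0, 9.0]))
        np.testing.assert_allclose(corr.R, np.eye(3))

    def test_rank_one_gives_all_ones(self):
        v = np.array([1.0, 2.0, 0.5])
        corr = error_correlation(np.outer(v, v))
        np.testing.assert_allclose(corr.R, 1.0, atol=1e-12)

    def test_zero_variance_channels_excluded_and_listed(self):
        Sigma = np.diag([1.0, 0.0, 2.0])
        corr = error_correlation(Sigma)
        np.testing.assert_array_equal(corr.retained, [0, 2])
        np.testing.assert_array_equal(corr.excluded, [1])

    def test_all_zero_variance_degenerate(self):
        with pytest.raises(ValueError):
            error_correlation(np.zeros((3, 3)))


class TestDiagonalShapes:
    """Each noise type leaves its fingerprint on the Σ diagonal."""

    def test_iid_noise_homoscedastic(self):
        ds = _sim(NoiseModel(0, 0, 0, 0.2, 0, 0), n=1000, seed=5)
        diag = error_covariance(error_matrix(ds, "per_session")).diagonal
        np.testing.assert_allclose(diag, 0.04, rtol=0.4)

    @pytest.mark.parametrize(
        "noise,power",
        [(NoiseModel(0, 0, 0.3, 0, 0, 0), 1),     # shot: diag ∝ μ
         (NoiseModel(0, 0.05, 0, 0, 0, 0), 2)],   # multiplicative: diag ∝ μ²
        ids=["shot", "multiplicative"],
    )
    def test_signal_dependent_noise_tracks_mean_spectrum(self, noise, power):
        from scipy.stats import spearmanr

        ds = _sim(noise, n=500, seed=6)
        diag = error_covariance(error_matrix(ds, "per_session")).diagonal
        mu = base_spectrum(NEOSPECTRA_LIKE) ** power
        assert spearmanr(diag, mu).statistic > 0.95


def test_pooled_diagonal_exceeds_per_session_with_session_variance():
    """Pooling across sessions folds the session shifts into the error."""
    noise = NoiseModel(0.3, 0.0, 0.0, 0.1, sigma_session=1.0, delta_background=0.0)
    design = DesignSpec(samples=("s",), sessions_per_mode=3,
                        replicates_per_session=30, instrument=NEOSPECTRA_LIKE)
    ds = simulate_dataset(design, noise, seed=21)
    pooled = error_covariance(error_matrix(ds, "all")).diagonal
    per_sess = error_covariance(error_matrix(ds, "per_session")).diagonal
    assert pooled.mean() > per_sess.mean()
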