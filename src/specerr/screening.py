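"""Exploratory PCA with Hotelling T² / Q-residual outlier screening.

A :class:`SpectralPCA` model is fitted to mean-centered spectra (no scaling by
default, matching common chemometric practice for reflectance data). The
resulting :class:`SpectralPCAResults` carries scores, loadings and eigenvalues
and computes the two distance statistics with their 95% control limits:

* Hotelling's T² — distance inside the model plane, scaled by the score
  variances; limit from the F distribution,
  ``T²_lim = k (n − 1) / (n − k) · F_{1−α}(k, n − k)``.
* Q (squared prediction error) — squared distance off the model plane; limit
  from the Jackson–Mudholkar approximation on the residual eigenvalues.

Samples exceeding *both* limits are flagged as outliers under the default
rule; "either" is available for more aggressive screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["SpectralPCA", "SpectralPCAResults", "ScreenResult"]


def _fix_loading_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip column signs so each loading's largest-|·| element is positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return signs


class SpectralPCA:
    """PCA model of an n×p spectra matrix, centered (optionally autoscaled).

    Parameters
    ----------
    X : array-like, shape (n, p)
        Spectra (or a :class:`~specerr.dataset.SpectraDataset`, whose matrix
        is used).
    n_components : int
        Number of retained components k, ``1 ≤ k ≤ min(n − 1, p)``.
    scale : bool
        Autoscale columns to unit variance before decomposition (off by
        default; reflectance spectra share a physical scale).
    """

    def __init__(self, X, n_components: int, scale: bool = False):
        X = np.asarray(getattr(X, "X", X), dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a 2-D matrix with at least 2 rows")
        n, p = X.shape
        kmax = min(n - 1, p)
        if not 1 <= n_components <= kmax:
            raise ValueError(
                f"n_components must be in [1, {kmax}] for an {n}×{p} matrix, "
                f"got {n_components}"
            )
        self.X = X
        self.n_components = int(n_components)
        self.scale = bool(scale)

    def fit(self) -> "SpectralPCAResults":
        X = self.X
        n = X.shape[0]
        center = X.mean(axis=0)
        Xc = X - center
        scale_ = np.ones(X.shape[1])
        if self.scale:
            scale_ = Xc.std(axis=0, ddof=1)
            scale_[scale_ == 0] = 1.0
            Xc = Xc / scale_
        # full SVD: residual eigenvalues are needed for the Q limit
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        signs = _fix_loading_signs(Vt.T)
        Vt = Vt * signs[:, None]
        U = U * signs[None, :]
        eigenvalues = s**2 / (n - 1)  # score variances, all components
        k = self.n_components
        return SpectralPCAResults(
            model=self,
            center=center,
            scale_=scale_,
            loadings=Vt[:k].T.copy(),
            eigenvalues=eigenvalues[:k].copy(),
            residual_eigenvalues=eigenvalues[k:].copy(),
            all_eigenvalues=eigenvalues,
            scores=(U[:, :k] * s[:k]),
            n_samples=n,
        )


@dataclass
class ScreenResult:
    """T²/Q statistics, control limits and outlier flags for a set of spectra."""

    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    alpha: float
    rule: str = "both"

    @property
    def exceeds_t2(self) -> np.ndarray:
        return self.t2 > self.t2_limit

    @property
    def exceeds_q(self) -> np.ndarray:
        return self.q > self.q_limit

    @property
    def flags(self) -> np.ndarray:
        return flag_outliers(self, self.rule)


def flag_outliers(result: ScreenResult, rule: str = "both") -> np.ndarray:
    """Boolean outlier flags; ``both`` requires exceeding the T² and Q limits."""
    if rule == "both":
        return result.exceeds_t2 & result.exceeds_q
    if rule == "either":
        return result.exceeds_t2 | result.exceeds_q
    raise ValueError(f"rule must be 'both' or 'either', got {rule!r}")


@dataclass
class SpectralPCAResults:
    """Fitted PCA model: center, loadings, eigenvalues, scores and statistics."""

    model: SpectralPCA
    center: np.ndarray
    scale_: np.ndarray
    loadings: np.ndarray           # p × k, columns orthonormal, sign-fixed
    eigenvalues: np.ndarray        # retained score variances, non-increasing
    residual_eigenvalues: np.ndarray
    all_eigenvalues: np.ndarray
    scores: np.ndarray             # n × k training scores
    n_samples: int

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.all_eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else np.zeros(self.k)

    # -- projection --------------------------------------------------------

    def _center_scale(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(getattr(X, "X", X), dtype=float))
        return (X - self.center) / self.scale_

    def transform(self, X=None) -> np.ndarray:
        if X is None:
            return self.scores
        return self._center_scale(X) @ self.loadings

    def residuals(self, X=None) -> np.ndarray:
        Xc = self._center_scale(X if X is not None else self.model.X)
        return Xc - (Xc @ self.loadings) @ self.loadings.T

    # -- statistics --------------------------------------------------------

    def t2_statistic(self, X=None) -> np.ndarray:
        """Hotelling T² per sample over the retained components."""
        if np.any(self.eigenvalues <= 0):
            raise ValueError("zero eigenvalue among retained components")
        t = self.transform(X)
        return np.sum(t**2 / self.eigenvalues, axis=1)

    def q_statistic(self, X=None) -> np.ndarray:
        """Squared residual norm per sample (off-model distance)."""
        return np.sum(self.residuals(X) ** 2, axis=1)

    def t2_limit(self, alpha: float = 0.05) -> float:
        """T² control limit at confidence 1−α from the F distribution."""
        n, k = self.n_samples, self.k
        if n <= k:
            raise ValueError("need n > k samples for the T² limit")
        return k * (n - 1) / (n - k) * stats.f.ppf(1 - alpha, k, n - k)

    def q_limit(self, alpha: float = 0.05) -> float:
        """Q control limit via the Jackson–Mudholkar approximation.

        Uses the residual eigenvalue moments θ_m = Σ λ_a^m over the discarded
        components; returns 0 when the residual space carries no variance.
        """
        lam = self.residual_eigenvalues
        lam = lam[lam > 0]
        if lam.size == 0:
            return 0.0
        th1, th2, th3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
        h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
        if h0 < 1e-3:
            h0 = 1e-3
        z = stats.norm.ppf(1 - alpha)
        inner = (
            z * np.sqrt(2.0 * th2 * h0**2) / th1
            + 1.0
            + th2 * h0 * (h0 - 1.0) / th1**2
        )
        if inner <= 0:
            return 0.0
        return float(th1 * inner ** (1.0 / h0))

    def screen(self, X=None, alpha: float = 0.05, rule: str = "both") -> ScreenResult:
        """T²/Q statistics with limits and flags for X (default: training set)."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return ScreenResult(
            t2=self.t2_statistic(X),
            q=self.q_statistic(X),
            t2_limit=self.t2_limit(alpha),
            q_limit=self.q_limit(alpha),
            alpha=alpha,
            rule=rule,
        )

    # -- contributions -----------------------------------------------------

    def q_contributions(self, x) -> np.ndarray:
        """Per-wavelength Q contributions (squared residuals); sum to Q(x)."""
        r = self.residuals(np.atleast_2d(np.asarray(x, dtype=float)))[0]
        return r**2

    def t2_contributions(self, x) -> np.ndarray:
        """Per-wavelength T² contributions via loadings-weighted scores.

        contrib_j = Σ_a (t_a / λ_a) · P_ja · x̃_j; the contributions sum to T².
        """
        xc = self._center_scale(np.atleast_2d(np.asarray(x, dtype=float)))[0]
        t = xc @ self.loadings
        weights = self.loadings @ (t / self.eigenvalues)
        return weights * xc
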