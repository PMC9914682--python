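"""Error matrices and error covariance/correlation estimation from replicates.

The measurement error of a replicated spectrum is its deviation from the mean
of its replicate group ("the real value"). Collecting those deviations row-wise
gives the error matrix E; the pooled error covariance matrix is

    Σ = EᵀE / (n − g)

with g the number of replicate groups (each group mean costs one degree of
freedom, so the divisor makes the pooled estimate unbiased). The residual
matrix Ê instead subtracts the grand mean of all spectra; comparing the
variance profile of Ê with that of Σ quantifies the uncorrelated error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ReplicateGrouping, SpectraDataset

__all__ = [
    "ErrorMatrix",
    "ErrorCovariance",
    "ErrorCorrelation",
    "error_matrix",
    "residual_matrix",
    "error_covariance",
    "error_correlation",
    "covariance_diagonal",
]

#: Relative tolerance for declaring a channel zero-variance.
ZERO_VARIANCE_RTOL = 1e-12


@dataclass
class ErrorMatrix:
    """Replicate deviations: rows of E sum to zero within each group.

    ``flavor`` distinguishes the group-mean error matrix E from the grand-mean
    residual matrix Ê.
    """

    E: np.ndarray
    group_labels: np.ndarray
    flavor: str  # "replicate_error" | "grand_residual"
    wavelengths: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.E.shape[0]

    @property
    def p(self) -> int:
        return self.E.shape[1]

    @property
    def n_groups(self) -> int:
        return len(set(self.group_labels.tolist()))

    @property
    def dof(self) -> int:
        return self.n - self.n_groups


@dataclass
class ErrorCovariance:
    """p×p symmetric PSD error covariance Σ in (%R)²."""

    Sigma: np.ndarray
    n_effective: int
    wavelengths: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.Sigma.shape[0]

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.Sigma).copy()

    def to_frame(self) -> pd.DataFrame:
        labels = self.wavelengths if self.wavelengths is not None else np.arange(self.p)
        return pd.DataFrame(self.Sigma, index=labels, columns=labels)


@dataclass
class ErrorCorrelation:
    """Error correlation matrix on channels with non-degenerate variance."""

    R: np.ndarray
    retained: np.ndarray           # indices of retained channels
    excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    wavelengths: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.R.shape[0]


def error_matrix(
    dataset: SpectraDataset, grouping: ReplicateGrouping | str = "all"
) -> ErrorMatrix:
    """Deviation of each replicate from its group mean.

    Every group must hold at least two replicates; the offending group is
    named otherwise.
    """
    if isinstance(grouping, str):
        grouping = ReplicateGrouping(grouping)
    labels = grouping.labels(dataset)
    E = np.empty_like(dataset.X)
    for label in pd.unique(labels):
        idx = np.flatnonzero(labels == label)
        if idx.size < 2:
            raise ValueError(
                f"replicate group {label!r} has only {idx.size} replicate(s); "
                "cannot form an error matrix"
            )
        E[idx] = dataset.X[idx] - dataset.X[idx].mean(axis=0)
    return ErrorMatrix(E, labels, "replicate_error", dataset.axis.values)


def residual_matrix(dataset: SpectraDataset) -> ErrorMatrix:
    """Residual matrix Ê: spectra minus the grand mean of all spectra."""
    if dataset.n < 2:
        raise ValueError("need at least 2 spectra for a residual matrix")
    E = dataset.X - dataset.X.mean(axis=0)
    labels = np.array(["all"] * dataset.n, dtype=object)
    return ErrorMatrix(E, labels, "grand_residual", dataset.axis.values)


def error_covariance(em: ErrorMatrix) -> ErrorCovariance:
    """Pooled error covariance Σ = EᵀE / (n − #groups)."""
    dof = em.dof
    if dof < 1:
        raise ValueError(
            f"no degrees of freedom left ({em.n} replicates, {em.n_groups} groups)"
        )
    Sigma = em.E.T @ em.E / dof
    Sigma = (Sigma + Sigma.T) / 2.0  # enforce exact symmetry
    return ErrorCovariance(Sigma, dof, em.wavelengths)


def error_correlation(
    sigma: ErrorCovariance | np.ndarray, rtol: float = ZERO_VARIANCE_RTOL
) -> ErrorCorrelation:
    """Correlation matrix R_jk = Σ_jk / √(Σ_jj Σ_kk).

    Channels whose variance is below ``rtol × max(diag)`` are excluded (and
    listed) rather than producing spurious ±1 entries from noise in the
    denominator.
    """
    wavelengths = None
    if isinstance(sigma, ErrorCovariance):
        wavelengths = sigma.wavelengths
        Sigma = sigma.Sigma
    else:
        Sigma = np.asarray(sigma, dtype=float)
    d = np.diag(Sigma)
    if d.max(initial=0.0) <= 0:
        raise ValueError("all channels have zero error variance")
    keep = d > rtol * d.max()
    if not keep.any():
        raise ValueError("all channels have zero error variance")
    idx = np.flatnonzero(keep)
    sub = Sigma[np.ix_(idx, idx)]
    scale = 1.0 / np.sqrt(np.diag(sub))
    R = sub * scale[:, None] * scale[None, :]
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    wl = wavelengths[idx] if wavelengths is not None else None
    return ErrorCorrelation(R, idx, np.flatnonzero(~keep), wl)


def covariance_diagonal(sigma: ErrorCovariance) -> np.ndarray:
    """Per-channel error variances (the heteroscedasticity profile)."""
    return sigma.diagonal
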