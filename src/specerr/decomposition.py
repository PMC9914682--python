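"""Bilinear (PCA) decomposition of the error covariance matrix and of Ê.

Σ is a second-moment object, so it is decomposed by an *uncentered*
eigendecomposition. Two variance-fraction conventions are reported:

* linear, λ_i / Σλ — appropriate for the PCA of the residual matrix Ê, where
  the eigenvalues already are variances;
* squared, λ_i² / Σλ² — appropriate when the decomposed matrix is itself a
  covariance: the sum of squares captured by component i of Σ scales with
  λ_i². When Σ = ÊᵀÊ/ν, the squared-convention fractions of Σ equal the
  squared-and-renormalised linear fractions of Ê, which is exactly the
  relationship seen between the two columns of the variance-comparison table.

A small gap between the cumulative profiles of Ê and Σ indicates that the
error is dominated by correlated (low-rank) structure, i.e. little
independent (uncorrelated) noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .error_structure import ErrorCovariance, ErrorMatrix
from .screening import _fix_loading_signs

__all__ = [
    "DecompositionResult",
    "VarianceComparison",
    "decompose_matrix",
    "decompose_residuals",
    "variance_comparison",
    "log_eigenvalue_curve",
]

_SYM_RTOL = 1e-8


@dataclass
class DecompositionResult:
    """Eigen-spectrum of a decomposed matrix with both variance conventions."""

    eigenvalues: np.ndarray        # non-increasing, ≥ 0 (clipped at 0)
    loadings: np.ndarray           # p × k, sign-fixed
    linear_fractions: np.ndarray   # λ_i / Σλ, full spectrum
    squared_fractions: np.ndarray  # λ_i² / Σλ², full spectrum

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_linear(self) -> np.ndarray:
        return np.cumsum(self.linear_fractions)

    @property
    def cumulative_squared(self) -> np.ndarray:
        return np.cumsum(self.squared_fractions)


def _fractions(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam = np.clip(eigenvalues, 0.0, None)
    total = lam.sum()
    linear = lam / total if total > 0 else np.zeros_like(lam)
    total2 = (lam**2).sum()
    squared = lam**2 / total2 if total2 > 0 else np.zeros_like(lam)
    return linear, squared


def decompose_matrix(M, k: int | None = None) -> DecompositionResult:
    """Uncentered eigendecomposition of a symmetric PSD matrix.

    Eigenvalues are sorted descending; tiny negative values from round-off are
    clipped to zero. ``k`` limits how many loading vectors are retained
    (default: all).
    """
    if isinstance(M, ErrorCovariance):
        M = M.Sigma
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    scale = np.abs(M).max(initial=1.0)
    if not np.allclose(M, M.T, atol=_SYM_RTOL * max(scale, 1.0)):
        raise ValueError("M is not symmetric within tolerance")
    lam, vec = np.linalg.eigh((M + M.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam = np.clip(lam, 0.0, None)
    vec = vec * _fix_loading_signs(vec)[None, :]
    if k is None:
        k = M.shape[0]
    if not 1 <= k <= M.shape[0]:
        raise ValueError(f"k must be in [1, {M.shape[0]}], got {k}")
    linear, squared = _fractions(lam)
    return DecompositionResult(lam, vec[:, :k].copy(), linear, squared)


def decompose_residuals(ehat: ErrorMatrix, k: int | None = None) -> DecompositionResult:
    """PCA of the residual matrix Ê (already centered; no further centering).

    The eigen-spectrum is that of ÊᵀÊ, obtained by SVD; linear fractions are
    the usual explained-variance fractions.
    """
    if ehat.flavor != "grand_residual":
        raise ValueError(
            f"expected a grand_residual error matrix, got flavor {ehat.flavor!r}"
        )
    U, s, Vt = np.linalg.svd(ehat.E, full_matrices=False)
    lam = s**2  # eigenvalues of ÊᵀÊ
    V = Vt.T
    V = V * _fix_loading_signs(V)[None, :]
    if k is None:
        k = V.shape[1]
    if not 1 <= k <= V.shape[1]:
        raise ValueError(f"k must be in [1, {V.shape[1]}], got {k}")
    linear, squared = _fractions(lam)
    return DecompositionResult(lam, V[:, :k].copy(), linear, squared)


@dataclass
class VarianceComparison:
    """Side-by-side per-component % variance in Ê and in Σ.

    ``gap`` is the Σ-column minus the Ê-column at component 1 (percentage
    points): near zero when independent noise is negligible, growing as
    uncorrelated error is added.
    """

    table: pd.DataFrame
    gap: float

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.3f}")


def variance_comparison(
    ehat: ErrorMatrix, sigma: ErrorCovariance, k: int = 5
) -> VarianceComparison:
    """Variance-comparison table up to k components.

    Ê column: linear explained-variance fractions of the residual matrix.
    Σ column: squared-convention fractions of the uncentered decomposition of
    the error covariance matrix. Both in percent, 3-decimal print precision.
    """
    if ehat.p != sigma.p:
        raise ValueError(
            f"channel mismatch: Ê has {ehat.p}, Σ has {sigma.p}"
        )
    res_e = decompose_residuals(ehat)
    res_s = decompose_matrix(sigma)
    k = min(k, res_e.linear_fractions.size, res_s.squared_fractions.size)
    e_col = 100.0 * res_e.linear_fractions[:k]
    s_col = 100.0 * res_s.squared_fractions[:k]
    table = pd.DataFrame(
        {
            "% Variance in Original Residuals (E-hat)": e_col,
            "% Variance in the Error Covariance Matrix (Sigma)": s_col,
        },
        index=pd.Index(np.arange(1, k + 1), name="# of Principal Components"),
    )
    return VarianceComparison(table, gap=float(s_col[0] - e_col[0]))


def log_eigenvalue_curve(result: DecompositionResult) -> np.ndarray:
    """(component, log10 eigenvalue) pairs for component-count selection.

    Zero eigenvalues are truncated (the curve stops at the matrix rank).
    """
    lam = result.eigenvalues
    pos = lam > 0
    if not pos.all() and pos.any():
        lam = lam[: int(np.argmin(pos))] if not pos[0] else lam[pos]
    elif not pos.any():
        return np.empty((0, 2))
    components = np.arange(1, lam.size + 1)
    return np.column_stack([components, np.log10(lam)])
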