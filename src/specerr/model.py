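"""Model/Results facade tying the analysis chain together.

:class:`MeasurementErrorModel` is built from a :class:`~specerr.dataset.SpectraDataset`
(or a plain DataFrame in the package CSV layout) plus a replicate grouping;
``fit()`` estimates the error matrix, the residual matrix Ê, the error
covariance Σ and correlation R, their bilinear decompositions, the
variance-comparison table and the K redundancy index, and returns a
:class:`MeasurementErrorResults` with a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from . import decomposition as dc
from . import error_structure as es
from .dataset import META_COLUMNS, ReplicateGrouping, SpectraDataset, WavelengthAxis
from .descriptives import DescriptiveSummary, describe
from .kindex import KResult, imbedded_correlation, k_index

__all__ = ["MeasurementErrorModel", "MeasurementErrorResults"]


class MeasurementErrorModel:
    """Multivariate measurement-error model for replicated spectra.

    Parameters
    ----------
    dataset : SpectraDataset
        Replicated spectra with metadata.
    grouping : str or ReplicateGrouping
        Which replicate means define the measurement error ("all",
        "per_session", "per_background_mode" or a custom grouping).
    n_components : int
        Components shown in the variance-comparison table and kept as
        loadings.
    """

    def __init__(self, dataset: SpectraDataset, grouping="all", n_components: int = 5):
        if isinstance(grouping, str):
            grouping = ReplicateGrouping(grouping)
        report = dataset.validate(grouping)
        if not report.ok:
            raise ValueError(f"invalid dataset:\n{report}")
        self.dataset = dataset
        self.grouping = grouping
        self.n_components = int(n_components)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MeasurementErrorModel":
        """Build from a DataFrame in the package CSV layout (metadata columns
        first, then numeric wavelength columns)."""
        wl_cols = [c for c in df.columns if c not in META_COLUMNS]
        axis = WavelengthAxis(np.array([float(c) for c in wl_cols]))
        ds = SpectraDataset(df[wl_cols].to_numpy(float), axis, df[list(META_COLUMNS)])
        return cls(ds, **kwargs)

    def fit(self) -> "MeasurementErrorResults":
        E = es.error_matrix(self.dataset, self.grouping)
        Ehat = es.residual_matrix(self.dataset)
        Sigma = es.error_covariance(E)
        return MeasurementErrorResults(
            model=self,
            error_mat=E,
            residual_mat=Ehat,
            sigma=Sigma,
        )


@dataclass
class MeasurementErrorResults:
    """Estimated error structure of a replicated-spectra dataset."""

    model: MeasurementErrorModel
    error_mat: es.ErrorMatrix
    residual_mat: es.ErrorMatrix
    sigma: es.ErrorCovariance

    # -- derived quantities (lazy) ----------------------------------------

    @cached_property
    def correlation(self) -> es.ErrorCorrelation:
        return es.error_correlation(self.sigma)

    @property
    def diagonal(self) -> np.ndarray:
        """Per-channel error variances (heteroscedasticity profile)."""
        return self.sigma.diagonal

    @cached_property
    def sigma_decomposition(self) -> dc.DecompositionResult:
        return dc.decompose_matrix(self.sigma, k=self.model.n_components)

    @cached_property
    def residual_decomposition(self) -> dc.DecompositionResult:
        return dc.decompose_residuals(self.residual_mat, k=self.model.n_components)

    @cached_property
    def variance_comparison(self) -> dc.VarianceComparison:
        return dc.variance_comparison(
            self.residual_mat, self.sigma, k=self.model.n_components
        )

    @property
    def uncorrelated_error_gap(self) -> float:
        """Σ-column minus Ê-column at component 1, in percentage points."""
        return self.variance_comparison.gap

    @cached_property
    def k_result(self) -> KResult:
        return k_index(self.error_mat)

    @property
    def k(self) -> float:
        return self.k_result.K

    @property
    def imbedded_correlation(self) -> float:
        """Rank-constraint floor on K for this dataset's n and p."""
        return imbedded_correlation(self.error_mat.n, self.error_mat.p)

    @cached_property
    def descriptives(self) -> DescriptiveSummary:
        return describe(self.model.dataset)

    def diagonal_by(self, grouping: str) -> pd.DataFrame:
        """Σ diagonals recomputed under another grouping, one column per group.

        Used for the session-wise / background-mode-wise diagonal overlays.
        """
        g = ReplicateGrouping(grouping)
        labels = g.labels(self.model.dataset)
        out = {}
        for label in pd.unique(labels):
            sub = self.model.dataset.take(np.flatnonzero(labels == label))
            E = es.error_matrix(sub, ReplicateGrouping("custom",
                                                       tuple([label] * sub.n)))
            out[label] = es.error_covariance(E).diagonal
        return pd.DataFrame(out, index=self.model.dataset.axis.values)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        ds = self.model.dataset
        vc = self.variance_comparison
        lines = [
            "Multivariate Measurement Error Results",
            "=" * 54,
            f"replicates            {ds.n}",
            f"channels              {ds.p}",
            f"grouping              {self.model.grouping.mode}"
            f" ({self.error_mat.n_groups} group(s),"
            f" dof={self.error_mat.dof})",
            f"mean error variance   {self.diagonal.mean():.6g} (%R)^2",
            f"K correlation index   {self.k:.4f}",
            f"imbedded correlation  {self.imbedded_correlation:.4f}",
            f"uncorrelated gap      {self.uncorrelated_error_gap:.3f} points",
            "",
            "Variance accounted for (%):",
            vc.table.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)
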