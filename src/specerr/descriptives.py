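"""Reproducibility statistics for replicated spectra.

Per-wavelength mean/SD/RSD, the per-replicate RMS repeatability statistic and
the per-wavelength signal-to-noise ratio, plus the six-row summary table used
to compare instruments and samples at a glance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SpectraDataset

__all__ = [
    "DescriptiveSummary",
    "per_wavelength_stats",
    "rms_statistic",
    "snr",
    "summary_table",
    "TABLE_ROWS",
]

#: Row labels of the descriptive summary table, in print order.
TABLE_ROWS = (
    "Absolute standard deviation-mean",
    "Relative standard deviation (%)-mean",
    "RMS-mean",
    "RMS-standard deviation",
    "Signal/Noise Ratio-mean",
    "Signal/Noise Ratio-standard deviation",
)


class DegenerateDataError(ValueError):
    """Raised when fewer than two replicates are available."""


def _require_replicates(dataset: SpectraDataset) -> None:
    if dataset.n < 2:
        raise DegenerateDataError(
            f"need at least 2 replicates, got {dataset.n}"
        )


@dataclass
class DescriptiveSummary:
    """Per-channel and per-replicate reproducibility statistics.

    ``rsd`` and ``snr`` are NaN at undefined channels (zero mean / zero SD);
    the scalar summaries skip those channels.
    """

    mean_spectrum: np.ndarray
    sd_spectrum: np.ndarray
    rsd_spectrum: np.ndarray
    rms_per_replicate: np.ndarray
    snr_spectrum: np.ndarray

    @property
    def sd_mean(self) -> float:
        return float(np.mean(self.sd_spectrum))

    @property
    def rsd_mean(self) -> float:
        return float(np.nanmean(self.rsd_spectrum))

    @property
    def rms_mean(self) -> float:
        return float(np.mean(self.rms_per_replicate))

    @property
    def rms_sd(self) -> float:
        return float(np.std(self.rms_per_replicate, ddof=1))

    @property
    def snr_mean(self) -> float:
        return float(np.nanmean(self.snr_spectrum))

    @property
    def snr_sd(self) -> float:
        return float(np.nanstd(self.snr_spectrum, ddof=1))

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.sd_mean, self.rsd_mean, self.rms_mean, self.rms_sd,
             self.snr_mean, self.snr_sd],
            index=list(TABLE_ROWS),
        )


def per_wavelength_stats(dataset: SpectraDataset):
    """Mean, SD (n−1 denominator) and relative SD (%) per wavelength channel.

    RSD_j = 100 · s_j / x̄_j; channels with zero mean are flagged NaN.
    """
    _require_replicates(dataset)
    mean = dataset.X.mean(axis=0)
    sd = dataset.X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean != 0, 100.0 * sd / mean, np.nan)
    if np.isnan(rsd).any():
        warnings.warn("RSD undefined at channels with zero mean", stacklevel=2)
    return mean, sd, rsd


def rms_statistic(dataset: SpectraDataset):
    """Root-mean-square deviation of each replicate from the mean spectrum.

    RMS_i = sqrt((1/p) Σ_j (x_ij − x̄_j)²); returns the n-vector plus its mean
    and SD over replicates.
    """
    _require_replicates(dataset)
    dev = dataset.X - dataset.X.mean(axis=0)
    rms = np.sqrt(np.mean(dev**2, axis=1))
    return rms, float(rms.mean()), float(rms.std(ddof=1))


def snr(dataset: SpectraDataset):
    """Per-channel signal-to-noise ratio SNR_j = x̄_j / s_j.

    Channels with zero SD are flagged NaN and excluded from the mean/SD
    summaries, with a warning.
    """
    _require_replicates(dataset)
    mean = dataset.X.mean(axis=0)
    sd = dataset.X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, mean / sd, np.nan)
    if np.isnan(ratio).any():
        warnings.warn(
            "SNR undefined at zero-variance channels; excluded from summaries",
            stacklevel=2,
        )
    if np.isnan(ratio).all():
        return ratio, float("nan"), float("nan")
    return ratio, float(np.nanmean(ratio)), float(np.nanstd(ratio, ddof=1))


def describe(dataset: SpectraDataset) -> DescriptiveSummary:
    """All reproducibility statistics for one replicate set."""
    mean, sd, rsd = per_wavelength_stats(dataset)
    rms, _, _ = rms_statistic(dataset)
    ratio, _, _ = snr(dataset)
    return DescriptiveSummary(mean, sd, rsd, rms, ratio)


def summary_table(dataset: SpectraDataset, by: str = "sample_id") -> pd.DataFrame:
    """Six-row descriptive table, one column per level of ``by``.

    Rows follow :data:`TABLE_ROWS`; each column is computed on the subset of
    replicates belonging to that partition cell.
    """
    if by not in dataset.meta.columns:
        raise KeyError(f"unknown metadata field: {by!r}")
    columns = {}
    for level in dataset.meta[by].unique():
        sub = dataset.subset(**{by: level})
        columns[level] = describe(sub).as_series()
    return pd.DataFrame(columns)
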