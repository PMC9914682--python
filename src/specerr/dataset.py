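"""Replicated-spectra data model and CSV I/O.

The universal input object is :class:`SpectraDataset`: an ``n × p`` matrix of
percent-reflectance spectra (rows are replicate measurements, columns are
wavelength channels) together with the wavelength axis in nm and one metadata
record per replicate (sample identity, analytical session, background-timing
mode, replicate index, instrument tag).

The CSV dialect is a single header row: the five metadata columns first, then
one numeric column per wavelength whose label is the nm value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "META_COLUMNS",
    "WavelengthAxis",
    "SpectraDataset",
    "ReplicateGrouping",
    "ValidationReport",
    "read_spectra",
    "write_spectra",
]

#: Metadata columns, in on-disk order.
META_COLUMNS = (
    "sample_id",
    "session_id",
    "background_mode",
    "replicate_index",
    "instrument_id",
)

#: Replicate-grouping modes understood throughout the package.
GROUPING_MODES = ("all", "per_session", "per_background_mode", "custom")


class SpectraFormatError(ValueError):
    """Raised when a spectra CSV cannot be parsed into a valid dataset."""


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise SpectraFormatError("wavelength axis must be a non-empty 1-D sequence")
        if np.any(v <= 0):
            raise SpectraFormatError("wavelengths must be positive (nm)")
        if np.any(np.diff(v) <= 0):
            raise SpectraFormatError("wavelength axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def p(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.p

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavelengthAxis) and np.array_equal(self.values, other.values)


@dataclass
class ValidationReport:
    """List of invariant violations found in a dataset; empty iff valid."""

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:
        return self.ok

    def __str__(self) -> str:
        return "valid dataset" if self.ok else "\n".join(self.issues)


class SpectraDataset:
    """Replicate spectra matrix with wavelength axis and per-row metadata.

    Parameters
    ----------
    X : array-like, shape (n, p)
        Spectra in percent reflectance; one replicate per row.
    axis : WavelengthAxis or array-like
        Wavelength axis in nm, length p.
    meta : pandas.DataFrame
        One row per replicate with at least the columns in :data:`META_COLUMNS`.
    """

    def __init__(self, X, axis, meta: pd.DataFrame):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not isinstance(axis, WavelengthAxis):
            axis = WavelengthAxis(np.asarray(axis, dtype=float))
        meta = pd.DataFrame(meta).reset_index(drop=True)
        if X.shape[0] != len(meta):
            raise SpectraFormatError(
                f"row count {X.shape[0]} does not match metadata count {len(meta)}"
            )
        if X.shape[1] != axis.p:
            raise SpectraFormatError(
                f"column count {X.shape[1]} does not match axis length {axis.p}"
            )
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise SpectraFormatError(f"missing metadata columns: {', '.join(missing)}")
        if (X[np.isfinite(X)].size and
                ((X[np.isfinite(X)] < 0).any() or (X[np.isfinite(X)] > 100).any())):
            warnings.warn(
                "reflectance values outside [0, 100] %R present", stacklevel=2
            )
        self.X = X
        self.axis = axis
        self.meta = meta

    # -- basic protocol ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return f"<SpectraDataset n={self.n} replicates, p={self.p} channels>"

    def copy(self) -> "SpectraDataset":
        return SpectraDataset(self.X.copy(), self.axis, self.meta.copy())

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        predicate: Callable[[pd.Series], bool] | None = None,
        **field_values,
    ) -> "SpectraDataset":
        """Select replicates by metadata condition, preserving row order.

        Either pass keyword equality conditions (``sample_id="lump"``) or a
        callable evaluated on each metadata row.
        """
        for key in field_values:
            if key not in self.meta.columns:
                raise KeyError(f"unknown metadata field: {key!r}")
        mask = np.ones(self.n, dtype=bool)
        for key, value in field_values.items():
            mask &= (self.meta[key] == value).to_numpy()
        if predicate is not None:
            mask &= self.meta.apply(predicate, axis=1).to_numpy(dtype=bool)
        if not mask.any():
            warnings.warn("subset predicate matched no replicates", stacklevel=2)
        return SpectraDataset(self.X[mask], self.axis, self.meta.loc[mask])

    def take(self, indices) -> "SpectraDataset":
        """Positional row selection (keeps axis, preserves given order)."""
        idx = np.asarray(indices)
        return SpectraDataset(self.X[idx], self.axis, self.meta.iloc[idx])

    # -- validation --------------------------------------------------------

    def validate(self, grouping: "ReplicateGrouping | None" = None) -> ValidationReport:
        """Check dataset invariants; returns a report, never raises."""
        report = ValidationReport()
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))
            report.issues.append(
                f"{len(bad)} missing/non-finite value(s), first at row "
                f"{bad[0][0]}, channel {bad[0][1]}"
            )
        key = self.meta[["sample_id", "session_id", "replicate_index"]]
        dup = key.duplicated()
        if dup.any():
            report.issues.append(
                f"duplicated (sample_id, session_id, replicate_index) for rows "
                f"{list(np.flatnonzero(dup.to_numpy()))}"
            )
        # background mode must not vary within a session (per sample)
        mode_counts = self.meta.groupby(["sample_id", "session_id"], sort=False)[
            "background_mode"
        ].nunique()
        mixed = mode_counts[mode_counts > 1]
        for (samp, sess) in mixed.index:
            report.issues.append(
                f"background_mode varies within session {sess!r} of sample {samp!r}"
            )
        if grouping is not None:
            labels = grouping.labels(self)
            counts = pd.Series(labels).value_counts()
            for label, count in counts.items():
                if count < 2:
                    report.issues.append(
                        f"group {label!r} has only {count} replicate(s); "
                        "error matrix would be degenerate"
                    )
        return report


@dataclass(frozen=True)
class ReplicateGrouping:
    """Assignment of replicates to groups whose means define the error matrix.

    Modes
    -----
    ``all``
        one group per sample (deviations from the sample mean);
    ``per_session``
        one group per (sample, session);
    ``per_background_mode``
        one group per (sample, background mode);
    ``custom``
        explicit labels supplied by the caller.
    """

    mode: str = "all"
    custom_labels: tuple | None = None

    def __post_init__(self) -> None:
        if self.mode not in GROUPING_MODES:
            raise ValueError(
                f"grouping mode must be one of {GROUPING_MODES}, got {self.mode!r}"
            )
        if self.mode == "custom" and self.custom_labels is None:
            raise ValueError("custom grouping requires explicit labels")

    def labels(self, dataset: SpectraDataset) -> np.ndarray:
        """Group label for each replicate row."""
        meta = dataset.meta
        if self.mode == "custom":
            labels = np.asarray(self.custom_labels, dtype=object)
            if labels.size != dataset.n:
                raise ValueError("custom labels length does not match dataset")
            return labels
        if self.mode == "all":
            cols = ["sample_id"]
        elif self.mode == "per_session":
            cols = ["sample_id", "session_id"]
        else:  # per_background_mode
            cols = ["sample_id", "background_mode"]
        return np.array(
            ["/".join(str(meta.iloc[i][c]) for c in cols) for i in range(dataset.n)],
            dtype=object,
        )


def read_spectra(path) -> SpectraDataset:
    """Read a replicated-spectra CSV into a validated :class:`SpectraDataset`.

    The header row must list the metadata columns of :data:`META_COLUMNS`
    followed by one numeric (nm) label per wavelength channel.
    """
    df = pd.read_csv(path, dtype={c: str for c in ("sample_id", "session_id",
                                                   "background_mode", "instrument_id")})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(
            f"missing metadata column(s): {', '.join(missing)}"
        )
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength label: {exc}") from exc
    axis = WavelengthAxis(wavelengths)  # raises on non-monotone header
    X = df[wl_cols].to_numpy(dtype=float)
    meta = df[list(META_COLUMNS)].copy()
    meta["replicate_index"] = meta["replicate_index"].astype(int)
    return SpectraDataset(X, axis, meta)


def write_spectra(dataset: SpectraDataset, path, float_format: str = "%.10g") -> None:
    """Write a dataset in the CSV dialect :func:`read_spectra` accepts."""
    wl_labels = [format(w, "g") for w in dataset.axis.values]
    values = pd.DataFrame(dataset.X, columns=wl_labels)
    df = pd.concat(
        [dataset.meta[list(META_COLUMNS)].reset_index(drop=True), values], axis=1
    )
    df.to_csv(path, index=False, float_format=float_format)
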