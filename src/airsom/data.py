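"""Dated multipollutant matrices: I/O, training-set construction, standardization.

The central container is :class:`PollutantMatrix`, an ``n`` days x ``p``
pollutant-metrics matrix keyed by strictly increasing calendar dates.
Missing observations are carried as NaN (distinct from zero) so that
complete-case training sets can be built and incomplete days can still be
projected onto a trained map later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PollutantMatrix",
    "CovariateTable",
    "StandardizationParams",
    "FormatError",
    "IntegrityError",
    "SchemaError",
    "read_pollutant_csv",
    "write_pollutant_csv",
    "complete_case_filter",
    "standardize",
    "apply_standardization",
]


class FormatError(ValueError):
    """A cell or date field could not be parsed."""


class IntegrityError(ValueError):
    """A structural invariant (e.g. unique, ordered dates) is violated."""


class SchemaError(ValueError):
    """Column names/order do not match what an operation expects."""


@dataclass
class _DatedMatrix:
    """n x p real matrix keyed by strictly increasing calendar dates."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    columns: list[str]
    units: list[str] | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.columns = list(self.columns)
        if self.values.ndim != 2:
            raise IntegrityError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise IntegrityError("matrix must have at least one row and one column")
        if len(self.dates) != n:
            raise IntegrityError(
                f"{len(self.dates)} dates for {n} rows: every row needs exactly one date"
            )
        if p != len(self.columns):
            raise IntegrityError("column_names length does not match value columns")
        if self.dates.has_duplicates:
            dup = self.dates[self.dates.duplicated()][0]
            raise IntegrityError(f"duplicate date {dup.date()}")
        if not self.dates.is_monotonic_increasing:
            raise IntegrityError("dates must be strictly increasing")
        if self.units is not None and len(self.units) != p:
            raise IntegrityError("units length does not match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.dates, columns=self.columns)

    def row_mask_complete(self) -> np.ndarray:
        """Boolean mask of rows with no missing entries."""
        return ~np.isnan(self.values).any(axis=1)


@dataclass
class PollutantMatrix(_DatedMatrix):
    """Daily multipollutant concentrations (the SOM input matrix)."""


@dataclass
class CovariateTable(_DatedMatrix):
    """Aligned covariates (e.g. meteorology) joinable on dates."""


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column location/scale fitted on a training set.

    ``sds`` use the n-1 (sample) denominator and must be strictly positive:
    a constant column carries no contrast and is rejected at fit time.
    """

    means: np.ndarray
    sds: np.ndarray
    columns: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        object.__setattr__(self, "columns", tuple(self.columns))
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise IntegrityError("means and sds must be 1-D and the same length")
        if np.any(self.sds <= 0):
            raise IntegrityError("standard deviations must be strictly positive")

    @property
    def p(self) -> int:
        return self.means.shape[0]


def read_pollutant_csv(
    path,
    date_column: str = "date",
    missing_token: str = "NA",
    units: Sequence[str] | None = None,
    kind=PollutantMatrix,
) -> PollutantMatrix:
    """Read a delimited daily time series into a :class:`PollutantMatrix`.

    Rows are sorted by date; cells equal to ``missing_token`` become missing.
    Raises :class:`FormatError` for an unparseable date or non-numeric cell
    (naming the offending row) and :class:`IntegrityError` for duplicates.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if date_column not in raw.columns:
        raise SchemaError(f"no column named {date_column!r} in {path}")
    dates = pd.to_datetime(raw[date_column], format="ISO8601", errors="coerce")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna())[0])
        raise FormatError(
            f"unparseable date {raw[date_column].iloc[row]!r} at data row {row}"
        )
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise IntegrityError(f"duplicate date {dup.date()} in {path}")

    value_cols = [c for c in raw.columns if c != date_column]
    cells = raw[value_cols].to_numpy(dtype=object)
    missing = cells == missing_token
    numeric = pd.DataFrame(np.where(missing, np.nan, cells)).apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna().to_numpy() & ~missing
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-numeric cell {cells[i, j]!r} in column {value_cols[j]!r} "
            f"at data row {i} (missing token is {missing_token!r})"
        )
    order = np.argsort(dates.to_numpy(), kind="stable")
    return kind(
        dates=pd.DatetimeIndex(dates.to_numpy()[order]),
        values=numeric.to_numpy(dtype=float)[order],
        columns=value_cols,
        units=list(units) if units is not None else None,
    )


def write_pollutant_csv(
    matrix: _DatedMatrix, path, date_column: str = "date", missing_token: str = "NA"
) -> None:
    """Write a dated matrix as CSV with ISO-8601 dates."""
    frame = matrix.to_frame().copy()
    frame.insert(0, date_column, matrix.dates.strftime("%Y-%m-%d"))
    frame.to_csv(path, index=False, na_rep=missing_token)


def complete_case_filter(Z: PollutantMatrix) -> PollutantMatrix:
    """Keep only days with complete observations for all pollutants.

    This is the training-set construction step: unsupervised training uses
    fully observed days, while incomplete days can still be projected onto
    the trained map through masked distances.
    """
    keep = Z.row_mask_complete()
    removed = int((~keep).sum())
    if not keep.any():
        raise IntegrityError("no complete cases: every row has a missing entry")
    logger.info("complete-case filter removed %d of %d days", removed, Z.n)
    return type(Z)(
        dates=Z.dates[keep], values=Z.values[keep], columns=Z.columns, units=Z.units
    )


def standardize(Z: PollutantMatrix) -> tuple[PollutantMatrix, StandardizationParams]:
    """Center and scale each column to mean 0 and sample sd 1.

    Standardizing removes absolute magnitude differences between pollutant
    metrics measured in different units while retaining the ratios between
    their amplitudes. The fitted parameters are returned so new days can be
    projected onto the same scale later.
    """
    if np.isnan(Z.values).any():
        raise IntegrityError("standardize requires a complete-case matrix")
    means = Z.values.mean(axis=0)
    sds = Z.values.std(axis=0, ddof=1)
    if np.any(sds == 0):
        j = int(np.flatnonzero(sds == 0)[0])
        raise IntegrityError(f"column {Z.columns[j]!r} is constant")
    params = StandardizationParams(means=means, sds=sds, columns=Z.columns)
    return apply_standardization(Z, params), params


def apply_standardization(
    Z: _DatedMatrix, params: StandardizationParams
) -> PollutantMatrix:
    """Apply previously fitted (value - mean) / sd per column.

    Missing entries stay missing. The column names and order must match the
    parameters' fit, otherwise a :class:`SchemaError` is raised.
    """
    if params.columns and tuple(Z.columns) != params.columns:
        raise SchemaError(
            f"columns {Z.columns} do not match standardization fit {list(params.columns)}"
        )
    if Z.p != params.p:
        raise SchemaError(f"matrix has {Z.p} columns, parameters were fit on {params.p}")
    return type(Z)(
        dates=Z.dates,
        values=(Z.values - params.means) / params.sds,
        columns=Z.columns,
        units=Z.units,
    )
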