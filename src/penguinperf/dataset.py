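"""Typed I/O for the four input tables and the package's result tables.

All interchange is comma-separated UTF-8 text with a "." decimal point, one
table per file.  Each input table has a fixed schema (exact header) and a
set of row-level invariants; violations are collected and reported together
rather than failing on the first bad row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASONS = ("summer", "winter")
STRATA = ("Bransfield", "Drake")
CLIMATE_INDICES = ("ONI", "SAM")

#: sanity window for acoustic biomass estimates (tonnes)
BIOMASS_WINDOW_T = (1e3, 1e8)

#: exact column order for every known table
SCHEMAS: dict[str, list[str]] = {
    "performance": ["site", "species", "parameter", "season", "year", "value"],
    "survey": ["stratum", "season", "year", "biomass_t"],
    "catch": ["stratum", "season", "year", "catch_t"],
    "climate": ["index", "year", "month", "value"],
}

_DTYPES: dict[str, dict[str, type]] = {
    "performance": {"year": int, "value": float},
    "survey": {"year": int, "biomass_t": float},
    "catch": {"year": int, "catch_t": float},
    "climate": {"year": int, "month": int, "value": float},
}


class SchemaError(ValueError):
    """Header does not match the declared schema."""


class TableValidationError(ValueError):
    """One or more rows violate a table invariant.

    Attributes
    ----------
    errors : list of (row_number, message)
        Row numbers are 1-based data-row indices (header excluded).
    """

    def __init__(self, table: str, errors: list[tuple[int, str]]):
        self.table = table
        self.errors = errors
        lines = "; ".join(f"row {i}: {msg}" for i, msg in errors[:20])
        more = "" if len(errors) <= 20 else f" (+{len(errors) - 20} more)"
        super().__init__(f"{table} table: {len(errors)} invalid row(s): {lines}{more}")


class _Row:
    def __init__(self, d: dict):
        self.__dict__.update(d)


@dataclass
class ValidationReport:
    """Outcome of validating one table, including non-fatal flags."""

    table: str
    n_rows: int
    errors: list[tuple[int, str]] = field(default_factory=list)
    flags: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_rows(df: pd.DataFrame, schema: str, year_range: tuple[int, int] | None) -> ValidationReport:
    rep = ValidationReport(schema, len(df))
    err = rep.errors.append
    # dict rows: a column named "index" (climate) would collide with the
    # namedtuple method of itertuples
    for i, row in enumerate(df.to_dict("records"), start=1):
        row = _Row(row)
        if schema == "performance":
            if row.season not in SEASONS:
                err((i, f"season {row.season!r} not in {SEASONS}"))
            if not np.isfinite(row.value):
                err((i, f"non-finite value {row.value!r}"))
            if year_range and not (year_range[0] <= row.year <= year_range[1]):
                err((i, f"year {row.year} outside study range {year_range}"))
        elif schema == "survey":
            if row.stratum not in STRATA:
                err((i, f"stratum {row.stratum!r} not in {STRATA}"))
            if row.season not in SEASONS:
                err((i, f"season {row.season!r} not in {SEASONS}"))
            if not (BIOMASS_WINDOW_T[0] <= row.biomass_t <= BIOMASS_WINDOW_T[1]):
                err((i, f"biomass_t {row.biomass_t!r} outside sanity window {BIOMASS_WINDOW_T}"))
        elif schema == "catch":
            if row.stratum not in STRATA:
                err((i, f"stratum {row.stratum!r} not in {STRATA}"))
            if row.season not in SEASONS:
                err((i, f"season {row.season!r} not in {SEASONS}"))
            if not (np.isfinite(row.catch_t) and row.catch_t >= 0):
                err((i, f"catch_t {row.catch_t!r} must be finite and >= 0"))
        elif schema == "climate":
            if row.index not in CLIMATE_INDICES:
                err((i, f"index {row.index!r} not in {CLIMATE_INDICES}"))
            if not (1 <= row.month <= 12):
                err((i, f"month {row.month} outside 1..12"))
            if not np.isfinite(row.value):
                err((i, f"non-finite value {row.value!r}"))
    # table-level duplicate checks
    if schema == "climate":
        dup = df.duplicated(subset=["index", "year", "month"])
        for i in np.flatnonzero(dup.to_numpy()):
            rep.errors.append((int(i) + 1, "duplicate (index, year, month)"))
    if schema == "survey":
        # duplicates within a season are legal: they are averaged downstream
        dup = df.duplicated(subset=["stratum", "season", "year"], keep=False)
        for i in np.flatnonzero(dup.to_numpy()):
            rep.flags.append((int(i) + 1, "multiple surveys in one season; will be averaged"))
    return rep


def read_table(
    path: str | os.PathLike,
    schema: str,
    year_range: tuple[int, int] | None = None,
    return_report: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, ValidationReport]:
    """Read and validate one of the known tables.

    Parameters
    ----------
    path
        CSV file whose header must match ``SCHEMAS[schema]`` exactly
        (order-insensitive, no missing columns).
    schema
        One of ``"performance"``, ``"survey"``, ``"catch"``, ``"climate"``.
    year_range
        Optional (first, last) study years; performance rows outside the
        range are invalid.
    return_report
        Also return the :class:`ValidationReport` (for access to non-fatal
        flags such as within-season duplicate surveys).

    Raises
    ------
    SchemaError
        Missing or unknown columns, naming the offending column.
    TableValidationError
        Any row violating an invariant, with 1-based row numbers.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table {path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        raise SchemaError(f"{schema} table {path}: unexpected column(s) {extra}")
    df = df[cols]
    # parse numeric cells, reporting line numbers for unparseable ones
    parse_errors: list[tuple[int, str]] = []
    for col, typ in _DTYPES[schema].items():
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        bad |= df[col] == ""
        for i in np.flatnonzero(bad.to_numpy()):
            parse_errors.append((int(i) + 1, f"cannot parse {col}={df[col].iloc[i]!r}"))
        if typ is int and not bad.any():
            frac = converted % 1 != 0
            for i in np.flatnonzero(frac.to_numpy()):
                parse_errors.append((int(i) + 1, f"{col}={df[col].iloc[i]!r} is not an integer"))
            if not frac.any():
                converted = converted.astype(int)
        df[col] = converted
    if parse_errors:
        raise TableValidationError(schema, parse_errors)
    rep = _check_rows(df, schema, year_range)
    if not rep.ok:
        raise TableValidationError(schema, rep.errors)
    df = df.reset_index(drop=True)
    return (df, rep) if return_report else df


def write_results(records: pd.DataFrame, path: str | os.PathLike, schema: str | None = None) -> None:
    """Write a result table as CSV with a stable column order.

    ``read_table(write_results(df))`` is the identity on typed content:
    labels and integers round-trip exactly, reals to full double precision.
    """
    if len(records) == 0:
        raise ValueError("refusing to write an empty result table")
    df = records
    if schema is not None:
        df = df[SCHEMAS[schema]]
    df.to_csv(path, index=False, float_format="%.17g")
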