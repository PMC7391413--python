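"""Reading and preparing record-level clinical tables.

The entry point for an analysis is a CSV file with one row per clinical
record or event: one column holds the reference date of the record and the
remaining columns hold the analysis variables (diagnostic codes, ages,
lab values, ...).  Dates are parsed against a single explicit
``strftime``-style pattern -- no guessing -- and rows whose date does not
parse are dropped and counted.  Each analysis column receives exactly one
*treatment* that decides how its distribution is estimated later:

``categorical``
    text labels (codes); the support is the set of observed labels.
``numeric-integer``
    integers; one support cell per integer unless the span is too wide.
``numeric-continuous``
    real values; equal-width binning.
``date-as-numeric``
    calendar dates analysed as numbers (days since 1970-01-01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("categorical", "numeric-integer", "numeric-continuous", "date-as-numeric")

_EPOCH = pd.Timestamp("1970-01-01")


@dataclass
class CodeMapping:
    """A user-supplied source->target code remapping (e.g. ICD-9-CM to PheWAS).

    Many-to-one entries are allowed (that is what makes it a grouping);
    duplicate *source* codes are not.  ``unmapped_policy`` controls what
    happens to values absent from the mapping: keep them verbatim
    (``"keep-original"``), drop the rows (``"drop"``), or replace the value
    with :attr:`tag_label` (``"tag"``).
    """

    entries: dict[str, str]
    unmapped_policy: str = "keep-original"
    tag_label: str = "UNMAPPED"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("code mapping is empty")
        if self.unmapped_policy not in ("keep-original", "drop", "tag"):
            raise ValueError(f"unknown unmapped_policy {self.unmapped_policy!r}")
        for src, tgt in self.entries.items():
            if tgt == "" or tgt is None:
                raise ValueError(f"empty target code for source {src!r}")

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CodeMapping":
        """Load a two-column (source,target) CSV with a header row."""
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 2:
            raise ValueError("mapping CSV needs two columns (source,target)")
        src = df.iloc[:, 0].str.strip()
        tgt = df.iloc[:, 1].str.strip()
        if src.duplicated().any():
            dups = sorted(src[src.duplicated()].unique())
            raise ValueError(f"duplicate source codes in mapping: {dups}")
        return cls(entries=dict(zip(src, tgt)), **kwargs)


@dataclass
class RawClinicalTable:
    """Record-level rows with one parsed reference-date column.

    ``data`` keeps the reference date as ``datetime64`` and every analysis
    column in its treatment's natural dtype (object for categorical, float
    for numeric).  ``dropped_count`` records rows lost so far (date-parse
    failures plus any filtering), so the row-accounting invariant
    ``len(data) + dropped_count == input rows`` holds across operations.
    """

    data: pd.DataFrame
    date_column: str
    variables: dict[str, str]  # column -> treatment
    dropped_count: int = 0
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col, treatment in self.variables.items():
            if treatment not in TREATMENTS:
                raise ValueError(f"unknown treatment {treatment!r} for column {col!r}")
            if col not in self.data.columns:
                raise ValueError(f"variable column {col!r} not in table")
        if self.date_column not in self.data.columns:
            raise ValueError(f"date column {self.date_column!r} not in table")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def dates(self) -> pd.Series:
        return self.data[self.date_column]


def _infer_treatment(series: pd.Series) -> tuple[str, pd.Series]:
    """Infer a treatment from content: all-numeric -> numeric (integer if all
    values are integral), anything else categorical."""
    stripped = series.astype("string").str.strip()
    non_missing = stripped.dropna()
    numeric = pd.to_numeric(stripped, errors="coerce")
    if len(non_missing) > 0 and numeric.notna().sum() == len(non_missing):
        values = numeric.astype(float)
        finite = values.dropna()
        if len(finite) and (finite == np.floor(finite)).all():
            return "numeric-integer", values
        return "numeric-continuous", values
    return "categorical", stripped.astype(object)


def _coerce(series: pd.Series, treatment: str, date_format: str | None = None) -> pd.Series:
    if treatment == "categorical":
        return series.astype("string").str.strip().astype(object)
    if treatment in ("numeric-integer", "numeric-continuous"):
        return pd.to_numeric(series, errors="coerce").astype(float)
    if treatment == "date-as-numeric":
        parsed = pd.to_datetime(series, format=date_format, errors="coerce")
        return (parsed - _EPOCH).dt.days.astype(float)
    raise ValueError(f"unknown treatment {treatment!r}")


def read_table(
    path: str | Path,
    date_column: str,
    date_format: str = "%Y-%m-%d",
    treatments: dict[str, str] | None = None,
) -> RawClinicalTable:
    """Read a record-level CSV and parse its reference-date column.

    Parameters
    ----------
    path
        CSV file: comma-separated, UTF-8, double-quote quoting, header row
        mandatory.
    date_column
        Name of the reference-date column.
    date_format
        ``strftime``-style pattern applied to every date.  Time-of-day, if
        the pattern parses one, is truncated to the calendar date.
    treatments
        Optional explicit ``column -> treatment`` overrides; columns not
        listed are inferred from content.

    Returns
    -------
    RawClinicalTable
        Rows with unparseable dates are dropped and counted in
        ``dropped_count``; the load report records the drop count and the
        treatment of every analysis column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    if date_column not in df.columns:
        raise ValueError(
            f"date column {date_column!r} not found; columns are {list(df.columns)}"
        )
    n_input = len(df)
    parsed = pd.to_datetime(df[date_column], format=date_format, errors="coerce")
    keep = parsed.notna()
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"no rows survived date parsing with format {date_format!r} "
            f"on column {date_column!r}"
        )
    df = df.loc[keep].reset_index(drop=True)
    df[date_column] = parsed.loc[keep].dt.normalize().reset_index(drop=True)

    variables: dict[str, str] = {}
    for col in df.columns:
        if col == date_column:
            continue
        if treatments and col in treatments:
            treatment = treatments[col]
            if treatment not in TREATMENTS:
                raise ValueError(f"unknown treatment {treatment!r} for column {col!r}")
            df[col] = _coerce(df[col], treatment, date_format)
        else:
            treatment, coerced = _infer_treatment(df[col])
            df[col] = coerced
        variables[col] = treatment

    report = {
        "input_rows": n_input,
        "dropped_unparseable_dates": dropped,
        "retained_rows": int(keep.sum()),
        "treatments": dict(variables),
    }
    logger.info(
        "read %s: %d rows in, %d dropped (unparseable dates), %d retained",
        path, n_input, dropped, keep.sum(),
    )
    return RawClinicalTable(
        data=df, date_column=date_column, variables=variables,
        dropped_count=dropped, report=report,
    )


def map_codes(table: RawClinicalTable, column: str, mapping: CodeMapping) -> RawClinicalTable:
    """Remap a categorical column through a user-supplied code mapping.

    Many-to-one mappings group codes (e.g. 780.x diagnostic codes into one
    phenotype).  Unmapped values follow ``mapping.unmapped_policy``.
    """
    if column not in table.variables:
        raise ValueError(f"column {column!r} is not an analysis variable")
    if table.variables[column] != "categorical":
        raise ValueError(f"column {column!r} is not categorical")

    df = table.data.copy()
    values = df[column]
    mapped = values.map(mapping.entries)
    unmapped_mask = mapped.isna() & values.notna()
    n_unmapped = int(unmapped_mask.sum())
    dropped = 0
    if mapping.unmapped_policy == "keep-original":
        mapped = mapped.where(~unmapped_mask, values)
    elif mapping.unmapped_policy == "tag":
        mapped = mapped.where(~unmapped_mask, mapping.tag_label)
    else:  # drop
        df = df.loc[~unmapped_mask].reset_index(drop=True)
        mapped = mapped.loc[~unmapped_mask].reset_index(drop=True)
        dropped = n_unmapped
    df[column] = mapped.astype(object)
    report = dict(table.report)
    report["map_codes"] = {
        "column": column, "unmapped_values": n_unmapped,
        "policy": mapping.unmapped_policy, "dropped_rows": dropped,
    }
    return RawClinicalTable(
        data=df, date_column=table.date_column, variables=dict(table.variables),
        dropped_count=table.dropped_count + dropped, report=report,
    )


def filter_values(table: RawClinicalTable, column: str, exclude: set) -> RawClinicalTable:
    """Remove rows whose ``column`` value is in ``exclude``.

    Used e.g. to drop residual "other symptoms"/"other tests" codes before
    re-estimating distributions.  An empty exclusion set is the identity.
    """
    if column not in table.data.columns:
        raise ValueError(f"column {column!r} not in table")
    if not exclude:
        return table
    mask = table.data[column].isin(exclude)
    removed = int(mask.sum())
    df = table.data.loc[~mask].reset_index(drop=True)
    if len(df) == 0:
        logger.warning("filter_values removed every row of the table")
    report = dict(table.report)
    report.setdefault("filter_values", []).append(
        {"column": column, "removed_rows": removed}
    )
    return RawClinicalTable(
        data=df, date_column=table.date_column, variables=dict(table.variables),
        dropped_count=table.dropped_count + removed, report=report,
    )
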