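"""Data temporal maps: per-batch distributions of one variable over time.

Records are grouped into calendar *batches* (weeks, months or years) by
their reference date, and within each batch the distribution of one
analysis variable is estimated over a *support* that is shared by every
batch -- the sorted observed labels for categorical variables, or a fixed
equal-width bin grid for numerical ones.  The result, a
:class:`DataTemporalMap`, holds an absolute-count matrix and a
relative-frequency matrix (batches x support cells); it is the object
behind the data temporal heat maps and the input to the IGT embedding.

Calendar periods inside the observed range that contain no records are
either kept as flagged missing rows (policy ``"zeros"``, the default, so
that batch spacing reflects real time) or omitted (policy ``"exclude"``).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import RawClinicalTable

logger = logging.getLogger(__name__)

GRANULARITIES = ("week", "month", "year")
PROB_TOL = 1e-9


@dataclass
class Support:
    """The shared domain over which every batch distribution is estimated.

    For ``kind="categorical"`` ``values`` is the ordered list of labels.
    For ``kind="numerical"`` ``values`` is the ordered list of bin
    representative points (centres); ``edges`` are the ``n_bins+1``
    contiguous equal-width bin edges.
    """

    kind: str  # "categorical" | "numerical"
    values: list
    n_bins: int | None = None
    edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numerical"):
            raise ValueError(f"unknown support kind {self.kind!r}")
        if len(self.values) != len(set(map(str, self.values))):
            raise ValueError("support values must be unique")
        if self.kind == "numerical":
            v = np.asarray(self.values, dtype=float)
            if len(v) > 1 and not (np.diff(v) > 0).all():
                raise ValueError("numerical support values must be increasing")
            if self.edges is not None:
                self.edges = np.asarray(self.edges, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Support):
            return NotImplemented
        if self.kind != other.kind or self.n_bins != other.n_bins:
            return False
        if self.kind == "categorical":
            return list(self.values) == list(other.values)
        same_vals = np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        if self.edges is None or other.edges is None:
            return same_vals and (self.edges is None) == (other.edges is None)
        return same_vals and np.allclose(self.edges, other.edges, rtol=0, atol=1e-12)

    @property
    def bin_width(self) -> float:
        if self.kind != "numerical" or self.edges is None or len(self.edges) < 2:
            raise ValueError("bin_width is defined for binned numerical supports only")
        return float(self.edges[1] - self.edges[0])


def period_start(date: dt.date, granularity: str) -> dt.date:
    """Map a calendar date to the start date of its containing period.

    Weeks are ISO-8601 (Monday start) and identified by the Monday date;
    months by the first of the month; years by January 1st.
    """
    if isinstance(date, (pd.Timestamp, dt.datetime)):
        date = date.date()
    if granularity == "week":
        return date - dt.timedelta(days=date.weekday())
    if granularity == "month":
        return date.replace(day=1)
    if granularity == "year":
        return date.replace(month=1, day=1)
    raise ValueError(f"unknown granularity {granularity!r}")


def assign_batches(dates, granularity: str) -> list[dt.date]:
    """Map each date to its containing period, identified by period start."""
    if granularity not in GRANULARITIES:
        raise ValueError(f"unknown granularity {granularity!r}")
    return [period_start(d, granularity) for d in dates]


def next_period(start: dt.date, granularity: str) -> dt.date:
    if granularity == "week":
        return start + dt.timedelta(days=7)
    if granularity == "month":
        y, m = divmod(start.month, 12)
        return dt.date(start.year + y, m + 1, 1)
    if granularity == "year":
        return dt.date(start.year + 1, 1, 1)
    raise ValueError(f"unknown granularity {granularity!r}")


def period_range(first: dt.date, last: dt.date, granularity: str) -> list[dt.date]:
    """All period-start dates from ``first`` through ``last`` inclusive."""
    first = period_start(first, granularity)
    last = period_start(last, granularity)
    out = [first]
    while out[-1] < last:
        out.append(next_period(out[-1], granularity))
    return out


def estimate_support(values, treatment: str, n_bins: int | None = None) -> Support:
    """Auto-calculate a support from observed values.

    Categorical variables get the sorted unique labels.  Continuous ones
    get ``n_bins`` (default 100) equal-width bins over [min, max].
    Integer variables get one cell per integer in [min, max] unless the
    span exceeds ``n_bins``, in which case equal-width binning is used.
    """
    if treatment == "categorical":
        series = pd.Series(values, dtype=object).dropna()
        if len(series) == 0:
            raise ValueError("all values missing; cannot estimate support")
        return Support(kind="categorical", values=sorted(map(str, series.unique())))

    arr = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    if len(arr) == 0:
        raise ValueError("all values missing; cannot estimate support")
    lo, hi = float(arr.min()), float(arr.max())
    n_bins = 100 if n_bins is None else int(n_bins)
    if n_bins < 1:
        raise ValueError("n_bins must be positive")

    if treatment == "numeric-integer" and (hi - lo) < n_bins:
        ints = np.arange(int(np.floor(lo)), int(np.floor(hi)) + 1, dtype=float)
        edges = np.concatenate([ints - 0.5, [ints[-1] + 0.5]])
        return Support(kind="numerical", values=list(ints), n_bins=len(ints), edges=edges)

    if hi == lo:
        logger.warning("zero range for numerical variable; single-cell support")
        return Support(kind="numerical", values=[lo], n_bins=1,
                       edges=np.array([lo - 0.5, lo + 0.5]))
    edges = np.linspace(lo, hi, n_bins + 1)
    centres = (edges[:-1] + edges[1:]) / 2
    return Support(kind="numerical", values=list(centres), n_bins=n_bins, edges=edges)


@dataclass
class DataTemporalMap:
    """Per-batch count and relative-frequency matrices over a fixed support.

    ``counts`` row sums equal the number of records assigned to that batch
    (before any smoothing).  Each row of ``probabilities`` sums to 1 unless
    the batch is flagged missing, in which case the row is NaN.
    """

    variable: str
    treatment: str
    granularity: str
    batch_dates: list[dt.date]
    support: Support
    counts: np.ndarray
    probabilities: np.ndarray
    missing_batches: list[dt.date] = field(default_factory=list)
    missing_policy: str = "zeros"
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        n, k = self.counts.shape
        if self.probabilities.shape != (n, k):
            raise ValueError("counts and probabilities shapes differ")
        if len(self.batch_dates) != n:
            raise ValueError("batch_dates length mismatch")
        if len(self.support) != k:
            raise ValueError("support length mismatch")
        if any(b >= a for a, b in zip(self.batch_dates[1:], self.batch_dates)):
            raise ValueError("batch_dates must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        missing = set(self.missing_batches)
        for i, d in enumerate(self.batch_dates):
            row = self.probabilities[i]
            if d in missing:
                continue
            if np.isnan(row).any() or (row < 0).any():
                raise ValueError(f"invalid probability row for batch {d}")

    @property
    def n_batches(self) -> int:
        return len(self.batch_dates)

    def missing_mask(self) -> np.ndarray:
        missing = set(self.missing_batches)
        return np.array([d in missing for d in self.batch_dates], dtype=bool)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DataTemporalMap):
            return NotImplemented
        return (
            self.variable == other.variable
            and self.treatment == other.treatment
            and self.granularity == other.granularity
            and self.batch_dates == other.batch_dates
            and self.support == other.support
            and np.array_equal(self.counts, other.counts)
            and np.allclose(self.probabilities, other.probabilities,
                            rtol=0, atol=1e-12, equal_nan=True)
            and self.missing_batches == other.missing_batches
        )


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    scale = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    return 0.9 * scale * n ** (-1 / 5)


def smooth_numerical_distribution(
    values, support: Support, bandwidth: float | None = None
) -> np.ndarray:
    """Gaussian-kernel density over the support grid, renormalised to sum 1.

    The density is evaluated at each bin representative point and
    renormalised, so the result is a probability mass vector on the same
    cells as the unsmoothed histogram.  The default bandwidth follows
    Silverman's rule on the batch's values, floored at one bin width when
    the rule degenerates to 0 (e.g. a single repeated value).
    """
    if support.kind != "numerical":
        raise ValueError("smoothing requires a numerical support")
    values = np.asarray(pd.Series(values, dtype=float).dropna(), dtype=float)
    if len(values) == 0:
        raise ValueError("no values to smooth")
    grid = np.asarray(support.values, dtype=float)
    if bandwidth is None:
        bandwidth = silverman_bandwidth(values)
        if bandwidth <= 0:
            bandwidth = support.bin_width if len(grid) > 1 else 1.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1)
    total = density.sum()
    if total == 0:  # all mass far off-grid; fall back to nearest-cell histogram
        idx = np.clip(np.searchsorted(grid, values), 0, len(grid) - 1)
        density = np.bincount(idx, minlength=len(grid)).astype(float)
        total = density.sum()
    return density / total


def _bin_numeric(values: np.ndarray, support: Support) -> np.ndarray:
    """Counts of values per support cell; values outside the edge range are
    clipped into the end bins (the support covers the observed range by
    construction, so clipping only matters for user-supplied supports)."""
    edges = support.edges
    idx = np.digitize(values, edges[1:-1], right=False)
    return np.bincount(idx, minlength=len(support)).astype(float)


def estimate_data_temporal_map(
    table: RawClinicalTable,
    variable: str,
    granularity: str = "month",
    support: Support | None = None,
    smooth: bool = False,
    missing_policy: str = "zeros",
    n_bins: int | None = None,
) -> DataTemporalMap:
    """Batch the table by ``granularity`` and estimate one distribution per
    batch for ``variable``.

    Rows with a missing value in ``variable`` are excluded (and counted in
    the log).  ``support`` defaults to auto-calculation over the whole date
    range so every batch shares one support.  With ``smooth=True`` the
    probability rows of numerical variables are kernel-density estimates on
    the bin grid instead of raw relative frequencies; counts are always the
    raw histogram.
    """
    if granularity not in GRANULARITIES:
        raise ValueError(f"unknown granularity {granularity!r}")
    if missing_policy not in ("zeros", "exclude"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if variable not in table.variables:
        raise ValueError(f"variable {variable!r} not in table")
    treatment = table.variables[variable]

    values = table.data[variable]
    dates = table.data[table.date_column]
    keep = values.notna()
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d rows with missing %r", n_excluded, variable)
    values, dates = values[keep], dates[keep]
    if len(values) == 0:
        raise ValueError(f"no rows left for variable {variable!r} after exclusions")

    if support is None:
        support = estimate_support(values, treatment, n_bins=n_bins)

    periods = assign_batches(dates, granularity)
    lattice = period_range(min(periods), max(periods), granularity)
    by_period: dict[dt.date, list] = {}
    for p, v in zip(periods, values):
        by_period.setdefault(p, []).append(v)

    if support.kind == "categorical":
        known = {v: i for i, v in enumerate(support.values)}
        observed = set(map(str, pd.unique(values)))
        unknown = observed - set(support.values)
        if unknown:
            raise ValueError(
                f"support is missing observed value(s): {sorted(unknown)}"
            )

    rows_counts, rows_probs, batch_dates, missing = [], [], [], []
    for p in lattice:
        vals = by_period.get(p)
        if not vals:
            missing.append(p)
            if missing_policy == "exclude":
                continue
            rows_counts.append(np.zeros(len(support)))
            rows_probs.append(np.full(len(support), np.nan))
            batch_dates.append(p)
            continue
        if support.kind == "categorical":
            cnt = np.zeros(len(support))
            for v in vals:
                cnt[known[str(v)]] += 1
        else:
            cnt = _bin_numeric(np.asarray(vals, dtype=float), support)
        if smooth and support.kind == "numerical":
            prob = smooth_numerical_distribution(vals, support)
        else:
            prob = cnt / cnt.sum()
        rows_counts.append(cnt)
        rows_probs.append(prob)
        batch_dates.append(p)

    return DataTemporalMap(
        variable=variable,
        treatment=treatment,
        granularity=granularity,
        batch_dates=batch_dates,
        support=support,
        counts=np.vstack(rows_counts),
        probabilities=np.vstack(rows_probs),
        missing_batches=missing,
        missing_policy=missing_policy,
        smoothed=bool(smooth and support.kind == "numerical"),
    )


def trim_dtm(
    dtm: DataTemporalMap,
    start_date: dt.date | None = None,
    end_date: dt.date | None = None,
    keep_values=None,
    renormalize: bool = False,
) -> DataTemporalMap:
    """Restrict a DTM to a date window and/or a subset of support values.

    With ``renormalize=True`` probabilities are re-derived from the trimmed
    counts so each row sums to 1 again; otherwise the original rows are
    carried over as-is (and may then sum to less than 1).
    """
    row_mask = np.ones(dtm.n_batches, dtype=bool)
    if start_date is not None:
        row_mask &= np.array([d >= start_date for d in dtm.batch_dates])
    if end_date is not None:
        row_mask &= np.array([d <= end_date for d in dtm.batch_dates])
    if not row_mask.any():
        raise ValueError("trim removed every batch")

    support = dtm.support
    col_idx = np.arange(len(support))
    if keep_values is not None:
        keep_values = list(keep_values)
        unknown = [v for v in keep_values if v not in support.values]
        if unknown:
            raise ValueError(f"keep_values not in support: {unknown}")
        keep_set = set(keep_values)
        col_idx = np.array([i for i, v in enumerate(support.values) if v in keep_set])
        if len(col_idx) == 0:
            raise ValueError("trim removed every support value")
        new_values = [support.values[i] for i in col_idx]
        if support.kind == "categorical":
            support = Support(kind="categorical", values=new_values)
        else:
            support = Support(kind="numerical", values=new_values,
                              n_bins=len(new_values), edges=None)

    batch_dates = [d for d, m in zip(dtm.batch_dates, row_mask) if m]
    counts = dtm.counts[np.ix_(row_mask, col_idx)]
    probs = dtm.probabilities[np.ix_(row_mask, col_idx)]
    missing = [d for d in dtm.missing_batches if d in set(batch_dates)]
    if renormalize:
        sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(sums > 0, counts / np.where(sums == 0, 1, sums), np.nan)
    return DataTemporalMap(
        variable=dtm.variable, treatment=dtm.treatment, granularity=dtm.granularity,
        batch_dates=batch_dates, support=support, counts=counts, probabilities=probs,
        missing_batches=missing, missing_policy=dtm.missing_policy,
        smoothed=dtm.smoothed,
    )


# ---------------------------------------------------------------------------
# serialization: JSON header + CSV matrices


def save_dtm(dtm: DataTemporalMap, prefix: str | Path) -> list[Path]:
    """Write ``<prefix>.json`` (header), ``<prefix>.counts.csv`` and
    ``<prefix>.probabilities.csv``.  Counts round-trip bit-exactly;
    probabilities within 1e-12 (17 significant digits)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "variable": dtm.variable,
        "treatment": dtm.treatment,
        "granularity": dtm.granularity,
        "missing_batches": [d.isoformat() for d in dtm.missing_batches],
        "missing_policy": dtm.missing_policy,
        "smoothed": dtm.smoothed,
        "support": {
            "kind": dtm.support.kind,
            "values": [str(v) if dtm.support.kind == "categorical" else float(v)
                       for v in dtm.support.values],
            "n_bins": dtm.support.n_bins,
            "edges": None if dtm.support.edges is None
                     else [float(e) for e in dtm.support.edges],
        },
    }
    json_path = Path(str(prefix) + ".json")
    json_path.write_text(json.dumps(header, indent=2))
    cols = [str(v) for v in dtm.support.values]
    index = [d.isoformat() for d in dtm.batch_dates]
    counts_path = Path(str(prefix) + ".counts.csv")
    probs_path = Path(str(prefix) + ".probabilities.csv")
    pd.DataFrame(dtm.counts, index=index, columns=cols).to_csv(
        counts_path, index_label="batch", float_format="%.17g")
    pd.DataFrame(dtm.probabilities, index=index, columns=cols).to_csv(
        probs_path, index_label="batch", float_format="%.17g")
    return [json_path, counts_path, probs_path]


def load_dtm(prefix: str | Path) -> DataTemporalMap:
    """Reload a DTM written by :func:`save_dtm`."""
    prefix = Path(prefix)
    header = json.loads(Path(str(prefix) + ".json").read_text())
    sup = header["support"]
    if sup["kind"] == "categorical":
        support = Support(kind="categorical", values=list(sup["values"]))
    else:
        support = Support(
            kind="numerical", values=[float(v) for v in sup["values"]],
            n_bins=sup["n_bins"],
            edges=None if sup["edges"] is None else np.asarray(sup["edges"]),
        )
    counts_df = pd.read_csv(Path(str(prefix) + ".counts.csv"), index_col="batch")
    probs_df = pd.read_csv(Path(str(prefix) + ".probabilities.csv"), index_col="batch")
    batch_dates = [dt.date.fromisoformat(d) for d in counts_df.index]
    return DataTemporalMap(
        variable=header["variable"],
        treatment=header["treatment"],
        granularity=header["granularity"],
        batch_dates=batch_dates,
        support=support,
        counts=counts_df.to_numpy(dtype=float),
        probabilities=probs_df.to_numpy(dtype=float),
        missing_batches=[dt.date.fromisoformat(d) for d in header["missing_batches"]],
        missing_policy=header["missing_policy"],
        smoothed=header["smoothed"],
    )
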