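"""Information-geometric temporal (IGT) embedding of time batches.

Each time batch of a :class:`~tempovar.dtm.DataTemporalMap` is treated as a
point on the statistical manifold of distributions over the variable's
support.  Pairwise dissimilarity between batches is the Jensen-Shannon
distance -- the square root of the base-2 Jensen-Shannon divergence, a
bounded [0, 1] metric -- and classical (Torgerson) multidimensional scaling
embeds the batches into a small number of coordinates ordered by variance
explained.  In the resulting IGT plot, trends appear as flowing sequences
of batches, abrupt changes as gaps, temporal subgroups as clusters and
seasonality as cycles.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .dtm import DataTemporalMap

logger = logging.getLogger(__name__)

#: single-letter month codes used in batch labels (Jan..Dec)
MONTH_LETTERS = ["J", "F", "M", "A", "m", "j", "x", "a", "S", "O", "N", "D"]

_NORM_TOL = 1e-6


def jsd(p, q) -> float:
    """Jensen-Shannon distance between two probability vectors.

    Computed as ``sqrt(JS divergence)`` with base-2 logarithms, so the
    result lies in [0, 1]: 0 for identical distributions, 1 for disjoint
    supports.  ``0 * log 0`` terms are treated as 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"{name} is not normalized (sum={v.sum():.6g})")
    m = 0.5 * (p + q)
    # KL(p||m) + KL(q||m) term-by-term, skipping zero-mass cells
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1) / np.where(m > 0, m, 1)), 0.0)
        t_q = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1) / np.where(m > 0, m, 1)), 0.0)
    div = 0.5 * (t_p.sum() + t_q.sum())
    return float(np.sqrt(max(div, 0.0)))


@dataclass
class DissimilarityMatrix:
    """Symmetric, zero-diagonal matrix of pairwise batch dissimilarities."""

    values: np.ndarray
    batch_dates: list[dt.date]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.batch_dates)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match batch_dates")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValueError("diagonal must be exactly zero")
        if (self.values < 0).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.batch_dates)

    def to_csv(self, path: str | Path) -> None:
        idx = [d.isoformat() for d in self.batch_dates]
        pd.DataFrame(self.values, index=idx, columns=idx).to_csv(
            path, index_label="batch", float_format="%.17g")


def _usable_rows(dtm: DataTemporalMap) -> tuple[np.ndarray, list[dt.date]]:
    mask = ~dtm.missing_mask()
    return dtm.probabilities[mask], [d for d, m in zip(dtm.batch_dates, mask) if m]


def dissimilarity_matrix(dtm: DataTemporalMap) -> DissimilarityMatrix:
    """Pairwise Jensen-Shannon distances between all usable batches.

    Batches flagged missing carry no distribution and are excluded; the
    surviving batch dates index the matrix.
    """
    probs, dates = _usable_rows(dtm)
    n = len(dates)
    if n < 2:
        raise ValueError("need at least 2 non-missing batches")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jsd(probs[i], probs[j])
    return DissimilarityMatrix(values=out, batch_dates=dates)


def consecutive_dissimilarity_series(
    dtm: DataTemporalMap,
) -> list[tuple[dt.date, float]]:
    """Jensen-Shannon distance between each batch and its predecessor.

    Entry ``i`` pairs the (i+1)-th usable batch's date with its distance to
    the i-th, so a spike at some date marks an abrupt distribution change
    entering that batch.
    """
    probs, dates = _usable_rows(dtm)
    if len(dates) < 2:
        raise ValueError("need at least 2 non-missing batches")
    return [
        (dates[i + 1], jsd(probs[i], probs[i + 1])) for i in range(len(dates) - 1)
    ]


def format_batch_label(period: dt.date | int, granularity: str) -> str:
    """Compact display label for a batch: ``yym`` for months (2-digit year
    plus a single month letter, Jan..Dec -> J F M A m j x a S O N D),
    ``yy`` for years, ``yym`` plus ISO week number for weeks."""
    if granularity == "year":
        year = period if isinstance(period, int) else period.year
        return f"{year % 100:02d}"
    if not isinstance(period, dt.date):
        raise ValueError("month/week periods must be dates")
    yy = f"{period.year % 100:02d}"
    if granularity == "month":
        return yy + MONTH_LETTERS[period.month - 1]
    if granularity == "week":
        iso = period.isocalendar()
        return f"{iso.year % 100:02d}{MONTH_LETTERS[period.month - 1]}w{iso.week:02d}"
    raise ValueError(f"unknown granularity {granularity!r}")


def season_index(period: dt.date, granularity: str) -> int:
    """Cyclic within-year position of a batch: month-of-year (1-12) for
    monthly batches, ISO week-of-year (1-53) for weekly ones.  Yearly
    batches have no within-year cycle."""
    if granularity == "month":
        return period.month
    if granularity == "week":
        return period.isocalendar().week
    if granularity == "year":
        raise ValueError("season index is not applicable at year granularity")
    raise ValueError(f"unknown granularity {granularity!r}")


@dataclass
class IGTProjection:
    """Low-dimensional batch coordinates plus labelling metadata.

    Columns of ``embedding`` are ordered by non-increasing variance
    explained and sign-normalised so that the first non-zero coordinate of
    each column is positive.  ``negative_eigenvalue_mass`` reports the
    magnitude of truncated negative eigenvalues (non-Euclidean part of the
    dissimilarities) as a diagnostic.
    """

    embedding: np.ndarray
    variance_explained: np.ndarray
    batch_dates: list[dt.date]
    granularity: str
    labels: list[str]
    season_indices: list[int] | None
    trajectory: np.ndarray | None = None
    negative_eigenvalue_mass: float = 0.0

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        n, d = self.embedding.shape
        if d < 1:
            raise ValueError("embedding needs at least one dimension")
        if len(self.batch_dates) != n or len(self.labels) != n:
            raise ValueError("batch metadata length mismatch")
        if (np.diff(self.variance_explained) > 1e-12).any():
            raise ValueError("variance_explained must be non-increasing")
        if self.trajectory is not None:
            self.trajectory = np.asarray(self.trajectory, dtype=float)
            if self.trajectory.shape != self.embedding.shape:
                raise ValueError("trajectory must have one point per batch")

    @property
    def n_batches(self) -> int:
        return self.embedding.shape[0]

    @property
    def n_dims(self) -> int:
        return self.embedding.shape[1]


def _orient_columns(coords: np.ndarray) -> np.ndarray:
    """Flip column signs so the first non-zero entry of each is positive."""
    coords = coords.copy()
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, j] = -col
    return coords


def classical_mds(
    dissimilarities: np.ndarray, dims: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Classical (Torgerson) MDS of a square dissimilarity matrix.

    Double-centres the squared dissimilarities, eigendecomposes, and keeps
    the top ``dims`` eigenvalues; negative eigenvalues are truncated to
    zero and their total magnitude returned as a diagnostic.

    Returns ``(coordinates, variance_explained, negative_mass)``.
    """
    D = np.asarray(dissimilarities, dtype=float)
    n = D.shape[0]
    if dims > n - 1:
        raise ValueError(f"dims={dims} exceeds usable batches - 1 = {n - 1}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    neg_mass = float(np.abs(eigvals[eigvals < 0]).sum())
    pos_sum = float(eigvals[eigvals > 0].sum())
    kept = np.clip(eigvals[:dims], 0.0, None)
    coords = eigvecs[:, :dims] * np.sqrt(kept)[None, :]
    if pos_sum == 0:
        logger.warning("degenerate all-zero dissimilarities; embedding at origin")
        var = np.zeros(dims)
    else:
        var = kept / pos_sum
    return _orient_columns(coords), var, neg_mass


def estimate_igt_projection(
    dtm: DataTemporalMap,
    dims: int = 3,
    with_trajectory: bool = False,
    smoothing_parameter: float | None = None,
) -> IGTProjection:
    """Embed the batches of a DTM into ``dims`` IGT coordinates.

    The axes (D1, D2, D3, ...) are the leading temporal components of
    variance of the batch distributions; inter-point distance approximates
    the Jensen-Shannon distance between batch distributions.
    """
    if dims < 2:
        raise ValueError("dims must be >= 2")
    dmat = dissimilarity_matrix(dtm)
    coords, var, neg_mass = classical_mds(dmat.values, dims)
    labels = [format_batch_label(d, dtm.granularity) for d in dmat.batch_dates]
    seasons = (
        None
        if dtm.granularity == "year"
        else [season_index(d, dtm.granularity) for d in dmat.batch_dates]
    )
    proj = IGTProjection(
        embedding=coords,
        variance_explained=var,
        batch_dates=dmat.batch_dates,
        granularity=dtm.granularity,
        labels=labels,
        season_indices=seasons,
        negative_eigenvalue_mass=neg_mass,
    )
    if with_trajectory:
        proj.trajectory = smooth_trajectory(proj, smoothing_parameter)
    return proj


def smooth_trajectory(
    projection: IGTProjection, smoothing_parameter: float | None = None
) -> np.ndarray:
    """Smoothed trajectory through the embedded batches.

    Fits, per embedding dimension, a cubic smoothing spline of coordinate
    against batch index and evaluates it at every batch index.  With
    ``smoothing_parameter=None`` the penalty is chosen by generalised
    cross-validation (needs at least 5 batches); an explicit non-negative
    penalty works from 4 batches up.
    """
    n = projection.n_batches
    min_n = 5 if smoothing_parameter is None else 4
    if n < min_n:
        raise ValueError(f"need at least {min_n} batches for trajectory smoothing")
    x = np.arange(n, dtype=float)
    out = np.empty_like(projection.embedding)
    for j in range(projection.n_dims):
        y = projection.embedding[:, j]
        if np.allclose(y, y[0], atol=1e-300):
            out[:, j] = y
            continue
        spl = make_smoothing_spline(x, y, lam=smoothing_parameter)
        out[:, j] = spl(x)
    return out


# ---------------------------------------------------------------------------
# serialization: coordinates CSV + JSON sidecar


def save_igt(projection: IGTProjection, prefix: str | Path) -> list[Path]:
    """Write ``<prefix>.csv`` (per-batch date, label, season index and
    coordinates) and ``<prefix>.json`` (variance explained, diagnostics)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    d = projection.n_dims
    df = pd.DataFrame(
        {
            "batch": [b.isoformat() for b in projection.batch_dates],
            "label": projection.labels,
            "season_index": (
                projection.season_indices
                if projection.season_indices is not None
                else [""] * projection.n_batches
            ),
        }
    )
    for j in range(d):
        df[f"D{j + 1}"] = projection.embedding[:, j]
    if projection.trajectory is not None:
        for j in range(d):
            df[f"trajectory_D{j + 1}"] = projection.trajectory[:, j]
    csv_path = Path(str(prefix) + ".csv")
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "granularity": projection.granularity,
        "dims": d,
        "variance_explained": [float(v) for v in projection.variance_explained],
        "negative_eigenvalue_mass": projection.negative_eigenvalue_mass,
        "has_trajectory": projection.trajectory is not None,
        "has_season_index": projection.season_indices is not None,
    }
    json_path = Path(str(prefix) + ".json")
    json_path.write_text(json.dumps(sidecar, indent=2))
    return [csv_path, json_path]


def load_igt(prefix: str | Path) -> IGTProjection:
    """Reload an IGT projection written by :func:`save_igt`."""
    prefix = Path(prefix)
    sidecar = json.loads(Path(str(prefix) + ".json").read_text())
    df = pd.read_csv(Path(str(prefix) + ".csv"), dtype={"label": str})
    d = sidecar["dims"]
    embedding = df[[f"D{j + 1}" for j in range(d)]].to_numpy(dtype=float)
    trajectory = None
    if sidecar["has_trajectory"]:
        trajectory = df[[f"trajectory_D{j + 1}" for j in range(d)]].to_numpy(dtype=float)
    seasons = None
    if sidecar["has_season_index"]:
        seasons = [int(s) for s in df["season_index"]]
    return IGTProjection(
        embedding=embedding,
        variance_explained=np.asarray(sidecar["variance_explained"]),
        batch_dates=[dt.date.fromisoformat(b) for b in df["batch"]],
        granularity=sidecar["granularity"],
        labels=list(df["label"]),
        season_indices=seasons,
        trajectory=trajectory,
        negative_eigenvalue_mass=sidecar["negative_eigenvalue_mass"],
    )
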