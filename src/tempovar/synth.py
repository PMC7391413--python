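"""Synthetic record-level datasets with known temporal structure.

Generates categorical clinical-code data over monthly (by default) batches
whose per-batch distributions carry injected effects from the four-way
temporal-variability taxonomy: gradual *trends*, *abrupt changes*,
*seasonality*, and *temporal subgroups*.  Every dataset comes with its
ground truth (the exact per-batch distributions and the injected
changepoints), so recovery of the injected structure by the DTM + IGT
pipeline can be asserted without any external data.

Effects compose in declared order on top of the baseline distribution:
a linear trend accumulates ``t * drift``; a seasonal effect adds
``amplitude * sin(2*pi*t/period)``; abrupt changes and subgroup blocks
*replace* the working distribution from their start batch (resp. within
their interval).  After composition the vector is clipped at zero and
renormalised.  Sampling uses numpy's PCG64 generator; the algorithm name
and seed are recorded in the ground-truth metadata so "same seed" stays
meaningful across releases.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dtm import next_period, period_start
from .ingest import RawClinicalTable

_PRNG_NAME = "numpy-PCG64"


@dataclass
class AbruptChange:
    """From batch ``at_batch`` (0-based) onwards the distribution becomes
    ``new_distribution`` (further effects still apply on top)."""

    at_batch: int
    new_distribution: list[float]


@dataclass
class LinearTrend:
    """Per-batch additive drift vector; batch t receives ``t * drift``."""

    drift: list[float]


@dataclass
class Seasonal:
    """Additive cyclic effect ``amplitude * sin(2*pi*t/period)``."""

    amplitude: list[float]
    period: int = 12


@dataclass
class SubgroupBlock:
    """Batches in ``[start_batch, end_batch)`` follow ``distribution``."""

    start_batch: int
    end_batch: int
    distribution: list[float]


Effect = AbruptChange | LinearTrend | Seasonal | SubgroupBlock


@dataclass
class SyntheticScenario:
    """Declarative description of a synthetic dataset.

    ``records_per_batch`` may be a single count or one count per batch
    (e.g. to emulate a step in absolute record volume alongside a
    distribution change).
    """

    categories: list[str]
    baseline: list[float]
    n_batches: int
    records_per_batch: int | list[int] = 500
    effects: list[Effect] = field(default_factory=list)
    granularity: str = "month"
    start_date: dt.date = dt.date(2010, 1, 1)
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        b = np.asarray(self.baseline, dtype=float)
        if len(b) != len(self.categories):
            raise ValueError("baseline length must match categories")
        if (b < 0).any() or abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("baseline must be a probability vector")
        for eff in self.effects:
            if isinstance(eff, AbruptChange) and not (0 <= eff.at_batch < self.n_batches):
                raise ValueError("at_batch out of range")

    def per_batch_counts(self) -> list[int]:
        if isinstance(self.records_per_batch, int):
            return [self.records_per_batch] * self.n_batches
        counts = list(self.records_per_batch)
        if len(counts) != self.n_batches:
            raise ValueError("records_per_batch list must have one entry per batch")
        return counts


@dataclass
class GroundTruth:
    """Exact per-batch distributions and the injected structure."""

    scenario: SyntheticScenario
    distributions: np.ndarray  # n_batches x n_categories
    changepoints: list[int]
    seasonal_period: int | None
    trend_direction: np.ndarray | None

    def __post_init__(self) -> None:
        self.distributions = np.asarray(self.distributions, dtype=float)
        if self.distributions.shape[0] != self.scenario.n_batches:
            raise ValueError("one distribution per batch required")

    def batch_dates(self) -> list[dt.date]:
        dates = [period_start(self.scenario.start_date, self.scenario.granularity)]
        for _ in range(self.scenario.n_batches - 1):
            dates.append(next_period(dates[-1], self.scenario.granularity))
        return dates

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.scenario.name,
            "prng": _PRNG_NAME,
            "seed": self.scenario.seed,
            "granularity": self.scenario.granularity,
            "categories": self.scenario.categories,
            "batch_dates": [d.isoformat() for d in self.batch_dates()],
            "records_per_batch": self.scenario.per_batch_counts(),
            "distributions": self.distributions.tolist(),
            "changepoints": self.changepoints,
            "seasonal_period": self.seasonal_period,
            "trend_direction": (
                None if self.trend_direction is None else self.trend_direction.tolist()
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _clip_renorm(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 0.0, None)
    total = v.sum()
    if total == 0:
        raise ValueError("effects produced an all-zero distribution")
    return v / total


def realize_distributions(scenario: SyntheticScenario) -> GroundTruth:
    """Compose the scenario's effects into one exact distribution per batch."""
    k = len(scenario.categories)
    dists = np.empty((scenario.n_batches, k))
    changepoints: list[int] = []
    seasonal_period: int | None = None
    trend: np.ndarray | None = None

    for eff in scenario.effects:
        if isinstance(eff, AbruptChange):
            changepoints.append(eff.at_batch)
        elif isinstance(eff, Seasonal):
            seasonal_period = eff.period
        elif isinstance(eff, LinearTrend):
            trend = np.asarray(eff.drift, dtype=float)

    for t in range(scenario.n_batches):
        base = np.asarray(scenario.baseline, dtype=float)
        for eff in scenario.effects:
            if isinstance(eff, AbruptChange):
                if t >= eff.at_batch:
                    base = np.asarray(eff.new_distribution, dtype=float)
            elif isinstance(eff, SubgroupBlock):
                if eff.start_batch <= t < eff.end_batch:
                    base = np.asarray(eff.distribution, dtype=float)
            elif isinstance(eff, LinearTrend):
                base = base + t * np.asarray(eff.drift, dtype=float)
            elif isinstance(eff, Seasonal):
                amp = np.asarray(eff.amplitude, dtype=float)
                base = base + amp * np.sin(2 * np.pi * t / eff.period)
            else:  # pragma: no cover
                raise TypeError(f"unknown effect {type(eff).__name__}")
        dists[t] = _clip_renorm(base)

    return GroundTruth(
        scenario=scenario,
        distributions=dists,
        changepoints=sorted(changepoints),
        seasonal_period=seasonal_period,
        trend_direction=trend,
    )


def sample_records(
    truth: GroundTruth,
    records_per_batch: int | list[int] | None = None,
    seed: int | None = None,
    category_column: str = "code",
) -> RawClinicalTable:
    """Draw record-level rows from the ground-truth batch distributions.

    For each batch, ``records_per_batch`` categorical draws from its true
    distribution; each record's reference date is uniform within the batch
    period.  Deterministic for a fixed seed (PCG64).
    """
    scenario = truth.scenario
    if records_per_batch is None:
        counts = scenario.per_batch_counts()
    elif isinstance(records_per_batch, int):
        counts = [records_per_batch] * scenario.n_batches
    else:
        counts = list(records_per_batch)
    if any(c <= 0 for c in counts):
        raise ValueError("records_per_batch must be positive")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    dates = truth.batch_dates()

    all_dates: list[dt.date] = []
    all_codes: list[str] = []
    cats = np.asarray(scenario.categories, dtype=object)
    for t, (start, n) in enumerate(zip(dates, counts)):
        end = next_period(start, scenario.granularity)
        n_days = (end - start).days
        idx = rng.choice(len(cats), size=n, p=truth.distributions[t])
        offsets = rng.integers(0, n_days, size=n)
        all_codes.extend(cats[idx])
        all_dates.extend(start + dt.timedelta(days=int(o)) for o in offsets)

    df = pd.DataFrame(
        {"date": pd.to_datetime(all_dates), category_column: all_codes}
    )
    return RawClinicalTable(
        data=df,
        date_column="date",
        variables={category_column: "categorical"},
        dropped_count=0,
        report={"synthetic": True, "prng": _PRNG_NAME,
                "seed": scenario.seed if seed is None else seed},
    )


def write_records_csv(table: RawClinicalTable, path: str | Path) -> None:
    """Write a sampled table as the package's standard record-level CSV."""
    df = table.data.copy()
    df[table.date_column] = df[table.date_column].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preset scenario library

_UNIFORM10 = [0.1] * 10
_CATS10 = [f"C{i:02d}" for i in range(10)]

# post-change distribution at total-variation distance 0.3 from uniform
_SHIFTED10 = [0.2, 0.2, 0.2, 0.1, 0.1, 0.1, 0.1, 0.0, 0.0, 0.0]

_TREND_DRIFT = [0.0015] * 5 + [-0.0015] * 5
_SEASONAL_AMP = [0.03] * 5 + [-0.03] * 5


def scenario_presets(seed: int = 0) -> dict[str, SyntheticScenario]:
    """Named scenarios covering the four temporal-variability patterns.

    ``abrupt``
        48 monthly batches, 10 categories, a 0.3 total-variation mass
        shift entering at batch 25.
    ``trend``
        60 batches with a linear per-batch drift.
    ``seasonal``
        60 batches with a period-12 sinusoidal modulation.
    ``subgroup``
        two regimes alternating in 12-batch blocks.
    ``mixed``
        trend + seasonality + one abrupt change, emulating the structure
        of a mortality registry with a certificate reform mid-series.
    """
    presets = {
        "abrupt": SyntheticScenario(
            name="abrupt", categories=_CATS10, baseline=_UNIFORM10,
            n_batches=48, records_per_batch=500,
            effects=[AbruptChange(at_batch=25, new_distribution=_SHIFTED10)],
            start_date=dt.date(2008, 1, 1), seed=seed,
        ),
        "trend": SyntheticScenario(
            name="trend", categories=_CATS10, baseline=_UNIFORM10,
            n_batches=60, records_per_batch=1000,
            effects=[LinearTrend(drift=_TREND_DRIFT)],
            start_date=dt.date(2008, 1, 1), seed=seed,
        ),
        "seasonal": SyntheticScenario(
            name="seasonal", categories=_CATS10, baseline=_UNIFORM10,
            n_batches=60, records_per_batch=1000,
            effects=[Seasonal(amplitude=_SEASONAL_AMP, period=12)],
            start_date=dt.date(2008, 1, 1), seed=seed,
        ),
        "subgroup": SyntheticScenario(
            name="subgroup", categories=_CATS10, baseline=_UNIFORM10,
            n_batches=48, records_per_batch=500,
            effects=[
                SubgroupBlock(start_batch=s, end_batch=s + 12,
                              distribution=_SHIFTED10)
                for s in (12, 36)
            ],
            start_date=dt.date(2008, 1, 1), seed=seed,
        ),
        "mixed": SyntheticScenario(
            name="mixed", categories=_CATS10, baseline=_UNIFORM10,
            n_batches=60, records_per_batch=1000,
            effects=[
                # replacement first so drift and seasonality persist across
                # the changepoint, as in a registry reform mid-series
                AbruptChange(at_batch=30, new_distribution=_SHIFTED10),
                LinearTrend(drift=_TREND_DRIFT),
                Seasonal(amplitude=_SEASONAL_AMP, period=12),
            ],
            start_date=dt.date(2008, 1, 1), seed=seed,
        ),
    }
    return presets
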