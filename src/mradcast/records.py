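"""Supercentenarian death records and country observation windows.

Validated supercentenarian registries (the International Database on
Longevity being the canonical one) include a death only if it occurred at or
beyond age 110 *and* inside a country-specific calendar window ``[b, e]``.
Because birth cohorts are not followed to extinction, the observable excess
lifetime ``x = age at death - 110`` is truncated, in one of two ways:

* case C1 — the person turned 110 at time ``t <= b`` (before the window
  opened): the death is seen only if it falls in ``[b, e]``, restricting
  ``x`` to ``[b - t, e - t]``;
* case C2 — the person turned 110 inside the window (``t > b``): the death
  is seen only if it occurs before ``e``, restricting ``x`` to
  ``[0, e - t]``.

This module provides the record/window/dataset containers, the CSV dialects
used to ship such data, the C1/C2 classification, and simple descriptive
statistics (raw one-year survival proportions, country/sex counts).  Time is
represented throughout as decimal calendar years; excess age is computed
from calendar dates as (death - birth in days) / 365.2425 - 110, and the
age-110 attainment time as ``t = death_time - x``.
"""

from __future__ import annotations

import calendar
import datetime
import io
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, NamedTuple, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "SEXES",
    "DataError",
    "DeathRecord",
    "ObservationWindow",
    "Dataset",
    "SummaryCounts",
    "decimal_year",
    "impute_death_time",
    "classify_case",
    "read_records",
    "write_records",
    "write_windows",
    "empirical_one_year_survival",
    "summary_counts",
]

#: Gregorian mean year length used to turn day counts into fractional years.
DAYS_PER_YEAR = 365.2425

SEXES = ("F", "M", "unknown")

_IMPUTE_CONVENTIONS = {"july1": 0.5, "jan1": 0.0, "dec31": 364.0 / 365.0}

RECORD_COLUMNS = ["id", "country", "sex", "birth_date", "death_date", "death_year_only"]
WINDOW_COLUMNS = ["country", "window_start", "window_end"]


class DataError(ValueError):
    """Raised when an input record or window violates the data contract."""


def decimal_year(date: datetime.date) -> float:
    """Calendar date -> decimal year, placing the event at mid-day
    (Jan 1 maps to ``year + 0.5/365``)."""
    length = 366.0 if calendar.isleap(date.year) else 365.0
    return date.year + (date.timetuple().tm_yday - 0.5) / length


def impute_death_time(year: int, convention: str = "july1") -> float:
    """Decimal death time for a record whose death is known only to the year.

    ``july1`` (the registry convention for records lacking an exact date)
    maps to ``year + 0.5``; ``jan1`` and ``dec31`` are the endpoints used
    for sensitivity checks.
    """
    try:
        frac = _IMPUTE_CONVENTIONS[convention]
    except KeyError:
        raise DataError(
            f"unknown imputation convention {convention!r}; "
            f"expected one of {sorted(_IMPUTE_CONVENTIONS)}"
        ) from None
    return float(year) + frac


@dataclass(frozen=True)
class ObservationWindow:
    """Country-specific inclusion interval [b, e] in decimal years.

    ``end`` may be ``math.inf`` for a window with no upper bound.
    """

    country: str
    start: float
    end: float = math.inf

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(
                f"window for {self.country!r} has start {self.start} >= end {self.end}"
            )

    def contains(self, death_time: float, tol: float = 1e-9) -> bool:
        return self.start - tol <= death_time <= self.end + tol


@dataclass(frozen=True)
class DeathRecord:
    """One verified supercentenarian death.

    ``excess_age`` is years lived beyond 110 (x), ``attainment_time`` the
    decimal year at which the person turned 110 (t); ``death_time`` equals
    ``t + x`` by construction.  The optional ``*_source`` fields preserve
    the raw CSV cells so a read file can be rewritten byte-for-byte.
    """

    record_id: str
    country: str
    sex: str
    attainment_time: float
    death_time: float
    excess_age: float
    validated: bool = True
    birth_date_source: str = ""
    death_date_source: str = ""
    death_year_only_source: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataError(f"record {self.record_id!r}: sex {self.sex!r} not in {SEXES}")
        if self.excess_age < 0:
            raise DataError(
                f"record {self.record_id!r}: negative excess age {self.excess_age:.4f} "
                "(death before age 110)"
            )
        if abs(self.death_time - (self.attainment_time + self.excess_age)) > 1e-9:
            raise DataError(
                f"record {self.record_id!r}: death_time != attainment_time + excess_age"
            )


def classify_case(record: DeathRecord, window: ObservationWindow) -> str:
    """Return ``"C1"`` if the record turned 110 at or before the window
    opened (t <= b), ``"C2"`` otherwise."""
    if record.country != window.country:
        raise DataError(
            f"record {record.record_id!r} is from {record.country!r}, "
            f"window is for {window.country!r}"
        )
    return "C1" if record.attainment_time <= window.start else "C2"


class Dataset:
    """An admitted collection of death records plus their country windows.

    Construction validates the contract: every record's country has a
    window and every death time lies inside its window.  Per-record arrays
    used by the truncated likelihoods are cached on first access.
    """

    def __init__(
        self,
        records: Sequence[DeathRecord],
        windows: Mapping[str, ObservationWindow],
    ) -> None:
        self.records: tuple[DeathRecord, ...] = tuple(records)
        self.windows: dict[str, ObservationWindow] = dict(windows)
        for rec in self.records:
            win = self.windows.get(rec.country)
            if win is None:
                raise DataError(f"no observation window for country {rec.country!r}")
            if not win.contains(rec.death_time):
                raise DataError(
                    f"record {rec.record_id!r}: death time {rec.death_time:.4f} outside "
                    f"window [{win.start}, {win.end}] for {rec.country!r}"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @cached_property
    def excess_ages(self) -> np.ndarray:
        """x_i, years beyond 110 at death."""
        return np.array([r.excess_age for r in self.records], dtype=float)

    @cached_property
    def lower_bounds(self) -> np.ndarray:
        """Lower end of the observable excess-age set: b - t for C1, 0 for C2."""
        return np.array(
            [
                max(self.windows[r.country].start - r.attainment_time, 0.0)
                for r in self.records
            ],
            dtype=float,
        )

    @cached_property
    def upper_bounds(self) -> np.ndarray:
        """Upper end of the observable excess-age set: e - t (may be inf)."""
        return np.array(
            [self.windows[r.country].end - r.attainment_time for r in self.records],
            dtype=float,
        )

    @cached_property
    def cases(self) -> np.ndarray:
        """Truncation case per record, 'C1' or 'C2'."""
        return np.array(
            [classify_case(r, self.windows[r.country]) for r in self.records]
        )

    def subset(self, mask: Iterable[bool]) -> "Dataset":
        recs = [r for r, keep in zip(self.records, mask) if keep]
        return Dataset(recs, self.windows)


def _parse_date(raw: str, what: str, record_id: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(raw)
    except ValueError:
        raise DataError(f"record {record_id!r}: bad {what} {raw!r} (expected ISO date)") from None


def _record_from_row(row: Mapping[str, str], convention: str) -> DeathRecord:
    record_id = str(row["id"]).strip()
    country = str(row["country"]).strip()
    sex = str(row["sex"]).strip() or "unknown"
    if sex in ("U", "u"):
        sex = "unknown"
    birth_raw = str(row["birth_date"]).strip()
    death_raw = str(row["death_date"]).strip()
    year_raw = str(row["death_year_only"]).strip()

    birth = _parse_date(birth_raw, "birth_date", record_id)
    if year_raw:
        # Death known only to the year: impute the decimal death time and
        # take excess age as the decimal-year difference minus 110.
        death_time = impute_death_time(int(year_raw), convention)
        excess = death_time - decimal_year(birth) - 110.0
    else:
        death = _parse_date(death_raw, "death_date", record_id)
        death_time = decimal_year(death)
        excess = (death - birth).days / DAYS_PER_YEAR - 110.0
    if excess < 0:
        raise DataError(
            f"record {record_id!r}: negative excess age {excess:.4f} (died before 110)"
        )
    return DeathRecord(
        record_id=record_id,
        country=country,
        sex=sex,
        attainment_time=death_time - excess,
        death_time=death_time,
        excess_age=excess,
        birth_date_source=birth_raw,
        death_date_source=death_raw,
        death_year_only_source=year_raw,
    )


def _read_csv(source: str | TextIO, columns: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise DataError(f"input is missing required columns {missing}")
    return frame


def read_windows(source: str | TextIO) -> dict[str, ObservationWindow]:
    """Read the windows CSV dialect: ``country,window_start,window_end``
    (decimal years; an empty end means unbounded)."""
    frame = _read_csv(source, WINDOW_COLUMNS)
    windows: dict[str, ObservationWindow] = {}
    for row in frame.itertuples(index=False):
        country = str(row.country).strip()
        end_raw = str(row.window_end).strip()
        windows[country] = ObservationWindow(
            country=country,
            start=float(row.window_start),
            end=float(end_raw) if end_raw else math.inf,
        )
    return windows


def read_records(
    records_source: str | TextIO,
    windows_source: str | TextIO,
    convention: str = "july1",
) -> Dataset:
    """Read the records and windows CSV dialects into a validated Dataset.

    Records CSV columns: ``id,country,sex,birth_date,death_date,
    death_year_only`` (ISO dates; a non-empty ``death_year_only`` triggers
    the year-only imputation under ``convention``).  A record whose death
    falls outside its country window, or whose country has no window, is a
    hard error: registries guarantee inclusion, so a violation means
    corrupted input.
    """
    windows = read_windows(windows_source)
    frame = _read_csv(records_source, RECORD_COLUMNS)
    records = [_record_from_row(row._asdict(), convention) for row in frame.itertuples(index=False)]
    return Dataset(records, windows)


def _date_from_decimal(value: float) -> datetime.date:
    """Nearest calendar date for a decimal year (used for synthetic records)."""
    year = int(math.floor(value))
    length = 366 if calendar.isleap(year) else 365
    day = int(round((value - year) * length - 0.5))  # invert the mid-day convention
    day = min(max(day, 0), length - 1)
    return datetime.date(year, 1, 1) + datetime.timedelta(days=day)


#: Smallest birth-to-death day count that re-reads as a nonnegative excess age.
_MIN_SUPERCENTENARIAN_DAYS = int(110.0 * DAYS_PER_YEAR) + 1


def _synthetic_dates(rec: DeathRecord, window: ObservationWindow) -> tuple[str, str]:
    """Birth/death ISO dates for a record that has only decimal-year fields.

    Day rounding can move a boundary death just outside its window or a
    tiny excess age below zero; both are nudged back so the written file
    re-reads as a valid dataset (the round trip is exact to the day).
    """
    death = _date_from_decimal(rec.death_time)
    for _ in range(3):
        dy = decimal_year(death)
        if dy < window.start:
            death += datetime.timedelta(days=1)
        elif dy > window.end:
            death -= datetime.timedelta(days=1)
        else:
            break
    days = max(
        int(round((rec.excess_age + 110.0) * DAYS_PER_YEAR)), _MIN_SUPERCENTENARIAN_DAYS
    )
    birth = death - datetime.timedelta(days=days)
    return birth.isoformat(), death.isoformat()


def write_records(dataset: Dataset, stream: TextIO) -> None:
    """Write the records CSV dialect.

    Records that were read from a file are written back from their source
    cells (byte-stable round trip); synthetic records get dates derived
    from their decimal-year fields (nearest day).
    """
    rows = []
    for rec in dataset.records:
        if rec.birth_date_source:
            birth, death, year_only = (
                rec.birth_date_source,
                rec.death_date_source,
                rec.death_year_only_source,
            )
        else:
            birth, death = _synthetic_dates(rec, dataset.windows[rec.country])
            year_only = ""
        sex = "" if rec.sex == "unknown" else rec.sex
        rows.append([rec.record_id, rec.country, sex, birth, death, year_only])
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(stream, index=False)


def write_windows(dataset: Dataset, stream: TextIO) -> None:
    rows = []
    for country in sorted(dataset.windows):
        win = dataset.windows[country]
        end = "" if math.isinf(win.end) else repr(win.end)
        rows.append([country, repr(win.start), end])
    pd.DataFrame(rows, columns=WINDOW_COLUMNS).to_csv(stream, index=False)


def records_to_csv_strings(dataset: Dataset) -> tuple[str, str]:
    """(records_csv, windows_csv) text for a dataset."""
    rec_buf, win_buf = io.StringIO(), io.StringIO()
    write_records(dataset, rec_buf)
    write_windows(dataset, win_buf)
    return rec_buf.getvalue(), win_buf.getvalue()


def empirical_one_year_survival(dataset: Dataset, age: int) -> float:
    """Raw proportion of records attaining ``age`` that also attained
    ``age + 1``.

    This is the descriptive statistic plotted in registry summaries; it
    applies no truncation adjustment, a documented limitation.  An empty
    denominator raises rather than silently returning zero.
    """
    if age < 110:
        raise ValueError(f"age must be >= 110, got {age}")
    x = dataset.excess_ages
    denom = int(np.sum(x >= age - 110))
    if denom == 0:
        raise DataError(f"no records attained age {age}: one-year survival undefined")
    numer = int(np.sum(x >= age - 109))
    return numer / denom


class SummaryCounts(NamedTuple):
    by_country: pd.Series
    by_sex: pd.Series


def summary_counts(dataset: Dataset) -> SummaryCounts:
    """Record counts by country and by sex, ordered by descending count
    then code; both sum to ``n``."""
    countries = pd.Series([r.country for r in dataset.records], dtype=object)
    sexes = pd.Series([r.sex for r in dataset.records], dtype=object)

    def _ordered(series: pd.Series) -> pd.Series:
        counts = series.value_counts()
        order = sorted(counts.index, key=lambda k: (-counts[k], k))
        return counts.reindex(order).astype(int)

    by_country = _ordered(countries) if len(countries) else pd.Series(dtype=int)
    by_sex = _ordered(sexes) if len(sexes) else pd.Series(dtype=int)
    return SummaryCounts(by_country=by_country, by_sex=by_sex)
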