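"""Reading, validation and descriptive statistics for incident catalogs.

An *event catalog* is a table of rare violent incidents (one row per
incident) with a calendar date, a US state, coordinates, a victim count
and binary firearm / perpetrator-suicide flags.  This module reads such
catalogs from CSV, applies selection filters, converts them to a
day-indexed count series (the object the contagion model consumes), and
computes the descriptive calendar and severity statistics usually
reported alongside: exposure-weighted day-of-week and month-of-year
chi-square tests, a school-year (September-April) versus summer binomial
comparison, and a perpetrator-suicide severity comparison.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_COLUMNS",
    "CatalogError",
    "SchemaError",
    "RowError",
    "EventCatalog",
    "DailySeries",
    "read_catalog",
    "read_covariates",
    "apply_filters",
    "to_daily_series",
    "weekday_seasonal_tests",
    "suicide_severity_comparison",
]

#: Canonical event CSV columns.  Only ``date`` is strictly required; the
#: remaining columns are validated when present and filled with NA otherwise.
CANONICAL_COLUMNS = (
    "date",
    "state",
    "latitude",
    "longitude",
    "n_killed",
    "n_shot",
    "firearm",
    "shooter_suicide",
)

_REQUIRED_COLUMNS = ("date",)

_TRUE_STRINGS = {"true", "t", "yes", "y", "1"}
_FALSE_STRINGS = {"false", "f", "no", "n", "0"}


class CatalogError(ValueError):
    """Base class for catalog validation failures."""


class SchemaError(CatalogError):
    """A required column is missing from the input file."""


class RowError(CatalogError):
    """One or more rows carry unparseable or out-of-range values."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        #: 1-based data-row numbers (header excluded) of the offending rows.
        self.rows = list(rows)


@dataclass(frozen=True)
class EventCatalog:
    """Validated, date-sorted incident table.

    ``data`` holds the canonical columns of :data:`CANONICAL_COLUMNS`;
    ``date`` is a datetime64 column at day resolution.
    """

    data: pd.DataFrame
    label: str = ""
    #: (step name, rows before, rows after) for each read/filter step.
    filter_report: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        dates = self.data["date"]
        if len(dates) > 1 and not dates.is_monotonic_increasing:
            raise CatalogError("catalog records must be sorted by date")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.Series:
        return self.data["date"]

    @property
    def date_span(self) -> tuple[_dt.date, _dt.date] | None:
        """(first, last) calendar day, or None for an empty catalog."""
        if len(self) == 0:
            return None
        return (self.dates.iloc[0].date(), self.dates.iloc[-1].date())

    def with_report(self, step: str, n_before: int, n_after: int) -> "EventCatalog":
        report = self.filter_report + ((step, n_before, n_after),)
        return dataclasses.replace(self, filter_report=report)


@dataclass(frozen=True)
class DailySeries:
    """Event counts on an integer day grid ``t = 0 .. T_span``.

    ``counts[d]`` is the number of catalog records on calendar day
    ``origin + d``; ``weekday`` (Monday=0) and ``month`` (1..12) carry the
    calendar metadata needed for exposure-weighted tests and baseline
    weights.
    """

    origin: _dt.date
    counts: np.ndarray
    weekday: np.ndarray
    month: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "weekday", np.asarray(self.weekday, dtype=np.int64))
        object.__setattr__(self, "month", np.asarray(self.month, dtype=np.int64))
        if counts.min(initial=0) < 0:
            raise ValueError("daily counts must be non-negative")
        if not (len(counts) == len(self.weekday) == len(self.month)):
            raise ValueError("counts/weekday/month arrays must be aligned")

    @property
    def n_days(self) -> int:
        return len(self.counts)

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())

    def event_days(self) -> np.ndarray:
        """Day indices with one entry per event (multiplicity preserved)."""
        return np.repeat(np.arange(self.n_days), self.counts)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.origin, periods=self.n_days, freq="D")


def _parse_bool_column(col: pd.Series) -> tuple[pd.Series, list[int]]:
    """Coerce a column of truthy/falsy tokens to nullable booleans."""
    out = pd.Series(pd.NA, index=col.index, dtype="boolean")
    bad: list[int] = []
    for idx, value in col.items():
        if pd.isna(value) or (isinstance(value, str) and not value.strip()):
            continue
        if isinstance(value, (bool, np.bool_)):
            out[idx] = bool(value)
            continue
        token = str(value).strip().lower()
        if token in _TRUE_STRINGS:
            out[idx] = True
        elif token in _FALSE_STRINGS:
            out[idx] = False
        else:
            bad.append(idx)
    return out, bad


def _validate_frame(raw: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw CSV frame to canonical dtypes, collecting row errors."""
    df = raw.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA

    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    bad_dates = [i + 1 for i in np.flatnonzero(dates.isna().to_numpy())]
    if bad_dates:
        raise RowError(
            f"unparseable date in data row(s) {bad_dates}", rows=bad_dates
        )
    df["date"] = dates.dt.normalize()

    bad_rows: list[int] = []
    for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        out_of_range = vals.notna() & ((vals < lo) | (vals > hi))
        bad_rows += [i + 1 for i in np.flatnonzero((bad | out_of_range).to_numpy())]
        df[col] = vals

    for col in ("n_killed", "n_shot"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        negative = vals.notna() & (vals < 0)
        bad_rows += [i + 1 for i in np.flatnonzero((bad | negative).to_numpy())]
        df[col] = vals.astype("Int64")

    for col in ("firearm", "shooter_suicide"):
        parsed, bad = _parse_bool_column(df[col])
        bad_rows += [i + 1 for i in bad]
        df[col] = parsed

    if bad_rows:
        bad_rows = sorted(set(bad_rows))
        raise RowError(f"invalid values in data row(s) {bad_rows}", rows=bad_rows)

    df["state"] = df["state"].astype("string")
    return df[list(CANONICAL_COLUMNS)]


def apply_filters(
    catalog: EventCatalog, filters: Mapping[str, Any] | None
) -> EventCatalog:
    """Apply a key-value selection spec to a catalog.

    Supported keys: ``min_killed``, ``max_killed``, ``firearm``,
    ``shooter_suicide`` (booleans select rows whose flag equals the value;
    rows with a missing flag are dropped by a flag filter).  Filtering is
    idempotent and each step is appended to the catalog's filter report.
    """
    if not filters:
        return catalog
    df = catalog.data
    out = catalog
    for key, value in filters.items():
        n_before = len(df)
        if key == "min_killed":
            mask = df["n_killed"].notna() & (df["n_killed"] >= int(value))
        elif key == "max_killed":
            mask = df["n_killed"].notna() & (df["n_killed"] <= int(value))
        elif key in ("firearm", "shooter_suicide"):
            mask = df[key].notna() & (df[key] == bool(value))
        else:
            raise ValueError(f"unknown filter key: {key!r}")
        df = df[mask.to_numpy(dtype=bool)].reset_index(drop=True)
        out = dataclasses.replace(out, data=df).with_report(
            f"{key}={value}", n_before, len(df)
        )
    return out


def read_catalog(
    path: str,
    filters: Mapping[str, Any] | None = None,
    column_map: Mapping[str, str] | None = None,
    label: str = "",
) -> EventCatalog:
    """Read, validate, sort and filter an event catalog CSV.

    Parameters
    ----------
    path:
        CSV file with a header row.  Canonical column names are listed in
        :data:`CANONICAL_COLUMNS`; non-canonical headers can be renamed via
        ``column_map`` (source name -> canonical name).
    filters:
        Selection spec forwarded to :func:`apply_filters`.
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = _validate_frame(raw)
    df = df.sort_values("date", kind="stable").reset_index(drop=True)
    catalog = EventCatalog(df, label=label or str(path))
    catalog = catalog.with_report("read", len(raw), len(df))
    return apply_filters(catalog, filters)


def read_covariates(path: str) -> pd.DataFrame:
    """Read a per-state covariate CSV.

    Canonical columns: ``state`` plus any of ``population``,
    ``suicides_total``, ``suicides_firearm``, ``mental_illness_prev``,
    ``brady_rank``.  Returns a frame indexed by state code.
    """
    df = pd.read_csv(path)
    if "state" not in df.columns:
        raise SchemaError("missing required column(s): state")
    return df.set_index("state")


def to_daily_series(catalog: EventCatalog) -> DailySeries:
    """Bin catalog records onto the integer day grid spanning the catalog."""
    if len(catalog) == 0:
        raise CatalogError("cannot build a daily series from an empty catalog")
    first, last = catalog.date_span  # type: ignore[misc]
    grid = pd.date_range(first, last, freq="D")
    day_index = (catalog.dates - pd.Timestamp(first)).dt.days.to_numpy()
    counts = np.bincount(day_index, minlength=len(grid))
    return DailySeries(
        origin=first,
        counts=counts,
        weekday=grid.weekday.to_numpy(),
        month=grid.month.to_numpy(),
    )


def series_to_dates(series: DailySeries) -> pd.Series:
    """Expand a daily series back to one dated entry per event."""
    grid = series.dates()
    return pd.Series(grid.repeat(series.counts))


@dataclass(frozen=True)
class CalendarTests:
    """Exposure-weighted calendar structure tests for a catalog."""

    weekday_chi2: float
    weekday_df: int
    weekday_p: float
    weekday_counts: np.ndarray
    weekday_expected: np.ndarray
    month_chi2: float
    month_df: int
    month_p: float
    school_year_events: int          # September-April
    school_year_expected_frac: float  # days-at-risk share of Sep-Apr
    school_year_p: float
    n_events: int

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["weekday_counts"] = self.weekday_counts.tolist()
        d["weekday_expected"] = self.weekday_expected.tolist()
        return d


def weekday_seasonal_tests(catalog: EventCatalog) -> CalendarTests:
    """Day-of-week and seasonal goodness-of-fit tests.

    The null for the weekday (month) test is that events fall uniformly
    over *days at risk*: expected counts are proportional to the number of
    Mondays, Tuesdays, ... (days in each month) contained in the catalog
    span, not to a flat 1/7 (1/12), because a span need not contain whole
    weeks or years.  The seasonal comparison tests the fraction of events
    in September-April against that period's share of days at risk
    (exact two-sided binomial test).
    """
    if len(catalog) < 2:
        raise CatalogError("calendar tests require at least 2 records")
    series = to_daily_series(catalog)
    if series.n_days < 7:
        raise CatalogError("catalog span shorter than one week")

    n = series.n_events
    event_weekday = np.repeat(series.weekday, series.counts)
    obs_wd = np.bincount(event_weekday, minlength=7).astype(float)
    exposure_wd = np.bincount(series.weekday, minlength=7).astype(float)
    exp_wd = n * exposure_wd / exposure_wd.sum()
    chi2_wd, p_wd = stats.chisquare(obs_wd, exp_wd)

    event_month = np.repeat(series.month, series.counts)
    obs_mo = np.bincount(event_month, minlength=13)[1:].astype(float)
    exposure_mo = np.bincount(series.month, minlength=13)[1:].astype(float)
    present = exposure_mo > 0
    exp_mo = n * exposure_mo / exposure_mo.sum()
    chi2_mo, p_mo = stats.chisquare(obs_mo[present], exp_mo[present])
    month_df = int(present.sum()) - 1

    school_months = {9, 10, 11, 12, 1, 2, 3, 4}
    in_school = np.isin(series.month, list(school_months))
    k_school = int(series.counts[in_school].sum())
    frac_days = float(in_school.sum() / series.n_days)
    p_school = stats.binomtest(k_school, n, frac_days, alternative="two-sided").pvalue

    return CalendarTests(
        weekday_chi2=float(chi2_wd),
        weekday_df=6,
        weekday_p=float(p_wd),
        weekday_counts=obs_wd.astype(int),
        weekday_expected=exp_wd,
        month_chi2=float(chi2_mo),
        month_df=month_df,
        month_p=float(p_mo),
        school_year_events=k_school,
        school_year_expected_frac=frac_days,
        school_year_p=float(p_school),
        n_events=n,
    )


@dataclass(frozen=True)
class SeverityComparison:
    """Victim counts in perpetrator-suicide vs non-suicide incidents."""

    n_suicide: int
    n_other: int
    mean_killed_suicide: float | None
    mean_killed_other: float | None
    ratio: float | None
    t_statistic: float | None
    p_value: float | None
    suicide_fraction: float
    available: bool

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def suicide_severity_comparison(catalog: EventCatalog) -> SeverityComparison:
    """Compare mean victims killed between suicide and non-suicide incidents.

    Uses the classical two-sided pooled-variance Student t-test.  When one
    subgroup is empty the comparison is marked unavailable but the suicide
    fraction is still reported.
    """
    df = catalog.data
    known = df[df["shooter_suicide"].notna()]
    suicide = known[known["shooter_suicide"].to_numpy(dtype=bool)]
    other = known[~known["shooter_suicide"].to_numpy(dtype=bool)]
    frac = len(suicide) / len(known) if len(known) else float("nan")

    if len(suicide) == 0 or len(other) == 0:
        return SeverityComparison(
            n_suicide=len(suicide),
            n_other=len(other),
            mean_killed_suicide=float(suicide["n_killed"].mean()) if len(suicide) else None,
            mean_killed_other=float(other["n_killed"].mean()) if len(other) else None,
            ratio=None,
            t_statistic=None,
            p_value=None,
            suicide_fraction=frac,
            available=False,
        )

    x = suicide["n_killed"].dropna().to_numpy(dtype=float)
    y = other["n_killed"].dropna().to_numpy(dtype=float)
    mean_x, mean_y = float(x.mean()), float(y.mean())
    if np.allclose(x.std(), 0) and np.allclose(y.std(), 0) and np.isclose(mean_x, mean_y):
        t_stat, p = 0.0, 1.0
    else:
        import warnings

        with warnings.catch_warnings():
            # zero within-group variance is a legitimate degenerate input
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p = stats.ttest_ind(x, y, equal_var=True)
    return SeverityComparison(
        n_suicide=len(suicide),
        n_other=len(other),
        mean_killed_suicide=mean_x,
        mean_killed_other=mean_y,
        ratio=mean_x / mean_y if mean_y else float("inf"),
        t_statistic=float(t_stat),
        p_value=float(p),
        suicide_fraction=frac,
        available=True,
    )
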