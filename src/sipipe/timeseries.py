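"""Monthly environmental series, annual recruitment records and observation windows.

The synchronicity analysis works on per-area monthly means of chlorophyll-a
(CHL, mg/m³), mixed layer depth (MLD, m) and sea surface temperature
(SST, °C), together with annual abundances of Age-1 anchovy recruits.  The
anchor of every downstream computation is the *observation window*: for a
recruitment year ``t`` it runs from the onset of spawning (April of year
``t − 1`` by default) to the month preceding the acoustic survey of year
``t`` (July for the Strait of Sicily and Gulf of Lions, June for the
Adriatic Sea), i.e. the first year of life of the fish counted at age 1.

Calendar convention: months are 1-based, a window is a closed interval of
calendar months, and no day-level resolution exists anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, GapError, ValidationError

logger = logging.getLogger(__name__)

#: canonical units per environmental variable; declared, never converted
VARIABLE_UNITS = {"CHL": "mg/m³", "MLD": "m", "SST": "°C"}

#: accepted spellings for each canonical unit string
_UNIT_ALIASES = {
    "mg/m³": "mg/m³",
    "mg/m3": "mg/m³",
    "mg m-3": "mg/m³",
    "m": "m",
    "°C": "°C",
    "degC": "°C",
    "deg C": "°C",
    "C": "°C",
}


@dataclass(frozen=True, order=True)
class MonthStamp:
    """A calendar month, totally ordered by (year, month)."""

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValidationError(f"month must be in 1..12, got {self.month}")

    @classmethod
    def from_string(cls, text: str) -> "MonthStamp":
        """Parse an ISO ``YYYY-MM`` stamp."""
        try:
            year_s, month_s = str(text).strip().split("-")[:2]
            return cls(int(year_s), int(month_s))
        except (ValueError, AttributeError) as exc:
            raise ValidationError(f"cannot parse month stamp {text!r}") from exc

    @classmethod
    def from_period(cls, period: pd.Period) -> "MonthStamp":
        return cls(period.year, period.month)

    def to_period(self) -> pd.Period:
        return pd.Period(year=self.year, month=self.month, freq="M")

    def plus_months(self, n: int) -> "MonthStamp":
        return MonthStamp.from_period(self.to_period() + n)

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


def month_range(start: MonthStamp, end: MonthStamp) -> tuple[MonthStamp, ...]:
    """All consecutive months from ``start`` to ``end`` inclusive."""
    if end < start:
        raise ValidationError(f"month range end {end} precedes start {start}")
    periods = pd.period_range(start.to_period(), end.to_period(), freq="M")
    return tuple(MonthStamp.from_period(p) for p in periods)


@dataclass
class EnvSeries:
    """One environmental variable for one area, at consecutive monthly steps.

    ``data`` is a float Series indexed by a monthly ``PeriodIndex``; rows are
    sorted on construction, so storage order of the input never matters.
    """

    area_id: str
    variable: str
    units: str
    data: pd.Series

    def __post_init__(self) -> None:
        if self.variable not in VARIABLE_UNITS:
            raise ValidationError(
                f"unknown variable {self.variable!r}; expected one of {sorted(VARIABLE_UNITS)}"
            )
        expected = VARIABLE_UNITS[self.variable]
        canonical = _UNIT_ALIASES.get(self.units)
        if canonical != expected:
            raise ValidationError(
                f"units {self.units!r} invalid for {self.variable} (expected {expected!r})"
            )
        self.units = canonical
        s = self.data.astype(float).sort_index()
        if not isinstance(s.index, pd.PeriodIndex) or s.index.freqstr not in ("M", "ME"):
            raise ValidationError("EnvSeries.data must be indexed by a monthly PeriodIndex")
        dup = s.index[s.index.duplicated()]
        if len(dup):
            raise GapError(
                f"duplicate months in {self.variable}/{self.area_id}: "
                + ", ".join(str(MonthStamp.from_period(p)) for p in dup.unique())
            )
        if len(s) == 0:
            raise ValidationError(f"empty series {self.variable}/{self.area_id}")
        full = pd.period_range(s.index[0], s.index[-1], freq="M")
        missing = full.difference(s.index)
        if len(missing):
            raise GapError(
                f"missing months in {self.variable}/{self.area_id}: "
                + ", ".join(str(MonthStamp.from_period(p)) for p in missing)
            )
        if not np.isfinite(s.to_numpy()).all():
            bad = s.index[~np.isfinite(s.to_numpy())]
            raise ValidationError(
                f"non-finite values in {self.variable}/{self.area_id} at "
                + ", ".join(str(MonthStamp.from_period(p)) for p in bad)
            )
        if self.variable in ("CHL", "MLD") and (s.to_numpy() <= 0).any():
            raise ValidationError(f"{self.variable} values must be positive ({self.area_id})")
        self.data = s

    @property
    def start(self) -> MonthStamp:
        return MonthStamp.from_period(self.data.index[0])

    @property
    def end(self) -> MonthStamp:
        return MonthStamp.from_period(self.data.index[-1])

    def __len__(self) -> int:
        return len(self.data)

    def values_for(self, months: tuple[MonthStamp, ...]) -> np.ndarray:
        """Values at the given months, raising CoverageError on any absence."""
        idx = pd.PeriodIndex([m.to_period() for m in months], freq="M")
        missing = idx.difference(self.data.index)
        if len(missing):
            raise CoverageError(
                f"{self.variable}/{self.area_id} does not cover: "
                + ", ".join(str(MonthStamp.from_period(p)) for p in missing)
            )
        return self.data.loc[idx].to_numpy(dtype=float)


@dataclass(frozen=True)
class AreaSpec:
    """Per-area calendar configuration: spawning onset and survey month."""

    area_id: str
    name: str
    survey_month: int
    spawning_start_month: int = 4

    def __post_init__(self) -> None:
        for label, m in (
            ("survey_month", self.survey_month),
            ("spawning_start_month", self.spawning_start_month),
        ):
            if not 1 <= m <= 12:
                raise ValidationError(f"{label} must be in 1..12, got {m}")


def default_areas() -> list[AreaSpec]:
    """The three Mediterranean ecosystems with their survey calendars.

    MEDIAS surveys the Strait of Sicily in July and the Adriatic in June;
    PELMED surveys the Gulf of Lions in July.  Spawning starts in April
    everywhere.
    """
    return [
        AreaSpec("SoS", "Strait of Sicily", survey_month=7),
        AreaSpec("GoL", "Gulf of Lions", survey_month=7),
        AreaSpec("AS", "Adriatic Sea", survey_month=6),
    ]


@dataclass(frozen=True)
class ObservationWindow:
    """The consecutive months tied to one recruitment-year observation."""

    area_id: str
    recruit_year: int
    months: tuple[MonthStamp, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.months)


def build_window(
    area: AreaSpec, recruit_year: int, forbid_short: bool = False
) -> ObservationWindow:
    """Window from spawning onset of year ``recruit_year − 1`` to the month
    preceding the survey of year ``recruit_year`` (both inclusive).

    When ``survey_month >= spawning_start_month`` the window has exactly
    ``12 + survey_month − spawning_start_month`` months.  A survey month
    earlier than the spawning month yields a sub-annual window: warned by
    default, an error when ``forbid_short`` is set.
    """
    start = MonthStamp(recruit_year - 1, area.spawning_start_month)
    if area.survey_month == 1:
        end = MonthStamp(recruit_year - 1, 12)
    else:
        end = MonthStamp(recruit_year, area.survey_month - 1)
    if area.survey_month < area.spawning_start_month:
        msg = (
            f"window for {area.area_id}/{recruit_year} is shorter than 12 months "
            f"(survey month {area.survey_month} precedes spawning month "
            f"{area.spawning_start_month})"
        )
        if forbid_short:
            raise ValidationError(msg)
        logger.warning(msg)
    return ObservationWindow(area.area_id, recruit_year, month_range(start, end))


def extract_paired_window(
    chl: EnvSeries, mld: EnvSeries, window: ObservationWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Month-aligned CHL and MLD vectors over the window, in window order."""
    for series in (chl, mld):
        if series.area_id != window.area_id:
            raise ValidationError(
                f"area mismatch: window {window.area_id} vs series {series.area_id}"
            )
    return chl.values_for(window.months), mld.values_for(window.months)


def window_mean_sst(sst: EnvSeries, window: ObservationWindow) -> float:
    """Arithmetic mean of the monthly SST values over the window."""
    if sst.area_id != window.area_id:
        raise ValidationError(
            f"area mismatch: window {window.area_id} vs series {sst.area_id}"
        )
    return float(np.mean(sst.values_for(window.months)))


def load_env_series(
    path, area_id: str | None = None, variable: str | None = None
) -> EnvSeries:
    """Load one monthly environmental series from a CSV file.

    Two dialects are accepted: a long table with columns
    ``area_id,date,variable,value[,units]`` (filtered by the ``area_id`` and
    ``variable`` arguments) or a per-variable file with columns
    ``[area_id,]date,value``.  Dates are ISO ``YYYY-MM`` stamps; rows may be
    in any order.
    """
    frame = pd.read_csv(path, dtype={"date": str})
    cols = set(frame.columns)
    if not {"date", "value"} <= cols:
        raise ValidationError(f"{path}: need at least 'date' and 'value' columns, got {sorted(cols)}")
    if "area_id" in cols and area_id is not None:
        frame = frame[frame["area_id"] == area_id]
    elif area_id is None and "area_id" in cols:
        uniq = frame["area_id"].unique()
        if len(uniq) != 1:
            raise ValidationError(f"{path}: multiple areas present, pass area_id explicitly")
        area_id = str(uniq[0])
    if "variable" in cols and variable is not None:
        frame = frame[frame["variable"] == variable]
    elif variable is None and "variable" in cols:
        uniq = frame["variable"].unique()
        if len(uniq) != 1:
            raise ValidationError(f"{path}: multiple variables present, pass variable explicitly")
        variable = str(uniq[0])
    if area_id is None or variable is None:
        raise ValidationError(f"{path}: area_id and variable must be given or inferable")
    if frame.empty:
        raise ValidationError(f"{path}: no rows for area {area_id!r} variable {variable!r}")

    stamps = []
    values = []
    for pos, row in enumerate(frame.itertuples(index=False), start=1):
        stamp = MonthStamp.from_string(getattr(row, "date"))
        raw = getattr(row, "value")
        try:
            val = float(raw)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: non-numeric value {raw!r} in data row {pos}"
            ) from exc
        if not np.isfinite(val):
            raise ValidationError(f"{path}: non-finite value in data row {pos}")
        stamps.append(stamp)
        values.append(val)

    units = VARIABLE_UNITS[variable] if variable in VARIABLE_UNITS else ""
    if "units" in cols:
        declared = frame["units"].unique()
        if len(declared) != 1:
            raise ValidationError(f"{path}: inconsistent units column for {variable}")
        units = str(declared[0])

    index = pd.PeriodIndex([s.to_period() for s in stamps], freq="M")
    return EnvSeries(area_id, variable, units, pd.Series(values, index=index))


@dataclass
class RecruitmentSeries:
    """Annual abundance of Age-1 recruits (thousands of individuals) for one area."""

    area_id: str
    records: dict[int, float]

    def __post_init__(self) -> None:
        years = list(self.records)
        if years != sorted(years):
            self.records = dict(sorted(self.records.items()))
        for year, value in self.records.items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"abundance for {self.area_id}/{year} must be finite and >= 0, got {value}"
                )

    @property
    def years(self) -> list[int]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)


def load_recruitment(path) -> list[RecruitmentSeries]:
    """Load annual recruitment from a CSV with columns ``area_id,year,abundance_thousands``."""
    frame = pd.read_csv(path)
    if frame.empty:
        logger.warning("%s: empty recruitment file", path)
        return []
    abundance_col = (
        "abundance_thousands" if "abundance_thousands" in frame.columns else "abundance"
    )
    required = {"area_id", "year", abundance_col}
    if not required <= set(frame.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    dup = frame.duplicated(subset=["area_id", "year"])
    if dup.any():
        pairs = frame.loc[dup, ["area_id", "year"]].itertuples(index=False)
        raise ValidationError(
            f"{path}: duplicate (area, year) rows: "
            + ", ".join(f"{a}/{y}" for a, y in pairs)
        )
    out = []
    for area, sub in frame.groupby("area_id", sort=True):
        records = {
            int(row.year): float(getattr(row, abundance_col))
            for row in sub.itertuples(index=False)
        }
        out.append(RecruitmentSeries(str(area), records))
    return out
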