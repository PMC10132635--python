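"""Robust Design sampling calendar.

The sampling design nests one-month secondary occasions inside six-month
primary periods aligned with the Maldivian monsoon seasons: the wet
southwest monsoon ("hulan'gu", May-October) and the dry northeast monsoon
("iruvai", November-April).  The population is treated as closed across the
months of a primary period and open (survival, temporary emigration)
between primary periods.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import yaml

WET = "wet"
DRY = "dry"

#: calendar month -> monsoon season
SEASON_OF_MONTH = {m: (WET if 5 <= m <= 10 else DRY) for m in range(1, 13)}

#: months at which a new primary period may begin (season boundaries)
PRIMARY_START_MONTHS = (5, 11)

MONTHS_PER_PRIMARY = 6


class OutOfWindowError(ValueError):
    """A date falls outside the study window."""


def season_of_month(month: int) -> str:
    """Monsoon season of a calendar month (wet = May-Oct, dry = Nov-Apr)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1..12, got {month}")
    return SEASON_OF_MONTH[month]


@dataclass(frozen=True)
class Occasion:
    """One monthly secondary sampling occasion."""

    index: int          # 0-based position in the study
    primary: int        # 1-based primary period
    secondary: int      # 1-based month within its primary
    year: int
    month: int

    @property
    def season(self) -> str:
        return season_of_month(self.month)

    @property
    def label(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


def _parse_ym(value) -> tuple[int, int]:
    if isinstance(value, (tuple, list)):
        y, m = int(value[0]), int(value[1])
    elif isinstance(value, (_dt.date, _dt.datetime)):
        y, m = value.year, value.month
    else:
        y, m = (int(p) for p in str(value).split("-")[:2])
    if not 1 <= m <= 12:
        raise ValueError(f"invalid month in {value!r}")
    return y, m


@dataclass(frozen=True)
class StudyDesign:
    """Layout of primary and secondary occasions over calendar time.

    Parameters
    ----------
    start_year, start_month
        First month of the first primary period.  Must coincide with a
        season boundary (May or November) so that primaries align with
        monsoon seasons.
    n_occasions
        Total number of monthly occasions.  The final primary period may be
        partial (1-6 months); all others span six months.
    """

    start_year: int
    start_month: int
    n_occasions: int
    occasions: tuple[Occasion, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.start_month not in PRIMARY_START_MONTHS:
            raise ValueError(
                "primary periods must start at a season boundary "
                f"(month 5 or 11), got month {self.start_month}"
            )
        if self.n_occasions < 1:
            raise ValueError("need at least one occasion")
        occ = []
        y, m = self.start_year, self.start_month
        for i in range(self.n_occasions):
            primary = i // MONTHS_PER_PRIMARY + 1
            secondary = i % MONTHS_PER_PRIMARY + 1
            occ.append(Occasion(i, primary, secondary, y, m))
            m += 1
            if m > 12:
                m, y = 1, y + 1
        object.__setattr__(self, "occasions", tuple(occ))

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_window(cls, start, end) -> "StudyDesign":
        """Design covering the inclusive month window ``start``..``end``.

        ``start``/``end`` accept ``"YYYY-MM"`` strings, (year, month) pairs
        or dates.  The default field study spans 2016-05 .. 2019-11: eight
        primary periods, the last containing a single month.
        """
        sy, sm = _parse_ym(start)
        ey, em = _parse_ym(end)
        n = (ey - sy) * 12 + (em - sm) + 1
        if n < 1:
            raise ValueError("end precedes start")
        return cls(sy, sm, n)

    @classmethod
    def regular(cls, start, n_primary: int,
                secondaries_per_primary: int = MONTHS_PER_PRIMARY) -> "StudyDesign":
        """Design with ``n_primary`` primaries of equal length.

        With fewer than six secondaries per primary the remaining months of
        each season go unsurveyed; occasion indices stay contiguous, so this
        constructor is intended for simulation designs where every surveyed
        month is consecutive (it compresses the calendar).
        """
        if not 1 <= secondaries_per_primary <= MONTHS_PER_PRIMARY:
            raise ValueError("secondaries_per_primary must be 1..6")
        if secondaries_per_primary == MONTHS_PER_PRIMARY:
            return cls(*_parse_ym(start), n_primary * MONTHS_PER_PRIMARY)
        # truncated primaries: enumerate occasions explicitly
        sy, sm = _parse_ym(start)
        design = cls(sy, sm, n_primary * MONTHS_PER_PRIMARY)
        keep = [o for o in design.occasions if o.secondary <= secondaries_per_primary]
        occ = tuple(
            Occasion(i, o.primary, o.secondary, o.year, o.month)
            for i, o in enumerate(keep)
        )
        object.__setattr__(design, "occasions", occ)
        object.__setattr__(design, "n_occasions", len(occ))
        return design

    # -- queries ----------------------------------------------------------

    @property
    def n_primary(self) -> int:
        return self.occasions[-1].primary

    @property
    def n_intervals(self) -> int:
        """Between-primary intervals over which survival/movement operate."""
        return self.n_primary - 1

    def secondaries_of(self, primary: int) -> list[Occasion]:
        return [o for o in self.occasions if o.primary == primary]

    def primary_season(self, primary: int) -> str:
        """Season of a primary period (shared by all its months)."""
        return self.secondaries_of(primary)[0].season

    def interval_season(self, interval: int) -> str:
        """Season of the primary at which a 1-based interval starts."""
        return self.primary_season(interval)

    def occasion_of_date(self, date: _dt.date) -> Occasion:
        """Occasion containing a calendar date.

        Raises
        ------
        OutOfWindowError
            If the date falls before the first or after the last occasion.
        """
        for o in self.occasions:
            if o.year == date.year and o.month == date.month:
                return o
        raise OutOfWindowError(f"{date.isoformat()} outside the study window")

    def assign(self, date: _dt.date) -> tuple[int, int, str]:
        """(primary index, secondary index, season) of a date, 1-based."""
        o = self.occasion_of_date(date)
        return o.primary, o.secondary, o.season

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "start": f"{self.start_year:04d}-{self.start_month:02d}",
            "n_occasions": self.n_occasions,
            "occasions": [
                {"label": o.label, "primary": o.primary,
                 "secondary": o.secondary, "season": o.season}
                for o in self.occasions
            ],
        }

    def to_yaml(self, stream=None):
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, stream) -> "StudyDesign":
        d = yaml.safe_load(stream)
        sy, sm = _parse_ym(d["start"])
        return cls(sy, sm, int(d["n_occasions"]))


def assign_occasion(date: _dt.date, design: StudyDesign) -> tuple[int, int, str]:
    """Map a calendar date to (primary, secondary, season) under a design."""
    return design.assign(date)
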