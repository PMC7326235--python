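"""Cross-tabulations of menstrual regularity and the proportion series.

Two cross-tabulations drive the score's development: regularity answers
("regular" / "irregular for a few months" / "stopped") counted by number
of periods in the last twelve months, and the same answers counted by
whole year of age. From these, two discrete proportion series are formed:

* ``P(period) = x / (x + y + z)`` — the proportion of women with regular
  menstruation among those reporting a given period count, and
* ``P(age) = z / (x + y + z)`` — the proportion whose menses have stopped
  among those of a given age,

where x, y, z count the three regularity answers in a row. These series
are the targets the continuous membership functions approximate.

The development cross-tabulations (3107 women, ages 38-66) ship as
packaged fixtures; see :func:`load_development_period_crosstab` and
:func:`load_development_age_crosstab`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .cohort import ParticipantRecord, Regularity

logger = logging.getLogger(__name__)

_COLUMNS = ["grid_value", "n_regular", "n_irregular", "n_stopped"]


class GridKind(Enum):
    PERIODS = "periods"
    AGE = "age"


@dataclass(frozen=True)
class Crosstab:
    """Counts of the three regularity answers along an integer grid.

    ``table`` is indexed by the grid value (period count or age in years)
    with integer columns ``n_regular`` (x), ``n_irregular`` (y),
    ``n_stopped`` (z).
    """

    kind: GridKind
    table: pd.DataFrame

    def __post_init__(self):
        tab = self.table
        if list(tab.columns) != _COLUMNS[1:]:
            raise ValueError(f"crosstab columns must be {_COLUMNS[1:]}")
        if len(tab) and (tab.values < 0).any():
            raise ValueError("crosstab counts must be nonnegative")
        if not tab.index.is_monotonic_increasing or tab.index.has_duplicates:
            raise ValueError("crosstab grid must be strictly increasing")

    @property
    def row_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.table.values.sum())

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.table.reset_index()
        out.columns = _COLUMNS
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: GridKind) -> "Crosstab":
        df = pd.read_csv(path)
        if list(df.columns) != _COLUMNS:
            raise ValueError(
                f"{path}: expected columns {_COLUMNS}, got {list(df.columns)}"
            )
        table = df.set_index("grid_value").astype(int).sort_index()
        return cls(kind=kind, table=table)


# Aliases matching the two grids; they share the implementation.
PeriodCrosstab = Crosstab
AgeCrosstab = Crosstab


@dataclass(frozen=True)
class ProportionSeries:
    """Ordered (grid value, proportion) pairs for one of the two grids."""

    kind: GridKind
    grid: tuple[int, ...]
    proportions: tuple[float, ...]

    def __post_init__(self):
        if len(self.grid) != len(self.proportions):
            raise ValueError("grid and proportions must have equal length")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("grid values must be strictly increasing")
        if any(not (0.0 <= p <= 1.0) for p in self.proportions):
            raise ValueError("proportions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.grid)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"grid_value": self.grid, "proportion": self.proportions}
        )


def _tally(records: Sequence[ParticipantRecord], key: GridKind) -> pd.DataFrame:
    rows: dict[int, list[int]] = {}
    for rec in records:
        grid = rec.periods_last_12m if key is GridKind.PERIODS else rec.age
        cell = rows.setdefault(int(grid), [0, 0, 0])
        if rec.regularity is Regularity.REGULAR:
            cell[0] += 1
        elif rec.regularity is Regularity.IRREGULAR_FEW_MONTHS:
            cell[1] += 1
        else:
            cell[2] += 1
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=_COLUMNS[1:], dtype=int
    ).sort_index()
    table.index.name = "grid_value"
    return table


def build_period_crosstab(records: Sequence[ParticipantRecord]) -> Crosstab:
    """Tally regularity answers by reported period count."""
    return Crosstab(kind=GridKind.PERIODS, table=_tally(records, GridKind.PERIODS))


def build_age_crosstab(records: Sequence[ParticipantRecord]) -> Crosstab:
    """Tally regularity answers by whole year of age."""
    return Crosstab(kind=GridKind.AGE, table=_tally(records, GridKind.AGE))


def _proportion(tab: Crosstab, column: str) -> ProportionSeries:
    totals = tab.row_totals
    empty = totals[totals == 0]
    if len(empty):
        logger.warning(
            "dropping %d zero-total rows at grid values %s",
            len(empty),
            list(empty.index),
        )
    keep = totals > 0
    props = (tab.table.loc[keep, column] / totals[keep]).astype(float)
    return ProportionSeries(
        kind=tab.kind,
        grid=tuple(int(g) for g in props.index),
        proportions=tuple(props.values),
    )


def proportion_regular(tab: Crosstab) -> ProportionSeries:
    """P(period) = x / (x + y + z) per period count. Rows with zero total
    are dropped with a warning; the fit uses only observed grid points."""
    if tab.kind is not GridKind.PERIODS:
        raise ValueError("proportion_regular needs a period crosstab")
    return _proportion(tab, "n_regular")


def proportion_stopped(tab: Crosstab) -> ProportionSeries:
    """P(age) = z / (x + y + z) per year of age."""
    if tab.kind is not GridKind.AGE:
        raise ValueError("proportion_stopped needs an age crosstab")
    return _proportion(tab, "n_stopped")


def _load_fixture(name: str, kind: GridKind) -> Crosstab:
    ref = resources.files("rascore.data").joinpath(name)
    with resources.as_file(ref) as path:
        return Crosstab.from_csv(path, kind)


def load_development_period_crosstab() -> Crosstab:
    """The packaged development cross-tabulation by period count (n=3107)."""
    return _load_fixture("development_periods.csv", GridKind.PERIODS)


def load_development_age_crosstab() -> Crosstab:
    """The packaged development cross-tabulation by age (n=3107, ages 38-66)."""
    return _load_fixture("development_ages.csv", GridKind.AGE)
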