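"""Region x row summary table: counts, percentages, suppression markers.

The cross-tabulation reported by the analysis has one column per region
stratum plus a total column, and rows for physician counts, sex, career
stages, per-service provider counts and the distribution of the number of
services provided.  Cells carry a raw count (when known), a display value
(exact count, ``0``, a suppressed marker such as ``<=6``, or a range like
``962-967``) and an integer percentage of the stratum denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import UndefinedPercentageError

#: Column order: the four strata then the row total.
COLUMNS = ("north_rural", "north_urban", "south_rural", "south_urban", "total")
REGION_COLUMNS = COLUMNS[:-1]


def percentage(numerator: int, denominator: int, decimals: int = 0) -> float | int:
    """``100 * numerator / denominator`` rounded half-up to *decimals*.

    Round-half-up (not banker's rounding) reproduces every checkable printed
    percentage in the reference summary.
    """
    if denominator == 0:
        raise UndefinedPercentageError(
            f"percentage undefined: {numerator}/{denominator}"
        )
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return int(value) if decimals == 0 else float(value)


@dataclass(frozen=True)
class RangeTotal:
    """A total over a row with suppressed cells, expressed as [low, high]."""

    low: int
    high: int

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"range total reversed: {self.low} > {self.high}")

    def __str__(self) -> str:
        return f"{self.low}-{self.high}"

    def __contains__(self, value: int) -> bool:
        return self.low <= value <= self.high


@dataclass(frozen=True)
class Cell:
    """One table cell.

    ``raw`` is the true count where known (``None`` for suppressed cells of
    the packaged reference fixture, whose true values were never published).
    ``display`` is what a disclosure-safe table prints.
    """

    raw: int | None
    display: str
    percent: float | int | None = None
    range: RangeTotal | None = None

    @property
    def is_suppressed(self) -> bool:
        return self.display.startswith("<=")

    @property
    def is_range(self) -> bool:
        return self.range is not None

    @property
    def value(self) -> int:
        """The raw count; raises if unknown."""
        if self.raw is None:
            raise ValueError(f"cell {self.display!r} has no known raw count")
        return self.raw


# row kinds, used to select row families without string-matching labels
KIND_PHYSICIANS = "physicians"
KIND_FEMALE = "female"
KIND_STAGE = "stage"
KIND_SERVICE = "service"
KIND_NSERVICES = "n_services"
KIND_DIAGNOSTIC = "diagnostic"


@dataclass
class Row:
    row_id: str
    label: str
    kind: str
    cells: dict[str, Cell]

    def cell(self, column: str) -> Cell:
        return self.cells[column]

    @property
    def region_cells(self) -> list[Cell]:
        return [self.cells[c] for c in REGION_COLUMNS]


@dataclass
class RegionalSummaryTable:
    """Ordered rows x (four strata + total) of :class:`Cell` values."""

    rows: list[Row] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def row(self, row_id: str) -> Row:
        for r in self.rows:
            if r.row_id == row_id:
                return r
        raise KeyError(row_id)

    def cell(self, row_id: str, column: str) -> Cell:
        return self.row(row_id).cell(column)

    def rows_of_kind(self, kind: str) -> list[Row]:
        return [r for r in self.rows if r.kind == kind]

    @property
    def row_ids(self) -> list[str]:
        return [r.row_id for r in self.rows]

    def to_dataframe(self, view: str = "display") -> pd.DataFrame:
        """Tabular view: ``display`` (strings as printed) or ``raw`` (counts).

        In the raw view, range totals appear as ``None`` alongside unknown
        suppressed cells — neither has a single true count.
        """
        records = {}
        for r in self.rows:
            if view == "display":
                records[r.label] = {
                    c: (f"{cell.display} ({cell.percent}%)" if cell.percent is not None else cell.display)
                    for c, cell in r.cells.items()
                }
            elif view == "raw":
                records[r.label] = {c: cell.raw for c, cell in r.cells.items()}
            else:
                raise ValueError(f"unknown view {view!r}")
        df = pd.DataFrame.from_dict(records, orient="index")
        return df.reindex(columns=list(COLUMNS))
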