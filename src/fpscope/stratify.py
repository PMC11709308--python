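"""Geographic and career-stage stratification of physicians.

Physicians are placed in a 2x2 matrix of geography (north vs. south of
Ontario) and rurality (rural vs. urban).  North membership is determined by
the physician's health-region code belonging to a configured set — by default
the two former northern LHINs (Local Health Integration Networks).  Rurality
uses the Rurality Index of Ontario (RIO), a 0-100 community score: a RIO
score >= 40 classifies the practice as rural (the cutoff is a parameter so
sensitivity analyses remain possible; 40 is the conventional ICES cutoff).

Career stage bins years in practice into <10, 10-19, 20-29 and >29 years,
read as the half-open intervals [0,10), [10,20), [20,30), [30,inf).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Mapping

from .errors import UnknownRegionError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .ingest import PhysicianRecord

#: Default RIO cutoff: score >= 40 is rural.
DEFAULT_RURAL_CUTOFF = 40

#: Identifiers of the two former northern LHINs (North East, North West).
DEFAULT_NORTH_REGION_CODES = frozenset({"LHIN-13", "LHIN-14"})

#: Default universe of Ontario health-region identifiers (the 14 former LHINs).
DEFAULT_REGION_CODE_UNIVERSE = frozenset(f"LHIN-{i:02d}" for i in range(1, 15))


class Region(str, Enum):
    """The four study strata."""

    NORTH_RURAL = "north_rural"
    NORTH_URBAN = "north_urban"
    SOUTH_RURAL = "south_rural"
    SOUTH_URBAN = "south_urban"


class CareerStage(str, Enum):
    """Years-in-practice bins."""

    LT10 = "lt10"
    S10_19 = "s10_19"
    S20_29 = "s20_29"
    GT29 = "gt29"


#: Display labels matching the published bin names.
CAREER_STAGE_LABELS = {
    CareerStage.LT10: "<10",
    CareerStage.S10_19: "10-19",
    CareerStage.S20_29: "20-29",
    CareerStage.GT29: ">29",
}

REGION_ORDER = (
    Region.NORTH_RURAL,
    Region.NORTH_URBAN,
    Region.SOUTH_RURAL,
    Region.SOUTH_URBAN,
)
STAGE_ORDER = (
    CareerStage.LT10,
    CareerStage.S10_19,
    CareerStage.S20_29,
    CareerStage.GT29,
)


@dataclass(frozen=True)
class StratumAssignment:
    physician_id: str
    region: Region
    career_stage: CareerStage


def assign_region(
    physician: "PhysicianRecord",
    north_region_codes: Iterable[str] = DEFAULT_NORTH_REGION_CODES,
    rural_cutoff: int = DEFAULT_RURAL_CUTOFF,
    region_code_universe: Iterable[str] | None = DEFAULT_REGION_CODE_UNIVERSE,
) -> Region:
    """Assign the 2x2 region stratum for one physician.

    Raises
    ------
    UnknownRegionError
        If the physician's ``region_code`` is outside the configured universe.
    """
    north = frozenset(north_region_codes)
    if region_code_universe is not None:
        universe = frozenset(region_code_universe) | north
        if physician.region_code not in universe:
            raise UnknownRegionError(
                f"physician {physician.physician_id!r}: region code "
                f"{physician.region_code!r} is not in the configured universe"
            )
    is_north = physician.region_code in north
    is_rural = physician.rio_score >= rural_cutoff
    if is_north:
        return Region.NORTH_RURAL if is_rural else Region.NORTH_URBAN
    return Region.SOUTH_RURAL if is_rural else Region.SOUTH_URBAN


def career_stage(years_in_practice: float) -> CareerStage:
    """Bin years in practice into the four career-stage categories."""
    if years_in_practice < 0:
        raise ValidationError(f"years_in_practice must be >= 0, got {years_in_practice}")
    if years_in_practice < 10:
        return CareerStage.LT10
    if years_in_practice < 20:
        return CareerStage.S10_19
    if years_in_practice < 30:
        return CareerStage.S20_29
    return CareerStage.GT29


def assign_strata(
    physicians: Iterable["PhysicianRecord"],
    north_region_codes: Iterable[str] = DEFAULT_NORTH_REGION_CODES,
    rural_cutoff: int = DEFAULT_RURAL_CUTOFF,
    region_code_universe: Iterable[str] | None = DEFAULT_REGION_CODE_UNIVERSE,
) -> dict[str, StratumAssignment]:
    """Assign every physician a region and career stage, keyed by id."""
    out: dict[str, StratumAssignment] = {}
    for p in physicians:
        out[p.physician_id] = StratumAssignment(
            physician_id=p.physician_id,
            region=assign_region(p, north_region_codes, rural_cutoff, region_code_universe),
            career_stage=career_stage(p.years_in_practice),
        )
    return out


def stratum_sizes(strata: Mapping[str, StratumAssignment]) -> dict[Region, int]:
    sizes = {r: 0 for r in REGION_ORDER}
    for a in strata.values():
        sizes[a.region] += 1
    return sizes
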