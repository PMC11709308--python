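"""Service-combination analysis: exclusive subset counts per region stratum.

For each region, physicians' provided-service sets are restricted to the
k most-provided services (k = 6 by default, selected over the whole cohort)
and tallied by *exact* restricted set — standard UpSet semantics, where each
physician contributes to exactly one combination bar, including an explicit
empty combination for physicians providing none of the selected services.
Each combination also carries its career-stage composition, and the
distribution of the total number of services (over all 18, not just the
selected ones) is computed per region, cross-classified by career stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .classify import ServiceProfile
from .errors import FpscopeError
from .stratify import REGION_ORDER, STAGE_ORDER, CareerStage, Region, StratumAssignment
from .summary import KIND_SERVICE, RegionalSummaryTable


@dataclass
class CombinationRecord:
    """One exclusive combination bar: members, count, stage composition."""

    combination: frozenset[str]          # abbrevs, subset of the selected list
    count: int
    proportion: float
    stage_composition: dict[CareerStage, int] = field(default_factory=dict)


def top_k_services(
    table: RegionalSummaryTable,
    k: int = 6,
    scope: str = "total",
) -> list[str]:
    """The k services with most providers, by descending count in *scope*.

    *scope* is a region column or ``"total"`` (the default: the published
    selection is global — the same six services caption every regional
    plot).  Ties break by taxonomy order, i.e. the order of service rows in
    the table, making the ranking deterministic.  Returns service row ids
    with their ``svc_`` prefix stripped (service ids).
    """
    if k < 1:
        raise FpscopeError(f"k must be >= 1, got {k}")
    rows = table.rows_of_kind(KIND_SERVICE)
    if k > len(rows):
        raise FpscopeError(f"k={k} exceeds the {len(rows)} services in the table")
    # stable sort: ties keep taxonomy order
    ranked = sorted(
        enumerate(rows),
        key=lambda ir: (-_rank_count(ir[1].cells[scope]), ir[0]),
    )
    return [r.row_id.removeprefix("svc_") for _, r in ranked[:k]]


def _rank_count(cell) -> int:
    if cell.raw is not None:
        return cell.raw
    if cell.range is not None:  # range total: rank by its midpoint
        return (cell.range.low + cell.range.high) // 2
    return 0  # suppressed region cell of the fixture: at most 6 providers


def combination_counts(
    profiles: Iterable[ServiceProfile],
    selected: list[str],
    strata: Mapping[str, StratumAssignment],
    *,
    inclusive: bool = False,
) -> list[CombinationRecord]:
    """Tally physicians by their provided-set restricted to *selected*.

    Exclusive (default) counting assigns each physician to the single record
    matching their exact restricted subset; counts over all records
    (including the empty combination) partition the cohort.  ``inclusive``
    switches to "at least these services" counting for sensitivity analyses,
    in which case counts overlap and no partition law holds.

    Records are sorted by count descending, ties lexicographically on the
    sorted combination members.
    """
    if not selected:
        raise FpscopeError("selected service list is empty")
    profiles = list(profiles)
    tallies: dict[frozenset[str], CombinationRecord] = {}
    denom = len(profiles)
    for prof in profiles:
        restricted = frozenset(s for s in selected if prof.provided.get(s, False))
        keys: list[frozenset[str]]
        if inclusive:
            keys = [k for k in _powerset(selected) if k <= restricted]
        else:
            keys = [restricted]
        for key in keys:
            rec = tallies.get(key)
            if rec is None:
                rec = tallies[key] = CombinationRecord(
                    combination=key, count=0, proportion=0.0,
                    stage_composition={s: 0 for s in STAGE_ORDER},
                )
            rec.count += 1
            stage = strata[prof.physician_id].career_stage
            rec.stage_composition[stage] += 1
    if not inclusive and denom and frozenset() not in tallies:
        # no empty-set physicians: still emit the record so the partition is explicit
        tallies[frozenset()] = CombinationRecord(
            combination=frozenset(), count=0, proportion=0.0,
            stage_composition={s: 0 for s in STAGE_ORDER},
        )
    for rec in tallies.values():
        rec.proportion = rec.count / denom if denom else 0.0
    return sorted(
        tallies.values(), key=lambda r: (-r.count, tuple(sorted(r.combination)))
    )


def _powerset(selected: list[str]) -> list[frozenset[str]]:
    out = [frozenset()]
    for s in selected:
        out += [prev | {s} for prev in out]
    return out


def combinations_by_region(
    profiles: Mapping[str, ServiceProfile],
    selected: list[str],
    strata: Mapping[str, StratumAssignment],
) -> dict[Region, list[CombinationRecord]]:
    """Exclusive combination records for each of the four region strata."""
    by_region: dict[Region, list[ServiceProfile]] = {r: [] for r in REGION_ORDER}
    for pid, prof in profiles.items():
        by_region[strata[pid].region].append(prof)
    return {
        region: combination_counts(members, selected, strata)
        for region, members in by_region.items()
    }


def services_count_distribution(
    profiles: Mapping[str, ServiceProfile],
    strata: Mapping[str, StratumAssignment],
) -> dict[Region, dict[int, dict[CareerStage, int]]]:
    """Per region: n_services -> career stage -> physician count.

    Uses the full 18-service ``n_services``, not the top-k restriction.
    """
    out: dict[Region, dict[int, dict[CareerStage, int]]] = {r: {} for r in REGION_ORDER}
    for pid, prof in profiles.items():
        a = strata[pid]
        per_n = out[a.region].setdefault(
            prof.n_services, {s: 0 for s in STAGE_ORDER}
        )
        per_n[a.career_stage] += 1
    return out


def export_upset_matrix(
    records: Iterable[CombinationRecord],
    selected: list[str],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Plot-ready membership matrix: one row per combination.

    Columns are one boolean per selected service (in the selected order),
    then ``count``, ``proportion`` and one column per career stage.  The
    frame is directly convertible to the boolean MultiIndex series consumed
    by UpSet plotting tools; with *path* it is also written as CSV.
    """
    rows = []
    for rec in records:
        row: dict = {s: (s in rec.combination) for s in selected}
        row["count"] = rec.count
        row["proportion"] = rec.proportion
        for stage in STAGE_ORDER:
            row[f"stage_{stage.value}"] = rec.stage_composition.get(stage, 0)
        rows.append(row)
    columns = list(selected) + ["count", "proportion"] + [
        f"stage_{s.value}" for s in STAGE_ORDER
    ]
    df = pd.DataFrame(rows, columns=columns)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def import_upset_matrix(path: str | Path, selected: list[str]) -> list[CombinationRecord]:
    """Inverse of :func:`export_upset_matrix` (CSV round-trip)."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            combo = frozenset(s for s in selected if row[s] == "True")
            records.append(CombinationRecord(
                combination=combo,
                count=int(row["count"]),
                proportion=float(row["proportion"]),
                stage_composition={
                    s: int(row[f"stage_{s.value}"]) for s in STAGE_ORDER
                },
            ))
    return records
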