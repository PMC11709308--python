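"""Regional cross-tabulation and small-cell suppression.

:func:`cross_tabulate` produces the raw region x row summary: physician
totals, female counts, career-stage counts, per-service provider counts and
the number-of-services distribution, each with integer percentages of the
stratum denominator (all physicians in the stratum, whether or not they
provide any defined service).

:func:`suppress` applies the privacy rule used for small cells in Ontario
health-administrative reporting: any nonzero count up to the cutoff (default
6) is displayed as a ``<=6`` marker — explicit zeros are printed, not
suppressed — and the total of a row containing k suppressed cells becomes a
range, since each suppressed cell's true value is only known to lie in
[1, cutoff]:  low = unsuppressed sum + k, high = unsuppressed sum + k*cutoff.
Raw counts are retained internally on every cell, so suppression is a pure
display transformation and is idempotent.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

from .classify import ServiceProfile
from .errors import ConsistencyError, FpscopeError
from .stratify import (
    CAREER_STAGE_LABELS,
    REGION_ORDER,
    STAGE_ORDER,
    StratumAssignment,
)
from .summary import (
    KIND_DIAGNOSTIC,
    KIND_FEMALE,
    KIND_NSERVICES,
    KIND_PHYSICIANS,
    KIND_SERVICE,
    KIND_STAGE,
    REGION_COLUMNS,
    Cell,
    RangeTotal,
    RegionalSummaryTable,
    Row,
    percentage,
)
from .taxonomy import SentinelRegistry

#: Smallest n-services value pooled into the open-ended top bin (">=8").
NSERVICES_TOP_BIN = 8

DEFAULT_SUPPRESSION_CUTOFF = 6


def _make_row(row_id, label, kind, region_counts, denominators, with_percent=True):
    cells = {}
    for col, n, denom in zip(REGION_COLUMNS, region_counts, denominators[:-1]):
        pct = percentage(n, denom) if (with_percent and denom > 0) else None
        cells[col] = Cell(raw=n, display=str(n), percent=pct)
    total = sum(region_counts)
    pct = percentage(total, denominators[-1]) if (with_percent and denominators[-1] > 0) else None
    cells["total"] = Cell(raw=total, display=str(total), percent=pct)
    return Row(row_id=row_id, label=label, kind=kind, cells=cells)


def cross_tabulate(
    profiles: Mapping[str, ServiceProfile],
    strata: Mapping[str, StratumAssignment],
    registry: SentinelRegistry,
    sexes: Mapping[str, str] | None = None,
) -> RegionalSummaryTable:
    """Build the raw (unsuppressed) regional summary table.

    *sexes* maps physician id to sex for the female-count row; when omitted
    the row is skipped.  Every profile must have a stratum assignment.

    Physicians providing zero defined services are reported in a separate
    diagnostic row rather than inside the published 1..>=8 distribution, and
    they remain in every stratum denominator.
    """
    missing = set(profiles) - set(strata)
    if missing:
        raise ConsistencyError(
            f"{len(missing)} profiles lack a stratum assignment, e.g. "
            f"{sorted(missing)[:3]}"
        )

    by_region: dict = {r: [] for r in REGION_ORDER}
    for pid, prof in profiles.items():
        by_region[strata[pid].region].append(prof)
    n_by_region = [len(by_region[r]) for r in REGION_ORDER]
    denominators = n_by_region + [sum(n_by_region)]

    table = RegionalSummaryTable(meta={"denominators": dict(zip(REGION_COLUMNS, n_by_region))})
    table.rows.append(
        _make_row("total_physicians", "Total Physicians", KIND_PHYSICIANS,
                  n_by_region, denominators, with_percent=False)
    )

    if sexes is not None:
        fem = [sum(1 for p in by_region[r] if sexes.get(p.physician_id) == "female")
               for r in REGION_ORDER]
        table.rows.append(_make_row("female", "Total Females", KIND_FEMALE,
                                    fem, denominators))

    for stage in STAGE_ORDER:
        counts = [
            sum(1 for p in by_region[r] if strata[p.physician_id].career_stage == stage)
            for r in REGION_ORDER
        ]
        table.rows.append(
            _make_row(f"stage_{stage.value.lstrip('s')}", CAREER_STAGE_LABELS[stage],
                      KIND_STAGE, counts, denominators)
        )

    for svc in registry.services:
        counts = [sum(1 for p in by_region[r] if p.provided[svc.service_id])
                  for r in REGION_ORDER]
        table.rows.append(
            _make_row(f"svc_{svc.service_id}", svc.display_name, KIND_SERVICE,
                      counts, denominators)
        )

    for k in range(1, NSERVICES_TOP_BIN):
        counts = [sum(1 for p in by_region[r] if p.n_services == k)
                  for r in REGION_ORDER]
        table.rows.append(
            _make_row(f"nsvc_{k}", str(k), KIND_NSERVICES, counts, denominators)
        )
    counts = [sum(1 for p in by_region[r] if p.n_services >= NSERVICES_TOP_BIN)
              for r in REGION_ORDER]
    table.rows.append(
        _make_row(f"nsvc_{NSERVICES_TOP_BIN}plus", f">={NSERVICES_TOP_BIN}",
                  KIND_NSERVICES, counts, denominators)
    )
    counts = [sum(1 for p in by_region[r] if p.n_services == 0) for r in REGION_ORDER]
    table.rows.append(
        _make_row("nsvc_0", "0 (no defined service)", KIND_DIAGNOSTIC,
                  counts, denominators)
    )
    return table


def _suppress_row(row: Row, cutoff: int) -> Row:
    new_cells: dict[str, Cell] = {}
    k = 0
    unsuppressed_sum = 0
    for col in REGION_COLUMNS:
        cell = row.cells[col]
        if cell.raw is None:  # already-masked fixture cell
            k += 1
            new_cells[col] = cell
        elif 1 <= cell.raw <= cutoff:
            k += 1
            new_cells[col] = replace(cell, display=f"<={cutoff}")
        else:
            unsuppressed_sum += cell.raw
            new_cells[col] = replace(cell, display=str(cell.raw))
    total = row.cells["total"]
    if k == 0:
        new_cells["total"] = total
    else:
        rng = RangeTotal(unsuppressed_sum + k, unsuppressed_sum + k * cutoff)
        new_cells["total"] = replace(total, display=str(rng), range=rng)
    return Row(row_id=row.row_id, label=row.label, kind=row.kind, cells=new_cells)


def suppress(
    table: RegionalSummaryTable, cutoff: int = DEFAULT_SUPPRESSION_CUTOFF
) -> RegionalSummaryTable:
    """Apply small-cell suppression to a raw summary table.

    Counts in [1, cutoff] display as ``<=cutoff``; zeros stay zeros.  A row
    total over k >= 1 suppressed cells becomes the range
    [unsuppressed sum + k, unsuppressed sum + k*cutoff].  Cohort size rows
    (total physicians) are left exact: denominators are not person-level
    attributes.  Raw counts stay attached to every cell, so applying suppress
    again yields the identical table.
    """
    if cutoff < 1:
        raise FpscopeError(f"suppression cutoff must be >= 1, got {cutoff}")
    out = RegionalSummaryTable(meta=dict(table.meta))
    out.meta["suppression_cutoff"] = cutoff
    for row in table.rows:
        if row.kind == KIND_PHYSICIANS:
            out.rows.append(row)
        else:
            out.rows.append(_suppress_row(row, cutoff))
    return out
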