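"""End-to-end pipeline: ingest -> classify -> stratify -> aggregate -> combos.

:func:`run_profile` ties the stages together for one study year and writes a
report bundle (per-physician profiles, raw and suppressed summary tables,
combination tables and UpSet matrices per region, the services-count
distribution, and a machine-readable run log).  :func:`run_validate_fixture`
re-derives every checkable quantity in the packaged reference summary —
row totals, printed percentages, suppression ranges, the northern share —
and reports pass/fail per check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import aggregate, setcombo
from .classify import build_profiles, profiles_to_frame
from .ingest import (
    drop_unregistered_claims,
    load_reference_summary,
    read_claims,
    read_physicians,
)
from .stratify import (
    DEFAULT_NORTH_REGION_CODES,
    DEFAULT_REGION_CODE_UNIVERSE,
    DEFAULT_RURAL_CUTOFF,
    STAGE_ORDER,
    assign_strata,
)
from .summary import REGION_COLUMNS, RegionalSummaryTable, percentage
from .taxonomy import default_registry, load_registry


@dataclass
class PipelineConfig:
    """Settings for one profiling run (mirrors the CLI flags)."""

    registry_path: str | Path
    claims_path: str | Path
    output_dir: str | Path
    study_year: int = 2017
    taxonomy_path: str | Path | None = None          # None = packaged default
    north_region_codes: tuple[str, ...] = tuple(sorted(DEFAULT_NORTH_REGION_CODES))
    region_code_universe: tuple[str, ...] | None = tuple(sorted(DEFAULT_REGION_CODE_UNIVERSE))
    rural_cutoff: int = DEFAULT_RURAL_CUTOFF
    suppression_cutoff: int = aggregate.DEFAULT_SUPPRESSION_CUTOFF
    top_k: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class ReportBundle:
    """In-memory results of a profiling run plus where they were written."""

    profiles: dict
    strata: dict
    raw_table: RegionalSummaryTable
    suppressed_table: RegionalSummaryTable
    selected_services: list[str]
    combinations: dict
    services_count: dict
    run_log: dict
    output_dir: Path | None = None


def _load_taxonomy(cfg: PipelineConfig):
    if cfg.taxonomy_path is None:
        return default_registry()
    with open(cfg.taxonomy_path, encoding="utf-8") as fh:
        return load_registry(yaml.safe_load(fh))


def _table_to_json(table: RegionalSummaryTable) -> list[dict]:
    rows = []
    for row in table.rows:
        cells = {}
        for col, cell in row.cells.items():
            cells[col] = {
                "raw": cell.raw,
                "display": cell.display,
                "percent": cell.percent,
                "range": [cell.range.low, cell.range.high] if cell.range else None,
            }
        rows.append({"row_id": row.row_id, "label": row.label,
                     "kind": row.kind, "cells": cells})
    return rows


def run_profile(cfg: PipelineConfig, write: bool = True) -> ReportBundle:
    """Execute the full profiling pipeline for one study year."""
    registry = _load_taxonomy(cfg)

    physician_result = read_physicians(cfg.registry_path)
    physicians = [p for p in physician_result.records if p.is_family_practice]
    n_excluded = len(physician_result.records) - len(physicians)

    claims_result = read_claims(cfg.claims_path, cfg.study_year)
    claims, n_unregistered = drop_unregistered_claims(
        claims_result.records, physicians
    )

    cohort_ids = [p.physician_id for p in physicians]
    profiles, count_result = build_profiles(claims, registry, cohort_ids)
    strata = assign_strata(
        physicians, cfg.north_region_codes, cfg.rural_cutoff,
        cfg.region_code_universe,
    )
    sexes = {p.physician_id: p.sex for p in physicians}

    raw_table = aggregate.cross_tabulate(profiles, strata, registry, sexes)
    suppressed = aggregate.suppress(raw_table, cfg.suppression_cutoff)

    selected = setcombo.top_k_services(raw_table, cfg.top_k)
    combos = setcombo.combinations_by_region(profiles, selected, strata)
    services_count = setcombo.services_count_distribution(profiles, strata)

    run_log = {
        "study_year": cfg.study_year,
        "physician_rows_accepted": len(physician_result.records),
        "physician_rows_rejected": len(physician_result.rejected),
        "physicians_excluded_not_family_practice": n_excluded,
        "cohort_size": len(cohort_ids),
        "claim_rows_accepted": len(claims_result.records),
        "claim_rows_rejected": len(claims_result.rejected),
        "claims_dropped_out_of_year": claims_result.dropped_out_of_year,
        "claims_dropped_unregistered_physician": n_unregistered,
        "unclassified_events": count_result.total_unclassified,
        "selected_services": selected,
        "config": {
            "north_region_codes": list(cfg.north_region_codes),
            "rural_cutoff": cfg.rural_cutoff,
            "suppression_cutoff": cfg.suppression_cutoff,
            "top_k": cfg.top_k,
        },
    }

    bundle = ReportBundle(
        profiles=profiles, strata=strata, raw_table=raw_table,
        suppressed_table=suppressed, selected_services=selected,
        combinations=combos, services_count=services_count, run_log=run_log,
    )
    if write:
        bundle.output_dir = _write_bundle(bundle, registry, cfg)
    return bundle


def _write_bundle(bundle: ReportBundle, registry, cfg: PipelineConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles_to_frame(bundle.profiles, registry).to_csv(
        out / "physician_profiles.csv", index=False
    )
    bundle.raw_table.to_dataframe("raw").to_csv(out / "summary_raw.csv")
    bundle.suppressed_table.to_dataframe("display").to_csv(out / "summary_suppressed.csv")
    with open(out / "summary_tables.json", "w", encoding="utf-8") as fh:
        json.dump({
            "raw": _table_to_json(bundle.raw_table),
            "suppressed": _table_to_json(bundle.suppressed_table),
        }, fh, indent=2)
    for region, records in bundle.combinations.items():
        setcombo.export_upset_matrix(
            records, bundle.selected_services,
            out / f"upset_{region.value}.csv",
        )
    rows = []
    for region, dist in bundle.services_count.items():
        for n in sorted(dist):
            row = {"region": region.value, "n_services": n}
            for stage in STAGE_ORDER:
                row[f"stage_{stage.value}"] = dist[n][stage]
            row["count"] = sum(dist[n].values())
            rows.append(row)
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "services_count_distribution.csv", index=False)
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.run_log, fh, indent=2)
    return out


@dataclass
class FixtureCheck:
    name: str
    expected: object
    actual: object

    @property
    def passed(self) -> bool:
        return self.expected == self.actual


@dataclass
class FixtureCheckReport:
    checks: list[FixtureCheck] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> list[FixtureCheck]:
        return [c for c in self.checks if not c.passed]

    def add(self, name, expected, actual):
        self.checks.append(FixtureCheck(name, expected, actual))


def run_validate_fixture(
    table: RegionalSummaryTable | None = None,
) -> FixtureCheckReport:
    """Recompute every derivable quantity in the reference summary.

    Checks, per row: the total equals the sum of the four region cells when
    all are unsuppressed; every printed percentage equals the round-half-up
    percentage of its cell count over the stratum denominator; every
    range-valued total equals the range implied by the suppression rule.
    Also checks the column-wise consistency of the career-stage and
    number-of-services blocks and the province-level northern share (to one
    decimal).
    """
    table = table if table is not None else load_reference_summary()
    report = FixtureCheckReport()
    denom = {col: table.cell("total_physicians", col).value
             for col in REGION_COLUMNS}
    denom["total"] = table.cell("total_physicians", "total").value

    for row in table.rows:
        cells = [row.cells[c] for c in REGION_COLUMNS]
        total = row.cells["total"]
        if all(c.raw is not None for c in cells):
            if total.raw is not None:
                report.add(f"{row.row_id}: region cells sum to total",
                           total.raw, sum(c.raw for c in cells))
        if any(c.raw is None for c in cells) and total.range is not None:
            cut = int(table.meta.get("suppression_cutoff", 6))
            k = sum(1 for c in cells if c.raw is None)
            known = sum(c.raw for c in cells if c.raw is not None)
            report.add(f"{row.row_id}: suppression range",
                       [total.range.low, total.range.high],
                       [known + k, known + k * cut])
        for col, cell in zip(REGION_COLUMNS, cells):
            if cell.percent is not None and cell.raw is not None and denom[col]:
                report.add(f"{row.row_id}/{col}: percent",
                           cell.percent, percentage(cell.raw, denom[col]))
        if total.percent is not None and total.raw is not None:
            report.add(f"{row.row_id}/total: percent",
                       total.percent, percentage(total.raw, denom["total"]))

    # column sums of the stage and n-services blocks equal the stratum sizes
    for kind, label in (("stage", "career-stage"), ("n_services", "n-services")):
        rows = table.rows_of_kind(kind)
        for col in REGION_COLUMNS:
            if all(r.cells[col].raw is not None for r in rows):
                report.add(f"{label} column {col} sums to stratum size",
                           denom[col], sum(r.cells[col].raw for r in rows))

    north = sum(denom[c] for c in ("north_rural", "north_urban"))
    report.add("northern share of cohort (%, 1 decimal)",
               6.5, percentage(north, denom["total"], decimals=1))
    return report
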