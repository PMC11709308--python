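"""Readers for physician-registry and claims files, and the packaged
reference summary.

Input files are UTF-8 comma-separated tables with a header row.  The
physician registry has one row per physician (pseudonymous id, sex, years in
practice, health-region code, RIO rurality score, family-practice flag); the
claims file has one row per billed fee-code event (physician id, fee code,
service year, optional event multiplicity).  Column names can be remapped via
``column_map`` to accommodate other jurisdictions' extracts.

Rows that violate a field invariant are rejected individually with a
row-numbered diagnostic (collected on the returned object and logged);
structural problems — a missing column, a duplicated physician id — abort the
read with an error.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import (
    DuplicateRecordError,
    FixtureIntegrityError,
    MalformedCodeError,
    SchemaError,
)
from .summary import REGION_COLUMNS, Cell, RangeTotal, RegionalSummaryTable, Row
from .taxonomy import normalize_code

log = logging.getLogger(__name__)

SEXES = ("female", "male", "unknown")
_SEX_ALIASES = {"f": "female", "female": "female", "m": "male", "male": "male",
                "u": "unknown", "unknown": "unknown", "": "unknown"}

PHYSICIAN_COLUMNS = ("physician_id", "sex", "years_in_practice", "region_code",
                     "rio_score", "is_family_practice")
CLAIM_COLUMNS = ("physician_id", "fee_code", "service_year")

_FIXTURE_NAME = "reference_summary.yaml"
_FIXTURE_SHA256 = "2278d1c9af4e1a51fbcd5e7c0d60bacb5714105d83cdf77c8286fce1d8a8a90a"


@dataclass(frozen=True)
class PhysicianRecord:
    """One registry row: demographics and region inputs for a physician."""

    physician_id: str
    sex: str
    years_in_practice: float
    region_code: str
    rio_score: int
    is_family_practice: bool = True

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 0 <= self.rio_score <= 100:
            raise ValueError(f"rio_score must be in [0, 100], got {self.rio_score}")
        if self.years_in_practice < 0:
            raise ValueError(f"years_in_practice must be >= 0, got {self.years_in_practice}")


@dataclass(frozen=True)
class ClaimRecord:
    """One billed fee-code event (or a collapsed count of identical events)."""

    physician_id: str
    fee_code: str
    service_year: int
    n_events: int = 1

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError(f"n_events must be >= 1, got {self.n_events}")


@dataclass
class ReadResult:
    """Records accepted by a reader plus per-row rejection diagnostics."""

    records: list
    rejected: list[str] = field(default_factory=list)
    dropped_out_of_year: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _resolve_columns(
    header: Sequence[str], required: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical column names to file column names; raise if any missing."""
    column_map = dict(column_map or {})
    resolved = {}
    for name in required:
        actual = column_map.get(name, name)
        if actual not in header:
            raise SchemaError(
                f"required column {actual!r} (for {name!r}) not in header {list(header)}"
            )
        resolved[name] = actual
    return resolved


def _parse_bool(raw: str) -> bool:
    v = raw.strip().lower()
    if v in {"1", "true", "t", "yes", "y"}:
        return True
    if v in {"0", "false", "f", "no", "n", ""}:
        return False
    raise ValueError(f"unparseable boolean {raw!r}")


def read_physicians(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> ReadResult:
    """Read and validate a physician-registry CSV.

    Returns a :class:`ReadResult` of :class:`PhysicianRecord`.  Rows failing a
    field invariant are rejected with a row-numbered diagnostic; a duplicated
    physician id aborts with :class:`DuplicateRecordError`.
    """
    records: list[PhysicianRecord] = []
    rejected: list[str] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        cols = _resolve_columns(reader.fieldnames, PHYSICIAN_COLUMNS, column_map)
        for lineno, row in enumerate(reader, start=2):
            pid = (row[cols["physician_id"]] or "").strip()
            if pid in seen:
                raise DuplicateRecordError(
                    f"{path}:{lineno}: duplicate physician_id {pid!r}"
                )
            try:
                rec = PhysicianRecord(
                    physician_id=pid,
                    sex=_SEX_ALIASES.get(row[cols["sex"]].strip().lower(),
                                         row[cols["sex"]].strip().lower()),
                    years_in_practice=float(row[cols["years_in_practice"]]),
                    region_code=row[cols["region_code"]].strip(),
                    rio_score=int(row[cols["rio_score"]]),
                    is_family_practice=_parse_bool(row[cols["is_family_practice"]]),
                )
                if not pid:
                    raise ValueError("physician_id is empty")
            except ValueError as exc:
                rejected.append(f"{path}:{lineno}: {exc}")
                continue
            seen.add(pid)
            records.append(rec)
    log.info("read_physicians(%s): accepted %d rows, rejected %d",
             path, len(records), len(rejected))
    for msg in rejected:
        log.warning("rejected row: %s", msg)
    return ReadResult(records=records, rejected=rejected)


def read_claims(
    path: str | Path,
    study_year: int,
    column_map: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read a claims CSV, normalizing fee codes and filtering to *study_year*.

    Claims outside the study year are dropped (counted, not rejected);
    rows with a blank fee code or unparseable year are rejected with a
    diagnostic.  An optional ``n_events`` column collapses identical claim
    lines into a count (default 1).
    """
    records: list[ClaimRecord] = []
    rejected: list[str] = []
    dropped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        cols = _resolve_columns(reader.fieldnames, CLAIM_COLUMNS, column_map)
        n_events_col = (column_map or {}).get("n_events", "n_events")
        has_n_events = n_events_col in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            try:
                year = int(row[cols["service_year"]])
            except ValueError:
                rejected.append(f"{path}:{lineno}: unparseable service_year "
                                f"{row[cols['service_year']]!r}")
                continue
            if year != study_year:
                dropped += 1
                continue
            try:
                code = normalize_code(row[cols["fee_code"]])
            except MalformedCodeError as exc:
                rejected.append(f"{path}:{lineno}: {exc}")
                continue
            try:
                n_events = int(row[n_events_col]) if has_n_events and row[n_events_col] else 1
                rec = ClaimRecord(
                    physician_id=row[cols["physician_id"]].strip(),
                    fee_code=code,
                    service_year=year,
                    n_events=n_events,
                )
            except ValueError as exc:
                rejected.append(f"{path}:{lineno}: {exc}")
                continue
            records.append(rec)
    log.info("read_claims(%s): accepted %d rows, rejected %d, "
             "dropped %d outside year %d",
             path, len(records), len(rejected), dropped, study_year)
    return ReadResult(records=records, rejected=rejected, dropped_out_of_year=dropped)


def write_physicians(records: Iterable[PhysicianRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PHYSICIAN_COLUMNS)
        for r in records:
            w.writerow([r.physician_id, r.sex, r.years_in_practice,
                        r.region_code, r.rio_score, r.is_family_practice])


def write_claims(records: Iterable[ClaimRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CLAIM_COLUMNS + ("n_events",))
        for r in records:
            w.writerow([r.physician_id, r.fee_code, r.service_year, r.n_events])


def drop_unregistered_claims(
    claims: Iterable[ClaimRecord], physicians: Iterable[PhysicianRecord]
) -> tuple[list[ClaimRecord], int]:
    """Drop claims whose physician is absent from the registry.

    The analysis cohort is registry-defined; claims from physicians outside
    it are discarded with a count, never silently.
    """
    ids = {p.physician_id for p in physicians}
    kept = [c for c in claims if c.physician_id in ids]
    n_dropped = sum(1 for c in claims if c.physician_id not in ids) \
        if not isinstance(claims, list) else len(claims) - len(kept)
    if n_dropped:
        log.warning("dropped %d claims from physicians not in the registry", n_dropped)
    return kept, n_dropped


def _fixture_cell(value, percent) -> Cell:
    if value == "<=6":
        return Cell(raw=None, display="<=6", percent=percent)
    value = int(value)
    return Cell(raw=value, display=str(value), percent=percent)


def load_reference_summary() -> RegionalSummaryTable:
    """Load the packaged reference regional summary.

    The fixture transcribes the published 2017 Ontario summary: suppressed
    cells become suppressed markers with unknown raw counts, range-valued
    totals become :class:`RangeTotal`, and percentages are stored exactly as
    printed (integers).  The file is checksum-verified so a silent edit of
    the reference numbers cannot masquerade as the published table.
    """
    data = resources.files("fpscope.data").joinpath(_FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"reference summary fixture checksum mismatch: {digest}"
        )
    doc = yaml.safe_load(data)
    table = RegionalSummaryTable(meta=dict(doc.get("meta", {})))
    for entry in doc["rows"]:
        percents = entry.get("percents") or [None] * 4
        cells = {
            col: _fixture_cell(v, p)
            for col, v, p in zip(REGION_COLUMNS, entry["cells"], percents)
        }
        total = entry["total"]
        tp = entry.get("total_percent")
        if isinstance(total, list):
            rng = RangeTotal(int(total[0]), int(total[1]))
            cells["total"] = Cell(raw=None, display=str(rng), percent=tp, range=rng)
        else:
            cells["total"] = Cell(raw=int(total), display=str(int(total)), percent=tp)
        table.rows.append(Row(row_id=entry["row_id"], label=entry["label"],
                              kind=entry["kind"], cells=cells))
    return table
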