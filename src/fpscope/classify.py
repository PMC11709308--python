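"""From claims to service profiles: count qualifying events, apply thresholds.

Each claim whose fee code matches a sentinel service contributes its event
count to that physician's annual tally for the service ("patient
interactions" are operationalized as claim events — the claims input carries
no patient identifiers, so distinct-patient counting is not possible; this is
a measurement assumption, stated up front).  A physician *provides* a service
when the tally reaches the service's annual threshold; the boundary is
inclusive (a count equal to the threshold qualifies).  Classification is per
study year — thresholds are annual — so multi-year inputs must be run year
by year.

Claims whose codes match no sentinel list are tallied as *unclassified*:
they never count toward any service, but their volume is the key caveat of a
sentinel-code design (activity in unlisted codes is invisible, so provider
counts are a lower bound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .ingest import ClaimRecord
from .taxonomy import SentinelRegistry


@dataclass(frozen=True)
class ServiceProfile:
    """One physician's per-service event counts and provider flags."""

    physician_id: str
    counts: Mapping[str, int]
    provided: Mapping[str, bool]
    n_services: int

    def provided_set(self) -> frozenset[str]:
        return frozenset(s for s, v in self.provided.items() if v)


@dataclass
class CountResult:
    """Per-physician service counts plus the unclassified-claims tally."""

    counts: dict[str, dict[str, int]]
    unclassified: dict[str, int]

    @property
    def total_unclassified(self) -> int:
        return sum(self.unclassified.values())


def count_service_events(
    claims: Iterable[ClaimRecord], registry: SentinelRegistry
) -> CountResult:
    """Tally qualifying events per physician per service.

    Pure and deterministic: every claim is matched independently against the
    registry, and matching claims contribute ``n_events`` to the owning
    service.  Non-matching claims accumulate in the unclassified tally.
    Physicians appear in the result only if they have at least one claim;
    absent physicians are treated as all-zero downstream.
    """
    counts: dict[str, dict[str, int]] = {}
    unclassified: dict[str, int] = {}
    for claim in claims:
        service_id = registry.match_code(claim.fee_code)
        if service_id is None:
            unclassified[claim.physician_id] = (
                unclassified.get(claim.physician_id, 0) + claim.n_events
            )
            counts.setdefault(claim.physician_id, {})
            continue
        per = counts.setdefault(claim.physician_id, {})
        per[service_id] = per.get(service_id, 0) + claim.n_events
    return CountResult(counts=counts, unclassified=unclassified)


def binarize(
    counts: Mapping[str, int], registry: SentinelRegistry, physician_id: str = ""
) -> ServiceProfile:
    """Convert one physician's service counts to a binary provider profile.

    Services absent from *counts* are zero.  ``provided[s]`` is true iff
    ``counts[s] >= threshold(s)`` — the threshold is the smallest qualifying
    count.
    """
    full: dict[str, int] = {}
    for s in registry.services:
        c = int(counts.get(s.service_id, 0))
        if c < 0:
            raise ValidationError(
                f"negative count {c} for service {s.service_id!r}"
            )
        full[s.service_id] = c
    unknown = set(counts) - set(full)
    if unknown:
        raise ValidationError(f"counts contain unknown service ids: {sorted(unknown)}")
    provided = {
        s.service_id: full[s.service_id] >= s.threshold for s in registry.services
    }
    return ServiceProfile(
        physician_id=physician_id,
        counts=full,
        provided=provided,
        n_services=sum(provided.values()),
    )


def build_profiles(
    claims: Iterable[ClaimRecord],
    registry: SentinelRegistry,
    physician_ids: Iterable[str] | None = None,
) -> tuple[dict[str, ServiceProfile], CountResult]:
    """Run the count-then-threshold pipeline for a whole cohort.

    *physician_ids*, when given, fixes the cohort: physicians with no claims
    receive an all-zero profile (they stay in every denominator), and the
    claims are assumed pre-filtered to the cohort.
    """
    result = count_service_events(claims, registry)
    ids = list(physician_ids) if physician_ids is not None else sorted(result.counts)
    profiles = {
        pid: binarize(result.counts.get(pid, {}), registry, physician_id=pid)
        for pid in ids
    }
    return profiles, result


def profiles_to_frame(
    profiles: Mapping[str, ServiceProfile], registry: SentinelRegistry
) -> pd.DataFrame:
    """One row per physician: boolean column per service abbrev, count
    columns (``n_<abbrev>``), and ``n_services``."""
    rows = []
    for pid, prof in profiles.items():
        row: dict = {"physician_id": pid}
        for s in registry.services:
            row[s.abbrev] = bool(prof.provided[s.service_id])
        for s in registry.services:
            row[f"n_{s.abbrev}"] = int(prof.counts[s.service_id])
        row["n_services"] = prof.n_services
        rows.append(row)
    columns = (["physician_id"] + [s.abbrev for s in registry.services]
               + [f"n_{s.abbrev}" for s in registry.services] + ["n_services"])
    return pd.DataFrame(rows, columns=columns)
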