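"""Sentinel fee-code taxonomy: services, code-matching rules, thresholds.

A *sentinel* fee code is a billing code unique to one broad service, so the
presence of that code in a physician's claims marks activity in that service.
The taxonomy groups Ontario OHIP fee codes into 18 such services (clinic,
emergency medicine, obstetrics, ...).  Each service owns

* a set of explicit codes (``A007``, ``H133``, ...),
* zero or more numeric code ranges (``Z491-Z499``), and
* zero or more single-character suffix rules (surgical assisting claims any
  code ending in ``B``),

plus an annual threshold: the minimum number of qualifying billed events per
year for a physician to be considered a provider of the service.

Matching precedence is explicit codes and ranges first, suffix rules last:
several anaesthesia codes carry a ``C`` suffix yet are explicitly listed, so
explicit ownership must dominate generic suffix capture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import yaml

from .errors import ConfigError, MalformedCodeError, TaxonomyConflictError

#: Number of services in the standard Ontario taxonomy.
STANDARD_SERVICE_COUNT = 18

_RANGE_RE = re.compile(r"^([A-Z]+)(\d+)-([A-Z]*)(\d+)$")
_CODE_RE = re.compile(r"^[A-Z]+\d+[A-Z]?$")


def normalize_code(raw: str) -> str:
    """Normalize a raw fee-code string: trim whitespace, uppercase.

    Raises
    ------
    MalformedCodeError
        If the code is empty (or whitespace only).
    """
    if raw is None:
        raise MalformedCodeError("fee code is missing")
    code = str(raw).strip().upper()
    if not code:
        raise MalformedCodeError(f"fee code is empty after trimming: {raw!r}")
    return code


@dataclass(frozen=True)
class CodeRange:
    """An inclusive range of fee codes sharing an alphabetic prefix.

    ``CodeRange("Z", 491, 499, width=3)`` matches Z491 ... Z499.  The range is
    stored symbolically and matched by prefix plus numeric comparison, which
    keeps the registry auditable against the shipped config.
    """

    prefix: str
    start: int
    end: int
    width: int

    def __post_init__(self):
        if self.start > self.end:
            raise ConfigError(f"range {self.prefix}{self.start}-{self.end} is reversed")

    def contains(self, code: str) -> bool:
        if not code.startswith(self.prefix):
            return False
        digits = code[len(self.prefix):]
        if len(digits) != self.width or not digits.isdigit():
            return False
        return self.start <= int(digits) <= self.end

    def expand(self) -> Iterator[str]:
        for n in range(self.start, self.end + 1):
            yield f"{self.prefix}{n:0{self.width}d}"


def _parse_range(token: str) -> CodeRange:
    m = _RANGE_RE.match(token)
    if m is None:
        raise ConfigError(f"unparseable code range: {token!r}")
    prefix, lo, prefix2, hi = m.groups()
    if prefix2 and prefix2 != prefix:
        raise ConfigError(f"range {token!r} mixes prefixes {prefix!r} and {prefix2!r}")
    if len(lo) != len(hi):
        raise ConfigError(f"range {token!r} mixes digit widths")
    return CodeRange(prefix, int(lo), int(hi), width=len(lo))


@dataclass(frozen=True)
class ServiceDefinition:
    """One broad service: its code rules and annual provider threshold."""

    service_id: str
    display_name: str
    abbrev: str
    explicit_codes: frozenset[str]
    code_ranges: tuple[CodeRange, ...] = ()
    suffix_rules: tuple[str, ...] = ()
    threshold: int = 1
    threshold_unit_label: str = "events"

    def __post_init__(self):
        if self.threshold < 1:
            raise ConfigError(
                f"service {self.service_id!r}: threshold must be >= 1, "
                f"got {self.threshold}"
            )
        if not (self.explicit_codes or self.code_ranges or self.suffix_rules):
            raise ConfigError(
                f"service {self.service_id!r} defines no codes, ranges or suffixes"
            )

    def owns_code(self, code: str) -> bool:
        """True if *code* belongs to this service via explicit list or range."""
        return code in self.explicit_codes or any(
            r.contains(code) for r in self.code_ranges
        )

    def iter_codes(self) -> Iterator[str]:
        """All explicit codes plus expanded range codes (sorted)."""
        seen = set(self.explicit_codes)
        for r in self.code_ranges:
            seen.update(r.expand())
        yield from sorted(seen)


@dataclass(frozen=True)
class SentinelRegistry:
    """The validated service taxonomy; matching is pure and deterministic."""

    services: tuple[ServiceDefinition, ...]
    _explicit_owner: Mapping[str, str] = field(repr=False, default_factory=dict)
    _suffix_owner: Mapping[str, str] = field(repr=False, default_factory=dict)

    @property
    def service_ids(self) -> tuple[str, ...]:
        return tuple(s.service_id for s in self.services)

    def service(self, service_id: str) -> ServiceDefinition:
        for s in self.services:
            if s.service_id == service_id:
                return s
        raise KeyError(service_id)

    def by_abbrev(self, abbrev: str) -> ServiceDefinition:
        for s in self.services:
            if s.abbrev == abbrev:
                return s
        raise KeyError(abbrev)

    def threshold(self, service_id: str) -> int:
        return self.service(service_id).threshold

    def code_universe(self) -> dict[str, str]:
        """Every explicit/range code in the registry, mapped to its owner."""
        return dict(self._explicit_owner)

    def match_code(self, code: str) -> str | None:
        """Resolve a normalized fee code to the service that owns it.

        Explicit codes and ranges take precedence over suffix rules; a code
        matching nothing returns ``None`` (no-match is a value, not an error).
        """
        owner = self._explicit_owner.get(code)
        if owner is not None:
            return owner
        # ranges are checked symbolically; _explicit_owner already covers them
        # for codes inside the configured universe, but a range can in
        # principle be wide, so fall through to the symbolic check.
        for s in self.services:
            if any(r.contains(code) for r in s.code_ranges):
                return s.service_id
        if code:
            owner = self._suffix_owner.get(code[-1])
            if owner is not None:
                return owner
        return None


def match_code(registry: SentinelRegistry, code: str) -> str | None:
    """Functional alias for :meth:`SentinelRegistry.match_code`."""
    return registry.match_code(code)


def _build_service(entry: Mapping) -> ServiceDefinition:
    try:
        service_id = entry["service_id"]
        raw_codes = entry.get("codes", []) or []
        threshold = entry["threshold"]
    except KeyError as exc:
        raise ConfigError(f"service entry missing required key: {exc}") from exc
    if "threshold" not in entry or threshold is None:
        raise ConfigError(f"service {service_id!r} has no threshold")
    explicit: set[str] = set()
    ranges: list[CodeRange] = []
    for token in raw_codes:
        token = normalize_code(token)
        if "-" in token:
            ranges.append(_parse_range(token))
        else:
            if not _CODE_RE.match(token):
                raise ConfigError(f"service {service_id!r}: malformed code {token!r}")
            explicit.add(token)  # duplicates within a service collapse silently
    suffixes = tuple(normalize_code(s) for s in entry.get("suffixes", []) or [])
    for s in suffixes:
        if len(s) != 1:
            raise ConfigError(f"service {service_id!r}: suffix rule {s!r} must be one character")
    return ServiceDefinition(
        service_id=service_id,
        display_name=entry.get("display_name", service_id),
        abbrev=entry["abbrev"],
        explicit_codes=frozenset(explicit),
        code_ranges=tuple(ranges),
        suffix_rules=suffixes,
        threshold=int(threshold),
        threshold_unit_label=entry.get("threshold_unit_label", "events"),
    )


def load_registry(
    config_document: Mapping,
    *,
    allow_nonstandard_taxonomy: bool = False,
) -> SentinelRegistry:
    """Build a validated :class:`SentinelRegistry` from a parsed config.

    Validation enforces the taxonomy invariants: exactly 18 services (unless
    ``allow_nonstandard_taxonomy`` permits reuse in other jurisdictions),
    distinct abbreviations, a threshold per service, and uniqueness of every
    code across services — sentinel codes are by construction unique to one
    service, so a duplicate is a config defect, not a tie to break.
    """
    try:
        entries = config_document["services"]
    except (KeyError, TypeError) as exc:
        raise ConfigError("taxonomy config must contain a 'services' list") from exc
    services = tuple(_build_service(e) for e in entries)

    if len(services) != STANDARD_SERVICE_COUNT and not allow_nonstandard_taxonomy:
        raise ConfigError(
            f"taxonomy defines {len(services)} services; the standard taxonomy "
            f"has {STANDARD_SERVICE_COUNT} (pass allow_nonstandard_taxonomy=True "
            "to override)"
        )
    ids = [s.service_id for s in services]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate service_id in taxonomy")
    abbrevs = [s.abbrev for s in services]
    if len(set(abbrevs)) != len(abbrevs):
        raise ConfigError("service abbreviations are not distinct")

    explicit_owner: dict[str, str] = {}
    for s in services:
        for code in s.iter_codes():
            other = explicit_owner.get(code)
            if other is not None and other != s.service_id:
                raise TaxonomyConflictError(code, other, s.service_id)
            explicit_owner[code] = s.service_id

    suffix_owner: dict[str, str] = {}
    for s in services:
        for suf in s.suffix_rules:
            other = suffix_owner.get(suf)
            if other is not None and other != s.service_id:
                raise TaxonomyConflictError(f"suffix {suf}", other, s.service_id)
            suffix_owner[suf] = s.service_id

    return SentinelRegistry(
        services=services,
        _explicit_owner=explicit_owner,
        _suffix_owner=suffix_owner,
    )


def default_registry() -> SentinelRegistry:
    """Load the packaged Ontario sentinel-code taxonomy."""
    text = resources.files("fpscope.data").joinpath("sentinel_codes.yaml").read_text()
    return load_registry(yaml.safe_load(text))
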