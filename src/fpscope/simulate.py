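"""Seeded synthetic cohort generator.

The real study inputs (a provincial physician registry and a year of billing
claims) are not distributable, so this module generates registry + claims
datasets with the statistical structure the pipeline assumes, plus the
ground-truth provider flags, making every stage testable end to end.

Default parameters are derived from the packaged reference summary: the four
stratum sizes, per-stratum female shares and career-stage mixes, and the
per-stratum per-service provision probabilities (a suppressed reference cell
— true count known only to lie in [1, 6] — gets the nominal small
probability 0.5 * 6 / stratum size).  Services are sampled independently
across services within a physician; the true joint distribution of services
is unpublished, so independence is a declared simplification, not an
inference.

The claim-count model guarantees label/classification consistency by
default: a provider of a service draws threshold + a negative-binomial
excess (overdispersed annual volumes), a non-provider draws 0 with
probability ``nonprovider_zero_prob`` and otherwise a uniform count in
[1, threshold - 1].  Counts are spread multinomially over the service's
explicit sentinel codes; non-sentinel "noise" claims use codes verified to
match no service.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .classify import ServiceProfile
from .errors import ConfigError, ConsistencyError
from .ingest import ClaimRecord, PhysicianRecord
from .stratify import REGION_ORDER, STAGE_ORDER, CareerStage, Region
from .summary import KIND_SERVICE, KIND_STAGE
from .taxonomy import SentinelRegistry, default_registry

#: Synthetic surgical-assisting codes: the service is defined only by the
#: "ends in B" suffix rule, so any suffix-B code not claimed elsewhere works.
SURGICAL_ASSIST_SAMPLING_CODES = ("S727B", "Z432B", "E668B")

#: Codes guaranteed to match no sentinel service (checked at config build).
DEFAULT_NOISE_CODES = ("Q999", "X010", "J888", "A999", "K999", "G999")

#: Career-stage year spans used to sample years_in_practice within a bin.
_STAGE_YEAR_SPANS = {
    CareerStage.LT10: (0.0, 10.0),
    CareerStage.S10_19: (10.0, 20.0),
    CareerStage.S20_29: (20.0, 30.0),
    CareerStage.GT29: (30.0, 45.0),
}

_DEFAULT_SOUTH_CODES = tuple(f"LHIN-{i:02d}" for i in range(1, 13))
_DEFAULT_NORTH_CODES = ("LHIN-13", "LHIN-14")


@dataclass(frozen=True)
class CountModel:
    """Law of annual claim counts given provider status.

    Providers draw ``threshold + NegBin(mean=excess_mean_factor*threshold,
    dispersion)``; non-providers draw 0 with probability
    ``nonprovider_zero_prob``, else uniform on [1, threshold-1].
    """

    excess_mean_factor: float = 2.0
    dispersion: float = 1.5
    nonprovider_zero_prob: float = 0.7

    def __post_init__(self):
        if not 0 <= self.nonprovider_zero_prob <= 1:
            raise ConfigError("nonprovider_zero_prob must be in [0, 1]")
        if self.excess_mean_factor < 0 or self.dispersion <= 0:
            raise ConfigError("invalid count-model parameters")


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic cohort."""

    seed: int
    n_physicians_by_region: dict[Region, int]
    female_prob_by_region: dict[Region, float]
    stage_probs_by_region: dict[Region, tuple[float, float, float, float]]
    provision_prob: dict[Region, dict[str, float]]
    count_model: CountModel = field(default_factory=CountModel)
    noise_code_rate: float = 5.0
    noise_codes: tuple[str, ...] = DEFAULT_NOISE_CODES
    study_year: int = 2017
    north_region_codes: tuple[str, ...] = _DEFAULT_NORTH_CODES
    south_region_codes: tuple[str, ...] = _DEFAULT_SOUTH_CODES

    def validate(self, registry: SentinelRegistry) -> None:
        for region in REGION_ORDER:
            if region not in self.n_physicians_by_region:
                raise ConfigError(f"no physician count for region {region.value}")
            if self.n_physicians_by_region[region] < 0:
                raise ConfigError(f"negative cohort size for {region.value}")
            p = self.female_prob_by_region[region]
            if not 0 <= p <= 1:
                raise ConfigError(f"female_prob out of [0,1] for {region.value}")
            probs = self.stage_probs_by_region[region]
            if len(probs) != len(STAGE_ORDER) or any(q < 0 for q in probs):
                raise ConfigError(f"bad stage probabilities for {region.value}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(
                    f"stage probabilities for {region.value} sum to {sum(probs)}"
                )
            per_svc = self.provision_prob[region]
            for svc in registry.services:
                q = per_svc.get(svc.service_id)
                if q is None or not 0 <= q <= 1:
                    raise ConfigError(
                        f"provision_prob missing/invalid for "
                        f"({region.value}, {svc.service_id})"
                    )
        if self.noise_code_rate < 0:
            raise ConfigError("noise_code_rate must be >= 0")
        for code in self.noise_codes:
            if registry.match_code(code) is not None:
                raise ConfigError(f"noise code {code!r} matches a sentinel service")
        for code in SURGICAL_ASSIST_SAMPLING_CODES:
            if registry.match_code(code) != "surgical_assisting":
                raise ConfigError(
                    f"surgical-assisting sampling code {code!r} resolves to "
                    f"{registry.match_code(code)!r}"
                )


@dataclass
class SimulatedCohort:
    physicians: list[PhysicianRecord]
    claims: list[ClaimRecord]
    truth: dict[str, dict[str, bool]]          # physician -> service -> provider
    truth_region: dict[str, Region]
    config: SimulationConfig


def default_simulation_config(
    seed: int, n_physicians_by_region: Mapping[Region, int] | None = None
) -> SimulationConfig:
    """Build the default config from the packaged reference summary.

    Stratum sizes, sex and career-stage mixes, and provision probabilities
    are the reference table's exact cell ratios; *n_physicians_by_region*
    overrides cohort sizes (e.g. for parameter-recovery experiments) while
    keeping the reference proportions.
    """
    from .ingest import load_reference_summary

    ref = load_reference_summary()
    denom = {r: ref.cell("total_physicians", r.value).value for r in REGION_ORDER}
    female = {r: ref.cell("female", r.value).value / denom[r] for r in REGION_ORDER}
    stage_rows = ref.rows_of_kind(KIND_STAGE)
    stages = {
        r: tuple(row.cells[r.value].value / denom[r] for row in stage_rows)
        for r in REGION_ORDER
    }
    provision: dict[Region, dict[str, float]] = {}
    for r in REGION_ORDER:
        per: dict[str, float] = {}
        for row in ref.rows_of_kind(KIND_SERVICE):
            cell = row.cells[r.value]
            sid = row.row_id.removeprefix("svc_")
            if cell.raw is None:  # suppressed: true count in [1, 6]
                per[sid] = 0.5 * 6 / denom[r]
            else:
                per[sid] = cell.raw / denom[r]
        provision[r] = per
    if n_physicians_by_region is None:
        n_physicians_by_region = denom
    return SimulationConfig(
        seed=seed,
        n_physicians_by_region=dict(n_physicians_by_region),
        female_prob_by_region=female,
        stage_probs_by_region=stages,
        provision_prob=provision,
    )


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _sampling_codes(svc) -> list[str]:
    if svc.service_id == "surgical_assisting":
        return list(SURGICAL_ASSIST_SAMPLING_CODES)
    return sorted(svc.iter_codes())


def simulate_cohort(
    cfg: SimulationConfig, registry: SentinelRegistry | None = None
) -> SimulatedCohort:
    """Generate a fully reproducible synthetic cohort.

    Physicians are generated region by region in a fixed order; all
    randomness flows from ``cfg.seed`` through one generator, so identical
    configs give identical cohorts.
    """
    registry = registry or default_registry()
    cfg.validate(registry)
    rng = np.random.default_rng(cfg.seed)
    physicians: list[PhysicianRecord] = []
    claims: list[ClaimRecord] = []
    truth: dict[str, dict[str, bool]] = {}
    truth_region: dict[str, Region] = {}
    codes_by_service = {s.service_id: _sampling_codes(s) for s in registry.services}

    idx = 0
    for region in REGION_ORDER:
        n = cfg.n_physicians_by_region[region]
        is_north = region in (Region.NORTH_RURAL, Region.NORTH_URBAN)
        is_rural = region in (Region.NORTH_RURAL, Region.SOUTH_RURAL)
        region_codes = cfg.north_region_codes if is_north else cfg.south_region_codes
        stage_probs = np.asarray(cfg.stage_probs_by_region[region], dtype=float)
        for _ in range(n):
            pid = f"P{idx:06d}"
            idx += 1
            stage = STAGE_ORDER[rng.choice(len(STAGE_ORDER), p=stage_probs)]
            lo, hi = _STAGE_YEAR_SPANS[stage]
            years = round(float(rng.uniform(lo, hi)), 1)
            if years >= hi:  # guard the rounding edge at the bin boundary
                years = lo
            rio = int(rng.integers(40, 101)) if is_rural else int(rng.integers(0, 40))
            physicians.append(PhysicianRecord(
                physician_id=pid,
                sex="female" if rng.random() < cfg.female_prob_by_region[region] else "male",
                years_in_practice=years,
                region_code=str(region_codes[rng.integers(0, len(region_codes))]),
                rio_score=rio,
                is_family_practice=True,
            ))
            truth_region[pid] = region
            flags: dict[str, bool] = {}
            for svc in registry.services:
                q = cfg.provision_prob[region][svc.service_id]
                is_provider = bool(rng.random() < q)
                flags[svc.service_id] = is_provider
                count = _draw_count(rng, svc.threshold, is_provider, cfg.count_model)
                if count > 0:
                    claims.extend(_spread_over_codes(
                        rng, pid, count, codes_by_service[svc.service_id],
                        cfg.study_year,
                    ))
            truth[pid] = flags
            n_noise = int(rng.poisson(cfg.noise_code_rate))
            if n_noise > 0:
                alloc = rng.multinomial(n_noise, [1 / len(cfg.noise_codes)] * len(cfg.noise_codes))
                for code, k in zip(cfg.noise_codes, alloc):
                    if k > 0:
                        claims.append(ClaimRecord(pid, code, cfg.study_year, int(k)))
    return SimulatedCohort(physicians, claims, truth, truth_region, cfg)


def _draw_count(rng, threshold: int, is_provider: bool, model: CountModel) -> int:
    if is_provider:
        return threshold + _nb_draw(
            rng, model.excess_mean_factor * threshold, model.dispersion
        )
    if threshold == 1 or rng.random() < model.nonprovider_zero_prob:
        return 0
    return int(rng.integers(1, threshold))


def _spread_over_codes(rng, pid, count, codes, year) -> list[ClaimRecord]:
    alloc = rng.multinomial(count, [1 / len(codes)] * len(codes))
    return [
        ClaimRecord(pid, code, year, int(k))
        for code, k in zip(codes, alloc) if k > 0
    ]


@dataclass
class AgreementReport:
    """Per-service confusion between simulated truth and pipeline output."""

    confusion: dict[str, dict[str, int]]      # service -> {tp, fp, fn, tn}
    n_physicians: int

    @property
    def agreement(self) -> float:
        """Fraction of (physician, service) cells classified identically."""
        cells = sum(sum(c.values()) for c in self.confusion.values())
        if cells == 0:
            return 1.0
        correct = sum(c["tp"] + c["tn"] for c in self.confusion.values())
        return correct / cells

    @property
    def is_exact(self) -> bool:
        return all(c["fp"] == 0 and c["fn"] == 0 for c in self.confusion.values())


def truth_versus_pipeline(
    truth: Mapping[str, Mapping[str, bool]],
    profiles: Mapping[str, ServiceProfile],
) -> AgreementReport:
    """Compare simulated provider flags with pipeline classifications.

    With the default count model the separation is built in (provider counts
    reach the threshold, non-provider counts do not), so agreement must be
    exact; a "leaky" count model can produce provider-side misses.
    """
    if set(truth) != set(profiles):
        raise ConsistencyError(
            "truth table and profiles describe different cohorts "
            f"({len(truth)} vs {len(profiles)} physicians)"
        )
    confusion: dict[str, dict[str, int]] = {}
    for pid, flags in truth.items():
        prof = profiles[pid]
        for sid, t in flags.items():
            c = confusion.setdefault(sid, {"tp": 0, "fp": 0, "fn": 0, "tn": 0})
            got = prof.provided[sid]
            key = ("tp" if got else "fn") if t else ("fp" if got else "tn")
            c[key] += 1
    return AgreementReport(confusion=confusion, n_physicians=len(truth))
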