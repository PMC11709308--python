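"""Top-k service selection and exclusive combination (UpSet) counting."""

import itertools
import random

import pytest

from fpscope.classify import binarize
from fpscope.errors import FpscopeError
from fpscope.setcombo import (
    combination_counts,
    export_upset_matrix,
    import_upset_matrix,
    services_count_distribution,
    top_k_services,
)
from fpscope.stratify import CareerStage, Region, StratumAssignment

TOP6 = {"clinic", "mental_health", "emergency_medicine",
        "palliative_care", "hospital_medicine", "home_visits"}


class TestTopKServices:
    def test_reference_top6(self, reference):
        assert set(top_k_services(reference, k=6)) == TOP6

    def test_reference_top1_is_clinic(self, reference):
        assert top_k_services(reference, k=1) == ["clinic"]

    def test_k18_is_full_ranking(self, reference):
        ranked = top_k_services(reference, k=18)
        assert len(ranked) == 18 and ranked[0] == "clinic"

    def test_descending_provider_counts(self, reference):
        ranked = top_k_services(reference, k=6)
        counts = [reference.cell(f"svc_{sid}", "total").raw for sid in ranked]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_k(self, reference):
        with pytest.raises(FpscopeError):
            top_k_services(reference, k=0)
        with pytest.raises(FpscopeError):
            top_k_services(reference, k=19)


def _cohort(registry, provided_sets, stages=None):
    """Build profiles + strata from explicit provided-service sets."""
    profiles, strata = {}, {}
    for i, services in enumerate(provided_sets):
        pid = f"P{i}"
        counts = {s: registry.service(s).threshold for s in services}
        profiles[pid] = binarize(counts, registry, physician_id=pid)
        stage = (stages or {}).get(i, CareerStage.LT10)
        strata[pid] = StratumAssignment(pid, Region.NORTH_RURAL, stage)
    return profiles, strata


SELECTED = ["clinic", "emergency_medicine", "mental_health"]


class TestCombinationCounts:
    def test_direct_enumeration(self, registry):
        profiles, strata = _cohort(registry, [
            {"clinic", "emergency_medicine"},
            {"clinic", "emergency_medicine"},
            {"clinic"},
        ])
        records = combination_counts(profiles.values(), SELECTED, strata)
        by_combo = {r.combination: r.count for r in records}
        assert by_combo[frozenset({"clinic", "emergency_medicine"})] == 2
        assert by_combo[frozenset({"clinic"})] == 1
        assert by_combo[frozenset()] == 0

    def test_all_false_profiles(self, registry):
        profiles, strata = _cohort(registry, [set(), set(), set()])
        records = combination_counts(profiles.values(), SELECTED, strata)
        assert records[0].combination == frozenset()
        assert records[0].count == 3 and records[0].proportion == 1.0

    def test_stage_composition_sums_to_count(self, registry):
        profiles, strata = _cohort(
            registry,
            [{"clinic"}, {"clinic"}, {"clinic"}],
            stages={0: CareerStage.LT10, 1: CareerStage.GT29, 2: CareerStage.GT29},
        )
        rec = next(r for r in combination_counts(profiles.values(), SELECTED, strata)
                   if r.combination == frozenset({"clinic"}))
        assert sum(rec.stage_composition.values()) == rec.count == 3
        assert rec.stage_composition[CareerStage.GT29] == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_powerset_oracle(self, registry, seed):
        """Exclusive counts equal brute-force enumeration over all 2^k subsets."""
        rng = random.Random(seed)
        selected = [s.service_id for s in registry.services[:6]]
        provided_sets = [
            {s for s in selected if rng.random() < 0.4} for _ in range(100)
        ]
        profiles, strata = _cohort(registry, provided_sets)
        records = combination_counts(profiles.values(), selected, strata)
        by_combo = {r.combination: r.count for r in records}
        total = 0
        for r in range(len(selected) + 1):
            for subset in itertools.combinations(selected, r):
                expected = sum(1 for ps in provided_sets if set(ps) == set(subset))
                assert by_combo.get(frozenset(subset), 0) == expected
                total += expected
        assert total == len(provided_sets)
        assert sum(r.count for r in records) == len(provided_sets)

    def test_order_invariance(self, registry):
        rng = random.Random(9)
        provided_sets = [{s for s in SELECTED if rng.random() < 0.5}
                         for _ in range(40)]
        profiles, strata = _cohort(registry, provided_sets)
        forward = combination_counts(list(profiles.values()), SELECTED, strata)
        backward = combination_counts(list(profiles.values())[::-1], SELECTED, strata)
        assert [(r.combination, r.count) for r in forward] == \
               [(r.combination, r.count) for r in backward]

    def test_projection_consistency(self, registry):
        """Counting over all 18 services then projecting onto the selected
        subset re-aggregates to the restricted counts."""
        rng = random.Random(21)
        all_ids = [s.service_id for s in registry.services]
        provided_sets = [{s for s in all_ids if rng.random() < 0.25}
                         for _ in range(80)]
        profiles, strata = _cohort(registry, provided_sets)
        restricted = combination_counts(profiles.values(), SELECTED, strata)
        full = combination_counts(profiles.values(), all_ids, strata)
        projected: dict[frozenset, int] = {}
        for r in full:
            key = r.combination & frozenset(SELECTED)
            projected[key] = projected.get(key, 0) + r.count
        for r in restricted:
            assert projected.get(r.combination, 0) == r.count

    def test_inclusive_mode_counts_supersets(self, registry):
        profiles, strata = _cohort(registry, [
            {"clinic", "emergency_medicine"}, {"clinic"},
        ])
        records = combination_counts(profiles.values(), SELECTED, strata,
                                     inclusive=True)
        by_combo = {r.combination: r.count for r in records}
        assert by_combo[frozenset({"clinic"})] == 2     # both contain clinic
        assert by_combo[frozenset()] == 2


class TestServicesCountDistribution:
    def test_conservation_and_point_mass(self, registry):
        profiles, strata = _cohort(registry, [{"clinic"}, {"clinic"}, {"obstetrics"}])
        dist = services_count_distribution(profiles, strata)
        nr = dist[Region.NORTH_RURAL]
        assert sum(sum(v.values()) for v in nr.values()) == 3
        assert set(nr) == {1}  # every physician provides exactly one service

    def test_stage_cross_classification(self, registry, small_cohort_profiles):
        profiles, strata, _ = small_cohort_profiles
        dist = services_count_distribution(profiles, strata)
        total = sum(
            sum(stage_counts.values())
            for per_region in dist.values()
            for stage_counts in per_region.values()
        )
        assert total == len(profiles)


class TestExportUpsetMatrix:
    def test_shape_contract(self, registry):
        profiles, strata = _cohort(registry, [
            {"clinic", "emergency_medicine"}, {"mental_health"},
        ])
        records = combination_counts(profiles.values(), SELECTED, strata)
        df = export_upset_matrix(records, SELECTED)
        assert list(df.columns[:3]) == SELECTED
        assert df["count"].sum() == 2

    def test_empty_records(self):
        df = export_upset_matrix([], SELECTED)
        assert len(df) == 0 and list(df.columns[:3]) == SELECTED

    def test_round_trip(self, registry, tmp_path):
        profiles, strata = _cohort(registry, [
            {"clinic"}, {"clinic", "mental_health"}, set(),
        ])
        records = combination_counts(profiles.values(), SELECTED, strata)
        path = tmp_path / "upset.csv"
        export_upset_matrix(records, SELECTED, path)
        back = import_upset_matrix(path, SELECTED)
        assert [(r.combination, r.count, r.stage_composition) for r in back] == \
               [(r.combination, r.count, r.stage_composition) for r in records]
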