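"""Filter cascade: stage rules, boundary arithmetic, oracle equivalence,
idempotence, monotonicity, and the audit of survivors."""

import dataclasses

import pytest

from asedit.intervals import GenomicInterval
from asedit.snv_filter import (
    FilterThresholds,
    brute_force_proximity,
    context_filter,
    prevalence_filter,
    proximity_filter,
    quality_filter,
    run_cascade,
)
from asedit.simulate import stream
from asedit.ssr import ssr_mask
from conftest import SAMPLES4, hand_annotation, hand_cascade_fixture, make_site


class TestQualityFilter:
    def test_single_failing_value_removes_site(self):
        site = make_site(100, quality={"MQ": 35.0, "DP": 100.0, "QD": 5.0})
        kept, removed = quality_filter([site])
        assert kept == [] and removed == [site]

    def test_all_passing_site_retained(self):
        site = make_site(
            100,
            quality={"MQ": 60, "DP": 100, "QD": 5, "ReadPosRankSum": 0, "MQRankSum": 0},
        )
        kept, _ = quality_filter([site])
        assert kept == [site]

    def test_threshold_equality_fails_strict_inequality(self):
        # thresholds are strict: exactly 40/10/2 do not pass
        site = make_site(100, quality={"MQ": 40.0, "DP": 100.0})
        assert quality_filter([site])[0] == []
        site = make_site(100, quality={"DP": 10.0})
        assert quality_filter([site])[0] == []

    def test_absent_annotations_pass_unless_strict(self):
        site = make_site(100, quality={})
        assert quality_filter([site])[0] == [site]
        strict = FilterThresholds(strict_quality=True)
        assert quality_filter([site], strict)[0] == []


class TestContextFilter:
    def test_junction_flank_boundary(self):
        ann = hand_annotation()  # junctions at 1200, 1700, 3200, 3300
        near = make_site(1203)  # distance 3 <= 5
        far = make_site(1206)  # distance 6 > 5
        kept, removed = context_filter([near, far], ann, [], [])
        assert kept == [far]
        assert removed[0][1] == ["junction"]

    def test_paralog_flank_boundary(self):
        ann = hand_annotation()
        paralogs = [GenomicInterval("chrT", 5000, 5100)]
        inside = make_site(5149)  # 1149-style boundary: within end+50
        outside = make_site(5150)
        kept, removed = context_filter([inside, outside], ann, paralogs, [])
        assert kept == [outside]
        assert removed[0][1] == ["paralog"]

    def test_ssr_and_bidirectional_reasons(self):
        ann = hand_annotation()  # bidirectional region [3400, 3500)
        ssrs = [GenomicInterval("chrT", 6000, 6020)]
        in_ssr = make_site(6010)
        in_bidir = make_site(3450)
        edge_bidir = make_site(3500)  # half-open: first base outside
        kept, removed = context_filter([in_ssr, in_bidir, edge_bidir], ann, [], ssrs)
        reasons = {s.pos0: r for s, r in removed}
        assert reasons[6010] == ["ssr"]
        assert reasons[3450] == ["bidirectional"]
        assert kept == [edge_bidir]

    def test_multiple_reasons_recorded(self):
        ann = hand_annotation()
        ssrs = [GenomicInterval("chrT", 3440, 3460)]
        site = make_site(3450)  # in SSR and in bidirectional region
        _, removed = context_filter([site], ann, [], ssrs)
        assert sorted(removed[0][1]) == ["bidirectional", "ssr"]

    def test_context_subrules_commute(self, sim_small):
        ann = sim_small.reference.annotation
        ssrs = ssr_mask(sim_small.reference.genome)
        paralogs = sim_small.reference.paralog_intervals
        sites = sim_small.sites[:400]
        kept_all, _ = context_filter(sites, ann, paralogs, ssrs)
        # applying sub-rules in sequence (any order) yields the same set
        empty_ann = hand_annotation()  # chrT only: no hits on sim chroms
        k1, _ = context_filter(sites, empty_ann, paralogs, [])
        k2, _ = context_filter(k1, empty_ann, [], ssrs)
        k3, _ = context_filter(k2, ann, [], [])
        assert {s.key for s in k3} == {s.key for s in kept_all}


class TestProximityFilter:
    def test_pair_within_window_both_removed(self):
        sites = [make_site(99), make_site(139)]  # 1-based distance 40
        kept, removed = proximity_filter(sites)
        assert kept == [] and len(removed) == 2

    def test_pair_outside_window_retained(self):
        sites = [make_site(99), make_site(149)]  # distance 50
        kept, removed = proximity_filter(sites)
        assert len(kept) == 2 and removed == []

    def test_different_chromosomes_do_not_pair(self):
        sites = [make_site(100, chrom="c1"), make_site(110, chrom="c2")]
        kept, _ = proximity_filter(sites)
        assert len(kept) == 2

    def test_triplet_window_independent_of_pair_rule(self):
        # spacing 20: pairs pass a 15-bp pair window, but 3 sites span 40
        sites = [make_site(100), make_site(120), make_site(140)]
        kept, removed = proximity_filter(sites, pair_window=15, triplet_window=40)
        assert kept == [] and len(removed) == 3

    def test_matches_brute_force_on_random_layouts(self):
        rng = stream(31, "proximity-oracle")
        for _ in range(200):
            n = int(rng.integers(2, 14))
            positions = sorted(int(p) for p in rng.integers(0, 400, size=n))
            positions = sorted(set(positions))
            chroms = ["c1" if rng.random() < 0.8 else "c2" for _ in positions]
            sites = [make_site(p, chrom=c) for p, c in zip(positions, chroms)]
            _, removed = proximity_filter(sites)
            oracle = brute_force_proximity(sites)
            assert {s.key for s in removed} == {s.key for s in oracle}


class TestPrevalenceFilter:
    def test_at_least_half_boundary(self):
        counts_half = {f"s{i}": (10, 1 if i < 5 else 0) for i in range(10)}
        counts_less = {f"s{i}": (10, 1 if i < 4 else 0) for i in range(10)}
        at_half = make_site(100, counts=counts_half)
        below = make_site(200, counts=counts_less)
        kept, removed = prevalence_filter([at_half, below], n_samples=10)
        assert kept == [at_half] and removed == [below]

    def test_zero_depth_samples_do_not_count(self):
        counts = {f"s{i}": (0, 0) for i in range(4)}
        site = make_site(100, counts=counts)
        assert prevalence_filter([site], n_samples=4)[0] == []


class TestCascade:
    def test_empty_input(self):
        survivors, report = run_cascade([], hand_annotation(), [], [], 4)
        assert survivors == []
        assert [(r["n_in"], r["n_removed"]) for r in report.as_dicts()] == [(0, 0)] * 4

    def test_hand_fixture_exact(self):
        sites, ann, paralogs, ssrs, expected_pos0, expected_report = (
            hand_cascade_fixture()
        )
        survivors, report = run_cascade(sites, ann, paralogs, ssrs, len(SAMPLES4))
        assert [s.pos0 for s in survivors] == expected_pos0
        assert [tuple(r.values()) for r in report.as_dicts()] == expected_report

    def test_cascade_is_idempotent(self, sim_small):
        ann = sim_small.reference.annotation
        ssrs = ssr_mask(sim_small.reference.genome)
        paralogs = sim_small.reference.paralog_intervals
        n = sim_small.design.n_samples
        survivors, _ = run_cascade(sim_small.sites, ann, paralogs, ssrs, n)
        again, report = run_cascade(survivors, ann, paralogs, ssrs, n)
        assert [s.key for s in again] == [s.key for s in survivors]
        assert all(r["n_removed"] == 0 for r in report.as_dicts())

    def test_each_stage_is_threshold_monotone(self, sim_small):
        """Loosening a stage's own thresholds never shrinks that stage's
        survivor set. (The composed cascade is not jointly monotone: a
        neighbour rescued by a looser context rule can create a new
        proximity pair.)"""
        ann = sim_small.reference.annotation
        ssrs = ssr_mask(sim_small.reference.genome)
        paralogs = sim_small.reference.paralog_intervals
        n = sim_small.design.n_samples
        sites = sim_small.sites

        tight_q, _ = quality_filter(sites, FilterThresholds())
        loose_q, _ = quality_filter(sites, FilterThresholds(mq_min=20, dp_min=2, qd_min=0.5))
        assert {s.key for s in tight_q} <= {s.key for s in loose_q}

        tight_c, _ = context_filter(sites, ann, paralogs, ssrs, FilterThresholds())
        loose_c, _ = context_filter(
            sites, ann, paralogs, ssrs,
            FilterThresholds(junction_flank=2, paralog_flank=10),
        )
        assert {s.key for s in tight_c} <= {s.key for s in loose_c}

        tight_p, _ = proximity_filter(sites, 45, 35)
        loose_p, _ = proximity_filter(sites, 20, 10)
        assert {s.key for s in tight_p} <= {s.key for s in loose_p}

        tight_v, _ = prevalence_filter(sites, n, 0.5)
        loose_v, _ = prevalence_filter(sites, n, 0.2)
        assert {s.key for s in tight_v} <= {s.key for s in loose_v}

    def test_downstream_thresholds_compose_monotonically(self, sim_small):
        """Loosening only the proximity windows and the prevalence fraction
        (which cannot change what reaches them) grows the cascade output."""
        ann = sim_small.reference.annotation
        ssrs = ssr_mask(sim_small.reference.genome)
        paralogs = sim_small.reference.paralog_intervals
        n = sim_small.design.n_samples
        strict, _ = run_cascade(sim_small.sites, ann, paralogs, ssrs, n)
        loose_th = FilterThresholds(
            pair_window=20, triplet_window=10, prevalence_fraction=0.2
        )
        loose, _ = run_cascade(sim_small.sites, ann, paralogs, ssrs, n, loose_th)
        assert {s.key for s in strict} <= {s.key for s in loose}

    def test_survivors_audit_clean(self, sim_small):
        """Full re-audit: no surviving site violates any individual rule."""
        ann = sim_small.reference.annotation
        ssrs = ssr_mask(sim_small.reference.genome)
        paralogs = sim_small.reference.paralog_intervals
        n = sim_small.design.n_samples
        survivors, _ = run_cascade(sim_small.sites, ann, paralogs, ssrs, n)
        assert quality_filter(survivors)[1] == []
        assert context_filter(survivors, ann, paralogs, ssrs)[1] == []
        assert proximity_filter(survivors)[1] == []
        assert prevalence_filter(survivors, n)[1] == []

    def test_stage_counts_equal_truth_ledger(self, sim_small):
        cc = sim_small.truth.class_counts()
        ann = sim_small.reference.annotation
        ssrs = ssr_mask(sim_small.reference.genome)
        _, report = run_cascade(
            sim_small.sites, ann, sim_small.reference.paralog_intervals,
            ssrs, sim_small.design.n_samples,
        )
        removed = {r["stage"]: r["n_removed"] for r in report.as_dicts()}
        assert removed == {
            "quality": cc["quality_fail"],
            "context": cc["context_fail"],
            "proximity": cc["proximity_fail"],
            "prevalence": cc["sparse"],
        }


def test_threshold_validation():
    with pytest.raises(ValueError):
        FilterThresholds(prevalence_fraction=0.0)
    with pytest.raises(ValueError):
        FilterThresholds(junction_flank=-1)
    th = FilterThresholds()
    assert dataclasses.asdict(th)["pair_window"] == 45
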