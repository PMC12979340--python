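"""Episode construction: recoding, linking, typing, patterns, invariants."""

import pytest

from oat_episodes import synthetic
from oat_episodes.core import (
    DEFAULT_PERMISSIBLE_GAPS,
    DrugPolicy,
    EpisodeConfig,
    Interval,
)
from oat_episodes.episodes import (
    CONTINUE,
    DISCONTINUE,
    aggregate_nested,
    build_episodes,
    co_dispensation_patterns,
    link_cross_drug,
    link_same_drug,
    recode_same_drug_overlap,
)


class TestRecodeSameDrugOverlap:
    def test_short_overlap_shifted_to_meets(self, disp):
        x, y = disp(day=0, ds=10), disp(day=7, ds=10)
        y2, rel = recode_same_drug_overlap(x, y, epsilon_same=7)
        assert rel.label == "meets"
        assert (y2.interval.start, y2.interval.end) == (10, 20)
        assert y2.shift_days == 3
        assert y2.days_supply == y.days_supply

    def test_long_overlap_untouched(self, disp):
        x, y = disp(day=0, ds=10), disp(day=2, ds=18)
        y2, rel = recode_same_drug_overlap(x, y, epsilon_same=7)
        assert rel.label == "overlaps" and y2 is y

    def test_non_overlap_rejected(self, disp):
        with pytest.raises(ValueError, match="overlaps"):
            recode_same_drug_overlap(disp(day=0, ds=5), disp(day=5, ds=5), 7)

    def test_cascading_shifts_accumulate(self, disp):
        # refills of 10 days arriving every 7 days: shifts cascade against
        # the shifted predecessor, so the k-th record is 3(k-1) days early
        records = [disp(day=7 * i, ds=10) for i in range(3)]
        eps = build_episodes(records)
        assert len(eps) == 1
        assert eps[0].end == 30  # three 10-day supplies laid back to back
        # with a margin wide enough for the growing overlaps, the cascade
        # continues: five records end at 50, the last shifted by 3 x 4
        records = [disp(day=7 * i, ds=10) for i in range(5)]
        cfg = EpisodeConfig(epsilon_same=20)
        eps = build_episodes(records, cfg)
        assert eps[0].end == 50

    def test_epsilon_zero_means_no_recoding(self, disp):
        records = [disp(day=0, ds=10), disp(day=7, ds=10)]
        cfg = EpisodeConfig(epsilon_same=0)
        eps = build_episodes(records, cfg)
        assert eps[0].end == 17  # raw coverage end, no shift


class TestAggregateNested:
    def test_equals_sums_dose(self, disp):
        x = disp(day=0, ds=5, quantity=250.0)  # 50 mg/day
        y = disp(day=0, ds=5, quantity=150.0)  # 30 mg/day
        segs = aggregate_nested(x, y)
        assert [(s.start, s.end, dose) for s, dose in segs] == [(0, 5, 80.0)]

    def test_contains_piecewise_sum_conserves_mg(self, disp):
        x = disp(day=0, ds=10, quantity=500.0)  # 50 mg/day over [0,10)
        y = disp(day=2, ds=3, quantity=90.0)  # 30 mg/day over [2,5)
        segs = aggregate_nested(x, y)
        assert [(s.start, s.end, dose) for s, dose in segs] == [
            (0, 2, 50.0),
            (2, 5, 80.0),
            (5, 10, 50.0),
        ]
        total = sum((s.end - s.start) * dose for s, dose in segs)
        assert total == pytest.approx(x.total_mg + y.total_mg)

    def test_starts_shared_prefix(self, disp):
        x = disp(day=0, ds=3, quantity=120.0)  # 40 mg/day
        y = disp(day=0, ds=8, quantity=320.0)  # 40 mg/day
        segs = aggregate_nested(x, y)
        assert [(s.start, s.end, dose) for s, dose in segs] == [
            (0, 3, 80.0),
            (3, 8, 40.0),
        ]

    def test_disjoint_pair_rejected(self, disp):
        with pytest.raises(ValueError, match="nested"):
            aggregate_nested(disp(day=0, ds=5), disp(day=10, ds=5))


class TestLinkSameDrug:
    @pytest.mark.parametrize(
        "drug, gap, expected",
        [
            ("methadone", 5, CONTINUE),
            ("methadone", 6, DISCONTINUE),
            ("srom", 5, CONTINUE),
            ("srom", 6, DISCONTINUE),
            ("bup_nal", 6, CONTINUE),
            ("bup_nal", 7, DISCONTINUE),
            ("ioat", 3, CONTINUE),
            ("ioat", 4, DISCONTINUE),
        ],
    )
    def test_permissible_gap_boundary(self, disp, drug, gap, expected):
        policy = DrugPolicy(drug, DEFAULT_PERMISSIBLE_GAPS[drug])
        x = disp(drug=drug, day=0, ds=5)
        y = disp(drug=drug, day=5 + gap, ds=5)
        decision, _, _ = link_same_drug(x, y, policy, epsilon_same=7)
        assert decision == expected

    def test_meets_always_continues(self, disp):
        policy = DrugPolicy("methadone", 5)
        decision, _, rel = link_same_drug(
            disp(day=0, ds=7), disp(day=7, ds=7), policy, 7
        )
        assert decision == CONTINUE and rel.label == "meets"


class TestLinkCrossDrug:
    def test_short_overlap_becomes_transition(self, disp, cfg):
        x = disp(drug="srom", day=0, ds=20)
        y = disp(drug="methadone", day=14, ds=16)
        decision, y2, _, switch = link_cross_drug(x, y, cfg)
        assert decision == "transition"
        assert (y2.interval.start, y2.interval.end) == (20, 36)
        assert switch.mechanism == "short_overlap_recode"

    def test_long_overlap_opens_multitherapy(self, disp, cfg):
        x = disp(drug="methadone", day=0, ds=30)
        y = disp(drug="srom", day=5, ds=20)
        decision, y2, _, switch = link_cross_drug(x, y, cfg)
        assert decision == "multitherapy_open"
        assert y2 is y and switch is None

    def test_short_nested_absorbed(self, disp, cfg):
        x = disp(drug="methadone", day=0, ds=30)
        y = disp(drug="bup_nal", day=10, ds=5)
        decision, _, rel, _ = link_cross_drug(x, y, cfg)
        assert decision == "absorb" and rel.label == "contains"

    def test_short_equals_excluded(self, disp, cfg):
        x = disp(drug="methadone", day=0, ds=10)
        y = disp(drug="srom", day=0, ds=10)
        decision, _, rel, _ = link_cross_drug(x, y, cfg)
        assert decision == "exclude" and rel.label == "equals"

    def test_within_gap_before_is_transition(self, disp, cfg):
        x = disp(drug="methadone", day=0, ds=10)
        y = disp(drug="bup_nal", day=13, ds=7)  # gap 3 <= G_methadone = 5
        decision, _, _, switch = link_cross_drug(x, y, cfg)
        assert decision == "transition"
        assert switch.mechanism == "within_gap_before"

    def test_beyond_gap_is_new_episode(self, disp, cfg):
        x = disp(drug="methadone", day=0, ds=10)
        y = disp(drug="bup_nal", day=16, ds=7)  # gap 6 > 5
        decision, _, _, _ = link_cross_drug(x, y, cfg)
        assert decision == "new_episode"

    def test_same_drug_rejected(self, disp, cfg):
        with pytest.raises(ValueError):
            link_cross_drug(disp(day=0), disp(day=20), cfg)


class TestBuildEpisodes:
    def test_monotherapy_with_gaps_within_limit(self, disp):
        eps = build_episodes(
            [disp(day=0, ds=7), disp(day=7, ds=7), disp(day=18, ds=7)]
        )
        assert [(e.start, e.end, e.type) for e in eps] == [(0, 25, "monotherapy")]
        assert eps[0].duration_days == 25

    def test_transition_via_within_gap_before(self, disp):
        eps = build_episodes(
            [disp(drug="methadone", day=0, ds=10), disp(drug="bup_nal", day=13, ds=7)]
        )
        (e,) = eps
        assert e.type == "transition"
        assert e.drug_sequence == ("methadone", "bup_nal")
        assert e.n_switches == 1

    def test_multitherapy_long_co_dispensation(self, disp):
        eps = build_episodes(
            [disp(drug="methadone", day=0, ds=40), disp(drug="srom", day=10, ds=30)]
        )
        (e,) = eps
        assert e.type == "multitherapy"
        assert e.max_co_dispensation_days == 30
        assert e.n_switches == 0

    def test_transition_multitherapy_combines_both(self, disp):
        eps = build_episodes(
            [
                disp(drug="methadone", day=0, ds=40),
                disp(drug="srom", day=10, ds=30),  # 30-day concurrency
                disp(drug="bup_nal", day=42, ds=10),  # within-gap switch
            ]
        )
        (e,) = eps
        assert e.type == "transition_multitherapy"
        assert e.n_switches == 1 and e.max_co_dispensation_days == 30

    def test_absorbed_record_keeps_monotherapy(self, disp):
        eps = build_episodes(
            [disp(drug="methadone", day=0, ds=30), disp(drug="bup_nal", day=10, ds=5)]
        )
        (e,) = eps
        assert e.type == "monotherapy"
        assert e.drug_sequence == ("methadone",)
        assert e.n_dispensations == 2

    def test_excluded_equals_pair_yields_no_episode(self, disp):
        eps = build_episodes(
            [disp(drug="methadone", day=0, ds=10), disp(drug="srom", day=0, ds=10)]
        )
        assert eps == []

    def test_episode_disjointness_and_coverage(self):
        res = synthetic.generate_cohort(synthetic.SimConfig(n_persons=120, seed=29))
        eps = build_episodes(res.dispensations)
        by_person = {}
        for e in eps:
            by_person.setdefault(e.person_id, []).append(e)
        for person_eps in by_person.values():
            person_eps.sort(key=lambda e: e.start)
            for a, b in zip(person_eps, person_eps[1:]):
                assert a.end <= b.start
        # every retained record lies inside exactly one of its person's episodes
        for d in res.dispensations:
            if "excluded_equals" in d.flags:
                continue
            spans = [
                e
                for e in by_person.get(d.person_id, [])
                if e.start <= d.interval.start and d.interval.start < e.end
            ]
            assert len(spans) == 1

    def test_dose_segments_conserve_dispensed_mg(self, disp):
        records = [
            disp(day=0, ds=10, quantity=500.0),
            disp(day=8, ds=10, quantity=500.0),  # overlap 2, recoded
            disp(day=20, ds=10, quantity=300.0),
        ]
        eps = build_episodes(records)
        (e,) = eps
        total = sum(
            s.mg_per_day * s.interval.duration for s in e.dose_segments
        )
        assert total == pytest.approx(sum(r.total_mg for r in records))

    def test_gap_monotonicity_in_permissible_gap(self, disp):
        records = [disp(day=0, ds=5), disp(day=9, ds=5), disp(day=20, ds=5)]
        counts = []
        for g in range(0, 10):
            cfg = EpisodeConfig(policies={"methadone": DrugPolicy("methadone", g)})
            counts.append(len(build_episodes(records, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_epsilon_cross_monotonicity(self, disp):
        # growing the cross-drug margin can turn a multitherapy into a
        # transition but never the reverse
        records = [disp(drug="srom", day=0, ds=20), disp(drug="methadone", day=10, ds=20)]
        types = []
        for eps_cross in range(0, 30):
            cfg = EpisodeConfig(epsilon_cross=eps_cross)
            (e,) = build_episodes(records, cfg)
            types.append(e.type)
        flips = [i for i, (a, b) in enumerate(zip(types, types[1:])) if a != b]
        assert types[0] == "multitherapy" and types[-1] == "transition"
        assert len(flips) == 1

    def test_ground_truth_recovery(self):
        res = synthetic.generate_cohort(synthetic.SimConfig(n_persons=150, seed=41))
        eps = build_episodes(res.dispensations)
        built = sorted(
            (e.person_id, e.start, e.end, e.type, e.drug_sequence, e.n_switches)
            for e in eps
        )
        truth = sorted(
            (t.person_id, t.start, t.end, t.type, t.drugs, t.n_switches)
            for t in res.truth_episodes
        )
        assert built == truth


class TestCoDispensationPatterns:
    def test_return_pattern(self, disp):
        rows = [disp(drug="ioat", day=0, ds=30), disp(drug="srom", day=10, ds=4)]
        pat = co_dispensation_patterns(rows)
        assert list(pat["sequence"]) == ["ioat->(ioat+srom)->ioat"]
        assert pat.loc[0, "pattern"] == "return"
        assert pat.loc[0, "median"] == 4

    def test_switch_pattern(self, disp):
        rows = [disp(drug="srom", day=0, ds=20), disp(drug="methadone", day=15, ds=25)]
        pat = co_dispensation_patterns(rows)
        assert list(pat["sequence"]) == ["srom->(srom+methadone)->methadone"]
        assert pat.loc[0, "pattern"] == "switch"
        assert pat.loc[0, "median"] == 5

    def test_no_overlap_empty_table(self, disp):
        rows = [disp(drug="srom", day=0, ds=10), disp(drug="methadone", day=20, ds=10)]
        assert co_dispensation_patterns(rows).empty
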