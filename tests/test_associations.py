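import numpy as np
import pandas as pd
import pytest

from flocknet import (AssociationParams, GatheringConfig, GroupingEvent,
                      detect_arrivals, detect_gathering_events,
                      detect_groups_arrival, detect_groups_time_window,
                      gbi_from_groups)
from flocknet.rfid_io import DetectionStream

from conftest import make_stream, random_stream
from _oracles import arrivals_by_scan, union_find_groups


def members_of(gbi):
    return sorted(tuple(sorted(g.members)) for g in gbi.groups)


class TestTimeWindow:
    def test_chain_rule_links_a_b_c(self):
        # C is within delta_t of B but not of A; the chain joins all three
        stream = make_stream([0.0, 0.8, 1.5], ["A", "B", "C"])
        gbi = detect_groups_time_window(stream, AssociationParams(delta_t=1.0))
        assert members_of(gbi) == [("A", "B", "C")]

    def test_single_detection_singleton_group(self):
        gbi = detect_groups_time_window(make_stream([3.0], ["A"]),
                                        AssociationParams(delta_t=1.0))
        assert members_of(gbi) == [("A",)]
        assert gbi.groups[0].start == gbi.groups[0].end == 3.0

    def test_empty_stream_empty_matrix(self):
        gbi = detect_groups_time_window(make_stream([], []),
                                        AssociationParams(delta_t=1.0))
        assert gbi.n_groups == 0 and gbi.individuals == []

    def test_matches_union_find_oracle(self, rng):
        for _ in range(50):
            stream = random_stream(rng, n=50, n_individuals=6, t_max=80.0)
            gbi = detect_groups_time_window(stream, AssociationParams(delta_t=1.0),
                                            by_day=False)
            expected = union_find_groups(stream.times,
                                         list(stream.df["individual"]), 1.0)
            assert sorted(members_of(gbi)) == sorted(tuple(sorted(m))
                                                     for m in expected)

    def test_groups_respect_location(self):
        stream = make_stream([0.0, 0.5], ["A", "B"])
        stream.df.loc[1, "location"] = "L2"
        gbi = detect_groups_time_window(stream, AssociationParams(delta_t=1.0))
        assert members_of(gbi) == [("A",), ("B",)]

    def test_refinement_in_delta_t(self, rng):
        # groups at a smaller delta_t partition those at a larger one
        for _ in range(20):
            stream = random_stream(rng, n=40, n_individuals=5, t_max=60.0)
            fine = detect_groups_time_window(stream, AssociationParams(0.5),
                                             by_day=False)
            coarse = detect_groups_time_window(stream, AssociationParams(2.0),
                                               by_day=False)
            coarse_spans = [(g.start, g.end, g.members) for g in coarse.groups]
            for g in fine.groups:
                hosts = [c for c in coarse_spans
                         if c[0] <= g.start and g.end <= c[1]
                         and g.members <= c[2]]
                assert len(hosts) >= 1

    def test_thinning_collapses_repeat_reads(self):
        stream = make_stream([0.0, 0.2, 0.4, 0.6], ["A", "A", "A", "B"])
        raw = detect_groups_time_window(stream, AssociationParams(0.25))
        thin = detect_groups_time_window(stream, AssociationParams(0.25),
                                         thin_interval=0.5)
        # raw: A's repeat reads chain A to B; thinned: the bridge is gone
        assert members_of(raw) == [("A", "B")]
        assert members_of(thin) == [("A",), ("B",)]


class TestArrivals:
    def test_continuous_presence_single_arrival(self):
        times = np.arange(0, 600, 0.25)
        stream = make_stream(times, ["A"] * len(times))
        arr = detect_arrivals(stream, AssociationParams(150.0, delta_i=300.0))
        assert len(arr) == 1 and arr[0].time == 0.0

    def test_absence_beyond_delta_i_resets(self):
        stream = make_stream([0.0, 400.0], ["A", "A"])
        arr = detect_arrivals(stream, AssociationParams(150.0, delta_i=300.0))
        assert [a.time for a in arr] == [0.0, 400.0]

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(30):
            stream = random_stream(rng, n=60, n_individuals=4, t_max=5000.0)
            arr = detect_arrivals(stream, AssociationParams(150.0, delta_i=300.0))
            expected = 0
            for ind, sub in stream.df.groupby("individual"):
                expected += arrivals_by_scan(sub["time"].to_numpy(), 300.0)
            assert len(arr) == expected

    def test_infinite_delta_i_one_arrival_each(self, rng):
        stream = random_stream(rng, n=80, n_individuals=6, t_max=1e6)
        arr = detect_arrivals(stream, AssociationParams(150.0, delta_i=np.inf))
        per = {}
        for a in arr:
            per[(a.individual, a.location)] = per.get((a.individual, a.location), 0) + 1
        assert all(v == 1 for v in per.values())

    def test_requires_delta_i(self):
        with pytest.raises(ValueError):
            detect_arrivals(make_stream([0.0], ["A"]), AssociationParams(150.0))


class TestArrivalGroups:
    def test_two_groups_after_departure(self):
        # A and B arrive together; B leaves, re-arrives with C much later:
        # two groups A-B and B-C, not one chain
        stream = make_stream([0.0, 100.0, 1000.0, 1100.0],
                             ["A", "B", "B", "C"])
        gbi = detect_groups_arrival(stream,
                                    AssociationParams(150.0, delta_i=300.0))
        assert members_of(gbi) == [("A", "B"), ("B", "C")]

    def test_late_lone_arriver_not_linked(self):
        # A and B still present (continuous reads) when C arrives alone
        times_a = list(np.arange(0, 600, 10.0))
        times_b = list(np.arange(5, 600, 10.0))
        stream = make_stream(times_a + times_b + [400.0],
                             ["A"] * len(times_a) + ["B"] * len(times_b) + ["C"])
        gbi = detect_groups_arrival(stream,
                                    AssociationParams(150.0, delta_i=300.0))
        assert members_of(gbi) == [("A", "B"), ("C",)]

    def test_empty_stream(self):
        gbi = detect_groups_arrival(make_stream([], []),
                                    AssociationParams(150.0, delta_i=300.0))
        assert gbi.n_groups == 0


class TestGatheringEvents:
    def test_two_bursts_recovered(self, rng):
        t1 = rng.normal(0.0, 30.0, size=50) + 5000.0
        t2 = rng.normal(0.0, 30.0, size=50) + 8600.0
        inds = ["A", "B"] * 25 + ["C", "D"] * 25
        df = pd.DataFrame({"time": np.concatenate([np.sort(t1), np.sort(t2)]),
                           "individual": inds, "antenna": "a", "location": "L"})
        stream = DetectionStream(df=df)
        gbi = detect_gathering_events(stream, GatheringConfig(presplit_gap=1e9))
        assert members_of(gbi) == [("A", "B"), ("C", "D")]

    def test_single_burst_single_event(self, rng):
        t = np.sort(rng.normal(0.0, 10.0, size=40)) + 1000.0
        stream = make_stream(t, ["A", "B"] * 20)
        gbi = detect_gathering_events(stream)
        assert members_of(gbi) == [("A", "B")]

    def test_membership_invariant_to_row_order(self, rng):
        t = np.concatenate([rng.uniform(0, 60, 30), rng.uniform(4000, 4060, 30)])
        inds = list(rng.choice(list("ABCD"), size=60))
        df = pd.DataFrame({"time": t, "individual": inds,
                           "antenna": "a", "location": "L"})
        shuffled = df.sample(frac=1.0, random_state=1)
        g1 = detect_gathering_events(DetectionStream(df=df))
        g2 = detect_gathering_events(DetectionStream(df=shuffled))
        assert members_of(g1) == members_of(g2)

    def test_deterministic(self, rng):
        stream = random_stream(rng, n=80, n_individuals=5, t_max=2000.0)
        g1 = detect_gathering_events(stream)
        g2 = detect_gathering_events(stream)
        assert members_of(g1) == members_of(g2)

    def test_tiny_block_single_trivial_event(self):
        gbi = detect_gathering_events(make_stream([5.0], ["A"]))
        assert members_of(gbi) == [("A",)]


class TestGbiFromGroups:
    def test_incidence_row_sums(self):
        groups = [GroupingEvent("L", 0, 1, frozenset("AB")),
                  GroupingEvent("L", 2, 3, frozenset("BC"))]
        gbi = gbi_from_groups(groups)
        assert gbi.individuals == ["A", "B", "C"]
        assert list(gbi.incidence.sum(axis=1)) == [2, 2]

    def test_no_groups(self):
        gbi = gbi_from_groups([])
        assert gbi.n_groups == 0 and gbi.incidence.shape == (0, 0)

    def test_column_sums_count_group_memberships(self, rng):
        names = list("ABCDEF")
        groups = []
        for k in range(25):
            size = rng.integers(1, 5)
            groups.append(GroupingEvent("L", k, k,
                                        frozenset(rng.choice(names, size=size,
                                                             replace=False))))
        gbi = gbi_from_groups(groups)
        for j, ind in enumerate(gbi.individuals):
            expected = sum(1 for g in groups if ind in g.members)
            assert gbi.incidence[:, j].sum() == expected

    def test_wide_csv_round_trip(self, tmp_path):
        groups = [GroupingEvent("L", 0.0, 1.0, frozenset("AB")),
                  GroupingEvent("L", 5.0, 9.0, frozenset("C"))]
        gbi = gbi_from_groups(groups)
        path = gbi.write_csv(tmp_path / "gbi.csv")
        back = type(gbi).read_csv(path)
        np.testing.assert_array_equal(back.incidence, gbi.incidence)
        assert back.individuals == gbi.individuals
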