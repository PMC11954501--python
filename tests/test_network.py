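import logging

import pytest

from nmalab import (ContrastRecord, TrialArm, build_network, connected_component,
                    merge_nodes, remove_trial, to_dot)
from nmalab.network import restrict_to_component
from nmalab.simulate import paper_shaped_scenario, simulate_contrast_network


def c(tid, t, b, y=0.1, se=0.1, outcome="os"):
    return ContrastRecord(tid, outcome, t, b, y, se)


class TestBuildNetwork:
    def test_triangle(self, triangle):
        assert triangle.n_treatments == 3
        assert triangle.n_trials == 3
        assert len(triangle.edges) == 3
        comp, excluded = connected_component(triangle)
        assert comp == {"A", "B", "C"} and not excluded

    def test_os_shaped_fixture_dimensions(self):
        recs, _ = simulate_contrast_network(paper_shaped_scenario("os", seed=1))
        net = build_network(recs, "os", "T00")
        assert net.n_treatments == 18
        assert net.n_trials == 20
        assert len(net.edges) == 20  # all two-arm trials

    def test_undeclared_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            build_network([c("t1", "B", "A")], "os", "Z")

    def test_duplicate_pair_errors(self):
        with pytest.raises(ValueError, match="t1"):
            build_network([c("t1", "B", "A"), c("t1", "B", "A", 0.3)], "os", "A")

    def test_single_arm_trial_errors(self):
        arms = [TrialArm("t1", "A", 10, 1)]
        with pytest.raises(ValueError, match="single arm"):
            build_network(arms, "orr", "A")

    def test_outcome_mismatch_errors(self):
        with pytest.raises(ValueError, match="outcome"):
            build_network([c("t1", "B", "A", outcome="os")], "rpfs", "A")

    def test_edge_count_equals_within_trial_pairs(self):
        # a three-arm trial contributes two contrasts against its baseline
        recs = [c("t1", "B", "A"), c("t1", "C", "A"), c("t2", "C", "B")]
        net = build_network(recs, "os", "A")
        assert len(net.edges) == 3
        assert net.trials["t1"] == ["A", "B", "C"]


class TestMergeNodes:
    def test_placebo_arms_collapse(self):
        recs = [c("t1", "X", "placebo_oral"), c("t2", "X", "placebo_iv")]
        net = build_network(recs, "os", "placebo_oral")
        merged = merge_nodes(net, {"placebo_oral": "pbo", "placebo_iv": "pbo"})
        assert set(merged.treatments) == {"pbo", "X"}
        assert merged.n_trials == 2
        assert merged.reference == "pbo"

    def test_empty_map_is_identity(self, triangle):
        merged = merge_nodes(triangle, {})
        assert merged.trials == triangle.trials
        assert set(merged.treatments) == set(triangle.treatments)

    def test_degenerate_trial_dropped_with_warning(self, caplog):
        recs = [c("t1", "prednisone", "placebo"), c("t2", "X", "placebo")]
        net = build_network(recs, "os", "placebo")
        with caplog.at_level(logging.WARNING, logger="nmalab"):
            merged = merge_nodes(net, {"prednisone": "pbo", "placebo": "pbo"})
        assert "t1" not in merged.trials
        assert "t2" in merged.trials
        assert any("dropped" in rec.message for rec in caplog.records)

    def test_idempotent(self, triangle):
        mm = {"B": "BC", "C": "BC"}
        once = merge_nodes(triangle, mm)
        twice = merge_nodes(once, mm)
        assert once.trials == twice.trials
        assert set(once.treatments) == set(twice.treatments)

    def test_unknown_key_errors(self, triangle):
        with pytest.raises(KeyError):
            merge_nodes(triangle, {"Z": "pbo"})


class TestConnectivity:
    def test_disjoint_pair_excluded(self, triangle_records):
        recs = triangle_records + [c("t4", "E", "D")]
        net = build_network(recs, "os", "A")
        comp, excluded = connected_component(net)
        assert excluded == {"D", "E"}
        sub = restrict_to_component(net)
        assert set(sub.treatments) == {"A", "B", "C"}
        assert "t4" not in sub.trials

    def test_bridge_removal_shrinks_component(self, triangle_records):
        # t4 bridges C-D, t5 hangs D-E off the bridge
        recs = triangle_records + [c("t4", "D", "C"), c("t5", "E", "D")]
        net = build_network(recs, "os", "A")
        reduced, orphans = remove_trial(net, "t4")
        comp, excluded = connected_component(reduced)
        assert comp == {"A", "B", "C"}
        assert excluded == {"D", "E"}
        assert orphans == set()  # D, E still carried by t5

    def test_isolated_reference_errors(self, triangle_records):
        net = build_network(triangle_records, "os", "A")
        net2, _ = remove_trial(net, "t1")
        net3, _ = remove_trial(net2, "t3")  # reference A now edgeless
        with pytest.raises(ValueError, match="isolated"):
            connected_component(net3)


class TestRemoveTrial:
    def test_orphaned_treatment_reported(self, triangle_records):
        recs = triangle_records + [c("t4", "D", "C")]
        net = build_network(recs, "os", "A")
        reduced, orphans = remove_trial(net, "t4")
        assert orphans == {"D"}
        assert "D" not in reduced.treatments

    def test_duplicate_comparison_keeps_nodes(self, triangle_records):
        recs = triangle_records + [c("t4", "B", "A", 0.3)]
        net = build_network(recs, "os", "A")
        reduced, orphans = remove_trial(net, "t4")
        assert orphans == set()
        assert set(reduced.treatments) == {"A", "B", "C"}

    def test_unknown_trial_errors(self, triangle):
        with pytest.raises(KeyError):
            remove_trial(triangle, "nope")

    def test_equals_build_on_filtered_records(self, triangle_records):
        net = build_network(triangle_records, "os", "A")
        removed, _ = remove_trial(net, "t2")
        rebuilt = build_network([r for r in triangle_records if r.trial_id != "t2"],
                                "os", "A")
        assert removed.trials == rebuilt.trials
        assert set(removed.treatments) == set(rebuilt.treatments)

    def test_os_fixture_sensitivity_removal(self):
        recs, _ = simulate_contrast_network(paper_shaped_scenario("os", seed=1))
        net = build_network(recs, "os", "T00")
        # drop a star trial whose non-reference arm appears nowhere else
        lone = next(tid for b, t, tid in net.edges
                    if sum(t in tr for tr in net.trials.values()) == 1)
        reduced, orphans = remove_trial(net, lone)
        assert reduced.n_treatments == 17
        assert len(orphans) == 1


def test_dot_export_lists_nodes_and_trial_edges(triangle):
    dot = to_dot(triangle)
    for node in ("A", "B", "C"):
        assert f'"{node}"' in dot
    for tid in ("t1", "t2", "t3"):
        assert tid in dot
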