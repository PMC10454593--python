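import pytest

from clonevo import phylogeny
from clonevo.types import ClonevoError, GenomicEvent, SamplePanel


def panel_for(samples, dates=None):
    return SamplePanel(
        samples=samples,
        purity={s: 0.7 for s in samples},
        dates=dates or {s: float(i) for i, s in enumerate(samples)},
        sex="male",
    )


class TestIdentifyMrca:
    def test_clonal_everywhere_cluster_wins(self):
        centers = {
            "A": {s: 1.0 for s in "1234"},
            "B": {"1": 0.6, "2": 0.0, "3": 0.0, "4": 0.0},
        }
        root, _, _ = phylogeny.identify_mrca(
            centers, {"A": 50, "B": 20}, list("1234")
        )
        assert root == "A"

    def test_single_cluster(self):
        centers = {"A": {"S1": 1.0, "S2": 1.0}}
        root, _, _ = phylogeny.identify_mrca(centers, {"A": 5}, ["S1", "S2"])
        assert root == "A"

    def test_tied_clonal_clusters_merged(self):
        centers = {
            "A": {"S1": 0.95, "S2": 0.92},
            "B": {"S1": 0.93, "S2": 0.97},
        }
        root, merged, sizes = phylogeny.identify_mrca(
            centers, {"A": 10, "B": 30}, ["S1", "S2"]
        )
        assert root == "A"
        assert set(merged) == {"A"}
        assert sizes["A"] == 40
        # size-weighted mean center
        assert merged["A"]["S1"] == pytest.approx((0.95 * 10 + 0.93 * 30) / 40)

    def test_no_clonal_cluster_falls_back_to_maximin(self):
        centers = {
            "A": {"S1": 0.8, "S2": 0.5},
            "B": {"S1": 0.6, "S2": 0.7},
        }
        root, _, _ = phylogeny.identify_mrca(
            centers, {"A": 5, "B": 5}, ["S1", "S2"]
        )
        assert root == "B"

    def test_empty_is_error(self):
        with pytest.raises(ClonevoError):
            phylogeny.identify_mrca({}, {}, ["S1"])


class TestBuildTree:
    def test_sibling_branches(self):
        centers = {
            "A": {"S1": 1.0, "S2": 1.0},
            "B": {"S1": 0.7, "S2": 0.0},
            "C": {"S1": 0.0, "S2": 0.6},
        }
        tree = phylogeny.build_tree(
            centers, {"A": 10, "B": 5, "C": 5}, panel_for(["S1", "S2"])
        )
        assert tree.root == "A"
        assert tree.nodes["B"].parent == "A"
        assert tree.nodes["C"].parent == "A"

    def test_single_node_tree(self):
        centers = {"A": {"S1": 1.0}}
        tree = phylogeny.build_tree(centers, {"A": 3}, panel_for(["S1"]))
        assert tree.root == "A"
        assert tree.to_newick() == "A:3;"

    def test_chain_attaches_to_deepest_valid_node(self):
        centers = {
            "A": {"S1": 1.0, "S2": 1.0},
            "B": {"S1": 0.0, "S2": 0.8},
            "C": {"S1": 0.0, "S2": 0.4},
        }
        tree = phylogeny.build_tree(
            centers, {"A": 10, "B": 8, "C": 4}, panel_for(["S1", "S2"])
        )
        assert tree.nodes["C"].parent == "B"

    def test_sum_rule_forces_sibling(self):
        # C cannot sit under the deeper B: B has only 0.4 in S1 while C
        # needs 0.7 there, so the pigeonhole rule pushes C up to the root
        centers = {
            "A": {"S1": 1.0, "S2": 1.0},
            "B": {"S1": 0.4, "S2": 0.4},
            "C": {"S1": 0.7, "S2": 0.0},
        }
        tree = phylogeny.build_tree(
            centers, {"A": 10, "B": 8, "C": 6}, panel_for(["S1", "S2"])
        )
        assert tree.nodes["B"].parent == "A"
        assert tree.nodes["C"].parent == "A"

    def test_impossible_cluster_flagged_at_root(self):
        # D overlaps both branches but fits under neither (subset rule)
        # nor under the root (sum rule with B and C already attached)
        centers = {
            "A": {"S1": 1.0, "S2": 1.0},
            "B": {"S1": 0.95, "S2": 0.0},
            "C": {"S1": 0.0, "S2": 0.95},
            "D": {"S1": 0.45, "S2": 0.45},
        }
        tree = phylogeny.build_tree(
            centers, {"A": 10, "B": 8, "C": 6, "D": 5},
            panel_for(["S1", "S2"]),
        )
        flagged = [c for c, n in tree.nodes.items()
                   if "unplaced-constraint-violation" in n.flags]
        assert flagged == ["D"]
        assert tree.nodes["D"].parent == "A"

    def test_truncal_and_private_cna_decoration(self):
        centers = {
            "A": {"S1": 1.0, "S2": 1.0},
            "B": {"S1": 0.7, "S2": 0.0},
        }
        truncal = GenomicEvent("LOH", "arm", "13q",
                               {"S1": True, "S2": True})
        private = GenomicEvent("LOH", "arm", "17p",
                               {"S1": True, "S2": False})
        tree = phylogeny.build_tree(
            centers, {"A": 10, "B": 5}, panel_for(["S1", "S2"]),
            event_partition={"shared_all": [truncal], "private": [private]},
        )
        assert [e.target for e in tree.nodes["A"].events] == ["13q"]
        assert [e.target for e in tree.nodes["B"].events] == ["17p"]

    def test_constraints_hold_after_construction(self, case1_run):
        bundle = case1_run["bundle"]
        # validate() raises on violation; also check the subset rule directly
        bundle.tree.validate(bundle.panel.samples)
        for cid, node in bundle.tree.nodes.items():
            if node.parent is None or node.flags:
                continue
            parent = bundle.tree.nodes[node.parent]
            assert node.presence <= parent.presence


class TestTimeEvents:
    def test_late_event_bracketed_between_samples(self):
        panel = panel_for(
            ["NE_2012", "NE_2015", "NE_2017"],
            {"NE_2012": 2012.0, "NE_2015": 2015.0, "NE_2017": 2017.0},
        )
        ev = GenomicEvent(
            "focal_amplification", "gene", "AR",
            {"NE_2012": False, "NE_2015": True, "NE_2017": True},
        )
        (timed,) = phylogeny.time_events([ev], panel)
        assert timed.last_absent == 2012.0
        assert timed.first_present == 2015.0
        assert timed.interval_str() == "(2012, 2015]"

    def test_truncal_event_from_origin(self):
        panel = panel_for(["S1", "S2"], {"S1": 2012.0, "S2": 2015.0})
        ev = GenomicEvent("LOH", "arm", "13q", {"S1": True, "S2": True})
        (timed,) = phylogeny.time_events([ev], panel)
        assert timed.last_absent is None
        assert timed.interval_str() == "(origin, 2012]"

    def test_non_persistent_pattern_flagged(self):
        panel = panel_for(["S1", "S2"], {"S1": 2012.0, "S2": 2015.0})
        ev = GenomicEvent("gain", "arm", "3p", {"S1": True, "S2": False})
        (timed,) = phylogeny.time_events([ev], panel)
        assert timed.non_persistent
        assert timed.interval_str() == "non-persistent"

    def test_same_date_samples_pooled(self):
        panel = panel_for(
            ["NE_2015", "DUCTAL_2015"],
            {"NE_2015": 2015.0, "DUCTAL_2015": 2015.0},
        )
        ev = GenomicEvent(
            "focal_amplification", "gene", "AR",
            {"NE_2015": True, "DUCTAL_2015": False},
        )
        (timed,) = phylogeny.time_events([ev], panel)
        assert not timed.non_persistent
        assert timed.interval_str() == "(origin, 2015]"
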