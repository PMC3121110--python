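from __future__ import annotations

import math

import numpy as np
import pytest

import oracles
from conftest import random_network
from nims import (
    BackgroundNetwork,
    InputFormatError,
    extract_pair_subnetwork,
    load_agents,
    load_network,
    load_phenotype_similarity,
    merge_node_groups,
    min_distance,
    save_network,
)


class TestLoadNetwork:
    def test_deduplicates_edges(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nb\tc\nb\tc\n")
        net = load_network(p)
        assert net.n_nodes == 3
        assert net.n_edges == 2

    def test_self_loop_dropped_with_warning(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\ta\na\tb\n")
        with pytest.warns(UserWarning, match="self-loop"):
            net = load_network(p)
        assert net.edges == {("a", "b")}
        assert "a" in net.nodes  # the looped node survives as a node

    def test_node_set_is_union_of_endpoints(self, tmp_path):
        rng = np.random.default_rng(7)
        lines, expected = [], set()
        for _ in range(10):
            u, v = f"g{rng.integers(20)}", f"g{rng.integers(20, 40)}"
            lines.append(f"{u}\t{v}")
            expected |= {u, v}
        p = tmp_path / "net.tsv"
        p.write_text("\n".join(lines) + "\n")
        assert load_network(p).nodes == expected

    def test_sif_relation_ignored(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("a pp b\nb pp c\n")
        net = load_network(p)
        assert net.edges == {("a", "b"), ("b", "c")}

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nonly_one_field\n")
        with pytest.raises(InputFormatError, match=":2"):
            load_network(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("# just a comment\n")
        with pytest.raises(InputFormatError, match="no edges"):
            load_network(p)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        net = random_network(rng, 15, p=0.3)
        p = tmp_path / "out.tsv"
        save_network(net, p)
        again = load_network(p)
        assert again.nodes >= net.nodes - {n for n in net.nodes if net.degree(n) == 0}
        assert again.edges == net.edges


class TestLoadAgents:
    def test_dedup_and_parsing(self, tmp_path):
        p = tmp_path / "agents.gmt"
        p.write_text("A1\tdesc\tg1\tg2\tg2\nA2\tdesc\tg3\n")
        agents = load_agents(p)
        assert len(agents) == 2
        assert agents[0].genes == {"g1", "g2"}

    def test_duplicate_agent_id_rejected(self, tmp_path):
        p = tmp_path / "agents.gmt"
        p.write_text("A1\td\tg1\nA1\td\tg2\n")
        with pytest.raises(InputFormatError, match="duplicate"):
            load_agents(p)

    def test_line_without_genes_rejected(self, tmp_path):
        p = tmp_path / "agents.gmt"
        p.write_text("A1\tdesc\n")
        with pytest.raises(InputFormatError):
            load_agents(p)


class TestMergeNodeGroups:
    @pytest.fixture
    def net(self):
        return BackgroundNetwork([("a", "b"), ("b", "c"), ("c", "d")])

    def test_keep_mode_keeps_overlapping_groups_distinct(self, net):
        out = merge_node_groups(net, {"K1": {"a", "b"}, "K2": {"b", "c"}}, mode="keep")
        assert out.nodes == {"K1", "K2"}
        # b-c adjacency crosses the groups
        assert out.edges == {("K1", "K2")}
        assert out.member_map["K1"] == {"a", "b"}

    def test_merge_mode_unions_overlapping_groups(self, net):
        out = merge_node_groups(net, {"K1": {"a", "b"}, "K2": {"b", "c"}}, mode="merge")
        assert out.n_nodes == 1
        assert out.n_edges == 0
        (members,) = out.member_map.values()
        assert members == {"a", "b", "c"}

    def test_singleton_groups_reproduce_input(self, net):
        groups = {n: {n} for n in net.nodes}
        for mode in ("keep", "merge"):
            out = merge_node_groups(net, groups, mode=mode)
            assert out.nodes == net.nodes
            assert out.edges == net.edges

    def test_merge_never_has_more_nodes_than_keep(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            net = random_network(rng, 12, p=0.25)
            nodes = sorted(net.nodes)
            groups = {}
            for k in range(4):
                size = int(rng.integers(1, 5))
                groups[f"G{k}"] = set(rng.choice(nodes, size=size, replace=False))
            keep = merge_node_groups(net, groups, mode="keep")
            merge = merge_node_groups(net, groups, mode="merge")
            assert merge.n_nodes <= keep.n_nodes

    def test_empty_group_is_error(self, net):
        with pytest.raises(InputFormatError, match="empty"):
            merge_node_groups(net, {"G": set()}, mode="keep")

    def test_unknown_member_warns_and_skips(self, net):
        with pytest.warns(UserWarning, match="unknown"):
            out = merge_node_groups(net, {"G": {"a", "zz"}}, mode="keep")
        assert out.member_map["G"] == {"a"}


class TestMinDistance:
    def test_path_length(self, path_net):
        assert min_distance(path_net, "a", {"d"}) == 3

    def test_membership_short_circuit(self, path_net):
        assert min_distance(path_net, "a", {"a", "e"}) == 0

    def test_unreachable_is_infinite(self, two_components):
        assert math.isinf(min_distance(two_components, "a", {"x"}))

    def test_unknown_source_is_error(self, path_net):
        with pytest.raises(KeyError, match="zz"):
            min_distance(path_net, "zz", {"a"})

    def test_agrees_with_brute_force_bfs(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(5, 50))
            net = random_network(rng, n, p=0.1)
            adj = oracles.adjacency(net.edges, net.nodes)
            nodes = sorted(net.nodes)
            src = nodes[int(rng.integers(n))]
            targets = set(rng.choice(nodes, size=int(rng.integers(1, 5)), replace=False))
            assert min_distance(net, src, targets) == oracles.min_distance_to_set(
                adj, src, targets
            )


class TestExtractPairSubnetwork:
    def test_whole_path_between_endpoints(self, path_net):
        sub = extract_pair_subnetwork(path_net, {"a"}, {"d"})
        assert sub.nodes == {"a", "b", "c", "d"}
        assert sub.edges == {("a", "b"), ("b", "c"), ("c", "d")}

    def test_identical_singletons_give_single_node(self, path_net):
        sub = extract_pair_subnetwork(path_net, {"a"}, {"a"})
        assert sub.nodes == {"a"}
        assert sub.n_edges == 0

    def test_star_leaves_route_through_center(self, star_net):
        sub = extract_pair_subnetwork(star_net, {"l1"}, {"l2"})
        assert sub.nodes == {"l1", "c", "l2"}

    def test_unmapped_sets_are_error(self, path_net):
        with pytest.raises(ValueError, match="maps"):
            extract_pair_subnetwork(path_net, {"q1"}, {"q2"})


def test_phenotype_similarity_rejects_asymmetry(tmp_path):
    p = tmp_path / "sim.tsv"
    p.write_text("\tp1\tp2\np1\t1.0\t0.3\np2\t0.8\t1.0\n")
    with pytest.raises(InputFormatError, match="symmetric"):
        load_phenotype_similarity(p)
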