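from __future__ import annotations

import math

import numpy as np
import pytest

import oracles
from conftest import make_agent, random_network
from nims import (
    NodeImportance,
    compute_centralities,
    integrate_ip,
    topology_score,
    topology_score_matrix,
)


def uniform_ip(net) -> NodeImportance:
    ids = sorted(net.nodes)
    return NodeImportance(ids, np.ones(len(ids)), 1.0)


class TestClosedForms:
    def test_identical_gene_sets_score_one(self, path_net):
        ip = uniform_ip(path_net)
        a = make_agent("A", {"a", "c", "e"})
        b = make_agent("B", {"a", "c", "e"})
        assert topology_score(path_net, ip, a, b).ts == 1.0

    def test_disconnected_agents_score_zero(self, two_components):
        ip = uniform_ip(two_components)
        a = make_agent("A", {"a", "b"})
        b = make_agent("B", {"x", "y"})
        assert topology_score(two_components, ip, a, b).ts == 0.0

    def test_single_genes_at_distance_d_score_exp_minus_d(self, path_net):
        ip = uniform_ip(path_net)
        ts = topology_score(path_net, ip, make_agent("A", {"a"}), make_agent("B", {"c"}))
        assert ts.ts == pytest.approx(math.exp(-2), abs=1e-12)

    def test_decay_rate_rescales_distances(self, path_net):
        ip = uniform_ip(path_net)
        a, b = make_agent("A", {"a"}), make_agent("B", {"c"})
        ts = topology_score(path_net, ip, a, b, decay_rate=0.5)
        assert ts.ts == pytest.approx(math.exp(-1.0), abs=1e-12)


class TestBehaviour:
    def test_symmetry(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            net = random_network(rng, 20, p=0.15)
            imp = integrate_ip(compute_centralities(net))
            nodes = sorted(net.nodes)
            g1 = set(rng.choice(nodes, size=4, replace=False))
            g2 = set(rng.choice(nodes, size=4, replace=False))
            t12 = topology_score(net, imp, make_agent("A", g1), make_agent("B", g2)).ts
            t21 = topology_score(net, imp, make_agent("B", g2), make_agent("A", g1)).ts
            assert t12 == pytest.approx(t21, abs=1e-12)

    def test_more_distant_gene_never_increases_ts(self, path_net):
        # partner at {a}; moving the single gene farther down the path
        ip = uniform_ip(path_net)
        b = make_agent("B", {"a"})
        scores = [
            topology_score(path_net, ip, make_agent("A", {g}), b).ts
            for g in ["a", "b", "c", "d", "e"]
        ]
        assert all(s1 >= s2 for s1, s2 in zip(scores, scores[1:]))

    def test_upweighting_near_gene_never_decreases_ts(self, path_net):
        # A has a near gene (b) and a far gene (e) w.r.t. partner at {a}
        b_agent = make_agent("B", {"a"})
        a_agent = make_agent("A", {"b", "e"})
        ids = sorted(path_net.nodes)

        def ts_with_near_weight(w: float) -> float:
            vals = {n: 1.0 for n in ids}
            vals["b"] = w
            ip = NodeImportance(ids, np.array([vals[n] for n in ids]), 1.0)
            return topology_score(path_net, ip, a_agent, b_agent).ts

        weights = [0.2, 0.5, 1.0, 2.0, 5.0]
        scores = [ts_with_near_weight(w) for w in weights]
        assert all(s2 >= s1 for s1, s2 in zip(scores, scores[1:]))

    def test_unmapped_genes_counted_not_scored(self, path_net):
        ip = uniform_ip(path_net)
        a = make_agent("A", {"a", "not_in_net"})
        b = make_agent("B", {"c"})
        res = topology_score(path_net, ip, a, b)
        assert res.unmapped_counts["A"] == 1
        assert res.mapped_counts["A"] == 1
        assert res.ts == pytest.approx(math.exp(-2))

    def test_agent_with_no_mapped_genes_is_error(self, path_net):
        ip = uniform_ip(path_net)
        with pytest.raises(ValueError, match="A"):
            topology_score(path_net, ip, make_agent("A", {"zz"}), make_agent("B", {"a"}))

    def test_zero_importance_agent_warns_and_zeroes_term(self, path_net):
        ids = sorted(path_net.nodes)
        vals = {n: 1.0 for n in ids}
        vals["a"] = 0.0
        ip = NodeImportance(ids, np.array([vals[n] for n in ids]), 1.0)
        with pytest.warns(UserWarning, match="zero importance"):
            res = topology_score(path_net, ip, make_agent("A", {"a"}), make_agent("B", {"c"}))
        # dual term of A is 0; dual term of B is exp(-2)
        assert res.ts == pytest.approx(0.5 * math.exp(-2), abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_formula(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(10):
            n = int(rng.integers(5, 30))
            net = random_network(rng, n, p=0.15)
            imp = integrate_ip(compute_centralities(net))
            nodes = sorted(net.nodes)
            g1 = set(rng.choice(nodes, size=int(rng.integers(1, 6)), replace=False))
            g2 = set(rng.choice(nodes, size=int(rng.integers(1, 6)), replace=False))
            got = topology_score(net, imp, make_agent("A", g1), make_agent("B", g2)).ts
            adj = oracles.adjacency(net.edges, net.nodes)
            want = oracles.brute_topology_score(adj, imp.as_dict(), g1, g2)
            assert got == pytest.approx(want, abs=1e-10)


class TestMatrix:
    def test_identical_agents_off_diagonal_one(self, path_net):
        ip = uniform_ip(path_net)
        agents = [make_agent("A", {"a", "b"}), make_agent("B", {"a", "b"})]
        m = topology_score_matrix(path_net, ip, agents)
        assert m.loc["A", "B"] == 1.0

    def test_symmetric_with_unit_diagonal(self, path_net):
        ip = uniform_ip(path_net)
        agents = [
            make_agent("A", {"a"}),
            make_agent("B", {"c"}),
            make_agent("C", {"e"}),
        ]
        m = topology_score_matrix(path_net, ip, agents)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert m.loc["A", "B"] == pytest.approx(math.exp(-2))

    def test_matrix_agrees_with_pairwise_calls(self):
        rng = np.random.default_rng(23)
        net = random_network(rng, 25, p=0.15)
        imp = integrate_ip(compute_centralities(net))
        nodes = sorted(net.nodes)
        agents = [
            make_agent(f"A{i}", set(rng.choice(nodes, size=4, replace=False)))
            for i in range(4)
        ]
        m = topology_score_matrix(net, imp, agents)
        for i in range(4):
            for j in range(i + 1, 4):
                direct = topology_score(net, imp, agents[i], agents[j]).ts
                assert m.iloc[i, j] == pytest.approx(direct, abs=1e-12)
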