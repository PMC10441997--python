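import networkx as nx
import numpy as np
import pytest

import oracles
from microstab import network, stability


def _positive_clique(n=8):
    g = nx.Graph()
    for i in range(n):
        g.add_node(f"n{i}", abundance=1.0 / n)
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(f"n{i}", f"n{j}", weight=0.7)
    return g


def _net_arrays(g):
    nodes = sorted(g.nodes())
    b = {v: g.nodes[v].get("abundance", 1.0) for v in nodes}
    s = {u: {v: 0.0 for v in nodes} for u in nodes}
    for u, v, d in g.edges(data=True):
        s[u][v] = s[v][u] = d["weight"]
    return nodes, b, s


class TestWmis:
    def test_hand_value(self):
        g = nx.Graph()
        g.add_node("i", abundance=0.1)
        g.add_node("a", abundance=0.5)
        g.add_node("b", abundance=0.25)
        g.add_node("c", abundance=0.25)
        g.add_edge("i", "a", weight=0.8)
        g.add_edge("i", "b", weight=-0.4)
        # (0.5*0.8 + 0.25*-0.4 + 0.25*0) / (0.5+0.25+0.25) = 0.3
        assert stability.wmis("i", g) == pytest.approx(0.3)

    def test_positive_when_all_incident_weights_positive(self, signed_network_factory):
        g = _positive_clique(5)
        for v in g.nodes():
            assert stability.wmis(v, g) > 0

    def test_invariant_to_abundance_rescaling(self):
        g = _positive_clique(4)
        before = stability.wmis("n0", g)
        for v in g.nodes():
            g.nodes[v]["abundance"] *= 17.0
        assert stability.wmis("n0", g) == pytest.approx(before)

    def test_no_other_live_nodes_gives_zero(self):
        g = _positive_clique(3)
        assert stability.wmis("n0", g, live=["n0"]) == 0.0


class TestExtinctionCascade:
    def test_all_positive_network_has_no_secondary_extinctions(self):
        g = _positive_clique(8)
        survivors = stability.extinction_cascade(g, ["n0", "n1"])
        assert survivors == {f"n{i}" for i in range(2, 8)}

    def test_hand_traced_two_round_cascade(self):
        # d leans on a; e leans on d; both carry a negative edge from c.
        g = nx.Graph()
        for v, ab in zip("abcde", [0.3, 0.3, 0.2, 0.1, 0.1]):
            g.add_node(v, abundance=ab)
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("b", "c", weight=0.6)
        g.add_edge("a", "d", weight=0.8)
        g.add_edge("c", "d", weight=-0.5)
        g.add_edge("d", "e", weight=0.7)
        g.add_edge("c", "e", weight=-0.3)
        # every node has positive wMIS at baseline (checked by hand):
        # e.g. d: (.3*.8 + .2*(-.5) + .1*.7)/.9 = 0.21/.9 > 0
        assert stability.extinction_cascade(g, []) == set("abcde")
        # remove a: d flips negative (-.1+.07)/.6 and dies; then e loses its
        # positive partner and dies on round two; b and c persist
        assert stability.extinction_cascade(g, ["a"]) == {"b", "c"}

    def test_matches_brute_force_and_is_idempotent(self, signed_network_factory):
        for _ in range(25):
            g = signed_network_factory(n=10)
            nodes, b, s = _net_arrays(g)
            removed = nodes[:3]
            got = stability.extinction_cascade(g, removed)
            expect = oracles.cascade_brute(set(nodes) - set(removed), b, s)
            assert got == expect
            # fixed point: running the cascade on its own output removes nothing
            again = stability.extinction_cascade(g, set(nodes) - got)
            assert again == got

    def test_result_invariant_to_node_processing_order(self, signed_network_factory):
        """Synchronous semantics make the fixed point order-independent."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = signed_network_factory(n=10)
            nodes = list(g.nodes())
            base = stability.extinction_cascade(g, nodes[:2])
            shuffled = nx.Graph()
            for v in rng.permutation(nodes):
                shuffled.add_node(v, **g.nodes[v])
            shuffled.add_edges_from(g.edges(data=True))
            assert stability.extinction_cascade(shuffled, nodes[:2]) == base

    def test_synchronous_and_sequential_agree_on_clean_cases(self):
        """Where the sequential oracle is unambiguous both semantics match."""
        g = _positive_clique(6)
        nodes, b, s = _net_arrays(g)
        assert oracles.cascade_brute(nodes, b, s) == oracles.cascade_sequential(
            nodes, b, s, nodes
        )


class TestRobustness:
    def test_fixed_points_on_positive_clique(self):
        g = _positive_clique(10)
        res = stability.robustness(g, fraction=0.5, repetitions=20, seed=3)
        assert np.allclose(res.proportions, 0.5)
        res0 = stability.robustness(g, fraction=0.0, repetitions=3, seed=3)
        assert np.allclose(res0.proportions, 1.0)
        with pytest.raises(ValueError):
            stability.robustness(g, fraction=1.0)

    def test_repetitions_match_oracle_under_shared_draws(self, signed_network_factory):
        g = signed_network_factory(n=12)
        nodes, b, s = _net_arrays(g)
        n = len(nodes)
        reps, frac, seed = 15, 0.4, 9
        res = stability.robustness(g, fraction=frac, repetitions=reps, seed=seed)
        rng = np.random.default_rng(seed)
        for r in range(reps):
            removed = {nodes[k] for k in rng.choice(n, size=int(frac * n), replace=False)}
            surv = oracles.cascade_brute(set(nodes) - removed, b, s)
            assert res.proportions[r] == pytest.approx(len(surv) / n)

    def test_mean_nonincreasing_in_removal_fraction(self, signed_network_factory):
        g = signed_network_factory(n=14, p_edge=0.5, p_neg=0.2)
        means = [
            stability.robustness(g, fraction=f, repetitions=60, seed=2).mean
            for f in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b - 0.06 for a, b in zip(means, means[1:]))

    def test_module_hub_strategy_deterministic(self, signed_network_factory):
        g = signed_network_factory(n=12, p_edge=0.5)
        network.detect_modules(g, seed=0)
        r1 = stability.robustness(g, strategy="module_hubs")
        r2 = stability.robustness(g, strategy="module_hubs")
        assert r1.proportions[0] == r2.proportions[0]
        assert r1.repetitions == 1


class TestVulnerability:
    def test_path_and_triangle_fixed_points(self):
        p3 = nx.path_graph(3)
        res = stability.vulnerability(p3)
        assert res.global_efficiency == pytest.approx(5 / 6)
        assert res.network_vulnerability == pytest.approx(1.0)  # center removal
        k3 = nx.complete_graph(3)
        res = stability.vulnerability(k3)
        assert res.global_efficiency == pytest.approx(1.0)
        assert res.network_vulnerability == pytest.approx(0.0)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for trial in range(15):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            res = stability.vulnerability(g)
            nodes = sorted(g.nodes())
            adj = [[1 if g.has_edge(i, j) else 0 for j in nodes] for i in nodes]
            v, e = oracles.vulnerability_brute(adj)
            assert res.global_efficiency == pytest.approx(e)
            assert np.allclose(res.node_vulnerability.loc[nodes], v)

    def test_edgeless_errors(self):
        g = nx.empty_graph(4)
        with pytest.raises(ValueError):
            stability.vulnerability(g)
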