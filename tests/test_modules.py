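import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from nmfem.modules import (
    detect_modules,
    module_pvalue,
    module_score,
    node_statistics,
    seeded_module_search,
)
from nmfem.simulate import simulate_ppi


def welch_t_oracle(a, b):
    """Textbook Welch statistic: (mean_b - mean_a) / sqrt(s_a^2/n_a + s_b^2/n_b)."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    return (np.mean(b) - np.mean(a)) / np.sqrt(va / na + vb / nb)


class TestNodeStatistics:
    def test_identical_groups_give_zero(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["g"])
        t = node_statistics(m, [1, 1, 2, 2])
        assert t["g"] == 0.0

    def test_sign_convention_group2_up(self):
        m = pd.DataFrame([[0.0, 0.1, 50.0, 60.0]], index=["g"])
        t = node_statistics(m, [1, 1, 2, 2])
        assert t["g"] > 0

    def test_matches_textbook_welch_formula(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.lognormal(1, 1, size=(20, 10)))
        labels = np.array([1] * 5 + [2] * 5)
        t = node_statistics(m, labels)
        log = np.log2(m.to_numpy() + 1)
        for i in range(20):
            expected = welch_t_oracle(log[i, :5], log[i, 5:])
            assert t.iloc[i] == pytest.approx(expected, abs=1e-10)

    def test_small_group_rejected(self):
        m = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValueError):
            node_statistics(m, [1, 2, 2])


class TestSeededSearch:
    def star(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        return nx.relabel_nodes(g, {i: f"n{i}" for i in range(5)})

    def test_star_with_one_informative_leaf(self):
        g = self.star()
        stats = {"n0": 0.0, "n1": 5.0, "n2": 0.0, "n3": 0.0, "n4": 0.0}
        mod = seeded_module_search(g, stats, "n0")
        assert mod.members == ["n0", "n1"]
        assert mod.score == pytest.approx(5.0 / np.sqrt(2))

    def test_all_zero_weights_stay_at_seed(self):
        g = self.star()
        mod = seeded_module_search(g, {n: 0.0 for n in g}, "n0")
        assert mod.members == ["n0"]
        assert mod.score == 0.0

    def test_missing_stats_default_to_zero(self):
        g = self.star()
        mod = seeded_module_search(g, {"n1": 3.0}, "n0")
        assert mod.members == ["n0", "n1"]

    def test_unknown_seed_lists_near_matches(self):
        with pytest.raises(ValueError, match="n0"):
            seeded_module_search(self.star(), {}, "n00")

    def test_module_connected_and_contains_seed(self, planted_graph):
        g, planted = planted_graph
        rng = np.random.default_rng(0)
        stats = {n: float(rng.normal()) for n in g}
        for seed_gene in list(g.nodes)[:10]:
            mod = seeded_module_search(g, stats, seed_gene)
            assert seed_gene in mod.members
            assert nx.is_connected(g.subgraph(mod.members))

    def test_score_invariant_to_global_sign_flip(self, planted_graph):
        g, _ = planted_graph
        rng = np.random.default_rng(1)
        stats = {n: float(rng.normal()) for n in g}
        flipped = {n: -v for n, v in stats.items()}
        for seed_gene in list(g.nodes)[:5]:
            a = seeded_module_search(g, stats, seed_gene)
            b = seeded_module_search(g, flipped, seed_gene)
            assert a.members == b.members
            assert a.score == pytest.approx(b.score)

    def test_planted_highweight_module_recovered(self):
        hits = []
        for gen_seed in range(20):
            g, planted = simulate_ppi(n_nodes=120, edge_prob=0.03,
                                      planted_module_size=10, seed=gen_seed)
            rng = np.random.default_rng(100 + gen_seed)
            stats = {n: float(rng.normal(0, 0.3)) for n in g}
            for n in planted:
                stats[n] = float(rng.normal(6, 0.5))
            mod = seeded_module_search(g, stats, planted[0], max_size=15)
            hits.append(len(set(mod.members) & set(planted)) / len(planted))
        assert np.mean([h >= 0.8 for h in hits]) >= 0.9


class TestModulePvalue:
    def test_exchangeable_null_gives_large_p(self):
        g, _ = simulate_ppi(n_nodes=60, edge_prob=0.05, planted_module_size=1, seed=2)
        stats = {n: 1.0 for n in g}
        mod = seeded_module_search(g, stats, sorted(g.nodes)[0], max_size=10)
        p = module_pvalue(g, stats, mod, n_perm=200, seed=0, max_size=10)
        assert p > 0.5

    def test_addone_lower_bound(self):
        g, planted = simulate_ppi(n_nodes=80, edge_prob=0.04,
                                  planted_module_size=8, seed=3)
        rng = np.random.default_rng(5)
        stats = {n: float(rng.normal(0, 0.2)) for n in g}
        for n in planted:
            stats[n] = 8.0
        mod = seeded_module_search(g, stats, planted[0], max_size=10)
        p = module_pvalue(g, stats, mod, n_perm=199, seed=1, max_size=10)
        assert p >= 1 / 200
        assert p == pytest.approx(1 / 200)  # no null permutation reaches the planted score

    def test_too_few_permutations_rejected(self):
        g, _ = simulate_ppi(n_nodes=20, edge_prob=0.2, planted_module_size=1, seed=0)
        stats = {n: 0.0 for n in g}
        mod = seeded_module_search(g, stats, sorted(g.nodes)[0])
        with pytest.raises(ValueError):
            module_pvalue(g, stats, mod, n_perm=10)

    def test_null_pvalues_approximately_uniform(self):
        # weights exchangeable across vertices -> permutation p-values uniform
        g, _ = simulate_ppi(n_nodes=50, edge_prob=0.06, planted_module_size=1, seed=7)
        nodes = sorted(g.nodes)
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            stats = {n: float(rng.normal()) for n in nodes}
            mod = seeded_module_search(g, stats, nodes[rep % len(nodes)], max_size=8)
            pvals.append(module_pvalue(g, stats, mod, n_perm=100, seed=rep, max_size=8))
        assert kstest(pvals, "uniform").statistic < 0.1


class TestDetectModules:
    def test_planted_modules_rank_top(self):
        g1, planted1 = simulate_ppi(n_nodes=100, edge_prob=0.03,
                                    planted_module_size=8, seed=11)
        rng = np.random.default_rng(6)
        stats = {n: float(rng.normal(0, 0.3)) for n in g1}
        for n in planted1:
            stats[n] = float(rng.normal(7, 0.5))
        seeds = sorted(g1.nodes)[:30] + [planted1[0]]
        mods = detect_modules(g1, stats, seeds, n_top=5, n_perm=199, seed=0, max_size=12)
        best = mods[0]
        assert len(set(best.members) & set(planted1)) / len(planted1) >= 0.8
        assert best.p_value == pytest.approx(1 / 200)

    def test_fewer_modules_than_requested_no_padding(self):
        g, _ = simulate_ppi(n_nodes=30, edge_prob=0.1, planted_module_size=1, seed=4)
        stats = {n: 1.0 for n in g}
        mods = detect_modules(g, stats, sorted(g.nodes)[:3], n_top=10, n_perm=100, seed=0)
        assert 1 <= len(mods) <= 3

    def test_overlapping_modules_deduplicated(self):
        g, planted = simulate_ppi(n_nodes=60, edge_prob=0.02,
                                  planted_module_size=8, seed=9)
        stats = {n: 0.1 for n in g}
        for n in planted:
            stats[n] = 5.0
        mods = detect_modules(g, stats, planted, n_top=5, n_perm=100, seed=0, max_size=10)
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                shared = len(set(a.members) & set(b.members))
                assert shared <= 0.5 * min(len(a.members), len(b.members))

    def test_deterministic_given_seed(self, planted_graph):
        g, planted = planted_graph
        rng = np.random.default_rng(2)
        stats = {n: float(rng.normal()) for n in g}
        seeds = sorted(g.nodes)[:8]
        a = detect_modules(g, stats, seeds, n_top=3, n_perm=100, seed=42)
        b = detect_modules(g, stats, seeds, n_top=3, n_perm=100, seed=42)
        assert [(m.seed_gene, m.members, m.score, m.p_value) for m in a] == \
               [(m.seed_gene, m.members, m.score, m.p_value) for m in b]

    def test_no_seed_in_graph_rejected(self, planted_graph):
        g, _ = planted_graph
        with pytest.raises(ValueError):
            detect_modules(g, {}, ["absent1", "absent2"], n_perm=100)

    def test_hub_is_max_degree_member(self, planted_graph):
        g, planted = planted_graph
        stats = {n: 1.0 for n in g}
        mod = seeded_module_search(g, stats, planted[0], max_size=8)
        deg = {v: sum(1 for w in g.neighbors(v) if w in set(mod.members))
               for v in mod.members}
        assert deg[mod.hub] == max(deg.values())
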