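import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drugmod import correlation, diamond, hotnet
from drugmod.exceptions import ValidationError
from drugmod.io import DrugModule

from conftest import random_connected_graph


class TestDiffusion:
    def test_two_node_hand_inversion(self):
        g = nx.Graph([("a", "b")])
        op = hotnet.build_diffusion(g, beta=0.5)
        expected = np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]])
        assert np.allclose(op.F, expected, atol=1e-12)

    def test_column_stochastic_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            n = int(rng.integers(10, 200))
            g = random_connected_graph(n, 3.0 / n, seed=int(rng.integers(1e9)))
            op = hotnet.build_diffusion(g, beta=0.4)
            assert np.abs(op.F.sum(axis=0) - 1.0).max() < 1e-8

    def test_beta_near_one_approaches_identity(self):
        g = nx.cycle_graph(8)
        op = hotnet.build_diffusion(g, beta=1 - 1e-9)
        assert np.allclose(op.F, np.eye(8), atol=1e-6)

    def test_disconnected_graph_rejected(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        with pytest.raises(ValidationError, match="largest connected"):
            hotnet.build_diffusion(g)

    def test_heat_conservation(self, rng):
        g = random_connected_graph(60, 0.08, seed=5)
        op = hotnet.build_diffusion(g, beta=0.4)
        h = np.zeros(op.n)
        h[rng.choice(op.n, size=12, replace=False)] = rng.uniform(0.5, 3, 12)
        support = np.flatnonzero(h > 0)
        E_full = op.F * h[None, :]
        assert E_full.sum() == pytest.approx(h.sum(), rel=1e-10)


class TestHotSubnetworks:
    @pytest.fixture()
    def clique_instance(self):
        g = random_connected_graph(100, 0.05, seed=1)
        nodes = sorted(g.nodes())[:6]
        for a, b in itertools.combinations(nodes, 2):
            g.add_edge(a, b)
        op = hotnet.build_diffusion(g, beta=0.4)
        h = op.heat_vector({x: 1.0 for x in nodes})
        return op, h, set(nodes)

    def test_no_heat_no_components(self, clique_instance):
        op, h, _ = clique_instance
        assert hotnet.hot_subnetworks(op, np.zeros(op.n), delta=0.01) == []

    def test_hot_clique_recovered_at_small_delta(self, clique_instance):
        op, h, clique = clique_instance
        comps = hotnet.hot_subnetworks(op, h, delta=1e-9)
        assert comps and set(comps[0]) == clique

    def test_delta_above_max_heat_gives_nothing(self, clique_instance):
        op, h, _ = clique_instance
        support = np.flatnonzero(h > 0)
        emax = hotnet.exchanged_heat(op, h, support).max()
        assert hotnet.hot_subnetworks(op, h, delta=emax * 1.01) == []

    def test_selected_delta_admits_planted_clique(self, clique_instance):
        op, h, clique = clique_instance
        delta = hotnet.select_delta(op, h, seed=0)
        comps = hotnet.hot_subnetworks(op, h, delta)
        assert comps and set(comps[0]) == clique

    def test_select_delta_seeding_contract(self, clique_instance):
        op, h, _ = clique_instance
        assert hotnet.select_delta(op, h, seed=4) == \
            hotnet.select_delta(op, h, seed=4)


class TestDetectModules:
    def _setup(self, module_sizes, seed=2):
        # sparse background so permuted heats do not percolate by chance
        g = random_connected_graph(600, 0.012, seed=seed)
        nodes = sorted(g.nodes())
        filtered = set()
        planted = []
        start = 0
        for size in module_sizes:
            members = nodes[start:start + size]
            start += size
            for a, b in itertools.combinations(members, 2):
                g.add_edge(a, b)
            planted.append(set(members))
            filtered |= set(members)
        # planted modules must not touch each other directly
        for ma, mb in itertools.combinations(planted, 2):
            for a in ma:
                for b in mb:
                    if g.has_edge(a, b):
                        g.remove_edge(a, b)
        z = pd.Series(0.5, index=nodes)
        for i, members in enumerate(planted):
            z.loc[sorted(members)] = 8.0 - i  # first module slightly hotter
        tab = correlation.CorrelationTable(
            zcor=z.to_frame("x").T.rename(index={"x": "drugA"}),
            n=pd.DataFrame(100, index=["drugA"], columns=nodes))
        sets = {"drugA": {"positive": filtered}}
        return g, tab, sets, planted

    def test_planted_module_recovered(self):
        g, tab, sets, planted = self._setup([14])
        modules = hotnet.detect_modules(g, tab, sets, seed=0)
        assert len(modules) == 1
        m = modules[0]
        jac = len(m.genes & planted[0]) / len(m.genes | planted[0])
        assert jac >= 0.6 and m.rank == 1

    def test_two_planted_modules_ranked_and_disjoint(self):
        g, tab, sets, planted = self._setup([14, 10], seed=6)
        modules = hotnet.detect_modules(g, tab, sets, seed=0)
        assert len(modules) >= 2
        first, second = modules[0], modules[1]
        assert len(first) >= len(second)
        assert not first.genes & second.genes
        assert len(first.genes & planted[0]) > len(first.genes) / 2
        assert all(len(m) >= 5 for m in modules)

    def test_small_support_yields_nothing(self):
        g, tab, _, _ = self._setup([8])
        sets = {"drugA": {"positive": set(sorted(g.nodes())[:4])}}
        modules = hotnet.detect_modules(g, tab, sets, seed=0)
        assert modules == []


class TestDiamond:
    def test_hand_enumerated_pvalue(self):
        # k=2 links both into a set of 3 on an 11-node graph: p = 3/45
        p = diamond.connectivity_pvalue(11, 3, 2, 2)
        assert p == pytest.approx(3 / 45)
        # exhaustive check: sum over the hypergeometric support
        total = sum(stats.hypergeom.pmf(k, 10, 3, 2) for k in (2,))
        assert p == pytest.approx(total)

    def test_star_graph_ties_resolve_lexicographically(self):
        g = nx.Graph()
        for leaf in "edcba":
            g.add_edge("hub", leaf)
        ranked = diamond.diamond_rank(g, {"hub"}, 3)
        assert ranked == ["a", "b", "c"]

    def test_matches_bruteforce_on_random_graphs(self):
        def brute(g, seed_set, n_rank):
            current = set(seed_set)
            n = g.number_of_nodes()
            out = []
            for _ in range(n_rank):
                best = None
                for cand in sorted(set(g.nodes()) - current):
                    ks = sum(1 for nb in g.neighbors(cand) if nb in current)
                    if ks == 0:
                        continue
                    k = g.degree(cand)
                    p = float(stats.hypergeom.sf(ks - 1, n - 1,
                                                 len(current), k))
                    key = (p, -ks, cand)
                    if best is None or key < best[0]:
                        best = (key, cand)
                if best is None:
                    break
                out.append(best[1])
                current.add(best[1])
            return out

        rng = np.random.default_rng(3)
        for trial in range(20):
            g = random_connected_graph(30, 0.15, seed=int(rng.integers(1e9)))
            seed_set = set(rng.choice(sorted(g.nodes()), size=3,
                                      replace=False))
            assert diamond.diamond_rank(g, seed_set, 10) == \
                brute(g, seed_set, 10)

    def test_absent_seed_dropped_empty_raises(self):
        g = nx.path_graph(5)
        with pytest.raises(ValidationError):
            diamond.diamond_rank(g, {"zz"}, 2)


class TestExpandModule:
    @pytest.fixture()
    def instance(self):
        g = random_connected_graph(60, 0.1, seed=9)
        nodes = sorted(g.nodes())
        m = DrugModule("d", "positive", 1, frozenset(nodes[:6]))
        ranked = diamond.diamond_rank(g, m.genes, 10)
        return g, m, ranked

    def test_pathway_member_never_added(self, instance):
        g, m, ranked = instance
        candidate = ranked[0]
        out = diamond.expand_module(m, {candidate}, {candidate}, g, top_k=10)
        assert candidate not in out.genes

    def test_candidate_beyond_top_k_not_added(self, instance):
        g, m, ranked = instance
        deep = ranked[5]
        out = diamond.expand_module(m, {deep}, set(), g, top_k=5)
        assert deep not in out.genes
        out2 = diamond.expand_module(m, {deep}, set(), g, top_k=6)
        assert deep in out2.genes
        assert out2.gene_origin(deep) == "diamond_recalled"

    def test_no_candidates_leaves_module_unchanged(self, instance):
        g, m, _ = instance
        out = diamond.expand_module(m, set(), set(), g)
        assert out.genes == m.genes
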