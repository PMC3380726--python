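"""Connected components, density, and the Monte Carlo density null."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from phenomod.io import canonical_pair
from phenomod.modules import (
    BackgroundGraph,
    FunctionalModule,
    connected_components,
    density,
    exhaustive_p,
    filter_significant,
    merge_duplicate_modules,
    monte_carlo_p,
)


def union_find_oracle(pairs):
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in pairs:
        parent[find(u)] = find(v)
    groups = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return {frozenset(g) for g in groups.values()}


def bfs_oracle(pairs):
    adj = {}
    for u, v in pairs:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen, comps = set(), set()
    for start in adj:
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            n = queue.pop()
            if n in comp:
                continue
            comp.add(n)
            queue.extend(adj[n] - comp)
        seen |= comp
        comps.add(frozenset(comp))
    return comps


def module_of(edges, mc_p=None, bias_p=None, sources=frozenset(), organisms=frozenset()):
    nodes = frozenset(n for e in edges for n in e)
    return FunctionalModule(
        cogs=nodes,
        edges=frozenset(edges),
        density=density(nodes, edges),
        mc_p=mc_p,
        bias_p=bias_p,
        source_bicluster_ids=sources,
        organisms=organisms,
    )


def random_background(rng, m=12, p=0.3):
    cogs = [f"G{i:02d}" for i in range(m)]
    edges = {
        canonical_pair(u, v)
        for u, v in combinations(cogs, 2)
        if rng.random() < p
    }
    return BackgroundGraph(cogs=frozenset(cogs), edges=frozenset(edges))


class TestComponents:
    def test_two_disjoint_edges(self):
        comps = connected_components({("A", "B"), ("C", "D")})
        assert [c[0] for c in comps] == [frozenset("AB"), frozenset("CD")]

    def test_triangle_is_one_dense_component(self):
        ((nodes, edges),) = connected_components({("A", "B"), ("B", "C"), ("A", "C")})
        assert len(nodes) == 3 and len(edges) == 3
        assert density(nodes, edges) == 1.0

    def test_empty_input(self):
        assert connected_components(set()) == []

    def test_random_graph_matches_two_independent_oracles(self):
        rng = np.random.default_rng(17)
        nodes = [f"N{i:02d}" for i in range(25)]
        pairs = set()
        while len(pairs) < 40:
            u, v = rng.choice(nodes, 2, replace=False)
            pairs.add(canonical_pair(str(u), str(v)))
        comps = connected_components(pairs)
        got_nodes = {c[0] for c in comps}
        assert got_nodes == union_find_oracle(pairs)
        assert got_nodes == bfs_oracle(pairs)
        # the edge sets partition the input
        all_edges = [e for _, es in comps for e in es]
        assert len(all_edges) == len(pairs) and set(all_edges) == pairs


class TestDensity:
    def test_small_cases_and_domain(self):
        assert density({"a", "b"}, {("a", "b")}) == 1.0
        assert density({"a", "b", "c"}, {("a", "b"), ("b", "c")}) == pytest.approx(2 / 3)
        with pytest.raises(ValueError, match="< 2"):
            density({"a"}, set())

    def test_random_connected_graphs_match_edge_count(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            bg = random_background(rng, m=10, p=0.5)
            nodes = bg.cogs
            d = density(nodes, bg.edges)
            assert d == pytest.approx(2 * len(bg.edges) / (10 * 9))


class TestMonteCarlo:
    def test_complete_background_gives_p_one(self):
        cogs = [f"G{i}" for i in range(10)]
        bg = BackgroundGraph(
            cogs=frozenset(cogs),
            edges=frozenset(canonical_pair(u, v) for u, v in combinations(cogs, 2)),
        )
        mod = module_of({("G0", "G1"), ("G1", "G2"), ("G0", "G2")})
        assert monte_carlo_p(mod, bg, W=500, seed=0) == 1.0

    def test_planted_clique_matches_exhaustive_enumeration(self):
        # only edges are a 4-clique; observed module is that clique
        clique = ["G00", "G01", "G02", "G03"]
        others = [f"G{i:02d}" for i in range(4, 10)]
        edges = frozenset(canonical_pair(u, v) for u, v in combinations(clique, 2))
        bg = BackgroundGraph(cogs=frozenset(clique + others), edges=edges)
        mod = module_of(edges)
        exact = exhaustive_p(mod, bg)
        assert exact == pytest.approx(1 / comb(10, 4))
        p_hat = monte_carlo_p(mod, bg, W=20000, seed=42)
        tol = 3 * np.sqrt(exact * (1 - exact) / 20000)
        assert abs(p_hat - exact) <= tol

    def test_reproducible_and_seed_sensitive(self):
        rng = np.random.default_rng(1)
        bg = random_background(rng)
        mod = module_of({("G00", "G01"), ("G01", "G02")})
        a = monte_carlo_p(mod, bg, W=200, seed=7)
        assert a == monte_carlo_p(mod, bg, W=200, seed=7)

    def test_subset_size_exceeding_universe_rejected(self):
        bg = BackgroundGraph(cogs=frozenset({"a", "b"}), edges=frozenset({("a", "b")}))
        mod = module_of({("a", "b"), ("b", "c"), ("a", "c")})
        with pytest.raises(ValueError, match="exceeds"):
            monte_carlo_p(mod, bg, W=10, seed=0)

    def test_edges_rule_draws_edge_count_sized_subsets(self):
        rng = np.random.default_rng(4)
        bg = random_background(rng)
        mod = module_of({("G00", "G01"), ("G01", "G02"), ("G00", "G02")})
        # 3 nodes, 3 edges: rules coincide here, larger module differs
        p_nodes = monte_carlo_p(mod, bg, W=500, seed=1, subset_size_rule="nodes")
        p_edges = monte_carlo_p(mod, bg, W=500, seed=1, subset_size_rule="edges")
        assert p_nodes == p_edges
        path = module_of({("G00", "G01"), ("G01", "G02"), ("G02", "G03"), ("G03", "G04")})
        from phenomod.modules import _subset_size
        assert _subset_size(path, "nodes") == 5 and _subset_size(path, "edges") == 4
        with pytest.raises(ValueError, match="rule"):
            monte_carlo_p(path, bg, W=10, seed=0, subset_size_rule="columns")

    def test_exhaustive_invariant_to_relabeling(self):
        rng = np.random.default_rng(8)
        bg = random_background(rng, m=9, p=0.35)
        mod = module_of({("G00", "G01"), ("G01", "G02"), ("G00", "G02")})
        relabel = {c: f"Z{ord(c[1]) * 7 % 91:02d}x{c}" for c in sorted(bg.cogs)}
        bg2 = BackgroundGraph(
            cogs=frozenset(relabel[c] for c in bg.cogs),
            edges=frozenset(
                canonical_pair(relabel[u], relabel[v]) for u, v in bg.edges
            ),
        )
        mod2 = module_of(
            {canonical_pair(relabel[u], relabel[v]) for u, v in mod.edges}
        )
        assert exhaustive_p(mod, bg) == exhaustive_p(mod2, bg2)

    def test_sampling_calibrated_against_exhaustive(self):
        rng = np.random.default_rng(12)
        bg = random_background(rng, m=11, p=0.3)
        mod = module_of({("G00", "G01"), ("G01", "G02"), ("G00", "G02")})
        exact = exhaustive_p(mod, bg)
        W = 10000
        for seed in range(5):
            p_hat = monte_carlo_p(mod, bg, W=W, seed=seed)
            tol = 3 * np.sqrt(exact * (1 - exact) / W) + 1e-12
            assert abs(p_hat - exact) <= tol


class TestFilterAndMerge:
    def test_retention_and_missing_mc_p(self):
        keep = module_of({("a", "b")}, mc_p=0.001)
        drop = module_of({("c", "d")}, mc_p=0.2)
        out = filter_significant([keep, drop], alpha=0.05)
        assert [m.edges for m in out] == [keep.edges]
        with pytest.raises(ValueError, match="mc_p"):
            filter_significant([module_of({("a", "b")})])

    def test_identical_components_merge_provenance(self):
        a = module_of({("a", "b")}, mc_p=0.01, bias_p=0.02,
                      sources=frozenset({"B1"}), organisms=frozenset({"o1"}))
        b = module_of({("a", "b")}, mc_p=0.01, bias_p=0.005,
                      sources=frozenset({"B2"}), organisms=frozenset({"o2", "o3"}))
        (merged,) = merge_duplicate_modules([a, b])
        assert merged.source_bicluster_ids == frozenset({"B1", "B2"})
        assert merged.organisms == frozenset({"o1", "o2", "o3"})
        assert merged.bias_p == 0.005

    def test_component_edges_partition_bicluster_pairs(self):
        rng = np.random.default_rng(31)
        nodes = [f"N{i}" for i in range(12)]
        pairs = set()
        while len(pairs) < 15:
            u, v = rng.choice(nodes, 2, replace=False)
            pairs.add(canonical_pair(str(u), str(v)))
        comps = connected_components(pairs)
        assert sum(len(es) for _, es in comps) == len(pairs)
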