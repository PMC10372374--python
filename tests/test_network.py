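"""Graph loading, LCC significance, RWR, proximity and ORA vs brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liveromics import network as net
from liveromics import synth


def _edges(rows):
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


class TestLoadGraph:
    def test_strict_score_threshold(self):
        g = net.load_graph(
            _edges([("a", "b", 0.9), ("b", "c", 0.7), ("c", "d", 0.5)]), 0.7
        )
        assert list(g.edges) == [("a", "b")]

    def test_duplicate_edge_both_directions_stored_once(self):
        g = net.load_graph(
            _edges([("a", "b", 0.9), ("b", "a", 0.8)]), score_min=0.0
        )
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["combined_score"] == 0.9

    def test_self_loops_dropped(self):
        g = net.load_graph(_edges([("a", "a", 0.9), ("a", "b", 0.9)]), 0.5)
        assert nx.number_of_selfloops(g) == 0

    def test_string_thousand_dialect(self):
        g = net.load_graph(_edges([("a", "b", 900), ("b", "c", 400)]), 0.7)
        assert g.edges["a", "b"]["combined_score"] == pytest.approx(0.9)
        assert not g.has_edge("b", "c")

    def test_counts_match_generator_ledger(self):
        g, _ = synth.gen_ppi(n_nodes=120, seed=3)
        table = synth.ppi_edge_table(g)
        loaded = net.load_graph(table, score_min=0.0)
        assert loaded.number_of_nodes() == g.number_of_nodes()
        assert loaded.number_of_edges() == g.number_of_edges()


class TestMapSeeds:
    def test_coverage_fractions(self):
        g = nx.Graph([("A1", "B2"), ("B2", "C3")])
        full = net.map_seeds(["a1", "b2", "c3"], g)
        assert full.coverage == 1.0
        none = net.map_seeds(["x", "y"], g)
        assert none.coverage == 0.0 and none.mapped == []
        part = net.map_seeds(["A1", "B2", "zz", "qq", "C3"], g)
        assert part.coverage == pytest.approx(0.6)


def _bruteforce_lcc(nodes, g):
    nodes = [n for n in nodes if n in g]
    best, seen = 0, set()
    node_set = set(nodes)
    for start in nodes:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(u for u in g.neighbors(v) if u in node_set)
        seen |= comp
        best = max(best, len(comp))
    return best


class TestLcc:
    def test_path_examples(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        assert net.lcc_size(["a", "b"], g) == 2
        assert net.lcc_size(["a", "c"], g) == 1

    def test_null_matches_bruteforce_oracle_stream(self):
        g, _ = synth.gen_ppi(n_nodes=40, attachment_parameter=2, seed=1)
        seeds = sorted(g.nodes)[:6]
        res = net.lcc_zscore(seeds, g, n_random=200, seed=42)
        # replay the identical sampling stream with a brute-force LCC
        rng = np.random.default_rng(42)
        nodes = np.array(sorted(g.nodes))
        null = np.array([
            _bruteforce_lcc(rng.choice(nodes, len(seeds), replace=False), g)
            for _ in range(200)
        ])
        assert res.observed == _bruteforce_lcc(seeds, g)
        assert res.null_mean == pytest.approx(null.mean())
        assert res.null_sd == pytest.approx(null.std(ddof=0))
        assert res.p_empirical == pytest.approx(
            (1 + (null >= res.observed).sum()) / 201
        )

    def test_planted_clique_scores_high(self):
        g, truth = synth.gen_ppi(n_nodes=500, planted_modules=((10, 1.0),), seed=5)
        mod = truth.index[truth["module"] == 0].tolist()
        res = net.lcc_zscore(mod, g, n_random=300, seed=0)
        assert res.z > 2 and res.p_empirical <= 0.01

    def test_too_few_seeds_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        with pytest.raises(ValueError):
            net.lcc_zscore(["a"], g)


class TestCores:
    def test_two_disjoint_cliques(self):
        g = nx.Graph()
        for block in ("abcde", "vwxyz"):
            for u, v in itertools.combinations(block, 2):
                g.add_edge(u, v)
        # background connectivity through a non-seed bridge node
        g.add_edge("a", "bridge")
        g.add_edge("bridge", "v")
        cores = net.extract_cores(list("abcdevwxyz"), g, n_random=50, seed=0)
        sizes = sorted(c["size"] for c in cores)
        assert sizes == [5, 5]

    def test_isolated_seeds_no_cores(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        cores = net.extract_cores(["a", "c", "e"], g, n_random=50, seed=0)
        assert cores == []


class TestRwr:
    def test_two_node_closed_form(self):
        g = nx.Graph([("a", "b")])
        p = net.rwr(g, ["a"], alpha=0.9)
        assert p["a"] == pytest.approx(10 / 11, abs=1e-7)
        assert p["b"] == pytest.approx(1 / 11, abs=1e-7)

    def test_alpha_one_is_pure_restart(self):
        g, _ = synth.gen_ppi(n_nodes=50, seed=2)
        seeds = sorted(g.nodes)[:5]
        p = net.rwr(g, seeds, alpha=1.0)
        assert p[seeds].to_numpy() == pytest.approx(0.2)
        assert p.drop(seeds).to_numpy() == pytest.approx(0.0)

    def test_scores_sum_to_one(self):
        g, _ = synth.gen_ppi(n_nodes=80, seed=3)
        p = net.rwr(g, sorted(g.nodes)[:4], alpha=0.9)
        assert p.sum() == pytest.approx(1.0)

    def test_symmetric_graph_symmetric_scores(self):
        g = nx.cycle_graph([f"n{i}" for i in range(6)])
        p = net.rwr(g, ["n0", "n3"], alpha=0.8)
        assert p["n1"] == pytest.approx(p["n2"])
        assert p["n1"] == pytest.approx(p["n4"])

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            net.rwr(nx.path_graph(3), [])


class TestRwrExpand:
    def test_already_connected_no_additions(self):
        g = nx.path_graph(["a", "b", "c", "x", "y"])
        res = net.rwr_expand(g, ["a", "b", "c"], target_coverage=0.9)
        assert res.added == [] and res.coverage == 1.0

    def test_star_hub_connects_leaves(self):
        g = nx.star_graph(["hub", "l1", "l2", "l3", "l4"])
        res = net.rwr_expand(g, ["l1", "l2"], target_coverage=1.0)
        assert res.added == ["hub"] and res.coverage == 1.0

    def test_removed_articulation_hub_recovered_first(self):
        # module split in two halves joined only through one hub
        g = nx.Graph()
        for u, v in itertools.combinations(["a1", "a2", "a3"], 2):
            g.add_edge(u, v)
        for u, v in itertools.combinations(["b1", "b2", "b3"], 2):
            g.add_edge(u, v)
        g.add_edge("a1", "hub")
        g.add_edge("hub", "b1")
        g.add_edge("hub", "far1")
        g.add_edge("far1", "far2")
        res = net.rwr_expand(
            g, ["a1", "a2", "a3", "b1", "b2", "b3"], target_coverage=0.9
        )
        assert res.added == ["hub"]


class TestJaccard:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [({"a", "b"}, {"a", "b"}, 1.0), ({"a"}, {"b"}, 0.0),
         ({"a", "b"}, {"b", "c"}, 1 / 3), (set(), set(), 0.0)],
    )
    def test_toy_values(self, s1, s2, expected):
        assert net.jaccard(s1, s2) == pytest.approx(expected)

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounds_and_symmetry(self, s1, s2):
        j = net.jaccard(s1, s2)
        assert 0 <= j <= 1
        assert j == net.jaccard(s2, s1)


class TestProximity:
    def test_subset_distance_zero(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        d, _ = net.closest_distance(g, ["a", "b"], ["a", "b", "c"])
        assert d == 0.0

    def test_path_endpoints(self):
        g = nx.path_graph(["a", "b", "c"])
        d, _ = net.closest_distance(g, ["a"], ["c"])
        assert d == 2.0

    def test_monotone_adding_adjacent_node(self):
        g, _ = synth.gen_ppi(n_nodes=60, seed=4)
        nodes = sorted(g.nodes)
        s1, s2 = nodes[:5], nodes[10:15]
        d0, _ = net.closest_distance(g, s1, s2)
        neighbour = next(iter(g.neighbors(s1[0])))
        d1, _ = net.closest_distance(g, s1, s2 + [neighbour])
        assert d1 <= d0

    def test_null_matches_bruteforce_bfs_oracle(self):
        g, _ = synth.gen_ppi(n_nodes=50, attachment_parameter=2, seed=6)
        nodes = sorted(g.nodes)
        s1, s2 = nodes[:4], nodes[20:26]
        res = net.network_proximity(
            s1, s2, g, n_random=100, seed=11, min_bin_size=10
        )
        apsp = dict(nx.all_pairs_shortest_path_length(g))

        def oracle_d(a, b):
            return np.mean([min(apsp[u][v] for v in b) for u in a])

        assert res.d_observed == pytest.approx(oracle_d(s1, s2), abs=1e-12)
        bins = net.degree_bins(g, min_bin_size=10)
        rng = np.random.default_rng(11)
        for i in range(100):
            r1 = net.sample_degree_matched(s1, bins, rng)
            r2 = net.sample_degree_matched(s2, bins, rng)
            assert res.null_distances[i] == pytest.approx(
                oracle_d(r1, r2), abs=1e-12
            )

    def test_degree_matched_null_preserves_bin_composition(self):
        g, _ = synth.gen_ppi(n_nodes=200, seed=7)
        bins = net.degree_bins(g, min_bin_size=20)
        lookup = net._bin_lookup(bins)
        nodes = sorted(g.nodes)[:12]
        rng = np.random.default_rng(0)
        for _ in range(20):
            sample = net.sample_degree_matched(nodes, bins, rng)
            assert len(sample) == len(nodes)
            assert sorted(lookup[n] for n in sample) == sorted(
                lookup[n] for n in nodes
            )

    def test_empty_mapped_set_rejected(self):
        g = nx.path_graph(["a", "b"])
        with pytest.raises(ValueError):
            net.network_proximity(["zz"], ["a"], g, n_random=10)


class TestDiseaseScreen:
    def test_strict_gda_filter(self):
        cat = pd.DataFrame(
            {"disease_id": ["d"] * 3, "gene": ["g1", "g2", "g3"],
             "gda_score": [0.2, 0.3, 0.31]},
        )
        kept = net.filter_catalog(cat, 0.3)
        assert kept["gene"].tolist() == ["g3"]

    def test_duplicate_pairs_keep_max_score(self):
        cat = pd.DataFrame(
            {"disease_id": ["d", "d"], "gene": ["g1", "g1"],
             "gda_score": [0.4, 0.9]},
        )
        kept = net.filter_catalog(cat, 0.3)
        assert len(kept) == 1 and kept["gda_score"].iloc[0] == 0.9

    def test_module_copy_disease_is_proximal(self):
        g, truth = synth.gen_ppi(n_nodes=300, planted_modules=((8, 1.0),), seed=8)
        module = truth.index[truth["module"] == 0].tolist()
        cat, _ = synth.gen_disease_catalog(
            10, sorted(g.nodes), overlap_spec={0: (module, len(module))},
            seed=2, size_range=(8, 8), low_score_frac=0,
        )
        screen = net.disease_screen(
            module, cat, g, n_random=100, seed=3, min_bin_size=30
        )
        assert screen.loc["D001", "jaccard"] == 1.0
        assert screen.loc["D001", "d_c"] == 0.0
        assert screen["p_adjusted"].idxmin() == "D001"


class TestOra:
    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = net.ora(["g0", "g1"], universe, {"s": ["g10", "g11"]})
        assert res.loc["s", "p"] == pytest.approx(1.0)
        assert res.loc["s", "overlap"] == 0

    def test_query_equals_set_equals_universe(self):
        u = [f"g{i}" for i in range(6)]
        res = net.ora(u, u, {"s": u})
        assert res.loc["s", "p"] == pytest.approx(1.0)
        assert res.loc["s", "enrichment"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # universe 20, set 5, query 5, overlap 3: enumerate all C(20,5) draws
        universe = list(range(20))
        gene_set = list(range(5))
        query = [0, 1, 2, 10, 11]
        res = net.ora(query, universe, {"s": gene_set})
        count = sum(
            1
            for draw in itertools.combinations(universe, 5)
            if len(set(draw) & set(gene_set)) >= 3
        )
        total = 15504  # C(20, 5)
        assert res.loc["s", "p"] == pytest.approx(count / total, abs=1e-12)

    def test_bh_adjustment_across_sets(self):
        universe = [f"g{i}" for i in range(30)]
        sets = {f"s{i}": universe[i : i + 5] for i in range(4)}
        res = net.ora(universe[:5], universe, sets)
        assert (res["p_adjusted"] >= res["p"] - 1e-12).all()
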