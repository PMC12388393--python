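"""Co-occurrence network construction, modules, keystones, topology.

Oracles: exhaustive permutation for Spearman p, naive all-shortest-path
counting for betweenness, brute-force partition search for modularity.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from bloomnet.network import (
    CorrelationMatrix, average_degree, build_network, compare_regions,
    extract_modules, fast_greedy_modules, keystone_rank, network_filter,
    network_stats, node_metadata, read_graphml, spearman_matrix, write_graphml,
)
from bloomnet.simulate import RANKS


def _corr_from(rho: pd.DataFrame, p: float = 1e-6) -> CorrelationMatrix:
    pm = pd.DataFrame(p, index=rho.index, columns=rho.columns)
    np.fill_diagonal(pm.values, 0.0)
    return CorrelationMatrix(rho=rho, p=pm, n=10)


def _meta_for(nodes, domain="prokaryote"):
    return pd.DataFrame({"domain": domain, "lineage": "d;p;c;o;f;g",
                         "mean_rel_abund": 0.01}, index=list(nodes))


def _graph_from_edges(edges, domain="prokaryote"):
    """Unit-weight test graph with the attribute schema build_network emits."""
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, rho=0.9, weight=0.9, sign="+", p=1e-6)
    for n in g.nodes:
        g.nodes[n].update(domain=domain, lineage="d;p;c;o;f;g",
                          mean_rel_abund=0.01)
    return g


class TestNetworkFilter:
    def test_prevalence_rule(self):
        rel = pd.DataFrame(
            {"rare_prev": [0.2, 0, 0, 0, 0, 0.0],   # 1/6 samples = 16.7%
             "common": [0.1] * 6,
             "abundant_half": [0.4, 0.4, 0.4, 0, 0, 0.0]},
            index=[f"s{i}" for i in range(6)])
        rel["fill"] = 1.0 - rel.sum(axis=1)
        kept = network_filter(rel)
        assert "rare_prev" not in kept
        assert "common" in kept and "abundant_half" in kept

    def test_mean_abundance_rule(self):
        rel = pd.DataFrame({"tiny": [5e-5] * 6, "small": [2e-4] * 6},
                           index=[f"s{i}" for i in range(6)])
        rel["fill"] = 1.0 - rel.sum(axis=1)
        kept = network_filter(rel)
        assert "tiny" not in kept and "small" in kept

    def test_toy_enumeration(self):
        # 8 ASVs, hand-enumerated: keep iff mean > 1e-4 AND prevalence > 0.2
        cols = {f"a{i}": v for i, v in enumerate([
            [0.3, 0.3, 0.3, 0.3, 0.3],     # keep
            [0.2, 0.2, 0, 0, 0],           # prevalence 0.4 -> keep
            [0.5, 0, 0, 0, 0],             # prevalence 0.2 (not >) -> drop
            [9e-5, 9e-5, 9e-5, 9e-5, 9e-5],  # mean below cut -> drop
            [1.1e-4, 1.1e-4, 1.1e-4, 1.1e-4, 1.1e-4],  # keep
            [0, 0, 0, 0, 0],               # absent -> drop
            [2e-4, 0, 2e-4, 0, 0],         # prevalence 0.4, mean 8e-5 -> drop
            [0.05, 0.05, 0, 0.05, 0],      # keep
        ])}
        rel = pd.DataFrame(cols, index=[f"s{i}" for i in range(5)])
        assert network_filter(rel) == ["a0", "a1", "a4", "a7"]

    def test_empty_retention_error(self):
        rel = pd.DataFrame({"a": [1e-6] * 5}, index=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="relax"):
            network_filter(rel)


class TestSpearmanMatrix:
    def test_monotone_pair(self):
        x = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6.0],
                          "b": [2, 4, 9, 16, 30, 70.0]})
        out = spearman_matrix(x)
        assert out.rho.loc["a", "b"] == pytest.approx(1.0)
        assert out.p.loc["a", "b"] == 0.0

    def test_tied_data_matches_midrank_and_permutation_oracle(self):
        """n=6 with one tie: rho equals Pearson on mid-ranks; the two-sided
        t-approximation p lies within 0.02 of the exhaustive permutation p
        over all 720 orderings."""
        xv = np.array([1, 2, 3, 4, 5, 6.0])
        yv = np.array([2, 1, 3, 3, 5, 6.0])
        out = spearman_matrix(pd.DataFrame({"x": xv, "y": yv}))
        rho = out.rho.loc["x", "y"]
        midrank = np.corrcoef(scipy.stats.rankdata(xv),
                              scipy.stats.rankdata(yv))[0, 1]
        assert rho == pytest.approx(midrank)
        rx = scipy.stats.rankdata(xv)
        hits = sum(
            abs(np.corrcoef(rx, scipy.stats.rankdata(perm))[0, 1])
            >= abs(rho) - 1e-12
            for perm in itertools.permutations(yv))
        p_exact = hits / 720
        assert abs(out.p.loc["x", "y"] - p_exact) < 0.02

    def test_null_tail_matches_t_approximation(self):
        """Independent normal pairs at n=30: frequency of |rho| > 0.6 agrees
        with the two-sided t tail to within 0.001."""
        rng = np.random.default_rng(0)
        reps, n = 100_000, 30
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        rx = scipy.stats.rankdata(x, axis=1)
        ry = scipy.stats.rankdata(y, axis=1)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean(axis=1, keepdims=True)
        rho = (rx * ry).sum(axis=1) / np.sqrt(
            (rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
        freq = (np.abs(rho) > 0.6).mean()
        t = 0.6 * np.sqrt((n - 2) / (1 - 0.36))
        tail = 2 * scipy.stats.t.sf(t, df=n - 2)
        assert abs(freq - tail) < 1e-3

    def test_constant_column_excluded(self):
        x = pd.DataFrame({"a": [1, 2, 3, 4, 5.0], "b": [2.0] * 5})
        out = spearman_matrix(x)
        assert np.isnan(out.rho.loc["a", "b"])
        net = build_network(out, _meta_for(["a", "b"]))
        assert net.number_of_edges() == 0


class TestBuildNetwork:
    def test_strict_threshold(self):
        rho = pd.DataFrame([[1.0, 0.6], [0.6, 1.0]],
                           index=["a", "b"], columns=["a", "b"])
        net = build_network(_corr_from(rho), _meta_for(["a", "b"]))
        assert net.number_of_edges() == 0

    def test_triangle(self):
        ids = ["a", "b", "c"]
        rho = pd.DataFrame(0.9, index=ids, columns=ids)
        np.fill_diagonal(rho.values, 1.0)
        net = build_network(_corr_from(rho), _meta_for(ids))
        assert net.number_of_edges() == 3

    def test_hand_thresholding_and_isolated_removal(self):
        ids = list("abcd")
        rho = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        rho.loc["a", "b"] = rho.loc["b", "a"] = 0.75
        rho.loc["c", "d"] = rho.loc["d", "c"] = -0.85
        rho.loc["a", "c"] = rho.loc["c", "a"] = 0.3
        net = build_network(_corr_from(rho), _meta_for(ids))
        assert set(map(frozenset, net.edges)) == {frozenset("ab"), frozenset("cd")}
        assert net.edges["c", "d"]["sign"] == "-"
        # p gate also strict
        pm = pd.DataFrame(1e-6, index=ids, columns=ids)
        pm.loc["a", "b"] = pm.loc["b", "a"] = 0.05
        corr = CorrelationMatrix(rho=rho, p=pm, n=10)
        net2 = build_network(corr, _meta_for(ids))
        assert frozenset("ab") not in set(map(frozenset, net2.edges))

    def test_edge_set_invariant_to_orderings(self, small_sim, rng):
        prok, tax = small_sim[0], small_sim[2]
        rel = prok.div(prok.sum(axis=1), axis=0).iloc[:, :60]
        kept = network_filter(rel, min_prev=0.1)
        base = rel[kept]
        meta = node_metadata(base, tax)
        net1 = build_network(spearman_matrix(base), meta)
        shuffled = base.iloc[rng.permutation(len(base)),
                             rng.permutation(base.shape[1])]
        net2 = build_network(spearman_matrix(shuffled), meta)
        assert set(map(frozenset, net1.edges)) == set(map(frozenset, net2.edges))


class TestFastGreedyModules:
    def test_bridged_cliques_match_exhaustive_optimum(self):
        """Two 4-cliques joined by one edge: greedy partition equals the
        global modularity optimum found by brute force over all partitions."""
        g = _graph_from_edges(
            [(a, b) for a, b in itertools.combinations(range(4), 2)]
            + [(a, b) for a, b in itertools.combinations(range(4, 8), 2)]
            + [(0, 4)])
        mods = fast_greedy_modules(g)
        got = {frozenset(mods.members(m)) for m in set(mods.assignment.values())}
        assert got == {frozenset(range(4)), frozenset(range(4, 8))}

        def partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[first] + part[i]] + part[i + 1:]
                yield [[first]] + part

        best_q, best = -1.0, None
        for part in partitions(list(g.nodes)):
            q = nx.community.modularity(g, [set(c) for c in part], weight="weight")
            if q > best_q:
                best_q, best = q, part
        assert {frozenset(c) for c in best} == got
        assert mods.modularity == pytest.approx(best_q)

    def test_single_clique_one_module(self):
        g = _graph_from_edges(list(itertools.combinations(range(4), 2)))
        mods = fast_greedy_modules(g)
        assert mods.n_modules == 1
        assert mods.modularity == pytest.approx(0.0)

    def test_edgeless_network_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        mods = fast_greedy_modules(g)
        assert mods.n_modules == 3 and mods.modularity == 0.0

    def test_modularity_recomputes_from_partition(self, default_sim):
        prok, _, tax, meta, _ = default_sim
        rel = prok.div(prok.sum(axis=1), axis=0)
        kept = network_filter(rel)
        net = build_network(spearman_matrix(rel[kept]), node_metadata(rel[kept], tax))
        mods = fast_greedy_modules(net)
        comms = {}
        for node, m in mods.assignment.items():
            comms.setdefault(m, set()).add(node)
        q = nx.community.modularity(net, list(comms.values()), weight="weight")
        assert mods.modularity == pytest.approx(q, abs=1e-9)
        assert -0.5 <= mods.modularity <= 1.0
        assert set(mods.assignment) == set(net.nodes)


class TestNetworkStats:
    def test_survey_average_degree_identity(self):
        """2E/N on the integrated-network node/edge counts: 401/1040 -> 5.187
        and 903/4300 -> 9.524 (3 decimals)."""
        assert round(average_degree(401, 1040), 3) == 5.187
        assert round(average_degree(903, 4300), 3) == 9.524

    def test_three_node_path(self):
        g = _graph_from_edges([("a", "b"), ("b", "c")])
        mods = fast_greedy_modules(g)
        stats = network_stats(g, mods)
        btw = nx.betweenness_centrality(g, normalized=False)
        assert btw["b"] == 1.0
        assert stats.mean_betweenness == pytest.approx(1 / 3)
        assert stats.average_path_length == pytest.approx(4 / 3)
        assert stats.diameter == 2
        assert stats.average_degree == pytest.approx(4 / 3)

    def test_degree_sum_identity(self, default_sim):
        prok, _, tax, *_ = default_sim
        rel = prok.div(prok.sum(axis=1), axis=0)
        kept = network_filter(rel)
        net = build_network(spearman_matrix(rel[kept]), node_metadata(rel[kept], tax))
        stats = network_stats(net, fast_greedy_modules(net))
        degsum = sum(dict(net.degree).values())
        assert degsum == 2 * stats.n_edges
        assert stats.average_degree == pytest.approx(
            2 * stats.n_edges / stats.n_nodes, abs=1e-9)
        assert 0.0 <= stats.proportion_positive <= 1.0

    def test_disconnected_path_length_connected_pairs_only(self):
        g = _graph_from_edges([("a", "b"), ("c", "d"), ("d", "e")])
        stats = network_stats(g, fast_greedy_modules(g))
        # pairs: ab (1), cd/de (1,1), ce (2) -> mean over 8 ordered = 10/8
        assert stats.average_path_length == pytest.approx(10 / 8)
        assert stats.diameter == 2


class TestKeystones:
    def test_star_center_sole_keystone(self):
        g = _graph_from_edges([("hub", f"x{i}") for i in range(5)])
        ks = keystone_rank(g)
        assert list(ks.index) == ["hub"]

    def test_disjoint_cliques_no_keystones(self):
        g = _graph_from_edges(
            [(f"a{i}", f"a{j}") for i, j in itertools.combinations(range(4), 2)]
            + [(f"b{i}", f"b{j}") for i, j in itertools.combinations(range(4), 2)])
        assert len(keystone_rank(g)) == 0

    def test_matches_naive_path_counting(self, rng):
        """Brandes betweenness equals naive all-shortest-paths counting on
        100 random graphs with <= 12 nodes."""
        for _ in range(100):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
            naive = {v: 0.0 for v in g.nodes}
            for s, t in itertools.combinations(g.nodes, 2):
                if not nx.has_path(g, s, t):
                    continue
                paths = list(nx.all_shortest_paths(g, s, t))
                for path in paths:
                    for v in path[1:-1]:
                        naive[v] += 1 / len(paths)
            brandes = nx.betweenness_centrality(g, normalized=False)
            for v in g.nodes:
                assert brandes[v] == pytest.approx(naive[v], abs=1e-9)

    def test_toy_ranking_matches_enumeration(self):
        g = _graph_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("b", "d"),
                               ("d", "e"), ("e", "f"), ("e", "g")])
        ks = keystone_rank(g)
        naive = {v: 0.0 for v in g.nodes}
        for s, t in itertools.combinations(g.nodes, 2):
            paths = list(nx.all_shortest_paths(g, s, t))
            for path in paths:
                for v in path[1:-1]:
                    naive[v] += 1 / len(paths)
        expected = sorted((v for v in naive if naive[v] > 0),
                          key=lambda v: (-naive[v], -g.degree(v), v))
        assert list(ks.index) == expected
        for v in ks.index:
            assert ks.loc[v, "betweenness"] == pytest.approx(naive[v])


class TestExtractModules:
    def _toy(self):
        g = _graph_from_edges(
            [("p1", "p2"), ("p2", "p3"), ("p1", "p3"),          # prok module
             ("q1", "q2"), ("q2", "q3"), ("q1", "q3"), ("q1", "q4"),
             ("n1", "n2")])
        g.edges["q1", "q2"]["sign"] = "-"
        g.edges["q1", "q2"]["rho"] = -0.9
        g.edges["n1", "n2"]["sign"] = "-"
        g.edges["n1", "n2"]["rho"] = -0.7
        for n in ("n1", "n2"):
            g.nodes[n]["domain"] = "eukaryote"
        g.nodes["n1"]["lineage"] = "Eukaryota;Dinoflagellata;Dinophyceae;Noctilucales;Noctilucaceae;Noctiluca"
        tax = pd.DataFrame(
            [["Eukaryota", "Dinoflagellata", "Dinophyceae", "Noctilucales",
              "Noctilucaceae", "Noctiluca"]],
            index=["n1"], columns=RANKS)
        return g, tax

    def test_toy_reports(self):
        g, tax = self._toy()
        mods = fast_greedy_modules(g)
        out = extract_modules(g, mods, "Noctiluca", tax)
        assert out["focal_found"]
        # largest module containing a negative edge is the 4-node q module
        assert set(out["largest_negative"]["members"]) == {"q1", "q2", "q3", "q4"}
        assert set(out["largest_prok_negative"]["members"]) == {"q1", "q2", "q3", "q4"}
        focal = out["focal_modules"]
        assert len(focal) == 1
        nb = focal[0]["neighbors"]
        assert nb["neighbor"].tolist() == ["n2"]
        assert nb["sign"].tolist() == ["-"]

    def test_all_positive_network(self):
        g = _graph_from_edges([("a", "b"), ("b", "c")])
        mods = fast_greedy_modules(g)
        out = extract_modules(g, mods, "Noctiluca",
                              pd.DataFrame(columns=RANKS))
        assert out["largest_negative"] is None
        assert out["largest_prok_negative"] is None
        assert out["focal_modules"] == [] and not out["focal_found"]


class TestCompareRegions:
    def _stats(self, **over):
        base = dict(n_nodes=401, n_prok_nodes=342, n_euk_nodes=59,
                    n_edges=1040, proportion_positive=0.791,
                    average_degree=5.187, average_path_length=1.303,
                    diameter=6, clustering_coefficient=0.953,
                    mean_betweenness=0.0005, n_modules=95, modularity=0.943)
        base.update(over)
        from bloomnet.network import NetworkStats
        return NetworkStats(**base)

    def test_survey_direction_flags(self):
        br = self._stats()
        nr = self._stats(n_nodes=903, n_prok_nodes=697, n_euk_nodes=206,
                         n_edges=4300, proportion_positive=0.941,
                         average_degree=9.524, average_path_length=1.123,
                         diameter=6, clustering_coefficient=0.995,
                         mean_betweenness=0.0001, n_modules=159,
                         modularity=0.946)
        out = compare_regions(br, nr)
        for metric in ("n_nodes", "n_edges", "average_degree",
                       "clustering_coefficient"):
            assert out.loc[metric, "direction"] == "BR_lower"
        for metric in ("average_path_length", "mean_betweenness"):
            assert out.loc[metric, "direction"] == "BR_higher"
        assert out.loc["diameter", "direction"] == "equal"
        assert out.loc["modularity", "multi_module"] == "BR:True NR:True"

    def test_identical_stats_all_equal(self):
        out = compare_regions(self._stats(), self._stats())
        assert (out["direction"] == "equal").all()

    @pytest.mark.parametrize("q,expected", [(0.41, True), (0.40, False)])
    def test_multi_module_strict_boundary(self, q, expected):
        out = compare_regions(self._stats(modularity=q), self._stats())
        assert f"BR:{expected}" in out.loc["modularity", "multi_module"]


class TestGraphml:
    def test_round_trip(self, tmp_path, default_sim):
        prok, _, tax, *_ = default_sim
        rel = prok.div(prok.sum(axis=1), axis=0)
        kept = network_filter(rel)
        net = build_network(spearman_matrix(rel[kept]),
                            node_metadata(rel[kept], tax))
        mods = fast_greedy_modules(net)
        path = tmp_path / "net.graphml"
        write_graphml(net, mods, path)
        back = read_graphml(path)
        assert back.number_of_nodes() == net.number_of_nodes()
        assert back.number_of_edges() == net.number_of_edges()
        some = next(iter(back.nodes))
        for attr in ("lineage", "domain", "mean_rel_abund", "module",
                     "betweenness"):
            assert attr in back.nodes[some]
        u, v = next(iter(back.edges))
        for attr in ("rho", "sign", "p"):
            assert attr in back.edges[u, v]
        assert back.edges[u, v]["rho"] == pytest.approx(net.edges[u, v]["rho"])

    def test_schema_valid_xml(self, tmp_path):
        from lxml import etree
        g = _graph_from_edges([("a", "b")])
        path = tmp_path / "net.graphml"
        write_graphml(g, fast_greedy_modules(g), path)
        doc = etree.parse(str(path))
        root = doc.getroot()
        assert root.tag.endswith("graphml")
        keys = {k.get("attr.name"): k.get("attr.type")
                for k in root.iter("{http://graphml.graphdrawing.org/xmlns}key")}
        assert keys["rho"] in ("double", "float")
        assert keys["module"] in ("int", "long")

    def test_empty_network(self, tmp_path):
        g = nx.Graph()
        path = tmp_path / "empty.graphml"
        write_graphml(g, fast_greedy_modules(g), path)
        back = read_graphml(path)
        assert back.number_of_nodes() == 0 and back.number_of_edges() == 0


def test_small_n_null_edge_density():
    """At n=9 the |rho|>0.6 & p<0.05 gate admits the same pairs as the
    attainable rank-correlation grid allows: the null edge rate matches the
    t-tail estimate for the binding threshold (documents small-n behavior)."""
    rng = np.random.default_rng(0)
    n, n_taxa, reps = 9, 40, 10
    rates = []
    for _ in range(reps):
        x = pd.DataFrame(rng.random(size=(n, n_taxa)),
                         index=[f"s{i}" for i in range(n)])
        corr = spearman_matrix(x)
        iu = np.triu_indices(n_taxa, 1)
        edge = (np.abs(corr.rho.to_numpy()[iu]) > 0.6) \
            & (corr.p.to_numpy()[iu] < 0.05)
        rates.append(edge.mean())
    # binding constraint at n=9 is p<0.05 (needs |rho| >= ~0.68 > 0.6)
    t_crit = scipy.stats.t.ppf(0.975, df=n - 2)
    rho_crit = t_crit / np.sqrt(n - 2 + t_crit ** 2)
    assert rho_crit > 0.6
    mean_rate = np.mean(rates)
    assert 0.0 < mean_rate < 0.10
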