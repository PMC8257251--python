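"""TF centrality metrics and the Z-score consolidation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import floyd_warshall

from cafrank import (
    KnowledgeNetworks,
    TFMetrics,
    anova_tukey,
    consolidate_ranking,
    infer_anchored_subnetwork,
    ppi_direct_connections,
    regulon_target_count,
    relatedness_summary,
    subnetwork_metrics,
)
from cafrank.tfrank import _zscore_population


def _ppi(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence", "channel"])


class TestDirectConnections:
    def test_threshold_rule(self):
        ppi = _ppi([("tf", "g1", 0.5, "exp"), ("tf", "g2", 0.5, "exp"),
                    ("tf", "g3", 0.1, "exp"), ("tf", "g9", 0.9, "exp")])
        assert ppi_direct_connections("tf", {"g1", "g2", "g3"}, ppi) == 2

    def test_duplicate_edges_counted_once(self):
        ppi = _ppi([("tf", "g1", 0.5, "exp"), ("g1", "tf", 0.7, "database"),
                    ("tf", "g1", 0.3, "textmining")])
        assert ppi_direct_connections("tf", {"g1"}, ppi) == 1

    def test_absent_tf_zero(self):
        assert ppi_direct_connections("nope", {"g1"},
                                      _ppi([("a", "b", 0.5, "exp")])) == 0


class TestAnchoredSubnetwork:
    def test_direct_edge_beats_two_hop(self):
        # -ln(0.9)=0.105 < -ln(0.8)+-ln(0.8)=0.446
        ppi = _ppi([("a", "t", 0.9, "exp"), ("a", "m", 0.8, "exp"),
                    ("m", "t", 0.8, "exp")])
        subnet, unreachable = infer_anchored_subnetwork("a", {"t"}, ppi)
        assert set(subnet.edges) == {("a", "t")}
        assert unreachable == []

    def test_two_hop_beats_weak_direct(self):
        # -ln(0.2... wait direct 0.25 -> 1.386 > 2*-ln(0.9)=0.211
        ppi = _ppi([("a", "t", 0.25, "exp"), ("a", "m", 0.9, "exp"),
                    ("m", "t", 0.9, "exp")])
        subnet, _ = infer_anchored_subnetwork("a", {"t"}, ppi)
        assert ("a", "m") in subnet.edges and ("m", "t") in subnet.edges

    def test_star_when_all_targets_adjacent(self):
        targets = {f"g{i}" for i in range(5)}
        ppi = _ppi([("a", g, 0.8, "exp") for g in targets])
        subnet, _ = infer_anchored_subnetwork("a", targets, ppi)
        assert subnet.number_of_edges() == 5
        assert all(subnet.has_edge("a", g) for g in targets)

    def test_lexicographic_tie_break(self):
        # two equal-cost routes a-b-t and a-c-t; smallest sequence goes via b
        ppi = _ppi([("a", "b", 0.5, "exp"), ("b", "t", 0.5, "exp"),
                    ("a", "c", 0.5, "exp"), ("c", "t", 0.5, "exp")])
        subnet, _ = infer_anchored_subnetwork("a", {"t"}, ppi)
        assert set(subnet.edges) == {("a", "b"), ("b", "t")}

    def test_unreachable_recorded(self):
        ppi = _ppi([("a", "b", 0.5, "exp"), ("x", "y", 0.5, "exp")])
        subnet, unreachable = infer_anchored_subnetwork("a", {"b", "y"}, ppi)
        assert unreachable == [("a", "y")]

    def test_no_anchor_in_network_raises(self):
        with pytest.raises(ValueError, match="anchor"):
            infer_anchored_subnetwork("zz", {"b"}, _ppi([("a", "b", 0.5, "exp")]))

    @pytest.mark.parametrize("seed", range(10))
    def test_path_costs_match_floyd_warshall(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        nodes = [f"n{i:02d}" for i in range(n)]
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.35:
                    rows.append((nodes[i], nodes[j],
                                 float(rng.uniform(0.25, 0.95)), "exp"))
        if not rows:
            pytest.skip("empty graph draw")
        ppi = _ppi(rows)
        anchor = nodes[0]
        # dense oracle over the confidence>0.2 graph
        mat = np.full((n, n), np.inf)
        for a, b, conf, _ in rows:
            i, j = nodes.index(a), nodes.index(b)
            cost = -np.log(conf)
            mat[i, j] = mat[j, i] = min(mat[i, j], cost)
        dist = floyd_warshall(mat)
        targets = set(nodes[1:])
        try:
            subnet, unreachable = infer_anchored_subnetwork(anchor, targets, ppi)
        except ValueError:
            assert all(not (a == anchor or b == anchor) for a, b, *_ in rows)
            return
        for t in targets:
            j = nodes.index(t)
            if (anchor, t) in unreachable or t not in subnet:
                assert np.isinf(dist[0, j]) or t not in subnet
                continue
            got = nx.dijkstra_path_length(
                subnet, anchor, t,
                weight=lambda u, v, d: -np.log(d["confidence"]))
            assert got == pytest.approx(dist[0, j], abs=1e-9)


class TestSubnetworkMetrics:
    def test_star_closed_form(self):
        k = 6
        g = nx.star_graph([f"g{i}" for i in range(k + 1)])  # center g0, k leaves
        direct, cpl, cent = subnetwork_metrics(g, "g0",
                                               {f"g{i}" for i in range(1, k + 1)})
        assert direct == k
        assert cpl == pytest.approx(1.0)
        assert cent == pytest.approx(1.0)

    def test_cycle_centralization_zero(self):
        g = nx.cycle_graph([f"g{i}" for i in range(6)])
        _, _, cent = subnetwork_metrics(g, "g0", set())
        assert cent == pytest.approx(0.0)

    def test_tiny_subnet_missing_centralization(self):
        g = nx.Graph([("tf", "g1")])
        direct, cpl, cent = subnetwork_metrics(g, "tf", {"g1"})
        assert direct == 1 and cpl == pytest.approx(1.0) and np.isnan(cent)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bfs_degree_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = nx.gnp_random_graph(int(rng.integers(5, 20)), 0.3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        tf = "n00"
        targets = set(rng.choice(sorted(g.nodes), size=4, replace=False))
        direct, cpl, cent = subnetwork_metrics(g, tf, targets)
        assert direct == len(targets & set(g.neighbors(tf))) if tf in g else 0
        # BFS oracle
        hops = []
        for node in g.nodes:
            if node == tf:
                continue
            try:
                hops.append(nx.shortest_path_length(g, tf, node))
            except nx.NetworkXNoPath:
                pass
        if hops:
            assert cpl == pytest.approx(np.mean(hops))
        n = g.number_of_nodes()
        if n >= 3:
            degrees = np.array([d for _, d in g.degree()])
            assert cent == pytest.approx(
                (degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


class TestTabularSources:
    def test_regulon_count(self):
        reg = pd.DataFrame({"tf": ["tf", "tf", "x"], "target": ["g1", "g9", "g2"]})
        assert regulon_target_count("tf", {"g1", "g2"}, reg) == 1
        assert regulon_target_count("tf", {"g1", "g2"},
                                    pd.DataFrame({"tf": [], "target": []})) == 0

    def test_relatedness_arithmetic(self):
        rel = pd.DataFrame({
            "gene": ["g1", "g2", "g3", "g4"],
            "tf": ["tf"] * 4,
            "score": [10.0, 20.0, 3.0, 99.0],
            "flag": ["direct", "direct", "indirect", "direct"],
        })
        n, md, mi = relatedness_summary("tf", {"g1", "g2", "g3"}, rel)
        assert (n, md, mi) == (2, 15.0, 3.0)

    def test_empty_class_imputed_zero(self):
        rel = pd.DataFrame({"gene": ["g1"], "tf": ["tf"], "score": [10.0],
                            "flag": ["direct"]})
        n, md, mi = relatedness_summary("tf", {"g1"}, rel)
        assert (n, md, mi) == (1, 10.0, 0.0)

    def test_matches_groupby_oracle(self, rng):
        genes = [f"g{i}" for i in range(40)]
        rel = pd.DataFrame({
            "gene": rng.choice(genes, size=60),
            "tf": rng.choice(["tf1", "tf2"], size=60),
            "score": rng.uniform(0, 30, size=60),
            "flag": rng.choice(["direct", "indirect"], size=60),
        }).drop_duplicates(subset=["gene", "tf"])
        signature = set(rng.choice(genes, size=20, replace=False))
        for tf in ("tf1", "tf2"):
            n, md, mi = relatedness_summary(tf, signature, rel)
            sub = rel[(rel["tf"] == tf) & rel["gene"].isin(signature)]
            by = sub.groupby("flag")["score"]
            direct = by.get_group("direct") if "direct" in by.groups else pd.Series(dtype=float)
            indirect = by.get_group("indirect") if "indirect" in by.groups else pd.Series(dtype=float)
            assert n == len(direct)
            assert md == pytest.approx(direct.mean() if len(direct) else 0.0)
            assert mi == pytest.approx(indirect.mean() if len(indirect) else 0.0)


def _metrics(tf, comparison, base, cpl=2.0):
    return TFMetrics(tf=tf, comparison=comparison, string_degree=base,
                     anat_direct=base, anat_cpl=cpl, anat_centralization=0.5,
                     regnet_targets=base, var_n_direct=base,
                     var_mean_direct=float(base), var_mean_indirect=float(base))


class TestConsolidateRanking:
    def test_two_point_zscore(self):
        z = _zscore_population(np.array([3.0, 7.0]))
        assert np.allclose(sorted(z), [-1.0, 1.0])

    def test_identical_tfs_degenerate(self):
        metrics = [_metrics(tf, "c1", 5) for tf in ("A", "B", "C")]
        ranking = consolidate_ranking(metrics)
        assert np.all(ranking.zscores.to_numpy() == 0)
        assert ranking.anova_f == 0.0
        assert np.all(ranking.tukey_p.to_numpy()[~np.isnan(ranking.tukey_p.to_numpy())] == 1.0)

    def test_dominant_tf_ranks_first(self):
        metrics = []
        for comp in ("c1", "c2"):
            metrics.append(_metrics("hub", comp, 30, cpl=1.2))
            metrics.append(_metrics("d1", comp, 5, cpl=3.0))
            metrics.append(_metrics("d2", comp, 6, cpl=2.8))
            metrics.append(_metrics("d3", comp, 4, cpl=3.3))
        ranking = consolidate_ranking(metrics)
        assert ranking.top == "hub"
        assert ranking.anova_p < 0.05
        for decoy in ("d1", "d2", "d3"):
            assert ranking.tukey_p.loc["hub", decoy] < 0.05
        # per-parameter Z-scores standardized
        z = ranking.zscores.to_numpy()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        sd = z.std(axis=1, ddof=0)
        assert np.all((np.abs(sd - 1) < 1e-9) | (sd == 0))

    def test_shorter_path_never_lowers_z(self, rng):
        for _ in range(20):
            cpls = rng.uniform(1.0, 5.0, size=4)
            base = [_metrics(f"t{i}", "c", int(rng.integers(1, 20)), cpl=c)
                    for i, c in enumerate(cpls)]
            ranking = consolidate_ranking(base)
            z0 = ranking.zscores.loc[("c", "anat_cpl")]
            # shorten t0's path; its transformed Z must not decrease
            shorter = [m if m.tf != "t0" else _metrics("t0", "c", m.string_degree,
                                                       cpl=cpls[0] * 0.5)
                       for m in base]
            z1 = consolidate_ranking(shorter).zscores.loc[("c", "anat_cpl")]
            assert z1["t0"] >= z0["t0"] - 1e-12

    def test_missing_cpl_is_worst_case(self):
        metrics = [_metrics("A", "c", 5, cpl=float("nan")),
                   _metrics("B", "c", 5, cpl=2.0),
                   _metrics("C", "c", 5, cpl=3.0)]
        z = consolidate_ranking(metrics).zscores.loc[("c", "anat_cpl")]
        assert z["A"] == z.min()


class TestAnovaTukey:
    def test_identical_groups(self):
        f, p, pairwise = anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert f == 0.0 and p == 1.0
        assert pairwise.loc["a", "b"] == 1.0

    def test_textbook_f_statistic(self):
        groups = {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.0, 4.0],
                  "g3": [10.0, 11.0, 12.0]}
        f, p, pairwise = anova_tukey(groups)
        # hand computation: SSB=146, MSB=73, SSW=6, MSW=1 -> F=73
        assert f == pytest.approx(73.0)
        assert p < 0.001
        assert pairwise.loc["g1", "g3"] < 0.01
        # symmetric with excluded diagonal
        assert pairwise.equals(pairwise.T)
        assert np.isnan(np.diag(pairwise)).all()

    def test_tukey_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(loc, 1.0, size=6)
                  for k, loc in [("a", 0.0), ("b", 1.0), ("c", 3.0)]}
        _, _, pairwise = anova_tukey(groups)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(data, labels)
        for row, p_sm in zip(np.array(sm._results_table.data[1:], dtype=object),
                             sm.pvalues):
            assert pairwise.loc[row[0], row[1]] == pytest.approx(p_sm, abs=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})
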