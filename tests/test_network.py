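"""Correlation network: Spearman oracle, top-K selection, density scan,
eigenvector centrality, export."""

import math
import warnings
import xml.etree.ElementTree as ET

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import toxmetnet as tn
from toxmetnet.network import CorrelationResult


def rank_pearson_oracle(x, y):
    """Textbook Pearson on explicit mid-ranks (independent of the library)."""
    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r
    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    mx, my = rx.mean(), ry.mean()
    num = ((rx - mx) * (ry - my)).sum()
    den = math.sqrt(((rx - mx) ** 2).sum() * ((ry - my) ** 2).sum())
    return num / den


def random_corr(rng, n_mets=28, n_samples=12):
    levels = pd.DataFrame(rng.standard_normal((n_samples, n_mets)),
                          columns=[f"m{i:02d}" for i in range(n_mets)])
    return tn.spearman_matrix(levels)


class TestSpearmanMatrix:
    def test_monotone_and_antitone_pairs(self):
        levels = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0],
                               "b": [2.0, 4.0, 9.0, 16.0, 25.0],
                               "c": [5.0, 4.0, 3.0, 2.0, 1.0]})
        res = tn.spearman_matrix(levels)
        assert res.scc.loc["a", "b"] == pytest.approx(1.0)
        assert res.scc.loc["a", "c"] == pytest.approx(-1.0)
        assert res.p_values.loc["a", "b"] == 0.0

    def test_agrees_with_rank_pearson_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            levels = pd.DataFrame(rng.standard_normal((12, 10)))
            levels.columns = [f"m{i}" for i in range(10)]
            res = tn.spearman_matrix(levels)
            i, j = rng.integers(0, 10, size=2)
            while i == j:
                j = rng.integers(0, 10)
            expect = rank_pearson_oracle(levels.iloc[:, i], levels.iloc[:, j])
            assert res.scc.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_metabolite_excluded(self):
        levels = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                               "b": [5.0, 5.0, 5.0, 5.0],
                               "c": [4.0, 3.0, 2.0, 1.0]})
        with pytest.warns(UserWarning, match="constant"):
            res = tn.spearman_matrix(levels)
        assert res.excluded == ["b"]
        assert np.isnan(res.scc.loc["a", "b"])
        net = tn.select_top_k(res, 1)
        assert "b" not in net.graph.nodes

    def test_p_monotone_in_abs_rho(self):
        rng = np.random.default_rng(1)
        res = random_corr(rng, n_mets=10)
        tri = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        pairs = [(abs(res.scc.iloc[i, j]), res.p_values.iloc[i, j])
                 for i, j in tri]
        pairs.sort()
        ps = [p for _, p in pairs]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            tn.spearman_matrix(pd.DataFrame(np.ones((3, 5))))
        with pytest.raises(ValueError):
            tn.spearman_matrix(pd.DataFrame(np.ones((6, 1))))


class TestSelectTopK:
    def test_k30_on_28_metabolites(self):
        rng = np.random.default_rng(2)
        res = random_corr(rng, n_mets=28)
        net = tn.select_top_k(res, 30)
        assert net.n_edges == 30
        assert net.density == pytest.approx(
            2 * 30 / (net.n_nodes * (net.n_nodes - 1)), abs=1e-12)

    def test_saturation_complete_graph(self):
        rng = np.random.default_rng(3)
        res = random_corr(rng, n_mets=6)
        net = tn.select_top_k(res, 15)
        assert net.n_edges == 15 and net.n_nodes == 6
        assert net.density == pytest.approx(1.0)

    def test_k_beyond_available_warns_and_saturates(self):
        rng = np.random.default_rng(4)
        res = random_corr(rng, n_mets=5)
        with pytest.warns(UserWarning, match="exceeds"):
            net = tn.select_top_k(res, 100)
        assert net.n_edges == 10

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            res = random_corr(rng, n_mets=10)
            pairs = {}
            cols = list(res.scc.columns)
            for i, a in enumerate(cols):
                for b in cols[i + 1:]:
                    pairs[(a, b)] = abs(res.scc.loc[a, b])
            expect = set(sorted(pairs, key=pairs.get, reverse=True)[:12])
            net = tn.select_top_k(res, 12)
            got = {tuple(sorted(e)) for e in net.graph.edges}
            assert got == expect

    def test_ranks_consecutive_and_nodes_incident(self):
        rng = np.random.default_rng(6)
        res = random_corr(rng, n_mets=12)
        net = tn.select_top_k(res, 8)
        assert list(net.edges["rank"]) == list(range(1, 9))
        incident = set(net.edges["source"]) | set(net.edges["target"])
        assert set(net.graph.nodes) == incident


def star_correlation(n_partners=80):
    """Correlation structure whose top edges all share one node."""
    names = ["hub"] + [f"p{i:02d}" for i in range(n_partners)]
    scc = pd.DataFrame(np.zeros((len(names), len(names))),
                       index=names, columns=names)
    np.fill_diagonal(scc.values, 1.0)
    rng = np.random.default_rng(7)
    for i, p in enumerate(names[1:]):
        scc.loc["hub", p] = scc.loc[p, "hub"] = 0.95 - i * 1e-4
    for i, a in enumerate(names[1:]):
        for b in names[1 + i + 1:]:
            v = rng.uniform(0.001, 0.01)
            scc.loc[a, b] = scc.loc[b, a] = v
    p_values = pd.DataFrame(np.zeros_like(scc), index=names, columns=names)
    return CorrelationResult(scc=scc, p_values=p_values, n_samples=12,
                             excluded=[])


class TestScanDensity:
    def test_star_closed_form_and_argmin(self):
        res = star_correlation()
        table, best_k = tn.scan_density(res)
        assert len(table) == 15                      # K = 10,15,...,80
        for _, row in table.iterrows():
            assert row["density"] == pytest.approx(
                2.0 / (row["K"] + 1), abs=1e-12)
        assert best_k == 80

    def test_saturated_scan_ties_give_smallest_k(self):
        rng = np.random.default_rng(8)
        res = random_corr(rng, n_mets=4)             # 6 pairs < 10
        table, best_k = tn.scan_density(res)
        assert best_k == 10
        assert table["density"].nunique() == 1

    def test_invalid_k_values_rejected(self):
        res = star_correlation(10)
        with pytest.raises(ValueError):
            tn.scan_density(res, [])
        with pytest.raises(ValueError):
            tn.scan_density(res, [20, 10])


class TestEigenvectorCentrality:
    def test_complete_graph_all_ones(self):
        rng = np.random.default_rng(9)
        res = random_corr(rng, n_mets=6)
        net = tn.select_top_k(res, 15)
        ranking = tn.eigenvector_centrality(net)
        assert np.allclose(ranking.scores, 1.0, atol=1e-6)

    def test_star_closed_form(self):
        """Star with m leaves: center 1, leaves 1/sqrt(m).

        Exercises the bipartite-oscillation restart (a star has eigenvalues
        +-sqrt(m), so plain power iteration cannot converge).
        """
        res = star_correlation(n_partners=9)
        net = tn.select_top_k(res, 9)                # hub edges only
        ranking = tn.eigenvector_centrality(net)
        assert ranking.scores["hub"] == pytest.approx(1.0)
        leaves = ranking.scores.drop("hub")
        assert np.allclose(leaves, 1.0 / math.sqrt(9), atol=1e-8)

    def test_agrees_with_dense_eigensolver(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(5, 41))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2 ** 31)))
            if g.number_of_edges() == 0:
                continue
            edges = pd.DataFrame(
                [{"source": str(a), "target": str(b), "scc": 0.5,
                  "p_value": 0.01, "rank": i + 1}
                 for i, (a, b) in enumerate(g.edges)])
            g2 = nx.relabel_nodes(g, str)
            g2.remove_nodes_from(list(nx.isolates(g2)))
            net = tn.MetaboliteNetwork(graph=g2, k_requested=len(edges),
                                       edges=edges)
            ranking = tn.eigenvector_centrality(net)
            nodes = sorted(g2.nodes)
            a = nx.to_numpy_array(g2, nodelist=nodes)
            evals, evecs = np.linalg.eigh(a)
            v = np.abs(evecs[:, np.argmax(evals)])
            v = v / v.max()
            got = ranking.scores[nodes].to_numpy()
            dominant = v > 1e-6
            assert np.allclose(got[dominant], v[dominant], atol=1e-8)

    def test_eigen_equation_residual(self):
        rng = np.random.default_rng(11)
        res = random_corr(rng, n_mets=20)
        net = tn.select_top_k(res, 30)
        ranking = tn.eigenvector_centrality(net)
        nodes = sorted(net.graph.nodes)
        a = nx.to_numpy_array(net.graph, nodelist=nodes)
        v = ranking.scores[nodes].to_numpy()
        dom = ranking.in_dominant[nodes].to_numpy()
        av = a @ v
        lam = (v[dom] @ av[dom]) / (v[dom] @ v[dom])
        resid = np.linalg.norm(av[dom] - lam * v[dom]) / np.linalg.norm(v)
        assert resid < 1e-6

    def test_relabel_invariance(self):
        rng = np.random.default_rng(12)
        res = random_corr(rng, n_mets=10)
        net = tn.select_top_k(res, 12)
        r1 = tn.eigenvector_centrality(net)
        mapping = {n: f"X_{n}" for n in net.graph.nodes}
        g2 = nx.relabel_nodes(net.graph, mapping)
        edges2 = net.edges.copy()
        edges2["source"] = edges2["source"].map(mapping)
        edges2["target"] = edges2["target"].map(mapping)
        net2 = tn.MetaboliteNetwork(graph=g2, k_requested=12, edges=edges2)
        r2 = tn.eigenvector_centrality(net2)
        for n in net.graph.nodes:
            assert r1.scores[n] == pytest.approx(r2.scores[mapping[n]],
                                                 abs=1e-9)

    def test_disconnected_minor_component_flagged(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c"), ("a", "d"),
                          ("x", "y")])
        edges = pd.DataFrame(
            [{"source": a, "target": b, "scc": 0.9, "p_value": 0.0,
              "rank": i + 1} for i, (a, b) in enumerate(g.edges)])
        net = tn.MetaboliteNetwork(graph=g, k_requested=5, edges=edges)
        ranking = tn.eigenvector_centrality(net)
        assert not ranking.in_dominant["x"]
        assert ranking.in_dominant["a"]


class TestExport:
    def _network(self, rng, n_mets=28, k=30, rename=None):
        res = random_corr(rng, n_mets=n_mets)
        if rename:
            res.scc.index = res.scc.columns = rename
            res.p_values.index = res.p_values.columns = rename
        net = tn.select_top_k(res, k)
        ranking = tn.eigenvector_centrality(net)
        return net, ranking

    def test_sif_line_count(self, tmp_path):
        rng = np.random.default_rng(13)
        net, ranking = self._network(rng)
        sif = tmp_path / "net.sif"
        tn.export_network(net, ranking, sif, tmp_path / "net.graphml")
        lines = sif.read_text().strip().splitlines()
        assert len(lines) == 30
        assert all(len(line.split("\t")) == 3 for line in lines)

    def test_graphml_roundtrip(self, tmp_path):
        rng = np.random.default_rng(14)
        net, ranking = self._network(rng, n_mets=10, k=12)
        path = tmp_path / "net.graphml"
        tn.export_network(net, ranking, tmp_path / "net.sif", path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.graph.nodes)
        assert len(back.edges) == net.n_edges
        for _, e in net.edges.iterrows():
            attrs = back.edges[e["source"], e["target"]]
            assert attrs["scc"] == pytest.approx(e["scc"])
            assert attrs["rank"] == e["rank"]
        for n in net.graph.nodes:
            assert back.nodes[n]["ec_score"] == pytest.approx(
                ranking.scores[n])

    def test_xml_escaping_of_names(self, tmp_path):
        rng = np.random.default_rng(15)
        names = [f"met & <{i}>" for i in range(8)]
        net, ranking = self._network(rng, n_mets=8, k=10, rename=names)
        path = tmp_path / "net.graphml"
        tn.export_network(net, ranking, tmp_path / "net.sif", path)
        tree = ET.parse(path)                        # strict parser
        assert tree.getroot() is not None
        back = nx.read_graphml(path)
        assert set(back.nodes) <= set(names)
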