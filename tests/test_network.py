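import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import bh_oracle, mic_oracle
from sadnet import network as nw
from sadnet.io_tables import OTUTable
from sadnet.network import (MICResult, _equipartition, adjust_pvalues,
                            build_network, cooccurrence_null_test, edge_table,
                            mic, pairwise_mic, permutation_pvalues,
                            topology_stats, write_graphml, write_sif)
from sadnet.synthetic import (CommunitySpec, plant_cooccurrence,
                              simulate_otu_table, simulate_sad)


def _planted_table(n_otus=12, n_samples=24, seed=0, pairs=()):
    community = simulate_sad(
        CommunitySpec(n_otus * 2, "pln", {"mu": 3.0, "sigma": 1.0}, seed=seed))
    table = simulate_otu_table(community, n_samples, depth=4000,
                               overdispersion=0.5, seed=seed + 1)
    table = OTUTable(table.counts.iloc[:, :n_otus], table.metadata)
    if pairs:
        table = plant_cooccurrence(table, list(pairs), seed=seed + 2)
    return table


class TestMic:
    def test_monotone_is_one(self, rng):
        x = np.sort(rng.normal(size=100))
        y = x ** 3 + 5
        assert mic(x, y) == pytest.approx(1.0, abs=1e-9)

    def test_constant_is_zero(self, rng):
        x = rng.normal(size=50)
        assert mic(x, np.full(50, 2.0)) == 0.0

    def test_symmetry(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert mic(x, y) == pytest.approx(mic(y, x), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60) + x
        a = mic(x, y)
        b = mic(np.exp(x), y)
        c = mic(x, np.argsort(np.argsort(y)).astype(float))
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-12)

    def test_length_checks(self):
        with pytest.raises(ValueError):
            mic([1, 2, 3], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            mic([1, 2, 3], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(12))
    def test_exhaustive_oracle_n10(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        expect = mic_oracle(x, y, 6, _equipartition)
        assert mic(x, y, max_bins=6) == pytest.approx(expect, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_exhaustive_oracle_n12_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.integers(0, 5, size=12).astype(float)
        y = rng.integers(0, 4, size=12).astype(float)
        expect = mic_oracle(x, y, 6, _equipartition)
        assert mic(x, y, max_bins=6) == pytest.approx(expect, abs=1e-9)

    def test_lower_bound_vs_equipartition_grid(self, rng):
        # MIC >= normalized MI of a fixed equipartitioned grid
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        n = 50
        xb = _equipartition(x, 3)
        yb = _equipartition(y, 3)
        tab = np.zeros((3, 3))
        for a, b in zip(xb, yb):
            tab[a, b] += 1
        p = tab / n
        px, py = p.sum(1), p.sum(0)
        mi = sum(p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
                 for i in range(3) for j in range(3) if p[i, j] > 0)
        assert mic(x, y) >= mi / np.log(3) - 1e-9


class TestPairwiseMic:
    def test_pair_count(self):
        table = _planted_table(n_otus=6)
        results = pairwise_mic(table, 0.0)
        assert len(results) == 15

    def test_duplicated_column_gives_one(self):
        table = _planted_table(n_otus=5, seed=3)
        counts = table.counts.copy()
        counts["twin"] = counts[counts.columns[0]]
        results = pairwise_mic(OTUTable(counts, table.metadata), 0.0)
        twin = [r for r in results
                if {r.otu_a, r.otu_b} == {counts.columns[0], "twin"}]
        assert twin[0].mic == pytest.approx(1.0, abs=1e-9)
        assert all(r.otu_a != r.otu_b for r in results)

    def test_planted_pair_high_mic_positive(self):
        table = _planted_table(seed=5, pairs=[("OTU00000", "OTU00001",
                                               "positive", 2.5)])
        results = pairwise_mic(table, 0.0)
        hit = [r for r in results
               if {r.otu_a, r.otu_b} == {"OTU00000", "OTU00001"}][0]
        assert hit.mic > 0.8
        assert hit.sign == "positive"


class TestPermutationPvalues:
    def test_perfect_pair_minimum_p(self):
        table = _planted_table(n_otus=4, seed=7)
        counts = table.counts.copy()
        counts["twin"] = counts[counts.columns[0]]
        t2 = OTUTable(counts, table.metadata)
        pairs = pairwise_mic(t2, 0.0)
        out = permutation_pvalues(t2, pairs, n_perm=99, seed=1)
        twin = [r for r in out
                if {r.otu_a, r.otu_b} == {counts.columns[0], "twin"}][0]
        assert twin.p_perm == pytest.approx(1 / 100)

    def test_p_bounds(self):
        table = _planted_table(n_otus=6, seed=9)
        pairs = pairwise_mic(table, 0.0)
        out = permutation_pvalues(table, pairs, n_perm=99, seed=2)
        for r in out:
            assert 0 < r.p_perm <= 1

    def test_null_p_approximately_uniform(self):
        # independent OTUs: KS distance of p-values from U(0,1) < 0.1
        from scipy.stats import kstest
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            rng.integers(1, 2000, size=(20, 30)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"o{i:02d}" for i in range(30)])
        table = OTUTable(counts)
        pairs = pairwise_mic(table, 0.0)
        out = permutation_pvalues(table, pairs, n_perm=199, seed=3)
        ps = [r.p_perm for r in out]
        assert len(ps) >= 200
        assert kstest(ps, "uniform").statistic < 0.1

    def test_determinism(self):
        table = _planted_table(n_otus=5, seed=13)
        pairs = pairwise_mic(table, 0.0)
        a = permutation_pvalues(table, pairs, n_perm=99, seed=5)
        b = permutation_pvalues(table, pairs, n_perm=99, seed=5)
        assert [r.p_perm for r in a] == [r.p_perm for r in b]

    def test_n_perm_floor(self):
        table = _planted_table(n_otus=4, seed=15)
        with pytest.raises(ValueError):
            permutation_pvalues(table, pairwise_mic(table, 0.0), n_perm=10)


class TestAdjustPvalues:
    def test_equal_ps_unchanged(self):
        p = [0.02, 0.02, 0.02]
        assert list(adjust_pvalues(p)) == pytest.approx(p)

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_hand_bh(self):
        out = adjust_pvalues([0.01, 0.02, 0.03])
        assert list(out) == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_oracle(self, rng):
        p = rng.uniform(size=25)
        assert np.allclose(adjust_pvalues(p), bh_oracle(p), atol=1e-12)

    def test_never_decreases(self, rng):
        p = rng.uniform(size=40)
        assert (adjust_pvalues(p) >= p - 1e-15).all()

    def test_bonferroni(self):
        out = adjust_pvalues([0.01, 0.4], method="bonferroni")
        assert list(out) == pytest.approx([0.02, 0.8])


class TestBuildNetwork:
    def _results(self):
        return [
            MICResult("a", "b", 0.95, "positive", 0.001, 0.0005),
            MICResult("b", "c", 0.85, "negative", 0.001, 0.0009),
            MICResult("c", "d", 0.95, "positive", 0.2, 0.4),
            MICResult("d", "e", 0.5, "positive", 0.0001, 0.0004),
        ]

    def test_filters_applied(self):
        net = build_network(self._results())
        assert set(net.graph.edges) == {("a", "b"), ("b", "c")}
        assert "e" not in net.graph.nodes  # isolated OTUs excluded

    def test_empty_network_conventions(self):
        net = build_network([MICResult("a", "b", 0.1, "positive", 0.9, 0.9)])
        assert net.topology["n_nodes"] == 0
        assert net.topology["n_components"] == 0
        assert np.isnan(net.topology["clustering_coefficient"])

    def test_thresholds_off_gives_complete_graph(self):
        results = [MICResult(a, b, 0.5, "positive", 0.5, 0.9)
                   for a, b in itertools.combinations("abcd", 2)]
        net = build_network(results, mic_threshold=0.0, p_threshold=1.0)
        assert net.graph.number_of_edges() == 6

    def test_edge_set_shrinks_with_tighter_thresholds(self):
        res = self._results()
        loose = build_network(res, 0.4, 0.5)
        tight = build_network(res, 0.9, 0.001)
        assert set(tight.graph.edges) <= set(loose.graph.edges)


class TestTopologyStats:
    def _net(self, edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        from sadnet.network import CooccurrenceNetwork
        return CooccurrenceNetwork(graph=g, edges=[])

    def test_triangle(self):
        t = topology_stats(self._net([("a", "b"), ("b", "c"), ("a", "c")]))
        assert t["clustering_coefficient"] == pytest.approx(1.0)
        assert t["characteristic_path_length"] == pytest.approx(1.0)
        assert t["diameter"] == 1
        assert t["n_components"] == 1
        assert t["avg_neighbours"] == pytest.approx(2.0)

    def test_path_graph_p4(self):
        t = topology_stats(self._net([("a", "b"), ("b", "c"), ("c", "d")]))
        assert t["clustering_coefficient"] == pytest.approx(0.0)
        assert t["diameter"] == 3
        assert t["characteristic_path_length"] == pytest.approx(10 / 6)

    def test_two_disjoint_edges(self):
        t = topology_stats(self._net([("a", "b"), ("c", "d")]))
        assert t["n_components"] == 2
        assert t["avg_neighbours"] == pytest.approx(1.0)
        assert t["characteristic_path_length"] == pytest.approx(1.0)


class TestEndToEnd:
    def test_planted_edges_recovered(self):
        # BH-adjusted minimum p is p_min * m / t, so the p threshold must sit
        # above 0.005 * 45 / 2 here for planted edges to be recoverable at all
        pairs = [("OTU00000", "OTU00001", "positive", 3.0),
                 ("OTU00002", "OTU00003", "negative", 3.0)]
        table = _planted_table(n_otus=10, n_samples=24, seed=21, pairs=pairs)
        results = pairwise_mic(table, 0.0)
        results = permutation_pvalues(table, results, n_perm=199, seed=4)
        net = build_network(results, 0.7, 0.15)
        assert ("OTU00000", "OTU00001") in net.graph.edges
        assert net.graph.edges["OTU00000", "OTU00001"]["sign"] == "positive"
        assert ("OTU00002", "OTU00003") in net.graph.edges
        assert net.graph.edges["OTU00002", "OTU00003"]["sign"] == "negative"

    def test_null_test_planted_is_minimum(self):
        pairs = [("OTU00000", "OTU00001", "positive", 3.0)]
        table = _planted_table(n_otus=6, n_samples=24, seed=23, pairs=pairs)
        p = cooccurrence_null_test(table, n_perm=99, seed=5, p_threshold=0.05,
                                   min_rel_abundance_pct=0.0)
        assert p == pytest.approx(1 / 100)

    def test_null_test_deterministic(self):
        table = _planted_table(n_otus=5, n_samples=20, seed=25)
        a = cooccurrence_null_test(table, n_perm=99, seed=6,
                                   min_rel_abundance_pct=0.0)
        b = cooccurrence_null_test(table, n_perm=99, seed=6,
                                   min_rel_abundance_pct=0.0)
        assert a == b


class TestExports:
    def _net(self):
        results = [MICResult("a", "b", 0.9, "positive", 0.001, 0.001),
                   MICResult("b", "c", 0.85, "negative", 0.001, 0.001)]
        return build_network(results, 0.8, 0.01,
                             domains={"a": "bacteria", "b": "archaea",
                                      "c": "eukarya"})

    def test_edge_table_columns(self):
        df = edge_table(self._net())
        assert list(df.columns) == ["otuA", "otuB", "mic", "sign", "p", "p_adj"]
        assert len(df) == 2

    def test_sif(self, tmp_path):
        write_sif(self._net(), tmp_path / "n.sif")
        lines = (tmp_path / "n.sif").read_text().splitlines()
        assert "a\tcooccurs_pos\tb" in lines
        assert "b\tcooccurs_neg\tc" in lines

    def test_graphml_round_trip(self, tmp_path):
        write_graphml(self._net(), tmp_path / "n.graphml")
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert g.number_of_edges() == 2
        assert g.nodes["a"]["domain"] == "bacteria"
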