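"""Consensus extraction and binary graph metrics against independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from netconsensus.consensus import (
    assortativity,
    characteristic_pathlength,
    clustering_coefficient,
    consensus_edges,
    global_efficiency,
    local_efficiency,
    metrics_table,
    network_metrics,
)
from netconsensus.netio import BinaryNetwork, NetworkError
from netconsensus.synthgen import synthetic_scheme


def _net(n, edges):
    scheme = synthetic_scheme(n)
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryNetwork(scheme=scheme, adjacency=a)


def _random_net(n, p, rng):
    scheme = synthetic_scheme(n)
    iu = np.triu_indices(n, k=1)
    a = np.zeros((n, n), dtype=int)
    mask = rng.random(len(iu[0])) < p
    a[iu[0][mask], iu[1][mask]] = 1
    return BinaryNetwork(scheme=scheme, adjacency=a | a.T)


K4 = _net(4, itertools.combinations(range(4), 2))
STAR4 = _net(4, [(0, 1), (0, 2), (0, 3)])


class TestClosedForms:
    def test_complete_graph(self):
        m = network_metrics(K4)
        assert m["PL"] == 1.0
        assert m["CC"] == 1.0
        assert m["Geff"] == 1.0
        assert m["Leff"] == 1.0

    def test_ring_pathlength_and_efficiency(self):
        """C5: distances per node are (1,1,2,2) so PL = 1.5 and
        Geff = mean(1,1,1/2,1/2) = 0.75 — restricted to the ring nodes."""
        from netconsensus.netio import ParcellationScheme

        scheme5 = ParcellationScheme(
            name="c5",
            labels=tuple("abcde"),
            hemispheres=("L", "L", "L", "R", "R"),
            lobes=("frontal",) * 5,
        )
        a = np.zeros((5, 5), dtype=int)
        for i in range(5):
            a[i, (i + 1) % 5] = a[(i + 1) % 5, i] = 1
        c5 = BinaryNetwork(scheme=scheme5, adjacency=a)
        pl = characteristic_pathlength(c5)
        assert pl.value == pytest.approx(1.5)
        assert pl.n_unreachable_pairs == 0
        assert global_efficiency(c5) == pytest.approx(0.75)

    def test_star_clustering_and_assortativity(self):
        assert clustering_coefficient(STAR4) == 0.0
        assert assortativity(STAR4) == pytest.approx(-1.0)

    def test_regular_graph_assortativity_undefined(self):
        from netconsensus.netio import ParcellationScheme

        scheme5 = ParcellationScheme(
            name="c5", labels=tuple("abcde"),
            hemispheres=("L", "L", "L", "R", "R"), lobes=("frontal",) * 5,
        )
        a = np.zeros((5, 5), dtype=int)
        for i in range(5):
            a[i, (i + 1) % 5] = a[(i + 1) % 5, i] = 1
        c5 = BinaryNetwork(scheme=scheme5, adjacency=a)
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(assortativity(c5))

    def test_disconnected_pathlength_reports_unreachable(self):
        two_k2 = _net(4, [(0, 1), (2, 3)])
        pl = characteristic_pathlength(two_k2)
        assert pl.value == 1.0
        assert pl.n_unreachable_pairs == 8

    def test_empty_graph_efficiency_zero(self):
        empty = _net(4, [])
        assert global_efficiency(empty) == 0.0


class TestOracleEquivalence:
    """All five metrics against independent brute-force / networkx oracles
    on random graphs, exact to 1e-12."""

    @pytest.mark.parametrize("seed", range(12))
    def test_random_graphs_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        net = _random_net(12, 0.3, rng)
        g = nx.from_numpy_array(np.asarray(net.adjacency))
        a = np.asarray(net.adjacency)

        # path length: mean over finite ordered pairs via BFS oracle
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        finite = [
            d for src, dd in lengths.items() for dst, d in dd.items() if src != dst
        ]
        if finite:
            assert characteristic_pathlength(net).value == pytest.approx(
                np.mean(finite), abs=1e-12
            )

        # clustering: triangle-enumeration oracle with deg<2 -> 0
        n = a.shape[0]
        local = []
        for i in range(n):
            nbrs = np.flatnonzero(a[i])
            if len(nbrs) < 2:
                local.append(0.0)
                continue
            links = sum(
                a[u, v] for u, v in itertools.combinations(nbrs, 2)
            )
            local.append(2 * links / (len(nbrs) * (len(nbrs) - 1)))
        assert clustering_coefficient(net) == pytest.approx(np.mean(local), abs=1e-12)

        # efficiencies vs networkx
        assert global_efficiency(net) == pytest.approx(
            nx.global_efficiency(g), abs=1e-12
        )
        assert local_efficiency(net) == pytest.approx(
            nx.local_efficiency(g), abs=1e-12
        )

        # assortativity: edge-list Pearson oracle (both orientations)
        deg = a.sum(axis=1)
        xs, ys = [], []
        for i, j in zip(*np.nonzero(np.triu(a, 1))):
            xs += [deg[i], deg[j]]
            ys += [deg[j], deg[i]]
        if len(xs) and np.std(xs) > 0:
            oracle = np.corrcoef(xs, ys)[0, 1]
            assert assortativity(net) == pytest.approx(oracle, abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(55)
        net = _random_net(10, 0.35, rng)
        perm = rng.permutation(10)
        permuted = BinaryNetwork(
            scheme=net.scheme,
            adjacency=np.asarray(net.adjacency)[np.ix_(perm, perm)],
        )
        m1, m2 = network_metrics(net), network_metrics(permuted)
        for key in ("PL", "CC", "Geff", "Leff", "AS"):
            if np.isnan(m1[key]):
                assert np.isnan(m2[key])
            else:
                assert m1[key] == pytest.approx(m2[key], abs=1e-12)


class TestConsensusEdges:
    def test_unanimous_edge_prevalence_one(self):
        nets = [_net(4, [(0, 1), (2, 3)]) for _ in range(3)]
        res = consensus_edges(nets, [n for n in nets])
        assert res.prevalence[0, 1] == 1.0
        assert res.intersection.edge_set() == {(0, 1), (2, 3)}

    def test_one_pipeline_only_prevalence_zero(self):
        p1 = [_net(4, [(0, 1), (0, 2)]) for _ in range(3)]
        p2 = [_net(4, [(1, 3), (2, 3)]) for _ in range(3)]
        res = consensus_edges(p1, p2)
        assert res.prevalence.sum() == 0.0
        assert res.intersection.k == 0

    def test_two_subject_mixed_prevalence(self):
        """Convergent sets {01,02} and {01,13}: edge 01 -> 1.0, the others 0.5,
        intersection = {01}."""
        sa1 = _net(4, [(0, 1), (0, 2)])
        sa2 = _net(4, [(0, 1), (0, 2)])
        sb1 = _net(4, [(0, 1), (1, 3)])
        sb2 = _net(4, [(0, 1), (1, 3)])
        res = consensus_edges([sa1, sb1], [sa2, sb2])
        assert res.prevalence[0, 1] == 1.0
        assert res.prevalence[0, 2] == 0.5
        assert res.prevalence[1, 3] == 0.5
        assert res.intersection.edge_set() == {(0, 1)}

    def test_intersection_subset_of_every_convergent_set(self):
        rng = np.random.default_rng(8)
        from netconsensus.similarity import threshold_by_rank

        from conftest import random_weighted
        from netconsensus.synthgen import synthetic_scheme

        scheme = synthetic_scheme(8)
        k = 10
        p1 = [threshold_by_rank(random_weighted(scheme, rng), k, seed=i)
              for i in range(4)]
        p2 = [threshold_by_rank(random_weighted(scheme, rng), k, seed=i + 99)
              for i in range(4)]
        res = consensus_edges(p1, p2)
        inter = res.intersection.edge_set()
        for conv in res.subject_convergent:
            assert inter <= conv.edge_set()
        assert (res.prevalence[np.asarray(res.intersection.adjacency) == 1] == 1.0).all()

    def test_mismatched_k_rejected(self):
        with pytest.raises(NetworkError, match="share k"):
            consensus_edges([_net(4, [(0, 1)])], [_net(4, [(0, 1), (2, 3)])])


class TestMetricsTable:
    def test_single_subject_zero_sd(self):
        table = metrics_table({"P1": [K4]})
        for cell in table["P1"].values():
            assert cell["sd"] == 0.0

    def test_identical_networks_mean_equals_single(self):
        single = network_metrics(K4)
        table = metrics_table({"P1": [K4, K4, K4]})
        for name in ("PL", "CC", "Geff", "Leff"):
            assert table["P1"][name]["mean"] == pytest.approx(single[name])
            assert table["P1"][name]["sd"] == pytest.approx(0.0)

    def test_aggregation_matches_per_network_oracle(self):
        rng = np.random.default_rng(21)
        nets = [_random_net(10, 0.4, rng) for _ in range(5)]
        table = metrics_table({"P": nets})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per = [network_metrics(n) for n in nets]
        for name in ("PL", "CC", "Geff", "Leff", "AS"):
            vals = np.array([m[name] for m in per])
            ok = vals[~np.isnan(vals)]
            assert table["P"][name]["mean"] == pytest.approx(ok.mean())
            assert table["P"][name]["n_undefined"] == int(np.isnan(vals).sum())

    def test_undefined_assortativity_counted_not_propagated(self):
        # stars have AS = -1; complete graphs have undefined AS
        table = metrics_table({"P": [K4, STAR4]})
        cell = table["P"]["AS"]
        assert cell["n"] == 1
        assert cell["n_undefined"] == 1
        assert cell["mean"] == pytest.approx(-1.0)
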