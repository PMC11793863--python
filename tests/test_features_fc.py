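import itertools

import networkx as nx
import numpy as np
import pytest

from nirstreat.features_fc import (BinaryGraph, ConnectivityMatrix,
                                   DisconnectedGraphError, NETWORK_METRIC_NAMES,
                                   connectivity_matrix, extract_task_segment,
                                   graph_metrics, omst_binarize,
                                   reconstruct_channels)
from nirstreat.montage import TaskParadigm
from nirstreat.preprocess import ChannelQCReport, HemoglobinSeries

FS = 10.0
NT = 1700
T = np.arange(NT) / FS


def make_hb(hbo):
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    return HemoglobinSeries(hbo=hbo, hbr=-hbo / 3.0,
                            channel_ids=tuple(f"C{i+1}" for i in range(hbo.shape[0])),
                            sampling_rate=FS, paradigm=TaskParadigm())


def make_qc(channel_ids, discarded=()):
    keep = np.array([c not in set(discarded) for c in channel_ids])
    return ChannelQCReport(tuple(channel_ids), np.full(len(channel_ids), 50.0),
                           np.zeros(len(channel_ids)), keep,
                           tuple("ok" if k else "snr" for k in keep))


class TestTaskSegment:
    def test_constant_channel_zeroes_out(self):
        seg = extract_task_segment(make_hb(np.full(NT, 4.2e-6)))
        np.testing.assert_allclose(seg, 0.0, atol=1e-12)

    def test_ramp_removed_by_two_point_baseline(self):
        seg = extract_task_segment(make_hb(3e-6 * T - 1e-6))
        np.testing.assert_allclose(seg, 0.0, atol=1e-10)

    def test_task_duration_is_60_seconds(self):
        seg = extract_task_segment(make_hb(np.random.default_rng(0).standard_normal(NT)))
        assert seg.shape[1] == int(60 * FS)


class TestReconstruction:
    def test_discarded_channel_becomes_mean_of_kept_neighbours(self, montage):
        in_use = tuple(montage.in_use_mask)
        rng = np.random.default_rng(1)
        task = rng.standard_normal((len(in_use), 600))
        qc = make_qc(in_use, discarded=("C14",))
        out = reconstruct_channels(task, in_use, qc, montage)
        idx = {c: i for i, c in enumerate(in_use)}
        donors = ["C7", "C8", "C20", "C21"]
        expected = np.mean([task[idx[d]] for d in donors], axis=0)
        np.testing.assert_allclose(out[idx["C14"]], expected, atol=1e-14)
        # all other channels untouched
        for c in in_use:
            if c != "C14":
                np.testing.assert_array_equal(out[idx[c]], task[idx[c]])

    def test_no_discards_is_identity(self, montage):
        in_use = tuple(montage.in_use_mask)
        task = np.random.default_rng(2).standard_normal((len(in_use), 100))
        out = reconstruct_channels(task, in_use, make_qc(in_use), montage)
        np.testing.assert_array_equal(out, task)

    def test_adjacent_discards_never_donate_to_each_other(self, montage):
        # C14 and C7 share an optode; discard both and verify donor sets by
        # brute-force neighbour enumeration
        in_use = tuple(montage.in_use_mask)
        rng = np.random.default_rng(3)
        task = rng.standard_normal((len(in_use), 200))
        qc = make_qc(in_use, discarded=("C14", "C7"))
        out = reconstruct_channels(task, in_use, qc, montage)
        idx = {c: i for i, c in enumerate(in_use)}

        def brute_donors(ch):
            own = set(montage.optode_pairs[ch])
            return sorted(
                c for c in in_use
                if c not in ("C14", "C7") and c != ch
                and own & set(montage.optode_pairs[c])
            )

        for ch in ("C14", "C7"):
            donors = brute_donors(ch)
            expected = np.mean([task[idx[d]] for d in donors], axis=0)
            np.testing.assert_allclose(out[idx[ch]], expected, atol=1e-14)

    def test_isolated_discard_fails_by_default(self, montage):
        in_use = ("C1", "C2", "C15")  # C1's only neighbours are C2 and C15
        task = np.random.default_rng(4).standard_normal((3, 50))
        qc = make_qc(in_use, discarded=("C2", "C15", "C1"))
        with pytest.raises(RuntimeError):
            reconstruct_channels(task, in_use, qc, montage)


class TestConnectivity:
    def test_identical_channels_fully_connected(self):
        x = np.vstack([np.sin(T[:100]), np.sin(T[:100])])
        cm = connectivity_matrix(x, ("C1", "C2"))
        assert cm.weights[0, 1] == pytest.approx(1.0)
        assert cm.weights[0, 0] == 0.0

    def test_anticorrelated_pair_clipped_to_zero(self):
        x = np.vstack([np.sin(T[:100]), -np.sin(T[:100])])
        cm = connectivity_matrix(x, ("C1", "C2"))
        assert cm.weights[0, 1] == 0.0

    def test_matches_textbook_pearson_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((5, 120))
        cm = connectivity_matrix(x, tuple(f"C{i+1}" for i in range(5)))
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cm.weights[i, j] == pytest.approx(max(r, 0.0), abs=1e-12)

    def test_zero_variance_channel_rejected(self):
        x = np.vstack([np.ones(50), np.sin(T[:50])])
        with pytest.raises(ValueError, match="C1"):
            connectivity_matrix(x, ("C1", "C2"))

    def test_invariance_under_positive_affine_rescaling(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((4, 200))
        cm1 = connectivity_matrix(x, ("C1", "C2", "C3", "C4"))
        y = 2.5 * x + rng.uniform(-3, 3, size=(4, 1))
        cm2 = connectivity_matrix(y, ("C1", "C2", "C3", "C4"))
        np.testing.assert_allclose(cm1.weights, cm2.weights, atol=1e-12)


def _brute_global_efficiency(adj_w):
    """Floyd-Warshall weighted efficiency oracle (distance = 1/weight)."""
    n = adj_w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if adj_w[i, j] > 0:
                dist[i, j] = 1.0 / adj_w[i, j]
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    inv = 1.0 / dist[~np.eye(n, dtype=bool)]
    return float(np.mean(np.where(np.isfinite(inv), inv, 0.0)))


def _brute_omst(weights):
    """Independent orthogonal-MST oracle: exhaustive MST per round."""
    n = weights.shape[0]
    edges = [(i, j, weights[i, j]) for i in range(n) for j in range(i + 1, n)
             if weights[i, j] > 0]
    total = sum(w for _, _, w in edges)
    residual = list(edges)
    union, best, best_gce, sel_w = [], None, -np.inf, 0.0
    while True:
        trees = []
        for cand in itertools.combinations(residual, n - 1):
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from([(i, j) for i, j, _ in cand])
            if nx.is_connected(g):
                trees.append(cand)
        if not trees:
            break
        tree = min(trees, key=lambda t: (sum(1.0 / w for _, _, w in t),
                                         sorted((i, j) for i, j, _ in t)))
        union.extend(tree)
        sel_w += sum(w for _, _, w in tree)
        residual = [e for e in residual if e not in tree]
        adj = np.zeros((n, n))
        for i, j, w in union:
            adj[i, j] = adj[j, i] = w
        gce = _brute_global_efficiency(adj) - sel_w / total
        if gce > best_gce:
            best_gce = gce
            best = {(i, j) for i, j, _ in union}
    return best


class TestOMST:
    def _cm(self, weights):
        n = weights.shape[0]
        return ConnectivityMatrix(weights, tuple(f"C{i+1}" for i in range(n)))

    def test_tree_input_returns_that_tree(self):
        w = np.zeros((4, 4))
        for i, j, v in [(0, 1, 0.9), (1, 2, 0.8), (2, 3, 0.7)]:
            w[i, j] = w[j, i] = v
        g = omst_binarize(self._cm(w))
        assert g.adjacency.sum() // 2 == 3
        np.testing.assert_array_equal(g.adjacency > 0, w > 0)

    def test_triangle_stops_after_first_tree(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.8
        w[0, 2] = w[2, 0] = 0.1
        g = omst_binarize(self._cm(w))
        # first MST on distance 1/w is {ab, bc}; the leftover edge {ac} is
        # not spanning, so aggregation stops there
        assert g.adjacency[0, 1] == 1 and g.adjacency[1, 2] == 1
        assert g.adjacency[0, 2] == 0
        assert g.n_trees == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle_on_5_nodes(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.05, 1.0, size=(5, 5))
        w = np.triu(w, 1)
        w = w + w.T
        g = omst_binarize(self._cm(w))
        got = {(i, j) for i in range(5) for j in range(i + 1, 5) if g.adjacency[i, j]}
        assert got == _brute_omst(w)

    @pytest.mark.parametrize("seed", range(3))
    def test_structural_invariants_on_random_graphs(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 8
        w = rng.uniform(0.01, 1.0, size=(n, n))
        w = np.triu(w, 1)
        w = w + w.T
        g = omst_binarize(self._cm(w))
        nxg = g.to_networkx()
        assert nx.is_connected(nxg)
        assert nxg.number_of_edges() <= g.n_trees * (n - 1)
        assert g.n_trees >= 1

    def test_disconnected_graph_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        with pytest.raises(DisconnectedGraphError):
            omst_binarize(self._cm(w))


def _brute_metrics(g: nx.Graph):
    """Exhaustive BFS/triangle-counting oracles, independent of networkx."""
    nodes = list(g.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=int)
    for a, b in g.edges:
        adj[index[a], index[b]] = adj[index[b], index[a]] = 1
    # all-pairs BFS
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if v not in seen:
                        seen.add(v)
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    off = ~np.eye(n, dtype=bool)
    cpl = float(dist[off].mean())
    geff = float((1.0 / dist[off]).mean())
    # clustering: triangles over wedges per node
    cc = []
    for u in range(n):
        nbrs = np.flatnonzero(adj[u])
        k = len(nbrs)
        if k < 2:
            cc.append(0.0)
            continue
        links = sum(adj[a, b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:])
        cc.append(2.0 * links / (k * (k - 1)))
    return cpl, geff, float(np.mean(cc))


class TestGraphMetrics:
    def _binary(self, g: nx.Graph) -> BinaryGraph:
        nodes = tuple(str(v) for v in g.nodes)
        n = len(nodes)
        index = {v: i for i, v in enumerate(g.nodes)}
        adj = np.zeros((n, n), dtype=int)
        for a, b in g.edges:
            adj[index[a], index[b]] = adj[index[b], index[a]] = 1
        return BinaryGraph(adj, nodes, 1, (0.0,))

    def test_star_graph_closed_forms(self):
        out = graph_metrics(self._binary(nx.star_graph(4)))
        assert out["assortativity"] == pytest.approx(-1.0)
        assert out["clustering"] == 0.0

    def test_complete_graph_closed_forms(self):
        out = graph_metrics(self._binary(nx.complete_graph(5)))
        assert out["clustering"] == pytest.approx(1.0)
        assert out["char_path_length"] == pytest.approx(1.0)
        assert out["global_efficiency"] == pytest.approx(1.0)

    def test_path_graph_characteristic_path_length(self):
        out = graph_metrics(self._binary(nx.path_graph(4)))
        assert out["char_path_length"] == pytest.approx(5.0 / 3.0)

    def test_seven_finite_metrics(self):
        out = graph_metrics(self._binary(nx.petersen_graph()))
        assert tuple(out.keys()) == NETWORK_METRIC_NAMES
        assert len(out) == 7
        assert all(np.isfinite(v) for v in out.values())

    def test_agrees_with_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 6:
            g = nx.gnp_random_graph(6, 0.5, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            checked += 1
            out = graph_metrics(self._binary(g))
            cpl, geff, clust = _brute_metrics(g)
            assert out["char_path_length"] == pytest.approx(cpl, rel=1e-12)
            assert out["global_efficiency"] == pytest.approx(geff, rel=1e-12)
            assert out["clustering"] == pytest.approx(clust, rel=1e-12)

    def test_disconnected_graph_rejected(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            graph_metrics(self._binary(g))
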