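"""Functional-connectivity features: task segment, channel reconstruction,
Pearson connectivity, orthogonal-MST binarization and network metrics.

The connectivity graph is built from pairwise Pearson correlation of the
task-period ΔHbO traces (negative correlations and the diagonal zeroed).
The weighted matrix is binarized with the orthogonal minimal spanning tree
scheme: successive edge-disjoint MSTs (distance = 1/weight) are aggregated
and the union maximizing global cost efficiency - the weighted global
efficiency of the selection minus its fraction of total connection weight -
is kept.  Seven graph-theory metrics summarise the resulting sparse network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .montage import Montage, TaskParadigm, neighbors
from .preprocess import ChannelQCReport, HemoglobinSeries

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "NETWORK_METRIC_NAMES",
    "extract_task_segment",
    "reconstruct_channels",
    "connectivity_matrix",
    "omst_binarize",
    "graph_metrics",
]

NETWORK_METRIC_NAMES = (
    "assortativity",
    "clustering",
    "char_path_length",
    "global_efficiency",
    "local_efficiency",
    "modularity",
    "small_worldness",
)


class DisconnectedGraphError(RuntimeError):
    """Positive-correlation graph is disconnected; subject should be excluded."""


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative edge-weight matrix with zero diagonal."""

    weights: np.ndarray
    channel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        self.weights = w


@dataclass
class BinaryGraph:
    """0/1 adjacency from OMST aggregation, with provenance."""

    adjacency: np.ndarray
    channel_ids: tuple[str, ...]
    n_trees: int
    gce_trace: tuple[float, ...]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.channel_ids)
        n = len(self.channel_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.adjacency[i, j]:
                    g.add_edge(self.channel_ids[i], self.channel_ids[j])
        return g


def extract_task_segment(hb: HemoglobinSeries, paradigm: TaskParadigm | None = None,
                         margin_s: float = 1.0) -> np.ndarray:
    """Task-period ΔHbO with a two-point linear baseline subtracted.

    The baseline line runs through the means of the ``margin_s`` windows
    immediately before and after the task period.  Returns (channels,
    task_samples).
    """
    paradigm = paradigm or hb.paradigm
    fs = paradigm.sampling_rate
    nt = hb.hbo.shape[1]
    pre = paradigm.slice_s(paradigm.task_onset_s - margin_s, paradigm.task_onset_s)
    post = paradigm.slice_s(paradigm.task_offset_s, paradigm.task_offset_s + margin_s)
    if pre.start < 0 or post.stop > nt:
        raise ValueError("task window plus margins falls outside the recording")
    t = np.arange(nt) / fs
    c1, c2 = t[pre].mean(), t[post].mean()
    m1 = hb.hbo[:, pre].mean(axis=1)
    m2 = hb.hbo[:, post].mean(axis=1)
    slope = (m2 - m1) / (c2 - c1)
    intercept = m1 - slope * c1
    corrected = hb.hbo - (slope[:, None] * t[None, :] + intercept[:, None])
    return corrected[:, paradigm.task_slice]


def reconstruct_channels(
    task_array: np.ndarray,
    channel_ids: tuple[str, ...],
    qc: ChannelQCReport,
    montage: Montage,
    on_isolated: str = "fail",
) -> np.ndarray:
    """Impute QC-discarded channels from their kept neighbours.

    Each discarded channel's trace becomes the arithmetic mean of the traces
    of its kept (never themselves reconstructed) neighbouring channels.
    ``on_isolated`` controls what happens when a discarded channel has no
    kept neighbour: ``"fail"`` raises, ``"exclude"`` leaves the channel as-is
    for the caller to drop.
    """
    if on_isolated not in ("fail", "exclude"):
        raise ValueError("on_isolated must be 'fail' or 'exclude'")
    kept = set(qc.kept_channels)
    discarded = [c for c in channel_ids if c not in kept]
    if not discarded:
        return task_array.copy()
    if not kept & set(channel_ids):
        raise RuntimeError("no kept channel available for reconstruction")
    index = {c: i for i, c in enumerate(channel_ids)}
    out = task_array.copy()
    for ch in discarded:
        donors = [d for d in neighbors(montage, ch, exclude=discarded) if d in kept and d in index]
        if not donors:
            if on_isolated == "fail":
                raise RuntimeError(
                    f"channel {ch!r} has no kept neighbour to reconstruct from"
                )
            continue
        out[index[ch]] = np.mean([task_array[index[d]] for d in donors], axis=0)
    return out


def connectivity_matrix(task_array: np.ndarray, channel_ids: tuple[str, ...]) -> ConnectivityMatrix:
    """Pairwise Pearson correlation; negatives and the diagonal set to zero."""
    x = np.asarray(task_array, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 3:
        raise ValueError("need at least 2 channels and 3 time points")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = channel_ids[int(np.argmin(sd))]
        raise ValueError(f"zero-variance channel {bad!r}: correlation undefined")
    r = np.corrcoef(x)
    r = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(weights=r, channel_ids=tuple(channel_ids))


def _weighted_global_efficiency(g: nx.Graph, n_nodes: int) -> float:
    """Mean of 1/shortest-path-distance over all unordered node pairs."""
    if n_nodes < 2:
        return 0.0
    total = 0.0
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="dist"):
        for dst, d in lengths.items():
            if dst != src and d > 0:
                total += 1.0 / d
    return total / (n_nodes * (n_nodes - 1))


def omst_binarize(cm: ConnectivityMatrix) -> BinaryGraph:
    """Orthogonal-MST binarization with the global-cost-efficiency stop rule.

    Minimum spanning trees over distance 1/weight are extracted from the
    residual graph round after round (each tree's edges removed before the
    next).  After each aggregation the global cost efficiency
    ``GCE = GlobalEfficiency(weighted union) - cost`` is evaluated, where
    cost is the selected weight fraction of the total positive weight; the
    union attaining the maximum GCE is returned as a 0/1 adjacency.
    MST ties are broken by lexicographic channel-pair order.
    """
    n = len(cm.channel_ids)
    w = cm.weights
    pos = [
        (cm.channel_ids[i], cm.channel_ids[j], w[i, j])
        for i in range(n)
        for j in range(i + 1, n)
        if w[i, j] > 0
    ]
    residual = nx.Graph()
    residual.add_nodes_from(cm.channel_ids)
    for a, b, weight in sorted(pos):  # sorted for deterministic tie-breaks
        residual.add_edge(a, b, weight=weight, dist=1.0 / weight)
    if not nx.is_connected(residual):
        raise DisconnectedGraphError(
            "positive-correlation graph is disconnected; exclude this subject"
        )
    total_weight = sum(weight for _, _, weight in pos)

    union = nx.Graph()
    union.add_nodes_from(cm.channel_ids)
    selected_weight = 0.0
    best_gce = -np.inf
    best_edges: set[tuple[str, str]] = set()
    gce_trace: list[float] = []
    n_trees = 0
    best_k = 0
    while nx.is_connected(residual) and residual.number_of_edges() >= n - 1:
        tree = nx.minimum_spanning_tree(residual, weight="dist", algorithm="kruskal")
        tree_edges = list(tree.edges())
        if len(tree_edges) != n - 1:
            break
        for a, b in tree_edges:
            weight = residual[a][b]["weight"]
            union.add_edge(a, b, weight=weight, dist=1.0 / weight)
            selected_weight += weight
            residual.remove_edge(a, b)
        n_trees += 1
        ge = _weighted_global_efficiency(union, n)
        cost = selected_weight / total_weight
        gce = float(ge - cost)
        gce_trace.append(gce)
        if gce > best_gce:
            best_gce = gce
            best_edges = {tuple(sorted(e)) for e in union.edges()}
            best_k = n_trees

    adj = np.zeros((n, n), dtype=int)
    idx = {c: i for i, c in enumerate(cm.channel_ids)}
    for a, b in best_edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
    return BinaryGraph(
        adjacency=adj,
        channel_ids=cm.channel_ids,
        n_trees=best_k,
        gce_trace=tuple(gce_trace),
    )


def graph_metrics(g: BinaryGraph | nx.Graph, seed: int = 0,
                  n_random: int = 10, nswap_per_edge: int = 20) -> dict[str, float]:
    """Seven network metrics of a connected binary graph.

    Degree assortativity (0 for degree-regular graphs, where the correlation
    is undefined), mean clustering coefficient, characteristic path length,
    global efficiency, mean local efficiency, greedy modularity, and
    small-worldness sigma = (C/C_rand)/(L/L_rand) against degree-matched
    random references (seeded rewiring; graphs too constrained to rewire use
    the graph itself as reference, giving sigma = 1).
    """
    graph = g.to_networkx() if isinstance(g, BinaryGraph) else g
    if graph.number_of_nodes() < 2 or not nx.is_connected(graph):
        raise ValueError("graph metrics require a connected graph on >= 2 nodes")

    with np.errstate(all="ignore"):
        assort = nx.degree_assortativity_coefficient(graph)
    if not np.isfinite(assort):
        assort = 0.0  # degree-regular graph: correlation undefined
    clustering = nx.average_clustering(graph)
    cpl = nx.average_shortest_path_length(graph)
    geff = nx.global_efficiency(graph)
    leff = nx.local_efficiency(graph)
    communities = nx.community.greedy_modularity_communities(graph)
    modularity = nx.community.modularity(graph, communities)

    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    m = graph.number_of_edges()
    for _ in range(n_random):
        ref = graph.copy()
        try:
            nx.double_edge_swap(
                ref,
                nswap=nswap_per_edge * m,
                max_tries=nswap_per_edge * m * 100,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXException:
            ref = graph.copy()  # too constrained to rewire
        if not nx.is_connected(ref):
            ref = graph.copy()
        c_rand.append(nx.average_clustering(ref))
        l_rand.append(nx.average_shortest_path_length(ref))
    c_ref = float(np.mean(c_rand))
    l_ref = float(np.mean(l_rand))
    if c_ref > 0 and l_ref > 0 and cpl > 0:
        sigma = (clustering / c_ref) / (cpl / l_ref) if clustering > 0 or c_ref > 0 else 1.0
        if not np.isfinite(sigma):
            sigma = 1.0
    else:
        sigma = 1.0

    out = dict(
        zip(
            NETWORK_METRIC_NAMES,
            (
                float(assort),
                float(clustering),
                float(cpl),
                float(geff),
                float(leff),
                float(modularity),
                float(sigma),
            ),
        )
    )
    assert len(out) == 7
    return out
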