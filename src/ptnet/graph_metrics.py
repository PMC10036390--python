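"""Node and whole-network topology metrics for binary trait networks.

Node parameters
---------------
degree (k)
    Number of traits directly correlated with the focal trait.
closeness (C)
    Reciprocal of the *mean* shortest-path length from the focal trait
    to the traits it can reach. Note this differs from the common
    library convention (reciprocal of the *sum*) by a factor of the
    number of reachable nodes; isolated traits get C = 0.
betweenness (B)
    Number of shortest paths between other trait pairs that pass
    through the focal trait, with fractional credit shared equally
    among tied shortest paths and endpoints excluded. Reported as a raw
    count by default; pair-normalisation is available.

Network metrics
---------------
edge density (ED)
    Realised edges over all possible pairs, 2|E| / (n(n-1)).
average path length (AL)
    Mean shortest-path distance over connected unordered pairs
    (disconnected pairs are excluded from the mean).
average clustering coefficient (AC)
    Mean over nodes of the fraction of a node's neighbour pairs that
    are themselves connected (0 for degree < 2).
modularity (Q)
    Newman-Girvan quality of the detected module partition: the
    within-module edge fraction minus its degree-based expectation.
    Modules are found by deterministic greedy agglomerative modularity
    maximisation.

Everything here is computed directly from the adjacency matrix with
breadth-first search and Brandes-style shortest-path counting; graph
libraries are not involved.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateNetworkError
from .network import TraitNetwork


@dataclass
class NodeMetrics:
    """Per-trait centrality scores."""

    trait_name: str
    degree: int
    closeness: float
    betweenness: float
    module: int | None = None


@dataclass
class TopologyMetrics:
    """Whole-network summary of a trait network."""

    edge_density: float
    average_path_length: float  # NaN when no connected pairs exist
    average_clustering: float
    modularity: float
    n_modules: int
    module_assignment: dict
    n_edges: int
    group: object = None


def _adjacency_lists(adjacency: np.ndarray) -> list[list[int]]:
    a = np.asarray(adjacency)
    return [np.nonzero(a[i])[0].tolist() for i in range(a.shape[0])]


def shortest_path_lengths(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path matrix by BFS; inf if unreachable."""
    n = adjacency.shape[0]
    adj = _adjacency_lists(adjacency)
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0.0
        q = deque([s])
        while q:
            v = q.popleft()
            for w in adj[v]:
                if not np.isfinite(dist[s, w]):
                    dist[s, w] = dist[s, v] + 1
                    q.append(w)
    return dist


def betweenness_counts(adjacency: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Shortest-path betweenness via Brandes' accumulation.

    Tied shortest paths share credit fractionally; endpoints are
    excluded. Each unordered pair contributes once. With
    ``normalized=True`` counts are divided by (n-1)(n-2)/2.
    """
    n = adjacency.shape[0]
    adj = _adjacency_lists(adjacency)
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest paths with path counts
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1.0)
        dist[s] = 0.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        q = deque([s])
        while q:
            v = q.popleft()
            order.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # undirected: each pair was counted from both endpoints
    if normalized:
        denom = (n - 1) * (n - 2) / 2.0
        if denom > 0:
            bc /= denom
    return bc


def node_metrics(net: TraitNetwork, normalized_betweenness: bool = False) -> list[NodeMetrics]:
    """Degree, closeness (reciprocal mean distance), betweenness per trait."""
    a = net.adjacency
    n = a.shape[0]
    degree = a.sum(axis=1).astype(int)
    dist = shortest_path_lengths(a)
    closeness = np.zeros(n)
    for i in range(n):
        reach = np.isfinite(dist[i]) & (np.arange(n) != i)
        if reach.any():
            closeness[i] = 1.0 / dist[i, reach].mean()
    bc = betweenness_counts(a, normalized=normalized_betweenness)
    return [
        NodeMetrics(net.trait_names[i], int(degree[i]), float(closeness[i]), float(bc[i]))
        for i in range(n)
    ]


def clustering_coefficients(adjacency: np.ndarray) -> np.ndarray:
    """Per-node local clustering: 2*triangles / (k(k-1)); 0 for k < 2."""
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(k >= 2, 2.0 * triangles / (k * (k - 1)), 0.0)
    return cc


def modularity(adjacency: np.ndarray, partition: dict | list) -> float:
    """Newman-Girvan modularity Q of a given node -> module partition.

    Q = sum over modules c of ( e_c / m  -  (d_c / 2m)^2 ), with e_c the
    within-module edge count, d_c the module degree sum, and m the total
    edge count. Q = 0 when the network has no edges.
    """
    a = np.asarray(adjacency)
    n = a.shape[0]
    if isinstance(partition, dict):
        labels = np.array([partition[i] for i in range(n)])
    else:
        labels = np.asarray(partition)
    m = a.sum() / 2.0
    if m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        e_c = a[np.ix_(idx, idx)].sum() / 2.0
        d_c = a[idx].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def greedy_modularity_communities(adjacency: np.ndarray) -> list[int]:
    """Deterministic greedy agglomerative modularity maximisation.

    Every node starts in its own module; the merge of two modules with
    the largest modularity gain is applied repeatedly until no merge
    improves Q. Ties break on the smallest (module, module) index pair,
    so the result is fully deterministic. Returns a module label per
    node, labels renumbered 0..n_modules-1 in order of first node.
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    m = a.sum() / 2.0
    labels = list(range(n))
    if m == 0:
        return labels
    # e[c][d]: edge count between communities; deg[c]: degree sum
    comms = {i: {i} for i in range(n)}
    e = {i: {} for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j]:
                e[i][j] = a[i, j]
                e[j][i] = a[i, j]
    deg = {i: float(a[i].sum()) for i in range(n)}
    while True:
        best = None
        best_gain = 1e-12  # require strictly positive improvement
        for c in sorted(e):
            for d in sorted(e[c]):
                if d <= c:
                    continue
                gain = e[c][d] / m - 2.0 * (deg[c] / (2 * m)) * (deg[d] / (2 * m))
                if gain > best_gain:
                    best_gain = gain
                    best = (c, d)
        if best is None:
            break
        c, d = best
        comms[c] |= comms.pop(d)
        deg[c] += deg.pop(d)
        # merge neighbour maps
        for x, w in e.pop(d).items():
            if x == c:
                continue
            e[x].pop(d, None)
            e[c][x] = e[c].get(x, 0.0) + w
            e[x][c] = e[c][x]
        e[c].pop(d, None)
        e[c].pop(c, None)
    out = [0] * n
    ordered = sorted(comms.values(), key=min)
    for lab, nodes in enumerate(ordered):
        for v in nodes:
            out[v] = lab
    return out


def detect_communities(
    adjacency: np.ndarray, method: str = "greedy", seed: int = 0
) -> list[int]:
    """Module assignment by the chosen algorithm.

    ``greedy`` (default) is the in-house deterministic agglomerative
    maximiser; ``louvain`` delegates to networkx with a fixed seed.
    """
    if method == "greedy":
        return greedy_modularity_communities(adjacency)
    if method == "louvain":
        import networkx as nx

        g = nx.from_numpy_array(np.asarray(adjacency))
        comms = nx.community.louvain_communities(g, seed=seed)
        out = [0] * adjacency.shape[0]
        for lab, nodes in enumerate(sorted(comms, key=min)):
            for v in nodes:
                out[v] = lab
        return out
    raise ConfigurationError(f"unknown community method {method!r}")


def topology_metrics(
    net: TraitNetwork, method: str = "greedy", seed: int = 0
) -> TopologyMetrics:
    """ED, AL, AC, and modularity of the detected module partition."""
    a = net.adjacency
    n = a.shape[0]
    if n < 2:
        raise DegenerateNetworkError(f"need at least 2 traits, got {n}")
    n_edges = int(a.sum()) // 2
    ed = 2.0 * n_edges / (n * (n - 1))

    dist = shortest_path_lengths(a)
    iu = np.triu_indices(n, 1)
    d = dist[iu]
    connected = np.isfinite(d)
    al = float(d[connected].mean()) if connected.any() else float("nan")

    ac = float(clustering_coefficients(a).mean())

    labels = detect_communities(a, method=method, seed=seed)
    q = modularity(a, labels)
    assignment = {net.trait_names[i]: labels[i] for i in range(n)}
    return TopologyMetrics(
        edge_density=ed,
        average_path_length=al,
        average_clustering=ac,
        modularity=q,
        n_modules=len(set(labels)),
        module_assignment=assignment,
        n_edges=n_edges,
        group=net.group,
    )


@dataclass
class HubReport:
    """Ranked hub (high k, then C) and mediator (high B) traits."""

    hubs: pd.DataFrame
    mediators: pd.DataFrame
    tied_hubs: bool = False
    tied_mediators: bool = False


def identify_hubs(nm: list[NodeMetrics], top_n: int = 5) -> HubReport:
    """Rank traits into hubs and mediators.

    Hubs sort by degree then closeness, descending; mediators by
    betweenness descending. Exact ties fall back to trait-name order
    and are flagged. ``top_n`` larger than the trait count returns all
    traits with a warning.
    """
    if not nm:
        raise ConfigurationError("empty node-metrics list")
    if top_n > len(nm):
        warnings.warn(
            f"top_n={top_n} exceeds {len(nm)} traits; returning all", stacklevel=2
        )
        top_n = len(nm)
    df = pd.DataFrame(
        {
            "trait": [x.trait_name for x in nm],
            "k": [x.degree for x in nm],
            "C": [x.closeness for x in nm],
            "B": [x.betweenness for x in nm],
        }
    )
    hubs = df.sort_values(
        ["k", "C", "trait"], ascending=[False, False, True], kind="mergesort"
    ).head(top_n)
    mediators = df.sort_values(
        ["B", "trait"], ascending=[False, True], kind="mergesort"
    ).head(top_n)
    tied_h = df.duplicated(subset=["k", "C"], keep=False).all()
    tied_m = df.duplicated(subset=["B"], keep=False).all()
    return HubReport(
        hubs=hubs.reset_index(drop=True),
        mediators=mediators.reset_index(drop=True),
        tied_hubs=bool(tied_h),
        tied_mediators=bool(tied_m),
    )


def node_metrics_frame(nm: list[NodeMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait": [x.trait_name for x in nm],
            "k": [x.degree for x in nm],
            "C": [x.closeness for x in nm],
            "B": [x.betweenness for x in nm],
            "module": [x.module for x in nm],
        }
    )
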