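"""Migration matrices and networks from parentage assignments.

A retained parent-offspring pair whose members were sampled in different
populations is direct evidence of a contemporary migration event: genes
flowed from the parent's population (origin) to the offspring's population
(destination).  Counting assignments per ordered population pair gives a
migration count matrix; row-normalizing gives multinomial migration-rate
estimates with Wilson binomial intervals per cell.

Two graphs are built from the counts: a directed, unweighted gene-flow
network (edge origin -> destination wherever at least one cross-population
assignment exists, node size = total degree), and an undirected projection
whose edges are weighted by shortest-path edge betweenness and clustered by
greedy (CNM-style) modularity maximization.  Sources and sinks are read
from directed-degree asymmetry, and key nodes from degree maxima and
inter-cluster bridge incidence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .data import PopulationSample
from .distance import geodesic_km
from .kinship import ParentagePair

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Count and rate matrices
# ---------------------------------------------------------------------------


@dataclass
class MigrationCountMatrix:
    """n[dest][origin]: offspring sampled in dest with assigned parent in origin."""

    labels: list[str]
    n: np.ndarray
    time_code: Optional[int] = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.n.shape != (len(self.labels), len(self.labels)):
            raise ValueError("count matrix shape does not match labels")
        if (self.n < 0).any():
            raise ValueError("negative counts")

    @property
    def off_diagonal_total(self) -> int:
        return int(self.n.sum() - np.trace(self.n))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.n, index=self.labels, columns=self.labels)


def migration_counts(
    pairs: Sequence[ParentagePair],
    populations: Sequence[PopulationSample | str],
    time_code: Optional[int] = None,
) -> MigrationCountMatrix:
    """Tally retained parentage pairs into a destination x origin count matrix.

    ``populations`` fixes the label set (populations with no assignments keep
    zero rows/columns); a pair referencing an unknown population is an error.
    """
    labels = [p if isinstance(p, str) else p.code for p in populations]
    idx = {c: i for i, c in enumerate(labels)}
    n = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for p in pairs:
        if p.offspring_pop not in idx or p.parent_pop not in idx:
            raise KeyError(
                f"pair ({p.offspring}, {p.parent}) references unknown population "
                f"{p.offspring_pop!r} or {p.parent_pop!r}")
        n[idx[p.offspring_pop], idx[p.parent_pop]] += 1
    return MigrationCountMatrix(labels, n, time_code)


@dataclass
class MigrationRateMatrix:
    labels: list[str]
    m: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_assigned: np.ndarray  # per destination row

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, dest in enumerate(self.labels):
            for j, orig in enumerate(self.labels):
                rows.append({"destination": dest, "origin": orig,
                             "m": self.m[i, j], "ci_low": self.ci_low[i, j],
                             "ci_high": self.ci_high[i, j],
                             "n_assigned": int(self.n_assigned[i])})
        return pd.DataFrame(rows)


def migration_rates(counts: MigrationCountMatrix, alpha: float = 0.05) -> MigrationRateMatrix:
    """Row-wise multinomial MLE of migration rates with Wilson 95% intervals.

    m[i][j] is the fraction of assigned offspring in destination i whose
    parent sits in origin j; each cell's interval treats cell-vs-rest as
    binomial.  Rows with zero assignments are flagged undefined (NaN).
    """
    n = counts.n
    tot = n.sum(axis=1)
    k = len(counts.labels)
    m = np.full((k, k), np.nan)
    lo = np.full((k, k), np.nan)
    hi = np.full((k, k), np.nan)
    for i in range(k):
        if tot[i] == 0:
            logger.info("migration_rates: destination %s has no assignments", counts.labels[i])
            continue
        m[i] = n[i] / tot[i]
        l, h = proportion_confint(n[i], tot[i], alpha=alpha, method="wilson")
        lo[i], hi[i] = l, h
    return MigrationRateMatrix(list(counts.labels), m, lo, hi, tot)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


@dataclass
class MigrationNetwork:
    """Directed unweighted gene-flow graph over population nodes."""

    graph: nx.DiGraph
    time_code: Optional[int] = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def in_degree(self, node: str) -> int:
        return self.graph.in_degree(node)

    def out_degree(self, node: str) -> int:
        return self.graph.out_degree(node)

    def degree(self, node: str) -> int:
        return self.graph.in_degree(node) + self.graph.out_degree(node)

    def undirected(self) -> nx.Graph:
        return nx.Graph(self.graph.to_undirected(as_view=False))

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            rows.append({"origin": u, "destination": v,
                         "count": d.get("count", 1),
                         "distance_km": d.get("distance_km", np.nan)})
        return pd.DataFrame(rows, columns=["origin", "destination", "count", "distance_km"])


def build_network(
    counts: MigrationCountMatrix,
    coords: Optional[dict[str, tuple[float, float]]] = None,
) -> MigrationNetwork:
    """Directed gene-flow network: edge origin -> destination per off-diagonal count >= 1."""
    g = nx.DiGraph()
    coords = coords or {}
    for code in counts.labels:
        lat, lon = coords.get(code, (np.nan, np.nan))
        g.add_node(code, latitude=lat, longitude=lon)
    k = len(counts.labels)
    for dest_i, orig_j in itertools.product(range(k), range(k)):
        if dest_i == orig_j:
            continue
        c = counts.n[dest_i, orig_j]
        if c >= 1:
            u, v = counts.labels[orig_j], counts.labels[dest_i]
            dist = np.nan
            if u in coords and v in coords:
                dist = geodesic_km(coords[u], coords[v])
            g.add_edge(u, v, count=int(c), distance_km=dist)
    return MigrationNetwork(g, counts.time_code)


def edge_betweenness(network: MigrationNetwork) -> dict[tuple[str, str], float]:
    """Shortest-path edge betweenness on the undirected, unweighted projection.

    Unnormalized Brandes counts: each unordered node pair contributes 1,
    split equally over tied shortest paths.  Keys are sorted node tuples.
    """
    und = network.undirected()
    if und.number_of_edges() == 0:
        raise ValueError("network has no edges")
    eb = nx.edge_betweenness_centrality(und, normalized=False)
    return {tuple(sorted((u, v))): val for (u, v), val in eb.items()}


# ---------------------------------------------------------------------------
# Greedy modularity clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusteringResult:
    partition: dict[str, int]
    q: float
    merges: list[tuple[str, str, float]]  # (community a, community b, Q after merge)
    weighted: bool

    @property
    def n_clusters(self) -> int:
        return len(set(self.partition.values()))

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for node, c in self.partition.items():
            out.setdefault(c, []).append(node)
        return [sorted(out[c]) for c in sorted(out)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"node": n, "cluster": c} for n, c in sorted(self.partition.items())])


def modularity(
    graph: nx.Graph, partition: dict[str, int], weight: Optional[str] = None
) -> float:
    """Newman modularity Q = sum_c [W_c/W - (S_c/2W)^2] of a node partition."""
    W = graph.size(weight=weight)
    if W == 0:
        return 0.0
    strength = dict(graph.degree(weight=weight))
    comms: dict[int, set[str]] = {}
    for n, c in partition.items():
        comms.setdefault(c, set()).add(n)
    q = 0.0
    for members in comms.values():
        w_c = sum(d.get(weight, 1) if weight else 1
                  for u, v, d in graph.edges(members, data=True)
                  if u in members and v in members)
        s_c = sum(strength[n] for n in members)
        q += w_c / W - (s_c / (2 * W)) ** 2
    return q


def fast_greedy_modularity(
    network: MigrationNetwork | nx.Graph,
    weights: Optional[dict[tuple[str, str], float]] = None,
) -> ClusteringResult:
    """Agglomerative greedy modularity clustering (CNM) with deterministic ties.

    Starting from singleton communities, repeatedly merges the pair of
    current communities with the largest modularity gain (ties broken
    toward the lexicographically smallest pair of community labels, a
    community being labeled by its smallest node) and returns the partition
    of maximal Q along the merge path.  ``weights`` maps sorted node-pair
    tuples to edge weights (e.g. edge betweenness); omit for the unweighted
    variant.  An edgeless graph yields singleton clusters with Q = 0.
    """
    graph = network.undirected() if isinstance(network, MigrationNetwork) else nx.Graph(network)
    wkey = None
    if weights is not None:
        wkey = "weight"
        for u, v in graph.edges:
            graph[u][v][wkey] = weights[tuple(sorted((u, v)))]

    nodes = sorted(graph.nodes)
    comm_of = {n: n for n in nodes}  # community label = smallest member node

    def _partition() -> dict[str, int]:
        labels = sorted(set(comm_of.values()))
        lab_ix = {l: i for i, l in enumerate(labels)}
        return {n: lab_ix[comm_of[n]] for n in nodes}

    if graph.number_of_edges() == 0:
        return ClusteringResult(_partition(), 0.0, [], weights is not None)

    def _q() -> float:
        return modularity(graph, {n: comm_of[n] for n in nodes}, weight=wkey)

    best_q = _q()
    best_assign = dict(comm_of)
    merges: list[tuple[str, str, float]] = []
    while len(set(comm_of.values())) > 1:
        comms = sorted(set(comm_of.values()))
        # candidate pairs: communities joined by at least one edge; if the
        # graph is disconnected these run out and remaining merges (always
        # Q-decreasing) are taken across components to finish the dendrogram.
        connected = set()
        for u, v in graph.edges:
            cu, cv = comm_of[u], comm_of[v]
            if cu != cv:
                connected.add(tuple(sorted((cu, cv))))
        candidates = sorted(connected) if connected else list(
            itertools.combinations(comms, 2))
        best_pair, best_gain = None, -np.inf
        for a, b in candidates:
            saved = dict(comm_of)
            target = min(a, b)
            for n in nodes:
                if comm_of[n] in (a, b):
                    comm_of[n] = target
            gain = _q()
            comm_of.update(saved)
            if gain > best_gain + 1e-12:
                best_gain, best_pair = gain, (a, b)
        a, b = best_pair
        target = min(a, b)
        for n in nodes:
            if comm_of[n] in (a, b):
                comm_of[n] = target
        q_now = best_gain
        merges.append((a, b, q_now))
        if q_now > best_q + 1e-12:
            best_q = q_now
            best_assign = dict(comm_of)

    comm_of = best_assign
    part = _partition()
    return ClusteringResult(part, float(best_q), merges, weights is not None)


# ---------------------------------------------------------------------------
# Source/sink classification and key nodes
# ---------------------------------------------------------------------------


def classify_source_sink(network: MigrationNetwork) -> dict[str, str]:
    """Label each node source (out > in), sink (in > out) or mixed (equal)."""
    labels = {}
    for node in network.nodes:
        i, o = network.in_degree(node), network.out_degree(node)
        labels[node] = "sink" if i > o else ("source" if o > i else "mixed")
    return labels


def label_persistence(labels_by_slice: dict[int, dict[str, str]]) -> pd.DataFrame:
    """Per-site label across slices plus a persistence verdict.

    Nodes are matched across slices by their site prefix (population code
    with the trailing time digit stripped).
    """
    def site_of(code: str) -> str:
        return code.rstrip("0123456789") or code

    sites = sorted({site_of(n) for labs in labels_by_slice.values() for n in labs})
    rows = []
    for site in sites:
        rec: dict = {"site": site}
        seen = []
        for t in sorted(labels_by_slice):
            lab = next((l for n, l in labels_by_slice[t].items() if site_of(n) == site), None)
            rec[f"time{t}"] = lab
            if lab is not None:
                seen.append(lab)
        rec["persistent"] = len(set(seen)) == 1 and len(seen) > 0
        rec["label"] = seen[0] if rec["persistent"] else None
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class KeyNodeReport:
    per_cluster_max_degree: dict[int, list[str]]
    bridge_nodes: list[str]
    global_max_degree: list[str]
    source_sink: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in sorted(self.source_sink):
            rows.append({
                "node": node,
                "cluster_max_degree": any(node in v for v in self.per_cluster_max_degree.values()),
                "bridge": node in self.bridge_nodes,
                "global_max_degree": node in self.global_max_degree,
                "role": self.source_sink[node],
            })
        return pd.DataFrame(rows)


def key_nodes(network: MigrationNetwork, clustering: ClusteringResult) -> KeyNodeReport:
    """Pivotal nodes: per-cluster and global degree maxima plus cluster bridges.

    Bridge nodes are endpoints of edges whose ends fall in different
    clusters — populations shared between clusters.  All degree ties are
    listed.  An edgeless network yields an empty report.
    """
    part = clustering.partition
    if set(part) != set(network.nodes):
        raise ValueError("clustering does not cover the network's nodes")
    degs = {n: network.degree(n) for n in network.nodes}
    per_cluster: dict[int, list[str]] = {}
    for c in sorted(set(part.values())):
        members = [n for n in network.nodes if part[n] == c]
        mx = max(degs[n] for n in members)
        if mx > 0:
            per_cluster[c] = sorted(n for n in members if degs[n] == mx)
    bridges = sorted({
        n for u, v in network.undirected().edges if part[u] != part[v] for n in (u, v)})
    gmax = max(degs.values()) if degs else 0
    global_max = sorted(n for n, d in degs.items() if d == gmax and gmax > 0)
    return KeyNodeReport(per_cluster, bridges, global_max, classify_source_sink(network))


# ---------------------------------------------------------------------------
# Migration distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceSummary:
    n_edges: int
    mean: float
    median: float
    q1: float
    q3: float
    maximum: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    distances: list[float] = field(repr=False, default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_edges": self.n_edges, "mean_km": self.mean, "median_km": self.median,
            "q1_km": self.q1, "q3_km": self.q3, "max_km": self.maximum,
            "ci_low_km": np.nan if self.ci_low is None else float(self.ci_low),
            "ci_high_km": np.nan if self.ci_high is None else float(self.ci_high)}])


def migration_distance_summary(
    networks: MigrationNetwork | Sequence[MigrationNetwork],
) -> DistanceSummary:
    """Geodesic edge lengths with mean, quartiles and a t-based 95% CI.

    Accepts one network (per-slice summary) or several (pooled).  The CI of
    the mean is the Student-t interval; it is undefined (None, flagged) for
    a single edge.  Missing node coordinates are an error naming the node.
    """
    nets = [networks] if isinstance(networks, MigrationNetwork) else list(networks)
    dists = []
    for net in nets:
        for u, v, d in net.graph.edges(data=True):
            km = d.get("distance_km", np.nan)
            if not np.isfinite(km):
                for node in (u, v):
                    attrs = net.graph.nodes[node]
                    if not np.isfinite(attrs.get("latitude", np.nan)):
                        raise ValueError(f"node {node} has no coordinates")
                km = geodesic_km(
                    (net.graph.nodes[u]["latitude"], net.graph.nodes[u]["longitude"]),
                    (net.graph.nodes[v]["latitude"], net.graph.nodes[v]["longitude"]))
            dists.append(float(km))
    if not dists:
        raise ValueError("no edges to summarize")
    arr = np.array(dists)
    ci_low = ci_high = None
    if len(arr) >= 2 and arr.std(ddof=1) > 0:
        sem = arr.std(ddof=1) / np.sqrt(len(arr))
        tcrit = stats.t.ppf(0.975, df=len(arr) - 1)
        ci_low, ci_high = float(arr.mean() - tcrit * sem), float(arr.mean() + tcrit * sem)
    elif len(arr) == 1:
        logger.warning("single edge: CI of the mean migration distance is undefined")
    return DistanceSummary(
        len(arr), float(arr.mean()), float(np.median(arr)),
        float(np.quantile(arr, 0.25)), float(np.quantile(arr, 0.75)),
        float(arr.max()), ci_low, ci_high, distances=dists)
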