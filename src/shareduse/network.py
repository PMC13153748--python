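"""Directed collaboration networks and their metrics.

Each network covers one (fiscal year, modality) stratum: nodes are the
facilities participating in at least one shared-use event, a directed edge
source -> target is weighted by the number of events for that ordered pair.

Metrics follow the social-network conventions for directed graphs:

* density = m / (n (n - 1)), with m the number of distinct ordered pairs
  carrying an edge (unweighted) and self-loops excluded;
* reciprocity is dyadic by default: a / (a + b + c) where a counts mutual
  *pairs* and b + c the one-way connected pairs (the ``edgewise`` convention
  2a / (2a + b + c) is available behind a flag);
* modularity is Newman–Girvan Q on the symmetrized weighted graph.

Louvain community detection is implemented here in its classical two-phase
form (seeded local moving, then aggregation) with an instrumentation hook
exposing the modularity reached after each pass, so that monotone
non-decrease is testable.  :func:`exhaustive_best_partition` enumerates all
partitions of small graphs as an independent optimum reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .detection import EVENT_COLUMNS, SharedUseEvent, events_to_frame


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty (e.g. density with n < 2)."""


@dataclass
class DirectedNetwork:
    """Weighted directed facility graph for one (fiscal year, modality)."""

    graph: nx.DiGraph
    modality: Optional[str] = None
    fiscal_year: Optional[int] = None

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self) -> dict[tuple[str, str], int]:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}


@dataclass
class DyadCensus:
    """Mutual vs asymmetric connected unordered pairs."""

    mutual: int
    asymmetric: int

    @property
    def connected(self) -> int:
        return self.mutual + self.asymmetric


@dataclass
class Partition:
    """Facility -> community assignment with its modularity Q."""

    community_of: dict[str, int]
    q: float
    pass_modularities: list[float] = field(default_factory=list)

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.community_of.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]

    def labels(self, nodes: Iterable[str]) -> list[int]:
        return [self.community_of[n] for n in nodes]


def build_network(
    events: Union[Iterable[SharedUseEvent], pd.DataFrame],
    modality: Optional[str] = None,
    fiscal_year: Optional[int] = None,
) -> DirectedNetwork:
    """Aggregate events of a single stratum into a weighted directed graph.

    Raises ValueError if the events mix (modality, fiscal_year) strata.
    """
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if not frame.empty:
        strata = frame[["modality", "fiscal_year"]].drop_duplicates()
        if len(strata) > 1:
            raise ValueError(f"events span multiple strata: {strata.to_dict('records')}")
        modality = modality or strata.iloc[0]["modality"]
        fiscal_year = fiscal_year if fiscal_year is not None else int(strata.iloc[0]["fiscal_year"])

    g = nx.DiGraph()
    if not frame.empty:
        counts = (
            frame.groupby(["source_facility_id", "target_facility_id"]).size().reset_index(name="weight")
        )
        for r in counts.itertuples(index=False):
            if r.source_facility_id == r.target_facility_id:
                raise ValueError(f"self-loop event at facility {r.source_facility_id}")
            g.add_edge(r.source_facility_id, r.target_facility_id, weight=int(r.weight))
    return DirectedNetwork(graph=g, modality=modality, fiscal_year=fiscal_year)


def density(network: DirectedNetwork) -> float:
    """Directed unweighted density m / (n (n-1)); undefined for n < 2."""
    n = network.n
    if n < 2:
        raise UndefinedMetricError(f"density undefined for n={n} (< 2 nodes)")
    return network.m / (n * (n - 1))


def dyad_census(network: DirectedNetwork) -> DyadCensus:
    g = network.graph
    mutual = asym = 0
    for u, v in g.edges():
        if u < v or not g.has_edge(v, u):
            if g.has_edge(v, u):
                mutual += 1
            else:
                asym += 1
    return DyadCensus(mutual=mutual, asymmetric=asym)


def reciprocity(network: DirectedNetwork, convention: str = "dyadic") -> float:
    """Share of bidirectional collaboration.

    ``dyadic``: mutual pairs / connected pairs, a / (a + b + c).
    ``edgewise``: reciprocated edges / all edges, 2a / (2a + b + c).
    """
    census = dyad_census(network)
    if census.connected == 0:
        raise UndefinedMetricError("reciprocity undefined: no connected dyads")
    a, bc = census.mutual, census.asymmetric
    if convention == "dyadic":
        return a / (a + bc)
    if convention == "edgewise":
        return 2 * a / (2 * a + bc)
    raise ValueError(f"unknown reciprocity convention {convention!r}")


# ---------------------------------------------------------------------------
# modularity and Louvain on the symmetrized weighted projection


def _symmetrized(network: DirectedNetwork, weighted: bool) -> dict[str, dict[str, float]]:
    adj: dict[str, dict[str, float]] = {u: {} for u in network.graph.nodes}
    for u, v, d in network.graph.edges(data=True):
        w = float(d.get("weight", 1)) if weighted else 1.0
        adj[u][v] = adj[u].get(v, 0.0) + w
        adj[v][u] = adj[v].get(u, 0.0) + w
    return adj


def modularity(
    network: DirectedNetwork,
    partition: Union[Partition, dict[str, int]],
    weighted: bool = True,
    resolution: float = 1.0,
) -> float:
    """Newman–Girvan modularity of a node partition.

    Evaluated on the symmetrized graph (w_ij = sum of the two directed
    weights):  Q = (1/2W) sum_ij [w_ij - r k_i k_j / (2W)] delta(c_i, c_j).
    """
    community_of = partition.community_of if isinstance(partition, Partition) else partition
    missing = [u for u in network.graph.nodes if u not in community_of]
    if missing:
        raise ValueError(f"partition missing node(s): {sorted(missing)[:5]}")
    adj = _symmetrized(network, weighted)
    degree = {u: sum(nbrs.values()) for u, nbrs in adj.items()}
    two_w = sum(degree.values())
    if two_w == 0:
        return 0.0
    q = 0.0
    # within-community edge weight (each unordered pair counted twice via adj)
    for u, nbrs in adj.items():
        for v, w in nbrs.items():
            if community_of[u] == community_of[v]:
                q += w
    # degree expectation per community
    sum_deg: dict[int, float] = {}
    for u, k in degree.items():
        sum_deg[community_of[u]] = sum_deg.get(community_of[u], 0.0) + k
    q -= resolution * sum(s * s for s in sum_deg.values()) / two_w
    return q / two_w


def louvain(
    network: DirectedNetwork,
    seed: int = 0,
    resolution: float = 1.0,
    weighted: bool = True,
    gain_tol: float = 1e-10,
    n_restarts: int = 10,
) -> Partition:
    """Two-phase Louvain modularity optimization with seeded restarts.

    Local moving visits nodes in a seed-shuffled order and accepts the best
    single-node move whose modularity gain exceeds ``gain_tol``; when no move
    improves, communities are aggregated into super-nodes and the procedure
    repeats until an aggregation pass yields no further gain.  Because the
    greedy sweep can stall in a local optimum that depends on the visiting
    order, the whole procedure is restarted ``n_restarts`` times with
    substreams derived from ``seed`` and the highest-Q partition is kept.
    The modularity reached after each pass of the winning run is recorded in
    ``Partition.pass_modularities`` (non-decreasing by construction).
    """
    best: Optional[Partition] = None
    for r, child in enumerate(np.random.SeedSequence(seed).spawn(max(1, n_restarts))):
        part = _louvain_once(
            network, np.random.default_rng(child), resolution, weighted, gain_tol,
            random_init=r > 0,
        )
        if best is None or part.q > best.q:
            best = part
    return best


def _louvain_once(
    network: DirectedNetwork,
    rng: np.random.Generator,
    resolution: float,
    weighted: bool,
    gain_tol: float,
    random_init: bool = False,
) -> Partition:
    nodes = list(network.graph.nodes)
    if not nodes:
        return Partition(community_of={}, q=0.0)
    adj = _symmetrized(network, weighted)

    # current partition of original nodes, via the aggregated graph.
    # the first restart begins from the classical all-singleton partition;
    # later restarts diversify with a random initial assignment.
    if random_init:
        membership = {u: int(rng.integers(0, len(nodes))) for u in nodes}
    else:
        membership = {u: i for i, u in enumerate(nodes)}  # original node -> community
    current_adj = adj
    current_nodes = nodes
    node_to_comm = {u: membership[u] for u in nodes}  # aggregated node -> community
    pass_q: list[float] = []

    while True:
        improved = _local_moving(current_adj, current_nodes, node_to_comm, rng, resolution, gain_tol)
        # project back onto original nodes
        if current_nodes is nodes:
            membership = dict(node_to_comm)
        else:
            membership = {u: node_to_comm[membership[u]] for u in nodes}
        q_now = modularity(network, _relabel(membership), weighted=weighted, resolution=resolution)
        pass_q.append(q_now)
        if not improved:
            break
        # aggregation phase: communities become super-nodes
        current_adj, comm_nodes = _aggregate(current_adj, node_to_comm)
        current_nodes = comm_nodes
        node_to_comm = {c: c for c in comm_nodes}
        # membership already maps original nodes to community ids == super-node ids

    final = _relabel(membership)
    q = modularity(network, final, weighted=weighted, resolution=resolution)
    return Partition(community_of=final, q=q, pass_modularities=pass_q)


def _relabel(membership: dict[str, int]) -> dict[str, int]:
    """Renumber communities 0..k-1 in order of first appearance (sorted nodes)."""
    mapping: dict[int, int] = {}
    out = {}
    for u in sorted(membership):
        c = membership[u]
        if c not in mapping:
            mapping[c] = len(mapping)
        out[u] = mapping[c]
    return out


def _local_moving(adj, nodes, node_to_comm, rng, resolution, gain_tol) -> bool:
    """Greedy single-node moves until no gain; mutates node_to_comm."""
    degree = {u: sum(adj[u].values()) for u in nodes}
    self_loop = {u: adj[u].get(u, 0.0) for u in nodes}
    two_w = sum(degree.values())
    if two_w == 0:
        return False
    sum_tot = {}
    for u in nodes:
        sum_tot[node_to_comm[u]] = sum_tot.get(node_to_comm[u], 0.0) + degree[u]

    improved_any = False
    order = list(nodes)
    fresh = max(sum_tot, default=-1) + 1  # next unused community id
    moved = True
    while moved:
        moved = False
        rng.shuffle(order)
        for u in order:
            cu = node_to_comm[u]
            k_u = degree[u]
            # links from u to each neighbouring community (excluding self-loop)
            links: dict[int, float] = {}
            for v, w in adj[u].items():
                if v == u:
                    continue
                links[node_to_comm[v]] = links.get(node_to_comm[v], 0.0) + w
            # remove u from its community
            sum_tot[cu] -= k_u
            base = links.get(cu, 0.0) - resolution * sum_tot[cu] * k_u / two_w
            best_c, best_gain = cu, 0.0
            for c, l_uc in sorted(links.items()):
                if c == cu:
                    continue
                gain = (l_uc - resolution * sum_tot[c] * k_u / two_w) - base
                if gain > best_gain + gain_tol:
                    best_c, best_gain = c, gain
            if -base > best_gain + gain_tol:
                # isolating u into a fresh empty community is the best move
                best_c = fresh
                fresh += 1
            node_to_comm[u] = best_c
            sum_tot[best_c] = sum_tot.get(best_c, 0.0) + k_u
            if best_c != cu:
                moved = True
                improved_any = True
    return improved_any


def _aggregate(adj, node_to_comm):
    """Collapse communities into super-nodes; returns (new_adj, new_nodes)."""
    new_adj: dict[int, dict[int, float]] = {}
    for u, nbrs in adj.items():
        cu = node_to_comm[u]
        row = new_adj.setdefault(cu, {})
        for v, w in nbrs.items():
            cv = node_to_comm[v]
            row[cv] = row.get(cv, 0.0) + w
    return new_adj, sorted(new_adj)


def exhaustive_best_partition(
    network: DirectedNetwork, weighted: bool = True, resolution: float = 1.0
) -> Partition:
    """Globally optimal-modularity partition by enumerating all set
    partitions; feasible only for small graphs (≲ 10 nodes)."""
    nodes = sorted(network.graph.nodes)
    if not nodes:
        return Partition(community_of={}, q=0.0)
    best_q, best = -np.inf, None
    for labels in _restricted_growth_strings(len(nodes)):
        part = dict(zip(nodes, labels))
        q = modularity(network, part, weighted=weighted, resolution=resolution)
        if q > best_q:
            best_q, best = q, part
    return Partition(community_of=_relabel(best), q=best_q)


def _restricted_growth_strings(n: int):
    """All set partitions of n items as canonical label sequences."""
    labels = [0] * n

    def rec(i: int, max_label: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0) if n > 1 else iter([(0,)])


# ---------------------------------------------------------------------------
# export


def export_network(
    network: DirectedNetwork,
    path: Union[str, Path],
    partition: Optional[Partition] = None,
    format: str = "graphml",
) -> Path:
    """Write the network as GraphML or a source/target/weight TSV edge list.

    GraphML carries directed edges with a ``weight`` attribute and, when a
    partition is given, a ``community`` node attribute.
    """
    path = Path(path)
    g = network.graph.copy()
    if partition is not None:
        missing = [u for u in g.nodes if u not in partition.community_of]
        if missing:
            raise ValueError(f"partition missing node(s): {sorted(missing)[:5]}")
        nx.set_node_attributes(g, {u: int(c) for u, c in partition.community_of.items()}, "community")
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edgelist_tsv":
        rows = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).sort_values(
            ["source", "target"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def events_frame_columns() -> list[str]:
    return list(EVENT_COLUMNS)
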