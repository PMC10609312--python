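"""Allosteric signaling pathways on residue interaction graphs.

Residues are nodes; an edge joins residues in spatial contact, weighted by
``w = −log(coupling)`` where coupling is either the |cross-correlation|
from the Gaussian network model or the learned edge probability from
relational inference.  Strong coupling → small weight, so minimum-weight
paths are the most strongly coupled signaling routes.  Pathways run from
the substrate-recognition residues (consensus 11 and 117 by default) to the
flexible I-Loop (consensus 98–112), and each residue's frequency of
occurrence across the path set measures its importance for signal
mediation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

#: Default signal sources and sinks in consensus numbering.
DEFAULT_SOURCES = (11, 117)
DEFAULT_SINKS = tuple(range(98, 113))   # the I-Loop

EPS_FLOOR = 1e-9


@dataclass
class ResidueGraph:
    """Undirected weighted graph over residues (lower weight = stronger)."""

    graph: nx.Graph

    def __post_init__(self):
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise ValueError("self-edge in residue graph")
            if w is None or w <= 0:
                raise ValueError(f"non-positive weight on edge ({u}, {v})")

    @property
    def nodes(self):
        return list(self.graph.nodes)


@dataclass
class Path:
    nodes: tuple[int, ...]
    weight: float

    @property
    def source(self) -> int:
        return self.nodes[0]

    @property
    def sink(self) -> int:
        return self.nodes[-1]


@dataclass
class PathSet:
    paths: list[Path] = field(default_factory=list)

    def __len__(self):
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)


def build_graph(coupling: np.ndarray, contacts: np.ndarray,
                eps: float = 1e-4,
                node_ids: np.ndarray | None = None) -> ResidueGraph:
    """Residue graph from a coupling matrix restricted to spatial contacts.

    ``coupling`` is symmetric with entries clipped into [0, 1] (e.g.
    |GNM correlation| or NRI edge probability); ``contacts`` is a boolean
    adjacency (e.g. from a distance cutoff).  Edge weight is
    ``−log(max(coupling, eps))``, floored at ``−log(1 − 1e−9)`` so perfect
    coupling still has positive weight.  ``node_ids`` relabels nodes (e.g.
    consensus numbering); default 1..N.
    """
    coupling = np.asarray(coupling, dtype=float)
    contacts = np.asarray(contacts, dtype=bool)
    n = coupling.shape[0]
    if coupling.shape != (n, n) or contacts.shape != (n, n):
        raise ValueError("coupling and contacts must be square and congruent")
    coupling = np.clip(np.abs(coupling), 0.0, 1.0 - EPS_FLOOR)
    if not np.any(coupling[contacts] > 0):
        raise ValueError("all-zero coupling on the contact set")
    ids = np.arange(1, n + 1) if node_ids is None else np.asarray(node_ids)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in ids)
    for i in range(n):
        for j in range(i + 1, n):
            if not contacts[i, j]:
                continue
            w = -np.log(max(coupling[i, j], eps))
            g.add_edge(int(ids[i]), int(ids[j]), weight=float(w))
    return ResidueGraph(graph=g)


def _dijkstra_best_path(g: nx.Graph, source: int, sink: int) -> Path | None:
    """Minimum-weight path with deterministic tie-breaks.

    Ties on total weight are broken by fewer hops, then by the
    lexicographically smallest node sequence.  Works in two passes: Dijkstra
    distance maps from both endpoints define the subgraph of weight-optimal
    edges (a DAG, since all weights are positive), on which minimum hop
    counts and the lexicographically smallest walk are computed exactly.
    """
    if source == sink:
        return Path(nodes=(source,), weight=0.0)
    try:
        dist_s = nx.single_source_dijkstra_path_length(g, source)
    except nx.NodeNotFound:
        return None
    if sink not in dist_s:
        return None
    dist_t = nx.single_source_dijkstra_path_length(g, sink)
    total = dist_s[sink]
    tol = 1e-10 * (1.0 + abs(total))

    # directed edges u->v on some minimum-weight source->sink path
    succ: dict[int, list[int]] = {}
    nodes_on = [
        u for u in g
        if u in dist_s and u in dist_t
        and abs(dist_s[u] + dist_t[u] - total) <= tol
    ]
    for u in nodes_on:
        for v in g.neighbors(u):
            if v not in dist_t:
                continue
            w = g.edges[u, v]["weight"]
            if abs(dist_s[u] + w + dist_t[v] - total) <= tol \
                    and dist_s.get(v, np.inf) > dist_s[u]:
                succ.setdefault(u, []).append(v)

    # min hops to the sink over the DAG (process by decreasing dist_s)
    hops = {sink: 0}
    for u in sorted(nodes_on, key=lambda n: -dist_s[n]):
        if u == sink:
            continue
        cand = [hops[v] + 1 for v in succ.get(u, []) if v in hops]
        if cand:
            hops[u] = min(cand)
    if source not in hops:
        return None
    path = [source]
    u = source
    while u != sink:
        u = min(v for v in succ[u] if v in hops and hops[v] == hops[u] - 1)
        path.append(u)
    return Path(nodes=tuple(path), weight=float(total))


def shortest_paths(rg: ResidueGraph, sources=DEFAULT_SOURCES,
                   sinks=DEFAULT_SINKS) -> PathSet:
    """One minimum-weight path per (source, sink) pair.

    Unreachable or absent pairs are skipped with a warning.
    """
    g = rg.graph
    out = PathSet()
    for s in sources:
        if s not in g:
            warnings.warn(f"source {s} not in graph; skipped")
            continue
        for t in sinks:
            if t == s:
                continue
            if t not in g:
                warnings.warn(f"sink {t} not in graph; skipped")
                continue
            p = _dijkstra_best_path(g, s, t)
            if p is None:
                warnings.warn(f"sink {t} unreachable from {s}; skipped")
                continue
            out.paths.append(p)
    return out


def residue_frequency(paths: PathSet) -> dict[int, int]:
    """Number of pathways containing each residue (once per path)."""
    if len(paths) == 0:
        raise ValueError("empty path set")
    freq: dict[int, int] = {}
    for p in paths:
        for node in set(p.nodes):
            freq[node] = freq.get(node, 0) + 1
    return freq


def top_pathway(paths: PathSet, freq: dict[int, int] | None = None) -> Path:
    """The pathway whose members have the highest mean occurrence frequency.

    Ties are broken by smaller total weight, then by the lexicographically
    smallest node sequence, so the result does not depend on path order.
    """
    if len(paths) == 0:
        raise ValueError("empty path set")
    freq = freq or residue_frequency(paths)

    def sort_key(p: Path):
        mean_freq = np.mean([freq.get(n, 0) for n in p.nodes])
        return (-mean_freq, p.weight, p.nodes)

    return min(paths, key=sort_key)
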