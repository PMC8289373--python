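"""Feature graph construction and spanning-tree sampling.

The full model couples every pair of MS features with distinct retention
times.  Exact inference on that graph is intractable, so it is approximated
by spanning trees: either random trees (minimum spanning tree over i.i.d.
Uniform(0,1) edge weights — by symmetry, every spanning tree of the eligible
graph with equal topology probability under the random-weight construction)
or the deterministic chain linking features in order of increasing RT.

Feature pairs with exactly equal retention times carry no order information
and their edge is never sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np

from .data_model import Dataset, ValidationError

__all__ = [
    "FeatureGraph",
    "SpanningTree",
    "DisconnectedGraphError",
    "build_feature_graph",
    "sample_spanning_tree",
    "sample_tree_ensemble",
    "chain_tree",
]


class DisconnectedGraphError(ValidationError):
    """The eligible feature graph is not connected (degenerate RT structure)."""


def _canonical(edge: Tuple[str, str]) -> Tuple[str, str]:
    a, b = edge
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class FeatureGraph:
    """All features plus the eligible (distinct-RT) unordered edges."""

    nodes: Tuple[str, ...]
    edges: Tuple[Tuple[str, str], ...]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class SpanningTree:
    """A cycle-free connected subgraph covering every feature.

    ``edges`` holds exactly N-1 canonical (sorted) unordered pairs.  The
    rooted form used by message passing is derived on demand via
    :meth:`rooted`.
    """

    nodes: Tuple[str, ...]
    edges: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.nodes) - 1:
            raise ValidationError(
                f"spanning tree over {len(self.nodes)} nodes needs "
                f"{len(self.nodes) - 1} edges, got {len(self.edges)}"
            )
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if len(self.nodes) > 1 and not nx.is_tree(g):
            raise ValidationError("edge set is not a spanning tree")

    def adjacency(self) -> Dict[str, List[str]]:
        adj: Dict[str, List[str]] = {n: [] for n in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def rooted(self, root: str | None = None) -> Tuple[List[str], Dict[str, str]]:
        """BFS order from ``root`` (default: lowest node id) and parent map."""
        if root is None:
            root = min(self.nodes)
        adj = self.adjacency()
        order = [root]
        parent: Dict[str, str] = {}
        seen = {root}
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    order.append(v)
                    queue.append(v)
        if len(order) != len(self.nodes):
            raise ValidationError("tree is not connected")
        return order, parent


def build_feature_graph(dataset: Dataset) -> FeatureGraph:
    """Eligible-edge graph: all pairs of features with distinct RTs.

    Raises :class:`DisconnectedGraphError` when the eligible graph is
    disconnected (this happens exactly when N >= 2 and every feature shares
    one retention time), naming the offending RT group.
    """
    nodes = tuple(dataset.feature_ids)
    rts = {f.feature_id: f.retention_time for f in dataset.features}
    edges = tuple(
        _canonical((a, b))
        for idx, a in enumerate(nodes)
        for b in nodes[idx + 1 :]
        if rts[a] != rts[b]
    )
    graph = FeatureGraph(nodes, edges)
    if len(nodes) > 1 and not nx.is_connected(graph.to_networkx()):
        groups: Dict[float, List[str]] = {}
        for fid, rt in rts.items():
            groups.setdefault(rt, []).append(fid)
        bad = {rt: fids for rt, fids in groups.items() if len(fids) > 1}
        raise DisconnectedGraphError(
            "eligible feature graph is disconnected; equal-RT groups with no "
            f"outside connection: {bad}"
        )
    return graph


def sample_spanning_tree(
    graph: FeatureGraph, rng_seed: int | np.random.Generator
) -> SpanningTree:
    """One random spanning tree: MST over i.i.d. Uniform(0,1) edge weights."""
    if len(graph.nodes) > 1 and not nx.is_connected(graph.to_networkx()):
        raise DisconnectedGraphError("cannot sample a spanning tree: disconnected")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    weights = rng.uniform(size=len(graph.edges))
    for (a, b), w in zip(graph.edges, weights):
        g.add_edge(a, b, weight=w)
    mst = nx.minimum_spanning_tree(g)
    return SpanningTree(
        tuple(graph.nodes), tuple(sorted(_canonical(e) for e in mst.edges()))
    )


def sample_tree_ensemble(
    graph: FeatureGraph, L: int, rng_seed: int
) -> List[SpanningTree]:
    """L independent random spanning trees; sub-seeds spawned from rng_seed.

    Deterministic given (graph, L, rng_seed); trees may repeat.
    """
    if L < 1:
        raise ValidationError("ensemble size L must be >= 1")
    children = np.random.SeedSequence(rng_seed).spawn(L)
    return [
        sample_spanning_tree(graph, np.random.default_rng(ss)) for ss in children
    ]


def chain_tree(dataset: Dataset) -> SpanningTree:
    """Chain linking features in increasing-RT order (a degenerate tree).

    RT ties are broken by feature_id so the chain is deterministic; the
    resulting equal-RT edge is handled by the inference layer as an
    uninformative constant factor.
    """
    ordered = sorted(
        dataset.features, key=lambda f: (f.retention_time, f.feature_id)
    )
    ids = [f.feature_id for f in ordered]
    edges = tuple(
        sorted(_canonical((a, b)) for a, b in zip(ids, ids[1:]))
    )
    return SpanningTree(tuple(dataset.feature_ids), edges)
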