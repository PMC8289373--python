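"""Exact tree inference: sum-product, max-product, MAP, ensemble averaging.

On a spanning tree T the model

    p(z | T) = 1/Z(T) * prod_i psi_i(z_i)^(1-D) * prod_(i,j) in E(T) psi_ij(z_i, z_j)^D

admits exact marginals by two-pass message passing (2(N-1) directed
messages from an arbitrary root; the result is root-invariant).  Sum-product
yields sum-marginals, normalized per feature to sum to 1; max-product yields
max-marginals, normalized per feature by their maximum (so the best
candidate's max-marginal is exactly 1).  Averaging per-tree marginals over a
random spanning-tree ensemble approximates the marginals of the full model.

All computation is in log-space: step-function edge potentials (epsilon =
1e-10) multiplied across many edges underflow any linear-space product.

A brute-force enumeration oracle over all candidate assignments is provided
for testing and for exact full-graph marginals at toy scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from joblib import Parallel, delayed
from scipy.special import logsumexp

from .data_model import Dataset, MarginalTable, PotentialConfig, ValidationError
from .graphs import SpanningTree
from .potentials import (
    log_edge_potential_matrix,
    log_node_potential_vector,
    log_sigma_map,
)

__all__ = [
    "TreeFactorization",
    "Assignment",
    "InferenceStats",
    "factorize",
    "sum_product_marginals",
    "max_product_marginals",
    "map_assignment",
    "brute_force_marginals",
    "ensemble_marginals",
]


@dataclass
class InferenceStats:
    """Instrumentation counters for the complexity contract.

    ``n_messages`` counts directed messages (exactly 2(N-1) per tree);
    ``n_potential_entries`` counts edge-potential entries touched, which is
    O(N * n_max^2) per tree.
    """

    n_messages: int = 0
    n_potential_entries: int = 0


@dataclass(frozen=True)
class Assignment:
    """One candidate index per feature (the MAP output)."""

    indices: Dict[str, int]

    def __getitem__(self, feature_id: str) -> int:
        return self.indices[feature_id]


@dataclass(frozen=True)
class TreeFactorization:
    """Log-space potentials of a tree- (or graph-) structured model.

    ``log_node[fid]`` is the (1-D)-weighted log node-potential vector;
    ``log_edge[(a, b)]`` (keys canonically sorted, a < b) is the D-weighted
    log edge-potential matrix with rows indexing a's candidates and columns
    b's.  All entries are finite because potentials are strictly positive.
    """

    feature_ids: Tuple[str, ...]
    candidate_ids: Dict[str, List[str]]
    log_node: Dict[str, np.ndarray]
    log_edge: Dict[Tuple[str, str], np.ndarray]

    def n_candidates(self, fid: str) -> int:
        return len(self.log_node[fid])

    def oriented_edge(self, u: str, v: str) -> np.ndarray:
        """Log edge matrix with rows over u's candidates, columns over v's."""
        if (u, v) in self.log_edge:
            return self.log_edge[(u, v)]
        return self.log_edge[(v, u)].T

    def edges(self) -> Iterable[Tuple[str, str]]:
        return self.log_edge.keys()


def factorize(
    dataset: Dataset,
    edges: Sequence[Tuple[str, str]],
    config: PotentialConfig,
) -> TreeFactorization:
    """Build the log-space factorization for the given edge set.

    Candidate sets must already carry normalized scores.  An equal-RT edge
    (possible only in the deterministic chain when RTs tie) contributes the
    constant matrix sigma(0)^D — no order information, cancelling in the
    normalization.
    """
    feats = {f.feature_id: f for f in dataset.features}
    sets = {cs.feature_id: cs for cs in dataset.candidate_sets}
    log_node = {
        fid: log_node_potential_vector(sets[fid], config) for fid in feats
    }
    log_edge: Dict[Tuple[str, str], np.ndarray] = {}
    for a, b in edges:
        a, b = (a, b) if a <= b else (b, a)
        fa, fb = feats[a], feats[b]
        if fa.retention_time == fb.retention_time:
            const = config.D * log_sigma_map(0.0, config)
            log_edge[(a, b)] = np.full((len(sets[a]), len(sets[b])), const)
        else:
            log_edge[(a, b)] = log_edge_potential_matrix(
                fa, fb, sets[a], sets[b], config
            )
    return TreeFactorization(
        feature_ids=tuple(dataset.feature_ids),
        candidate_ids={
            fid: [c.candidate_id for c in sets[fid].candidates] for fid in feats
        },
        log_node=log_node,
        log_edge=log_edge,
    )


def _check_match(tree: SpanningTree, factors: TreeFactorization) -> None:
    if set(tree.nodes) != set(factors.feature_ids):
        raise ValidationError("tree nodes do not match factorization features")
    for a, b in tree.edges:
        key = (a, b) if a <= b else (b, a)
        if key not in factors.log_edge:
            raise ValidationError(f"factorization missing edge {key}")
        mat = factors.log_edge[key]
        if mat.shape != (factors.n_candidates(key[0]), factors.n_candidates(key[1])):
            raise ValidationError(f"edge {key}: matrix shape mismatch")


def _message_passing(
    tree: SpanningTree,
    factors: TreeFactorization,
    combine,
    stats: Optional[InferenceStats],
    root: Optional[str] = None,
) -> Dict[str, np.ndarray]:
    """Two-pass schedule; returns unnormalized log beliefs per feature.

    ``combine`` reduces a (n_u, n_v) matrix of log terms over axis 0 — either
    logsumexp (sum-product) or max (max-product).  Each message is shifted by
    its maximum before storing; the constant cancels in the final per-feature
    normalization.
    """
    _check_match(tree, factors)
    order, parent = tree.rooted(root)
    adj = tree.adjacency()
    messages: Dict[Tuple[str, str], np.ndarray] = {}

    def send(u: str, v: str) -> None:
        b = factors.log_node[u].copy()
        for w in adj[u]:
            if w != v:
                b = b + messages[(w, u)]
        mat = factors.oriented_edge(u, v)
        msg = combine(b[:, None] + mat, axis=0)
        messages[(u, v)] = msg - msg.max()
        if stats is not None:
            stats.n_messages += 1
            stats.n_potential_entries += mat.size

    for u in reversed(order):  # leaves towards root
        if u in parent:
            send(u, parent[u])
    for u in order:  # root towards leaves
        for w in adj[u]:
            if parent.get(w) == u:
                send(u, w)

    beliefs = {}
    for fid in factors.feature_ids:
        b = factors.log_node[fid].copy()
        for w in adj[fid]:
            b = b + messages[(w, fid)]
        beliefs[fid] = b
    return beliefs


def sum_product_marginals(
    tree: SpanningTree,
    factors: TreeFactorization,
    stats: Optional[InferenceStats] = None,
    root: Optional[str] = None,
) -> MarginalTable:
    """Exact per-feature sum-marginals on a tree, normalized to sum to 1."""
    beliefs = _message_passing(tree, factors, logsumexp, stats, root)
    marginals = {
        fid: np.exp(b - logsumexp(b)) for fid, b in beliefs.items()
    }
    return MarginalTable(
        marginals, dict(factors.candidate_ids), "sum", "single-tree"
    )


def max_product_marginals(
    tree: SpanningTree,
    factors: TreeFactorization,
    stats: Optional[InferenceStats] = None,
    root: Optional[str] = None,
) -> MarginalTable:
    """Exact per-feature max-marginals on a tree, normalized by their maximum.

    Entry r is the highest unnormalized probability any assignment with
    z_i = r can reach, divided by the unconstrained maximum, so each
    feature's best candidate scores exactly 1.
    """
    beliefs = _message_passing(tree, factors, np.max, stats, root)
    marginals = {fid: np.exp(b - b.max()) for fid, b in beliefs.items()}
    return MarginalTable(
        marginals, dict(factors.candidate_ids), "max", "single-tree"
    )


def map_assignment(
    tree: SpanningTree,
    factors: TreeFactorization,
    root: Optional[str] = None,
) -> Assignment:
    """Assignment maximizing the tree's unnormalized product.

    Max-product upward pass followed by backtracking from the root; ties are
    broken towards the lowest candidate index.
    """
    _check_match(tree, factors)
    order, parent = tree.rooted(root)
    adj = tree.adjacency()
    up: Dict[Tuple[str, str], np.ndarray] = {}
    partial: Dict[str, np.ndarray] = {}  # log node + msgs from children

    for u in reversed(order):
        b = factors.log_node[u].copy()
        for w in adj[u]:
            if parent.get(w) == u:
                b = b + up[(w, u)]
        partial[u] = b
        if u in parent:
            mat = factors.oriented_edge(u, parent[u])
            up[(u, parent[u])] = np.max(b[:, None] + mat, axis=0)

    indices: Dict[str, int] = {}
    rootid = order[0]
    indices[rootid] = int(np.argmax(partial[rootid]))
    for u in order[1:]:
        p = parent[u]
        mat = factors.oriented_edge(u, p)
        indices[u] = int(np.argmax(partial[u] + mat[:, indices[p]]))
    return Assignment(indices)


def brute_force_marginals(
    tree_or_graph,
    factors: TreeFactorization,
    kind: str = "sum",
    cap: int = 10**6,
) -> MarginalTable:
    """Exact marginals by exhaustive enumeration of all assignments.

    Accepts a :class:`SpanningTree`, a :class:`FeatureGraph`, or a bare edge
    sequence; on the full feature graph this computes the exact marginals of
    the complete pairwise model (intractable at scale, exact at toy scale).
    Refuses inputs with more than ``cap`` joint configurations.
    """
    if kind not in ("sum", "max"):
        raise ValidationError(f"kind must be 'sum' or 'max', got {kind!r}")
    edges = getattr(tree_or_graph, "edges", tree_or_graph)
    fids = list(factors.feature_ids)
    sizes = [factors.n_candidates(f) for f in fids]
    total = int(np.prod(sizes, dtype=np.int64))
    if total > cap:
        raise ValidationError(
            f"{total} configurations exceed the enumeration cap {cap}"
        )
    pos = {f: i for i, f in enumerate(fids)}
    configs = np.array(
        list(itertools.product(*[range(n) for n in sizes])), dtype=np.intp
    )
    logp = np.zeros(len(configs))
    for f in fids:
        logp += factors.log_node[f][configs[:, pos[f]]]
    for a, b in edges:
        a, b = (a, b) if a <= b else (b, a)
        logp += factors.log_edge[(a, b)][configs[:, pos[a]], configs[:, pos[b]]]

    marginals: Dict[str, np.ndarray] = {}
    for f in fids:
        col = configs[:, pos[f]]
        if kind == "sum":
            m = np.array(
                [logsumexp(logp[col == r]) for r in range(factors.n_candidates(f))]
            )
            marginals[f] = np.exp(m - logsumexp(m))
        else:
            m = np.array(
                [logp[col == r].max() for r in range(factors.n_candidates(f))]
            )
            marginals[f] = np.exp(m - m.max())
    return MarginalTable(
        marginals, dict(factors.candidate_ids), kind, "single-tree"
    )


def _single_tree(dataset, tree, config, kind, root):
    factors = factorize(dataset, tree.edges, config)
    infer = sum_product_marginals if kind == "sum" else max_product_marginals
    return infer(tree, factors, root=root)


def ensemble_marginals(
    dataset: Dataset,
    trees: Sequence[SpanningTree],
    config: PotentialConfig,
    kind: str = "max",
    n_jobs: int = 1,
    root: Optional[str] = None,
) -> MarginalTable:
    """Arithmetic mean of per-tree normalized marginals over an ensemble.

    Per-tree inference is independent (parallelizable with ``n_jobs``; the
    result does not depend on evaluation order).  Averaged sum-marginals stay
    on the probability simplex; averaged max-marginals are a plain mean and
    are deliberately not re-normalized.
    """
    if kind not in ("sum", "max"):
        raise ValidationError(f"kind must be 'sum' or 'max', got {kind!r}")
    trees = list(trees)
    if not trees:
        raise ValidationError("ensemble must contain at least one tree")
    if n_jobs != 1 and len(trees) > 1:
        tables = Parallel(n_jobs=n_jobs)(
            delayed(_single_tree)(dataset, t, config, kind, root) for t in trees
        )
    else:
        tables = [_single_tree(dataset, t, config, kind, root) for t in trees]
    avg = {
        fid: np.mean([t.marginals[fid] for t in tables], axis=0)
        for fid in tables[0].marginals
    }
    return MarginalTable(
        avg, dict(tables[0].candidate_ids), kind, "ensemble-average"
    )
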