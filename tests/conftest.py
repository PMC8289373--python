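"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from typing import Dict, Tuple

import numpy as np
import pytest

from msrtrank import (
    Candidate,
    CandidateSet,
    Dataset,
    FeatureGraph,
    MSFeature,
    TreeFactorization,
)


def make_dataset(rts, prefs, scores, correct=None, masses=None, has_ms2=True):
    """Small hand-built dataset: rts is a list per feature, prefs/scores are
    per-feature lists of per-candidate values."""
    features, sets = [], []
    for i, rt in enumerate(rts):
        fid = f"f{i}"
        features.append(
            MSFeature(fid, float(rt), 100.0 + i, has_ms2=has_ms2)
        )
        cands = []
        for j, (w, s) in enumerate(zip(prefs[i], scores[i])):
            m = masses[i][j] if masses is not None else 100.0 + i
            flag = None if correct is None else (j == correct[i])
            cands.append(
                Candidate(f"f{i}c{j}", float(s), float(m), float(w), is_correct=flag)
            )
        sets.append(CandidateSet(fid, cands))
    return Dataset(features, sets)


def random_factorization(
    rng: np.random.Generator, n_features: int, max_cands: int = 4
) -> Tuple[TreeFactorization, FeatureGraph]:
    """Random strictly-positive potentials over a complete feature graph."""
    fids = tuple(f"f{i}" for i in range(n_features))
    sizes = {f: int(rng.integers(1, max_cands + 1)) for f in fids}
    log_node = {f: rng.uniform(-2.0, 0.0, size=sizes[f]) for f in fids}
    log_edge: Dict[Tuple[str, str], np.ndarray] = {}
    edges = []
    for a, b in itertools.combinations(fids, 2):
        log_edge[(a, b)] = rng.uniform(-3.0, 0.0, size=(sizes[a], sizes[b]))
        edges.append((a, b))
    factors = TreeFactorization(
        feature_ids=fids,
        candidate_ids={f: [f"{f}c{r}" for r in range(sizes[f])] for f in fids},
        log_node=log_node,
        log_edge=log_edge,
    )
    return factors, FeatureGraph(fids, tuple(edges))


def linear_space_marginals(edges, factors: TreeFactorization, kind: str):
    """Independent enumeration oracle working entirely in linear space.

    Plain Python products and sums over all joint assignments; shares no
    code path with the package's log-space message passing or its log-space
    enumerator.
    """
    fids = list(factors.feature_ids)
    sizes = [factors.n_candidates(f) for f in fids]
    pos = {f: i for i, f in enumerate(fids)}
    node = {f: np.exp(factors.log_node[f]) for f in fids}
    edge = {key: np.exp(mat) for key, mat in factors.log_edge.items()}
    acc = {
        f: [([] if kind == "sum" else [0.0]) for _ in range(factors.n_candidates(f))]
        for f in fids
    }
    sums = {f: np.zeros(n) for f, n in zip(fids, sizes)}
    maxs = {f: np.zeros(n) for f, n in zip(fids, sizes)}
    for z in itertools.product(*[range(n) for n in sizes]):
        p = 1.0
        for f in fids:
            p *= node[f][z[pos[f]]]
        for a, b in edges:
            a, b = (a, b) if a <= b else (b, a)
            p *= edge[(a, b)][z[pos[a]], z[pos[b]]]
        for f in fids:
            r = z[pos[f]]
            sums[f][r] += p
            maxs[f][r] = max(maxs[f][r], p)
    if kind == "sum":
        return {f: sums[f] / sums[f].sum() for f in fids}
    return {f: maxs[f] / maxs[f].max() for f in fids}


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
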