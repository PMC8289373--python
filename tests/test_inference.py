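"""Sum-/max-product message passing against enumeration oracles."""

import numpy as np
import pytest

from conftest import linear_space_marginals, make_dataset, random_factorization
from msrtrank import (
    InferenceStats,
    PotentialConfig,
    SpanningTree,
    TreeFactorization,
    ValidationError,
    brute_force_marginals,
    ensemble_marginals,
    factorize,
    map_assignment,
    max_product_marginals,
    sample_spanning_tree,
    sum_product_marginals,
)
from msrtrank.potentials import normalize_dataset


def _single_node_factors(pots):
    return TreeFactorization(
        feature_ids=("f0",),
        candidate_ids={"f0": [f"c{i}" for i in range(len(pots))]},
        log_node={"f0": np.log(np.asarray(pots, dtype=float))},
        log_edge={},
    )


def test_single_node_sum_marginals_normalize_node_potential():
    t = SpanningTree(("f0",), ())
    out = sum_product_marginals(t, _single_node_factors([0.8, 0.2]))
    np.testing.assert_allclose(out.marginals["f0"], [0.8, 0.2], atol=1e-12)


def test_single_node_max_marginals_divide_by_max():
    t = SpanningTree(("f0",), ())
    out = max_product_marginals(t, _single_node_factors([0.8, 0.2]))
    np.testing.assert_allclose(out.marginals["f0"], [1.0, 0.25], atol=1e-12)


def test_constant_edge_factor_cancels():
    """Two nodes, all edge entries equal: marginals = normalized node potentials."""
    factors = TreeFactorization(
        feature_ids=("f0", "f1"),
        candidate_ids={"f0": ["a", "b"], "f1": ["c", "d", "e"]},
        log_node={
            "f0": np.log([0.6, 0.3]),
            "f1": np.log([0.2, 0.5, 0.3]),
        },
        log_edge={("f0", "f1"): np.full((2, 3), np.log(0.7))},
    )
    t = SpanningTree(("f0", "f1"), (("f0", "f1"),))
    out = sum_product_marginals(t, factors)
    np.testing.assert_allclose(out.marginals["f0"], [2 / 3, 1 / 3], atol=1e-12)
    np.testing.assert_allclose(out.marginals["f1"], [0.2, 0.5, 0.3], atol=1e-12)


def test_brute_force_matches_hand_expanded_two_by_two():
    """2 features x 2 candidates: marginals from the explicit 4-term expansion."""
    node0, node1 = [0.8, 0.4], [0.5, 0.25]
    edge = [[0.9, 0.2], [0.3, 0.7]]
    factors = TreeFactorization(
        feature_ids=("f0", "f1"),
        candidate_ids={"f0": ["a", "b"], "f1": ["c", "d"]},
        log_node={"f0": np.log(node0), "f1": np.log(node1)},
        log_edge={("f0", "f1"): np.log(edge)},
    )
    weights = {
        (r, s): node0[r] * node1[s] * edge[r][s] for r in (0, 1) for s in (0, 1)
    }
    z = sum(weights.values())
    t = SpanningTree(("f0", "f1"), (("f0", "f1"),))
    out = brute_force_marginals(t, factors, kind="sum")
    np.testing.assert_allclose(
        out.marginals["f0"],
        [(weights[0, 0] + weights[0, 1]) / z, (weights[1, 0] + weights[1, 1]) / z],
        atol=1e-12,
    )
    np.testing.assert_allclose(
        out.marginals["f1"],
        [(weights[0, 0] + weights[1, 0]) / z, (weights[0, 1] + weights[1, 1]) / z],
        atol=1e-12,
    )
    m = brute_force_marginals(t, factors, kind="max").marginals["f0"]
    best = max(weights.values())
    np.testing.assert_allclose(
        m,
        [
            max(weights[0, 0], weights[0, 1]) / best,
            max(weights[1, 0], weights[1, 1]) / best,
        ],
        atol=1e-12,
    )


def test_brute_force_refuses_oversized_inputs(rng):
    factors, graph = random_factorization(rng, 4, 4)
    with pytest.raises(ValidationError):
        brute_force_marginals(graph, factors, kind="sum", cap=2)


@pytest.mark.parametrize("kind", ["sum", "max"])
def test_message_passing_matches_linear_space_oracle(kind, rng):
    """Log-space message passing equals an independent linear-space enumerator."""
    for trial in range(30):
        n = int(rng.integers(2, 6))
        factors, graph = random_factorization(rng, n, 4)
        tree = sample_spanning_tree(graph, int(rng.integers(0, 2**31)))
        infer = sum_product_marginals if kind == "sum" else max_product_marginals
        got = infer(tree, factors)
        expected = linear_space_marginals(tree.edges, factors, kind)
        for fid in factors.feature_ids:
            np.testing.assert_allclose(
                got.marginals[fid], expected[fid], atol=1e-9
            )


def test_brute_force_agrees_with_message_passing_on_trees(rng):
    for trial in range(10):
        factors, graph = random_factorization(rng, 5, 3)
        tree = sample_spanning_tree(graph, trial)
        sp = sum_product_marginals(tree, factors)
        bf = brute_force_marginals(tree, factors, kind="sum")
        for fid in factors.feature_ids:
            np.testing.assert_allclose(
                sp.marginals[fid], bf.marginals[fid], atol=1e-12
            )


def test_root_invariance(rng):
    factors, graph = random_factorization(rng, 5, 4)
    tree = sample_spanning_tree(graph, 3)
    for kind, infer in (("sum", sum_product_marginals), ("max", max_product_marginals)):
        ref = infer(tree, factors)
        for root in factors.feature_ids:
            out = infer(tree, factors, root=root)
            for fid in factors.feature_ids:
                np.testing.assert_allclose(
                    out.marginals[fid], ref.marginals[fid], atol=1e-9
                )


def test_map_single_node_and_tie_rule():
    t = SpanningTree(("f0",), ())
    assert map_assignment(t, _single_node_factors([0.8, 0.2]))["f0"] == 0
    # exact tie: lowest candidate index wins
    assert map_assignment(t, _single_node_factors([0.5, 0.5]))["f0"] == 0


def test_map_matches_brute_force_argmax(rng):
    for trial in range(15):
        factors, graph = random_factorization(rng, 4, 3)
        tree = sample_spanning_tree(graph, 100 + trial)
        got = map_assignment(tree, factors)
        # exhaustive argmax with lexicographic tie-break
        import itertools

        fids = list(factors.feature_ids)
        best, best_z = -np.inf, None
        for z in itertools.product(
            *[range(factors.n_candidates(f)) for f in fids]
        ):
            lp = sum(factors.log_node[f][z[i]] for i, f in enumerate(fids))
            for a, b in tree.edges:
                lp += factors.log_edge[(a, b)][
                    z[fids.index(a)], z[fids.index(b)]
                ]
            if lp > best + 1e-12:
                best, best_z = lp, z
        assert tuple(got[f] for f in fids) == best_z


def test_message_count_is_twice_edges(rng):
    factors, graph = random_factorization(rng, 6, 3)
    tree = sample_spanning_tree(graph, 0)
    for infer in (sum_product_marginals, max_product_marginals):
        stats = InferenceStats()
        infer(tree, factors, stats=stats)
        assert stats.n_messages == 2 * (len(factors.feature_ids) - 1)


def test_ensemble_average_of_identical_trees_is_single_tree(rng):
    ds = make_dataset(
        [1.0, 2.0, 3.0],
        [[0.1, 0.9], [0.4, 0.2], [0.5, 0.6]],
        [[1.0, 0.5], [0.2, 1.0], [1.0, 1.0]],
    )
    scored, c = normalize_dataset(ds)
    config = PotentialConfig(floor_c=c, D=0.5)
    tree = SpanningTree(("f0", "f1", "f2"), (("f0", "f1"), ("f1", "f2")))
    factors = factorize(scored, tree.edges, config)
    single = sum_product_marginals(tree, factors)
    avg = ensemble_marginals(scored, [tree] * 4, config, kind="sum")
    for fid in single.marginals:
        np.testing.assert_allclose(
            avg.marginals[fid], single.marginals[fid], atol=1e-12
        )


def test_ensemble_average_is_elementwise_mean(rng):
    ds = make_dataset(
        [1.0, 2.0, 3.0],
        [[0.1, 0.9], [0.4, 0.2], [0.5, 0.6]],
        [[1.0, 0.5], [0.2, 1.0], [1.0, 0.3]],
    )
    scored, c = normalize_dataset(ds)
    config = PotentialConfig(floor_c=c, D=0.5)
    t1 = SpanningTree(("f0", "f1", "f2"), (("f0", "f1"), ("f1", "f2")))
    t2 = SpanningTree(("f0", "f1", "f2"), (("f0", "f1"), ("f0", "f2")))
    m1 = sum_product_marginals(t1, factorize(scored, t1.edges, config))
    m2 = sum_product_marginals(t2, factorize(scored, t2.edges, config))
    avg = ensemble_marginals(scored, [t1, t2], config, kind="sum")
    for fid in avg.marginals:
        np.testing.assert_allclose(
            avg.marginals[fid],
            (m1.marginals[fid] + m2.marginals[fid]) / 2,
            atol=1e-12,
        )
    with pytest.raises(ValidationError):
        ensemble_marginals(scored, [], config, kind="sum")


def test_ensemble_result_independent_of_parallelism(rng):
    ds = make_dataset(
        [1.0, 2.0, 3.0, 4.0],
        [[0.1, 0.9], [0.4, 0.2], [0.5, 0.6], [0.0, 0.3]],
        [[1.0, 0.5], [0.2, 1.0], [1.0, 0.3], [0.7, 0.1]],
    )
    scored, c = normalize_dataset(ds)
    config = PotentialConfig(floor_c=c, D=0.5)
    from msrtrank import build_feature_graph, sample_tree_ensemble

    trees = sample_tree_ensemble(build_feature_graph(scored), 6, 11)
    serial = ensemble_marginals(scored, trees, config, kind="max", n_jobs=1)
    par = ensemble_marginals(scored, trees, config, kind="max", n_jobs=2)
    for fid in serial.marginals:
        np.testing.assert_allclose(par.marginals[fid], serial.marginals[fid])
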