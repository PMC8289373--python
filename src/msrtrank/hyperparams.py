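"""Hyper-parameter selection: the retention-order weight D and sigmoid scale k.

D is selected on a training split by running the full pipeline over a grid
of D values (reusing one tree ensemble so the comparison isolates D) and
keeping the value with the highest top20AUC.  The sigmoid scale k is
calibrated from labelled order pairs by Platt-style maximum likelihood: the
probability that a pair's observed elution order matches the prediction is
modelled as sigma(k x) with x the oriented preference-value difference; the
intercept is fixed at zero since a zero difference should map to 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .data_model import Dataset, PotentialConfig, ValidationError
from .evaluation import rank_candidates, top20auc
from .graphs import build_feature_graph, chain_tree, sample_tree_ensemble
from .inference import ensemble_marginals
from .potentials import normalize_dataset

__all__ = [
    "OrderedPairSample",
    "fit_platt_k",
    "order_pair_samples",
    "select_D",
]

K_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class OrderedPairSample:
    """One calibration pair for the sigmoid scale.

    ``x`` is the preference-value difference oriented so that positive means
    the predicted order agrees with the observed RT order; ``y`` is 1 when
    the observed order holds, 0 when it is reversed.
    """

    x: float
    y: int


def fit_platt_k(samples: Sequence[OrderedPairSample]) -> float:
    """Maximum-likelihood sigmoid scale k for P(y=1 | x) = 1/(1+exp(-k x)).

    One-dimensional bounded optimization over log k; the result is clipped
    to [1e-3, 1e3].  Raises when only one label class is present (k is then
    unidentifiable — the likelihood is monotone in k).
    """
    x = np.array([s.x for s in samples], dtype=float)
    y = np.array([s.y for s in samples], dtype=int)
    if len(x) == 0 or y.min() == y.max():
        raise ValidationError(
            "fit_platt_k needs samples from both label classes"
        )
    sgn = np.where(y == 1, 1.0, -1.0)

    def nll(log_k: float) -> float:
        k = np.exp(log_k)
        # -log sigma(k*x) for y=1, -log sigma(-k*x) for y=0
        return float(np.logaddexp(0.0, -k * sgn * x).sum())

    res = minimize_scalar(
        nll, bounds=(np.log(K_BOUNDS[0]), np.log(K_BOUNDS[1])), method="bounded"
    )
    return float(np.clip(np.exp(res.x), *K_BOUNDS))


def order_pair_samples(dataset: Dataset) -> List[OrderedPairSample]:
    """Calibration pairs from a ground-truth dataset.

    For every feature pair with distinct RTs, take the correct candidates'
    preference-value difference oriented by the observed order.  All labels
    are 1 by construction when the predictor is perfect; disagreements give
    negative x, so a symmetric 0-labelled mirror pair is added to keep the
    likelihood identifiable (sigma(k x) with zero intercept is antisymmetric,
    so mirroring does not bias k).
    """
    if not dataset.has_ground_truth():
        raise ValidationError("ground truth required to build order pairs")
    feats = list(dataset.features)
    prefs = {}
    for f, cs in zip(dataset.features, dataset.candidate_sets):
        prefs[f.feature_id] = cs.candidates[cs.correct_index].preference_value
    samples: List[OrderedPairSample] = []
    for i, fi in enumerate(feats):
        for fj in feats[i + 1 :]:
            if fi.retention_time == fj.retention_time:
                continue
            later, earlier = (
                (fi, fj) if fi.retention_time > fj.retention_time else (fj, fi)
            )
            x = prefs[later.feature_id] - prefs[earlier.feature_id]
            samples.append(OrderedPairSample(x=float(x), y=1))
            samples.append(OrderedPairSample(x=float(-x), y=0))
    return samples


def select_D(
    train_dataset: Dataset,
    D_grid: Sequence[float],
    config_template: PotentialConfig,
    L: int,
    seed: int,
    marginal_kind: str = "max",
    tree_kind: str = "ensemble",
    ppm: float = 5.0,
    n_jobs: int = 1,
) -> float:
    """Retention-order weight with the highest training top20AUC.

    The same tree ensemble (same seed) is reused for every grid value so
    that the comparison isolates D.  Ties break towards the smallest D; the
    result is invariant to grid order.
    """
    grid = sorted(set(float(d) for d in D_grid))
    if not grid:
        raise ValidationError("D grid must be non-empty")
    if not train_dataset.has_ground_truth():
        raise ValidationError("select_D requires ground truth on the training set")
    scored, c = normalize_dataset(train_dataset, ppm=ppm)
    if tree_kind == "chain":
        trees = [chain_tree(scored)]
    else:
        trees = sample_tree_ensemble(build_feature_graph(scored), L, seed)
    best_D, best_auc = grid[0], -np.inf
    for D in grid:
        config = replace(config_template, D=D, floor_c=c)
        table = ensemble_marginals(
            scored, trees, config, kind=marginal_kind, n_jobs=n_jobs
        )
        auc = top20auc(rank_candidates(table, scored))
        if auc > best_auc:
            best_D, best_auc = D, auc
    return best_D
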