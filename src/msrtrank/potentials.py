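"""Node and edge potential functions.

The joint model over candidate assignments z = (z_1, ..., z_N) is a pairwise
Markov random field

    p(z) ∝ prod_i psi_i(z_i)^(1-D) * prod_(i,j) psi_ij(z_i, z_j)^D

with node potentials psi_i(z_i=r) = max(theta_ir, c) scoring how well
candidate r matches the observed spectrum, and edge potentials

    psi_ij(z_i=r, z_j=s) = sigma(sign(t_i - t_j) * (w_ir - w_js))

scoring the agreement between the observed retention-time order of features
i, j and the predicted retention order of their candidates (w_* are scalar
preference values).  D in [0, 1] trades off the two information sources.

Everything is mirrored in log-space: with the step map's epsilon = 1e-10
raised to D and multiplied across dozens of edges, linear-space products
underflow, so inference consumes only the ``log_*`` accessors.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .data_model import (
    CandidateSet,
    Dataset,
    MSFeature,
    PotentialConfig,
    ValidationError,
)

__all__ = [
    "normalize_scores",
    "compute_floor_constant",
    "node_potential",
    "weighted_node_potential",
    "sigma_map",
    "log_sigma_map",
    "edge_potential_matrix",
    "log_edge_potential_matrix",
    "log_node_potential_vector",
    "ms1_gaussian_scores",
]


def normalize_scores(candidate_set: CandidateSet) -> CandidateSet:
    """Normalize raw scores to [0, 1] by dividing by the set maximum.

    The best candidate receives exactly 1.  If every raw score is zero the
    normalized scores are all zero (the node-potential floor ``c`` then
    applies uniformly).
    """
    raw = np.asarray([c.raw_score for c in candidate_set.candidates], dtype=float)
    if np.any(raw < 0):
        raise ValidationError(
            f"feature {candidate_set.feature_id!r}: negative raw score"
        )
    top = raw.max()
    norm = raw / top if top > 0 else np.zeros_like(raw)
    return CandidateSet(
        candidate_set.feature_id,
        [
            replace(c, normalized_score=float(s))
            for c, s in zip(candidate_set.candidates, norm)
        ],
    )


def compute_floor_constant(dataset: Dataset) -> float:
    """Floor constant c: one tenth of the smallest non-zero normalized score
    across all candidate sets of the dataset."""
    nonzero = [
        c.normalized_score
        for cs in dataset.candidate_sets
        for c in cs.candidates
        if c.normalized_score is not None and c.normalized_score > 0
    ]
    if not nonzero:
        raise ValidationError(
            "every normalized score is zero; set floor_c explicitly"
        )
    return min(nonzero) / 10.0


def node_potential(theta: float, c: float) -> float:
    """psi_i(z_i=r) = max(theta_ir, c); strictly positive for c > 0."""
    return max(theta, c)


def weighted_node_potential(theta: float, c: float, D: float) -> float:
    """max(theta, c)^(1-D): the node potential after information weighting.

    At D=1 the node side contributes nothing (returns 1 for every theta).
    """
    return node_potential(theta, c) ** (1.0 - D)


def sigma_map(x, config: PotentialConfig):
    """Monotone map from preference-value difference to (0, 1].

    sigmoid        : 1 / (1 + exp(-k x))
    step           : epsilon if x < 0 else 1
    hinge_sigmoid  : min(2 / (1 + exp(-k x)), 1)
    """
    return np.exp(log_sigma_map(x, config))


def log_sigma_map(x, config: PotentialConfig):
    """log of :func:`sigma_map`, computed stably (no overflow for large |x|)."""
    x = np.asarray(x, dtype=float)
    if config.sigma_kind == "sigmoid":
        out = -np.logaddexp(0.0, -config.k * x)
    elif config.sigma_kind == "step":
        out = np.where(x < 0, np.log(config.epsilon), 0.0)
    elif config.sigma_kind == "hinge_sigmoid":
        out = np.minimum(np.log(2.0) - np.logaddexp(0.0, -config.k * x), 0.0)
    else:  # pragma: no cover - PotentialConfig already rejects this
        raise ValidationError(f"unknown sigma_kind {config.sigma_kind!r}")
    return out if out.ndim else float(out)


def log_edge_potential_matrix(
    fi: MSFeature,
    fj: MSFeature,
    Ci: CandidateSet,
    Cj: CandidateSet,
    config: PotentialConfig,
    weighted: bool = True,
) -> np.ndarray:
    """n_i x n_j matrix of log psi_ij(z_i=r, z_j=s), D-weighted by default.

    Entry (r, s) = D * log sigma(sign(t_i - t_j) * (w_ir - w_js)).  The
    matrix for the reversed pair (j, i) is exactly the transpose, since both
    orientations evaluate sigma at the same scalar.
    """
    if fi.retention_time == fj.retention_time:
        raise ValidationError(
            f"features {fi.feature_id!r} and {fj.feature_id!r} share a "
            "retention time; equal-RT edges must not be constructed"
        )
    sign = 1.0 if fi.retention_time > fj.retention_time else -1.0
    diff = Ci.preference_values()[:, None] - Cj.preference_values()[None, :]
    logm = log_sigma_map(sign * diff, config)
    return config.D * logm if weighted else logm


def edge_potential_matrix(
    fi: MSFeature,
    fj: MSFeature,
    Ci: CandidateSet,
    Cj: CandidateSet,
    config: PotentialConfig,
) -> np.ndarray:
    """Linear-space, D-weighted edge potential matrix (strictly positive)."""
    return np.exp(log_edge_potential_matrix(fi, fj, Ci, Cj, config))


def log_node_potential_vector(
    candidate_set: CandidateSet, config: PotentialConfig
) -> np.ndarray:
    """Vector of (1-D) * log max(theta_ir, c) over the set's candidates."""
    theta = candidate_set.normalized_scores()
    return (1.0 - config.D) * np.log(np.maximum(theta, config.floor_c))


def ms1_gaussian_scores(
    feature: MSFeature, candidate_set: CandidateSet, ppm: float = 5.0
) -> CandidateSet:
    """Candidate scores for features without an MS² spectrum.

    Each candidate is scored by the Gaussian density of its mass deviation
    from the measured neutral mass, self-normalized by the best candidate:

        theta_ir = N(m_i - m_ir | 0, sigma) / max_s N(m_i - m_is | 0, sigma)

    with sigma = ppm * m_i / (2 * 10^6), i.e. the instrument's ppm accuracy
    interpreted as a +/-2-sigma window.  Scores land in (0, 1] with the
    closest-mass candidate at exactly 1.  Both raw and normalized scores are
    set, so a later :func:`normalize_scores` pass is a no-op.
    """
    if ppm <= 0:
        raise ValidationError("ppm must be > 0")
    sigma = ppm * feature.precursor_mass / 2e6
    dev = np.asarray(
        [feature.precursor_mass - c.exact_mass for c in candidate_set.candidates]
    )
    logd = -(dev**2) / (2.0 * sigma**2)
    scores = np.exp(logd - logd.max())
    return CandidateSet(
        candidate_set.feature_id,
        [
            replace(c, raw_score=float(s), normalized_score=float(s))
            for c, s in zip(candidate_set.candidates, scores)
        ],
    )


def normalize_dataset(
    dataset: Dataset, ppm: float = 5.0, floor_c: Optional[float] = None
) -> tuple[Dataset, float]:
    """Score every candidate set and determine the floor constant.

    MS² features get max-division normalization of their raw scores; features
    without MS² get the self-normalized MS¹ Gaussian mass score.  Returns the
    re-scored dataset and the floor c (computed from the data unless
    ``floor_c`` overrides it).
    """
    sets = []
    for feat, cs in zip(dataset.features, dataset.candidate_sets):
        if feat.has_ms2:
            sets.append(normalize_scores(cs))
        else:
            sets.append(ms1_gaussian_scores(feat, cs, ppm=ppm))
    scored = dataset.with_candidate_sets(sets)
    c = floor_c if floor_c is not None else compute_floor_constant(scored)
    if c <= 0:
        raise ValidationError("floor_c must be > 0")
    return scored, c


__all__.append("normalize_dataset")
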