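"""Candidate ranking and identification-accuracy metrics.

Candidates are ranked per feature by decreasing marginal probability with
tie-aware mid-ranks: rank(r) = #{strictly greater} + (#{equal} + 1) / 2,
the expected rank under a uniformly random shuffle of tied candidates.
Identification performance is summarized by top-k accuracy (fraction of
features whose correct candidate has rank <= k) and by top20AUC, the mean
of the top-k accuracies for k = 1..20 — the model-selection metric used to
pick the retention-order weight D.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np

from .data_model import CandidateSet, Dataset, MarginalTable, ValidationError

__all__ = [
    "RankingResult",
    "tie_aware_ranks",
    "collapse_stereoisomers",
    "rank_candidates",
    "top_k_accuracy",
    "top20auc",
]

# relative tolerance for treating two marginals as tied; exact float equality
# would miss ties produced by different but mathematically equal schedules
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class RankingResult:
    """Per-feature candidate ordering plus the rank of the correct candidate.

    ``ranks[fid]`` holds a tie-aware rank per candidate (aligned with the
    marginal table's candidate order); ``rank_of_correct[fid]`` is absent for
    features without ground truth.
    """

    ranks: Dict[str, np.ndarray]
    candidate_ids: Dict[str, list]
    rank_of_correct: Dict[str, float]

    @property
    def n_features(self) -> int:
        return len(self.ranks)


def tie_aware_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks on descending value: rank = #greater + (#equal + 1)/2."""
    v = np.asarray(values, dtype=float)
    scale = max(np.abs(v).max(), 1.0)
    greater = (v[None, :] > v[:, None] + _TIE_RTOL * scale).sum(axis=1)
    equal = (np.abs(v[None, :] - v[:, None]) <= _TIE_RTOL * scale).sum(axis=1)
    return greater + (equal + 1) / 2.0


def collapse_stereoisomers(candidate_set: CandidateSet) -> CandidateSet:
    """Retain one candidate per stereo_group: the one with highest MS score.

    Ties break towards the lowest candidate_id.  If any member of a group is
    flagged correct, the retained representative inherits the flag (the
    stereo-free structure counts as identified).  Requires stereo_group on
    every candidate.
    """
    if any(c.stereo_group is None for c in candidate_set.candidates):
        raise ValidationError(
            f"feature {candidate_set.feature_id!r}: stereo_group missing; "
            "skip stereoisomer collapsing for this dataset"
        )
    groups: Dict[str, list] = {}
    for c in candidate_set.candidates:
        groups.setdefault(c.stereo_group, []).append(c)
    kept = []
    for members in groups.values():
        scores = [
            c.normalized_score if c.normalized_score is not None else c.raw_score
            for c in members
        ]
        best = min(
            range(len(members)),
            key=lambda i: (-scores[i], members[i].candidate_id),
        )
        rep = members[best]
        if any(c.is_correct for c in members) and not rep.is_correct:
            rep = replace(rep, is_correct=True)
        kept.append(rep)
    # preserve original candidate order among the retained representatives
    kept_ids = {c.candidate_id for c in kept}
    by_id = {c.candidate_id: c for c in kept}
    ordered = [
        by_id[c.candidate_id]
        for c in candidate_set.candidates
        if c.candidate_id in kept_ids
    ]
    return CandidateSet(candidate_set.feature_id, ordered)


def rank_candidates(
    marginals: MarginalTable, dataset: Optional[Dataset] = None
) -> RankingResult:
    """Rank every feature's candidates by decreasing marginal.

    When ``dataset`` carries is_correct flags, the tie-aware rank of each
    feature's correct candidate is recorded for the accuracy metrics.
    """
    ranks = {
        fid: tie_aware_ranks(np.asarray(p, dtype=float))
        for fid, p in marginals.marginals.items()
    }
    rank_of_correct: Dict[str, float] = {}
    if dataset is not None:
        for cs in dataset.candidate_sets:
            if cs.feature_id not in ranks:
                continue
            idx = cs.correct_index
            if idx is None:
                continue
            cid = cs.candidates[idx].candidate_id
            order = marginals.candidate_ids[cs.feature_id]
            rank_of_correct[cs.feature_id] = float(
                ranks[cs.feature_id][order.index(cid)]
            )
    return RankingResult(ranks, dict(marginals.candidate_ids), rank_of_correct)


def _require_ground_truth(rankings: RankingResult) -> None:
    if len(rankings.rank_of_correct) != len(rankings.ranks):
        raise ValidationError(
            "ground truth (is_correct) required for every feature"
        )


def top_k_accuracy(rankings: RankingResult, k: int) -> float:
    """Fraction of features whose correct candidate has rank <= k."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    _require_ground_truth(rankings)
    r = np.array(list(rankings.rank_of_correct.values()))
    return float(np.mean(r <= k))


def top20auc(rankings: RankingResult) -> float:
    """Area under the ranking curve up to rank 20.

    top20AUC = (1/20) * sum_{i=1..20} #top(i) / N, where #top(i) counts
    features with correct-candidate rank <= i.  Equals the mean of
    top_k_accuracy over k = 1..20.
    """
    _require_ground_truth(rankings)
    r = np.array(list(rankings.rank_of_correct.values()))
    return float(np.mean([(r <= i).mean() for i in range(1, 21)]))
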