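"""Core data types and delimited-text I/O.

An LC-MS experiment is represented as a :class:`Dataset`: a list of observed
:class:`MSFeature` objects (retention time, neutral precursor mass, MS²
availability) together with one :class:`CandidateSet` per feature holding the
molecular structure hypotheses and their scores.  Inference results are
carried in a :class:`MarginalTable`.

All files are tab-separated UTF-8 with a mandatory header row.  Schemas:

``features.tsv``
    feature_id, retention_time, precursor_mass, has_ms2

``candidates.tsv``
    feature_id, candidate_id, raw_score, exact_mass, preference_value,
    [stereo_group], [is_correct]

``marginals.tsv``
    feature_id, candidate_id, marginal, rank, marginal_kind

Retention-time units are the caller's responsibility: only the sign of
pairwise differences is ever used, so any consistent unit works.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MSFeature",
    "Candidate",
    "CandidateSet",
    "Dataset",
    "PotentialConfig",
    "MarginalTable",
    "ValidationError",
    "MissingColumnError",
    "DuplicateFeatureError",
    "UnknownFeatureError",
    "EmptyCandidateSetError",
    "read_dataset",
    "write_dataset",
    "write_marginals",
    "read_marginals",
]

SIGMA_KINDS = ("sigmoid", "step", "hinge_sigmoid")


class ValidationError(ValueError):
    """Base class for all dataset validation failures."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input file."""


class DuplicateFeatureError(ValidationError):
    """The same feature_id appears more than once in the feature table."""


class UnknownFeatureError(ValidationError):
    """A candidate row references a feature_id not present in the feature table."""


class EmptyCandidateSetError(ValidationError):
    """A feature has no candidate rows (every feature needs n_i >= 1)."""


@dataclass(frozen=True)
class MSFeature:
    """One observed LC-MS feature.

    Parameters
    ----------
    feature_id : str
        Opaque unique key.
    retention_time : float
        Observed retention time, any consistent unit; must be >= 0.
    precursor_mass : float
        Neutral exact mass of the measured ion (Da); must be > 0.
    has_ms2 : bool
        Whether an MS² spectrum (and hence an MS²-based score) is available.
    """

    feature_id: str
    retention_time: float
    precursor_mass: float
    has_ms2: bool = True

    def __post_init__(self) -> None:
        if self.retention_time < 0:
            raise ValidationError(
                f"feature {self.feature_id!r}: retention_time must be >= 0"
            )
        if self.precursor_mass <= 0:
            raise ValidationError(
                f"feature {self.feature_id!r}: precursor_mass must be > 0"
            )


@dataclass(frozen=True)
class Candidate:
    """One molecular structure hypothesis for an MS feature.

    ``raw_score`` is the scorer output before normalization; the per-set
    normalized score theta in [0, 1] is filled in by
    :func:`msrtrank.potentials.normalize_scores`.  ``preference_value`` is the
    scalar retention-order preference (e.g. a RankSVM decision value) whose
    pairwise differences predict elution order.
    """

    candidate_id: str
    raw_score: float
    exact_mass: float
    preference_value: float
    normalized_score: Optional[float] = None
    stereo_group: Optional[str] = None
    is_correct: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValidationError(
                f"candidate {self.candidate_id!r}: raw_score must be >= 0"
            )
        if self.exact_mass <= 0:
            raise ValidationError(
                f"candidate {self.candidate_id!r}: exact_mass must be > 0"
            )
        if self.normalized_score is not None and not (
            0.0 <= self.normalized_score <= 1.0
        ):
            raise ValidationError(
                f"candidate {self.candidate_id!r}: normalized_score outside [0, 1]"
            )


@dataclass(frozen=True)
class CandidateSet:
    """The ordered, non-empty candidate list of one feature."""

    feature_id: str
    candidates: tuple

    def __init__(self, feature_id: str, candidates: Sequence[Candidate]):
        candidates = tuple(candidates)
        if len(candidates) == 0:
            raise EmptyCandidateSetError(
                f"feature {feature_id!r} has an empty candidate set"
            )
        ids = [c.candidate_id for c in candidates]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"feature {feature_id!r}: duplicate candidate ids"
            )
        if sum(1 for c in candidates if c.is_correct) > 1:
            raise ValidationError(
                f"feature {feature_id!r}: more than one candidate flagged correct"
            )
        object.__setattr__(self, "feature_id", feature_id)
        object.__setattr__(self, "candidates", candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def correct_index(self) -> Optional[int]:
        for idx, c in enumerate(self.candidates):
            if c.is_correct:
                return idx
        return None

    def normalized_scores(self) -> np.ndarray:
        vals = [c.normalized_score for c in self.candidates]
        if any(v is None for v in vals):
            raise ValidationError(
                f"feature {self.feature_id!r}: normalized scores not set; "
                "run normalize_scores or ms1_gaussian_scores first"
            )
        return np.asarray(vals, dtype=float)

    def preference_values(self) -> np.ndarray:
        return np.asarray(
            [c.preference_value for c in self.candidates], dtype=float
        )


@dataclass(frozen=True)
class Dataset:
    """Features plus one candidate set per feature (a bijection)."""

    features: tuple
    candidate_sets: tuple

    def __init__(
        self, features: Sequence[MSFeature], candidate_sets: Sequence[CandidateSet]
    ):
        features = tuple(features)
        candidate_sets = tuple(candidate_sets)
        if len(features) == 0:
            raise ValidationError("dataset must contain at least one feature")
        fids = [f.feature_id for f in features]
        if len(set(fids)) != len(fids):
            dups = sorted({x for x in fids if fids.count(x) > 1})
            raise DuplicateFeatureError(f"duplicate feature ids: {dups}")
        by_fid = {cs.feature_id: cs for cs in candidate_sets}
        unknown = sorted(set(by_fid) - set(fids))
        if unknown:
            raise UnknownFeatureError(
                f"candidate sets reference unknown features: {unknown}"
            )
        missing = sorted(set(fids) - set(by_fid))
        if missing:
            raise EmptyCandidateSetError(
                f"features without candidates: {missing}"
            )
        # store candidate sets in feature order
        object.__setattr__(self, "features", features)
        object.__setattr__(
            self, "candidate_sets", tuple(by_fid[fid] for fid in fids)
        )

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> List[str]:
        return [f.feature_id for f in self.features]

    def feature(self, feature_id: str) -> MSFeature:
        return next(f for f in self.features if f.feature_id == feature_id)

    def candidate_set(self, feature_id: str) -> CandidateSet:
        return next(
            cs for cs in self.candidate_sets if cs.feature_id == feature_id
        )

    def has_ground_truth(self) -> bool:
        return all(cs.correct_index is not None for cs in self.candidate_sets)

    def with_candidate_sets(self, candidate_sets: Sequence[CandidateSet]) -> "Dataset":
        return Dataset(self.features, candidate_sets)


@dataclass(frozen=True)
class PotentialConfig:
    """Hyper-parameters of the node and edge potential functions.

    Attributes
    ----------
    floor_c : float
        Strictly positive floor applied to normalized MS scores so node
        potentials never vanish.
    sigma_kind : str
        Map from preference-value difference to edge potential:
        ``sigmoid`` 1/(1+e^{-kx}); ``step`` (epsilon below 0, 1 at/above 0);
        ``hinge_sigmoid`` min(2/(1+e^{-kx}), 1).
    k : float
        Sigmoid scale (slope); > 0.
    epsilon : float
        Step-function floor; > 0.
    D : float
        Retention-order weight in [0, 1]: node potentials are raised to
        (1-D), edge potentials to D.
    """

    floor_c: float = 1e-3
    sigma_kind: str = "sigmoid"
    k: float = 1.0
    epsilon: float = 1e-10
    D: float = 0.5

    def __post_init__(self) -> None:
        if self.floor_c <= 0:
            raise ValidationError("floor_c must be > 0")
        if self.k <= 0:
            raise ValidationError("k must be > 0")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if not (0.0 <= self.D <= 1.0):
            raise ValidationError("D must be in [0, 1]")
        if self.sigma_kind not in SIGMA_KINDS:
            raise ValidationError(
                f"unknown sigma_kind {self.sigma_kind!r}; expected one of {SIGMA_KINDS}"
            )


@dataclass
class MarginalTable:
    """Per-feature, per-candidate (averaged) marginal probabilities.

    ``marginals[fid]`` is a probability vector aligned with the candidate
    order of feature ``fid``; ``candidate_ids[fid]`` records that order.
    ``marginal_kind`` is ``"sum"`` or ``"max"``; ``provenance`` is
    ``"single-tree"`` or ``"ensemble-average"``.
    """

    marginals: Dict[str, np.ndarray]
    candidate_ids: Dict[str, List[str]]
    marginal_kind: str = "sum"
    provenance: str = "single-tree"

    def validate(self, atol: float = 1e-9) -> None:
        if self.marginal_kind not in ("sum", "max"):
            raise ValidationError(f"bad marginal_kind {self.marginal_kind!r}")
        for fid, p in self.marginals.items():
            p = np.asarray(p, dtype=float)
            if np.any(p < -atol) or np.any(p > 1 + atol):
                raise ValidationError(f"feature {fid!r}: marginal outside [0, 1]")
            if self.marginal_kind == "sum" and abs(p.sum() - 1.0) > atol:
                raise ValidationError(
                    f"feature {fid!r}: sum-marginals sum to {p.sum()}, not 1"
                )
            if (
                self.marginal_kind == "max"
                and self.provenance == "single-tree"
                and abs(p.max() - 1.0) > atol
            ):
                raise ValidationError(
                    f"feature {fid!r}: single-tree max-marginal max is {p.max()}, not 1"
                )
            if len(p) != len(self.candidate_ids[fid]):
                raise ValidationError(f"feature {fid!r}: length mismatch")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ["feature_id", "retention_time", "precursor_mass", "has_ms2"]
_CANDIDATE_COLUMNS = [
    "feature_id",
    "candidate_id",
    "raw_score",
    "exact_mass",
    "preference_value",
]
_OPTIONAL_CANDIDATE_COLUMNS = ["stereo_group", "is_correct"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")


def read_dataset(features_path, candidates_path) -> Dataset:
    """Read and validate a dataset from ``features.tsv`` + ``candidates.tsv``.

    Raises
    ------
    MissingColumnError, DuplicateFeatureError, UnknownFeatureError,
    EmptyCandidateSetError
        On the corresponding schema or referential-integrity violation.
    """
    fdf = pd.read_csv(
        features_path, sep="\t", dtype={"feature_id": str},
        float_precision="round_trip",
    )
    _require_columns(fdf, _FEATURE_COLUMNS, features_path)
    cdf = pd.read_csv(
        candidates_path, sep="\t", dtype={"feature_id": str, "candidate_id": str},
        float_precision="round_trip",
    )
    _require_columns(cdf, _CANDIDATE_COLUMNS, candidates_path)

    features = [
        MSFeature(
            feature_id=row.feature_id,
            retention_time=float(row.retention_time),
            precursor_mass=float(row.precursor_mass),
            has_ms2=_parse_bool(row.has_ms2),
        )
        for row in fdf.itertuples()
    ]
    fids = [f.feature_id for f in features]
    if len(set(fids)) != len(fids):
        dups = sorted({x for x in fids if fids.count(x) > 1})
        raise DuplicateFeatureError(f"{features_path}: duplicate feature ids {dups}")

    has_stereo = "stereo_group" in cdf.columns
    has_correct = "is_correct" in cdf.columns
    sets: Dict[str, List[Candidate]] = {}
    for row in cdf.itertuples():
        if row.feature_id not in set(fids):
            raise UnknownFeatureError(
                f"{candidates_path}: candidate {row.candidate_id!r} references "
                f"unknown feature {row.feature_id!r}"
            )
        stereo = None
        if has_stereo and not pd.isna(row.stereo_group):
            stereo = str(row.stereo_group)
        correct = None
        if has_correct and not pd.isna(row.is_correct):
            correct = _parse_bool(row.is_correct)
        sets.setdefault(row.feature_id, []).append(
            Candidate(
                candidate_id=row.candidate_id,
                raw_score=float(row.raw_score),
                exact_mass=float(row.exact_mass),
                preference_value=float(row.preference_value),
                stereo_group=stereo,
                is_correct=correct,
            )
        )
    return Dataset(
        features, [CandidateSet(fid, cands) for fid, cands in sets.items()]
    )


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValidationError(f"cannot parse boolean value {v!r}")


def write_dataset(dataset: Dataset, features_path, candidates_path) -> None:
    """Write a dataset to the two-file TSV layout read by :func:`read_dataset`."""
    fdf = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in dataset.features],
            "retention_time": [repr(f.retention_time) for f in dataset.features],
            "precursor_mass": [repr(f.precursor_mass) for f in dataset.features],
            "has_ms2": [f.has_ms2 for f in dataset.features],
        }
    )
    fdf.to_csv(features_path, sep="\t", index=False)

    rows = []
    any_stereo = any(
        c.stereo_group is not None
        for cs in dataset.candidate_sets
        for c in cs.candidates
    )
    any_correct = any(
        c.is_correct is not None
        for cs in dataset.candidate_sets
        for c in cs.candidates
    )
    for cs in dataset.candidate_sets:
        for c in cs.candidates:
            row = {
                "feature_id": cs.feature_id,
                "candidate_id": c.candidate_id,
                "raw_score": repr(c.raw_score),
                "exact_mass": repr(c.exact_mass),
                "preference_value": repr(c.preference_value),
            }
            if any_stereo:
                row["stereo_group"] = c.stereo_group
            if any_correct:
                row["is_correct"] = c.is_correct
            rows.append(row)
    pd.DataFrame(rows).to_csv(candidates_path, sep="\t", index=False)


def write_marginals(table: MarginalTable, path) -> None:
    """Write a marginal table: one row per (feature, candidate, marginal, rank).

    Ranks are tie-aware mid-ranks on descending marginal.  Read-back with
    :func:`read_marginals` reproduces every probability to full precision
    (values are written with ``repr``).
    """
    from .evaluation import tie_aware_ranks  # local import avoids a cycle

    table.validate()
    rows = []
    for fid in table.marginals:
        p = np.asarray(table.marginals[fid], dtype=float)
        ranks = tie_aware_ranks(p)
        for cid, prob, rank in zip(table.candidate_ids[fid], p, ranks):
            rows.append(
                {
                    "feature_id": fid,
                    "candidate_id": cid,
                    "marginal": repr(float(prob)),
                    "rank": rank,
                    "marginal_kind": table.marginal_kind,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["feature_id", "candidate_id", "marginal", "rank", "marginal_kind"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_marginals(path) -> MarginalTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"feature_id": str, "candidate_id": str},
        float_precision="round_trip",
    )
    _require_columns(
        df, ["feature_id", "candidate_id", "marginal", "marginal_kind"], path
    )
    marginals: Dict[str, np.ndarray] = {}
    candidate_ids: Dict[str, List[str]] = {}
    kind = "sum" if df.empty else str(df["marginal_kind"].iloc[0])
    for fid, grp in df.groupby("feature_id", sort=False):
        marginals[fid] = grp["marginal"].to_numpy(dtype=float)
        candidate_ids[fid] = list(grp["candidate_id"])
    # round-tripped tables may be ensemble averages; skip single-tree checks
    return MarginalTable(marginals, candidate_ids, kind, provenance="ensemble-average")
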