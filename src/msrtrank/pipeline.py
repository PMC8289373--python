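"""End-to-end score integration: normalize, build graph, sample trees,
infer, average, rank, write.

``run_pipeline`` realizes the full workflow: MS²/MS¹ score normalization →
floor constant → eligible feature graph → spanning-tree ensemble (or RT
chain) → per-tree log-space inference → marginal averaging → ranked
marginals table.  Identical configuration and seed give identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

from .data_model import (
    Dataset,
    MarginalTable,
    PotentialConfig,
    read_dataset,
    write_marginals,
)
from .graphs import build_feature_graph, chain_tree, sample_tree_ensemble
from .inference import ensemble_marginals
from .potentials import normalize_dataset

__all__ = ["RunConfig", "run_pipeline", "integrate_scores"]

logger = logging.getLogger("msrtrank")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Defaults follow the method's standard operating point: an ensemble of
    L = 128 random spanning trees, max-marginals, sigmoid edge potentials.
    """

    features_path: Optional[str] = None
    candidates_path: Optional[str] = None
    output_path: Optional[str] = None
    potential: PotentialConfig = field(default_factory=PotentialConfig)
    floor_c: Optional[float] = None  # None: computed from the data
    ppm: float = 5.0
    L: int = 128
    marginal_kind: str = "max"
    tree_kind: str = "ensemble"
    seed: int = 0
    n_jobs: int = 1


def integrate_scores(dataset: Dataset, config: RunConfig) -> MarginalTable:
    """Run score integration on an in-memory dataset."""
    scored, c = normalize_dataset(
        dataset, ppm=config.ppm, floor_c=config.floor_c
    )
    pot = replace(config.potential, floor_c=c)
    n_cands = sorted(len(cs) for cs in scored.candidate_sets)
    logger.info(
        "N=%d features, median n_i=%g, L=%d, D=%g, c=%g, trees=%s, marginal=%s",
        len(scored),
        n_cands[len(n_cands) // 2],
        config.L,
        pot.D,
        c,
        config.tree_kind,
        config.marginal_kind,
    )
    if config.tree_kind == "chain":
        trees = [chain_tree(scored)]
    elif config.tree_kind == "ensemble":
        graph = build_feature_graph(scored)
        trees = sample_tree_ensemble(graph, config.L, config.seed)
    else:
        raise ValueError(f"unknown tree_kind {config.tree_kind!r}")
    logger.info("inferring marginals on %d tree(s)", len(trees))
    table = ensemble_marginals(
        scored,
        trees,
        pot,
        kind=config.marginal_kind,
        n_jobs=config.n_jobs,
    )
    table.validate()
    return table


def run_pipeline(config: RunConfig) -> MarginalTable:
    """File-to-file pipeline: read TSVs, integrate, write ranked marginals."""
    dataset = read_dataset(config.features_path, config.candidates_path)
    table = integrate_scores(dataset, config)
    if config.output_path is not None:
        write_marginals(table, config.output_path)
        logger.info("wrote %s", config.output_path)
    return table
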