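"""Synthetic LC-MS datasets with known ground truth.

The generator emulates the statistical structure the integration method
relies on, without simulating spectra or chromatography:

* each feature has a latent elution coordinate u_i ~ Uniform(0, 1); its RT
  is a monotone transform of u_i, so observed RT order equals the latent
  order and all RTs are distinct by construction;
* the correct candidate's retention preference value is u_i plus Gaussian
  noise with sd ``order_noise_sd``, decoys draw an independent latent
  coordinate plus the same noise — ``order_noise_sd`` therefore controls
  the pairwise order accuracy of the predictor (0 → perfect, large → 0.5;
  the default 0.1539 yields ~0.85);
* MS² raw scores: decoys are Beta(2, 5) draws; the correct candidate draws
  from a shifted Beta(2 + t, 5), with the shift t solved numerically so that
  the correct candidate holds the top raw score with probability exactly
  p = ``ms_informativeness``.  A shifted distribution (rather than a
  forced-top mixture) keeps non-top correct candidates close to the top,
  mirroring how real MS² scorers behave;
* features outside ``ms2_fraction`` carry only MS¹ information: their
  candidates are scored by the Gaussian mass-deviation score.  Decoy exact
  masses deviate uniformly within +/- ``mass_ppm_spread`` ppm of the true
  mass, and the measured precursor mass itself carries Gaussian error at
  ``mass_noise_ppm`` (so the correct candidate is not trivially on top);
* ``adversarial=True`` replaces the noise model with a worst-case decoy
  placement for the D=1 consistency regime: correct candidates are exactly
  order-consistent, and every decoy's preference value violates the observed
  order against every candidate of every later-eluting feature (the max-RT
  feature's decoys violate against everything earlier).  On the RT-ordered
  chain every assignment containing a decoy then has at least one
  order-violating edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List

import numpy as np
from scipy import integrate, optimize, stats

from .data_model import Candidate, CandidateSet, Dataset, MSFeature, ValidationError
from .potentials import ms1_gaussian_scores

__all__ = ["SimulationConfig", "generate_dataset", "measure_order_accuracy"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data generator (defaults = study conditions)."""

    n_features: int = 50
    n_candidates: int = 20
    ms_informativeness: float = 0.4
    order_noise_sd: float = 0.1539  # ~0.85 pairwise order accuracy
    mass_ppm_spread: float = 10.0
    mass_noise_ppm: float = 5.0
    ms2_fraction: float = 1.0
    scorer_ppm: float = 5.0
    adversarial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_candidates < 1:
            raise ValidationError("n_features and n_candidates must be >= 1")
        if not (0.0 <= self.ms_informativeness <= 1.0):
            raise ValidationError("ms_informativeness must be in [0, 1]")
        if self.order_noise_sd < 0:
            raise ValidationError("order_noise_sd must be >= 0")
        if not (0.0 <= self.ms2_fraction <= 1.0):
            raise ValidationError("ms2_fraction must be in [0, 1]")
        if self.mass_ppm_spread < 0 or self.mass_noise_ppm < 0:
            raise ValidationError("mass spreads must be >= 0")
        if self.scorer_ppm <= 0:
            raise ValidationError("scorer_ppm must be > 0")


# decoy MS2 raw scores are Beta(2, 5); the correct candidate draws from
# Beta(2 + t, 5) with t solved so P(correct holds the top score) is exact
_DECOY_BETA = (2.0, 5.0)


@lru_cache(maxsize=None)
def _beta_shift(p: float, n: int) -> float:
    """Shift t with P(Beta(2+t, 5) > max of n-1 iid Beta(2, 5)) = p."""
    a, b = _DECOY_BETA
    if n == 1:
        return 0.0

    def p_top(t: float) -> float:
        f = lambda x: stats.beta.pdf(x, a + t, b) * stats.beta.cdf(x, a, b) ** (n - 1)
        return integrate.quad(f, 0.0, 1.0)[0]

    lo, hi = -a + 1e-6, 500.0
    p = min(max(p, p_top(lo)), p_top(hi))  # clip to the attainable range
    return optimize.brentq(lambda t: p_top(t) - p, lo, hi, xtol=1e-10)


def generate_dataset(config: SimulationConfig) -> Dataset:
    """One reproducible synthetic dataset with exactly one correct candidate
    per feature."""
    rng = np.random.default_rng(config.seed)
    N, n = config.n_features, config.n_candidates

    u = rng.uniform(size=N)
    while len(np.unique(u)) < N:  # pragma: no cover - probability zero
        u = rng.uniform(size=N)
    rts = 60.0 + 540.0 * u  # monotone transform; order equals latent order

    true_mass = rng.uniform(100.0, 800.0, size=N)
    measured = true_mass * (
        1.0 + rng.normal(0.0, config.mass_noise_ppm / 2e6, size=N)
    )

    n_ms2 = int(round(config.ms2_fraction * N))
    ms2_flags = np.zeros(N, dtype=bool)
    ms2_flags[rng.permutation(N)[:n_ms2]] = True

    rt_rank = np.argsort(np.argsort(rts))  # 0-based rank by RT
    shift = _beta_shift(config.ms_informativeness, n)

    features: List[MSFeature] = []
    sets: List[CandidateSet] = []
    for i in range(N):
        fid = f"f{i:04d}"
        features.append(
            MSFeature(
                feature_id=fid,
                retention_time=float(rts[i]),
                precursor_mass=float(measured[i]),
                has_ms2=bool(ms2_flags[i]),
            )
        )

        # retention preference values
        if config.adversarial:
            correct_pref = float(u[i])
            if rt_rank[i] == N - 1:  # last-eluting feature: decoys far below
                decoy_pref = -2.0 - 1e-3 * np.arange(1, n)
            else:  # decoys above everything, decreasing with RT rank
                decoy_pref = 2.0 + (N - rt_rank[i]) + 1e-3 * np.arange(1, n)
        else:
            correct_pref = float(u[i] + rng.normal(0.0, config.order_noise_sd))
            decoy_pref = rng.uniform(size=n - 1) + rng.normal(
                0.0, config.order_noise_sd, size=n - 1
            )

        # MS² raw scores calibrated so P(correct is top) = ms_informativeness
        decoy_scores = rng.beta(*_DECOY_BETA, size=n - 1)
        correct_score = float(rng.beta(_DECOY_BETA[0] + shift, _DECOY_BETA[1]))

        decoy_mass = true_mass[i] * (
            1.0
            + rng.uniform(
                -config.mass_ppm_spread, config.mass_ppm_spread, size=n - 1
            )
            * 1e-6
        )

        cands = [
            Candidate(
                candidate_id=f"{fid}_c000",
                raw_score=correct_score,
                exact_mass=float(true_mass[i]),
                preference_value=correct_pref,
                is_correct=True,
            )
        ]
        for j in range(n - 1):
            cands.append(
                Candidate(
                    candidate_id=f"{fid}_c{j + 1:03d}",
                    raw_score=float(decoy_scores[j]),
                    exact_mass=float(decoy_mass[j]),
                    preference_value=float(decoy_pref[j]),
                    is_correct=False,
                )
            )
        order = rng.permutation(n)
        cs = CandidateSet(fid, [cands[j] for j in order])
        if not ms2_flags[i]:
            cs = ms1_gaussian_scores(features[-1], cs, ppm=config.scorer_ppm)
        sets.append(cs)

    return Dataset(features, sets)


def measure_order_accuracy(dataset: Dataset) -> float:
    """Pairwise retention-order accuracy of the correct candidates.

    Fraction of distinct-RT feature pairs whose correct candidates'
    preference-value order matches the observed RT order.
    """
    if len(dataset) < 2:
        raise ValidationError("need at least two features")
    if not dataset.has_ground_truth():
        raise ValidationError("ground truth required")
    prefs, rts = [], []
    for f, cs in zip(dataset.features, dataset.candidate_sets):
        prefs.append(cs.candidates[cs.correct_index].preference_value)
        rts.append(f.retention_time)
    agree = total = 0
    for i in range(len(rts)):
        for j in range(i + 1, len(rts)):
            if rts[i] == rts[j]:
                continue
            total += 1
            if np.sign(prefs[i] - prefs[j]) == np.sign(rts[i] - rts[j]):
                agree += 1
    if total == 0:
        raise ValidationError("no distinct-RT feature pairs")
    return agree / total
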