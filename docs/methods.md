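# Methods

This note documents the model implemented by `msrtrank`, the numerical and
design choices that were genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Model and inference

The joint candidate assignment over all LC-MS features is a pairwise Markov
random field: node potentials `max(θ_ir, c)` carry the MS evidence, edge
potentials `σ(sign(t_i−t_j)·(w_ir−w_js))` carry retention-order consistency,
and the exponents `(1−D)` / `D` weight the two sources. All potentials are
strictly positive — `c > 0` floors the node side, and every `σ` maps into
`(0, 1]` — so the distribution is well defined for every configuration.

Exact marginals on the complete feature graph require summing over
`∏ n_i` configurations, so inference runs on spanning trees:

* **Sampling.** A tree is the minimum spanning tree of the eligible graph
  under i.i.d. Uniform(0,1) edge weights. On symmetric graphs (e.g. the
  triangle) this makes every tree topology equally likely; the construction
  is the standard random-MST device and is not an exact uniform spanning
  tree sampler (Wilson's algorithm is deliberately out of scope). Edges
  between features with exactly equal RTs carry no order information and
  are never eligible. Ensembles draw `L` independent trees from sub-seeds
  spawned off the master seed (`numpy.random.SeedSequence`), so runs are
  reproducible and trivially parallelizable. Trees are not deduplicated.
* **Message passing.** Each tree is rooted at its lexicographically
  smallest feature id (the result is provably root-invariant and a test
  asserts it) and processed with the two-pass schedule: exactly `2(N−1)`
  directed messages, touching `O(N·n_max²)` potential entries —
  instrumentation counters verify both. Sum-product marginals are
  normalized per feature to sum to 1; max-product marginals are divided by
  the per-feature maximum so the best candidate scores exactly 1. The MAP
  assignment backtracks over max-product messages with ties broken towards
  the lowest candidate index.
* **Log-space.** All inference runs in log-space with per-message
  max-subtraction. This is not optional: step-function potentials of
  `ε = 10⁻¹⁰` raised to `D` and multiplied across tens of edges underflow
  any linear-space product. A brute-force enumerator (capped at 10⁶
  configurations) provides exact reference marginals for trees and for the
  full graph at toy scale; the test suite additionally checks message
  passing against an independent linear-space enumerator on moderate
  potentials.
* **Averaging.** Ensemble marginals are the plain arithmetic mean of
  per-tree normalized marginals. Averaged sum-marginals remain on the
  simplex automatically; averaged max-marginals are deliberately **not**
  re-normalized — the mean is the definition, and its per-feature maximum
  may fall below 1 when trees disagree about the best candidate.

## Scores and potentials

* **Normalization** of raw MS scores is per candidate set, dividing by the
  set maximum: it preserves the scorer's ordering, puts the best candidate
  at exactly 1, and matches the structure of the self-normalized MS¹ score.
  (Global normalization across sets would couple unrelated features through
  a single scale.)
* **Floor constant.** `c` defaults to one tenth of the smallest non-zero
  normalized score across all candidate sets, and is applied uniformly —
  including to MS¹-scored sets, whose scores are already in `(0, 1]`. An
  explicit override is available for degenerate data (all scores zero).
* **D-weighting** is folded into the potential construction
  (exponentiation in log-space), keeping the inference code
  weighting-agnostic.
* **Missing MS².** Features without a spectrum are scored by the Gaussian
  mass-deviation score with `σ = ppm·m_i/(2·10⁶)` and `ppm = 5` by default,
  self-normalized per set.
* **Equal RTs.** Sampled trees never contain equal-RT edges; the
  deterministic RT chain breaks ties by feature id, and such a tied chain
  edge contributes the constant `σ(0)^D`, which cancels in normalization.
  Datasets in which *all* features share one RT are rejected outright
  rather than silently reduced to MS-only ranking.

## Hyper-parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `D` | retention-order weight | selected | grid `{0, 0.05, …, 1}`, highest training top20AUC, ties → smallest `D`; one shared tree ensemble across the grid isolates the effect of `D` |
| `k` | sigmoid scale | fitted | Platt-style Bernoulli ML of `σ(kx)` on oriented order pairs; intercept fixed at 0 (a zero preference difference must map to ½); result clipped to `[10⁻³, 10³]` |
| `ε` | step-function floor | `10⁻¹⁰` | small enough that one violated edge vetoes an assignment, non-zero to keep the distribution proper |
| `L` | ensemble size | 128 | identification accuracy saturates in `L`; top-20 keeps improving to ~128 trees |
| marginal kind | sum vs max | max | max-marginals are more robust to mass placed on many low-probability configurations |
| `ppm` | MS¹ mass accuracy | 5 | typical high-resolution instrument accuracy |

The hinge-sigmoid edge potential (the map used implicitly by chain-graph
dynamic-programming approaches) is provided for comparison and its `k` is
calibrated by the same Platt procedure.

## Synthetic data

The generator emulates exactly the statistical structure the method
consumes, nothing more:

* a latent elution coordinate `u_i ~ U(0,1)` per feature; RT is a monotone
  transform of it (so RTs are distinct by construction — the equal-RT rules
  are tested with hand-built fixtures instead);
* correct candidates' preference values are `u_i` plus Gaussian noise;
  decoys draw an independent coordinate plus the same noise. The default
  noise sd 0.1539 solves `E[Φ(|Δu|/(s√2))] = 0.85`, i.e. a predictor with
  ~85% pairwise order accuracy;
* MS² raw scores: decoys are Beta(2,5); the correct candidate draws from
  Beta(2+t, 5) with `t` solved numerically so that it holds the top score
  with probability `ms_informativeness` (default 0.4 at 20 candidates) —
  a shifted distribution keeps non-top correct candidates near the top,
  as real MS² scorers do;
* MS¹-only features: the measured precursor mass carries Gaussian error at
  the instrument's ppm accuracy and decoy masses deviate uniformly within
  ±10 ppm, so the mass score is informative but imperfect;
* an adversarial mode for the `D=1` limit: correct candidates are exactly
  order-consistent while every decoy's preference violates the observed
  order against *everything at any later-eluting feature* (the last
  feature's decoys violate against everything earlier). On the RT chain,
  every assignment containing a decoy then has at least one violating
  edge, making the all-correct assignment the unique MAP under step
  potentials at `D=1`. A decoy violating against the correct candidates of
  **all** other features is geometrically impossible for interior features
  (it would have to sit below every earlier and above every later
  preference simultaneously), which is why this guarantee is stated — and
  tested — on the chain.

What passing these tests shows: the inference machinery is exact on trees,
the integration direction is right, and retention order measurably improves
identification when the order predictor is informative. What they do not
show: performance on real spectra — the generator has no fragmentation,
isotope patterns, correlated decoy structure, or candidate-set size
distributions of real databases.

## Evaluation conventions

Ranks are tie-aware mid-ranks (`#greater + (#equal+1)/2`, the expected rank
under random tie shuffling), with ties detected at a relative tolerance of
1e-9 to absorb round-off between mathematically equal marginals. top-k
accuracy is the fraction of features with correct-candidate rank ≤ k;
top20AUC is exactly the mean of top-k accuracies for k = 1..20. Optional
stereoisomer collapsing keeps the best-MS-scoring member of each
`stereo_group` and transfers the correctness flag to it (identification is
judged on the stereo-free structure); it is a pre-processing step the
caller applies before integration.

## Problem sizes

The acceptance checks run at deliberately modest scale chosen for tight
feedback loops: exactness on 200 random instances with ≤6 features and ≤4
candidates (where enumeration is exact), and identification trends on 20
synthetic experiments of 50 features × 20 candidates with `L = 32` trees
and `D` tuned on disjoint 50-feature training splits. The method itself has
no such limits; per-tree cost is linear in the number of features.

## Known limitations

* The random-MST sampler is not an exact uniform spanning-tree sampler on
  asymmetric graphs; the model definition does not require uniformity.
* `select_D` optimizes top20AUC, which can prefer `D` values that improve
  mid-rank mass at a small cost in top-1 on some datasets.
* Averaged max-marginals are not probabilities (they need not sum to 1);
  they are ranking scores.
* Stereochemistry is handled purely through the opaque `stereo_group` key;
  no structure parsing is performed.
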