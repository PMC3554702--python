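# Methods

## Model and assumptions

The gnostic field assumes a stimulus is exchangeable-with-location: a bag of
local feature vectors per channel, where category identity is carried by the
*directions* of the vectors, not their magnitudes.  Whitening plus spherical
normalization makes that assumption operational — after it, every comparison
in the model is a cosine similarity.  Category knowledge is stored as
exemplar units (cluster centroids on the unit sphere), one redundant bank per
(category, channel), trained on that category's data alone.  Discrimination
comes from two later stages: local competition between banks, and a learned
linear decoder over accumulated evidence.

Processing is strictly feed-forward and per-location until accumulation, so
the model is invariant to the order of locations and linear in per-location
evidence before the final normalizations.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `whiten_eps` | `1e-4` (relative) | Added to eigenvalues before `(Λ+εI)^(-1/2)`. Scaled by the mean eigenvalue (trace/d) so one setting works across channels with different feature scales; stabilizes near-null directions while leaving leading components essentially untouched (a direction keeps variance `λ/(λ+ε)`). |
| `alpha` | `10` | Scale of the unit-allocation curve `min(n, ⌈α·log₂(n+1)²/√d⌉)`. The curve's shape is the commitment: polylog in exposure `n`, shrinking with feature dimension, capped at `n` so tiny categories memorize their data. `α=10` allocates on the order of a few hundred units per set at `n ≈ 10³`, a few units per category when data are scarce. |
| `eta` | `0.8` | Winnow learning rate in the sinh-re-expressed (additive) space. |
| `max_epochs` | `500` | Winnow epoch cap; training normally stops earlier at the first mistake-free epoch. Non-convergence warns rather than fails: label noise makes the data non-separable by design in some experiments. |
| `floor` | `1e-9` | Added to the contraharmonic-mean denominator; pure division safety, far below any meaningful activity. |
| `competition` | `soft` | `hard` is the grandmother-cell ablation (one-hot at the most active set). |
| `location_augment` | on | Appends `(x, y, 1)/‖(x, y, 1)‖` to spatial features. The constant component keeps the image center distinct from a zero block; the block is unit-norm so location and appearance contribute on comparable scales. Temporal channels are never augmented. |
| `accumulation` | `max` | Divide category sums by the most active category. `center_l2` (subtract mean, divide by Euclidean norm) suits margin-based external decoders. |

Competition composes mean-thresholding, half-wave rectification, and
division by the contraharmonic mean of the rectified pattern.  The
contraharmonic mean equals the arithmetic mean plus the Fano factor
(variance/mean), so for a fixed rectified sum, a higher-variability
population yields uniformly smaller outputs — noisy channels self-inhibit.
This denominator is exact in the many-category limit of the underlying
divisive-normalization scheme and is used at every K for simplicity; its
monotonicity in population noise is what the architecture needs and is
property-tested.

## Numerical choices

- Whitening uses the symmetric eigensolver on the sample covariance
  (`ddof=1`); eigenvalues are clamped at zero before the inverse square
  root.  With `ε=0` and a singular covariance, null directions are projected
  out rather than amplified.
- A vector that whitens to exactly zero (it equals the training mean) is
  passed downstream as the zero vector — "no evidence at this location" —
  and flagged with a warning in the single-vector API.
- Spherical k-means: seeding is the cosine analogue of k-means++ (first
  centroid uniform over points, later ones with probability ∝
  `max(0, 1 − best cosine so far)`); assignment ties break to the lowest
  centroid index; empty clusters, and clusters whose vector sum cancels to
  zero, are reseeded from the worst-served point; Lloyd stops when
  assignments are stable or after 100 iterations.  Runs are bit-reproducible
  given the seed, and all seeds derive from the single model seed via
  per-(category, channel) `SeedSequence` spawning.
- All argmax decisions (competition winner, Winnow prediction,
  winner-take-all) break ties toward the lowest category index.
- Winnow updates only on misclassification, in dataset order by default
  (optionally a seeded per-epoch shuffle), so training is deterministic.
- A complete tie at a location (all set activities equal) contributes a zero
  response vector rather than an error.

## The synthetic generator

Each category owns a few mean directions per channel, drawn uniformly on the
unit sphere; stimulus vectors are those directions plus Gaussian noise of
scale `1/√κ`, re-normalized — a von Mises–Fisher-like draw that is simpler
to sample and adequate for testing.  A configurable fraction of vectors is
replaced by uniformly random background directions, per-channel multipliers
on κ make some channels less discriminative than others, and a fixed random
anisotropic axis scaling (condition number 10 by default) gives the raw
features the badly conditioned variance structure that whitening exists to
fix.  Spatial channels get 6×6 grid coordinates in `[−0.9, 0.9]²`; temporal
channels get consecutive frame indices.

What it does *not* emulate: correlations between neighboring locations,
multi-scale structure, heavy-tailed feature distributions, temporal
autocorrelation of frames, and class imbalance.  Tests passing on this
generator therefore validate the mechanics and the qualitative ablation
directions, not performance on any real corpus.

The standard benchmark is the generator's defaults: K=10 categories, U=2
channels (one spatial, one noisier temporal), 3 clusters per category, d=16
raw dimensions, κ=40, 25% background, 36 locations per stimulus, 30 training
and 15 test stimuli per category.  These sizes keep a full train/evaluate
cycle under a few seconds while leaving room below ceiling for the harder
variants; the acceptance script runs the benchmark and its four ablations in
well under a minute.

## Design choices where the design was open

- **Unit allocation.** Only the qualitative properties of the allocation
  rule are canonical (polylogarithmic in `n`, dependent on `d`, ≈`n` for
  tiny `n`); the specific `⌈α·log₂(n+1)²/√d⌉` is this package's choice and
  is deliberately isolated behind `AllocationPolicy`.
- **Location block.** `(x, y, 1)` before normalization; configurable off.
- **WTA scope.** The winner-take-all rule is defined over a single channel's
  evidence; on multi-channel models the decoder scores a designated channel
  (the first by default) and `wta_predict` rejects multi-channel input.
- **Serialization.** One NPZ archive holding all arrays plus a JSON metadata
  string; loading restores a model whose predictions are bit-identical.

## Known limitations

- On very small or very noisy instances the learned Winnow decoder can
  generalize worse than winner-take-all on the cleanest channel: with few
  evidence vectors it cannot reliably learn to down-weight a noisy channel
  that WTA simply ignores.  The expected ordering (learned decoder ≥ WTA)
  holds at the benchmark conditions and is the regime the architecture
  targets.
- A shuffled-label control can score slightly above `100/K`: a random
  permutation fixes ≈`1/K` of the labels, so the "control" model retains a
  sliver of signal.  Fixed-seed controls in the tests stay within the
  binomial 3σ band of chance.
- Balanced Winnow here uses mistake-driven updates with no margin; data that
  are separable in evidence space converge, but no mistake bound is enforced
  programmatically beyond the epoch cap.
- Spherical k-means guarantees a nondecreasing objective, not the global
  optimum; the exhaustive-partition equality tested on tiny instances relies
  on well-separated bundles where k-means++ seeding reliably finds the
  optimum.
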