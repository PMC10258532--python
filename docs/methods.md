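# Methods

## Problem and model

Probabilistic tractography propagates streamlines along directions
sampled from fibre-orientation distributions, so it explores many
plausible paths and systematically produces spurious connections. The
contamination is distance-dependent: nearby region pairs accumulate
chance streamlines far more readily than distant ones, so a single
uniform cutoff on connection strength either floods short-range edges
with false positives or erases true long-range bundles.

`dddthresh` addresses this with distance-dependent empirical nulls. For
a set of spherical ROIs with pairwise distances d and connection scores
s, the procedure is:

1. **Connection score.** For ROIs A, B the directed score is the
   proportion of streamlines with at least one terminus assigned to A
   whose other terminus is assigned to B; the reported score is the mean
   of the two directions, a symmetric value in [0, 1]. A terminus is
   assigned to the ROI whose sphere surface lies within the radial
   search distance (default 4 mm, the MRtrix3 convention), nearest
   centre winning; interior streamline points never count.
2. **Distance.** Either the centre-to-centre Euclidean distance, or the
   minimum connecting-streamline arc length averaged across subjects
   (subjects without a connecting streamline are dropped from the
   average). Both are rounded half-away-from-zero to integer mm.
3. **Binning.** Unique integer distances are pooled greedily, in
   increasing order, into contiguous bins until each holds at least
   `min_samples` ROI-pair samples; a terminal shortfall merges into the
   previous bin. The bin count is emergent from the occupancy floor.
4. **Monte-Carlo null.** Each bin's candidate scores are resampled with
   replacement (default 100,000 draws). The threshold at level α is the
   empirical quantile leaving a fraction α of the draws strictly above
   it — the nearest-rank-lower (1 − α) quantile.
5. **Application.** Each edge of a (group-average or individual)
   connectivity matrix is routed to its distance bin and survives at the
   smallest α whose threshold its score strictly exceeds. Survivor sets
   are nested across α by construction.

A distance-blind baseline is included for comparison: one nearest-rank
percentile cutoff over all off-diagonal scores, edges strictly above it
surviving, optionally matched to a target surviving-edge count.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| ROI radius | 8 mm | sphere radius in template space |
| grid spacing | 16 mm | lattice step; touching spheres at default radius |
| radial search | 4 mm | terminus capture zone beyond the sphere surface |
| `min_samples` | 100 (desk scale) | occupancy floor per distance bin; hemisphere-scale grids use ~1000 |
| `alphas` | 0.1, 0.2, 0.3 | fraction of the null above the threshold; smaller = stricter |
| `n_draws` | 100,000 | Monte-Carlo draws per bin |
| seed | user-set | master seed; bin *b* resamples with seed + *b* |

## Numerical conventions

- **Rounding** of distances is half-away-from-zero (16.5 → 17), fixed so
  distance matrices are bit-reproducible; numpy's banker's rounding is
  deliberately avoided.
- **Quantile convention** is nearest-rank-lower: with n sorted draws and
  k = ⌊αn⌋, the threshold is the order statistic at index n − k − 1
  (0-based). Under heavy ties — typical of zero-inflated scores — the
  realised fraction above the threshold can be well below α.
- **Survival is strict** (score > threshold). An all-zero bin yields
  threshold 0 and zero-score edges never survive, so null edges in
  zero-inflated long-distance bins are not declared significant.
- **Ties in endpoint assignment** break to the nearest centre, then to
  the lexicographically smallest ROI id.
- **Thresholds are step functions** of distance (per-bin constants); no
  interpolation between bins. Distances outside the binned range clamp
  to the nearest bin; a distance falling in a gap maps to the nearer
  boundary, lower bin on ties.
- **Directed-score denominator** is the number of streamlines with at
  least one terminus assigned to the seed ROI, which makes the score a
  conditional endpoint frequency in [0, 1] and scale-free across
  subjects. Streamlines with both termini in one ROI enter that ROI's
  denominator but no pair's numerator. A direction with an empty
  denominator contributes 0 to the two-direction mean.
- **Missing streamline distances** carry the sentinel −1 in distance
  matrices; edges with missing distance are excluded from thresholding.
- **Determinism.** All randomness flows from numpy `default_rng` seeded
  explicitly; per-bin seeds are master + bin index so results do not
  depend on bin evaluation order. Refitting with the same inputs and
  seed reproduces the serialized model byte-for-byte.

## Group-level use

Group thresholding operates on the unthresholded entrywise mean of the
per-subject matrices; the same `apply_ddd` works on a single subject's
matrix. No sparsification of individual matrices is required, unlike
consensus-style group thresholding.

## The synthetic cohort generator

The generator reproduces the distributional phenomenology the method
assumes, not fibre geometry. For a pair at distance d (mm):

- **Null pairs** score 0 with probability
  π₀(d) = 0.9 − 0.8·exp(−d/80), otherwise |N(0, σ(d))| with
  σ(d) = 0.5·exp(−d/λ), λ = 40 mm. Zero-inflation rises and the
  magnitude scale decays with distance, giving the right-skewed,
  mostly-near-zero long-range bins seen in real connectomes.
- **Planted bundles** draw from a log-normal with shape 0.4 and median
  m·exp(−d/2λ): half the null decay rate, so long bundles are weak in
  absolute score but strong against their distance-matched null. Long
  bundles (m = 0.1, d ≥ 80 mm) and short bundles (m = 0.6, d ≤ 40 mm)
  are planted on randomly chosen pairs.
- Scores are clipped to [0, 1]; matrices are symmetric with zero
  diagonal; everything is deterministic per seed.

The default cohort is 30 subjects over 60 ROIs placed uniformly in a
120 mm cube, with 20 long and 10 short planted bundles. These defaults
deliberately realise the failure mode of uniform thresholding: the
long-bundle group scores (≈ 0.03–0.05) sit below the global cutoff that
a count-matched uniform rule needs (≈ 0.06–0.08, set by the mass of
short-range null scores) yet above their own bins' α = 0.1 thresholds
(≈ 0.01–0.03). The parameter choices follow from the closed-form means
and quantiles of the zero-inflated half-normal above, not from fitting
to any dataset.

A smaller streamline-level path (`simulate_tractogram`) emits jittered
polylines between requested ROI pairs plus unassignable background
tracks, to exercise endpoint assignment and streamline-length distances;
score-level simulation remains the primary test path because the
thresholding method consumes scores.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring pairs, subject-level registration error, SIFT-style
streamline weighting, crossing-fibre geometry, or scanner noise.
Passing recovery tests therefore show that the method behaves as
designed under its own distributional assumptions — they do not certify
performance on any particular acquisition.

## Problem sizes used in tests

The acceptance checks run at desk scale: 2,000-candidate bins with
100,000 draws and 30 resampling seeds for the quantile oracle;
eight geometrically-shrinking bins of 300 candidates for monotonicity;
100 random 12-ROI matrices for tier nesting; and 20 replicates of the
default 30-subject, 60-ROI cohort for the recovery experiment. The
quantile-oracle fixture stores scores on a 1/25 grid, as proportions of
integer streamline counts are in practice; with heavily tied candidates
the resampled threshold pins the analytic quantile to within adjacent
order statistics, which is not true of continuous candidate sets at
this draw count.

## Known limitations

- Null distributions are data-specific: thresholds fitted on one ROI
  grid, tracking configuration or score definition do not transfer to
  another; only the α level is comparable across datasets.
- The greedy left-to-right binning is not an optimal equal-mass
  partition; bins near the distance extremes can be wide.
- Scores are unweighted streamline-count proportions; SIFT2-style
  per-streamline weights are out of scope.
- No multiple-comparison correction is applied across edges; α is a
  per-bin distributional level, not a family-wise error rate.
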