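# Methods

`blapipe` implements the statistical core of a study design in which
genetically defined basolateral-amygdala (BLA) neuron populations are
characterized three ways: by their calcium activity as a function of the
animal's distance to a motivationally relevant target (food container or
caged conspecific), by their responses to discrete events (footshocks,
freezing bouts, social engagement), and by the spatial distribution of their
transcriptomic cell types measured with multiplexed smFISH.  This note
documents the models, the defaults and why they were chosen, what the
synthetic data do and do not emulate, and the numerical choices that matter.

## Distance-tuning permutation test

For each session the animal's distance to the target is computed per frame
(15 frames/s), normalized by the chamber radius and clipped to [0, 1]
(rectangular-arena corners can exceed the normalizer; clipping keeps the bin
domain fixed).  The normalized range is split into `n_bins = 31` equal,
left-closed bins (the last right-closed).  A neuron's tuning statistic is
the maximum over occupied bins of its mean firing rate (spikes/frame); its
preferred distance is the peak bin's centre, converted back to cm, and its
zone is

- **pro** if the peak distance is at or inside the inner zone radius,
- **anti** if strictly outside the outer radius,
- **neutral** in between,

with radii 5/17 cm for feeding sessions and 10/20 cm for social sessions.
Peak ties break to the smallest bin index (nearest distance).

The null distribution resamples the same statistic over `n_shuffles = 1000`
*rotary shuffles* — circular shifts of the neuron's own spike train by an
offset drawn uniformly from {1, …, T−1}.  A circular shift preserves the
train's values and autocorrelation exactly while breaking its alignment
with behavior, which is what makes the test robust to the strong temporal
smoothness of deconvolved calcium activity.  The p-value uses the add-one
rule p = (1 + #{null ≥ observed}) / (1 + n_shuffles), so p is never 0 and
Benjamini–Hochberg correction (FDR 5%, applied across the neurons of one
session) stays well defined.  Constant trains (including silent neurons)
are shift-invariant and get p = 1 directly.

Implementation: the binned sum of a circularly shifted train is a circular
cross-correlation of the train with the bin's indicator function, so the
statistic is evaluated for *all* T offsets at once with FFTs and the
sampled offsets are read off; tests assert bit-level agreement (to 1e-9)
with the literal roll-and-bin computation.  Because FFT round-off could
spuriously rank a tied null value below the observation, the comparison
null ≥ observed − 1e-9·max(1, observed) is used.  Each neuron draws its
offsets from a stream seeded by (session seed, CRC32 of the neuron id), so
results are independent of neuron order and chunking.

## Population-composition test

Whether one population's percentage of, say, pro-food neurons exceeds
chance is tested by pooling the zone labels of all recorded populations and
drawing, 1000 times, N labels without replacement (N = size of the tested
population, which remains part of the pool).  The observed percentage is
compared with the empirical 2.5% and 97.5% quantiles of the resampled
percentages; verdicts are `above`, `below` or `ns`.  Labels are fixed
during resampling (only membership is resampled).  On small pools the
verdicts agree with the exact two-tailed hypergeometric decision in ≥ 95%
of random instances (asserted in tests); the resampling form is kept
because it generalizes to any label statistic and mirrors the study's
procedure.

## Event-response scores

All event scores share the contrast form (A − B)/(A + B) on mean firing
rates, defined as 0 when both rates are 0; ±1 mean maximal activation /
inhibition:

- **SRC (shock response score)** — A = mean rate in the 2 s from shock
  onset, B = mean rate in the 2 s before; the per-neuron score is the
  unweighted mean over events (per-event rates, not pooled frames).  Events
  whose windows would be truncated by the recording edges are dropped with
  a warning.
- **Freezing score** — A/B = mean rates in freezing vs non-freezing frames;
  input freezing bouts shorter than 2 s are filtered out, matching the 2-s
  minimum bout duration of automated freezing detection.
- **SoRC (social response score)** — A/B = mean rates in social vs
  non-social frames.  A frame is social when the animal is within 10 cm of
  the wired-container centre *and* its heading is within 45° of the
  cell-to-container direction.  The angular threshold is a configurable
  choice; the study validated its auto-detection only by agreement with
  manual scoring and reports no angle.  Neurons with SoRC > 0 are `ON`,
  otherwise `OFF` (a score of exactly 0 is OFF; ON requires strictly
  positive).

Footshock responders are classified against a rotary-shuffle null of the
mean SRC (whole train shifted once per shuffle, same operator as the tuning
test): `pro` strictly above the 97.5% empirical null quantile, `anti`
strictly below the 2.5% quantile, `neutral` otherwise.  The null is
evaluated with O(T) circular sliding-window sums, making 1000 shuffles per
neuron essentially free.

Regressions between score pairs (e.g. SRC vs SoRC) use closed-form simple
least squares with the usual t-test on the slope; constant y returns slope
0 and R² 0, constant x is a degenerate design and raises.

## Marker selection and cluster profiles

Candidate cluster markers are screened per (gene, cluster) by one-vs-rest
AUROC computed as the Mann–Whitney rank statistic with mid-rank ties
(identical to pairwise win/tie counting, asserted against that oracle), and
by the percentage of cells with count > 0 inside (`pct_in`) and outside
(`pct_out`) the cluster.  A gene passes iff AUC > 0.5, pct_in ≥ 20 and
pct_out ≤ 20 — strict on the AUC threshold, non-strict on the percentages,
mirroring the presto-style convention; "expressed" means count > 0.  A
zero-variance gene scores AUC = 0.5 and can never pass.  The default report
keeps the top 5 passing genes per cluster by AUC.  The screen reports
candidates only; the study's final panel additionally involved curation by
atlas inspection, which is human judgment and out of scope.

Cluster profiles aggregate read counts by *sum* per (cluster, gene) and
scale each gene by its maximum across clusters, giving values in [0, 1]
(all-zero genes scale to 0); scaling is invariant to per-gene rescaling of
the counts.  The cluster dendrogram applies average-linkage agglomerative
clustering to Euclidean distances between profile rows (the study names
only the metric; the linkage is a config option).

## smFISH quantification and cluster assignment

Per-gene positive/negative thresholds are computed on log1p raw values —
Otsu's criterion by default, with quantile and fixed-value overrides — and
recorded in the output metadata.  The study thresholded by double-blind
visual inspection; Otsu is the reproducible, parameter-free stand-in.
Subregion fractions are 100 · (#positive)/(#cells) per subregion and gene;
multi-positive cells count once per gene, so a subregion's row may sum past
100%.  Empty subregions are flagged undefined and excluded from the
subregion Pearson correlation matrix, which is ordered by average-linkage
clustering of 1 − r.

Eigen-images rasterize per-gene positive-cell counts onto a 50 µm pixel
grid per section, smooth with a Gaussian of σ = 1 px, and decompose the
pixels × genes matrix (columns centred) by SVD; variance fractions are
reported over all components (they sum to 1) and the top-4 cumulative
fraction is exposed directly since it is the study's headline summary of
spatial structure.

For cluster assignment each cell's 10-gene vector is correlated (Pearson)
with every cluster's scaled profile row and assigned to the argmax, ties
breaking to the lowest cluster id; no minimum-r threshold is applied.
Cells with zero-variance or undefined feature vectors stay unassigned.
Two feature choices are supported:

- raw per-cell values — exact for proportional data and the default for
  synthetic recovery checks;
- `local_normalize` — per-cell sums over all same-section cells within
  50 µm (boundary inclusive, self included) followed by per-gene z-scoring
  across the section's cells (population SD).  The study's description of
  this normalization is grammatically broken ("normalized z-scores … in a
  of radius 50 µm"); neighborhood-sum-then-global-z is the chosen reading,
  per section, and both the radius and the reading are configurable.

## Synthetic data

Generators are pure functions of (parameters, seed) and provide ground
truth for every recovery test.

- **Trajectory** — reflected Gaussian random walk (steps iid N(0, σ²) per
  axis, boundary reflection) *plus intermittent target visits*: at 2
  visits/min the walker heads to the target at twice the roaming step size
  and dwells for an exponential mean 3 s.  The visits emulate the approach
  behavior the assays are built around (a fasted mouse feeds at the
  container; a test mouse investigates the conspecific).  They matter
  statistically: under a pure unbiased walk the innermost of 31 distance
  bins receives only ~10 of 9000 frames (occupancy ∝ annulus area), which
  makes the max-bin-rate null dominated by small-sample noise and destroys
  power; with visits every bin holds ≥ ~100 frames.  `visit_rate_per_min=0`
  recovers the pure walk.  Validity of the permutation test does not depend
  on this choice (circular shifts are exchangeable under the null either
  way) — only power does.
- **Spikes** — Poisson counts with rate baseline + amplitude ·
  exp(−(d_norm − d₀)²/2σ²) for distance tuning (default σ = 0.1, the
  minimal shape that makes "peak distance" well defined), and baseline ×
  gain inside event windows for responders (default gain 3).  Counts are
  integers although the pipeline accepts any nonnegative reals, as real
  spike inference produces.
- **Expression** — negative-binomial (gamma–Poisson) counts with per-gene
  means `library_scale · scaled_profile` and shape `dispersion`
  (near-Poisson as dispersion → ∞).  Reference profiles give each cluster
  two (near-)exclusive high genes over a low shared floor, mimicking a
  curated marker panel.
- **smFISH cells** — uniform placement in rectangular subregion tiles (one
  subregion per section row; invented plumbing — real subregions span
  sections), true cluster drawn from the subregion's mixture row, raw
  values `scale · profile + N(0, noise_sd)` clipped at 0 — exactly
  proportional at `noise_sd = 0`, which is what makes the noiseless
  100%-recovery check exact.

Not emulated: calcium-indicator dynamics (GCaMP kinetics, deconvolution
artifacts), momentum or thigmotaxis in locomotion, transcriptome-wide
expression structure, segmentation errors or optical crosstalk in smFISH.
Passing recovery tests therefore demonstrates correctness of the
statistics, not robustness to these real-data nuisances.

## Problem sizes and reproducibility

The calibration script (`scripts/acceptance.py`) uses 20 replicates of 200
untuned neurons × 9000 frames for the FDR check and 2000 replicates of the
3 × 100-neuron exchangeable null for the composition check; the FFT and
sliding-window formulations keep the whole run under a minute on one core.
All replicate streams derive from a single seed via `numpy.SeedSequence`,
and the demo pipeline writes a run manifest sufficient to reproduce every
output byte for byte.

## Known limitations

- BH grouping is per session/population; the study does not state its
  grouping.
- The composition test resamples labels only (fixed per-neuron labels); an
  alternative reading — recomputing significance within each resample — is
  not implemented.
- Positive-cell thresholds are global per gene, not per section; section
  effects (round order, bleaching) are assumed removed upstream.
- The study's per-cell correlation figures and population fractions (e.g.
  40.8% pro-food) depend on unreleased raw recordings and cannot be
  reproduced here; calibration and recovery on synthetic data are the
  testable surrogate.
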