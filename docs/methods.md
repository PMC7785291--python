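# Methods

This note documents the models, parameter choices and numerical
conventions behind `dynapquant`, and what the synthetic-data generators do
and do not emulate.

## Spectral-count enrichment model

**Inputs and preprocessing.** PSM tables are long-form
(run, bait label, protein, count) with integer counts and unique
(run, protein) pairs. Proteins are collapsed to orthology groups by a
user-supplied map before any statistic; homeolog counts are summed within
each run, never across runs. Proteins absent from the map are retained as
singleton groups (with a warning) rather than dropped, so user-supplied
partial maps degrade gracefully. Replicate bait runs, and separately
replicate control runs, are pooled by summing counts; the comparison is
always one pooled bait sample against one pooled control sample.

**Universe.** The set of groups considered, of size *n*, is the union of
groups with at least one PSM in the pooled bait or pooled control sample —
the largest set for which any datum exists. Groups absent on one side
enter with a zero there.

**Statistics.** The fold-change uses +1 pseudocounts on every group so it
is finite for groups absent on one side; it is compositional (frequencies
of the pseudocounted totals), so it is invariant to sequencing depth in
expectation. The Z statistic deliberately uses *raw* frequencies without
pseudocounts — it is the standard pooled two-proportion z-test, and its
null calibration would be distorted by pseudocounting. Where the pooled
frequency is 0 or 1 the variance vanishes and the statistic is undefined;
the convention is Z = 0 and p = 1 (conservative; only reachable in
degenerate one-group universes). p-values are upper-tail normal
(enrichment only); BH adjustment is the classic step-up, implemented as a
vectorized numpy kernel so that thousands of simulated experiments can be
adjusted in one call (cross-checked in the tests against both
statsmodels' `fdr_bh` and a loop-based transcription).

**Significance and ranking.** The default gate is z ≥ 1.645, the
one-sided standard-normal 95% critical value; FDR is reported but not used
as the default filter. Rows are ranked by z descending with deterministic
tie-breaks (log2 fold-change descending, then group id). The bait row is
retained and flagged rather than removed: recovering the bait as the top
hit is the screen's positive control. Note that when other preys are both
highly abundant and strongly enriched they can legitimately out-rank a
low-abundance bait on Z; the bait-recovery property holds for the
bait-only enrichment design.

## Pulldown simulation

Each run draws a fixed total of PSMs from a multinomial over the group
universe — conditioning on depth mirrors the compositional normalization
of the statistics (as opposed to independent Poisson counts). Background
binding propensities default to log-uniform over two orders of magnitude
(spectral counts span a wide dynamic range); bait and designated prey
groups have their propensity multiplied by an enrichment factor ≥ 1 in
bait runs only. The default configuration is one bait run against two
pooled GFP-control runs, 5,000 PSMs per run, 200 groups, bait enriched
50× — a single-bait screen design. Runs emit only groups with ≥ 1 PSM, as
real search-engine exports do.

The generator does **not** emulate peptide-level sampling, protein length
or detectability bias, run-to-run overdispersion beyond multinomial
noise, or carry-over between runs. Calibration results on it therefore
show that the statistics behave correctly under the stated sampling model,
not that real pulldowns are free of overdispersion (where the test will be
anti-conservative).

The null calibration experiment (1,000 pairs × 200 equal-abundance groups
at depth 10,000) yields the empirical specificity of the Z gate; with
~50 expected counts per group the normal approximation is good and the
non-rejection fraction sits at ≈ 95%.

## FRAP model

Normalization is the standard double normalization: the ROI trace is
divided frame-by-frame by an unbleached reference trace (removing
acquisition photobleaching and illumination drift common to both) and
scaled so the pre-bleach mean is exactly 1. Any positive rescaling of
either channel therefore leaves the analysis invariant.

Recovery is modeled as a single exponential
I(t) = F + (P − F)(1 − exp(−k t)) over post-bleach frames, with the floor
F pinned to the first post-bleach sample, and plateau P and rate k fitted
by least squares (`scipy.optimize.curve_fit`). Frames during the bleach
pulse are assumed absent; t = 0 is the first post-bleach frame. A
diffusion-reaction model or a two-component exponential is out of scope —
with hundreds of frames at 0.2 s the single exponential captures
organelle-exchange recoveries well, and the mobile fraction
(P − F)/(1 − F), clamped to [0, 1], is robust to the model choice.

Numerical choices: the rate is initialized at the reciprocal of the time
to half the apparent recovery and bounded to (1e-4, 1e3) s⁻¹; the plateau
starts at the mean of the last 10% of frames; a fixed grid of fallback
rate starts (0.01, 0.1, 1, 10 s⁻¹) guards against non-convergence, which
otherwise raises a fit error carrying the attempted starts. If the floor
reaches 1 (nothing bleached) the mobile fraction is reported as 0 rather
than dividing by zero.

The trace simulator applies a shared multiplicative acquisition decay
exp(−a·t) to both channels and independent Gaussian noise relative to
channel scale; its bleach depth defaults to 0.8 (floor 0.2). It does not
simulate diffusion during the bleach pulse, detector offsets, or focal
drift.

## Colocalization and profiles

Colocalization is the plain sample Pearson correlation of the two
channels over the pixels of a focus ROI mask, computed per z-section and
averaged (unweighted) per cell; sections whose mask has fewer than two
pixels or zero variance are skipped and counted. Pooling pixels across
sections is a documented alternative that weights sections by mask area;
per-section averaging was chosen as the per-cell aggregate. No Costes
randomization or Manders coefficients: the readout of interest is the
Pearson R. ROI masks come either from the user or from Otsu thresholding
of the reference (red) channel; Otsu on a constant section is an error.

Profiles are sampled along a polyline at 1-pixel arc-length steps with
bilinear interpolation, averaged across a perpendicular 3-pixel band, and
positions rescaled to [0, 1] (coordinates are 0-based pixel centers).
Normalization against the membrane-reference channel is a pointwise ratio
(with an optional reference floor to keep near-zero references from
exploding the ratio), not a global scaling — the reference is meant to
correct local geometry/expression, which a global factor cannot.

## Foci phantom calibration

Each synthetic focus is a Gaussian blob (σ = 3 px) whose sub-structure is
a mixture of a shared central component and two channel-specific
components displaced to opposite sides; the `overlap` parameter in [0, 1]
is the shared fraction. Two generator constants were calibrated once, by
scanning, so that the per-cell mean R under default noise lands at the
two anchor values of full vs. partitioned marker pairs: additive noise
sd 0.12 (relative to unit focus amplitude) sets R ≈ 0.85 at overlap 1,
and a sub-structure displacement of 0.53·σ sets R ≈ 0.45 at overlap 0.
Between the anchors the mean R is strictly increasing in overlap. The
partitioned case stays well above zero because both channels share each
focus envelope against a dark background — exactly the situation in real
images of sub-structured organelles, where "little colocalization" still
means substantially positive R. The phantom's sections are independent
2-D fields; no optical PSF, z-correlation or chromatic shift is modeled.

The axoneme phantom is a straight 3-px-thick line with a uniform
reference channel and signal confined to normalized positions ≤
`proximal_fraction`, lightly blurred (σ = 1 px) and noised; it exists to
validate the profile/ratio machinery, not to model cilium geometry.

## Problem sizes

Default analysis sizes — 1,000 simulated pairs for calibration, 200
replicates for bait recovery, 100 traces for FRAP error, 20 seeds per
overlap level — were chosen so each analysis completes in seconds on a
laptop while leaving Monte-Carlo standard errors well inside the decision
margins (e.g. SE < 0.001 on the calibration fraction over 200,000 tests).

## Known limitations

- The enrichment test assumes multinomial sampling; overdispersed real
  data will inflate the type-I rate. No spike-in or empirical-null
  correction is provided.
- Replicates are pooled, not modeled; between-replicate variance never
  enters the statistic.
- The FRAP fit fixes the floor at a single noisy sample, which feeds that
  sample's noise directly into the mobile-fraction estimate; with 0.02
  noise this contributes ≲ 0.03 error.
- ROI automation (Otsu) is a stand-in for expert manual ROI drawing and
  will differ from it on dim or crowded images.
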