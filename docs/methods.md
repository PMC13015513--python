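# Methods

## Model and assumptions

`refnorm` models the difference between a target coverage track and a
control track as the composition of two technical effects:

1. a multiplicative shift of the background (non-enriched) level, and
2. a distortion of true signal that is well approximated by an affine map
   in log2 space (depth differences, saturation/compression of strong
   signal, antibody-efficiency differences).

The correction is anchored on **internal reference regions** — sites assumed
invariant between the two samples (e.g. constitutive CTCF sites intersected
with the dataset's peaks). The assumptions this requires of the data are:
(i) the reference set really is stable up to a minority of violations, which
the Mahalanobis filter can remove; (ii) reference sites are enriched over
their local background; and (iii) background and signal levels are separable
in log2 space so a noise cutoff exists. All three are checked at run time
and produce explicit errors when violated (no enrichment → estimation error;
indistinguishable distributions → estimation error advising a manual noise
override).

The control is always the anchor: it is never transformed, and with several
targets each is normalized against the same control independently. Whether
one could instead normalize both samples toward a consensus is a design
question we resolved in favor of the fixed anchor — it keeps the correction
composable (tracks normalized in different runs against the same control are
mutually comparable) and avoids re-emitting the control with incidental
binning changes.

## Estimation pipeline

1. **Extraction.** Each reference site contributes a profile over
   center ± 4000 bp in 25-bp bins (320 columns). The central **signal
   window** is ±200 bp (the central 20% of the nominal ±1000 bp
   aggregate-plot window; the conventional metaplot scale for TF sites).
   The **background windows** are the [2000, 4000) bp flanks on both sides;
   background bins overlapping another reference site are excluded via an
   interval tree. Minus-strand sites are reversed. Missing track data is
   zero coverage; windows are clipped at chromosome ends with clipped bins
   set to zero — reference sites should therefore sit > 4 kb from
   chromosome ends, or their background estimate is diluted.

2. **Outlier filtering.** Per-site control/target signal means (signal
   window) are mapped to (M, A); squared Mahalanobis distances use the
   single-pass sample mean and covariance of all points, with removal above
   the χ²(2 df) quantile (default 0.99). Single-pass estimation is
   deterministic and simple, but exhibits classical *masking*: when several
   strong outliers are present they inflate the covariance and a weak
   outlier can escape the cutoff. A second pass after removal is available
   (`second_pass=True`) but is off by default. If the covariance is singular
   or ill-conditioned (e.g. identical samples make M constant), the filter
   falls back to independent robust per-axis z-scores (median/MAD) at the
   matching χ²(1 df) cutoff; the fallback is logged. An axis with zero
   spread flags only points that differ from the common value.

3. **Scale factors.** sfbg is the ratio of masked background means
   (control/target). sfsig is the ratio of background-subtracted
   signal-window means, so a pure background difference cannot leak into
   the signal scale; raw ratios are available behind
   `background_subtract=False`. Non-positive background-subtracted signal
   in either sample is a hard error ("no enrichment over background").

4. **Alignment.** With x = log2(control site means + c) and
   y = log2(sfsig · target site means + c), the z-score map gives
   α = sd(x)/sd(y) and β = mean(x) − α·mean(y) in closed form; applying
   ŷ = αy + β reproduces the control's mean and sd exactly. α ≤ 0 is
   impossible by construction; a non-positive user override is rejected
   because it would reverse signal ranking.

5. **Noise cutoff.** The classification rule compares *sfsig-scaled target*
   values to the cutoff, so both samples are pooled on that scale before
   density estimation: target background × sfsig, control background ×
   sfsig/sfbg, target signal × sfsig, and control signal through the
   inverse affine map 2^((log2(v+c)−β)/α) − c (which transports
   control-scale signal onto the sfsig-scaled target scale). A Gaussian KDE
   with Silverman bandwidth is fitted to each pooled log2 sample on a
   1024-point grid; the cutoff is the first density crossing between the
   background mode and the signal mode, refined by root bracketing. If the
   signal mode is not above the background mode or no crossing exists, the
   fallback is the midpoint of the two means (logged). The cutoff is
   reported in track units as 2^t − c, floored at 0. Pooling both samples
   (rather than using the target alone) stabilizes the cutoff when one
   sample is shallow; this was a genuinely open choice and is exposed by
   the `noise` override for users who disagree.

6. **Application.** The genome is tiled at 50 bp (configurable); bins with
   value·sfsig strictly above the cutoff take the signal branch
   2^(α·log2(v·sfsig + c) + β) − c (floored at 0), all others take
   v·sfbg. Ties at the cutoff are background — deterministic and
   conservative. One pseudocount c (default 1.0 track units) is shared by
   every log2 in the package; it is what keeps zero-coverage bins finite,
   and it is deliberately a *track-unit* quantity, so users working with
   very small signal values should scale it down.

Modes: `two-tier` (the default, everything above), `background-only`
(multiply every bin by sfbg; appropriate when the signal-to-background
contrast is too modest for a stable two-branch split, e.g. nucleosome
occupancy data), and `single-factor` (multiply every bin by one global
factor such as a spike-in read-count ratio; equivalent to
sfbg = sfsig = factor, α = 1, β = 0). Spike-in profile mode runs stages
1–5 on spike-in tracks/regions and returns the parameters (flagged
`spikein_profile`) for application to the endogenous target.

## Differential stage

Region means are computed over [start, end) in both tracks (missing data
= 0). The fold-change rule is (t+c)/(ctrl+c) ≥ cutoff for "up" and the
reciprocal for "down", boundary inclusive (a region at exactly the cutoff
is called). The Poisson test converts means to counts by multiplying by
the region width in bins (tracks store densities; the test needs counts),
floors both counts at `pseudo_floor` (default 1) so empty regions cannot
reach significance, and computes the exact two-sided p-value
p = 2·min(P[X ≤ k], P[X ≥ k]) with X ~ Poisson(exposure_ratio ·
floored control count), capped at 1. Benjamini–Hochberg adjustment is
applied across tested regions in Poisson mode by default (`adjust=False`
reproduces raw-p behavior). In `both` mode a region must pass both rules.
Overlapping input regions are analyzed as given. The BED outputs carry
round(M×100) clamped to [0, 1000] in the score column, per the BED format's
score range; for down-calls this clamps to 0, so use the sign of M in
`calls.tsv` for magnitude-aware downstream work.

## Synthetic data generator

`simulate_pair` emulates exactly the structure the model assumes: flat
background (1.0 track units), Gaussian-shaped peaks (sd 75 bp) at reference
and candidate sites with lognormal height spread (median 12× background,
log-sd 0.5 — gives a realistic spread of A values), multiplicative
lognormal bin noise (default σ = 0.05), and a target built by pushing the
control's latent signal through the *inverse* of the two-tier map:
background ÷ sfbg, bins above a latent threshold (2× background) through
the inverted log2-affine map. Unless β is dialed explicitly it is chosen so
the two branches agree at the threshold (a continuous distortion). Planted
differential candidates get a region-level fold change before distortion
(half up, half down); planted outlier references get an independent fold so
the filter has true positives. Sites are placed on a jittered grid snapped
to the bin raster, spaced so reference background flanks stay clean; the
default genome is 2 chromosomes × 500 kb at 50 bp bins so the full suite
runs in seconds, and the differential study uses 2 × 2 Mb to hold 500
candidate regions with the same geometry.

**Ground truth and identifiability.** The dialed (sfsig, α, β) of the
generative map are not jointly identifiable under the model's estimation
conventions: sfsig is pinned by the background-subtracted aggregate ratio,
which does not commute with the nonlinear log2 map, and β trades off
against log2(sfsig). `SimulationTruth` therefore records the *effective*
truth — the values the model's own parameter definitions take on the
noiseless latent tracks, computed by direct array slicing independent of
the estimation code. Recovery tests compare pipeline estimates (from noisy
data, through extraction and filtering) against these effective truths.
One consequence: for distortions with α ≠ 1 the applied correction is a
moment approximation fit on reference-site central means, so
near-threshold peak-shoulder bins retain a residual of up to ~10% after
normalization; for α = 1 (depth/background-type distortions) the map is
exactly invertible and profiles are restored to within the bin noise. The
tests encode both regimes.

What the generator does *not* emulate: read-level sampling (bin noise is
lognormal, not Poisson-binomial from reads), fragment-length and GC biases,
copy-number variation, non-flat background, or reference sites whose
stability degrades gradually rather than by a discrete fold. Passing tests
therefore demonstrate correctness of the estimation and application
machinery under the model's assumptions, not robustness to every failure
mode of real data — the QC outputs (background scaling, SNR, outlier
count, density plot) are what the analyst should inspect on real tracks.

## Numerical choices and degenerate inputs

- Sample sd uses ddof = 1 throughout; α is a ratio, so the convention
  cancels there.
- Alignment requires ≥ 3 sites and non-constant signals in both samples.
- KDE degenerate cases: a constant log2 sample skips the KDE and uses the
  midpoint-of-means fallback; identical background/signal distributions are
  an error advising a manual `noise` override.
- The α/β estimator is unbiased but its errors are strongly
  anti-correlated (slope/intercept trade-off); with 100 reference sites and
  5% bin noise, sd(β̂ − β) ≈ 0.02 in log2 units, so worst-case-of-many
  deviations of ~0.05 are expected sampling behavior, not bias.
- BigWig values are float32 on disk; round-trips are exact to that
  precision. Genome-wide binning loads one chromosome of per-base values at
  a time, which is appropriate up to mammalian chromosome sizes but not
  optimized for minimal memory.
- Exit codes: 0 success, 2 usage/config error, 3 data error, 4 estimation
  failure.

## Known limitations

- Single-pass Mahalanobis masking (above); enable `second_pass` when many
  reference violations are expected.
- No joint multi-sample normalization, no replicate-aware dispersion
  modeling in the differential stage (the Poisson test is conservative for
  over-dispersed data in the null direction, anti-conservative for truly
  under-dispersed counts), no peak calling, no BAM/FASTQ processing.
- Chromosome names are matched exactly; `chr1` vs `1` mismatches are an
  error by design, not silently harmonized.
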