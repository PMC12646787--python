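# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `eggid`, in the order the pipeline runs.

## Imaging

**Input contract.** An egg is a set of co-registered 2-D reflectance
rasters (`R, G, B, UV, LUM`, each in [0, 1]) with a boolean egg mask and a
pixel scale, long axis horizontal, blunt pole declared in metadata (an
automatic wider-half heuristic exists but is a flagged convenience — it
fails on nearly symmetric eggs). The working convention is 30 px/mm for
field photographs; the synthetic renderer defaults to 15 px/mm, which keeps
test images small while leaving every metric comfortably inside its
tolerance.

**Flat-field correction.** Each channel is divided by its Gaussian-blurred
version (division, not subtraction, preserves reflectance ratios under
multiplicative illumination), rescaled to keep the within-mask mean, and
clipped to [0, 1]. The blur kernel is edge-renormalised (convolution of the
image and of an all-ones raster share the same kernel) so borders are not
darkened, and the sigma is capped at half the smaller image dimension:
without the cap, the default 2048 px radius on a small crop degenerates to
a global mean and corrects nothing.

**Spot segmentation.** Phansalkar local thresholding,
T = m·(1 + p·e^(−q·m) + k·(s/R − 1)), with the local mean m and s.d. s of
luminance over a disk of radius 50 px (FFT convolution). Defaults
p = 2, q = 10, k = 0.25, R = 0.5 follow the original formulation as
implemented in common image toolkits. Pixels below T inside the analysis
mask are spots; components use 8-connectivity; zero spots is a valid
outcome. The analysis mask is the egg mask eroded by 3 % of egg width
(distance-transform erosion, equivalent to a disk structuring element),
which removes the darker egg rim that otherwise triggers false spots.

**Colour and luminance.** Means of each channel over spot and background
(analysis mask minus spots) pixels; a spotless egg copies background means
into the spot slots (with a warning) so the trait PCA never sees missing
values. The luminance histogram uses ten equal bins over [0, 1], the last
bin closed.

**Granularity spectrum.** Twelve scale fractions (1/√2)^i, i = 0…11
(1 down to ≈ 0.0221 of egg length) are realised as difference-of-Gaussians
band-pass filters with sigma ratio √2. The smaller sigma is d/5.336 where
d is the scale fraction times egg length in px: the DoG transfer function
e^(−2π²σ²f²) − e^(−4π²σ²f²) peaks at wavelength 5.336 σ, so each band's
peak response sits exactly at its nominal period (a sinusoid of period d
maximises energy at that scale, which the tests verify). Pixels outside the
mask are filled with the within-mask mean before filtering to suppress edge
bleed; because the fill tracks the mean, the +constant invariance and the
negative-image symmetry (equal energies, opposite skewness) hold exactly.
Energy is the s.d. of band-passed pixels per region, skewness the third
standardised moment (defined 0 when the s.d. vanishes). Spectra are
computed for the whole egg and its blunt/middle/sharp thirds (split at
thirds of the x-extent) — 12 × 4 energies plus 12 × 4 skewnesses all feed
the pattern PCA; a whole-egg-only variant (12 + 12 columns) is switchable
via `feature_groups(pattern_whole_only=True)` since the narrower reading of
the source protocol is also defensible.

**Spot metrics.** Mean component area (mm²), coverage (% of analysis
mask), and longitudinal dispersion: mean, population s.d. (n = 3) and
CV = s.d./mean × 100 of the per-third coverages (CV defined 0 when the mean
is 0).

**Shape metrics.** The egg is a solid of revolution about its long axis.
The half-width profile r(x) comes from per-column pixel counts (count/2),
lightly smoothed (Gaussian, σ = 2 px) and resampled to ≥ 400 stations.
Volume is π∫r²dx; surface is 2π∫√(r² + (r r′)²)dx — differentiating
g = r² rather than r keeps the integrand finite at the poles where r′
diverges. Both match closed forms for rendered prolate spheroids to well
under 1 % at 15 px/mm. Ellipse deviation is the mean absolute radial
difference between the outline (marching squares at 0.5) and its
least-squares ellipse, normalised by egg length; aspect ratio is
length/width. Masks touching the image border raise (clipped egg).

## Traits

Five separate PCAs on z-scored columns (means/s.d.s of the fitted table,
ddof = 1): colour (10 vars → 3 components), luminance (10 → 1), pattern
(energies + skewnesses → 2), spot pattern (5 → 2), shape (6 → 1). The
fixed counts replace scree-plot inspection for reproducibility and are
configurable. Constant columns are dropped with a warning. Each
component's sign is fixed so its largest-|loading| variable loads
positively — scores are then reproducible across fits and platforms.

**Trait ranking.** A 500-tree random forest classifies female identity
from the nine traits; importance is out-of-bag permutation importance
(mean decrease in accuracy): per tree, accuracy on the tree's out-of-bag
eggs minus accuracy after permuting one trait among them, averaged over
trees. Out-of-bag evaluation keeps noise-trait importances centred on zero
(training-set permutation importance is biased upward by the forest's
interpolation of noise). Negative importances are clamped to zero before
use as multiplicative weights. The published percentage-scale ranking from
the original 270-egg dataset ships as `REFERENCE_WEIGHTS`
(provenance "reference"); fitted importances are on a 0–1 accuracy scale,
so the two are proportional in role but not in magnitude.

**Weighting.** Weighted traits (trait × importance) are used only by the
Euclidean methods (MED, unsupervised identification). The same/different
classifier uses unweighted z-scored traits: per-feature monotone scaling
cannot change tree splits, so weighting a forest's inputs is a no-op.

## Identity statistics

*Variance metrics.* Within, per clutch: s.d. of each trait over the
clutch's eggs (ddof = 1), averaged over the nine traits. Between: s.d. of
the clutch-mean ("average egg") vectors across clutches, averaged over
traits. Clutches with one egg are excluded with a warning. A one-sample
t-test compares the per-clutch within metrics to the between value. Note
the null behaviour: shuffling clutch labels does *not* equalise the two
metrics — the between metric collapses toward 1/√(clutch size) of the
within metric, because means of random groups vary less than individuals.
The meaningful signature of true clutch structure is within < between, and
shuffling reverses it.

*Beecher's H_S.* Traits are decorrelated by a full PCA (components
truncated with a warning when eggs < variables); each component is tested
for a female effect by one-way ANOVA and significant components (p < 0.05)
contribute ½·log₂ F bits; F is capped at 10⁶ so degenerate (zero
within-variance) data stay finite. A label-shuffled control (stored seed)
estimates the noise floor. H_S is computed on the nine traits by default —
computing it on raw features instead is possible but correlated inputs are
exactly what the decorrelation step is meant to absorb.

*Laying order.* Per egg, the mean Euclidean distance (scaled traits) to
its clutchmates, averaged by laying position; clutches with incomplete
order are skipped. First/last-egg deviation is the standing confound of
outlier-based parasite detection.

## Detection

*MED.* All pairwise weighted distances within a clutch; per-egg mean over
its n−1 pairs; the maximum is the clutch's MED, compared with a threshold
(default 350). The threshold is only meaningful under the
percentage-scale reference weights — a warning fires for other provenance.

*Unsupervised.* Game 1: per-egg mean distance over its five pairs among
the six eggs, argmax called parasitic. Game 2: each candidate's mean
distance to the four known host eggs, excluding the candidate–candidate
pair (the competing candidate is equally suspect, so its distance is
uninformative); larger mean called. Exact ties return no call.

*Supervised.* Pair features are |Δ| of the nine z-scored traits — the
encoding is symmetric under egg swap, which makes the two comparison
directions of a pair identical; the "two comparisons per pair" convention
is then pure bookkeeping (each 'different' verdict credits both members
once per direction, so a game-1 egg accrues 2 × 5 comparisons per repeat).
Training draws 265 same and 265 different pairs uniformly without
replacement (with replacement plus a warning on small pools) from the
validation pool: leave-one-clutch-out excludes the tested clutch's five
eggs (the parasite egg, belonging to another female, stays — matching the
fixed published pool size of 265 = 270 − 5); leave-one-egg-out (game 2
only) adds the four regular-sequence host eggs and forces their C(4,2) = 6
same pairs into the training set. Votes accumulate over `n_repeats`
(default 10) independently re-drawn trainings of a 500-tree forest; the
egg with most votes is called, exact ties are reported ambiguous and
excluded from accuracy denominators — never broken.

Seed plumbing: a master seed spawns per-repeat `SeedSequence` children; an
optional classifier cache memoises fits keyed by (pool signature, repeat),
with the training seed derived from the pool signature so results are
identical regardless of call order. Caching exploits that a training set
depends only on the pool, not on the tested layout.

## Synthetic data

The trait-level generator draws female means ~ N(0, σ_b²·I₉) and eggs ~
N(mean, σ_w²·I₉), with optional additive shifts on first/last-laid eggs.
Defaults σ_b = 0.82, σ_w = 0.58 and 54 × 5 eggs reproduce the variance
metrics observed in real swallow clutches (and 0.82² + 0.58² ≈ 1 is
consistent with traits z-scored over the full egg set). Identity
covariance is the default because real traits are PCA scores and nearly
uncorrelated. What the generator deliberately does **not** model: trait
correlations, per-female differences in within-clutch variability (real
clutches range 0.30–1.06 in the within metric), non-Gaussian tails, and
measurement error structure. Consequences worth knowing: detection
accuracies on synthetic data run higher than on real eggs (the signal is
cleaner), and the leave-one-egg-out scheme cannot beat leave-one-clutch-out
here — its real-world advantage comes precisely from females differing in
variability, which an exchangeable generator removes. Passing tests
demonstrate correctness of the machinery and the direction of effects, not
field-realistic accuracy levels.

Zero identity signal means σ_b = 0 (eggs i.i.d.; same and different pairs
indistinguishable); equal sigmas σ_w = σ_b do *not* remove the signal —
they correspond to a strong signature (multiple correct-choice rates near
the real-data values).

The image-level renderer (prolate ellipse mask, anti-aliased disk spots
with per-zone density weights and minimum separation, per-channel
reflectances, optional multiplicative illumination gradient) exists to
exercise the imaging path against ground truth; it is deliberately
decoupled from the trait-level generator and makes no claim to
photorealism (no 3-D shading, no pyriform asymmetry, no spot texture).

## Problem sizes and statistical tolerances in the test suite

All sizes are chosen as the package's own defaults for a single-CPU run.
The heavy stochastic checks use: chance-level convergence — 1 026 trials
per game, one vote repeat, 50-tree forests, tolerance 3 binomial standard
errors at the realised number of decided trials; accuracy orderings — 540
shared trials at the calibrated spreads, three vote repeats, 100-tree
forests, paired one-sided sign tests on discordant trials (game 2 vs game 1
at p < 0.05; leave-one-egg-out assessed for non-inferiority, i.e. rejected
only if leave-one-clutch-out is significantly better, matching the "at
least as good" claim); variance recovery — 50 replicates of 54 × 5 eggs,
band ± 0.05. Forest size and repeat counts affect runtime and vote
granularity, not the chance level or the direction of orderings.

## Known limitations

- Shape metrics assume the long axis is horizontal in the raster; arbitrary
  orientations need a pre-rotation step.
- The granularity spectrum inherits DoG band overlap: adjacent scales are
  correlated by construction (σ ratio √2), which the pattern PCA absorbs.
- Phansalkar constants are tuned for dark-on-light maculation; light spots
  on dark ground would need the negative image.
- MED's absolute threshold is dataset- and weight-scale-specific; treat it
  as a calibration constant, not a biological quantity.
- `beecher_hs` uses one-way ANOVA per component and assumes balanced-ish
  clutch sizes; heavily unbalanced data would warrant a mixed model.
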