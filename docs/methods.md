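# Methods

This note documents the models and procedures implemented in
`embryoflow`, the parameters that matter, the synthetic ground truth the
tests rely on, and the numerical choices made where the design was open.

## Motion model

An embryo in its egg capsule is treated as a deformable body that can
rotate (in both directions at once, since different body parts may move
oppositely), translate, and twitch. The observable is sparse optic flow:
a set of corner features tracked between consecutive frames.

**Corner detection.** Shi-Tomasi minimum-eigenvalue response
(`skimage.feature.corner_shi_tomasi`, σ = 1.5) with non-maximum
suppression; at most `max_features` corners (default 400), relative
response threshold `quality` (0.01), minimum separation `min_distance`
(5 px), strongest first. An optional circular region-of-interest mask can
exclude clutter but is off by default — stray features on a static
capsule are tracked at near-zero velocity and do not bias the rotation
means appreciably.

**Tracking.** Pyramidal Lucas-Kanade, authored in-package. Per pyramid
level (default 3 levels, ×2 decimation after σ = 1 Gaussian smoothing)
the local translation of each corner is solved iteratively from the
spatial-gradient normal equations over a `window`×`window` patch
(default 21 px), coarse to fine, to `epsilon` = 10⁻³ px or 20 iterations.
Two deliberate choices:

* frames are pre-smoothed with a σ = 0.75 Gaussian before
  differentiation, suppressing sensor noise without measurable bias on
  clean imagery;
* patches are weighted by a Gaussian window (σ = half-width/1.5), which
  keeps a corner near a texture boundary from being dragged toward the
  interior gradient mass — without this, rotation rates of compact bodies
  are systematically underestimated because rim features' windows
  straddle the textured/flat boundary.

A feature is flagged lost when its gradient matrix is near-singular
(per-pixel minimum eigenvalue < 10⁻⁵), the solution diverges beyond the
window, the final position leaves the frame, or the mean photometric
residual exceeds `max_residual` (0.15 on unit-scaled intensities — an
uncorrelated-content match).

**Velocity-variance rejection.** Each feature keeps a trailing history of
its displacement magnitudes (window 15 frames). Once at least 3
observations exist, a variance above `variance_threshold`
(4 px²/frame²) marks the feature as unreliably tracked and removes it.
Rejected and lost features are replaced by re-detection, which is also
forced every 50 frames or when the retained count falls below half the
count found at the last detection epoch.

**Decomposition.** For the matched features of one transition, with
per-frame centroids c_prev, c_next: the centre-of-mass step is
v = c_next − c_prev, reported as (ρ, θ) = (|v|, atan2(v_y, v_x)). Each
feature's angular position about its own frame's centroid is differenced
and wrapped into (−π, π]; in screen coordinates (y down) a positive
difference is clockwise. `pos_angle` is the mean of the positive
differences, `neg_angle` the mean magnitude of the negative ones — means,
not sums, so the two series are comparable across feature counts, and
both are non-negative energy-bearing signals. Rotation is measured about
the feature centroid, not the image centre, because the embryo drifts
inside the capsule. Features within 10⁻⁶ px of the centroid are excluded
from rotation (undefined angle) but kept in the centroid. A transition
with no usable features emits zeros, never gaps, so downstream spectra
stay well-defined; `θ = 0` is likewise emitted when ρ = 0.

For a rigid rotation about *any* centre, this decomposition recovers the
rotation rate exactly (differencing against each frame's own centroid
cancels the induced translation), and a pure translation yields exactly
zero rotation — both are property-tested.

## Spectral fingerprint

Each of the four series is mean-centred (DC removed; no further
detrending) and transformed with a rectangular-window DFT. For length N
at fps f, coefficient k = 1…⌊N/2⌋ carries period N/(k·f) seconds and
energy (2/N²)|X_k|², so a unit-amplitude on-grid sinusoid contributes
energy exactly ½ at its period; the Nyquist coefficient of an even-length
series is not doubled. Squared magnitude (energy) rather than amplitude
is binned, which makes Parseval-style conservation testable: over any
gap-free partition of the period axis the bin sums equal the total non-DC
energy to 10⁻⁹ relative.

Bins are inclusive period ranges in seconds. Three presets are built in —
`DANIO_XENOPUS_18` (18 bins, 598–0.1 s), `RADIX_STAGE_18` (18 bins,
598–0.26 s) and `RADIX_STRESSOR_30` (30 bins, 300–0.13 s) — and custom
binsets load from the YAML config as `[hi_s, lo_s]` pairs. A coefficient
in an inter-bin gap contributes nowhere; one on a shared boundary (the
first preset's bins 6 and 7 overlap on [20.5, 21] s as published) goes to
the longer-period bin, a deterministic tie-break. Because binning is by
absolute period using each record's own N and f, fingerprints are
comparable across acquisition rates (7.5 vs 15 fps designs) and record
lengths; series are never padded or truncated.

The fingerprint concatenates the four binned vectors in the fixed order
(pos_angle, neg_angle, com_rho, com_theta) — 4 × 18 = 72 values for an
18-bin preset — and applies x ↦ ln(x+1), which tames the heavy right
tail of energies while keeping zeros at zero.

## Group comparison

**Bray-Curtis** d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on the non-negative
fingerprints (via `scipy.spatial.distance`); a pair of all-zero vectors
has no defined distance and raises with the offending ids.

**ANOSIM.** All n(n−1)/2 dissimilarities are rank-transformed (mid-ranks
for ties) and R = (r̄_between − r̄_within)/(n(n−1)/4) ∈ [−1, 1]. The
null distribution permutes group labels. When the number of *distinct set
partitions* of the individuals into groups of the observed sizes is at
most 200 000 they are enumerated exhaustively — enumerating partitions
rather than label vectors avoids double-counting label-swapped identical
splits in 2-group designs (two groups of six give 462, not 924) — and
p = #{R_perm ≥ R_obs}/total with the observed partition included.
Otherwise 9 999 seeded label shuffles (default) give the standard
(hits+1)/(perms+1) estimate. Identical seeds give bit-identical results.
Pairwise tables run the same test on each group pair's sub-matrix, with
significance coded *** p ≤ 0.001, ** ≤ 0.01, * ≤ 0.05, else ns, and no
multiplicity adjustment by default (a Bonferroni flag exists) — pairwise
screens of this kind are conventionally reported unadjusted.

**nMDS.** Non-metric MDS via SMACOF majorization alternated with
isotonic regression on the dissimilarity ranks
(`sklearn.manifold.smacof`, metric=False), 20 random restarts (seeded),
best solution by Kruskal stress-1. Note that at the non-metric optimum
the isotonic fit typically pools adjacent ranks into tied disparity
blocks, so embedded distances reproduce the input ranking only *weakly*
(no strict inversions); exact rank equality should not be expected even
at very low stress.

## Synthetic ground truth

The video generator renders a disc of Gaussian-blob texture rotating and
drifting inside a static capsule ring, resampled per frame with bilinear
interpolation from a single texture image, so the true per-transition
motion is known exactly and is expressed directly in the motion-record
vocabulary. Defaults: 192×192 frames, disc radius 60 px, capsule 88 px,
500 blobs of σ ≈ 1 px — chosen so ≥ 50 corners are detectable at
tracking defaults and a field-filling embryo is emulated; per-frame
Gaussian sensor noise sd 0.005 on unit-scaled intensities (≈ 1 LSB of an
8-bit monochrome camera). Blob centres are kept inside 85% of the disc
radius and the rim fades over ~6 px so that corners sit on body texture
rather than on the (rotationally near-symmetric) boundary.

The time-series generator sums per-series sinusoids, Poisson-timed
rectangular bursts (emulating tail flicks) and Gaussian noise, rectifies
the three non-negative series at zero and wraps θ into (−π, π]. Cohort
generation derives one child seed per individual from a master seed
(`numpy` SeedSequence), so whole studies are bit-reproducible. Default
study conditions mirror the acquisition design the package targets:
10-minute records, 7.5 fps, six individuals per group; "moderate noise"
is sd 0.3 against oscillation amplitude 1.0.

What the generators do *not* emulate: photorealistic embryo appearance,
heartbeat/blood-flow microtexture, non-rigid body deformation, occlusion
by the capsule, illumination drift, and compression artifacts. Passing
tests therefore demonstrate correctness of the measurement chain on
rigid-motion ground truth and the statistical machinery at realistic
noise levels — not tracker robustness to every failure mode of real
embryo footage.

## Numerical choices and edge cases

* Intensities are scaled to [0, 1] on load by the integer dtype's range;
  colour inputs are averaged over channels unweighted (the target cameras
  are monochrome).
* The motion CSV serialises with 17 significant digits and is parsed with
  round-trip float precision, so write∘read is the identity on float64.
* A static scene rendered without sensor noise tracks to exactly zero on
  all four series. With sensor noise the rotation means stay below
  10⁻³ rad and centroid jitter below 10⁻² px, but the jitter *direction*
  series is an isotropic random angle whose sample mean is not a
  meaningful quantity.
* Rotation-recovery accuracy at defaults is ≈ 2–4% low across spins of
  0.005–0.1 rad/frame (window-averaging bias of local flow); doubling a
  small spin doubles the recovered mean within 10%.
* Exact ANOSIM p-values include the observed partition in the count, so
  the smallest attainable p on two groups of six is 1/462 ≈ 0.0022.
* ANOSIM requires ≥ 2 groups with ≥ 2 members each; nMDS requires
  n ≥ dims + 1; spectra require ≥ 4 samples.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` validate on 40-frame videos
(192×192), 10-minute motion records at 7.5 fps, and 20 replicate
two-cohort studies of 6 + 6 individuals — sizes chosen to exercise every
code path, including exhaustive permutation inference, at desk-scale
runtimes.

## Known limitations

Single embryo per field of view; no segmentation of embryo vs capsule
(an ROI mask is the only containment tool); dense flow and wavelet/
short-time spectra are out of scope; automatic bin optimisation is not
provided (custom binsets are).
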