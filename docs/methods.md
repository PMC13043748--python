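# Methods

This note documents the models, estimators, parameter choices and known
limitations of `omdiff`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## FRAP model and estimator

A FRAP experiment is modeled as a 2-D spherocylindrical cell (default
3 × 1 µm at 0.0274 µm/px) carrying `n_particles` fluorophores, of which a
fraction `mobile_fraction` performs lateral Brownian motion with
`d_mobile_um2_s` (default 0.02 µm²/s) while the rest is static. Between the
last pre-bleach and first post-bleach frame, each particle inside a
rectangular bleach box (default 50 × 30 px at the cell pole) loses its
fluorescence with probability `bleach_depth` (default 0.85; the bleach is
treated as instantaneous because the laser-pulse train is not temporally
resolved). Frames are Gaussian-rendered particle-count images (unit σ of
1 px) scaled by a per-frame acquisition decay `acquisition_bleach_rate^k`
(default 0.995), plus a constant background (10 counts), Poisson shot
noise and Gaussian read noise (σ = 2). The default schedule is one
pre-bleach frame, five post-bleach frames at 1-s intervals, then 60, 120
and 300 s.

The double-normalized curve Î_t = (T̂_0·B̂_t)/(T̂_t·B̂_0) cancels the
acquisition decay exactly (both numerator and denominator scale by λ^k
after background subtraction), and the end-point estimator
(I_end − I_postbleach)/(1 − I_postbleach) is exactly unbiased under
complete mixing *regardless of the measured bleach region*: for any region
M with mean destroyed fraction β_M larger than the cell-wide destroyed
fraction βf, both the numerator and the denominator of the estimator are
proportional to (β_M − βf), which cancels. This is why modest segmentation
errors do not bias the mobile fraction. Incomplete mixing at 300 s is
negligible at the default geometry (slowest diffusive mode decays as
exp(−π²Dt/L²) ≈ 10⁻³).

Mobile fractions are reported raw — they can fall outside [0, 1] under
noise; the formula has no clamp — and outlier handling is left to the
distribution summary (Tukey 1.5×IQR fences, the convention the standard
box-plot software actually applies).

### Region identification

Operators are deliberately simple and deterministic:

* cell: Otsu threshold of the mean pre-bleach frame; among connected
  components, the one with the largest summed (pre − first-post)
  difference — i.e. the cell that was actually photobleached — falling
  back to the largest component if no difference exists;
* bleach: the (σ = 2 px smoothed) difference image thresholded at half its
  robust maximum (99.5th percentile inside the cell), morphologically
  closed. Smoothing is required because single-frame differences carry
  particle-count graininess much larger than per-pixel signal. A bleach is
  declared present only when the positive extreme of the difference
  exceeds 1.6× the negative extreme: pure noise and diffusive
  redistribution are near-symmetric about zero (measured ratios ≤ 1.5 on
  unbleached synthetic stacks across mobility 0–0.9), while a genuine
  bleach skews strongly positive (≥ 1.7);
* background: pixels below threshold in every frame, eroded by 2 px,
  excluding the bounding boxes of all above-threshold components.

Drift correction registers each frame's above-threshold mask to the
pre-bleach reference at integer-pixel resolution (sub-pixel registration
adds nothing at this magnification). The bleached region, dilated by 5 px,
is excluded from both masks: its disappearance after the bleach otherwise
drags the registration by several pixels. A shift exceeding 25 % of the
field aborts the cell (it moved).

With several pre-bleach frames, the *last* one is the normalization
reference. I_end is taken at the frame nearest 300 s when one exists
within ±30 s, otherwise at the last frame with a flag.

### Group comparison

`compare_mobile_fractions` uses the exact Mann–Whitney null distribution
for combined n ≤ 20 without ties and the tie-corrected normal
approximation otherwise; significance at P ≤ 0.05.

## SPT model and estimators

Trajectories are sampled at 30 Hz (default) with per-axis Gaussian
localization noise (default σ = 25 nm, contributing a constant 4σ² offset
to the MSD). Confinement is a circular disc with specular reflection of
the sub-step segment — the shape is a modeling choice; a disc is the
isotropic reading of a scalar "confinement diameter". Photobleach
lifetimes are geometric (memoryless single-step); after the drop, up to 5
trailing frames hold the last localized position at background intensity,
mimicking tracker death frames, so the step is present inside the attached
trace. The analysis pipeline trims a track at the detected change point
before computing its MSD.

* **MSD**: time-averaged over *all overlapping* pairs at each lag
  (overlapping vs independent pairs is a convention choice; overlapping
  has lower variance and is the common default). MSD(0) = 0 is included.
* **Immobility filter**: "end-of-trajectory MSD" is the mean over the last
  quarter of lags (robust to single-lag noise); retention requires it to
  exceed 0.008 µm² strictly. The localization-noise floor 4σ² =
  0.0025 µm² sits safely below.
* **Single-step bleach check**: the best two-level (one change point) fit
  must reduce the residual sum of squares ≥ 4-fold versus a constant fit;
  must not be beaten ≥ 4-fold by the best three-level fit (rejects double
  steps); must be at least as good as a straight-line fit (rejects
  monotone ramps, which the 4× rules alone admit — for a discrete ramp the
  constant/two-level SSE ratio is 4(n²−1)/(n²−4) > 4); and the step must
  be downward.
* **Classification**: a line through the origin is fitted to the first 4
  lags; the plateau ratio ρ compares the mean MSD over the 0.5–0.8 s lag
  window to the line's value at the window's mean lag. ρ ≈ 1 for free
  Brownian motion, ≲ 0.25 for hard confinement at the relevant scales;
  confined iff ρ < 0.6.
* **Diffusion fit**: ordinary least squares with a *free intercept* (the
  intercept absorbs the localization-noise offset 4σ², which an anchored
  fit would fold into D) over the first 4 (confined) or 13 (free) lags;
  D₂D = slope/4; a negative slope reports D₂D = 0 with a degenerate flag.
* **Confinement diameter**: d_confine = 2·√(6·MSD_average) with
  MSD_average the mean MSD over lags in the closed 0.5–0.8 s window.

### The two confinement-diameter conventions

The relation MSD_average = (d/2)²/6 does **not** equal the stationary
plateau of a disc of diameter d: two independent uniform points in a disc
of radius R satisfy E|x₁−x₂|² = R², i.e. plateau = (d/2)². The package
implements the printed factor-6 relation verbatim, so an estimate from a
disc of geometric diameter d_geo (plus noise floor 4σ²) converges to
2·√(6·(d_geo²/4 + 4σ²)), about √6 ≈ 2.45× the geometric diameter at zero
noise. Synthetic-recovery tests state which convention they use; the
generator's ground truth records the geometric disc diameter.

### Classification accuracy is estimator-variance limited at short tracks

At the study scales (1.5-s tracks at 30 Hz), the time-averaged MSD of a
*single* track at lags 0.5–0.8 s has a relative sampling standard
deviation near 0.4–0.5 and is strongly right-skewed, so the per-track
plateau ratio of a free walker has median ≈ 0.81 (not its theoretical
0.92) with a heavy left tail. Measured accuracy of the ρ < 0.6 rule on
200 + 200 tracks is ≈ 86 %, and sweeping the threshold over [0.4, 0.6]
cannot raise it above ≈ 89 % — the limit is the discriminant's variance,
not the cut-point. Accuracy rises with track duration (≈ 95 % at 6 s,
≈ 98 % at 10 s, → 1 asymptotically); the corresponding property test
checks the 10-s behavior. This is the motivation for the richer (e.g.
learned, multi-feature) classifiers used by tracking software on short
trajectories; a deterministic single-statistic rule was chosen here for
reproducibility and is documented as such.

## Co-localization and islands

PCC is computed exactly as the standard Pearson formula over masked
pixels. The mask realizes the "minimal threshold from the lower-signal
channel" as the ISODATA (iterative intermeans) criterion: T ←
(mean below + mean above)/2 from the mid-range start until the change is
< 0.5 intensity units; a uniformly bright channel yields a full-frame mask
and a dark constant channel is an error. Island height/width use
axis-aligned calipers: extent of the pixel *footprints* (corners, not
centers) along the component's principal axis and perpendicular to it.
Calipers on the principal axis, rather than the max-Feret pair, keep an
axis-aligned rectangle's height equal to its side rather than its
diagonal. Components with height ≤ 50 nm are discarded; 8-connectivity;
boundary-touching islands retained.

## Patch-map generator: two study configurations

* **Co-localization configuration (default)**: a 2.2 × 1.4 µm cell
  footprint inside a 2.56 µm field at 10 nm/px, a uniform in-cell
  "membrane" localization density (3000 µm⁻²), 25 circular patches per
  channel (lognormal diameters, median 0.22 µm) at 1.5× the base density,
  localization precision 20 nm, dark exterior. The modest patch contrast
  is what makes the minimal ISODATA threshold select the whole cell
  rather than the patches, as the masking step intends. Anti-correlation
  strength −1 makes cross-channel patch discs disjoint (the rejection
  region is the other channel's disc inflated by the new patch's radius);
  intermediate strengths reject overlaps with that probability; positive
  strengths co-locate patch centers.
* **Morphometry configuration** (`PatchMapParams.for_morphometry()`):
  sparse high-contrast patches (30 000 µm⁻² vs 100 µm⁻² background) over
  the whole 5.12 µm field, non-overlapping within the channel, so ISODATA
  isolates individual patches for size measurement.

What the generator does *not* emulate: membrane curvature and the
projection of a cylindrical surface into 2-D (tracks live in a plane),
blinking/re-activation statistics and localization multiplicity of real
single-molecule maps, structured backgrounds, cell-to-cell size variation,
and intensity-dependent localization precision. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every artifact of real microscopy data.

## Numerical choices and degenerate inputs

* Brownian propagation inside the cell uses sub-steps bounded so the step
  σ is ≤ 0.2× the cell radius (capped at 256 sub-steps per interval;
  beyond that, large steps merely resample toward the uniform stationary
  distribution). Steps leaving the cell are redrawn (up to 20×), which
  approximates a reflecting boundary.
* Disc reflection solves the quadratic wall-crossing exactly and reflects
  the residual segment, iterating (≤ 64×) for multi-bounce steps.
* Problem sizes in the test and acceptance runs (30 cells per FRAP
  condition, 200 tracks per SPT set, 50 patch-map seeds) were chosen so
  median/ensemble statistics are stable at a few percent while a full run
  completes in a couple of minutes.
* Mann–Whitney with ties always uses the tie-corrected approximation;
  identical samples give U = n²/2, P = 1.
* ISODATA on a constant image, PCC with zero variance or a < 2-pixel
  mask, an empty region mask, a non-positive normalization reference, and
  a bleach box outside the image all raise typed errors
  (`omdiff.errors`).
* All generators take integer seeds; identical seeds give bit-identical
  outputs, and every derived seed stays below 2³¹.

## Known limitations

* The confined/free classifier is a single-statistic rule; on 1.5-s
  tracks its accuracy is variance-limited near 86 % (see above). Directed
  motion is never assigned.
* Drift correction is integer-pixel and assumes the cell outline
  dominates the threshold mask.
* The FRAP camera model (Poisson + Gaussian read noise on
  Gaussian-rendered counts) is generic, not calibrated to a specific
  detector.
* Raw-video spot detection and linking are out of scope; the SPT entry
  point is a track table. The upstream tracking constants
  (0.096 µm/px, 0.4 µm max displacement, 5 death frames, 12-frame
  minimum, eccentricity 1.7) are recorded in
  `omdiff.spt.TRACKING_METADATA` for provenance only.
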