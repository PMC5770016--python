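# Methods

## Model and procedure

Dentin accretes by circadian pulses of mineralization, so each day leaves
one dark incremental line in stained sections. If a Growth Layer Group
(GLG) of thickness *T* μm along the growth direction accumulates over *d*
days with mean daily increment *m* μm, then *T* = *d·m* in expectation;
hence the estimator *D* = *T*/*m̂* for the days a GLG represents, where
*m̂* is the sample mean of measured centre-to-centre line spacings. Under
annual deposition *D* ≈ 365, under semi-annual deposition *D* ≈ 182.5;
equivalently the observed mean spacing can be compared with the
predictions *T*/365 and *T*/182.5.

Assumptions worth stating explicitly:

* **Constant deposition rate within a GLG.** Only a fraction of each GLG
  is legible; days are estimated from *total* thickness over the mean of
  *readable* spacings, which imputes unreadable stretches at the readable
  rate. The readable fraction (summed readable length / thickness) is
  always reported next to the estimate so the weight of this assumption
  is visible. No within-GLG trend (e.g. seasonal slowdown) is modelled.
* **Error convention.** Uncertainty on *m̂* is quoted as 3·SE
  (SE = sd/√n with the sample, n−1, standard deviation; the multiplier is
  configurable via `ChronologyConstants`). Pushing *m̂* ∓ 3·SE through
  the ratio gives asymmetric day bounds
  *err⁻* = *D* − *T*/(*m̂* + 3·SE), *err⁺* = *T*/(*m̂* − 3·SE) − *D*,
  with *err⁺* > *err⁻* by convexity of 1/x. This inversion rule is the
  package's inference; a brute-force scan in `scripts/acceptance.py`
  confirms it reproduces the packaged reference dataset's published
  bounds within their printed rounding. When 3·SE ≥ *m̂* the upper bound
  is unbounded and an error is raised rather than a number invented.
* **Hypothesis call.** The published comparison was visual; a
  reproducible rule is needed here. A GLG "supports" the hypothesis whose
  predicted spacing is nearer its observed mean; both distances (in units
  of 3·SE) and the day-interval coverage of 365 and 182.5 days are
  reported so users can apply a different criterion. Equidistance is a
  tie; 3·SE = 0 yields infinite distance flags and coverage only.
* **Aggregation** across GLGs is the unweighted mean of each numeric
  column (each GLG counts once, not weighted by its n), matching how
  cross-GLG averages are conventionally tabulated.
* **Shrinkage.** Demineralized sections shrink relative to ground
  sections; a single multiplicative factor
  `spacing / (1 − shrink_fraction)` restores demineralized spacings
  toward ground scale. Periodicity (and hence the annual/semi-annual
  call) is unaffected by a global scale factor.

## Line detection

Measurement paths follow the dentin tubules (the growth direction), as a
user-supplied polyline; the package never infers tubule direction.
Stages, all with μm units and pixel coordinates 0-based at pixel centres:

1. **Focus projection** of a z-stack: each output pixel is copied from
   the plane with maximal local intensity variance (9 px window) — a
   simplified extended-depth-of-field composite.
2. **Profile extraction**: bilinear sampling every `step_um` (default:
   one pixel; never finer than the raster by default) of arc length,
   averaged over `normal_window_px` points perpendicular to the path.
3. **Detrending**: subtraction of a centred running mean (default 20 μm;
   forced to an odd sample count so a linear ramp is removed exactly).
   A 20 μm window attenuates a 1.65 μm sine by under 3%.
4. **Centre picking**: dark lines are local minima with prominence ≥
   `prominence_rel` (default 0.1) × interquartile range, separation ≥
   `min_separation_um` (default 0.8 μm ≈ half the smallest plausible
   daily spacing; conflicts resolved in favour of the more prominent
   minimum), refined by a 3-point parabola to sub-sample precision.
   Before peak picking the profile is low-passed with a Gaussian of
   sigma `smooth_um` (default 0.25 μm, matched to the ~0.4 μm line
   width): without it, uncorrelated pixel noise seeds spurious minima
   between lines (≈40% extra detections at the generator's default noise
   level; ≈0.3% with it). Unreadable stretches simply yield no centres;
   missing lines are never interpolated — imputation happens only at the
   day-estimation stage.
5. **Spacings**: consecutive centre differences, positioned at pair
   midpoints — one measurement per line pair.
6. **GLG thickness** is the arc length between user-supplied boundaries
   on the same profile (curved paths give arc length, not chord).
7. **Spectral cross-check**: a Welch periodogram (zero-padded, linear
   detrend per segment) restricted to a period band; the peak must stand
   ≥ 10× above the median in-band power, which rejects white noise. This
   estimator is an independent oracle for the mean spacing, never the
   primary measurement.

## Synthetic dentin

The generator defines the study conditions for every recovery test.
Defaults: 7 GLGs × 365 days at mean spacing 1.65 μm (so ~602 μm GLGs,
inside the observed 409–712 μm range), lognormal daily spacings with
cv = 0.2, readable fraction 0.35 (the observed readable fractions average
≈ 0.3–0.37, and 0.35 of 365 days ≈ 128 emitted spacings per GLG, inside
the observed 113–220), images at 0.1 μm/px so one period spans ~16 px,
line FWHM 0.4 μm and depth 0.25 of the matrix brightness, GLG modulation
0.15, calcospheres at 0.3 per 1000 μm² with radii 2–6 μm, 2 tubule
streaks per 100 μm, noise sd 0.05. The daily-spacing distribution is
lognormal for positive support and mild right skew; it is pluggable and
nothing downstream depends on the choice at these cvs.

Readability is masked in contiguous blocks (2–5 per GLG), not i.i.d.
dropout, mirroring how legibility fades in and out laterally in real
sections; the per-GLG readable fraction wobbles ±0.03. Thickness is the
*exact* sum of the GLG's daily spacings, so cv → 0 recovery is exact by
construction and any bias observed at cv > 0 is attributable to the
estimator, not the generator.

Images are rendered from a deposition-time field u(x, y): the minimum of
the planar front (u = x) and one spherical wavefront per calcosphere
(`x_c − r + ‖p − c‖`). The minimum of 1-Lipschitz functions is
1-Lipschitz, so iso-lines (the incremental lines) never cross, and they
wrap arcuately around calcospheres exactly as globular dentin looks.
Daily lines are Gaussian intensity dips at the drawn deposition times
along u. A consequence kept deliberately: a straight transect near a
calcosphere can cross the same arcuate line twice, as in real material —
which is why GLG boundaries (and the paths users draw along tubules)
matter for clean counts. The focus-stack generator blurs the micrograph
with a smooth random depth map so each region is sharp in exactly one
plane.

## What the synthetic data does not emulate

Staining chemistry and its spatial artifacts, section-thickness effects,
stitching seams, sub-daily (intra-dian) lines, and any within-GLG
deposition-rate trend. Passing recovery tests therefore shows the
estimator chain is correct and robust to the modelled degradations
(noise, patchy readability, arcuate warping, defocus), not that real
sections of arbitrary quality can be read automatically.

## Numerical choices and problem sizes

* Detection distances are enforced in integer samples
  (`round(min_separation/step)`), and parabolic refinement is clipped to
  ±half a sample; border round-off in profile sampling is tolerated at
  1e-6 px. Images render in float32; u-field comparisons therefore carry
  ~1e-3 μm round-off.
* The spectral-vs-spacing agreement check uses noiseless profiles at
  cv = 0.1. This is deliberate: the spectral peak of a renewal-jitter
  line comb is displaced from the mean interval by O(cv²), so at cv = 0.2
  the two estimators measure genuinely different quantities (~4% apart by
  construction) and the comparison stops being an implementation check.
  At cv = 0.1 the displacement is ≤ ~1% and observed disagreement is
  ≤ 3.6% over 10 replicates.
* Default end-to-end image runs render 7 GLGs (~42 000 × 500 px); one
  such render plus detection takes ~30 s on one core. Detection-level
  unit tests use single short GLGs (80–120 days) to stay fast.
* All randomness flows through a single integer seed per simulated
  dataset; identical parameters give bit-identical outputs, and every
  written table carries the package version and a config hash.

## Known limitations

* The packaged reference dataset carries only per-GLG summaries (the raw
  spacings were never published), so reference-dataset checks operate on
  summary statistics; raw-spacing workflows are exercised on synthetic
  data only.
* Recomputing day estimates from the published *rounded* means shifts
  the 7-GLG average from 354.22 to 354.39 (+0.05%) and individual bounds
  by up to ~3%; both are reported rather than reconciled.
* GLG segmentation is out of scope: boundaries are user-supplied, since
  ambiguous boundaries are precisely the case practitioners exclude.
* The hypothesis call assumes exactly two candidate deposition rates;
  other periodicities (e.g. lunar sub-layers) are not modelled.
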