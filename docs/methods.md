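# Methods notes

This note records the model, the numerical choices, and what the synthetic
phantom does and does not establish. Units throughout: mm, mm², mm³ for
geometry (cm³ in reports), ms for time, s⁻¹ for normalized rates.

## Tracking

NCC is the zero-mean normalized (Pearson) correlation of a fixed template
against every fully contained placement inside a search window, computed
densely (stride 1). Choices:

* **Window sizes.** The classical 20-px template / 40-px search squares are
  realized as odd 21/41 windows so the tracked point is a true center
  pixel; results are insensitive to the precise size. `TrackConfig`
  exposes both.
* **Tie-breaking.** The correlation argmax takes the first occurrence in
  row-major order — deterministic by construction.
* **Borders.** The search window is clipped at image edges; placements
  without full template support are never scored. Seeds are clamped
  inward so the initial template has full support.
* **Zero variance.** A constant template is an error ("untrackable
  feature"); a constant placement gets −∞ and can never win.
* **Sub-pixel refinement** (3-point parabolic) exists behind
  `TrackConfig(subpixel=True)` but is off by default: the method is defined
  at pixel resolution, and all validation bounds below assume that.
* **Drift.** Chained matching accumulates per-step rounding as a random
  walk; on the noiseless default phantom the worst-case error is ~1 px and
  the RMS ≤ 2 px over a full cycle. This is inherent to pixel-level
  chaining — it is exactly what the interactive correction step exists
  for. Corrections are replayed from a JSON file (view, point, phase, row,
  col); positions before the corrected phase are untouched, everything
  after is re-tracked.
* **Quality control.** Phases whose peak correlation falls below
  `min_corr` (default 0.5) are flagged in the tracking log as candidates
  for correction. The threshold is a package decision, standing in for
  interactive visual review in batch mode.

## Reconstruction and sweep volume

* **Coordinates.** DICOM LPS patient space; 0-based fractional pixel
  indices address pixel centers. `pixel_to_patient` is the standard affine
  map built from ImagePositionPatient, ImageOrientationPatient and
  PixelSpacing (first orientation triplet = direction along a row, i.e. of
  increasing column; PixelSpacing[0] = spacing between rows).
* **Frame ordering / timing.** Series sort by TriggerTime, falling back to
  InstanceNumber; phase 0 is end-diastole (retrospective gating). RR comes
  from NominalInterval, else P × mean inter-trigger spacing; the source is
  logged since either tag may be absent.
* **Point ordering.** The six labelled junction points are sorted by angle
  about their centroid in the best-fit plane, counter-clockwise, starting
  at the four-chamber septal point. Coincident or near-collinear
  configurations are errors.
* **Spline.** Closed periodic cubic, chord-length parameterized, through
  all six points, resampled at N = 120 uniform parameter values (doubling
  N changes areas by < 0.1 %, verified in tests).
* **Area of a saddle-shaped ring.** Defined as the triangle fan about the
  sample centroid with each triangle's vector area projected onto the
  best-fit plane normal (signed sum, absolute total). This reduces to the
  shoelace area for planar rings and converges with sampling; the annular
  area of a non-planar curve has no unique definition, so this one is
  isolated in `annulus_area_centroid`.
* **Long axis.** A fixed direction per study: the end-diastolic best-fit
  plane normal, oriented toward the side the centroid moves during systole
  (the apex). A fixed axis prevents sign flips from frame-to-frame normal
  jitter. Plane normals of later phases are sign-aligned to it.
* **Quadrature.** `V_n = ½ (A_{n−1} + A_n) d_n` — the trapezoid (frustum)
  rule, second-order accurate; exact for a translating rigid ring and
  within 0.1 % of the cone-frustum closed form at 100 phases.
* **Closure.** The wrap increment from the last phase back to phase 0 is
  computed and logged as a closure residual but not added to the curve; a
  large residual indicates tracking drift.
* **End-systole.** Argmax of the cumulative curve. Pixel quantization can
  flatten the systolic peak into a tied plateau; the middle of the maximal
  plateau is then used (any tied index leaves the normalized curve at 1
  there, and the midpoint is the least-biased time estimate).

## Diastolic parameters

* The recovery rate is −d(normalized)/dt by central differences on the
  periodic phase grid (spacing RR/P); recovery is reported positive, and
  the signed derivative is kept alongside.
* **Automatic segmentation** stands in for manual slope-transition
  division: within diastole, rate maxima with prominence ≥ 10 % of the
  peak rate give the E (first) and A (last) waves; the ED end / AS onset
  boundaries are the rate minima after/before those peaks. On a flat
  diastasis the minimum is non-unique, so the boundary is placed at the
  plateau edge — the first/last sample whose rate enters a band 5 % (of
  the smaller peak height) above the inter-peak minimum. Fewer than two
  qualifying peaks raises an E/A-fusion error, and every boundary can be
  overridden manually (MD end snaps to an overridden AS onset unless
  pinned itself).
* **DT_SV** fits a least-squares line to the monotone descending rate
  samples from the E peak toward the next minimum and extrapolates it to
  zero; with 25 phases a two-point tangent is unstable, the fitted line is
  deterministic. **AT_SV** is the E-peak time minus ED onset.
* **DSVRT_50** is the linearly interpolated first crossing of the
  normalized curve below 0.5 after end-systole, as % of RR. The crossing
  is searched only within sampled phases — the periodic wrap back to the
  phase-0 value is reconstruction, not recovery, so a curve that never
  reaches the threshold is flagged (`incomplete_recovery`), not
  extrapolated. The 0.5 threshold is the published choice (alternatives
  classify worse) but remains a parameter for research use.
* Percentage recoveries use interval *endpoint* values of the normalized
  curve (not within-interval extrema). Absolute volumes are the
  percentages times ESSV; ratios to stroke volume appear only when a
  stroke volume is supplied.

## Phantom

The phantom prescribes the annular centroid's axial displacement z(t):
half-cosine systolic descent (default 12 mm over 35 % of RR), then an
E-wave raised-cosine velocity pulse recovering `e_fraction` (default 0.7)
of the descent in early diastole (20 % RR), a diastasis plateau (25 %),
and an A-wave pulse recovering the remainder (20 %). Raised-cosine pulses
are smooth, with closed-form integrals and peak velocities, so prescribed
E:A peak ratios and recovered fractions are exact. With both `e_fraction`
and `ea_peak_ratio` pinned, pulses are narrowed inside their intervals to
honor the ratio; `spec_for_peak_ratio` instead co-varies `e_fraction`
(= ρ·T_ED/(ρ·T_ED + T_AS), full-width pulses) the way filling fraction
and e′/a′ co-vary physiologically — that constructor defines the
conditions of the E:A monotonicity sweep, keeping both pulses resolvable
at 25 phases across ratios 0.5–3.0.

Rendering: three planes through the long axis at 0°/60°/120°, 96×96 px at
1 mm, a 15 mm-radius ring with a ±2 mm saddle, simple blood-pool and
myocardium bands, and high-contrast textured blobs centered on the exact
(fractional) annulus–plane intersections. Ground truth (continuous pixel
trajectories, analytic sweep curve, parameters computed from the dense
analytic profile with the same diastology code) is captured before
optional blur/noise; rendering is deterministic under a fixed seed.

What the phantom does **not** emulate: SSFP tissue contrast and banding,
through-plane motion, respiration, arrhythmia, anisotropic pixels, or
realistic junction appearance. Passing tests therefore establish the
geometry/numerics of the pipeline, not tracker robustness on clinical
images — on real data the correction workflow and QC flags carry that
load. Sizes used in validation (25–100 phases, 96–512 px frames) were
chosen so the full suite and the acceptance script run in seconds.

## Cohort statistics

Spearman uses average ranks with the large-sample p approximation. ROC
AUC is trapezoidal over all thresholds; the reported cutoff maximizes
accuracy with ties broken toward higher specificity, and `direction`
states which tail of the score is disease-positive. Bland–Altman is mean
difference ± 1.96 SD. The ICC is the two-way, absolute-agreement,
single-measure form (ICC(A,1); the standard choice for two fixed readers)
with an F-based 95 % CI — the form is configurable because reported ICCs
are not comparable across forms. A labeling helper implements the
reference rule (septal e′ < 8 cm/s, lateral e′ < 10 cm/s, or LA volume
index ≥ 34 mL/m²) so synthetic cohorts can be auto-labeled.

## Known limitations

* Six points under-sample a strongly non-planar annulus; the spline area
  is a smooth-ring idealization (~0.5 % low for a circle).
* Pixel-level tracking quantizes the descent (≈1 px floor on ESSV and
  descent-derived times at 1 mm spacing); sub-pixel refinement is
  available but off by default.
* Automatic segmentation needs two separated rate peaks; E/A fusion
  (tachycardia, heavy noise) requires manual boundaries.
* The sweep curve does not close exactly under tracking drift; the
  residual is logged, not redistributed.
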