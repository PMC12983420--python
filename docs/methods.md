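# Methods

This note documents what the package computes, the assumptions behind it,
the parameters that matter, and what the synthetic validation does and does
not establish.

## Coordinate conventions

Image coordinates are raster: x = column (rightward), y = row (downward).
An ROI rectangle is stored by its *origin* — the bottom-left corner in
anatomical display orientation (smallest column, largest row) — plus width
and height; the origin is the tracked point whose trajectory all metrics
describe.

The pelvic frame is anchored at the inferior pubic point (IPP). Its +x axis
points from the IPP toward the annotated tangent point (the annotator must
click the tangent point *posterior* to the IPP, on the line tangent to the
inferior pubic margin); +y is the perpendicular pointing superiorly.
Because image rows grow downward while anatomical +y is superior, one sign
flip is applied — in `pelvic_frame` and nowhere else. Rotations in the
pelvic frame are positive counterclockwise in anatomical display (posterior
axis sweeping toward superior).

The frame is *rigidly transported* by the tracked pubis pose each frame
rather than re-detected: the pubis is bone, so its image motion is exactly
the probe–pubis confounder, and attaching the frame to it removes that
confounder from every trajectory. Whether one should instead re-fit the
tangent line per frame is untestable without real data; rigid transport is
the assumption made here.

## Tracking model

Sparse feature tracking with a rigid pose model:

- **Detection.** Shi-Tomasi corners (`skimage`), structure-tensor sigma 0.5,
  response threshold 1 % of the maximum, minimum mutual distance 2 px,
  detections kept `detect_margin_px` (5 px) away from the rectangle edge.
  The 2-px spacing with the small integration scale is what makes speckle
  yield 50+ features per 40 × 40 px window; at 3-px spacing the response
  field's own smoothness caps the count far lower regardless of texture.
- **Flow.** Pyramidal Lucas-Kanade, 21-px windows with Gaussian weighting
  (sigma = 5 px), 3 levels, iterated to 0.02 px. The window weighting
  matters: unweighted windows straddling a moving-patch boundary produce a
  *consistent* (forward-backward-stable) bias toward the background motion.
- **Validity.** A point survives a frame step only if (i) its structure
  tensor is well-conditioned, (ii) its backward-tracked position lands
  within `fb_tol_px` (1.0 px) of where it started, and (iii) the normalized
  cross-correlation between its template and matched patch is ≥ 0.5. The
  backward pass is seeded with the negated forward flow and run at full
  resolution only (a cost choice); the NCC check is what catches
  geometrically self-consistent but wrong matches (decorrelated speckle,
  occlusion, uncorrelated frames).
- **Pose.** Per frame step, a 2-point-sample RANSAC (inlier threshold 2 px,
  100 iterations, seeded) selects a consensus, followed by a closed-form
  2-D Kabsch refit on the inliers. Rotation + translation only: the
  segmental metrics are positions and rotations of rigid segments, so scale
  and shear are deliberately excluded. Poses compose frame-to-frame;
  features are re-seeded inside the current ROI pose when fewer than half
  the original points survive. Frame-to-frame matching (not
  frame-0-to-frame-t) is used because speckle decorrelates over long
  intervals; the resulting drift is not assumed away but measured against
  synthetic ground truth (RMS ≈ 0.05–0.1 px over full loops at default
  noise, versus a 0.5 px accuracy contract).

## Kinematic metrics

All metrics derive from pelvic-frame pose series, with frame 0 as the rest
frame (configurable):

- Δx, Δy, Δθ: pose(t) − pose(rest).
- |d| = √(Δx² + Δy²) and φ = atan2(Δy, Δx) ∈ (−180°, 180°]. φ computed from
  sub-resolution motion (|d| < 0.1 mm) is flagged unreliable and excluded
  from direction averages — tiny positional noise makes the angle
  meaningless.
- Kink angle ω: the signed angle between (mid − proximal) and
  (distal − mid); magnitude from the vector angle, sign from their 2-D
  cross product, so ω > 0 means the chain is convex toward anterior. The
  sign convention is a package choice (the distinction in the field is
  convex vs. concave without a printed formula); it is mirror-consistent
  and rotation/translation invariant.
- Relative mobility r = (|d|_lower − |d|_upper) / Δy_rest, normalized by the
  *rest-frame* superior–inferior distance between segment origins. Using
  the rest distance (not the per-frame distance) keeps r a pure function of
  displacement. Negative r = proximal-dominant motion. Both signed r and
  |r| are available; the signed value is canonical.
- Maximum excursion: the frame maximizing the proximal segment's |d|
  (bladder-neck descent being the clinically emphasized quantity); ties
  break to the earliest frame. The selection segment is configurable.
  Best-of-repetitions trial selection maximizes the same statistic.

## Statistics

- SD uses the n−1 denominator; SEM = SD/√n; CV = round(100·SD/|mean|). The
  absolute value makes CVs of negative-mean direction metrics positive;
  circular statistics are not used because the reference tables this
  mirrors are plainly linear SD/mean ratios.
- The 2 × 3 mixed ANOVA uses the classic split-plot decomposition (between:
  group; within: maneuver), p-values from the F distribution, no sphericity
  correction (recorded in the result metadata). It is cross-checked in the
  tests against both an explicit-loop sums-of-squares oracle and
  `pingouin.mixed_anova`, and its type-I error rate is verified near the
  nominal 5 % on null simulations with random subject intercepts.
- Pairwise families: per segment and metric, 3 independent (group at each
  maneuver, pooled-variance t) + 2 paired (cough vs. Valsalva within each
  group) contrasts; Bonferroni multiplies by the declared family size
  (m = 5) and caps at 1. The family is explicit and configurable because
  published practice rarely states m.
- Degenerate inputs: zero within-cell variance yields F = 0 (p = 1) for a
  zero-SS effect and F = ∞ (p = 0) for a nonzero effect over zero error;
  incomplete repeated-measures cells raise an error rather than being
  imputed.

## Synthetic data: what it emulates, and what it does not

The simulator exists because the task's real imaging data are not publicly
deposited; it renders scenes the *tracker* finds realistic, with exact
ground truth.

- **Texture.** Two-scale Gaussian-filtered white noise in [0, 1]: a fine
  component (sigma = grain/3, grain 3 px by default, matching speckle-scale
  autocorrelation) plus a coarse component (sigma = 3·grain, weight 0.6)
  standing in for anatomy-scale intensity structure. The coarse component
  is essential for pyramidal tracking of fast motion: pure single-scale
  speckle has featureless coarse pyramid levels, so the convergence basin
  is the grain size, not the window size, and a 10 px/frame cough peak
  becomes untrackable. This is a deliberate, physically motivated texture
  model, not beamformed speckle.
- **Scene.** 384 × 384 px frames at 0.2 mm/px and 30 Hz. Pubis ROI
  anterior; three 40 × 40 px urethral ROIs posterior to it, spaced 75 px
  (15 mm) apart superior-to-inferior so that even large differential
  displacements keep the rigidly moving patches disjoint. Patches are
  warped with bicubic interpolation and blended over an 8-px raised-cosine
  margin to avoid seam edges that would attract the detector.
- **Waveforms.** Cough: raised-cosine pulse (onset 0.5 s, rise 0.15 s,
  rebound 0.35 s) preceded by a +0.5 mm superior pre-lift bump 0.2 s ahead —
  the anticipatory pelvic-floor contraction. Valsalva: smoothstep ramp
  (1.5 s), 2 s plateau, 1 s release over a 5 s loop. PMC: superior
  ramp-hold-release plus an anterior-posterior signature of a small
  posterior (+0.5 mm) pulse reversing into a sustained anterior drift, with
  exactly one sign crossing. No quantitative waveform timings are published
  for these maneuvers; the defaults are physiologically plausible shapes and
  every timing is a template parameter.
- **Cohorts.** Per-subject displacement magnitudes are drawn from
  group-level normal distributions truncated at 0, calibrated to the
  embedded reference summary table (e.g. proximal Valsalva control
  5.98 ± 2.01 mm vs. SUI 10.64 ± 3.69 mm; directions at the group-mean φ).
  One standard-normal severity factor per subject-maneuver is shared along
  the three segments — each segment's marginal distribution matches its
  group spec, but the chain moves coherently. Independent per-segment
  draws were rejected because they routinely make adjacent rigid patches
  overtake each other in image space, which is both anatomically impossible
  for a continuous urethra and physically corrupting for the rendered
  scene. Probe motion defaults to a ±3 px / ±1° sinusoid at 0.7 Hz with
  random phase.
- **Not modeled:** acoustic/beamforming physics, out-of-plane motion,
  tissue deformation within a segment, intra-abdominal pressure dynamics,
  inter-operator annotation variability. Passing the synthetic suite
  therefore shows the *algorithmic* chain is correct and self-consistent at
  realistic effect sizes and noise — it does not certify performance on
  clinical B-mode images, where shadowing, decorrelation and out-of-plane
  motion are harsher.

## Validation problem sizes

Cohort-scale validation (the power experiment in `validation.py` and the
reproduction script) uses a shortened 1.8 s Valsalva (same
ramp-hold-release shape, plateau ≥ 25 % of the loop) and tracks the
proximal segment plus pubis, so one 21-subject cohort runs in about a
minute; three calibrated-effect cohorts and three null cohorts are run per
invocation. Tracking-accuracy and probe-invariance checks use full default
scenes. The type-I simulation uses 1000 null cohorts at the study's 10 + 11
design.

## Known limitations

- The rigid-per-segment model cannot represent within-segment deformation;
  strongly curved or compressing urethras will show it as residual error
  and rotation bias.
- The appearance (NCC ≥ 0.5) check assumes brightness constancy between
  consecutive frames; aggressive time-gain variation in real loops would
  need the threshold lowered.
- CVs recomputed from *rounded* published means/SDs can differ from the
  published CV column by one integer unit in a few rows (the upstream
  table was evidently computed from unrounded values); the package
  reproduces 15 of 18 magnitude-row CVs exactly and all 18 within one
  unit.
- The mixed ANOVA applies no sphericity correction; with three
  within-subject levels and the reference design this matches the
  analysis it mirrors, but strongly non-spherical data would inflate the
  maneuver-effect F.
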