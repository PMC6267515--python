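# Methods

## Model and coordinate conventions

All lengths are millimetres and all angles degrees at API boundaries. The
**tracker frame** has its origin at camera 1's nodal point, x/y parallel to
that camera's image plane and +z toward the participant — the frame the
stereo camera calibration naturally delivers. The **screen (stimulus) frame**
has its origin at the screen center, x right, y up, +z out of the screen
toward the participant; the display surface is the plane Z = 0. The rigid
tracker-to-screen transform (R, T) comes from the mirror calibration.

Gaze directions are parameterized Fick-style,

    g(theta, phi) = [cos(phi) sin(theta), sin(phi), -cos(phi) cos(theta)],

for the optical axis (through corneal-curvature center c and pupil center),
the visual axis (offset by the per-participant angles alpha, beta — additive
in theta/phi by construction) and the simulator's scripted orientations.

## Reconstruction pipeline

1. **Synchronization.** The two cameras sample asynchronously; each stream's
   pixel features are linearly interpolated at the other stream's
   timestamps, so the paired stream contains one record per input timestamp
   of either camera inside the temporal overlap. Records bracketed by an
   invalid frame are flagged invalid and never interpolated through.
2. **Virtual pupil.** p_v is the closed-form least-squares midpoint of the
   two back-projected pupil-center rays (2x2 normal equations for the two
   line parameters; near-parallel rays, |cos| >= 1 - 1e-9, are rejected as
   corrupt input rather than returned with a huge residual).
3. **Corneal-curvature center.** For each illuminator, its virtual image
   behind the cornea is triangulated from the paired glints; c is the
   least-squares intersection of the illuminator-to-virtual-image lines.
4. **Depth constraint.** The z coordinate of p_v (tracker frame — the
   direction pixel noise hits hardest) is recomputed so that
   |p_v' - c| = K exactly, taking the root with the pupil nearer the cameras
   than c; samples whose planar offset exceeds K are flagged invalid, never
   clamped.
5. **Filtering.** Screen-frame C and P'_v components and the raw measured
   |c - p_v| track are median filtered with a 20-sample window: even widths
   center as closely as parity allows (10 before, 9 after), average the two
   middle order statistics, and truncate at the edges, so the output length
   equals the input length and constant series pass unchanged. Filtering is
   applied per contiguous valid run; invalid samples are never bridged.
6. **POG.** Optical-axis angles from the filtered C, P'_v; visual axis
   g(theta + alpha, phi + beta); lambda_g = Z_c / (cos(phi+beta) cos(theta+alpha));
   POG = C + lambda_g * g, whose screen-frame Z vanishes identically.
7. **Gain correction.** POG_corrected = (K / K_actual) (C + lambda_g g) with
   K_actual the median-filtered measured |c - p_v|; the corrected gaze
   direction is (POG_corrected - C) normalized — the *unscaled* C, so the
   correction is the identity whenever K_actual = K. The correction acts
   about the screen-frame origin because K is estimated while the
   participant fixates the screen center.

**One-point calibration.** K = median measured |c - p_v| over >= 20 valid
central-fixation samples; alpha, beta = medians of the per-sample differences
between the line-of-sight angles (from C to the known target, same Fick
parameterization) and the optical-axis angles. Medians throughout for
robustness to outliers and pixel noise.

## Forward simulator

The simulator is the package's oracle: it generates exactly the feature
streams the reconstruction consumes, plus ground truth.

* **Glints.** The anterior cornea is a sphere (radius 7.8 mm). The specular
  point for an illuminator-camera pair lies in the plane spanned by the two
  points and the sphere center; the stationary point of the path length
  (Fermat) is bracketed between the two directions seen from the center and
  found by vectorized bisection to ~1e-15 rad reflection-law residual.
* **Pupil imaging.** `no_refraction` projects the true pupil center
  directly, making the inverse problem as exact as the corneal-center
  estimate allows — the round-trip testing mode. `snell` finds the corneal
  entry point of the chief ray camera -> pupil center (again planar, solved
  by coarse scan + bisection on the refracted ray's signed miss distance,
  n_cornea = 1.3375) and projects that entry point — what a pinhole camera
  actually images. The measured |c - p_v| then sits near 4.75 mm for a true
  4.2 mm pupil distance (the entrance pupil appears closer to the cornea)
  and varies with gaze and head position — the phenomenon the gain
  correction targets.
* **Validity.** The cornea is a ~50 deg spherical cap, not a full sphere:
  specular/entry points outside the cap, pupils viewed more than ~70 deg
  off-axis (iris occlusion), and features off the sensor make a frame
  invalid rather than raising.
* **Eye kinematics.** The eye rotates about a center 5.7 mm behind the
  corneal-curvature center, so gaze shifts also translate c slightly; the
  pupil center sits K_true = 4.2 mm in front of c on the optical axis, and
  the visual axis is offset by alpha = 5.0, beta = 1.5 deg (standard
  schematic-eye values; fixture choices, not measurements).
* **Trials.** Saccades follow a raised-cosine velocity profile whose peak
  velocity obeys the main sequence v_peak = v0 (1 - exp(-Amp/Amp0)) with
  defaults v0 = 500 deg/s, Amp0 = 5 deg, latency 180 ms; the two cameras
  sample near 330 and 300 Hz with uniform +/-10 % frame-interval jitter;
  isotropic Gaussian pixel noise defaults to 0.1 px. All randomness flows
  from one seed per script.
* **Stimulus.** The 54-target grid: eccentricities 3, 6, 9, 12 deg in 12
  directions plus 15 deg in 6 directions, converted to screen mm for an
  imaginary eye 650 mm from the screen. Head positions: the 3 x 3 grid of
  +/-50 mm horizontal and +/-30 mm vertical offsets.

**Reference rig.** Cameras 12 cm apart, ~10 cm in front of the screen near
the height of its lower edge (160 mm below the screen center), toed in on
the expected eye position 65 cm from the screen; one illuminator 6 cm
outboard of each camera; 16-mm lenses on 5.5-um pixels (focal length 2909
px), 1048 x 480 px sensors; 1920 x 1200 px screen at 0.27 mm pitch. These
are realistic desk-scale fixture choices.

What the simulator deliberately does **not** model: corneal asphericity (the
dominant source of systematic K_actual variation in real eyes), eyelid
occlusion and blinks, pupil-size changes, ocular torsion, photometric image
formation. Passing round-trip tests therefore demonstrates internal
consistency of the geometry and the stated idealizations — not performance
on real recordings.

## System calibration

Mirror markers are triangulated and a total-least-squares plane fitted (SVD
of the centered points; the second singular value guards against collinear
markers). Hidden points (illuminators, screen dots) are triangulated from
their virtual images and reflected back across the mirror plane. The screen
pose is the orthogonal-Procrustes (Kabsch) rigid transform from the
reconstructed dots to their known screen-layout positions, with the proper
rotation enforced via the determinant sign. RMS residuals are always logged;
no silent pass/fail threshold is applied. The default fixture uses one
mirror pose and a 3 x 3 dot grid.

## Validation analytics

POG traces are converted to degrees of an imaginary eye on the screen z-axis
at 650 mm, each component independently as atan(offset/distance) — matching
per-component accuracy reporting. For saccade analysis the angles are
resampled to a uniform 500 Hz grid (2-ms interval), low-pass filtered with an
8th-order 40-Hz Butterworth applied forward-backward (zero phase; the
magnitude response squares), differentiated by central differences, and
combined into vectorial speed. Saccades are maximal runs above 45 deg/s with
linearly interpolated threshold crossings; amplitude is the vectorial angle
between the positions at offset and onset. A saccade starting within 250 ms
of the previous offset with less than half its amplitude is marked
*corrective* (the windowing rule needs this classification; the criterion is
this package's choice and is deliberately conservative). Fixation windows
span 80 ms starting 20 ms after the first saccade's offset — or after its
corrective follower — and trials whose window contains invalid samples are
excluded and counted. Accuracy is the per-component MAE of window-mean POG
vs. target; precision is the per-window SD and the RMS of successive-sample
displacements (RMS-s2s), averaged over trials. The main sequence
v_peak = v0 (1 - exp(-Amp/Amp0)) is fitted by bounded nonlinear least
squares. Bland-Altman limits of agreement use mean +/- 1.96 SD of the paired
differences; the companion error-propagation helper
sqrt(sum of four squared accuracies) reports its CI half-width as 2 x SD, by
convention.

## Known systematic limits (measured, not hidden)

* **Virtual-image bias.** Even with perfect spherical-mirror glints, the two
  cameras do not see an illuminator's virtual image at exactly the same
  point; triangulating it and intersecting the illuminator lines biases c by
  ~0.026 mm (mostly along the viewing axis) on the reference rig. The
  one-point calibration absorbs the constant part into alpha/beta, but the
  K estimate inherits a ~0.02-0.03 mm offset, which turns into a gaze-angle
  scale error of ~0.1 deg at 15 deg eccentricity. Noiseless round trips are
  therefore accurate to ~0.1 deg, not machine precision.
* **Filter attenuation of small saccades.** A 3-deg raised-cosine saccade
  lasts ~27 ms; the 40-Hz zero-phase Butterworth attenuates its peak
  velocity by ~18 % (measured on ground-truth traces). Fitting the main
  sequence to filtered peaks inflates Amp0 by ~25-50 % and v0 by ~5-15 %
  relative to the generating values. Comparisons between two identically
  filtered systems are unaffected.
* **Gain correction under refraction only.** With a spherical cornea the
  systematic POG error is dominated by a near-constant radial scale error
  from the entrance pupil's lateral aberration, only partly correlated with
  K_actual. At a 30-mm downward head offset the gain correction lowers the
  *mean* grid error (~2-16 % in our runs) and helps most eccentric targets,
  but the grid *median* can move a few percent either way. With an
  aspherical cornea — the regime the correction was designed for —
  K_actual varies far more strongly; that regime is out of the simulator's
  scope.
* **Toed-in rigs and mirror symmetry.** The depth constraint acts along
  camera 1's optical axis, so reflecting a scene across the rig midplane is
  an exact symmetry of the pipeline only when that axis lies in the
  midplane (parallel cameras); with toe-in the asymmetry is ~0.1 deg.

## Numerical choices and problem sizes

Two-line least squares is solved in closed form; planar sphere solvers use
70-iteration bisection on provably bracketed roots (glints) or a 121-point
coarse scan plus bisection with forward-ray and residual validation (Snell
entry points). Degenerate inputs (parallel rays, collinear markers, planar
offsets exceeding K, gaze parallel to the screen) raise typed errors or set
validity flags; nothing is silently clamped. Tests and the acceptance script
use 25-30 frames per fixation target, 150-400 frames for calibration/noise
fixtures and one 54-trial session for the kinematics — sizes chosen so the
complete suite runs in about a minute on one CPU while keeping every
statistic comfortably away from small-sample noise; the `demo` command runs
the full-length study (1.0-1.6 s fixations, 1 s targets, 9 positions) in a
few minutes.
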