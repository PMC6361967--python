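# Methods

`tarsokin4d` quantifies talocrural (ankle) joint kinematics from dynamic CT
image sequences, and ships a synthetic 4D phantom generator so every stage of
the pipeline can be validated against exact ground truth.  The intended
experiment is a 4DCT acquisition of an ankle driven from maximum dorsiflexion
to full inversion under four ligament-integrity states ("scenarios"): intact,
then sequential sectioning of the anterior talo-fibular (ATFL),
calcaneo-fibular (CFL) and posterior talo-fibular (PTFL) ligaments, each
acquired in (up to) four repetitions.

## Coordinate conventions

All coordinates are millimetres in a right-handed anatomical frame: +X points
lateral→medial (rotation about X = dorsi-/plantar-flexion), +Z runs cranially
along the tibia (rotation about Z = ab-/adduction, translation = cranio-
caudal), +Y completes the frame (rotation = pronation/supination, translation
= antero-posterior; +Y is treated as posterior when naming axis-shift
directions).  Volumes are axis-aligned: world = origin + index · spacing;
oblique direction cosines are rejected at I/O time.  Rigid transforms are
stored in the reference→moving direction (a moving-frame sample is taken at
`T(x)`), which for the synthetic data makes the registered transform directly
comparable to the generator's motion transform.

## Synthetic phantom

The phantom is two smooth high-intensity bodies on a low-intensity background
(~50): a capsule-shaped tibia shaft elongated along Z (label 1, static) and a
talus below it (label 2, moving), built as an ellipsoid body plus an offset
head lobe.  The head lobe is not cosmetic: a bare ellipsoid is nearly
symmetric under 180° rotations about its principal axes, which makes the pose
ambiguous for an intensity metric; the lobe (like the real talar head) breaks
that symmetry at every pyramid resolution.  Bones carry a smooth sinusoidal
internal texture (plateau ≈ 600–1100) so rotations are identifiable by
mutual information, and edges get a 0.7 mm Gaussian blur.  No CT physics
(beam hardening, reconstruction artefacts, dose) is modelled.  Geometry
scales with the physical extent; each axis must span ≥ 31 mm.

Ground-truth motion: per-frame ZYX Cardan angles and translations follow a
smoothstep schedule `s(u) = 3u² − 2u³` from zero to the scenario end range —
monotone, differentiable and endpoint-exact.  The rotation is taken about
the trochlea-tali centre landmark with the translation applied on top, so
the trochlea-centre displacement equals the translation schedule exactly and
angle/displacement round-trips are exact by construction.  Scenario end
ranges default to the bundled reference measurements: scenario 1 uses the
mean of the four measured intact repetitions, (37.60, −1.81, 12.05)° and
(−0.07, −11.05, −5.90) mm; scenarios 2–4 add the measured signed
between-scenario maximum differences componentwise.  Literal addition is
used even where it flips the sign of the small Y rotation, because it makes
the scenario comparison recover exactly the published signed deltas.

Repetition noise is a single zero-mean Gaussian draw on the end range per
repetition, default σ = 0.2° / 0.1 mm.  With four repetitions the expected
maximum pairwise end-range difference is ≈ 2.06 σ ≈ 0.4°, matching the
sub-degree/sub-millimetre repeatability of the emulated rig with headroom
for registration error.  Rendering resamples only the talus (linear
interpolation; tibia and background are static), adds optional Gaussian
intensity noise (default σ = 20 against a ≥ 550 bone/background contrast),
and refuses transforms that push talus surface voxels out of the field.

What the phantom does *not* emulate: soft tissue, the calcaneus and subtalar
joint, CT noise statistics and artefacts, non-rigid motion, and oblique
scanner orientations.  Tests passing on the phantom therefore validate the
*processing chain* (segmentation → registration → kinematics → statistics),
not robustness to real CT image quality.

## Segmentation

Semi-automatic, deterministic and replayable: global threshold → morphological
closing then opening (ball radius 1 voxel) → 26-connected component
labelling; each bone is the component containing its seed point (the label
follows the seed), with components under `min_component_voxels` rejected.
The default threshold used by the pipeline is the midpoint of the robust
intensity range (1st/99.5th percentiles).  "Manual refinement" is an ordered
list of spherical paint/erase edits; connectivity violations after editing
are reported, never silently repaired.  Registration regions are the bone
mask dilated by 2 mm (Euclidean distance transform, correct under
anisotropic spacing) to include edge context.

## Registration

Per bone and frame the six rigid parameters (three ZYX Euler angles about
the region centroid, three translations; degrees and millimetres are
deliberately the parameter units so Powell's isotropic steps are sensible)
maximize mutual information over the region.  MI is estimated from the joint
intensity histogram (default 32 bins at full resolution, halved per
downsampling factor) of region voxels, pairing fixed values with linearly
interpolated moving values; voxels mapping outside the moving volume are
excluded.  Two numerical details matter:

- **Jittered, supersampled sampling.**  The optimizer's sampler evaluates
  both images at sub-voxel jittered positions (fixed seed).  Sampling
  exactly on the grid would make the identity transform special: on-grid
  samples keep full noise variance while off-grid interpolation smooths
  noise, which inflates MI away from exact alignment and biases rotationally
  near-symmetric regions (the tibia shaft) by up to ~2°.  At the finest
  level four jittered samples are drawn per voxel (capped at 28 000 total
  samples, with seeded voxel subsampling above the cap, plus a σ = 0.5 voxel
  Gaussian pre-smooth): averaging over jitter patterns lowers the
  MI-estimator noise floor, which otherwise limits weakly-constrained
  parameters — rotation about a long bone's axis wanders ~0.1–0.15° with a
  single sample per voxel and ~0.05° with four.
- **Partial-volume binning.**  The moving value's histogram weight is split
  linearly between the two neighbouring bins, keeping the cost smooth in the
  parameters; hard binning leaves plateau ripple that stalls Powell ~0.5°
  from the optimum.

The public `mutual_information` function, by contrast, samples exactly on
the grid with hard binning and per-call histogram edges so that its contract
holds exactly (MI(f, f | identity) = H(f); symmetric at identity).

Optimization is coarse-to-fine (default pyramid 2×, 1×, Gaussian smoothing
σ = factor/2 voxels before decimation) with Powell's method (step tolerance
1e-3 ° / mm at the finest level).  Cold starts (no previous-frame solution)
get a centroid-shift pre-alignment plus a rotation grid search (±40° in 20°
steps per axis) at the coarsest level; the top three grid candidates are
refined and the two best basins are carried through the pyramid, with the
finest level deciding.  The grid search is run at 2× rather than 4×
downsampling because with a ~6000-voxel region the 4× level has too few
samples to rank rotation basins reliably.  Within a frame sequence each
frame is initialized from the previous frame's solution (no grid search),
which keeps per-frame steps small at large inversion angles.  Optional
restart passes at the finest level (fresh Powell direction sets) are
available but off by default: with the partial-volume-smoothed metric a
single pass reaches the same optimum.
Non-convergence returns a flagged result rather than raising.  Accuracy on
noiseless phantoms is ≤ 0.1° / 0.05 mm (contract: 0.5° / 0.5 mm); the
static tibia registers to identity within ~0.07° / 0.02 mm at default noise
over all 17 frames (contract: 0.1° / 0.1 mm).

TRE is the Euclidean distance between transformed reference points and known
moving-frame correspondences; for synthetic data the correspondences are the
generator's exact landmark trajectories (≥ 10 seeded points per bone).

## Kinematics

Talus motion is expressed in the tibia frame (`tibia⁻¹ ∘ talus`) and
summarized three ways:

1. **ZYX Cardan angles**, `R = Rz(z) Ry(y) Rx(x)`; y ∈ [−90°, 90°] by the
   decomposition.  Near gimbal lock (|cos y| < 1e-8) z is set to zero, x
   absorbs the free degree and the result carries an explicit flag.
2. **Trochlea-centre displacement**, `T(p₀) − p₀`.
3. **Finite helical axis** in the Spoor–Veldpaus least-squares form:
   direction and angle from the skew-symmetric part of R (switching to the
   symmetric-part extraction above 135°, where the sine form degenerates);
   axial translation = direction · t; the axis point closest to the origin
   solves `(I − R)s = t − d·n` under `s·n = 0` (least squares).  Angles
   below 0.1° raise a degenerate-rotation error — an axis direction is
   meaningless for near-pure translation.  The four fields reconstruct the
   source transform to 1e-9.

The per-repetition "total" helical axis is taken from the frame-0→final
transform (one axis per repetition, matching the one-row-per-repetition
layout of the reference tables); incremental per-frame axes can be computed
from the individual transforms.  For reporting, axis orientations are
canonicalized to X ≤ 0, and orientation changes are unsigned *line* angles
(in [0°, 90°]) between projections onto the YZ/XY/XZ planes — an axis has no
intrinsic sign, so vector angles would be convention-dependent.  Axis
position is the (Y, Z) intersection with a sagittal plane at fixed X
(through the trochlea centre in the pipeline).

## Scenario statistics

Scenario curves are the per-frame component-wise mean of the repetitions
(sample SD attached; n = 1 is allowed and flagged, mirroring a scenario with
a single usable acquisition).  Repeatability is the maximum pairwise
absolute difference of end-range (final-frame) values across repetitions —
for scalars this equals the range.  Between-scenario comparison reports, per
component, the signed difference at the frame where |difference| peaks
(maxima commonly occur mid-motion, not at the end point), plus a percent
change.  The percent denominator is the reference scenario's peak absolute
value of that component over the time course: this convention reproduces the
published percentages of the emulated experiment (e.g. 6.07/37.81 → +16%,
5.12/1.97 → +260%, 2.61/5.94 → +44%) and is the stated meaning in all
reports.  Axis shifts between scenarios report the three projected line
angles and the Euclidean displacement of the sagittal-plane intersection,
with a coarse direction word (postero/antero × cranial/caudal) from the
signs of ΔY/ΔZ.

## Problem sizes and determinism

Default phantom: 64×64×96 voxels at 1 mm.  The package default is 18 frames
per repetition (one reference + 17 moving); validation runs in the test
suite and acceptance script use 2–8 frame schedules, since end-range and
repeatability statistics depend only on the final frame — a deliberate
scaling choice, stated here once.  Every stochastic component (phantom
texture phases, landmark sampling, repetition noise, intensity noise) is a
pure function of an integer seed; identical configuration and seeds produce
byte-identical report files.

## Known limitations

- The per-frame motion schedule is an emulation: the source experiment
  published only end-range values and plots, not numeric trajectories.
- Printed reference orientation vectors are rounded and non-unit (norm
  ≈ 0.82); the package always emits unit vectors.  The printed per-repetition
  axis rotation (~43.4°) is also slightly larger than the helical angle
  implied by the printed Cardan triples (~39.8°); the generator reproduces
  the Cardan angles exactly and reports the implied helical angle.
- Registration assumes per-bone rigidity and bones that stay largely within
  the field of view; there is no deformable or 2D–3D support.
- Single-specimen scenario presets: no inferential statistics are provided,
  only descriptive differences.
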