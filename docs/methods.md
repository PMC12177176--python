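# Methods

## Coordinate conventions and units

Head frame: right-handed, x anterior, y toward the animal's left, z dorsal;
eye landmarks in micrometres. Lab frame (flight): z vertical-up,
millimetres. All angles are degrees. Azimuth is measured from anterior (+x),
positive toward +y; elevation is positive dorsal. Head width — the distance
between the two ocelli — is the normalization length for cross-individual
eye averaging; scaling leaves every angular quantity unchanged, so
single-eye reconstructions run on raw micrometre coordinates.

## Lens reconstruction

**Basis plane.** The criterion is maximal projected area of the base
polygon. For a fixed vertex ordering the projected area onto a plane with
unit normal n is |S·n| with S = ½ Σ pᵢ × pᵢ₊₁, maximized exactly at
n = S/|S|; because the angular vertex ordering itself depends on the plane,
the solver alternates ordering (initialized at the total-least-squares
plane) with the closed-form normal until the ordering is stable (≤ 20
rounds; in practice 1–2). For near-planar hexagons the result coincides with
the TLS plane; the acceptance suite verifies it beats every normal on a 2°
hemispheric grid. Vertex order is by angle about the centroid — input row
order is never trusted.

**Circle fit.** Algebraic (Kåsa) least squares solved as a linear system,
then one geometric refinement of Σ(dᵢ − r)² with `scipy.optimize.least_squares`
(xtol/ftol/gtol 1e-10). Diameter is taken from the fitted radius; for an
exact circle the area route d = 2√(A/π) coincides.

**Axis and curvature.** The visual axis points outward, from the fitted 3D
circle center through the apex. Cap height h is the orthogonal distance of
the apex from the basis plane (not along the axis; the difference is
second-order for near-normal apices). R = (a² + h²)/(2h) is exact for a
spherical cap; h ≤ 0 (apex on or below the plane) is a hard error rather
than a silent sign fix. Only the outer surface is modelled — no inner-lens
radius, no thick-lens ray tracing.

## Interommatidial angles and the eye map

Each facet's φ is the arithmetic mean of the angular differences between
its axis and its six angularly nearest facets (ties broken toward lower
id). Edge facets have no literal six-ring, so the six nearest are used
regardless of ring position; records whose sixth neighbor exceeds a 45°
cutoff are flagged, not dropped. The neighbor search pools both sections of
an eye (facets at the section border may have cross-border neighbors;
configurable to per-section). The relation is directional — no symmetry is
assumed. Section summary statistics are pooled over facets rather than
averaged per individual. Cross-individual averaging matches landmarks by
digitization order (ommatidium id) unless an explicit correspondence is
supplied, and refuses incomplete correspondences.

## Optics

Single refracting surface, air to cornea, n = 1.4 by default. The default
focal length is the front-focal form f = R/(n−1); the back-focal form
f = nR/(n−1) is selectable via `OpticsConfig.formula` and recorded in the
outputs, since the two bracket the plausible readings of a single-surface
model and per-lens subsampling makes the original computation
unrecoverable from printed means alone. Focal depth is f/L with L = 34 um
by default. The expected aperture area of a diameter distribution (μ, σ) is
π/4·(μ² + σ²) — distribution-free given the first two moments. Section
contrasts are reported as |a − b|/max(a, b)·100.

## Gaze under body rotation

Mean gaze per section is the normalized axis sum; an exactly balanced
antiparallel set is a degenerate-gaze error. Rotations compose intrinsically
as z(yaw)·y(pitch)·x(roll), right-handed, with positive pitch lifting the
anterior axis tip dorsally. Rotations are applied about the center of mass
(default: the sphere origin) to both gaze directions and ray origins;
translation is ignored; the projection sphere (10 mm radius) stays fixed in
the lab frame, so azimuth/elevation are read off a stationary panorama as
the body rotates. The sphere origin is the midpoint of the left and right
convergence points of all visual axes — the least-squares point minimizing
summed squared line distances (normal equations); single-side digitizations
are mirrored across the sagittal plane. Because head dimensions are ~10³
times smaller than the sphere radius, a 1 mm shift of the ray origin
perturbs (Az, EL) by at most arcsin(1/10) ≈ 5.74°, asserted over random
configurations. Default sweep envelopes: pitch 0–150°, yaw ±90°, roll ±50°,
in 1° steps.

## Flight kinematics

Body pitch is measured in the vertical plane spanned by the vertical axis
and a horizontal forward reference (the track's net horizontal
displacement; +x for the standalone function), mapped to [0°, 180°] so that
pitch-past-vertical (head behind thorax, as at landing) lands above 90°.
Forward speed is the horizontal-plane speed of the tracked head point
(configurable to thorax/midpoint, or total 3D speed), central-differenced
at interior frames and one-sided at the ends — at 7000 fps the differencing
error on realistic profiles is well under 1%. Time normalization uses a
natural cubic spline (no smoothing) resampled on [0, 1]; endpoints are
preserved exactly. The speed-pitch relation is summarized in contiguous
2 cm/s bins; empty bins stay empty and single-observation bins report a
missing SD rather than 0. Head wobble is the deviation of the two-marker
line angle from its series mean, with coincident-marker frames flagged.
Inferential statistics on the original animals are out of scope — only
descriptive statistics and effect sizes are produced.

## Synthetic data: what it emulates, what it does not

`generate_eye` places visual-axis directions on two spherical caps by a
golden-angle (sunflower) layout whose radial density follows a target local
pitch rising linearly from 1° at the cap center to 30° at the rim — the
measured center-to-edge acute-zone gradient. Each section's axis set is
rigidly rotated so its exact mean gaze equals the nominal section direction,
making the generated section separation exactly the spec value (53° by
default). The dorsal nominal gaze is lateral-dorsal (az −90°, el 50°); the
ventral one sits near the sagittal plane (az −20°, elevation solved for the
requested separation). This geometry reproduces the qualitative division of
labor — pitch moves dorsal gaze in azimuth and ventral gaze in elevation,
roll the reverse, yaw azimuth only. Per lens, six base points are placed
exactly on a circle of a drawn diameter (per-section normal distributions,
6.35 ± 0.51 um dorsal / 7.67 ± 0.89 um ventral, truncated at 1 um) in the
plane orthogonal to the true axis, with the apex at the cap height implied
by a drawn curvature radius (3.98 ± 0.72 / 5.81 ± 0.92 um; draws with R < a
are redrawn and counted). Isotropic Gaussian noise on all seven landmarks
models digitization error last. All lens bases sit at 40 um from a common
eye center, so every true axis passes through one point — a convenient,
slightly idealized convergence geometry.

Cap angular radii (67° dorsal, 85° ventral) are a one-off calibration
chosen so the default eye's per-section mean interommatidial angles land
near the measured 12.5°/16.2°; they are a generator design constant, not a
measurement. Counts (42/31), head width (126 um) and the pitch-gradient
endpoints are the measured values.

`generate_flight` produces a straight bout along +x at 7000 fps (default
260 frames ≈ 37 ms, the mean bout duration) whose head-point speed decays
smoothly (smoothstep) from 27.5 to 17.8 cm/s while pitch follows
β = β₀ − k·v through the measured endpoints (27.5 cm/s, 48.1°) and
(17.8 cm/s, 113°), plus per-frame Gaussian jitter (default SD 5°,
representing within-bout posture variability — smaller than the across-
animal SDs of the measured endpoints). Thorax and abdomen-tip points are
placed from the pitch series at a 0.92 mm body length. `generate_head_wobble`
rotates two markers sinusoidally about their midpoint near wingbeat
frequency (170 Hz).

What the generators do **not** emulate: real facet lattices (no hexagonal
packing constraints, no section-shape irregularity), anisotropic or
correlated digitization error, tissue deformation from specimen
preparation, curved flight paths, wind, wingbeat-coupled body oscillation,
or camera projection noise. Passing tests therefore demonstrate correctness
of the computations and well-posedness of the recovery problem at realistic
noise levels — not robustness to every artifact of real micro-CT or video
data.

## Numerical choices and degenerate inputs

- Circle/plane fits reject collinear or coincident points with a
  degenerate-geometry error naming the record.
- `arccos` of clamped dot products is used for angles in [0°, 180°]; tests
  use the chord form 2·arcsin(‖a−b‖/2) where sub-microdegree resolution
  matters.
- Convergence solve refuses condition numbers above 1e12 (near-parallel
  axis bundles).
- Azimuth is reported in (−180°, 180°]; the azimuth of a pole (|el| = 90°)
  is arbitrary and not asserted anywhere.
- Problem sizes in the test suite (e.g. ~500 lenses per noise level, 50
  seeded flights, 200k Monte-Carlo draws) were chosen as the smallest sizes
  at which the checked statistics are stable.

## Known limitations

- The maximal-projected-area plane is found by ordered vector-area
  iteration; pathological strongly non-planar polygons could in principle
  cycle between orderings (capped at 20 rounds, falling back to the last
  normal). Not observed for realistic lens bases.
- The printed section focal-length means of the source system (10.5 and
  13.8 um) are not exactly R/(n−1) of the printed curvature means (9.95 and
  14.53 um); per-lens subsampling in the original analysis is the likely
  cause, and both focal formulas are exposed rather than tuned to match.
- Body pitch needs an external horizontal forward reference; for strongly
  curved flights the net-displacement default is crude.
- The whole-eye convergence point is a single least-squares point; real
  split eyes may have distinct per-section convergence regions.
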