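# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `aortaflow`. Units throughout: mm, ms, m/s, N/m² (Pa),
Pa·s.

## Synthetic phantoms

The generator emulates what a 4D-flow acquisition of a vessel embedded in
tissue looks like statistically, not the MR physics. A tube (straight, or
a U-bend standing in for the candy-cane thoracic aorta: two straight legs
joined by a half-circle of configurable bend radius) is surrounded by a
thin air gap (default 3 voxels) and then static tissue filling the rest of
the grid. The magnitude image is 100 in lumen and tissue, 5 in air, plus
unit-SD Gaussian noise — arbitrary but documented values that make noise
masking well posed.

Axial velocity profiles:

* **poiseuille** — `v(r) = v_max (1 − r²/R²)`; exact at voxel centers, so
  wall shear stress is exactly `2 μ v_max / R`.
* **plug** — uniform speed; used with solid-body swirl so that every
  tracer shares one transit time and the transit rotation `Ω·T` is exact.
* **womersley** — the oscillatory pipe-flow solution per harmonic `k`:
  `ŵ_k(r) = A_k (1 − J₀(i^{3/2} α_k r/R) / J₀(i^{3/2} α_k))`, with
  `α_k = R √(kω/ν)` and `ν = μ/ρ` (ρ = 1060 kg/m³); harmonic 0 is the
  steady Poiseuille component. Truth WSS per frame is the numeric radial
  derivative of this profile at the wall with step `1e-4·R` (relative
  error below 1e-4 % on the parabolic profile; symbolic Bessel derivatives
  are avoided deliberately).

Artifacts are injected in the physically ordered inverse of the
preprocessing chain: `stored = wrap(v_true + eddy(x) + noise)` with
`wrap(v) = ((v + venc) mod 2 venc) − venc`, a first-order spatial
polynomial `eddy` identical across frames, and i.i.d. Gaussian noise
everywhere (air voxels are pure noise). All randomness flows through
`numpy.random.SeedSequence(seed)` children, so equal seeds are
bit-reproducible and different seeds change only the noise realization.

Default acquisition parameters mirror a typical clinical protocol: venc
1.5 m/s (protocols use 150–200 cm/s), 16 frames at 40 ms, 2 mm voxels.
The noise SD is a free parameter (no scanner calibration data exist for
it); tests use 0.02–0.03 m/s, roughly 2% of venc.

## Preprocessing

Order: noise mask → unwrap → static-tissue detection → eddy correction.
Unwrapping before the eddy fit inverts the corruption model exactly
whenever `|v_true + eddy| < 2 venc`; static-tissue speeds are far below
venc, so the fit is insensitive to the order either way.

* **Noise mask** — voxels whose time-averaged magnitude falls below
  `threshold_frac` (default 0.1) of the 99th-percentile magnitude.
* **Anti-aliasing** — seeded region growing per velocity component.
  Voxels with `|v| ≤ venc/2` are trusted seeds (wrapping folds values near
  ±venc, so slow voxels are reliable). The trusted region grows over
  spatial 6-neighbors and temporal neighbors; each newly reached voxel is
  compared with the median of its already-trusted neighbors and shifted by
  the multiple of `2 venc` minimizing the difference when it exceeds venc.
  A plain fixed-point sweep against the local median stalls on wrapped
  regions wider than one voxel (the median is then dominated by wrapped
  neighbors); region growing handles arbitrary wrapped-core sizes, is
  idempotent, and never touches voxels within venc of all neighbors. It
  requires true neighbor velocity differences below venc — satisfied by
  resolved laminar profiles, violated by under-resolved oscillatory
  boundary layers (see limitations).
* **Eddy-current correction** — per component, a total-degree ≤ `order`
  polynomial (default 1, options 0–2) is least-squares fitted to the
  temporal-mean velocity over static-tissue voxels (high magnitude,
  temporal SD of every component < 0.05 m/s by default) and subtracted
  from all frames. The offset model is time-invariant. Static-tissue
  detection is pulsatility-based, so a *steady* flow phantom is
  indistinguishable from tissue — pulsatile phantoms must be used to
  exercise this stage, which is also why the preprocessing test phantoms
  carry an oscillatory harmonic.

## Anatomy

* **PC-MRA** — `sqrt(mean_t (magnitude² |v|²))`.
* **Segmentation** — triangle (histogram-foot) threshold by default; the
  PC-MRA fades smoothly toward the wall because near-wall flow is slow, so
  a mid-histogram bimodal split (Otsu) systematically erodes the lumen
  (measured Dice 0.79 vs 1.00 on a noiseless tube). A fraction-of-99th-
  percentile override is available. Largest 6-connected component, then a
  one-voxel closing (union with the original, so thresholding stays
  monotone).
* **Surface** — marching cubes at 0.5 on the mask smoothed with a Gaussian
  of σ = 1 voxel. Smoothing preserves the mean wall position but removes
  the staircase facets of a binary isosurface, whose corrupted vertex
  normals would otherwise bias wall-normal velocity sampling. Vertex area
  is one third of incident triangle area; normals are consistently
  outward (checked via signed volume). End caps where the vessel meets the
  volume boundary are identified by normal-tangent alignment (> cos 45°)
  and excluded from all wall statistics.
* **Centerline** — a medialness-weighted minimal path: the two
  geodesically farthest voxels (ends centered on the deepest voxel of the
  end region) are joined by the path minimizing `length / depth²`, where
  depth is the Euclidean distance transform; this pulls the path onto the
  medial axis. The voxel path is resampled at 1 mm, Gaussian-smoothed at
  the vessel-radius scale, and differentiated with a quadratic
  Savitzky–Golay filter (window ≈ 6 radii; exact on circular arcs to
  fourth order). Measured on the U-bend phantom: arc length within 3% and
  apex curvature within 10% of the analytic values. An explicit
  orientation step aligns arc length with the net flow direction at peak
  systole.
* **Ten-segment partition** — landmarks at arc-length fractions
  0.2/0.4/0.6/0.8 (configurable) split the wall into five longitudinal
  zones; the inner/outer dichotomy uses the local curvature vector
  (pointing toward the curvature center = inner) where curvature exceeds
  0.01 mm⁻¹, the direction toward the arch curvature center on straight
  stretches, and a configurable reference direction (default +x) for
  entirely straight vessels. The 0.01 mm⁻¹ floor separates anatomical
  bends (≈ 0.02 mm⁻¹ for a 50 mm arch) from the residual wiggle of an
  extracted straight centerline (≈ 0.007 mm⁻¹).

## Wall shear stress

Velocity is sampled by trilinear interpolation along the inward normal at
spacing `h` (default: the smallest voxel dimension) and a quadratic
profile is fitted per vertex. Two wall models:

* **quadratic_wall_locating (default)** — free quadratic through interior
  samples at `{h, 2h, 3h}`; the shear is evaluated at the parabola's zero
  crossing nearest the surface. No-slip enters as the *fitted* wall
  position, which makes the estimate insensitive to the sub-voxel,
  lattice-phase-dependent offset between the extracted isosurface and the
  true wall, and avoids the partial-volume-contaminated sample at the
  surface itself. On the Poiseuille phantom the mean-wall error is −4.1%
  at 8 voxels/diameter, −2.0% at 16 and −1.4% at 32 (monotone).
* **quadratic_no_slip** — the classical variant anchoring `v = 0` at the
  surface vertex. Kept for comparison; its error is dominated by the wall
  offset (−10…−26% on the same phantoms, not monotone in resolution),
  which is why it is not the default.

The shear-rate vector's wall-normal component is projected out, so the
stress is tangential by construction. WSSsys is the mean |WSS| over the
five frames centered on the peak-systolic frame (argmax of mean lumen
speed, earliest frame on ties), with the window clamped — never shrunk —
at cycle boundaries. Segmental means are area-weighted; empty segments are
reported as missing, never zero. Viscosity defaults to 3.2e-3 Pa·s, the
common large-vessel blood assumption.

Peak-systolic velocity MIPs erode the mask by one 6-connected voxel to
suppress wall partial-volume voxels; regional peaks are taken over the
ascending (zones 1–2), arch (zone 3) and descending (zones 4–5)
longitudinal zones.

## Flow-pattern grading

Massless tracers (default 200, seeded on a disk at the region entry from a
fixed RNG) are advected with RK4 at a time step of one tenth of the frame
duration, linear interpolation in space and time, the cycle treated as
periodic. Winding is the accumulated angle of the tracer position about
its nearest centerline point in a parallel-transported normal frame,
counted while the tracer remains within the region's arc-length span.
Grades: helix 0 below 90°, 1 from 90° to 360°, 2 at or above 360° (only
the 360° boundary has an external anchor; the 90° floor is this package's
choice for "moderate"). The vortex grade applies the same thresholds to
tracers seeded in voxels where a cross-section has more than 5% retrograde
axial flow, and is 0 when no such cross-section exists; the combined score
is their sum (0–4).

Grading uses the 90th percentile of |winding| over tracers rather than the
single maximum: under coherent rotation every tracer winds together and
the quantile equals the maximum (the programmed-rotation validations are
insensitive to this choice), while with measurement noise the slowest
near-wall tracers random-walk and the sample maximum alone can spuriously
cross the 90° threshold over a full cardiac cycle.

## Statistics

Normality is gated per sample by a Kolmogorov–Smirnov test against a
normal with moment-estimated parameters (no Lilliefors correction; the
gate is conservative toward normality, and the null simulations below
confirm the level). Paired data: t-test vs Wilcoxon signed-rank; two
groups: pooled-variance t-test (Welch optional) vs Mann–Whitney U; all
two-sided at α = 0.05, no multiple-testing correction. Degenerate inputs
(all-zero differences, constant groups) return p = 1 with a warning
instead of failing. Measured type-I error over 1000 null simulations at
the study-scale sample sizes (19 pairs; 19 vs 10) is 0.044/0.046.

Body surface area uses Mosteller √(h·w/3600) by default (DuBois
optional). Z-scores use a configurable normative model (mean and SD as
polynomials of BSA, height or age with a declared validity range); the
shipped example model is synthetic, and Z > 2 flags dilatation. Cohen's
kappa uses marginal-product expected agreement; Bland–Altman reports bias,
bias ± 1.96 SD of differences, and percentages of the grand mean.

The `cohort` module draws synthetic follow-up cohorts (19 patients twice,
10 volunteers) whose group means and spreads mirror an adolescent
aortopathy study — proximal inner descending-aorta WSS 0.60 ± 0.18 /
0.55 ± 0.16 vs 0.78 ± 0.15 N/m², a −0.60 WSS–Z-score correlation — for
exercising the battery at realistic effect sizes.

## Validation problem sizes

The analytic validations run on one CPU in seconds to a couple of
minutes: steady WSS at 8–32 voxels/diameter (grids up to ~54³), the
segmentation/partition checks on a 64×24×48 U-bend, grading on 36³ swirl
phantoms, and 1000-replicate null simulations for the test level.

The pulsatile WSS validation uses a small-caliber tube — R = 2 mm,
0.15 mm voxels, 20 frames of 50 ms, harmonics (0.6, 0.3) m/s, Womersley
number α ≈ 2.9 — because the quadratic wall model can only see the
oscillatory Stokes layer `√(2ν/ω)` (≈ 1 mm for blood at 60 bpm) if it
spans several voxels and several sample points. Per-frame wall-shear
errors are then ≤ ~10% against the Bessel oracle.

## Known limitations

* At aortic caliber and clinical resolution (α ≈ 10–20, 2–3 mm voxels)
  the oscillatory boundary layer is thinner than one voxel: the harmonic
  component of WSS is under-resolved and underestimated, consistent with
  the well-documented in-vivo behavior of 4D-flow WSS. Passing the
  pulsatile validation at α ≈ 3 demonstrates estimator correctness where
  its assumptions hold, not accuracy at aortic Womersley numbers.
* The same under-resolution breaks the anti-aliasing smoothness
  precondition if a strong harmonic wraps; wrapped acquisitions are
  validated on resolved profiles.
* Phantom fields are kinematic constructions (e.g. the U-bend profile is
  extruded along the centerline, without Dean secondary flow; the
  recirculation patch is a velocity-scaled sphere, not a Navier–Stokes
  solution). They validate the measurement chain, not hemodynamic realism.
* Static-tissue detection relies on pulsatility and cannot separate
  steady flow from tissue.
* The visual helix/vortex reading it replaces produces half-point grades
  via observer averaging; the automatic grader emits integers.
* Segmentation and segment borders are automatic (threshold + arc-length
  landmarks) where a clinical workflow uses manual anatomy; segment
  borders on real aortas should be reviewed against the landmark
  fractions recorded in every report.
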