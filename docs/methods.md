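# Methods

This note documents the models, numerical choices and known limitations
of `fetalflow`. Units throughout: mm for length, ms for time, cm/s for
velocity, mL/s for instantaneous flow, mL/min (per kg) for (indexed)
mean flow, radians for phase.

## The phantom

### Vessel network

The default network is a schematic 3D layout of 14 fetal vessels and
shunts (UV, DV, IVCd, IVCp, RHV, SVC, MPA, DA, LPA, RPA, AAo, BT, DAo,
FO) drawn inside a 120 mm field of view for a 2.8 kg fetus at
140 bpm — the mean weight and heart rate of the sheep cohort the flow
table comes from. Lumen radii (2.3–4.3 mm) are chosen so that (a) every
vessel spans at least ~3.7 voxels per diameter at 1.25 mm resolution,
the regime in which flux integration is accurate, and (b) systolic
centerline speeds reach ~130 cm/s in the great arteries — well above
the low VENC of 50 cm/s (so dual-VENC de-aliasing is genuinely
exercised) and below the high VENC of 150 cm/s. Radii scale as
weight^(1/3); centerline geometry is fixed.

Mean flows are anchored to indexed flows measured by 4D-flow CMR in
fetal sheep (see `fetalflow.tables`): MPA 284, AAo 245, DAo 333, UV 197,
DV 144, IVCd 117, SVC 181, LPA 20, RPA 18 mL/min per kg. Measured
tables never close the mass balance exactly (in vivo discrepancies of
~14% are typical), but a phantom must; the remaining vessels are
therefore *derived* from conservation: RHV = DAo − DV − IVCd = 72,
IVCp = 333, FO = SVC + IVCp − MPA = 230, DA = MPA − LPA − RPA = 246,
BT = AAo + DA − DAo = 158. The anchored MPA, AAo and DAo values — the
ones that define CVO and the distal identity — are preserved exactly;
DA and FO deviate from their measured counterparts (265, 174) as the
price of exact closure.

### Waveforms

Three template classes emulate the characteristic fetal waveform shapes:
peaked arterial (MPA, AAo and derivatives), biphasic venous (systemic
veins, S- and D-wave lobes, pulsatility increasing toward the heart)
and near-constant umbilical. Templates are built from cosine-power
lobes ((1 + cos 2πτ)/2)^m on a baseline, parameterised by peak timing,
peak-to-mean ratio, second-lobe ratio and sharpness m. These are
trigonometric polynomials of degree m (default 4), so uniform sampling
with n ≥ 2m+1 cardiac frames reproduces the continuous cycle mean
*exactly* — the 8-frame flux oracle carries no waveform-aliasing error,
which a compact-support lobe would not achieve. The amplitude is solved
analytically so the cycle mean equals the requested mean flow
(verified to 0.1%).

Waveforms are composed across junctions so that physical confluences
and splitters balance at *every* time point, not just on the mean:
daughters of a splitter carry fixed fractions of the parent waveform
(DA, LPA, RPA from MPA; DAo, BT from AAo+DA), confluences carry sums
(IVCp = RHV + DV + IVCd), and the foramen ovale carries the difference
FO = (SVC + IVCp) − MPA, which naturally yields the diastolic-dominant
FO pattern with transient systolic reversal. The one exception is the
distal identity IVCp = DAo: it relates flows through the entire
compliant lower body and holds only on the cycle mean, exactly as in
vivo; the junction is flagged `instantaneous=False` accordingly.

The default umbilical-vein waveform is a low-pulsatility venous
template (peak-to-mean 1.3) rather than a strictly flat one: a
perfectly steady flow is indistinguishable from static tissue in a
phase time-series, which real UV flow — slightly modulated — is not.
A strict `constant` kind exists for test rigs.

### Rasterization and encoding

Voxel velocities follow a parabolic (Poiseuille) profile across each
vessel, oriented along the local centerline tangent and scaled per
frame by the waveform: v(r, t) = 2·q(t)/(πR²)·(1 − r²/R²). Centerlines
are resampled at 0.25 mm; each voxel takes the profile of its nearest
centerline point. Where vessels overlap — the mouths of junctions,
within about a radius of the shared node — the voxel velocity is the
mean-flux-weighted average of the overlapping fields, a C0 blend of the
continuous anatomy. Voxel centers sit at (index + 0.5)·spacing with the
world origin at the volume corner.

Encoding stores φ = wrap(π·v/VENC + background + noise) in (−π, π] per
component and frame. The background is a polynomial (default linear) on
volume-normalised coordinates, shared by all VENCs, emulating
eddy-current offsets; coefficients are O(0.1) rad. Magnitude is 1.0 in
the lumen, 0.7 in static tissue (an ellipsoidal body plus a 5 mm margin
around every vessel) and 0.05 in air — arbitrary but fixed levels that
make static-tissue detection meaningful. Noise uses the small-angle
limit of complex Gaussian noise: phase standard deviation 1/SNR
radians, magnitude standard deviation 1/SNR, independent per
voxel/frame/component. Everything is deterministic for a fixed seed.

## Reconstruction

* **Static-tissue detection**: temporal phase standard deviation below
  0.1 rad in all components AND time-mean magnitude above 0.3 of the
  volume maximum. On noise-free data the mask necessarily also captures
  a thin near-wall shell of lumen voxels whose velocities are below the
  threshold-equivalent (the parabolic profile vanishes at the wall);
  these contaminate the background fit by well under 0.1 cm/s because
  static voxels outnumber them by ~100:1. Detection runs on the
  low-VENC stack, whose phase is most velocity-sensitive.
* **Background correction**: per component, a polynomial of total
  degree 0–2 (default 1) in world coordinates is least-squares fitted
  to the time-mean velocity over static voxels and subtracted
  everywhere. Matching-order contamination with a perfect mask is
  removed to machine precision, and the operation is idempotent (a
  refit of the residual is identically zero).
* **Unwrapping** (high VENC): temporal first — frame-to-frame jumps
  larger than VENC are removed by 2·VENC shifts, sequential from frame
  0 — then spatial region growing from the static seed: a voxel whose
  time-mean differs from the median of its already-unwrapped 6-neighbors
  by more than VENC is shifted, in all frames, by the nearest multiple
  of 2·VENC. Growth is restricted to the body (magnitude above the
  static threshold); air phase is meaningless and left untouched. Every
  change is by construction a multiple of 2·VENC, and unaliased input
  passes through bit-identical.
* **Dual-VENC merge**: per voxel/component/frame, keep v_low if
  |v_low − v_high| ≤ VENC_low (ties keep the low value — deterministic
  boundary), else shift v_low by the nearest multiple of 2·VENC_low; a
  shifted value still further than VENC_low from v_high falls back to
  v_high and is flagged. A `per_vector` flag moves the aliasing
  decision to whole velocity vectors for software that merges
  vector-wise. Provenance records the per-voxel source.
* **PC angiogram**: time-mean of magnitude·|v|; the lumen is the
  26-connected component(s) above a threshold fraction (default 0.1) of
  the intensity maximum containing the seed points (or the global
  maximum). Slow small vessels lose their near-wall shell at any
  positive threshold; on the default phantom the Dice overlap with the
  true lumen is ≈ 0.94.

## Quantification

Analysis planes are square pixel grids (pixel = half the smallest voxel
spacing) spanning the lumen disc plus one pixel of margin; velocity is
trilinearly interpolated at pixel centers and the through-plane
component integrated per frame (cm/s·mm² → mL/s via 0.01). The default
contour radius is 1.15× the lumen radius so the partial-volume skirt of
edge voxels — which carries real momentum after trilinear smearing — is
captured; without it flows bias low by a few percent. Plane alignment
iterates the normal toward the mean lumen velocity direction until the
change is below 0.5°. Flux is exactly linear in the field and exactly
antisymmetric under normal flips.

%CVO values are rounded half-away-from-zero to integers, matching how
flow distributions are reported. The junction percent difference uses
the mean of the two sides as denominator (symmetric and bounded); an
inflow-denominator variant is config-exposed. The consistency summary
reports the sample standard deviation (n−1), with SD = 0 flagged at
n = 1. Method comparison uses ordinary least squares with a
normal-theory 95% slope interval, Bland-Altman bias ± 1.96·SD(diff),
and a two-sided paired t-test (undefined and flagged when the
differences have zero variance). On the default phantom, measured mean
flows land within ~2% of the analytic oracles and all four junction
identities close below 2%; the residual is partial-volume flux loss,
common-mode across vessels of similar caliber and hence largely
cancelling in the junction differences.

## Pathlines and streaming

Particles are advected with classical RK4 (exact on uniform fields,
fourth-order otherwise, verified by step-halving on a rigid-rotation
field where trilinear interpolation is exact). Sampling is trilinear in
space and linear in time with periodic wrap — the last cardiac frame
interpolates to the first. Between boundary voxel centers and the
volume faces the edge value is extended rather than faded to zero, so
escaping particles terminate as `exited_volume` instead of stalling.
Default dt = period/(40·frames); default emission 500 particles per
plane, uniform over the lumen pixels of the emitter (seeded RNG,
jittered within pixels, rejection-sampled against the contour).
Integration itself is deterministic. Pathlines are integrated through
the time-varying field (the physically meaningful choice); a steady
field simply has identical frames.

Streaming matrices assign each particle to the *first* sink region its
trajectory enters — so a particle transiting the right atrium and then
the foramen ovale is credited to the FO, matching the shunt-routing
question — with never-arriving particles counted as `unassigned`;
fractions over emitted particles sum to one exactly.

On an engineered Y-split phantom carrying an 80/20 flux split with
velocity-matched branches, uniform-area emission recovers a
0.78 ± few-hundredths FO fraction: slightly below the flux fraction
because the slowest near-wall particles (a few percent of the emitted
area) never reach a sink within the integration window, and because
area-uniform seeding under-weights the fast core relative to
flux-weighted seeding. Both effects are inherent to particle counting
in laminar flow, affect real 4D-flow particle traces identically, and
stay well within a ±0.1 tolerance.

## What the phantom does and does not emulate

Emulated: pulsatile laminar flow in a branching fetal network,
phase-velocity encoding with aliasing at multiple VENCs, smooth
eddy-current-like background phase, Gaussian phase/magnitude noise,
partial-volume effects at vessel walls, static tissue and air
compartments. Not emulated: k-space acquisition and parallel-imaging
artifacts, coil sensitivities, fetal or maternal motion and gating
errors, turbulence or secondary (non-axial) flow, intra-cardiac
chambers (the heart is collapsed to junction nodes), T1/T2 contrast.
Passing phantom tests therefore demonstrates correctness of the
*processing* — not robustness to motion or sequence artifacts, which
dominate real in-utero data quality.

## Numerical and design notes

* Phase wrapping uses the half-open convention (−π, π]; the identity
  v = VENC·φ/π is exact at ±VENC.
* Background polynomials are evaluated on coordinates normalised to
  [−1, 1] across the volume, keeping design matrices well-conditioned
  at any field of view; fitting and simulation use the same basis
  construction but are independent computations.
* The merge fallback (source code 2) cannot fire on exact arithmetic —
  the nearest 2·VENC multiple is always within VENC_low of the
  referee — it exists as a guard for noisy or inconsistent inputs.
* Degenerate inputs raise early with specific messages: empty static
  masks, fewer static voxels than polynomial coefficients, empty lumen
  contours, zero mean velocity during plane alignment, overlapping sink
  regions, out-of-grid vessel segments (named), unbalanced junctions.
* Test problem sizes: the full-geometry rig (96³ × 8 frames, dual VENC)
  is built once per session and shared across end-to-end tests; unit
  tests use 48³–72³ single-vessel phantoms.

## Known limitations

* The phantom's junction blending is kinematic, not incompressible;
  velocity fields near junctions do not satisfy a divergence-free
  constraint, so flux planes should sit at mid-segment (the default).
* Angiogram segmentation is a threshold/connected-component rule, not a
  centerline tracker; very slow vessels adjacent to fast ones can fall
  below any global threshold.
* The in-vivo method-comparison statistics (regression slope, R², bias
  against 2D PC-CMR) depend on real acquisitions and are exercised here
  only on synthetic pairs with known ground truth.
* Spatial unwrapping assumes aliased regions are reachable from static
  tissue through the body; fully enclosed aliasing islands with no
  smooth path to a seed would be missed.
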