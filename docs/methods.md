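# Methods

This note documents the models, algorithms, defaults, and known limitations of
`pbsautoplan`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the acceptance script, not
asserted from outside.

## Scope and model overview

The toolkit automates a four-field multi-field-optimized (MFO) pencil-beam-
scanning (PBS) proton planning technique for bilateral head-and-neck (H&N)
targets: a horseshoe-shaped elective nodal CTV wrapping the midline, prescribed
50 CGE in 25 fractions, treated with beams at gantry 30°, 330°, 135°, and 225°
(a "modified X"). The pipeline stages are

1. **Planning-structure construction** (`structgen`): anterior-beam avoidance
   (oral cavity minus target, plus dental hardware, plus an 8 mm margin),
   posterior-beam shoulder avoidance (everything inferior to the shoulder
   apex plane), a posterior-neck midline structure (spinal cord grown
   laterally and posteriorly), a 5 mm skin rind, the below-shoulder SFO
   region, and external-minus-target.
2. **OAR dose prediction** (`oar_predict`): simulated isodose rings around the
   target at every 10% of prescription, from a monotone distance-to-dose
   fall-off model; ring–OAR overlap predicts mean dose and DVH points for the
   peripheral OARs (parotids, oral cavity, larynx, trachea — never the
   esophagus, which the target surrounds).
3. **Spot placement** (`beamspot`): lateral lattice at the 80% overlap
   spacing, energy layers on a fixed water-equivalent-thickness (WET) grid,
   followed by minimum-depth, minimum-energy, and avoidance filtering.
4. **Minimax robust optimization** (`robust_opt`): 15 scenarios (2 mm
   right/left/superior/inferior collective shifts × {−1%, 0, +1%} range
   scaling), one-sided quadratic penalties, non-negative spot weights.
5. **Robust evaluation** (`evaluate`): 24 perturbations — 3 mm patient shifts
   (±x, ±y, ±z), ±3.5% range scaling, ±3° roll and yaw, and 3 mm independent
   shifts of one anterior and one posterior beam — with the pass rule that
   the target D95% changes by at most 3% of its nominal value on any
   perturbation.

## Coordinate and beam conventions

Right-handed patient frame: x toward the patient's left, y anterior,
z superior. Voxels are addressed by their centers; masks are voxel-center
membership, with no partial volumes. Gantry 0° enters from anterior and
increases clockwise viewed from superior, so a beam is *anterior* iff its
angle lies in (270°, 360°] ∪ [0°, 90°); the four standard angles split two
anterior (30°, 330°) and two posterior (135°, 225°). Beams are modeled as
parallel (no divergence); the 5 cm anterior / 10 cm posterior air gaps are
recorded as snout positions along each beam axis and reserved for a future
divergence model.

## Machine model

* Bragg–Kleeman range–energy law `R(E) = α·E^p` with `p = 1.77` and α
  calibrated so the minimum deliverable energy, 97.5 MeV, has a 7.5 cm range
  in water. The anchor is exact by construction.
* Spot size 16 mm FWHM in air (σ_air ≈ 6.79 mm); spot spacing from the 80%
  overlap rule, `s = 2 σ_air √(2 ln(1/0.8)) ≈ 9.08 mm`.
* 7.5 cm WET range shifter on every beam; minimum in-patient radiological
  depth 0.5 cm per spot; deliverable MU window: minimum spot weight 0.2 MU
  (in the engine's MU unit — one MU gives one CGE at the Bragg peak in
  water), maximum 150× the minimum.
* Energy layers every 5 mm WET, with a 5 mm distal WET margin beyond the
  deepest target WET per lateral position, a standard range-robustness
  allowance.

## Analytic pencil-beam dose engine

Monte Carlo transport is out of scope; the engine is an analytic stand-in
whose *relative* plan structure is what matters. Each spot deposits

    dose(v) = S(E) · f(W(v); R) · exp(−ρ²/2σ²) / (2πσ²)

with `W(v)` the accumulated WET (shifter included) along the beam to the
voxel, `f` a plateau-plus-Gaussian-peak depth-dose,

    f(w; R) = ½ erfc((w−R)/√2 σ_R) + (r_pp − ½) exp(−(w−R)²/2σ_R²),

peak-to-plateau ratio `r_pp = 3.5`, and lateral width
`σ(d)² = σ_air² + (10 k_mcs d)²` (mm, depth d in cm, `k_mcs = 0.05`). The
Bragg-peak width combines range straggling `0.012 R^0.935` cm with a beam
energy-spread term of 4.5% of range, added in quadrature. The energy-spread
default emulates the heavily degraded spectrum of a low-energy beam behind a
7.5 cm range shifter at a large air gap, for which distal 80%–20% fall-offs
of roughly a centimetre are realistic; a sharper setting makes the engine's
SOBPs unrealistically brittle under the ±3.5% range evaluation, because the
energy-layer comb and the distal edges then dominate the perturbation
response. The lateral profile is normalized to unit integral at every depth
and truncated at 3.5σ; `S(E)` is set so one MU yields one CGE at the peak in
water. The depth-dose maximum sits at the spot's range to within one depth
step.

WET bookkeeping runs on two consistent paths: per-ray Siddon traversal
(`trace_wet`, exact voxel crossings; used by spot placement and avoidance
filtering) and a beam-frame resampling with a cumulative sum along depth
(`geometry.BeamFrame`; used by the dose engine for speed). Both include the
shifter WET and scale only patient material under a range-uncertainty
scenario.

Scenarios are realized as the inverse rigid transform of the beam geometry
about the isocenter: patient translation shifts the beam frame the opposite
way; roll (about y) and yaw (about z) rotate the beam axes; per-beam shifts
move only that beam's frame; rotations beyond 15° are rejected as outside the
model's validity.

## Objectives and optimizer

The automated objective set: robust minimum dose at prescription and robust
minimum-DVH D97% > 97% on the CTV; a dose fall-off on external-minus-target
(allowed dose ramps from prescription at the target boundary to 50% at 20 mm,
constant beyond); robust and non-robust external maximum dose (110%/105%);
maximum dose on the skin rind (75%), posterior-neck structure (55%), brachial
plexus (100%), spinal cord (55%), and brainstem (50%); a per-anterior-beam
maximum (60%) on the SFO region; and predicted mean-dose objectives on the
peripheral OARs at their ring-model values. Levels and weights are package
defaults (target 400, maximum-dose 10, mean-dose 1), chosen once so the
default phantom plan is simultaneously covered, robust, and OAR-sparing; all
are configurable. Penalties are one-sided quadratics normalized by structure
volume and prescription squared.

The minimax objective — non-robust terms on the nominal dose plus the worst
scenario's robust terms — is minimized over non-negative weights either by
bound-constrained L-BFGS on a log-sum-exp smoothing of the scenario maximum
(default; temperature 5% of the initial worst-case value) or by projected
subgradient descent on the active worst scenario with backtracking line
search (`method="subgradient"`; accepted iterates are monotone in the exact
minimax objective). Initialization is deterministic: uniform weights scaled
so the median target dose equals prescription. Stopping: 500 iterations or
relative objective change below 1e-5; hitting the budget returns the best
iterate with a warning, not an error.

Robust scenario matrices restrict their rows to the CTV plus a strided sample
of the remaining body voxels (default every 13th), keeping the 15 influence
matrices desk-scale; the nominal matrix covers every body voxel.

Deliverable-MU enforcement deletes spots below half the minimum MU, clips
survivors up to the minimum, and caps weights at 150× the minimum, so the
final nonzero max/min ratio never exceeds 150.

## Synthetic phantom

The phantom emulates a bilateral H&N case on a 4 mm isotropic grid
(56×56×72): an external contour of stacked elliptical sections (shoulder
slab, neck, head), a horseshoe CTV50 (annulus of inner radius 26 mm, outer
46 mm, open 35° half-angle posteriorly around the cord) spanning 164 mm
craniocaudally with bilateral supraclavicular arms reaching below the
shoulder apex, and OARs placed as in the clinical pattern: oral cavity
anterior (overlapping the target's anterior arc), parotids lateral and
abutting, spinal cord posterior midline inside a bony shell (RSP 1.4),
brainstem as its superior continuation, larynx/trachea/esophagus midline
(trachea air-filled, RSP 0.001), paired brachial-plexus cords, and optional
dental hardware (RSP 7.0) inside the oral cavity. Soft tissue has RSP 1.0.
The default CTV50 volume is ≈ 485 cm³, inside the 352–537 cm³ span of
bilateral H&N nodal targets. A seeded ±2 mm jitter of structure centers
varies the anatomy without changing any structure's topology. The wall of
the nodal horseshoe is 20 mm thick; much thinner walls are dominated by
boundary voxels at 4 mm resolution and make the D95 robustness metric
unrepresentatively brittle.

What the phantom does **not** emulate: CT texture and heterogeneity beyond
the four materials, realistic nodal-level shapes, breathing or posture
variation, and site-specific differences between patients. Passing the
end-to-end checks therefore demonstrates the *pipeline's* correctness and the
planning technique's internal consistency on a representative geometry, not
clinical performance on patients.

## Problem sizes and numerical choices

Shipped examples run the full pipeline at 4 mm resolution: ≈ 7 400 spots over
four beams, ≈ 80 000 body voxels in the nominal influence matrix, 15
optimization scenarios on ≈ 13 000 restricted rows, and 24 evaluation
scenarios on the ≈ 7 500 target voxels — a desk-scale configuration chosen so
a complete plan optimizes in a few minutes on one core. DVHs use 0.1 CGE
bins with voxel counting; Dv queries resolve plateaus to their high-dose
edge, matching the sort-based order statistic. DVH-band fractions count a
perturbed point as "within q%" when it differs from nominal by at most q% of
prescription (inclusive); the D95 deviation is measured relative to the
nominal D95. Dilation/erosion are Euclidean on voxel centers via exact
distance transforms (ties included, `≤ margin`); the posterior-neck
expansion uses rectangular per-axis margins (lateral ±x, posterior −y only),
matching commercial directional-margin semantics with corners included.

## Known limitations

* The dose engine is analytic: no nuclear halo, no heterogeneity-induced
  peak degradation beyond the WET line integral, fixed RBE folded into CGE.
* Parallel-beam geometry; air gaps are bookkeeping, not divergence.
* Maximum-dose penalties are volume-normalized, so isolated hotspot voxels
  are weakly penalized; nominal hotspots around 125–130% of prescription
  remain in the shipped example. Controlling them would need voxel-wise or
  quantile hotspot penalties, which are out of scope for the printed
  objective set.
* The ring prediction model assigns ring-midpoint doses; its error bound is
  half a ring (5% of prescription), which the self-consistency tests assert.
* Optimization-time robustness uses the clinical 15-scenario family; the
  evaluation's rotations and independent-beam shifts are never optimized
  against, so their margins come entirely from the technique (beam number,
  avoidance design, SFO region), as intended.
* The hardest evaluation scenario is the +3.5% range scaling: optimizing at
  ±1% leaves the default-phantom plan just inside the 3% D95-change rule
  (≈ 2.9%), and jittered anatomy variants can land slightly past it
  (≈ 3.1–3.3% on the range scenario; every other scenario stays ≤ 2.4%).
  The gap is structural — all four beams' depth-dose patterns slide together
  under a range error, and a 20 mm-thick nodal wall is boundary-dominated at
  4 mm resolution — and is insensitive to optimizer weight, temperature,
  iteration budget, and energy-layer spacing within the fixed optimization
  protocol.
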