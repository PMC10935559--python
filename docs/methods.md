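# Methods

This note documents the models, numerical choices and synthetic-bench
design behind `pftwin`, in the spirit of a methods appendix: what is
simulated, under which assumptions, with which defaults, and what the
package's own tests do and do not demonstrate about real data.

## Mechanical model

Three rigid bodies: femur, tibia(+foot), patella.  The femur is pinned at
a fixed hip point by a spherical joint; femur and tibia are *guided* —
their full pose histories are rheonomic prescriptions built from
(synthetic) marker data — and the patella is free with six degrees of
freedom.  Elastic deformation of the bones is neglected (rigid-body
assumption), which is what makes the approach orders of magnitude cheaper
than finite elements at the cost of losing stress/strain fields.

Tendons are linear spring-dampers, `F = K (L − L0) + c L̇` with
`c = 0.01 K` by default.  The damping sign is chosen dissipative — the
damper resists length change — because a sign that injects energy over a
closed cycle contradicts the model's purpose; the opposite (as sometimes
printed) convention is available behind `printed_damping_sign=True`.
Each tendon is realized as a two-strand strap (K/2 per strand, strands
offset ±6 mm in the medial-lateral direction at both ends).  A single
point-to-point spring cannot be the whole story for the patella: the
contact force of a spherical button passes through the sphere center and
exerts no torque, so with two point springs the patella's orientation is
nearly indifferent and can flop or spin.  The strap pair adds the
orientation stiffness the physical straps provide.  With the default
anchor heights (below the patellar attachment plane) the groove-aligned
orientation is elastically stable about all three axes; the strap
attachments sit on the posterior face of the patella (z = −6 mm) for the
same reason.

Contact is normal-only (the physical bench lubricates the interface, so
friction is excluded) and follows the Flores model

    F_n = k_n δ^p [ 1 + 8(1−ε)/(5ε) · δ̇/δ̇₀ ] n ,

clamped non-adhesive.  Defaults: Hertz exponent `p = 3/2` (smooth
non-conforming contact), restitution `ε = 0.9` (nearly elastic, lubricated
interface), and generalized stiffness `k_n = 1e7 N/m^1.5`.  The stiffness
is an *effective bench compliance*: bulk Hertz theory for rigid polymers
would give ~1e8–1e9, but the printed parts, mounts and the force-sensor
stack are far softer; 1e7 puts static indentations at tens of micrometers
and contact forces at the tens of newtons the bench instruments record.
`δ̇₀` is latched per contact episode at first detection.  Episodes that
open without a clearly positive approach speed (> 1 mm/s) — initialization
inside contact, grazing starts — run purely elastic: normalizing by a
near-zero or negative impact speed would make the damping factor diverge
or flip sign (this failure mode is real; we hit it).

## Integrator

Augmented-Lagrangian index-3 formulation in Euler-parameter coordinates
(7 per body; the unit-norm condition is itself a constraint), Newmark
average acceleration (γ=1/2, β=1/4; unconditionally stable, second order),
iterating penalized constraint forces with multiplier updates until the
position residual meets `pos_tol = 1e-9`, followed by velocity and
acceleration projections onto the constraint subspace
(`vel_tol = 1e-9`).  The projected velocity residual is taken over the
constraint rows that touch free coordinates: rows acting purely on guided
bodies (e.g. the hip joint of the prescribed femur) carry the ~1e-9
interpolation inconsistency of the pose splines, which no projection of
the free coordinates can remove.  The penalty is
`α = max(1e7, 10/(β h²)) × (leading mass)` — tying α to the Newmark
leading term keeps the multiplier iteration contraction rate step-size
independent (a fixed α stalls at small h).  Guided coordinates are
eliminated from the unknowns, so the bench solves a 7-coordinate system.
Newton updates are clamped (2 cm) and a failing step is retried as 4
sub-steps (3 levels deep) before giving up; this is what carries the
integrator through the violent ridge-crossing transient of a dislocation.

Force Jacobians: springs/gravity by finite differences, refreshed every
`jac_refresh = 5` steps; contact contributes its dominant analytic block
`k_c n nᵀ` on the sphere body's translations.  An inexact tangent only
affects the iteration count, not the converged solution.

Time steps: 1 ms for the analytic backend; 0.1 ms for mesh backends
(switchable to 0.05 ms).  With mesh backends the default is additionally
one geometric detection per step (`contact_mode="per_step"`): the patch is
frozen at the predictor and the indentation updated to first order along
the frozen normal within the Newton loop.  Against the analytic backend
this approximation changes forces by < 1e-4 N at 1 ms steps.

Static equilibrium: inner Newton at fixed multipliers with Armijo
backtracking and step clamping, outer multiplier updates, a
kinetic-damping dynamic-relaxation fallback (velocities zeroed every 10
steps), and a Levenberg–Marquardt polish of the residual.  For mesh
backends the equilibrium is solved on the smooth analytic twin of the same
groove and the state handed over — facet noise puts a micrometer-scale
floor under the mesh residual that defeats a 1e-8 N tolerance.

## Collision backends

*Mesh-to-mesh*: AABB trees (median split of the dominant axis, one
triangle per leaf) over both meshes.  Per query the patella's box is
pushed through the femur tree, both candidate sets are iteratively shrunk
to their mutual overlap region, surviving box pairs go through a
vectorized triangle–triangle intersection, the segments are chained into
closed contours, and each contour yields one patch: length-weighted
centroid as the contact point, area-weighted femur-face normal, and the
maximum penetration depth of patella vertices below the femur surface as
δ.  Open chains fall back to a deepest-point contact with a warning;
near-coplanar triangle pairs are resolved by a deterministic 1 nm jitter.

*Analytic*: the button is a sphere, the implant a fitted polynomial height
field.  The foot point solves the two-equation stationarity system by
Newton, warm-started from the previous foot point plus the vertical
projection; cold starts (and warm-start failures) fall back to a 5×5 seed
grid over the fit domain, keeping the global minimum — the groove ridges
create genuine local minima.  The surface is not extrapolated: a foot
point leaving the fit domain ends the contact episode and is logged as a
candidate dislocation marker.

The monomial basis is centered/scaled to the fit domain before the
least-squares solve (SVD; normal equations are never formed) and mapped
back, which keeps order-5 fits well conditioned.  R² is computed on the
fitting cloud.  Mesh-refinement-style emphasis near the lateral ridge is
exposed as per-point weights and as a grid-density weight in the mesh
generator.

## The synthetic bench

No implant CAD or motion captures are distributed with the original
bench, so the package generates an equivalent one with known ground
truth.  Design constraints that shaped it:

* The femoral contact surface is a closed-form height field in the
  femoral frame (x sagittal toward the hip, y medial, z toward the
  patella): a convex parabolic sagittal arc (radius 0.10 m over a 0.8 rad
  extent) plus a quintic medial-lateral cross-section with stationary
  ridges at ±24 mm, ridge heights `gain × 4.5 mm` (lateral gain 1.15,
  medial 1.0), falling off beyond the ridges so a dislocating patella can
  actually leave.  The full field is a bivariate polynomial of total
  degree 5, so the P5 fit is exact (R² = 1) and the analytic backend has
  zero geometric error — the mesh backends can be benchmarked against an
  exact reference.  The fitted R² ordering (P2 ≈ 0.84 < P4 ≈ 0.999 < P5 = 1)
  mirrors the qualitative behavior expected of increasing order.
* The groove-bottom transverse curvature radius (~22 mm) stays above the
  button radius (15 mm); a conformal groove would make the closest-point
  problem degenerate (two symmetric minima).
* Anchor geometry (quadriceps support at x = 0.21 m, z = 5 mm; tuberosity
  at 9 cm below the knee on the tibia) was chosen so that both straps stay
  taut through the motion, tension rises with flexion (tibial strap
  ~8→20 N, quadriceps ~7→10 N), and the tension always presses the button
  into the groove (anchors below the local tangent plane).  Medial support
  positions are nearly centered (+3 mm); lateral positions (−15 mm femur,
  −28 mm tibia) model an increased Q-angle.  With both lateral the
  lateral pull (~2–3 N) exceeds the ridge's restoring capacity only when
  the normal load drops near full extension — the patella rides at
  −10..−15 mm through mid-flexion and crosses the ridge at the end of
  extension, reproducing the "dislocation at complete extension"
  phenomenology; medializing only the tibial attachment (the modeled
  tibial tuberosity transfer) keeps the patella within ~2 mm of center.
* Motion: piecewise-cosine flexion profiles, C¹, with exactly one local
  maximum per cycle.  The default capture is two cycles over 6 s starting
  at 45°, peaking at 60° with a partial (20°) first extension and a
  complete second extension.  The 60° ceiling is a limitation of the
  single-patch polynomial surface: beyond ~65° the tuberosity rotates far
  enough posterior that the shallow-arc geometry no longer pulls the
  patella distally, so tracking is studied over 0–60°.  Event/calibration
  fixtures use one fast 1.2 s cycle (45→60→0°) to keep run times short.
* Markers: femur 2 + known hip-joint entity, tibia 3, patella 3 (eight
  markers total), 100 Hz, optional iid Gaussian noise.  Clusters span
  ≥ 9 cm so 0.5 mm marker noise maps to sub-degree orientation error.
* Masses: patella 30 g (solid-sphere inertia), femur 0.4 kg, tibia 0.5 kg
  (guided, so only their prescribed motion matters).  Gravity presses the
  button into the groove (bench lying horizontal).

What the bench does *not* emulate: real implant geometry (multi-patch,
non-polynomial), soft-tissue wrapping, marker soft-tissue artifact,
force-sensor noise, and tibiofemoral contact.  Passing tests therefore
demonstrate the correctness and internal consistency of the machinery —
contact detection, integration, reconstruction, calibration — on a bench
whose ground truth is known exactly, not clinical validity on a real knee.

## Signal processing

Butterworth low-pass: second order, 12 Hz cutoff, applied forward-backward
(zero phase, squared magnitude, exact unit DC gain) because guided
constraints need phase-true trajectories.  SSA: window 30, trajectory
matrix SVD, diagonal averaging; the default component selector keeps
singular values above 3× the median (a flat-noise-floor estimate), which
reduces broadband noise power by ~90 % on sinusoid-plus-noise benchmarks —
selecting by cumulative variance (e.g. 99 %) retains most of the noise and
is available but not the default.  Pose reconstruction builds an
orthogonal frame from three non-collinear entities (markers or known joint
points) and applies the same construction to the entities' body-frame
coordinates; noiseless closure is exact to machine precision.

## Kinematic reporting

Patellar kinematics are expressed in the femoral body frame to avoid
error accumulation: sphere-center position plus intrinsic Y–X–Z Euler
angles of the relative rotation — flexion (Y, medial-lateral), tilt
(X, patellar long axis), rotation (Z, anterior-posterior).  Validation
reports are channel-wise RMSE (forces in N, angles in degrees,
coordinates in mm) plus the mean Euclidean distance error of the sphere
center.  Event detection uses fixture-calibrated thresholds, logged with
every event: ≥ 50 ms of lost groove engagement with the center beyond the
lateral ridge line while the knee extends (dislocation), or ≥ 50 ms
superior to the groove entrance (0.75 × sagittal half-extent) past 30°
flexion with no engagement (high riding).

## Calibration and treatment prediction

The objective is the RMSE (mm) over frames of the Euclidean distance
between simulated and observed sphere centers in the femur frame — forces
are deliberately excluded, since intra-operative navigation provides
motion only.  Candidate simulations share the observed run's initial
state and collision backend; parameters (K1, L1, K2, L2) vary in a ±30 %
box.  The optimizer is a real-coded GA (tournament 3, blend crossover,
Gaussian mutation, elitism 1, seeded) with a bounded Nelder–Mead polish
of the best individual — the hybrid-GA pattern common in engineering
toolboxes.  Default budgets (population 8–12, 5–8 generations, ≤ 40
polish evaluations) keep a calibration under ~100 simulations; on
noiseless synthetic data the objective at the true parameters is exactly
zero and recovery lands within a few percent per parameter.
Identifiability is checked against sampled corners of the box rather than
a dense grid (a 5⁴ grid would cost 625 simulations for the same
conclusion).  Treatment prediction re-simulates the calibrated twin with
the edited attachment; an empty edit reproduces the baseline bitwise.

## Problem sizes

Defaults were sized for interactive use on one core: analytic-backend
steps run ≈ 3 ms, fine-mesh steps ≈ 17 ms.  The test-suite and acceptance
runs use the 1.2 s single-cycle fixture for events and calibration, a
0.8 s sweep at 2 kHz for backend comparison, and small GA budgets; the
6 s two-cycle capture remains the default for interactive scenarios.

## Known limitations

* Single-patch polynomial surface limits flexion range (~0–65°) and
  cannot represent a real implant's posterior condyles.
* No friction; no tibiofemoral contact; treatment edits are restricted to
  changes that do not affect the captured femur/tibia motion.
* The mesh backend's indentation (deepest penetrated vertex) is biased low
  by roughly the chordal tolerance; with the fine tolerances this is a
  few-percent force effect, with the coarse ones it contributes to the
  documented high-frequency artifact.
* Orientation dynamics of the patella are only as stiff as the strap
  geometry; tilt/rotation channels are soft modes and their RMSE is more
  sensitive to initialization than position channels.
* The GA is a small-budget global search; with real (noisy) data the
  objective's local minima (observed also in practice) would warrant
  larger populations or restarts.
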