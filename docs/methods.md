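# Methods

This note documents the models, numerical choices and limitations behind
`avmflow`. Everything below is implemented and exercised by the test suite;
no empirical claim is made beyond what the tests and `scripts/acceptance.py`
compute.

## Synthetic AVM generator

Patient imaging (3D rotational angiography and its segmentation) is outside
this package's scope, so study inputs come from a seeded generator that
emulates the anatomy classes of a segmented AVM model: a parent artery, N
feeders, a nidus, draining veins and veins.

Layout (SI units, meters, along the x axis of a configurable domain,
default 40 × 24 × 24 mm):

* **Parent artery** from the inlet to a branching point, jittered polyline.
  By default the artery continues past the branching point to its own
  outlet (`bypass_artery=True`), as a parent cerebral artery keeps
  supplying distal territory in vivo. The bypass also makes every
  blocked/unblocked variant hemodynamically feasible; switching it off
  yields topologies where the all-feeders-blocked variant has no open
  outflow path, which the pipeline records as infeasible.
* **Nidus**: `n_nidus_nodes` points sampled uniformly in a ball; edges from
  a random geometric graph whose distance threshold is chosen as the
  pairwise-distance quantile matching the requested mean degree, unioned
  with the Euclidean minimum spanning tree so the nidus is always
  connected. No generative model of real nidus architecture is claimed —
  only the compartment topology artery → feeder → nidus → drainer → vein.
* **Feeders** connect the arterial branching point to the nidus nodes
  nearest the arterial side; **drainers** leave from the nidus nodes
  nearest the venous side into a confluence, and one vein reaches the
  outlet. Feeder entry and drainer exit nodes are disjoint (enforced by
  `n_nidus_nodes ≥ n_feeders + n_drainers`).
* **Radii** are drawn uniformly per compartment; defaults reflect cerebral
  calibers (artery 1.5–2.0 mm, feeder 0.4–0.8 mm, nidus 0.15–0.35 mm,
  drainer 0.8–1.2 mm, vein 1.5–2.5 mm radius).

All randomness flows through one `numpy` generator seeded from the config;
two runs with equal configs produce byte-identical JSON serializations.

What the generator does **not** emulate: real nidus compactness and
plexiform/fistulous subtypes, vessel tapering, tortuosity statistics,
flow-associated aneurysms, and imaging artifacts. Tests passing on these
synthetic networks therefore validate the algorithms (enumeration, solving,
export, advection), not anatomical realism.

## Virtual embolization

Occlusion is modeled as *removal* of the feeder edge from the flow graph —
infinite resistance — rather than a large finite resistance, matching a
complete sclerosant occlusion and avoiding ill-conditioned systems. The
occlusion marker sits at the feeder's distal (nidus-side) centerline end,
where the agent is deposited in practice; its display length is 10 % of the
feeder length.

`enumerate_variants(n)` returns all `2^n` states in lexicographic order
(all-open first), so a 3-feeder case yields 8 flow solutions.

The ordering heuristic sorts feeders by (diameter ascending, centerline
path distance from the inlet ascending, segment id). Diameter is ranked
before proximity because the clinical rule names small caliber jointly with
proximal location but a deterministic lexicographic order is needed;
"proximal" is quantified as shortest-path centerline distance from the
inlet, a pragmatic metric rather than a clinically standardized one. The id
tie-break makes the plan invariant to segment-list permutations.

## Reduced-order hemodynamics

The reference workflow runs 3D finite-volume CFD on polyhedral/prism meshes
per variant. That is deliberately replaced here by a 0D/1D resistor-network
model — the standard lumped-parameter reduction for laminar vessel flow —
because it is desk-scale, analytically testable, and preserves the same
fluid model and boundary conditions:

* incompressible Newtonian blood, ρ = 1055 kg/m³, η = 4 mPa·s;
* steady laminar flow in rigid vessels;
* fixed inflow: `Q_in = v_in · A_in` with `v_in` the constant inflow
  velocity (case templates 0.1 m/s for the simplified case, 0.39 m/s for
  complex cases; published values report these inflows with units printed
  as m/s², read here as velocities). When a reference velocity/area pair is
  supplied, the inflow is rescaled as `v = v_ref · A_ref / A_case`,
  preserving volumetric flow — the flow-preserving reading of
  "scaled by the ratio of cross-sectional inflow areas";
* zero pressure at every outlet.

Each segment's resistance is `R = 8ηL/(πr⁴)` with `L` the centerline
polyline arc length. Nodal pressures solve the weighted graph Laplacian
with outlet rows eliminated (pinned to 0 Pa), a symmetric positive-definite
sparse system handled by a direct sparse solve. Components with an inlet
must reach an outlet, otherwise the variant raises a "no open outflow path"
error; components with neither source nor sink are stagnant (0 Pa, zero
flow). Nidus vessels are treated like any other segment — no porous-medium
closure is introduced. The mass-balance residual at interior nodes is
audited after every solve; across 100 seeded networks it stays at the
1e-15 level, far inside the 1e-9 contract.

Limitations: no wall shear stress, no pulsatility, no non-Newtonian
rheology, no 3D secondary flow — the solver predicts per-segment flow rates
and pressure drops, which is what variant comparison needs.

## Velocity-grid reconstruction and file formats

The particle engine needs a per-voxel velocity texture. For a solved
network the field is reconstructed analytically: a voxel center at distance
`d ≤ r` from a segment centerline gets velocity `2 v̄ (1 − (d/r)²)` along
the local tangent, signed by the flow direction — the Poiseuille profile
consistent with the laminar model, satisfying no-slip at the wall and
integrating to the solver's `Q` (grid-summed cross-section flux agrees with
`Q` to ≈ 0.9 % at step = r/5). At junctions, where tubes overlap, the voxel
is claimed by the tube whose *wall* is nearest (smallest `d − r`), which
keeps the profile continuous for vessels of unequal caliber. Blocked
vessels and extra-luminal space are zero.

The sampling lattice defaults to a 0.2 mm step, with the origin one step
below the lumen bounding box and `ceil(extent/step)+1` points per axis;
each dim must fit in 16 bits.

**VF format**: magic `VF_F`, three little-endian uint16 dims, then
`nx·ny·nz` little-endian float32 vector triples with x varying fastest —
exactly `10 + 12·nx·ny·nz` bytes. Only the 3-component float dialect is
implemented (scalar `VF_V` textures are not needed). Round trips are
bit-exact by test.

**Legacy VTK ASCII** is the supported entry point for externally simulated
fields (POINTS + VECTORS, or a 3-wide FIELD array); binary legacy and XML
dialects are rejected. Scattered samples are binned to the grid by
per-voxel arithmetic mean — a deterministic, order-independent kernel
chosen over nearest-neighbor or inverse-distance weighting; empty voxels
stay zero and out-of-bounds samples are counted in a warning, never fatal.
Text round trips use 12 significant digits.

## Particle engine

The lifecycle mirrors a GPU visual-effect graph. *Spawn* draws
`floor(accumulated spawn_rate · dt)` positions uniformly on the inlet disc
(fractional parts carry over), clamped so the population never exceeds
`max_alive` (default 2,000,000, the capacity exercised by the acceptance
check); *initialize* is folded into spawn (age 0, velocity looked up).
*Update* integrates each particle with explicit Euler or classic RK4 over
the trilinearly interpolated field — the interpolant is exact for linear
fields, so a solid-rotation benchmark isolates integrator error: RK4 holds
the orbital radius to ~5e-12 relative over a full revolution at dt = 0.01 s
and exhibits its fourth-order convergence down to the float32 storage noise
of the grid. Particles are killed when their age exceeds the lifetime or
when they *move into* a zero-velocity voxel (outside the lumen); a particle
resting in a stagnant voxel merely ages out, and positions beyond the grid
sample the (zero) border voxels. *Output* writes VTK PolyData snapshots
with speed and RGB attributes.

Color scales are piecewise-linear with documented stops at
t = 0, 0.25, 0.5, 0.75, 1: rainbow blue→cyan→green→yellow→red, heated body
black→red→orange→yellow→white; speeds clamp to [vmin, vmax]. The exact stop
values are implementation choices. The ghosted-view weight per vertex is
`α = α_min + (1 − α_min)(1 − |n̂·v̂|)^k` from area-weighted vertex normals;
rendering itself (blend modes, textures, VR) is out of scope — the engine
exports attributes, not pixels.

## Tube meshes and voxelization

Surface meshes are per-segment capped tubes (parallel-transport frames, s
ring vertices per centerline point, triangle-fan caps), outward-oriented by
signed-volume test, labeled per vertex — adequate for display and labeling;
boolean union into a watertight surface is out of scope. Lumen voxelization
marks a voxel inside iff its center lies within one radius of a centerline;
steps coarser than the smallest radius trigger an undersampling warning
rather than an error. The analytic-cylinder check (count vs `πr²L/step³`)
agrees within 10 %, the residual coming from lattice quantization and the
spherical end-cap volume inherent to the distance-to-polyline definition.

## Problem sizes

Default study conditions: 3-feeder (simplified) and 8-feeder (complex) case
templates; 0.2 mm grids (~10⁶ voxels for the default domain); 100 seeded
networks for the conservation audit; 628 RK4 steps for the orbit benchmark;
one spawn+update cycle at 2,000,000 particles for the capacity check. The
full pipeline on the 3-feeder case (8 variants with VF export) completes in
about one second on a single CPU.
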