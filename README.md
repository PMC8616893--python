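# avmflow

Virtual embolization planning for cerebral arteriovenous malformations
(AVMs), as a scriptable Python toolkit.

An AVM is a tangle of aberrant vessels — the *nidus* — connecting feeding
arteries directly to draining veins without a capillary bed. Endovascular
treatment occludes the *feeders* one by one with a sclerosing agent, and
because blocking one feeder redistributes flow (and rupture risk) into the
others, planners want to preview the hemodynamics of every blocked/unblocked
combination before touching the patient. `avmflow` provides that preview
loop at desk scale:

1. **Synthetic vasculature** — a seeded generator emits labeled vessel
   networks (`artery -> feeder -> nidus -> drainer -> vein`) with geometry,
   radii, tube meshes, and lumen voxelization.
2. **Virtual embolization** — all `2^N` feeder blocked/unblocked variants,
   occlusion markers at the feeder–nidus transition, and the clinical
   ordering heuristic (small, proximal feeders first, venous outflow kept).
3. **Hemodynamics** — steady laminar flow of incompressible Newtonian blood
   (ρ = 1055 kg/m³, η = 4 mPa·s) on the vessel graph: every segment is a
   Hagen–Poiseuille resistor `R = 8ηL/(πr⁴)`, Kirchhoff conservation
   `Σ Q = 0` holds at interior nodes, with a fixed inflow velocity at the
   inlet (0.1 or 0.39 m/s case templates) and zero-pressure outlets.
4. **Field export** — the solved flow is sampled onto a Cartesian grid
   (default 0.2 mm step) with the analytic Poiseuille paraboloid
   `v(d) = 2 v̄ (1 − (d/r)²)` per vessel, and written as a binary VF
   3D-texture (`VF_F` magic, uint16 dims, little-endian float32 vectors)
   consumable by game-engine particle systems. Externally simulated fields
   arriving as legacy ASCII VTK point clouds can be resampled to the same
   grids.
5. **Particles** — a seeded advection engine (Euler/RK4, trilinear
   sampling, spawn-rate accounting, 2,000,000-particle capacity, lifetime
   and lumen-exit culling) with rainbow / heated-body color scales and
   view-angle ghosting weights, exporting VTK snapshots.

## Worked example

```python
from avmflow import (SyntheticAVMConfig, generate_synthetic_avm,
                     EmbolizationState, solve_flow, flow_change_report)

net = generate_synthetic_avm(SyntheticAVMConfig(n_feeders=3, seed=42))
base = solve_flow(net)                                # all feeders open
var = solve_flow(net, EmbolizationState((False, True, True)))
for row in flow_change_report(net, base, var):
    print(row["feeder_id"], row["blocked"], f"{row['relative_change']:+.1%}")
```

prints

```
1 False +77.3%
2 True -100.0%
3 True -100.0%
```

— feeders 2 and 3 are occluded (−100 % by convention) and the surviving
feeder 1 picks up 77.3 % more flow, the redistribution a planner wants to
keep small across embolization steps.

The same loop from the shell:

```bash
avmflow generate --case simple --seed 42 --out net.json
avmflow embolize --network net.json --plan 1      # embolization order
avmflow pipeline --case simple --seed 42 --out-dir run/
```

The pipeline writes, for each of the 8 variants of the 3-feeder case, a
per-feeder flow report (CSV) and a VF velocity texture, plus a
`manifest.json` with SHA-256 checksums; re-running with the same seed
reproduces the files byte for byte.

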