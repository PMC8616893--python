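"""End-to-end virtual embolization pipeline.

Reproduces the planning workflow on a synthetic case: generate the vascular
network, enumerate every blocked/unblocked feeder combination, solve the
steady flow for each variant, reconstruct a Cartesian velocity texture,
export it as a VF file, and (optionally) advect particle snapshots.  Every
artifact is listed in a manifest with SHA-256 checksums so a re-run into a
clean directory can be verified byte for byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .embolize import EmbolizationState, apply_embolization, enumerate_variants
from .fieldio import grid_spec_for_network, reconstruct_velocity_field, write_vf
from .hemoflow import (
    BoundaryConditions,
    FluidProperties,
    FlowSolution,
    NoOpenPathError,
    flow_change_report,
    solve_flow,
)
from .particles import (
    ColorScale,
    InletDisc,
    ParticleState,
    ParticleSystemConfig,
    advect_step,
    color_by_velocity,
    export_snapshot,
    spawn,
)
from .vessels import SyntheticAVMConfig, VascularNetwork, generate_synthetic_avm

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "case_template"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, with an explicit mandatory seed."""

    avm: SyntheticAVMConfig
    inlet_velocity: float = 0.1  # m/s
    grid_step: float = 2.0e-4  # m
    particles: ParticleSystemConfig | None = None
    n_snapshot_steps: int = 0
    out_dir: str = "avmflow_out"
    seed: int = 0

    def __post_init__(self) -> None:
        self.avm.seed = self.seed
        self.avm.validate()
        if self.inlet_velocity <= 0:
            raise ValueError("inlet_velocity must be > 0")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.n_snapshot_steps < 0:
            raise ValueError("n_snapshot_steps must be >= 0")


def case_template(name: str, seed: int = 0) -> PipelineConfig:
    """Built-in case templates.

    ``simple`` mimics a cropped introductory case: three feeders, inflow
    0.1 m/s.  ``complex`` mimics a full clinical case: eight feeders, inflow
    0.39 m/s.
    """
    if name == "simple":
        return PipelineConfig(
            avm=SyntheticAVMConfig(n_feeders=3, seed=seed),
            inlet_velocity=0.1,
            seed=seed,
        )
    if name == "complex":
        return PipelineConfig(
            avm=SyntheticAVMConfig(n_feeders=8, n_nidus_nodes=24, n_drainers=3, seed=seed),
            inlet_velocity=0.39,
            seed=seed,
        )
    raise ValueError(f"unknown case template {name!r}; use 'simple' or 'complex'")


_MM = 1e-3


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from YAML.

    Lengths in the file are in millimeters (``units: mm``, the only accepted
    value) and are converted to meters on load, so everything downstream is
    strictly SI.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    units = raw.get("units", "mm")
    if units != "mm":
        raise ValueError(f"unsupported units {units!r}: config files are in mm")
    avm_raw = raw.get("avm", {})
    kwargs = {}
    for key in ("n_feeders", "n_nidus_nodes", "n_drainers", "nidus_mean_degree",
                "bypass_artery"):
        if key in avm_raw:
            kwargs[key] = avm_raw[key]
    if "radius_ranges_mm" in avm_raw:
        ranges = SyntheticAVMConfig().radius_ranges  # defaults for absent compartments
        ranges.update(
            {
                comp: (lo * _MM, hi * _MM)
                for comp, (lo, hi) in avm_raw["radius_ranges_mm"].items()
            }
        )
        kwargs["radius_ranges"] = ranges
    if "domain_extent_mm" in avm_raw:
        kwargs["domain_extent"] = tuple(x * _MM for x in avm_raw["domain_extent_mm"])
    seed = int(raw["seed"])
    particles = None
    if "particles" in raw:
        particles = ParticleSystemConfig(seed=seed, **raw["particles"])
    return PipelineConfig(
        avm=SyntheticAVMConfig(seed=seed, **kwargs),
        inlet_velocity=float(raw.get("inlet_velocity_m_per_s", 0.1)),
        grid_step=float(raw.get("grid_step_mm", 0.2)) * _MM,
        particles=particles,
        n_snapshot_steps=int(raw.get("n_snapshot_steps", 0)),
        out_dir=raw.get("out_dir", "avmflow_out"),
        seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_flow_csv(path: Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=[
                "feeder_id", "blocked", "Q_m3_per_s", "mean_velocity_m_per_s",
                "delta_p_Pa", "relative_change",
            ],
        )
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Run generate -> embolize variants -> solve -> field -> VF -> report.

    For each of the 2^n feeder variants the run emits a per-feeder flow
    report (CSV) and a VF velocity texture; variants with no open
    inlet->outlet path are recorded as infeasible rather than aborting the
    run.  Returns (and writes) a manifest listing every artifact with its
    SHA-256 checksum.  With ``dry_run`` only the variant plan is returned.
    """
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    network = generate_synthetic_avm(config.avm)
    feeders = network.feeder_segments()
    variants = enumerate_variants(len(feeders))
    log.info("generated network: %d segments, %d feeders, %d variants",
             len(network.segments), len(feeders), len(variants))
    if dry_run:
        return {
            "dry_run": True,
            "feeder_ids": [f.id for f in feeders],
            "variants": [s.bitstring() for s in variants],
        }

    out.mkdir(parents=True, exist_ok=True)
    (out / "network.json").write_text(network.to_json())
    bc = BoundaryConditions(inlet_velocity=config.inlet_velocity)
    fluid = FluidProperties()
    spec = grid_spec_for_network(network, config.grid_step)
    baseline = solve_flow(network, EmbolizationState.all_open(len(feeders)), fluid, bc)

    manifest_variants = []
    files: list[Path] = [out / "network.json"]
    for state in variants:
        bits = state.bitstring()
        vdir = out / f"variant_{bits}"
        t_var = time.perf_counter()
        entry: dict = {"bits": bits, "n_blocked": state.n_blocked}
        try:
            solution = solve_flow(network, state, fluid, bc)
        except NoOpenPathError as exc:
            entry["feasible"] = False
            entry["reason"] = str(exc)
            manifest_variants.append(entry)
            log.info("variant %s infeasible: %s", bits, exc)
            continue
        vdir.mkdir(parents=True, exist_ok=True)
        entry["feasible"] = True
        flow_net, markers = apply_embolization(network, state)
        rows = flow_change_report(network, baseline, solution)
        _write_flow_csv(vdir / "flow.csv", rows)
        grid = reconstruct_velocity_field(flow_net, solution, spec=spec)
        write_vf(grid, vdir / "field.vf")
        entry["flow_report"] = str((vdir / "flow.csv").relative_to(out))
        entry["vf"] = str((vdir / "field.vf").relative_to(out))
        entry["markers"] = [
            {
                "feeder_id": m.feeder_id,
                "position_m": [float(x) for x in m.position],
                "axis": [float(x) for x in m.axis],
                "radius_m": m.radius,
                "length_m": m.length,
            }
            for m in markers
        ]
        entry["inflow_m3_per_s"] = solution.inflow
        files += [vdir / "flow.csv", vdir / "field.vf"]

        if config.particles is not None and config.n_snapshot_steps > 0:
            inlet_seg = network.segment(
                min(s.id for s in network.segments
                    if network.inlet_nodes[0] in (s.proximal_node, s.distal_node))
            )
            disc = InletDisc(
                center=tuple(float(x) for x in inlet_seg.centerline[0]),
                normal=tuple(
                    float(x)
                    for x in (inlet_seg.centerline[1] - inlet_seg.centerline[0])
                ),
                radius=inlet_seg.radius,
            )
            pstate = ParticleState.empty(config.particles)
            vmax = max(
                (abs(v) for v in solution.mean_velocity.values()), default=1.0
            )
            scale = ColorScale(kind="heated_body", vmin=0.0, vmax=max(2 * vmax, 1e-9))
            snaps = []
            for step_i in range(config.n_snapshot_steps):
                pstate = spawn(pstate, config.particles, disc, config.particles.dt, grid)
                pstate = advect_step(pstate, grid, config.particles)
                snap = vdir / f"particles_{step_i:04d}.vtk"
                export_snapshot(pstate, color_by_velocity(pstate, scale), snap)
                snaps.append(str(snap.relative_to(out)))
                files.append(snap)
            entry["snapshots"] = snaps
        manifest_variants.append(entry)
        log.info("variant %s done in %.3f s", bits, time.perf_counter() - t_var)

    manifest = {
        "seed": config.seed,
        "n_feeders": len(feeders),
        "feeder_ids": [f.id for f in feeders],
        "grid": {"origin_m": list(spec.origin), "step_m": spec.step,
                 "dims": list(spec.dims)},
        "inlet_velocity_m_per_s": config.inlet_velocity,
        "variants": manifest_variants,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in files},
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
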