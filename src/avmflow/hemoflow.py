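"""Steady laminar blood flow on the vessel graph.

Blood is modeled as an incompressible Newtonian fluid (density 1055 kg/m^3,
dynamic viscosity 4 mPa*s) in rigid vessels under steady laminar flow.  Each
segment is a Hagen–Poiseuille resistor

    R = 8 eta L / (pi r^4),        Q = (p_prox - p_dist) / R,

and Kirchhoff mass conservation (sum of Q = 0) holds at every interior node.
Boundary conditions: a fixed volumetric inflow Q_in = v_in * A_in at each
inlet (a constant inflow velocity over the inlet cross-section) and zero
pressure at every outlet.  The resulting symmetric positive-definite linear
system on nodal pressures is solved sparsely.

This is a 0D/1D network reduction: it preserves the boundary conditions and
fluid model of a full 3D finite-volume simulation while remaining
analytically checkable against series/parallel resistor compositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .embolize import EmbolizationState, apply_embolization
from .vessels import VascularNetwork, VesselSegment

__all__ = [
    "FluidProperties",
    "BoundaryConditions",
    "FlowSolution",
    "NoOpenPathError",
    "segment_resistance",
    "scale_inflow",
    "solve_flow",
    "flow_change_report",
]

BLOCKED_CHANGE = -1.0  # relative change reported for a blocked feeder
UNDEFINED_CHANGE = float("nan")  # baseline flow was zero in an open feeder


class NoOpenPathError(RuntimeError):
    """No open inlet->outlet path exists; the variant is infeasible."""


@dataclass(frozen=True)
class FluidProperties:
    """Bulk blood properties (SI)."""

    density: float = 1055.0  # kg/m^3
    dynamic_viscosity: float = 0.004  # Pa*s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be > 0")


@dataclass(frozen=True)
class BoundaryConditions:
    """Inflow velocity plus zero-pressure outlets.

    ``inlet_velocity`` is the constant inflow speed at the inlet
    cross-section (case templates use 0.1 m/s for the simplified case and
    0.39 m/s for the complex cases, volunteer-derived values).  If a
    reference velocity/area pair is given, the effective inlet velocity is
    rescaled so the volumetric flow of the reference is preserved:
    v = v_ref * A_ref / A_case.
    """

    inlet_velocity: float = 0.1  # m/s
    reference_velocity: float | None = None  # m/s
    reference_area: float | None = None  # m^2
    outlet_pressure: float = 0.0  # Pa, fixed

    def __post_init__(self) -> None:
        if self.inlet_velocity <= 0:
            raise ValueError("inlet_velocity must be > 0")
        if self.outlet_pressure != 0.0:
            raise ValueError("outlet pressure is fixed at 0 Pa")

    def velocity_for_area(self, inlet_area: float) -> float:
        if self.reference_velocity is not None and self.reference_area is not None:
            return scale_inflow(self.reference_velocity, self.reference_area, inlet_area)
        return self.inlet_velocity


@dataclass
class FlowSolution:
    """Node pressures and signed segment flows for one embolization variant.

    ``segment_flow[i] > 0`` means flow from the segment's proximal to its
    distal node.  Blocked segments are absent from ``segment_flow`` (they are
    removed from the system; their flow is identically zero).
    """

    node_pressure: dict[int, float]  # Pa
    segment_flow: dict[int, float]  # m^3/s, open segments only
    mean_velocity: dict[int, float]  # m/s, = Q / (pi r^2)
    inflow: float  # total prescribed Q_in, m^3/s
    state: EmbolizationState | None = None
    residuals: dict[int, float] = field(default_factory=dict)  # node mass defect

    def max_relative_residual(self) -> float:
        """Largest interior-node mass defect relative to the inflow."""
        if not self.residuals:
            return 0.0
        return max(abs(r) for r in self.residuals.values()) / abs(self.inflow)


def segment_resistance(segment: VesselSegment, dynamic_viscosity: float) -> float:
    """Hagen–Poiseuille resistance R = 8 eta L / (pi r^4) in Pa*s/m^3."""
    if segment.radius <= 0:
        raise ValueError("segment radius must be > 0")
    return 8.0 * dynamic_viscosity * segment.length / (math.pi * segment.radius**4)


def scale_inflow(v_ref: float, a_ref: float, a_case: float) -> float:
    """Rescale an inflow velocity to a different inlet cross-section.

    Preserves volumetric flow: Q = v_ref * A_ref = v * A_case, so
    v = v_ref * A_ref / A_case.
    """
    if a_ref <= 0 or a_case <= 0:
        raise ValueError("cross-sectional areas must be > 0")
    return v_ref * a_ref / a_case


def _inlet_segment(network: VascularNetwork, inlet: int) -> VesselSegment:
    for seg in network.segments:
        if inlet in (seg.proximal_node, seg.distal_node):
            return seg
    raise ValueError(f"inlet node {inlet} has no incident segment")


def solve_flow(
    network: VascularNetwork,
    state: EmbolizationState | None = None,
    fluid: FluidProperties = FluidProperties(),
    bc: BoundaryConditions = BoundaryConditions(),
) -> FlowSolution:
    """Solve the steady network flow for one embolization variant.

    Assembles the weighted graph Laplacian over nodal pressures with outlet
    rows eliminated (outlets pinned to 0 Pa) and fixed inflow injections at
    the inlets, and solves the sparse SPD system.  Components unreachable
    from any inlet through open segments are stagnant: zero pressure, zero
    flow.

    Raises
    ------
    NoOpenPathError
        If some inlet has no open path to any outlet (infeasible variant).
    """
    if state is not None:
        network, _ = apply_embolization(network, state)

    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for seg in network.segments:
        g.add_edge(seg.proximal_node, seg.distal_node)
    outlets = set(network.outlet_nodes)
    live: set[int] = set()
    for inlet in network.inlet_nodes:
        comp = nx.node_connected_component(g, inlet)
        if not comp & outlets:
            raise NoOpenPathError(
                f"no open outflow path from inlet {inlet}: all routes blocked"
            )
        live |= comp

    unknown = sorted(n for n in live if n not in outlets)
    index = {n: i for i, n in enumerate(unknown)}
    n_unknown = len(unknown)

    resistances = {s.id: segment_resistance(s, fluid.dynamic_viscosity) for s in network.segments}

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_unknown)
    for seg in network.segments:
        if seg.proximal_node not in live:
            continue
        gcond = 1.0 / resistances[seg.id]
        for a, b in ((seg.proximal_node, seg.distal_node),
                     (seg.distal_node, seg.proximal_node)):
            if a in index:
                rows.append(index[a]); cols.append(index[a]); vals.append(gcond)
                if b in index:
                    rows.append(index[a]); cols.append(index[b]); vals.append(-gcond)
                # else b is an outlet at 0 Pa: contributes nothing to the RHS

    inflow_total = 0.0
    for inlet in network.inlet_nodes:
        seg = _inlet_segment(network, inlet)
        v_in = bc.velocity_for_area(seg.cross_section_area)
        q_in = v_in * seg.cross_section_area
        inflow_total += q_in
        if inlet in index:
            rhs[index[inlet]] += q_in

    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n_unknown, n_unknown))
    try:
        pressures = spla.spsolve(matrix.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"singular pressure system: {exc}") from exc
    if not np.all(np.isfinite(pressures)):
        raise RuntimeError("singular pressure system: non-finite pressures")

    node_pressure = {n: 0.0 for n in network.nodes}
    for n, i in index.items():
        node_pressure[n] = float(pressures[i])

    segment_flow: dict[int, float] = {}
    mean_velocity: dict[int, float] = {}
    for seg in network.segments:
        dp = node_pressure[seg.proximal_node] - node_pressure[seg.distal_node]
        q = dp / resistances[seg.id]
        segment_flow[seg.id] = q
        mean_velocity[seg.id] = q / seg.cross_section_area

    # Interior-node mass balance audit (inlets carry their injection).
    residuals: dict[int, float] = {}
    net_flux = {n: 0.0 for n in live}
    for seg in network.segments:
        if seg.proximal_node not in live:
            continue
        q = segment_flow[seg.id]
        net_flux[seg.proximal_node] -= q
        net_flux[seg.distal_node] += q
    for inlet in network.inlet_nodes:
        seg = _inlet_segment(network, inlet)
        net_flux[inlet] += bc.velocity_for_area(seg.cross_section_area) * seg.cross_section_area
    for n in unknown:
        residuals[n] = net_flux[n]

    return FlowSolution(
        node_pressure=node_pressure,
        segment_flow=segment_flow,
        mean_velocity=mean_velocity,
        inflow=inflow_total,
        state=state,
        residuals=residuals,
    )


def flow_change_report(
    network: VascularNetwork,
    baseline: FlowSolution,
    variant: FlowSolution,
) -> list[dict]:
    """Per-feeder flow change of a variant against a baseline solution.

    Occluding one feeder redistributes flow into the remaining ones, raising
    their rupture risk — the quantity a planner wants per feeder.  Rows
    carry the flow rate, mean velocity, pressure drop and the relative change
    (Q_variant - Q_baseline) / Q_baseline.  Blocked feeders report -1.0
    (i.e. -100%); an open feeder whose baseline flow is exactly zero reports
    NaN (undefined) rather than dividing by zero.
    """
    rows = []
    for f in network.feeder_segments():
        q_base = baseline.segment_flow.get(f.id)
        q_var = variant.segment_flow.get(f.id)
        blocked = q_var is None
        if blocked:
            change = BLOCKED_CHANGE
        elif q_base in (None, 0.0):
            change = UNDEFINED_CHANGE
        else:
            change = (q_var - q_base) / q_base
        dp = (
            variant.node_pressure[f.proximal_node]
            - variant.node_pressure[f.distal_node]
        )
        rows.append(
            {
                "feeder_id": f.id,
                "blocked": blocked,
                "Q_m3_per_s": 0.0 if blocked else q_var,
                "mean_velocity_m_per_s": 0.0 if blocked else variant.mean_velocity[f.id],
                "delta_p_Pa": 0.0 if blocked else dp,
                "relative_change": change,
            }
        )
    return rows
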