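"""Virtual embolization of AVM feeders.

In endovascular practice a sclerosing agent is injected into a feeder as
close as possible to the nidus, occluding it completely.  Here that becomes a
pure graph transformation: a blocked feeder is removed from the flow graph
(infinite resistance) and an occlusion marker is emitted at the feeder's
distal, nidus-side end.  With N feeders there are 2^N blocked/unblocked
variants; all of them can be enumerated and solved.

The module also implements the clinical ordering heuristic: embolize
small-diameter, proximally located feeders first, keeping at least one feeder
open so the venous system still fills.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .vessels import VascularNetwork, VesselSegment

__all__ = [
    "EmbolizationState",
    "EmbolizationPlan",
    "OcclusionMarker",
    "enumerate_variants",
    "apply_embolization",
    "plan_embolization_order",
]


@dataclass(frozen=True)
class EmbolizationState:
    """Blocked/open flag per feeder, ordered by feeder segment id.

    ``blocked[i]`` refers to the i-th feeder in ascending segment-id order.
    The bitstring form writes feeder 0 leftmost, '1' = blocked.
    """

    blocked: tuple[bool, ...]

    @property
    def n_feeders(self) -> int:
        return len(self.blocked)

    @property
    def n_blocked(self) -> int:
        return sum(self.blocked)

    def bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.blocked)

    @classmethod
    def from_bitstring(cls, bits: str) -> "EmbolizationState":
        bits = bits.removeprefix("0b")
        if any(c not in "01" for c in bits):
            raise ValueError(f"invalid state bitstring {bits!r}")
        return cls(tuple(c == "1" for c in bits))

    @classmethod
    def all_open(cls, n_feeders: int) -> "EmbolizationState":
        return cls((False,) * n_feeders)


@dataclass(frozen=True)
class OcclusionMarker:
    """Display marker for one occlusion: a short cylinder at the blocking site."""

    feeder_id: int
    position: np.ndarray  # distal (nidus-side) centerline point, m
    axis: np.ndarray  # unit tangent at the blocking site
    radius: float  # feeder radius, m
    length: float  # marker length (display only), m


@dataclass
class EmbolizationPlan:
    """Ordered feeder occlusion sequence leaving ``keep_open`` feeders open."""

    order: list[int]  # feeder segment ids, in embolization order
    keep_open: int


def enumerate_variants(n_feeders: int) -> list[EmbolizationState]:
    """All 2^n blocked/unblocked combinations, lexicographic, all-open first."""
    if n_feeders < 0:
        raise ValueError("n_feeders must be >= 0")
    return [
        EmbolizationState(bits)
        for bits in itertools.product((False, True), repeat=n_feeders)
    ]


def apply_embolization(
    network: VascularNetwork, state: EmbolizationState
) -> tuple[VascularNetwork, list[OcclusionMarker]]:
    """Apply a blocking state: drop blocked feeders from the flow graph.

    Returns a new network (the input is never mutated) whose segment list
    omits the blocked feeders, together with one :class:`OcclusionMarker` per
    blocked feeder placed at its distal end — the feeder–nidus transition
    where the sclerosant is deposited.  The marker length is 10% of the
    feeder's length (display convention).

    The resulting network may have no open inlet->outlet path (e.g. all
    feeders blocked on a topology without an arterial bypass); feasibility is
    the flow solver's concern, not this function's.
    """
    feeders = network.feeder_segments()
    if len(feeders) != state.n_feeders:
        raise ValueError(
            f"state has {state.n_feeders} flags but network has "
            f"{len(feeders)} feeders"
        )
    blocked_ids = {f.id for f, b in zip(feeders, state.blocked) if b}
    open_segments = [s for s in network.segments if s.id not in blocked_ids]
    markers = []
    for f, b in zip(feeders, state.blocked):
        if not b:
            continue
        tail = f.centerline[-1] - f.centerline[-2]
        norm = np.linalg.norm(tail)
        markers.append(
            OcclusionMarker(
                feeder_id=f.id,
                position=f.centerline[-1].copy(),
                axis=tail / norm if norm > 0 else np.array([1.0, 0.0, 0.0]),
                radius=f.radius,
                length=0.1 * f.length,
            )
        )
    flow_net = VascularNetwork(
        nodes={k: v.copy() for k, v in network.nodes.items()},
        segments=open_segments,
        inlet_nodes=list(network.inlet_nodes),
        outlet_nodes=list(network.outlet_nodes),
    )
    return flow_net, markers


def _feeder_inlet_distance(network: VascularNetwork, feeder: VesselSegment) -> float:
    """Centerline path length from the nearest inlet to the feeder's origin."""
    g = network.graph()
    best = np.inf
    for inlet in network.inlet_nodes:
        try:
            d = nx.shortest_path_length(
                g, inlet, feeder.proximal_node, weight="weight"
            )
        except nx.NetworkXNoPath:
            continue
        best = min(best, d)
    return float(best)


def plan_embolization_order(
    network: VascularNetwork, keep_open: int
) -> EmbolizationPlan:
    """Order feeders for staged embolization, keeping ``keep_open`` open.

    Sort key: diameter ascending, then centerline path distance from the
    inlet ascending, then segment id — small proximal feeders are occluded
    first to limit pressure redistribution, and enough feeders stay open to
    preserve venous outflow.
    """
    feeders = network.feeder_segments()
    if keep_open < 1:
        raise ValueError("keep_open must be >= 1")
    if keep_open > len(feeders):
        raise ValueError(
            f"keep_open={keep_open} exceeds feeder count {len(feeders)}"
        )
    ranked = sorted(
        feeders,
        key=lambda f: (2 * f.radius, _feeder_inlet_distance(network, f), f.id),
    )
    n_close = len(feeders) - keep_open
    return EmbolizationPlan(order=[f.id for f in ranked[:n_close]], keep_open=keep_open)
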