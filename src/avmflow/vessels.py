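"""Labeled vascular networks: domain types, a seeded synthetic AVM generator,
tube-mesh synthesis, lumen voxelization, and compartment colors.

An arteriovenous malformation (AVM) is modeled as a labeled vessel graph with
five compartments along the flow direction::

    artery -> feeder -> nidus -> drainer -> vein

All geometry is in SI units (meters).  Configuration loaders that accept
millimeters convert on load; nothing below this module ever sees mm.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterator

import networkx as nx
import numpy as np

__all__ = [
    "COMPARTMENTS",
    "VesselSegment",
    "VascularNetwork",
    "SyntheticAVMConfig",
    "SurfaceMesh",
    "generate_synthetic_avm",
    "network_to_mesh",
    "voxelize_lumen",
    "compartment_color",
    "polyline_length",
]

#: Valid compartment labels, ordered from inflow to outflow.
COMPARTMENTS = ("artery", "feeder", "nidus", "drainer", "vein")

# Display colors per compartment (RGBA in [0, 1]).  Shades follow the common
# angiographic convention: arteries dark red (#8B0000), feeders red (#FF0000),
# nidus light red (#FF7F7F), draining veins purple (#800080), veins blue
# (#0000FF).
_COMPARTMENT_RGBA = {
    "artery": (0.545, 0.0, 0.0, 1.0),
    "feeder": (1.0, 0.0, 0.0, 1.0),
    "nidus": (1.0, 0.498, 0.498, 1.0),
    "drainer": (0.502, 0.0, 0.502, 1.0),
    "vein": (0.0, 0.0, 1.0, 1.0),
}


def polyline_length(points: np.ndarray) -> float:
    """Arc length of an ordered (n, 3) point array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("centerline must be an (n>=2, 3) array")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def compartment_color(compartment: str) -> tuple[float, float, float, float]:
    """RGBA display color for a compartment label.

    The mapping is total and injective over the five labels; unknown labels
    raise ``KeyError``.
    """
    try:
        return _COMPARTMENT_RGBA[compartment]
    except KeyError:
        raise KeyError(f"unknown compartment label: {compartment!r}") from None


@dataclass
class VesselSegment:
    """One vessel segment: a tube of constant radius swept along a centerline.

    Parameters
    ----------
    id
        Unique integer id within the network.
    proximal_node, distal_node
        Node ids at the upstream / downstream ends.
    radius
        Lumen radius in meters, > 0.
    centerline
        Ordered (n >= 2, 3) array of points in meters; the first and last
        points coincide with the proximal and distal node positions.
    compartment
        One of ``COMPARTMENTS``.
    """

    id: int
    proximal_node: int
    distal_node: int
    radius: float
    centerline: np.ndarray
    compartment: str

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"segment {self.id}: radius must be > 0")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"segment {self.id}: unknown compartment {self.compartment!r}"
            )
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: centerline has zero length")

    @property
    def length(self) -> float:
        """Centerline arc length in meters."""
        return polyline_length(self.centerline)

    @property
    def cross_section_area(self) -> float:
        """Lumen cross-sectional area pi*r^2 in m^2."""
        return math.pi * self.radius**2


@dataclass
class VascularNetwork:
    """A connected, labeled vessel graph with explicit inlets and outlets."""

    nodes: dict[int, np.ndarray]
    segments: list[VesselSegment]
    inlet_nodes: list[int]
    outlet_nodes: list[int]

    def __post_init__(self) -> None:
        self.nodes = {int(k): np.asarray(v, dtype=float) for k, v in self.nodes.items()}

    # -- graph views ---------------------------------------------------------

    def graph(self) -> nx.Graph:
        """Undirected view with a ``segment`` attribute per edge."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for seg in self.segments:
            g.add_edge(seg.proximal_node, seg.distal_node, segment=seg, weight=seg.length)
        return g

    def feeder_segments(self) -> list[VesselSegment]:
        """Feeder segments in stable (segment-id) order."""
        return sorted(
            (s for s in self.segments if s.compartment == "feeder"), key=lambda s: s.id
        )

    def segments_by_compartment(self, compartment: str) -> list[VesselSegment]:
        return [s for s in self.segments if s.compartment == compartment]

    def segment(self, seg_id: int) -> VesselSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(f"no segment with id {seg_id}")

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("segment ids are not unique")
        g = self.graph()
        if g.number_of_nodes() and not nx.is_connected(g):
            raise ValueError("vessel graph is not connected")
        if not self.inlet_nodes or not self.outlet_nodes:
            raise ValueError("inlet and outlet node sets must be non-empty")
        if set(self.inlet_nodes) & set(self.outlet_nodes):
            raise ValueError("inlet and outlet sets must be disjoint")
        for n in (*self.inlet_nodes, *self.outlet_nodes):
            if g.degree(n) != 1:
                raise ValueError(f"boundary node {n} must have degree 1")
        for seg in self.segments:
            for node, end in ((seg.proximal_node, 0), (seg.distal_node, -1)):
                if not np.allclose(self.nodes[node], seg.centerline[end], atol=1e-12):
                    raise ValueError(
                        f"segment {seg.id}: centerline end does not coincide "
                        f"with node {node}"
                    )
        # Every feeder must sit on some inlet->outlet path: with both of its
        # endpoints connected (the graph is connected) this reduces to the
        # feeder not being a bridge to a dead subtree without outlets.
        for seg in self.feeder_segments():
            h = g.copy()
            h.remove_edge(seg.proximal_node, seg.distal_node)
            reach_distal = nx.node_connected_component(h, seg.distal_node)
            reach_prox = nx.node_connected_component(h, seg.proximal_node)
            upstream_ok = any(n in reach_prox for n in self.inlet_nodes) or any(
                n in reach_distal for n in self.inlet_nodes
            )
            downstream_ok = any(n in reach_distal for n in self.outlet_nodes) or any(
                n in reach_prox for n in self.outlet_nodes
            )
            if not (upstream_ok and downstream_ok):
                raise ValueError(f"feeder {seg.id} lies on no inlet->outlet path")

    # -- geometry ------------------------------------------------------------

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounds of the lumen (centerlines dilated by radius)."""
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for seg in self.segments:
            lo = np.minimum(lo, seg.centerline.min(axis=0) - seg.radius)
            hi = np.maximum(hi, seg.centerline.max(axis=0) + seg.radius)
        return lo, hi

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "units": "m",
            "nodes": {str(k): [float(x) for x in v] for k, v in self.nodes.items()},
            "segments": [
                {
                    "id": s.id,
                    "proximal_node": s.proximal_node,
                    "distal_node": s.distal_node,
                    "radius": float(s.radius),
                    "compartment": s.compartment,
                    "centerline": [[float(x) for x in p] for p in s.centerline],
                }
                for s in self.segments
            ],
            "inlet_nodes": list(self.inlet_nodes),
            "outlet_nodes": list(self.outlet_nodes),
        }

    def to_json(self) -> str:
        """Deterministic JSON text (sorted keys, full float precision)."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "VascularNetwork":
        if d.get("units", "m") != "m":
            raise ValueError(f"unsupported units {d.get('units')!r}; expected 'm'")
        segs = [
            VesselSegment(
                id=s["id"],
                proximal_node=s["proximal_node"],
                distal_node=s["distal_node"],
                radius=s["radius"],
                centerline=np.asarray(s["centerline"], dtype=float),
                compartment=s["compartment"],
            )
            for s in d["segments"]
        ]
        return cls(
            nodes={int(k): np.asarray(v) for k, v in d["nodes"].items()},
            segments=segs,
            inlet_nodes=list(d["inlet_nodes"]),
            outlet_nodes=list(d["outlet_nodes"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "VascularNetwork":
        return cls.from_dict(json.loads(text))


@dataclass
class SyntheticAVMConfig:
    """Parameters of the synthetic AVM generator.

    Radii ranges are (min, max) in meters per compartment; defaults are in the
    range of cerebral vessel calibers (arteries ~1.5-2 mm radius, feeders
    ~0.4-0.8 mm, nidus vessels a few tenths of a mm, draining veins larger).
    ``domain_extent`` bounds the scene; the vessel tree is laid out along x.
    """

    n_feeders: int = 3
    n_nidus_nodes: int = 15
    n_drainers: int = 2
    nidus_mean_degree: float = 4.0
    radius_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "artery": (1.5e-3, 2.0e-3),
            "feeder": (4.0e-4, 8.0e-4),
            "nidus": (1.5e-4, 3.5e-4),
            "drainer": (8.0e-4, 1.2e-3),
            "vein": (1.5e-3, 2.5e-3),
        }
    )
    domain_extent: tuple[float, float, float] = (0.04, 0.024, 0.024)
    #: Continue the parent artery past the feeder take-offs to its own outlet,
    #: as the parent artery does in vivo.  With the bypass present every
    #: blocked/unblocked variant still has an open inlet->outlet path.
    bypass_artery: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_feeders < 1:
            raise ValueError("n_feeders must be >= 1")
        if self.n_drainers < 1:
            raise ValueError("n_drainers must be >= 1")
        if self.n_nidus_nodes < self.n_feeders + self.n_drainers:
            raise ValueError(
                "n_nidus_nodes must be >= n_feeders + n_drainers so that "
                "feeder entry and drainer exit nodes are distinct"
            )
        if self.nidus_mean_degree <= 0:
            raise ValueError("nidus_mean_degree must be > 0")
        for comp, (lo, hi) in self.radius_ranges.items():
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment in radius_ranges: {comp!r}")
            if not (0 < lo < hi):
                raise ValueError(f"radius range for {comp} must satisfy 0 < min < max")
        if any(e <= 0 for e in self.domain_extent):
            raise ValueError("domain_extent components must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["radius_ranges"] = {k: list(v) for k, v in self.radius_ranges.items()}
        d["domain_extent"] = list(self.domain_extent)
        return d


@dataclass
class SurfaceMesh:
    """Triangle surface mesh with a compartment label per vertex."""

    vertices: np.ndarray  # (nv, 3) float, meters
    faces: np.ndarray  # (nf, 3) int
    vertex_compartment: np.ndarray  # (nv,) of str labels

    def signed_volume(self, face_slice: slice | None = None) -> float:
        """Signed enclosed volume via the divergence theorem.

        Positive for consistently outward-oriented closed surfaces.
        """
        f = self.faces if face_slice is None else self.faces[face_slice]
        v0 = self.vertices[f[:, 0]]
        v1 = self.vertices[f[:, 1]]
        v2 = self.vertices[f[:, 2]]
        return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


# ---------------------------------------------------------------------------
# Synthetic AVM generation
# ---------------------------------------------------------------------------


def _jittered_polyline(
    rng: np.random.Generator,
    a: np.ndarray,
    b: np.ndarray,
    n_points: int = 5,
    jitter: float = 0.0,
) -> np.ndarray:
    """Polyline from a to b with lateral jitter on interior points only."""
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    pts = (1 - t) * a[None, :] + t * b[None, :]
    if jitter > 0 and n_points > 2:
        pts[1:-1] += rng.normal(scale=jitter, size=(n_points - 2, 3))
    return pts


def generate_synthetic_avm(config: SyntheticAVMConfig) -> VascularNetwork:
    """Generate a seeded synthetic AVM vessel network.

    The layout places an inlet (parent artery) on the -x side, the nidus ball
    in the middle of the domain, and the venous outflow on the +x side:

    * one parent artery from the inlet to an arterial branching point,
      optionally continued past the branching point to a distal arterial
      outlet (``bypass_artery``);
    * ``n_feeders`` feeder segments from the branching point to distinct
      nidus entry nodes;
    * a nidus built as a random geometric graph over ``n_nidus_nodes`` points
      in a ball, made connected with a Euclidean minimum spanning tree;
    * ``n_drainers`` drainer segments from distinct nidus exit nodes to a
      venous confluence, and one vein from the confluence to the outlet.

    Fully deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ex, ey, ez = config.domain_extent
    center_yz = np.array([0.0, ey / 2, ez / 2])

    def radius(comp: str) -> float:
        lo, hi = config.radius_ranges[comp]
        return float(rng.uniform(lo, hi))

    nodes: dict[int, np.ndarray] = {}
    segments: list[VesselSegment] = []
    next_node = 0
    next_seg = 0

    def add_node(pos: np.ndarray) -> int:
        nonlocal next_node
        nodes[next_node] = np.asarray(pos, dtype=float)
        next_node += 1
        return next_node - 1

    def add_segment(prox: int, dist: int, comp: str, centerline: np.ndarray) -> VesselSegment:
        nonlocal next_seg
        centerline = np.array(centerline, dtype=float)
        centerline[0] = nodes[prox]
        centerline[-1] = nodes[dist]
        seg = VesselSegment(next_seg, prox, dist, radius(comp), centerline, comp)
        segments.append(seg)
        next_seg += 1
        return seg

    jit = 0.02 * min(config.domain_extent)

    # Parent artery: inlet -> arterial branching point.
    inlet = add_node(np.array([0.03 * ex, 0, 0]) + center_yz)
    hub = add_node(np.array([0.28 * ex, 0, 0]) + center_yz)
    add_segment(inlet, hub, "artery", _jittered_polyline(rng, nodes[inlet], nodes[hub], 6, jit))

    # Nidus point cloud in a ball.
    nidus_center = np.array([0.55 * ex, 0, 0]) + center_yz
    nidus_radius = 0.3 * min(config.domain_extent) / 2
    n = config.n_nidus_nodes
    # Uniform sampling in a ball via normalized Gaussians and cubic-root radii.
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = nidus_radius * rng.uniform(size=(n, 1)) ** (1 / 3)
    nidus_pts = nidus_center + dirs * radii
    nidus_ids = [add_node(p) for p in nidus_pts]

    # Feeder entries: nidus nodes closest to the artery (smallest x);
    # drainer exits: nidus nodes closest to the veins (largest x).
    order_x = np.argsort(nidus_pts[:, 0], kind="stable")
    entry_idx = list(order_x[: config.n_feeders])
    exit_idx = [i for i in order_x[::-1] if i not in entry_idx][: config.n_drainers]

    for i in entry_idx:
        add_segment(
            hub, nidus_ids[i], "feeder",
            _jittered_polyline(rng, nodes[hub], nidus_pts[i], 6, jit),
        )

    # Nidus wiring: random geometric graph + Euclidean MST for connectivity.
    d2 = np.linalg.norm(nidus_pts[:, None, :] - nidus_pts[None, :, :], axis=2)
    iu, ju = np.triu_indices(n, k=1)
    pair_d = d2[iu, ju]
    target_edges = min(len(pair_d), max(n - 1, int(round(n * config.nidus_mean_degree / 2))))
    # Threshold at the distance quantile that yields ~target_edges edges.
    thresh = np.sort(pair_d)[target_edges - 1]
    edge_set = {(int(a), int(b)) for a, b in zip(iu[pair_d <= thresh], ju[pair_d <= thresh])}
    complete = nx.Graph()
    complete.add_nodes_from(range(n))
    for a, b in zip(iu, ju):
        complete.add_edge(int(a), int(b), weight=d2[a, b])
    for a, b in nx.minimum_spanning_edges(complete, data=False):
        edge_set.add((min(a, b), max(a, b)))
    for a, b in sorted(edge_set):
        add_segment(
            nidus_ids[a], nidus_ids[b], "nidus",
            _jittered_polyline(rng, nidus_pts[a], nidus_pts[b], 3, 0.15 * float(d2[a, b])),
        )

    # Venous side: drainers -> confluence -> vein -> outlet.
    confluence = add_node(np.array([0.8 * ex, 0, 0]) + center_yz)
    for i in exit_idx:
        add_segment(
            nidus_ids[i], confluence, "drainer",
            _jittered_polyline(rng, nidus_pts[i], nodes[confluence], 5, jit),
        )
    outlet = add_node(np.array([0.97 * ex, 0, 0]) + center_yz)
    add_segment(confluence, outlet, "vein",
                _jittered_polyline(rng, nodes[confluence], nodes[outlet], 5, jit))

    inlets = [inlet]
    outlets = [outlet]
    if config.bypass_artery:
        distal_outlet = add_node(np.array([0.35 * ex, 0.42 * ey, 0]) + center_yz)
        add_segment(hub, distal_outlet, "artery",
                    _jittered_polyline(rng, nodes[hub], nodes[distal_outlet], 5, jit))
        outlets.append(distal_outlet)

    net = VascularNetwork(nodes=nodes, segments=segments,
                          inlet_nodes=inlets, outlet_nodes=outlets)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Tube meshing
# ---------------------------------------------------------------------------


def _frames(centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parallel-transport orthonormal frames (t, n, b) along a polyline."""
    pts = np.asarray(centerline, dtype=float)
    m = len(pts)
    seg_dirs = np.diff(pts, axis=0)
    lens = np.linalg.norm(seg_dirs, axis=1)
    if np.any(lens <= 0):
        raise ValueError("degenerate centerline: repeated consecutive points")
    seg_dirs = seg_dirs / lens[:, None]
    tangents = np.empty((m, 3))
    tangents[0] = seg_dirs[0]
    tangents[-1] = seg_dirs[-1]
    for i in range(1, m - 1):
        t = seg_dirs[i - 1] + seg_dirs[i]
        norm = np.linalg.norm(t)
        tangents[i] = t / norm if norm > 1e-12 else seg_dirs[i]
    # Initial normal: any unit vector perpendicular to t0.
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tangents[0], ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n0 = np.cross(tangents[0], ref)
    n0 /= np.linalg.norm(n0)
    normals = np.empty((m, 3))
    normals[0] = n0
    for i in range(1, m):
        # Project previous normal onto the plane perpendicular to t_i.
        v = normals[i - 1] - np.dot(normals[i - 1], tangents[i]) * tangents[i]
        norm = np.linalg.norm(v)
        if norm < 1e-12:  # right-angle kink; restart the frame
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(tangents[i], ref)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            v = np.cross(tangents[i], ref)
            norm = np.linalg.norm(v)
        normals[i] = v / norm
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def network_to_mesh(network: VascularNetwork, sides_per_ring: int = 12) -> SurfaceMesh:
    """Sweep a capped triangular tube along every segment centerline.

    Each segment with an m-point centerline contributes ``sides_per_ring * m``
    ring vertices plus two cap apexes, ``2 * sides_per_ring * (m - 1)`` side
    triangles and ``2 * sides_per_ring`` cap triangles.  Tubes are closed and
    outward-oriented per segment; neighbouring tubes are not unioned.
    """
    if sides_per_ring < 3:
        raise ValueError("sides_per_ring must be >= 3")
    s = sides_per_ring
    verts: list[np.ndarray] = []
    faces: list[np.ndarray] = []
    labels: list[str] = []
    offset = 0
    theta = 2 * np.pi * np.arange(s) / s
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    for seg in network.segments:
        pts = seg.centerline
        m = len(pts)
        _, normals, binormals = _frames(pts)
        rings = (
            pts[:, None, :]
            + seg.radius * (cos_t[None, :, None] * normals[:, None, :]
                            + sin_t[None, :, None] * binormals[:, None, :])
        )  # (m, s, 3)
        verts.append(rings.reshape(-1, 3))
        verts.append(pts[0][None, :])
        verts.append(pts[-1][None, :])
        apex0 = offset + m * s
        apex1 = apex0 + 1
        ring = lambda i, j: offset + i * s + (j % s)
        f = []
        for i in range(m - 1):
            for j in range(s):
                f.append((ring(i, j), ring(i, j + 1), ring(i + 1, j + 1)))
                f.append((ring(i, j), ring(i + 1, j + 1), ring(i + 1, j)))
        for j in range(s):  # proximal cap, normal opposing the tangent
            f.append((apex0, ring(0, j + 1), ring(0, j)))
        for j in range(s):  # distal cap, normal along the tangent
            f.append((apex1, ring(m - 1, j), ring(m - 1, j + 1)))
        faces.append(np.asarray(f, dtype=np.int64))
        labels.extend([seg.compartment] * (m * s + 2))
        offset += m * s + 2
    return SurfaceMesh(
        vertices=np.concatenate(verts, axis=0),
        faces=np.concatenate(faces, axis=0),
        vertex_compartment=np.asarray(labels, dtype=object),
    )


def mesh_to_stl(mesh: SurfaceMesh, path) -> None:
    """Export a surface mesh as binary STL (labels are not representable)."""
    import trimesh

    trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, process=False
    ).export(path, file_type="stl")


def mesh_to_vtk(mesh: SurfaceMesh, path) -> None:
    """Export as legacy VTK PolyData ASCII with a per-vertex compartment id.

    The integer attribute indexes into ``COMPARTMENTS``.
    """
    comp_id = {c: i for i, c in enumerate(COMPARTMENTS)}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("avmflow vessel surface\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for p in mesh.vertices:
            fh.write(" ".join("%.12g" % x for x in p) + "\n")
        nf = len(mesh.faces)
        fh.write(f"POLYGONS {nf} {4 * nf}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        fh.write(f"POINT_DATA {len(mesh.vertices)}\n")
        fh.write("SCALARS compartment int 1\nLOOKUP_TABLE default\n")
        for c in mesh.vertex_compartment:
            fh.write(f"{comp_id[c]}\n")


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def iter_subsegments(
    network: VascularNetwork,
) -> Iterator[tuple[np.ndarray, np.ndarray, float, VesselSegment]]:
    """Yield (A, B, radius, segment) straight pieces of every centerline."""
    for seg in network.segments:
        pts = seg.centerline
        for i in range(len(pts) - 1):
            yield pts[i], pts[i + 1], seg.radius, seg


def voxelize_lumen(network: VascularNetwork, step: float, spec=None):
    """Rasterize the lumen onto a Cartesian grid.

    A voxel is inside the lumen iff its center lies within one radius of some
    segment centerline.  Returns ``(mask, spec)`` where ``mask`` is an
    (nx, ny, nz) boolean array on the grid ``spec`` (a
    :class:`~avmflow.fieldio.GridSpec`).  A step coarser than the smallest
    radius only triggers an undersampling warning, never an error.
    """
    from .fieldio import GridSpec, grid_spec_for_network  # local: avoid cycle

    if step <= 0:
        raise ValueError("step must be > 0")
    min_r = min(s.radius for s in network.segments)
    if step > min_r:
        warnings.warn(
            f"voxel step {step:g} m exceeds the smallest vessel radius "
            f"{min_r:g} m; thin vessels will be undersampled",
            UserWarning,
            stacklevel=2,
        )
    if spec is None:
        spec = grid_spec_for_network(network, step)
    dist, _ = distance_field(network, spec)
    return dist <= 0.0, spec


def distance_field(network, spec, solution=None):
    """Signed-by-construction tube scan over a grid.

    Returns ``(excess, vel)`` where ``excess[i,j,k] = min_seg (d - r)`` is the
    distance of the voxel center beyond the nearest tube wall (<= 0 inside the
    lumen; +inf where no tube's bounding box was visited), and ``vel`` is the
    per-voxel laminar (Poiseuille) velocity of the nearest tube when a flow
    ``solution`` is given, else ``None``.

    The axial velocity profile is the paraboloid ``v(d) = 2 v_mean
    (1 - (d/r)^2)`` directed along the local centerline tangent, with the sign
    of the segment's flow rate.
    """
    nx_, ny_, nz_ = spec.dims
    excess = np.full((nx_, ny_, nz_), np.inf, dtype=float)
    vel = None
    if solution is not None:
        vel = np.zeros((nx_, ny_, nz_, 3), dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    step = spec.step
    for a, b, r, seg in iter_subsegments(network):
        if solution is not None and seg.id not in solution.segment_flow:
            continue  # blocked segment: no flow, leave voxels to neighbours
        lo = np.minimum(a, b) - r
        hi = np.maximum(a, b) + r
        i0 = np.maximum(np.ceil((lo - origin) / step - 1e-9).astype(int), 0)
        i1 = np.minimum(np.floor((hi - origin) / step + 1e-9).astype(int), np.array(spec.dims) - 1)
        if np.any(i1 < i0):
            continue
        xs = origin[0] + step * np.arange(i0[0], i1[0] + 1)
        ys = origin[1] + step * np.arange(i0[1], i1[1] + 1)
        zs = origin[2] + step * np.arange(i0[2], i1[2] + 1)
        px, py, pz = np.meshgrid(xs, ys, zs, indexing="ij")
        p = np.stack([px, py, pz], axis=-1)  # (bx, by, bz, 3)
        ab = b - a
        ab2 = float(ab @ ab)
        t = np.clip(((p - a) @ ab) / ab2, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d = np.linalg.norm(p - closest, axis=-1)
        box = (slice(i0[0], i1[0] + 1), slice(i0[1], i1[1] + 1), slice(i0[2], i1[2] + 1))
        better = (d - r) < excess[box]
        excess[box] = np.where(better, d - r, excess[box])
        if vel is not None:
            q = solution.segment_flow[seg.id]
            v_mean = abs(q) / seg.cross_section_area
            axis = ab / math.sqrt(ab2) * (1.0 if q >= 0 else -1.0)
            inside = better & (d <= r)
            speed = 2.0 * v_mean * (1.0 - (d / r) ** 2)
            vbox = vel[box]
            vbox[inside] = speed[inside, None] * axis[None, :]
            vel[box] = vbox
    return excess, vel
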