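"""Particle advection with the spawn / initialize / update / output lifecycle.

Blood flow is visualized by millions of massless tracer particles advected
through the precomputed velocity texture.  The engine mirrors the four
lifecycle stages of a GPU visual-effect graph:

* **spawn** — emit ``spawn_rate * dt`` particles per step (fractional parts
  accumulate) uniformly over an inlet disc, never exceeding ``max_alive``;
  *initialize* is folded in: age 0, velocity looked up at the birth position;
* **update** — move each particle one explicit Euler or classic RK4 step
  through the trilinearly interpolated grid, age it, and kill it when its
  lifetime expires or it enters a zero-velocity (non-lumen) voxel;
* **output** — export snapshots as VTK PolyData point clouds with speed and
  color attributes instead of rendering.

All randomness flows through one seeded generator held by the state, so a
full simulation trace is reproducible from the config alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fieldio import VelocityGrid

__all__ = [
    "ParticleSystemConfig",
    "ParticleState",
    "InletDisc",
    "ColorScale",
    "spawn",
    "advect_step",
    "color_by_velocity",
    "ghost_opacity",
    "export_snapshot",
]


@dataclass(frozen=True)
class ParticleSystemConfig:
    """Tunable particle population parameters.

    ``max_alive`` caps the simultaneously existing population (default two
    million, the scale needed for a dense flow impression); ``lifetime``
    recycles particles so the inlet keeps emitting.
    """

    spawn_rate: float = 1.0e6  # particles per second
    max_alive: int = 2_000_000
    lifetime: float = 2.0  # s
    particle_size: float = 1.0e-4  # display radius, m
    seed: int = 0
    integrator: str = "rk4"  # "euler" or "rk4"
    dt: float = 0.01  # s

    def __post_init__(self) -> None:
        if self.spawn_rate < 0:
            raise ValueError("spawn_rate must be >= 0")
        if self.max_alive < 1:
            raise ValueError("max_alive must be >= 1")
        if self.lifetime <= 0 or self.dt <= 0:
            raise ValueError("lifetime and dt must be > 0")
        if self.integrator not in ("euler", "rk4"):
            raise ValueError("integrator must be 'euler' or 'rk4'")


@dataclass(frozen=True)
class InletDisc:
    """Circular emission region: center, unit normal, radius (m)."""

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    radius: float

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(n, ref)
        u /= np.linalg.norm(u)
        return u, np.cross(n, u), n


@dataclass
class ParticleState:
    """Positions, velocities, ages and alive flags of the population.

    Arrays are congruent in length and hold the current population only;
    dead entries are compacted away at the end of each update.
    """

    positions: np.ndarray
    velocities: np.ndarray
    ages: np.ndarray
    alive: np.ndarray
    rng: np.random.Generator
    spawn_accumulator: float = 0.0

    @classmethod
    def empty(cls, config: ParticleSystemConfig) -> "ParticleState":
        return cls(
            positions=np.empty((0, 3)),
            velocities=np.empty((0, 3)),
            ages=np.empty(0),
            alive=np.empty(0, dtype=bool),
            rng=np.random.default_rng(config.seed),
        )

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def compact(self) -> None:
        """Drop dead particles."""
        if self.alive.all():
            return
        keep = self.alive
        self.positions = self.positions[keep]
        self.velocities = self.velocities[keep]
        self.ages = self.ages[keep]
        self.alive = self.alive[keep]


@dataclass(frozen=True)
class ColorScale:
    """Piecewise-linear speed-to-color mapping.

    ``rainbow`` sweeps blue -> cyan -> green -> yellow -> red over
    [vmin, vmax]; ``heated_body`` ramps black -> red -> orange -> yellow ->
    white.  Speeds are clamped to the range before normalization.
    """

    kind: str = "rainbow"
    vmin: float = 0.0
    vmax: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _COLOR_STOPS:
            raise ValueError(f"unknown color scale {self.kind!r}")
        if not self.vmin < self.vmax:
            raise ValueError("vmin must be < vmax")


_COLOR_STOPS = {
    "rainbow": (
        np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
        np.array(
            [[0, 0, 1], [0, 1, 1], [0, 1, 0], [1, 1, 0], [1, 0, 0]], dtype=float
        ),
    ),
    "heated_body": (
        np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
        np.array(
            [[0, 0, 0], [1, 0, 0], [1, 0.5, 0], [1, 1, 0], [1, 1, 1]], dtype=float
        ),
    ),
}


# ---------------------------------------------------------------------------
# Velocity sampling
# ---------------------------------------------------------------------------


def sample_velocity(grid: VelocityGrid, points: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate grid velocities at (n, 3) points.

    Points beyond the grid are clamped to the border voxels (which are zero
    for any padded lumen grid).
    """
    dims = np.asarray(grid.spec.dims)
    u = (np.atleast_2d(points) - np.asarray(grid.spec.origin)) / grid.spec.step
    i0 = np.clip(np.floor(u).astype(int), 0, np.maximum(dims - 2, 0))
    f = np.clip(u - i0, 0.0, 1.0)
    i1 = np.minimum(i0 + 1, dims - 1)
    v = grid.vectors
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    x1, y1, z1 = i1[:, 0], i1[:, 1], i1[:, 2]
    fx, fy, fz = f[:, 0:1], f[:, 1:2], f[:, 2:3]
    c000, c100 = v[x0, y0, z0], v[x1, y0, z0]
    c010, c110 = v[x0, y1, z0], v[x1, y1, z0]
    c001, c101 = v[x0, y0, z1], v[x1, y0, z1]
    c011, c111 = v[x0, y1, z1], v[x1, y1, z1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return (c0 * (1 - fz) + c1 * fz).astype(float)


def _nearest_voxel_speed(grid: VelocityGrid, points: np.ndarray) -> np.ndarray:
    dims = np.asarray(grid.spec.dims)
    u = (np.atleast_2d(points) - np.asarray(grid.spec.origin)) / grid.spec.step
    idx = np.clip(np.rint(u).astype(int), 0, dims - 1)
    v = grid.vectors[idx[:, 0], idx[:, 1], idx[:, 2]]
    return np.linalg.norm(v, axis=1)


# ---------------------------------------------------------------------------
# Lifecycle stages
# ---------------------------------------------------------------------------


def spawn(
    state: ParticleState,
    config: ParticleSystemConfig,
    inlet_region: InletDisc,
    dt: float,
    grid: VelocityGrid | None = None,
) -> ParticleState:
    """Emit new particles over the inlet disc.

    The emission count is the floor of the accumulated ``spawn_rate * dt``
    (the fractional remainder carries over), truncated so the population
    never exceeds ``max_alive``.  New particles start with age 0 at uniform
    random positions on the disc; their velocity is initialized from the
    grid when one is supplied.
    """
    state.spawn_accumulator += config.spawn_rate * dt
    n_new = int(math.floor(state.spawn_accumulator))
    state.spawn_accumulator -= n_new
    n_new = min(n_new, config.max_alive - state.n_alive)
    if n_new <= 0:
        return state
    u, v, _ = inlet_region.basis()
    r = inlet_region.radius * np.sqrt(state.rng.uniform(size=n_new))
    theta = state.rng.uniform(0.0, 2 * np.pi, size=n_new)
    pos = (
        np.asarray(inlet_region.center)
        + r[:, None] * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
    )
    vel = sample_velocity(grid, pos) if grid is not None else np.zeros((n_new, 3))
    state.positions = np.concatenate([state.positions, pos])
    state.velocities = np.concatenate([state.velocities, vel])
    state.ages = np.concatenate([state.ages, np.zeros(n_new)])
    state.alive = np.concatenate([state.alive, np.ones(n_new, dtype=bool)])
    return state


def advect_step(
    state: ParticleState, grid: VelocityGrid, config: ParticleSystemConfig
) -> ParticleState:
    """Advance every particle one time step through the velocity field.

    Euler: x += v(x) dt.  RK4: the classic four-stage Runge–Kutta update.
    Afterwards ages advance by dt; particles past their lifetime, or that
    moved into a zero-velocity (outside-lumen) voxel, are killed and
    compacted away.  A particle resting in a stagnant voxel is not killed —
    it simply does not move and ages out.
    """
    if state.n_alive == 0:
        return state
    dt = config.dt
    x = state.positions
    if config.integrator == "euler":
        k1 = sample_velocity(grid, x)
        x_new = x + dt * k1
        v_new = k1
    else:
        k1 = sample_velocity(grid, x)
        k2 = sample_velocity(grid, x + 0.5 * dt * k1)
        k3 = sample_velocity(grid, x + 0.5 * dt * k2)
        k4 = sample_velocity(grid, x + dt * k3)
        x_new = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        v_new = sample_velocity(grid, x_new)
    state.positions = x_new
    state.velocities = v_new
    state.ages = state.ages + dt
    expired = state.ages > config.lifetime
    moved = np.linalg.norm(x_new - x, axis=1) > 0.0
    outside = moved & (_nearest_voxel_speed(grid, x_new) == 0.0)
    state.alive = state.alive & ~expired & ~outside
    state.compact()
    return state


# ---------------------------------------------------------------------------
# Output stage
# ---------------------------------------------------------------------------


def color_by_velocity(state: ParticleState, scale: ColorScale) -> np.ndarray:
    """RGB in [0, 1] per alive particle from its speed.

    Speed is clamped to [vmin, vmax], normalized to [0, 1] and mapped
    through the scale's piecewise-linear stops.
    """
    speeds = np.linalg.norm(state.velocities[state.alive], axis=1)
    t = np.clip((speeds - scale.vmin) / (scale.vmax - scale.vmin), 0.0, 1.0)
    stops, colors = _COLOR_STOPS[scale.kind]
    rgb = np.column_stack([np.interp(t, stops, colors[:, c]) for c in range(3)])
    return rgb


def ghost_opacity(
    mesh,
    view_point: np.ndarray,
    exponent: float = 2.0,
    alpha_min: float = 0.05,
) -> np.ndarray:
    """View-dependent vessel-wall opacity (ghosted view).

    Surfaces facing the viewer become transparent so interior particles show
    through, while silhouettes stay opaque and preserve the anatomical
    outline:  alpha = alpha_min + (1 - alpha_min) * (1 - |n.v|)^k with n the
    vertex normal and v the unit vertex-to-viewpoint direction.  Vertices
    with degenerate (zero) normals get alpha_min.
    """
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    if not 0 <= alpha_min < 1:
        raise ValueError("alpha_min must be in [0, 1)")
    verts = mesh.vertices
    normals = np.zeros_like(verts)
    v0, v1, v2 = (verts[mesh.faces[:, i]] for i in range(3))
    fn = np.cross(v1 - v0, v2 - v0)  # area-weighted face normals
    for i in range(3):
        np.add.at(normals, mesh.faces[:, i], fn)
    norm = np.linalg.norm(normals, axis=1)
    ok = norm > 1e-30
    to_view = np.asarray(view_point) - verts
    view_norm = np.linalg.norm(to_view, axis=1)
    ok &= view_norm > 0
    cosine = np.zeros(len(verts))
    cosine[ok] = np.abs(
        np.einsum("ij,ij->i", normals[ok] / norm[ok, None], to_view[ok] / view_norm[ok, None])
    )
    alpha = np.full(len(verts), alpha_min)
    alpha[ok] = alpha_min + (1 - alpha_min) * (1 - cosine[ok]) ** exponent
    return alpha


def export_snapshot(state: ParticleState, colors: np.ndarray | None, path) -> None:
    """Write the alive population as a VTK PolyData ASCII point cloud.

    Attributes: per-point velocity magnitude (SCALARS) and, when given, RGB
    colors (COLOR_SCALARS).  Valid output is produced even for an empty
    population.
    """
    alive = state.alive
    pos = state.positions[alive]
    speed = np.linalg.norm(state.velocities[alive], axis=1)
    n = len(pos)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("avmflow particle snapshot\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for p in pos:
            fh.write(" ".join("%.12g" % x for x in p) + "\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS speed double 1\nLOOKUP_TABLE default\n")
        for s in speed:
            fh.write("%.12g\n" % s)
        if colors is not None and len(colors) == n:
            fh.write("COLOR_SCALARS rgb 3\n")
            for c in colors:
                fh.write(" ".join("%.6g" % x for x in c) + "\n")
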