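"""Cartesian velocity grids and their file formats.

The particle engine consumes a 3D texture of velocities — the VF vector-field
format used by game-engine visual-effect graphs
(https://github.com/peeweek/VectorFieldFile).  The dialect implemented here
is the 3-component float variant:

    bytes 0..3   magic "VF_F"
    bytes 4..9   three little-endian uint16 dims (nx, ny, nz)
    then         nx*ny*nz vectors of three little-endian float32,
                 x index varying fastest, then y, then z

so a file is exactly ``10 + 12 * nx * ny * nz`` bytes.  Round trips are
bit-exact.

Velocity grids come from two sources: reconstruction of a network flow
solution (analytic Poiseuille paraboloid per segment) or resampling of an
externally simulated point-sampled field delivered as a legacy ASCII VTK
file with POINTS and VECTORS sections.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass

import numpy as np

from .hemoflow import FlowSolution
from .vessels import VascularNetwork, distance_field

__all__ = [
    "VF_MAGIC",
    "GridSpec",
    "VelocityGrid",
    "VFFormatError",
    "VTKFormatError",
    "grid_spec_for_network",
    "reconstruct_velocity_field",
    "resample_points_to_grid",
    "write_vf",
    "read_vf",
    "read_vtk_ascii",
    "write_vtk_points",
    "write_vtk_structured_points",
]

VF_MAGIC = b"VF_F"
_MAX_DIM = 0xFFFF  # dims are stored as uint16


class VFFormatError(ValueError):
    """Malformed VF file (bad magic, bad dims, or truncated payload)."""


class VTKFormatError(ValueError):
    """Legacy VTK ASCII file missing required sections or inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Cartesian sampling lattice: points at origin + index * step.

    ``step`` defaults to 0.2 mm, the grid resolution used for the exported
    velocity textures.  Each dim must fit in 16 bits (VF header constraint).
    """

    origin: tuple[float, float, float]
    step: float = 2.0e-4
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must each be >= 1")
        if any(d > _MAX_DIM for d in self.dims):
            raise ValueError(f"dims {self.dims} overflow the 16-bit VF header")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(o[i] + self.step * np.arange(self.dims[i]) for i in range(3))


@dataclass
class VelocityGrid:
    """A per-voxel 3-component velocity field (m/s) on a :class:`GridSpec`.

    ``vectors`` has shape (nx, ny, nz, 3); voxels outside the lumen are zero.
    """

    spec: GridSpec
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.ascontiguousarray(self.vectors, dtype=np.float32)
        expected = (*self.spec.dims, 3)
        if self.vectors.shape != expected:
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match grid dims "
                f"{expected}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("velocity components must be finite")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VelocityGrid):
            return NotImplemented
        return self.spec == other.spec and np.array_equal(self.vectors, other.vectors)


def grid_spec_for_network(network: VascularNetwork, step: float = 2.0e-4) -> GridSpec:
    """Grid covering the lumen: origin at the bounding-box minimum minus one
    step of padding, dims = ceil(extent/step) + 1 per axis."""
    lo, hi = network.bounding_box()
    origin = lo - step
    dims = tuple(int(np.ceil((hi[i] + step - origin[i]) / step)) + 1 for i in range(3))
    if any(d > _MAX_DIM for d in dims):
        raise ValueError(
            f"grid dims {dims} overflow the 16-bit VF header; increase step"
        )
    return GridSpec(origin=tuple(float(x) for x in origin), step=step, dims=dims)


def reconstruct_velocity_field(
    network: VascularNetwork,
    solution: FlowSolution,
    spec: GridSpec | None = None,
    step: float = 2.0e-4,
) -> VelocityGrid:
    """Sample the solved network flow onto a Cartesian grid.

    Inside each vessel the axial profile is the laminar Poiseuille paraboloid
    ``v(d) = 2 v_mean (1 - (d/r)^2)`` along the local centerline tangent
    (signed by the flow direction), where ``d`` is the voxel center's distance
    to the centerline; at the wall (d = r) the no-slip condition gives zero.
    Voxels outside every lumen, or inside a blocked vessel, are zero.  At
    junction overlaps the tube whose wall is nearest claims the voxel.
    """
    if spec is None:
        spec = grid_spec_for_network(network, step)
    _, vel = distance_field(network, spec, solution=solution)
    return VelocityGrid(spec=spec, vectors=vel)


def resample_points_to_grid(
    samples: list[tuple[np.ndarray, np.ndarray]] | tuple[np.ndarray, np.ndarray],
    spec: GridSpec,
) -> VelocityGrid:
    """Bin scattered (point, vector) samples onto a grid by per-voxel mean.

    Each sample is assigned to the voxel whose lattice point is nearest
    (half-step binning); a voxel's value is the arithmetic mean of its
    samples and empty voxels stay zero, so the result is independent of
    sample order.  Samples outside the grid are counted and reported with a
    warning, never fatal.  The grid step sets the level of detail.
    """
    if isinstance(samples, tuple) and len(samples) == 2 and np.ndim(samples[0]) == 2:
        points, vectors = (np.asarray(a, dtype=float) for a in samples)
    else:
        samples = list(samples)
        if not samples:
            return VelocityGrid(spec=spec, vectors=np.zeros((*spec.dims, 3)))
        points = np.asarray([p for p, _ in samples], dtype=float)
        vectors = np.asarray([v for _, v in samples], dtype=float)
    if len(points) == 0:
        return VelocityGrid(spec=spec, vectors=np.zeros((*spec.dims, 3)))

    idx = np.rint((points - np.asarray(spec.origin)) / spec.step).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(spec.dims)), axis=1)
    n_outside = int((~inside).sum())
    if n_outside:
        warnings.warn(
            f"{n_outside} of {len(points)} samples fall outside the grid and "
            "were ignored",
            UserWarning,
            stacklevel=2,
        )
    idx = idx[inside]
    vec = vectors[inside]
    sums = np.zeros((*spec.dims, 3))
    counts = np.zeros(spec.dims)
    np.add.at(sums, (idx[:, 0], idx[:, 1], idx[:, 2]), vec)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    nonzero = counts > 0
    sums[nonzero] /= counts[nonzero][:, None]
    return VelocityGrid(spec=spec, vectors=sums)


# ---------------------------------------------------------------------------
# VF binary format
# ---------------------------------------------------------------------------


def write_vf(grid: VelocityGrid, path) -> None:
    """Write a grid as a VF 3D vector texture (see module docstring)."""
    nx, ny, nz = grid.spec.dims
    payload = np.ascontiguousarray(
        grid.vectors.transpose(2, 1, 0, 3), dtype="<f4"
    )  # z slowest, x fastest
    with open(path, "wb") as fh:
        fh.write(VF_MAGIC)
        fh.write(struct.pack("<HHH", nx, ny, nz))
        fh.write(payload.tobytes())


def read_vf(path, origin=(0.0, 0.0, 0.0), step: float = 2.0e-4) -> VelocityGrid:
    """Read a VF vector texture written by :func:`write_vf`.

    The VF format stores no grid placement, so ``origin`` and ``step`` are
    caller-supplied (defaults give an abstract unit grid at 0.2 mm).
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != VF_MAGIC:
        raise VFFormatError(
            f"bad magic {data[:4]!r}; expected {VF_MAGIC!r} (only the "
            "3-component float dialect is supported)"
        )
    if len(data) < 10:
        raise VFFormatError("truncated header: file shorter than 10 bytes")
    nx, ny, nz = struct.unpack("<HHH", data[4:10])
    expected = 10 + 12 * nx * ny * nz
    if len(data) != expected:
        raise VFFormatError(
            f"payload length mismatch for dims ({nx}, {ny}, {nz}): expected "
            f"{expected} bytes, got {len(data)}"
        )
    flat = np.frombuffer(data, dtype="<f4", offset=10)
    vectors = flat.reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)
    spec = GridSpec(origin=tuple(origin), step=step, dims=(nx, ny, nz))
    return VelocityGrid(spec=spec, vectors=vectors)


# ---------------------------------------------------------------------------
# Legacy VTK ASCII
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # 12 significant digits for text round trips


def _read_floats(tokens: list[str], start: int, count: int, what: str) -> np.ndarray:
    chunk = tokens[start : start + count]
    if len(chunk) < count:
        raise VTKFormatError(
            f"truncated {what}: expected {count} values, found {len(chunk)}"
        )
    try:
        return np.asarray([float(t) for t in chunk])
    except ValueError as exc:
        raise VTKFormatError(f"non-numeric value in {what}: {exc}") from exc


def read_vtk_ascii(path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Parse a legacy ASCII VTK file into (point, vector) samples.

    Supports the intermediate produced when externally simulated fields are
    exported to legacy VTK: a POINTS section plus a 3-component VECTORS point
    data section (a 3-wide FIELD array named anything is accepted too).
    Binary legacy files and XML dialects are rejected.
    """
    with open(path, "r", errors="replace") as fh:
        text = fh.read()
    lines = text.splitlines()
    if len(lines) >= 3 and lines[2].strip().upper() == "BINARY":
        raise VTKFormatError("binary legacy VTK is unsupported; export as ASCII")
    tokens = text.split()
    upper = [t.upper() for t in tokens]

    try:
        i = upper.index("POINTS")
    except ValueError:
        raise VTKFormatError("no POINTS section found") from None
    n_points = int(tokens[i + 1])
    points = _read_floats(tokens, i + 3, 3 * n_points, "POINTS section").reshape(n_points, 3)

    vectors = None
    if "VECTORS" in upper:
        j = upper.index("VECTORS")
        vectors = _read_floats(tokens, j + 3, 3 * n_points, "VECTORS section")
    else:
        # Fallback: a FIELD array with 3 components and n_points tuples.
        for j, t in enumerate(upper):
            if t == "FIELD":
                n_arrays = int(tokens[j + 2])
                k = j + 3
                for _ in range(n_arrays):
                    name, ncomp, ntup = tokens[k], int(tokens[k + 1]), int(tokens[k + 2])
                    if ncomp == 3 and ntup == n_points:
                        vectors = _read_floats(
                            tokens, k + 4, 3 * n_points, f"FIELD array {name}"
                        )
                        break
                    k += 4 + ncomp * ntup
                break
    if vectors is None:
        raise VTKFormatError(
            "no 3-component point-data VECTORS (or 3-wide FIELD) section found"
        )
    vectors = vectors.reshape(n_points, 3)
    return [(points[i], vectors[i]) for i in range(n_points)]


def write_vtk_points(
    samples: list[tuple[np.ndarray, np.ndarray]], path, name: str = "velocity"
) -> None:
    """Write (point, vector) samples as a legacy ASCII VTK PolyData file."""
    n = len(samples)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("avmflow point-sampled velocity field\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for p, _ in samples:
            fh.write(" ".join(_FLOAT_FMT % x for x in p) + "\n")
        fh.write(f"POINT_DATA {n}\n")
        fh.write(f"VECTORS {name} double\n")
        for _, v in samples:
            fh.write(" ".join(_FLOAT_FMT % x for x in v) + "\n")


def write_vtk_structured_points(grid: VelocityGrid, path, name: str = "velocity") -> None:
    """Export a velocity grid as legacy VTK STRUCTURED_POINTS (ASCII)."""
    nx, ny, nz = grid.spec.dims
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("avmflow velocity grid\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN " + " ".join(_FLOAT_FMT % x for x in grid.spec.origin) + "\n")
        fh.write("SPACING " + " ".join(_FLOAT_FMT % grid.spec.step for _ in range(3)) + "\n")
        fh.write(f"POINT_DATA {grid.spec.n_voxels}\n")
        fh.write(f"VECTORS {name} float\n")
        flat = grid.vectors.transpose(2, 1, 0, 3).reshape(-1, 3)  # x fastest
        for v in flat:
            fh.write(" ".join(_FLOAT_FMT % x for x in v) + "\n")
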