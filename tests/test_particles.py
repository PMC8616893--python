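import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avmflow.fieldio import GridSpec, VelocityGrid
from avmflow.particles import (
    ColorScale,
    InletDisc,
    ParticleState,
    ParticleSystemConfig,
    advect_step,
    color_by_velocity,
    export_snapshot,
    ghost_opacity,
    sample_velocity,
    spawn,
)
from avmflow.vessels import network_to_mesh
from conftest import make_single_tube


def uniform_grid(v=(1.0, 0.0, 0.0), extent=1.0, n=11):
    vec = np.tile(np.asarray(v, dtype=np.float32), (n, n, n, 1))
    return VelocityGrid(
        spec=GridSpec((-extent / 2, -extent / 2, -extent / 2), extent / (n - 1), (n, n, n)),
        vectors=vec,
    )


def rotation_grid(omega=1.0, extent=4.0, n=41):
    """Solid rotation about z: v = omega * (-y, x, 0), linear in position so
    trilinear interpolation reproduces it exactly."""
    xs = np.linspace(-extent / 2, extent / 2, n)
    X, Y, _ = np.meshgrid(xs, xs, xs, indexing="ij")
    vec = np.stack([-omega * Y, omega * X, np.zeros_like(X)], axis=-1)
    return VelocityGrid(
        spec=GridSpec((xs[0], xs[0], xs[0]), xs[1] - xs[0], (n, n, n)), vectors=vec
    )


def seeded_state(positions, config):
    st_ = ParticleState.empty(config)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    st_.positions = positions
    st_.velocities = np.zeros_like(positions)
    st_.ages = np.zeros(len(positions))
    st_.alive = np.ones(len(positions), dtype=bool)
    return st_


DISC = InletDisc(center=(0.0, 0.0, 0.0), normal=(1.0, 0.0, 0.0), radius=0.1)


class TestSpawn:
    def test_zero_rate_spawns_nothing(self):
        cfg = ParticleSystemConfig(spawn_rate=0.0, seed=1)
        state = spawn(ParticleState.empty(cfg), cfg, DISC, dt=0.1)
        assert state.n_alive == 0

    def test_rate_times_dt_accounting(self):
        cfg = ParticleSystemConfig(spawn_rate=1000.0, seed=1, max_alive=10_000)
        state = spawn(ParticleState.empty(cfg), cfg, DISC, dt=0.1)
        assert state.n_alive == 100

    def test_fractional_rate_accumulates_across_steps(self):
        cfg = ParticleSystemConfig(spawn_rate=2.5, seed=1)
        state = ParticleState.empty(cfg)
        counts = []
        for _ in range(4):
            state = spawn(state, cfg, DISC, dt=1.0)
            counts.append(state.n_alive)
        assert counts == [2, 5, 7, 10]

    def test_cap_suppresses_excess(self):
        cfg = ParticleSystemConfig(spawn_rate=1e6, max_alive=50, seed=1)
        state = ParticleState.empty(cfg)
        state = spawn(state, cfg, DISC, dt=1.0)
        assert state.n_alive == 50
        state = spawn(state, cfg, DISC, dt=1.0)
        assert state.n_alive == 50

    def test_positions_lie_on_the_disc(self):
        cfg = ParticleSystemConfig(spawn_rate=500.0, seed=7)
        state = spawn(ParticleState.empty(cfg), cfg, DISC, dt=1.0)
        assert np.allclose(state.positions[:, 0], 0.0, atol=1e-12)
        assert np.all(np.linalg.norm(state.positions[:, 1:], axis=1) <= DISC.radius)

    def test_seeded_determinism(self):
        cfg = ParticleSystemConfig(spawn_rate=100.0, seed=9)
        a = spawn(ParticleState.empty(cfg), cfg, DISC, dt=1.0)
        b = spawn(ParticleState.empty(cfg), cfg, DISC, dt=1.0)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestAdvection:
    def test_uniform_field_euler_displacement_exact(self):
        cfg = ParticleSystemConfig(integrator="euler", dt=0.1, lifetime=10, seed=0)
        grid = uniform_grid((1.0, 0.0, 0.0))
        state = seeded_state([[0.0, 0.0, 0.0], [0.1, 0.1, -0.1]], cfg)
        before = state.positions.copy()
        state = advect_step(state, grid, cfg)
        np.testing.assert_allclose(state.positions - before, [[0.1, 0, 0]] * 2)

    def test_zero_field_freezes_positions_but_ages_advance(self):
        cfg = ParticleSystemConfig(dt=0.1, lifetime=10, seed=0)
        grid = uniform_grid((0.0, 0.0, 0.0))
        state = seeded_state([[0.0, 0.0, 0.0]], cfg)
        state = advect_step(state, grid, cfg)
        assert state.n_alive == 1
        np.testing.assert_array_equal(state.positions, [[0.0, 0.0, 0.0]])
        assert state.ages[0] == pytest.approx(0.1)

    def test_moving_into_a_dead_voxel_kills(self):
        # interior flow carries the particle into the zero-velocity border
        grid = uniform_grid((1.0, 0.0, 0.0), extent=1.0)
        vec = grid.vectors.copy()
        vec[-2:, :, :, :] = 0.0  # dead zone on the +x side
        grid = VelocityGrid(spec=grid.spec, vectors=vec)
        cfg = ParticleSystemConfig(dt=0.5, lifetime=10, integrator="euler", seed=0)
        state = seeded_state([[0.0, 0.0, 0.0]], cfg)
        state = advect_step(state, grid, cfg)
        assert state.n_alive == 0

    def test_lifetime_expiry_kills(self):
        cfg = ParticleSystemConfig(dt=0.6, lifetime=1.0, integrator="euler", seed=0)
        grid = uniform_grid((1e-6, 0, 0))
        state = seeded_state([[0.0, 0.0, 0.0]], cfg)
        state = advect_step(state, grid, cfg)
        assert state.n_alive == 1 and state.ages[0] == pytest.approx(0.6)
        state = advect_step(state, grid, cfg)
        assert state.n_alive == 0

    def test_rk4_orbit_radius_drift_below_1e6(self):
        cfg = ParticleSystemConfig(integrator="rk4", dt=0.01, lifetime=100, seed=0)
        grid = rotation_grid(omega=1.0)
        state = seeded_state([[1.0, 0.0, 0.0]], cfg)
        for _ in range(628):  # one full revolution at omega = 1 rad/s
            state = advect_step(state, grid, cfg)
        assert state.n_alive == 1
        r = np.linalg.norm(state.positions[0, :2])
        assert abs(r - 1.0) < 1e-6

    def test_rk4_converges_four_orders_faster_than_euler(self):
        grid = rotation_grid(omega=1.0)

        def orbit_error(integrator, dt, t_total=1.0):
            cfg = ParticleSystemConfig(integrator=integrator, dt=dt, lifetime=100, seed=0)
            state = seeded_state([[1.0, 0.0, 0.0]], cfg)
            for _ in range(int(round(t_total / dt))):
                state = advect_step(state, grid, cfg)
            exact = np.array([np.cos(t_total), np.sin(t_total), 0.0])
            return np.linalg.norm(state.positions[0] - exact)

        # dt pairs chosen so truncation error dominates the float32
        # grid-storage noise (~1e-7) for each integrator
        for integ, dts, expected_order in (
            ("euler", (0.02, 0.01), 1),
            ("rk4", (0.25, 0.125), 4),
        ):
            e1 = orbit_error(integ, dts[0])
            e2 = orbit_error(integ, dts[1])
            order = np.log2(e1 / e2)
            assert order == pytest.approx(expected_order, abs=0.6)

    def test_full_trace_deterministic_for_fixed_seed(self):
        grid = rotation_grid()

        def run():
            cfg = ParticleSystemConfig(
                spawn_rate=200.0, dt=0.05, lifetime=2.0, seed=11, max_alive=1000
            )
            disc = InletDisc(center=(1.0, 0.0, 0.0), normal=(0.0, 1.0, 0.0), radius=0.2)
            state = ParticleState.empty(cfg)
            for _ in range(20):
                state = spawn(state, cfg, disc, cfg.dt, grid)
                state = advect_step(state, grid, cfg)
            return state.positions

        np.testing.assert_array_equal(run(), run())

    @given(rate=st.floats(0, 5000), steps=st.integers(1, 10))
    @settings(max_examples=10, deadline=None)
    def test_cap_and_age_invariants_hold_under_any_rate(self, rate, steps):
        cfg = ParticleSystemConfig(
            spawn_rate=rate, max_alive=300, lifetime=0.5, dt=0.1, seed=2
        )
        grid = rotation_grid(n=11)
        disc = InletDisc(center=(1.0, 0.0, 0.0), normal=(0.0, 1.0, 0.0), radius=0.2)
        state = ParticleState.empty(cfg)
        for _ in range(steps):
            state = spawn(state, cfg, disc, cfg.dt, grid)
            assert state.n_alive <= cfg.max_alive
            state = advect_step(state, grid, cfg)
            assert state.n_alive <= cfg.max_alive
            assert np.all(state.ages[state.alive] <= cfg.lifetime)


class TestColorScales:
    def test_rainbow_endpoints_and_midpoint(self):
        scale = ColorScale(kind="rainbow", vmin=0.0, vmax=2.0)
        cfg = ParticleSystemConfig(seed=0)
        state = seeded_state([[0, 0, 0]] * 3, cfg)
        state.velocities = np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        rgb = color_by_velocity(state, scale)
        np.testing.assert_allclose(rgb[0], [0, 0, 1])  # vmin: blue
        np.testing.assert_allclose(rgb[1], [0, 1, 0])  # midpoint: green
        np.testing.assert_allclose(rgb[2], [1, 0, 0])  # vmax: red

    def test_heated_body_ramps_black_to_white(self):
        scale = ColorScale(kind="heated_body", vmin=0.0, vmax=1.0)
        cfg = ParticleSystemConfig(seed=0)
        state = seeded_state([[0, 0, 0]] * 2, cfg)
        state.velocities = np.array([[0.0, 0, 0], [5.0, 0, 0]])  # clamped above vmax
        rgb = color_by_velocity(state, scale)
        np.testing.assert_allclose(rgb[0], [0, 0, 0])
        np.testing.assert_allclose(rgb[1], [1, 1, 1])

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            ColorScale(kind="viridis")
        with pytest.raises(ValueError):
            ColorScale(vmin=1.0, vmax=1.0)


class TestGhostOpacity:
    def test_formula_on_synthetic_normals(self):
        # one triangle in the z=0 plane; normal +z; viewpoint manipulated
        class Mesh:
            vertices = np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
            faces = np.array([[0, 1, 2]])

        # viewpoint straight above vertex 0: |n.v| = 1 -> alpha_min
        a = ghost_opacity(Mesh, np.array([0.0, 0.0, 5.0]), exponent=2, alpha_min=0.1)
        assert a[0] == pytest.approx(0.1)
        # viewpoint in-plane (silhouette): |n.v| = 0 -> 1
        a = ghost_opacity(Mesh, np.array([5.0, 0.0, 0.0]), exponent=2, alpha_min=0.1)
        assert a[0] == pytest.approx(1.0)
        # 60-degree case: |n.v| = 0.5, k=2, alpha_min=0 -> 0.25
        v = np.array([0.0, np.sqrt(3), 1.0]) * 2  # cos(angle to +z) = 0.5
        a = ghost_opacity(Mesh, v, exponent=2, alpha_min=0.0)
        assert a[0] == pytest.approx(0.25, rel=1e-12)

    def test_tube_silhouette_is_opaque_facing_is_transparent(self):
        net = make_single_tube()
        mesh = network_to_mesh(net, sides_per_ring=16)
        view = np.array([10e-3, 0.0, 1.0])  # far along +z
        alpha = ghost_opacity(mesh, view, exponent=2, alpha_min=0.05)
        assert alpha.min() >= 0.05 and alpha.max() <= 1.0
        assert alpha.max() > 0.9  # silhouette vertices
        assert alpha.min() < 0.1  # facing vertices

    def test_parameter_validation(self):
        net = make_single_tube()
        mesh = network_to_mesh(net, sides_per_ring=6)
        with pytest.raises(ValueError):
            ghost_opacity(mesh, np.zeros(3), exponent=0.0)
        with pytest.raises(ValueError):
            ghost_opacity(mesh, np.zeros(3), alpha_min=1.0)


class TestSnapshot:
    def test_empty_population_still_valid_file(self, tmp_path):
        cfg = ParticleSystemConfig(seed=0)
        path = tmp_path / "empty.vtk"
        export_snapshot(ParticleState.empty(cfg), None, path)
        assert "POINTS 0" in path.read_text()

    def test_point_count_and_text_round_trip(self, tmp_path):
        from avmflow.fieldio import read_vtk_ascii

        cfg = ParticleSystemConfig(spawn_rate=50.0, seed=5)
        state = spawn(ParticleState.empty(cfg), cfg, DISC, dt=1.0)
        state.velocities = np.random.default_rng(0).normal(size=state.positions.shape)
        scale = ColorScale(vmin=0.0, vmax=5.0)
        path = tmp_path / "snap.vtk"
        export_snapshot(state, color_by_velocity(state, scale), path)
        text = path.read_text()
        assert f"POINTS {state.n_alive}" in text
        # positions recoverable to 12 significant digits via the VTK reader
        # (speed scalars are not VECTORS, so parse points only)
        lines = text.splitlines()
        i = next(k for k, l in enumerate(lines) if l.startswith("POINTS"))
        pts = np.array(
            [[float(x) for x in lines[i + 1 + j].split()] for j in range(state.n_alive)]
        )
        np.testing.assert_allclose(pts, state.positions, rtol=1e-11, atol=1e-15)
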