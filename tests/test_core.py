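"""Agent dynamics: initialisation, gaze, sector search, movement rules,
sweeps, quasi-stationarity and absorbing states."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import attention_swarm as asw
from attention_swarm.core import TWO_PI, movable_agents, sweep
from attention_swarm.fixtures import make_triangular_lattice

D = 0.1


def brute_force_sector_nn(pos, i, gaze, alpha):
    """Exhaustive all-pairs oracle with explicit angle arithmetic."""
    best, best_d = None, np.inf
    for j in range(len(pos)):
        if j == i:
            continue
        dx, dy = pos[j] - pos[i]
        diff = math.atan2(dy, dx) - gaze
        diff = (diff + math.pi) % TWO_PI - math.pi
        if abs(diff) <= alpha / 2 + 1e-15:
            d = math.hypot(dx, dy)
            if d < best_d:
                best, best_d = j, d
    return best


class TestInitialisation:
    def test_uniform_in_box(self):
        params = asw.SimulationParams(P=91, L=1.74, seed=0)
        state = asw.init_uniform(params, np.random.default_rng(0))
        assert state.positions.shape == (91, 2)
        assert state.t == 0
        assert np.all(state.positions >= 0) and np.all(state.positions <= 1.74)

    def test_single_agent(self):
        params = asw.SimulationParams(P=1, L=5.0)
        state = asw.init_uniform(params, np.random.default_rng(1))
        assert state.n == 1 and state.t == 0

    def test_law_of_large_numbers(self):
        # mean of 1000 uniforms on [0, 1] is within 3 sigma of 1/2
        params = asw.SimulationParams(P=1000, L=1.0)
        state = asw.init_uniform(params, np.random.default_rng(42))
        sigma = 1.0 / math.sqrt(12 * 1000)
        assert abs(state.positions[:, 0].mean() - 0.5) < 3 * sigma

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            asw.SimulationParams(P=0)
        with pytest.raises(ValueError):
            asw.SimulationParams(alpha=0.0)
        with pytest.raises(ValueError):
            asw.SimulationParams(alpha=2 * math.pi + 0.1)
        with pytest.raises(ValueError):
            asw.SimulationParams(eta=1.5)
        with pytest.raises(ValueError):
            asw.SimulationParams(v=-1.0)


class TestGaze:
    def test_range_and_reproducibility(self):
        rng = np.random.default_rng(7)
        draws = [asw.sample_gaze(rng) for _ in range(1000)]
        assert all(0.0 <= g < TWO_PI for g in draws)
        rng2 = np.random.default_rng(7)
        assert draws == [asw.sample_gaze(rng2) for _ in range(1000)]

    def test_uniform_distribution(self):
        rng = np.random.default_rng(3)
        draws = rng.uniform(0, TWO_PI, size=10**6)
        stat = stats.kstest(draws / TWO_PI, "uniform").statistic
        assert stat < 1.63 / math.sqrt(len(draws))  # 1% critical value


class TestSectorNearestNeighbour:
    def test_sector_geometry(self):
        state = asw.SwarmState(np.array([[0, 0], [1, 0], [0.1, 0.9]]))
        assert asw.sector_nearest_neighbour(state, 0, 0.0, math.pi / 2) == 1

    def test_full_circle_is_global_nn(self):
        state = asw.SwarmState(np.array([[0, 0], [1, 0], [0, 0.5]]))
        assert asw.sector_nearest_neighbour(state, 0, 0.0, TWO_PI) == 2

    def test_empty_sector_returns_none(self):
        state = asw.SwarmState(np.array([[0, 0], [-1, 0]]))
        assert asw.sector_nearest_neighbour(state, 0, 0.0, math.pi / 2) is None

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            pos = rng.uniform(0, 1, size=(50, 2))
            state = asw.SwarmState(pos)
            i = int(rng.integers(50))
            gaze = float(rng.uniform(0, TWO_PI))
            alpha = float(rng.uniform(0.05, TWO_PI))
            got = asw.sector_nearest_neighbour(state, i, gaze, alpha)
            assert got == brute_force_sector_nn(pos, i, gaze, alpha)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        pts=st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            min_size=3,
            max_size=25,
            unique=True,
        ),
        gaze=st.floats(0, TWO_PI, exclude_max=True),
        alpha=st.floats(0.05, TWO_PI),
    )
    def test_oracle_equivalence_property(self, pts, gaze, alpha):
        pos = np.asarray(pts)
        state = asw.SwarmState(pos)
        got = asw.sector_nearest_neighbour(state, 0, gaze, alpha)
        assert got == brute_force_sector_nn(pos, 0, gaze, alpha)


class TestMoveAgent:
    @pytest.mark.parametrize(
        "xi, xj, v, expected",
        [
            ((0, 0), (1, 0), 0.3, (0.3, 0)),  # plain attraction step
            ((0, 0), (0.15, 0), 0.1, (0.05, 0)),  # stress-zone stop at D
            ((0, 0), (0.05, 0), 0.2, (-0.05, 0)),  # repulsion stop at D
        ],
    )
    def test_deterministic_step_examples(self, xi, xj, v, expected):
        offset = np.array([50.0, 50.0])  # keep the pair away from the walls
        params = asw.SimulationParams(P=2, L=100.0, D=D, v=v, eta=0.0)
        state = asw.SwarmState(np.array([xi, xj], dtype=float) + offset)
        out = asw.move_agent(state, 0, 1, params, np.random.default_rng(0))
        assert out.moved
        np.testing.assert_allclose(state.positions[0], np.array(expected) + offset,
                                   atol=1e-12)
        assert abs(np.linalg.norm(state.positions[0] - state.positions[1]) - D) >= 0

    def test_at_ideal_distance_no_move(self):
        params = asw.SimulationParams(P=2, L=100.0, D=D, v=0.3)
        state = asw.SwarmState(np.array([[0.0, 0.0], [D, 0.0]]))
        out = asw.move_agent(state, 0, 1, params, np.random.default_rng(0))
        assert not out.moved and out.displacement_norm == 0.0

    def test_self_target_rejected(self):
        params = asw.SimulationParams(P=2, L=1.0)
        state = asw.SwarmState(np.array([[0.0, 0.0], [0.5, 0.5]]))
        with pytest.raises(ValueError):
            asw.move_agent(state, 1, 1, params, np.random.default_rng(0))

    def test_noisy_steps_respect_stop_rules(self):
        # attraction never ends inside D; repulsion never ends beyond D;
        # displacement never exceeds v
        rng = np.random.default_rng(5)
        params = asw.SimulationParams(P=2, L=100.0, D=D, v=0.08, eta=0.7)
        for _ in range(500):
            xi = rng.uniform(40, 60, size=2)
            xj = xi + rng.uniform(-0.2, 0.2, size=2)
            d0 = np.linalg.norm(xj - xi)
            if d0 < 1e-6 or abs(d0 - D) < 1e-9:
                continue
            state = asw.SwarmState(np.array([xi, xj]))
            out = asw.move_agent(state, 0, 1, params, rng)
            assert out.displacement_norm <= params.v + 1e-12
            d1 = np.linalg.norm(state.positions[1] - state.positions[0])
            if d0 > D:
                assert d1 >= D - 1e-12
            else:
                assert d1 <= D + 1e-12

    def test_positions_clamped_to_box(self):
        # repulsion that would stop outside the box is clamped to the wall
        params = asw.SimulationParams(P=2, L=1.0, D=D, v=0.5)
        state = asw.SwarmState(np.array([[0.99, 0.5], [0.98, 0.5]]))
        out = asw.move_agent(state, 0, 1, params, np.random.default_rng(0))
        assert out.moved
        assert np.all(state.positions >= 0) and np.all(state.positions <= 1.0)
        assert state.positions[0, 0] == 1.0


class TestSweepAndRun:
    def test_lattice_is_fixed_point_at_wide_attention(self):
        # every sought neighbour of a lattice agent is at exactly D once the
        # attention field is at least a half-plane
        fix = make_triangular_lattice(D, shells=3, center=(5.0, 5.0))
        params = asw.SimulationParams(P=fix.n, L=10.0, D=D, alpha=math.pi)
        state = asw.SwarmState(fix.positions.copy())
        rng = np.random.default_rng(0)
        for _ in range(20):
            _, moved = sweep(state, params, rng)
            assert moved == 0
        np.testing.assert_array_equal(state.positions, fix.positions)

    def test_lattice_not_fixed_point_below_60_degrees(self):
        # a sector narrower than pi/3 can frame a second-shell neighbour
        # (sqrt(3) D) while hiding both flanking first-shell ones: the
        # crystal is unstable for small attention fields
        fix = make_triangular_lattice(D, shells=3, center=(5.0, 5.0))
        params_narrow = asw.SimulationParams(P=fix.n, L=10.0, D=D, alpha=math.radians(30))
        params_wide = asw.SimulationParams(P=fix.n, L=10.0, D=D, alpha=math.pi)
        state = asw.SwarmState(fix.positions.copy())
        assert len(movable_agents(state, params_narrow)) == fix.n
        assert len(movable_agents(state, params_wide)) == 0

    def test_two_agents_converge_to_exact_ideal_distance(self):
        v = 0.0112
        params = asw.SimulationParams(
            P=2, L=10.0, D=D, v=v, alpha=TWO_PI, seed=9, qs_window=20, max_sweeps=5000
        )
        initial = asw.SwarmState(np.array([[5.0, 5.0], [5.0 + 3 * v + D, 5.0]]))
        traj = asw.run(params, initial=initial)
        assert traj.converged
        gap = np.linalg.norm(traj.final.positions[0] - traj.final.positions[1])
        assert abs(gap - D) < 1e-12

    def test_moved_count_in_range(self):
        params = asw.SimulationParams(P=25, L=0.9, seed=4)
        state = asw.init_uniform(params, np.random.default_rng(4))
        rng = np.random.default_rng(4)
        for _ in range(50):
            _, moved = sweep(state, params, rng)
            assert 0 <= moved <= params.P

    def test_run_from_quiescent_lattice_converges_at_zero(self):
        fix = make_triangular_lattice(D, shells=2, center=(5.0, 5.0))
        params = asw.SimulationParams(
            P=fix.n, L=10.0, D=D, alpha=math.pi, qs_window=50, max_sweeps=1000
        )
        traj = asw.run(params, initial=asw.SwarmState(fix.positions.copy()))
        assert traj.converged and traj.t_conv == 0

    def test_max_sweeps_cap(self):
        params = asw.SimulationParams(P=20, L=0.8, seed=1, max_sweeps=1)
        traj = asw.run(params)
        assert not traj.converged and traj.final.t == 1
        assert len(traj.samples) == 2

    def test_positions_stay_in_box_under_noise(self):
        params = asw.SimulationParams(
            P=30, L=0.5, seed=2, alpha=TWO_PI, eta=0.8, max_sweeps=300
        )
        traj = asw.run(params, sample_every=50)
        for state in traj.samples:
            assert np.all(state.positions >= 0)
            assert np.all(state.positions <= params.L)

    def test_fixed_seed_reproduces_trajectory_exactly(self):
        params = asw.SimulationParams(P=40, L=1.2, seed=123, eta=0.3, max_sweeps=500)
        a = asw.run(params, sample_every=100)
        b = asw.run(params, sample_every=100)
        assert a.converged == b.converged and a.t_conv == b.t_conv
        for sa, sb in zip(a.samples, b.samples):
            np.testing.assert_array_equal(sa.positions, sb.positions)
        c = asw.run(params.with_(seed=124), sample_every=100)
        assert not np.array_equal(a.final.positions, c.final.positions)


class TestAbsorbingState:
    def test_lattice_is_absorbing(self):
        fix = make_triangular_lattice(D, shells=2)
        assert asw.is_absorbing(asw.SwarmState(fix.positions.copy()), D)

    def test_random_points_are_not(self):
        rng = np.random.default_rng(0)
        state = asw.SwarmState(rng.uniform(0, 1.74, size=(91, 2)))
        assert not asw.is_absorbing(state, D)

    def test_perturbed_lattice_is_not(self):
        tol = 1e-9
        fix = make_triangular_lattice(D, shells=2)
        pos = fix.positions.copy()
        pos[3, 0] += 10 * tol
        assert not asw.is_absorbing(asw.SwarmState(pos), D, tol=tol)

    def test_collinear_configuration_reported_not_absorbing(self):
        pos = np.column_stack([np.linspace(0, 1, 5), np.zeros(5)])
        assert not asw.is_absorbing(asw.SwarmState(pos), D)
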