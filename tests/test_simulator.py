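"""Agent-based movement model: components, stepping, emergent behaviour."""

import math

import numpy as np
import pytest
import shapely

import tubeswarm as ts
from tubeswarm.geometry import RegionLabel, build_region_polygons, classify_points
from tubeswarm.simulator import (ModelParams, SwarmState, initialize_swarm,
                                 neighbors_in_fov, nearest_neighbor_velocity,
                                 simulate, step_swarm, swarm_following_velocity,
                                 wall_avoidance_velocity)


def _swarm(positions, velocities=None, active=None):
    p = np.asarray(positions, float)
    v = np.zeros_like(p) if velocities is None else np.asarray(velocities, float)
    a = np.ones(len(p), bool) if active is None else np.asarray(active, bool)
    return SwarmState(positions=p, velocities=v, active=a)


@pytest.fixture(scope="module")
def big_tube():
    # wide, long tube so mid-tube fish are far from the walls
    return ts.make_tube_fixture(29.05, opening_width=400, length=1000)


class TestNeighborsInFov:
    def test_fish_directly_behind_excluded(self, big_tube):
        mid = np.asarray(build_region_polygons(big_tube)["middle"].centroid.coords[0])
        swarm = _swarm([mid, mid - [50, 0]], velocities=[[1, 0], [1, 0]])
        nb = neighbors_in_fov(0, swarm, ModelParams(), big_tube)
        assert nb.m == 0 and nb.nearest_index is None

    def test_single_fish_ahead(self, big_tube):
        mid = np.asarray(build_region_polygons(big_tube)["middle"].centroid.coords[0])
        swarm = _swarm([mid, mid + [50, 0]], velocities=[[1, 0], [1, 0]])
        nb = neighbors_in_fov(0, swarm, ModelParams(), big_tube)
        assert list(nb.ids) == [1]
        assert nb.nearest_index == 1
        assert nb.n_front == 1
        np.testing.assert_allclose(nb.front_centroid, mid + [50, 0])
        assert nb.d_n == pytest.approx(50.0)

    def test_out_of_range_excluded(self, big_tube):
        mid = np.asarray(build_region_polygons(big_tube)["middle"].centroid.coords[0])
        params = ModelParams(fov_range=30.0)
        swarm = _swarm([mid, mid + [50, 0]], velocities=[[1, 0], [1, 0]])
        nb = neighbors_in_fov(0, swarm, params, big_tube)
        assert nb.m == 0

    def test_passed_fish_not_perceived(self, big_tube):
        mid = np.asarray(build_region_polygons(big_tube)["middle"].centroid.coords[0])
        swarm = _swarm([mid, mid + [50, 0]], velocities=[[1, 0], [1, 0]],
                       active=[True, False])
        nb = neighbors_in_fov(0, swarm, ModelParams(), big_tube)
        assert nb.m == 0

    def test_matches_brute_force_oracle(self, big_tube, rng):
        """Membership equals an explicit angle/distance check on random
        configurations (the heavy 10^4-configuration sweep runs in the
        acceptance suite; this is a quick version)."""
        params = ModelParams()
        n_checks = 0
        for _ in range(200):
            n = rng.integers(2, 8)
            pts = np.column_stack([rng.uniform(100, 900, n), rng.uniform(-150, 150, n)])
            vels = rng.normal(0, 3, (n, 2))
            swarm = _swarm(pts, vels)
            i = int(rng.integers(0, n))
            nb = neighbors_in_fov(i, swarm, params, big_tube)
            heading = swarm.heading(i, big_tube.x_axis_direction)
            expected = set()
            for j in range(n):
                if j == i:
                    continue
                off = pts[j] - pts[i]
                d = math.hypot(*off)
                if d > params.fov_range or d == 0:
                    if d == 0:
                        expected.add(j)
                    continue
                ang = math.degrees(math.acos(
                    np.clip(off @ heading / d, -1, 1)))
                if ang <= params.fov_half_angle + 1e-9:
                    expected.add(j)
            assert set(nb.ids) == expected
            n_checks += 1
        assert n_checks == 200


class TestVelocityComponents:
    def test_following_pulls_halfway_gain(self, big_tube):
        swarm = _swarm([[500, 0], [502, 0]], velocities=[[1, 0], [1, 0]])
        nb = neighbors_in_fov(0, swarm, ModelParams(k=1.0), big_tube)
        v = swarm_following_velocity(0, swarm, nb, ModelParams(k=1.0))
        np.testing.assert_allclose(v, [1.0, 0.0])

    def test_no_front_fish_gives_zero_follow(self, big_tube):
        swarm = _swarm([[500, 0], [450, 0]], velocities=[[0, 1], [1, 0]])
        nb = neighbors_in_fov(0, swarm, ModelParams(), big_tube)
        v = swarm_following_velocity(0, swarm, nb, ModelParams())
        np.testing.assert_allclose(v, [0.0, 0.0])

    def test_front_centroid_of_three(self, big_tube, rng):
        base = np.array([400.0, 0.0])
        front = base + rng.uniform(5, 60, (3, 2)) * [1, 0.5]
        swarm = _swarm(np.vstack([base, front]),
                       velocities=np.tile([1.0, 0.0], (4, 1)))
        params = ModelParams(k=0.2)
        nb = neighbors_in_fov(0, swarm, params, big_tube)
        v = swarm_following_velocity(0, swarm, nb, params)
        np.testing.assert_allclose(v, 0.5 * 0.2 * (front.mean(axis=0) - base),
                                   atol=1e-12)

    def test_repulsion_inside_d1(self, big_tube):
        params = ModelParams(k=1.0, d1=2.0, d2=5.0)
        swarm = _swarm([[500, 0], [501, 0]], velocities=[[1, 0], [1, 0]])
        nb = neighbors_in_fov(0, swarm, params, big_tube)
        np.testing.assert_allclose(
            nearest_neighbor_velocity(0, swarm, nb, params), [-1.0, 0.0])

    def test_parallel_band_gives_zero(self, big_tube):
        params = ModelParams(k=1.0, d1=2.0, d2=5.0)
        swarm = _swarm([[500, 0], [503, 0]], velocities=[[1, 0], [1, 0]])
        nb = neighbors_in_fov(0, swarm, params, big_tube)
        np.testing.assert_allclose(
            nearest_neighbor_velocity(0, swarm, nb, params), [0.0, 0.0])

    def test_attraction_beyond_d2(self, big_tube):
        params = ModelParams(k=0.5, d1=2.0, d2=3.0)
        swarm = _swarm([[500, 0], [500, 5]], velocities=[[0, 1], [0, 1]])
        nb = neighbors_in_fov(0, swarm, params, big_tube)
        np.testing.assert_allclose(
            nearest_neighbor_velocity(0, swarm, nb, params), [0.0, 2.5])

    def test_nearest_tie_breaks_to_lowest_id(self, big_tube):
        swarm = _swarm([[500, 0], [500, 10], [500, -10]],
                       velocities=np.tile([1.0, 0.0], (3, 1)))
        nb = neighbors_in_fov(0, swarm, ModelParams(), big_tube)
        assert nb.nearest_index == 1

    def test_wall_push_zero_beyond_d3(self, tube_a):
        axis_pt = np.array([100.0, 0.0])  # on the axis, far from both walls
        swarm = _swarm([axis_pt])
        v = wall_avoidance_velocity(0, swarm, ModelParams(), tube_a)
        np.testing.assert_allclose(v, [0.0, 0.0])

    def test_wall_push_magnitude(self, tube_a):
        # place a fish exactly 10 px off the left wall
        from shapely.ops import nearest_points
        foot = nearest_points(tube_a.wall_line("l"),
                              shapely.Point([300.0, 0.0]))[0]
        p = np.asarray(foot.coords[0]) + tube_a.inward_wall_normal("l") * 10.0
        swarm = _swarm([p])
        params = ModelParams(b=0.8, d3=18.0)
        v = wall_avoidance_velocity(0, swarm, params, tube_a)
        assert np.linalg.norm(v) == pytest.approx(8.0, abs=1e-9)

    def test_wall_push_points_inward(self, tube_a, rng):
        """The push never has a component out of the tube (geometric oracle
        over random near-wall states)."""
        params = ModelParams()
        polys = build_region_polygons(tube_a)
        pts = []
        while len(pts) < 300:
            cand = np.array([rng.uniform(0, tube_a.length),
                             rng.uniform(-300, 300)])
            if tube_a.trapezoid.covers(shapely.Point(cand)):
                pts.append(cand)
        for p in pts:
            swarm = _swarm([p])
            v = wall_avoidance_velocity(0, swarm, params, tube_a)
            if np.linalg.norm(v) > 0:
                _, side = tube_a.wall_distance(p)
                assert v @ tube_a.inward_wall_normal(side) >= 0

    def test_outside_tube_rejected(self, tube_a):
        swarm = _swarm([[-1000.0, 0.0]])
        with pytest.raises(ValueError):
            wall_avoidance_velocity(0, swarm, ModelParams(), tube_a)


class TestStepSwarm:
    def test_lone_fish_moves_at_forward_drive(self, big_tube):
        mid = np.asarray(build_region_polygons(big_tube)["middle"].centroid.coords[0])
        params = ModelParams(v0=4.0, n_fish=1)
        swarm = _swarm([mid], velocities=[[4.0, 0.0]])
        nxt = step_swarm(swarm, params, big_tube)
        np.testing.assert_allclose(nxt.velocities[0], [4.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(nxt.positions[0], mid + [4.0, 0.0], atol=1e-12)

    def test_velocity_is_sum_of_components(self, tube_a):
        """v(t+1) equals v0 + v_s + v_n + v_w computed independently."""
        params = ModelParams()
        rng = np.random.default_rng(5)
        state = initialize_swarm(params, tube_a, rng)
        nxt = step_swarm(state, params, tube_a)
        v0_vec = params.v0 * tube_a.x_axis_direction
        for i in range(state.n_fish):
            if not nxt.active[i]:
                continue  # passed the exit during this step; velocity zeroed
            nb = neighbors_in_fov(i, state, params, tube_a)
            expected = (v0_vec
                        + swarm_following_velocity(i, state, nb, params)
                        + nearest_neighbor_velocity(i, state, nb, params)
                        + wall_avoidance_velocity(i, state, params, tube_a,
                                                  check_inside=False))
            np.testing.assert_allclose(nxt.velocities[i], expected, atol=1e-12)

    def test_update_is_synchronous(self, big_tube):
        """Every fish sees positions at time t, not a partially updated mix."""
        params = ModelParams(k=1.0, d1=2.0, d2=5.0, v0=1.0)
        p = [[500.0, -20.0], [500.0, 20.0]]
        swarm = _swarm(p, velocities=[[1, 0], [1, 0]])
        nxt = step_swarm(swarm, params, big_tube)
        # symmetric attraction: y-components must be exactly opposite
        assert nxt.velocities[0][1] == pytest.approx(-nxt.velocities[1][1], abs=1e-12)

    def test_exit_crossing_marks_passed(self, tube_a):
        near_exit = np.array([tube_a.length - 1.0, 0.0])
        params = ModelParams(v0=5.0, n_fish=1)
        swarm = _swarm([near_exit], velocities=[[5.0, 0.0]])
        nxt = step_swarm(swarm, params, tube_a)
        assert nxt.n_passed == 1
        # frozen thereafter
        nxt2 = step_swarm(nxt, params, tube_a)
        np.testing.assert_allclose(nxt2.positions, nxt.positions)


class TestSimulate:
    def test_zero_steps_gives_initial_frame_only(self, tube_a):
        frames = simulate(ModelParams(n_fish=12), tube_a, 0, seed=2)
        assert len(frames) == 1
        assert frames[0].n_fish == 12

    def test_seed_determinism(self, tube_a):
        a = simulate(ModelParams(), tube_a, 50, seed=9)
        b = simulate(ModelParams(), tube_a, 50, seed=9)
        for ta, tb in zip(a, b):
            assert ta.data.equals(tb.data)

    def test_distinct_seeds_differ(self, tube_a):
        a = simulate(ModelParams(), tube_a, 0, seed=1)
        b = simulate(ModelParams(), tube_a, 0, seed=2)
        assert not a[0].data.equals(b[0].data)

    def test_fish_conservation(self, tube_a):
        _, states = simulate(ModelParams(n_fish=20), tube_a, 300, seed=4,
                             return_states=True)
        for st in states:
            assert int(st.active.sum()) + st.n_passed == 20

    def test_active_fish_stay_inside(self, tube_a):
        """No active fish is ever classified outside the tube (wall
        containment over a full passage)."""
        polys = build_region_polygons(tube_a)
        _, states = simulate(ModelParams(v0=5.0), tube_a, 400, seed=3,
                             return_states=True)
        for st in states:
            act = st.positions[st.active]
            if len(act) == 0:
                continue
            labels = classify_points(act, tube_a, polys)
            assert all(lab != RegionLabel.OUTSIDE for lab in labels)

    def test_middle_over_occupancy_at_25_degrees(self):
        """Time-averaged N_middle/N_edge exceeds 1 at a 25-degree opening."""
        g = ts.make_tube_fixture(25.0)
        polys = build_region_polygons(g)
        _, states = simulate(ModelParams(), g, 300, seed=8, return_states=True)
        n_mid = n_edge = 0
        for st in states:
            act = st.positions[st.active]
            if len(act) == 0:
                continue
            labels = classify_points(act, g, polys)
            n_mid += sum(lab == RegionLabel.MIDDLE for lab in labels)
            n_edge += sum(lab in (RegionLabel.LEFT_EDGE, RegionLabel.RIGHT_EDGE)
                          for lab in labels)
        assert n_mid > n_edge

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(d1=30, d2=10)
        with pytest.raises(ValueError):
            ModelParams(v0=-1)
        with pytest.raises(ValueError):
            ModelParams(b=0)

    def test_initial_counts_follow_number_ratio_law(self, tube_a):
        params = ModelParams(n_fish=30)
        rng = np.random.default_rng(0)
        state = initialize_swarm(params, tube_a, rng)
        polys = build_region_polygons(tube_a)
        labels = classify_points(state.positions, tube_a, polys)
        n_mid = sum(lab == RegionLabel.MIDDLE for lab in labels)
        r = ts.predict_number_ratio(29.05)
        assert n_mid == round(30 * r / (1 + r))
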