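"""Environment contract: task geometry, device kinematics, forces, lifecycle."""

import numpy as np
import pytest

from mtnav.navigation_env import (EnvConfig, GUIDEWIRE, CATHETER, LifecycleError,
                                  NavigationEnv, TaskError)
from mtnav.vasculature import (generate_straight_tree, generate_tree, TreeParams,
                               geodesic_distance, sample_target, target_by_index)


@pytest.fixture
def env():
    return NavigationEnv()


def reset_default(env, tree, idx=5):
    target = target_by_index(tree, idx)
    return env.reset(tree, target, seed=0), target


class TestConfig:
    def test_defaults_encode_the_task_contract(self):
        cfg = EnvConfig()
        assert cfg.dt * cfg.timeout_steps == pytest.approx(27.0, rel=0.01)
        assert cfg.max_rotation_speed == 180.0
        assert cfg.max_translation_speed == 40.0
        assert cfg.success_threshold == 5.0
        assert cfg.timeout_steps == 200
        assert cfg.tracked_point_spacing == 2.0

    def test_inconsistent_timeout_rejected(self):
        with pytest.raises(ValueError):
            EnvConfig(dt=0.2)

    def test_yaml_overrides(self, tmp_path):
        p = tmp_path / "env.yaml"
        p.write_text("success_threshold: 4.0\nwall_stiffness: 2.0\n")
        cfg = EnvConfig.from_yaml(p)
        assert cfg.success_threshold == 4.0
        assert cfg.wall_stiffness == 2.0
        assert cfg.dt == 0.135


class TestReset:
    def test_reset_is_deterministic(self, env, right_tree):
        a, _ = reset_default(env, right_tree)
        b, _ = reset_default(env, right_tree)
        assert np.array_equal(a.as_vector(), b.as_vector())

    def test_first_observation_duplicates_previous_positions(self, env, right_tree):
        obs, _ = reset_default(env, right_tree)
        np.testing.assert_array_equal(obs.guidewire_points, obs.prev_guidewire_points)
        np.testing.assert_array_equal(obs.catheter_points, obs.prev_catheter_points)
        np.testing.assert_array_equal(obs.prev_action, np.zeros(4))

    def test_initial_pathlength_matches_geodesic_oracle(self, env, right_tree):
        obs, target = reset_default(env, right_tree)
        expected = geodesic_distance(right_tree, obs.guidewire_points[0], target)
        assert env.pathlength == pytest.approx(expected, abs=1e-9)

    def test_side_mismatch_raises(self, env, right_tree, left_tree):
        target = target_by_index(left_tree, 0)
        with pytest.raises(TaskError):
            env.reset(right_tree, target, seed=0)


class TestStep:
    def test_zero_action_is_a_fixed_point(self, env, right_tree):
        obs0, _ = reset_default(env, right_tree)
        res = env.step(np.zeros(4))
        np.testing.assert_array_equal(res.observation.guidewire_points,
                                      obs0.guidewire_points)
        assert res.info["delta_pathlength"] == 0.0
        assert np.linalg.norm(res.tip_force) == 0.0

    def test_saturating_translation_advances_printed_distance(self, env, straight_tree):
        obs, _ = reset_default(env, straight_tree, idx=9)
        tip0 = obs.guidewire_points[0].copy()
        res = env.step(np.array([0.0, 1.0, 0.0, 0.0]))
        tip1 = res.observation.guidewire_points[0]
        # 40 mm/s * 0.135 s = 5.4 mm
        assert np.linalg.norm(tip1 - tip0) == pytest.approx(5.4, abs=1e-9)

    def test_speeds_never_exceed_clamps(self, env, right_tree):
        reset_default(env, right_tree)
        res = env.step(np.array([3.0, -7.0, 2.0, 5.0]))  # out-of-range input
        sp = res.info["applied_speeds"]
        assert abs(sp["guidewire_rotation_dps"]) <= 180.0
        assert abs(sp["guidewire_translation_mmps"]) <= 40.0

    def test_nan_action_rejected(self, env, right_tree):
        reset_default(env, right_tree)
        with pytest.raises(ValueError):
            env.step(np.array([np.nan, 0, 0, 0]))

    def test_step_after_termination_raises(self, env, right_tree):
        reset_default(env, right_tree)
        for _ in range(200):
            env.step(np.zeros(4))
        assert env.done
        with pytest.raises(LifecycleError):
            env.step(np.zeros(4))


class TestTrackedPoints:
    def test_points_are_tip_then_2mm_then_4mm_behind(self, env, straight_tree):
        reset_default(env, straight_tree, idx=9)
        for _ in range(3):
            env.step(np.array([0.0, 1.0, 0.0, 0.0]))
        pts = env.track_points(GUIDEWIRE)
        tip_y = pts[0, 1]
        np.testing.assert_allclose(pts[:, 1], [tip_y, tip_y - 2.0, tip_y - 4.0],
                                   atol=1e-9)
        np.testing.assert_allclose(pts[:, 0], 0.0, atol=1e-9)

    @staticmethod
    def _arc_param(tree, route, point):
        """Arc-length parameter of a point lying on the route polyline."""
        best = (np.inf, 0.0)
        cum = 0.0
        for a, b in zip(route[:-1], route[1:]):
            pa, pb = tree.nodes[a], tree.nodes[b]
            seg = pb - pa
            L = np.linalg.norm(seg)
            t = np.clip((point - pa) @ seg / (L * L), 0.0, 1.0)
            d = np.linalg.norm(point - (pa + t * seg))
            if d < best[0]:
                best = (d, cum + t * L)
            cum += L
        return best[1]

    def test_arc_spacing_invariant_under_random_actions(self, env, right_tree):
        reset_default(env, right_tree)
        rng = np.random.default_rng(0)
        for _ in range(60):
            if env.done:
                break
            env.step(rng.uniform(-1, 1, 4))
            for device in (GUIDEWIRE, CATHETER):
                pts = env.track_points(device)
                dev = env.guidewire if device == GUIDEWIRE else env.catheter
                # spacing holds whenever the inserted length covers the span
                if dev.insertion_length >= 4.0:
                    params = [self._arc_param(right_tree, dev.route, p) for p in pts]
                    np.testing.assert_allclose(np.diff(params), -2.0, atol=1e-6)

    def test_tip_point_is_distal_endpoint(self, env, right_tree):
        reset_default(env, right_tree)
        env.step(np.array([0.0, 1.0, 0.0, 0.0]))
        np.testing.assert_allclose(env.track_points(GUIDEWIRE)[0],
                                   env.tip_position(), atol=1e-12)


class TestTipForce:
    def test_zero_when_tip_follows_centerline(self, env, straight_tree):
        reset_default(env, straight_tree, idx=9)
        res = env.step(np.array([0.0, 1.0, 0.0, 0.0]))
        assert np.linalg.norm(res.tip_force) == 0.0

    def test_force_is_linear_in_penetration(self):
        # identical tip pose, two lumen radii chosen so penetration doubles
        def ram_force(radius):
            tree = generate_straight_tree(length=60.0, radius=radius)
            env = NavigationEnv()
            env.reset(tree, target_by_index(tree, 9), seed=0)
            # rotate to full in-plane deflection (axial 90 -> 0 deg)
            for _ in range(4):
                res = env.step(np.array([-1.0, 0.2, 0.0, 0.0]))
            return np.linalg.norm(res.tip_force)

        k = EnvConfig().wall_stiffness
        r1 = 2.0
        f1 = ram_force(r1)
        assert f1 > 0
        clearance = f1 / k + r1     # free-tip distance to the centerline
        r2 = 2 * r1 - clearance     # penetration exactly doubles
        assert np.linalg.norm(ram_force(r2)) == pytest.approx(2.0 * f1, rel=1e-9)

    def test_direction_is_inward_normal(self, env, straight_tree):
        env.reset(straight_tree, target_by_index(straight_tree, 9), seed=0)
        for _ in range(4):
            res = env.step(np.array([-1.0, 0.2, 0.0, 0.0]))
        force = res.tip_force
        assert np.linalg.norm(force) > 0
        # deflected toward -x (rotation to 0 deg), so the wall pushes back +x
        assert abs(force[1]) < abs(force[0])


class TestEpisodeProperties:
    def test_containment_under_random_policies(self, right_tree, left_tree):
        for tree, seed in ((right_tree, 0), (left_tree, 1)):
            env = NavigationEnv()
            env.reset(tree, target_by_index(tree, 3), seed=seed)
            rng = np.random.default_rng(seed)
            while not env.done:
                env.step(rng.uniform(-1, 1, 4))
                for device in (GUIDEWIRE, CATHETER):
                    for p in env.track_points(device):
                        d, idx = tree.kdtree().query(p)
                        assert d <= tree.radius[idx] + 1e-6

    def test_monotone_insertion_toward_trunk_end_target(self, straight_tree):
        env = NavigationEnv()
        env.reset(straight_tree, target_by_index(straight_tree, 9), seed=0)
        prev = env.pathlength
        while not env.done:
            res = env.step(np.array([0.0, 0.7, 0.0, 0.0]))
            assert res.info["pathlength"] <= prev + 1e-9
            prev = res.info["pathlength"]
        assert res.reached

    def test_episode_cap_and_success_semantics(self, right_tree):
        env = NavigationEnv()
        target = target_by_index(right_tree, 5)
        env.reset(right_tree, target, seed=0)
        steps = 0
        rng = np.random.default_rng(5)
        while not env.done:
            res = env.step(rng.uniform(-0.3, 0.3, 4))
            steps += 1
        assert steps <= 200
        if res.reached:
            tip = res.observation.guidewire_points[0]
            assert np.linalg.norm(tip - np.asarray(target.position)) <= 5.0
        else:
            assert res.truncated and steps == 200

    def test_trajectories_bitwise_reproducible(self, right_tree):
        def rollout():
            env = NavigationEnv()
            env.reset(right_tree, target_by_index(right_tree, 2), seed=3)
            rng = np.random.default_rng(9)
            out = []
            for _ in range(50):
                if env.done:
                    break
                res = env.step(rng.uniform(-1, 1, 4))
                out.append(res.observation.as_vector())
            return np.array(out)

        a, b = rollout(), rollout()
        assert np.array_equal(a, b)

    def test_wrong_branch_recovery_by_rotation(self, right_tree):
        """Advancing with a neutral tip enters the distractor; retracting and
        rotating lets the wire re-select the target branch."""
        from mtnav.vasculature import DISTRACTOR_BRANCH, TARGET_BRANCH
        env = NavigationEnv()
        env.reset(right_tree, target_by_index(right_tree, 5), seed=0)
        for _ in range(40):
            if env.done:
                break
            env.step(np.array([0.0, 1.0, 0.0, 0.0]))
        wrong = right_tree.branch_label[right_tree.nearest_node(env.tip_position())]
        assert wrong == DISTRACTOR_BRANCH
        for _ in range(25):  # retract back into the trunk
            env.step(np.array([0.0, -1.0, 0.0, 0.0]))
        for _ in range(5):   # rotate the curved tip toward the target branch
            env.step(np.array([-1.0, 0.0, 0.0, 0.0]))
        for _ in range(60):
            if env.done:
                break
            env.step(np.array([0.0, 0.8, 0.0, 0.0]))
        label = right_tree.branch_label[right_tree.nearest_node(env.tip_position())]
        assert label == TARGET_BRANCH
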