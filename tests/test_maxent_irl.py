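"""Max-ent IRL: gradient identity, reward recovery, per-side training."""

from dataclasses import replace

import numpy as np
import pytest

from _mdp_oracles import (expert_demos, grid_next, random_trajectory_sampler,
                          soft_value_iteration, GRID_N, GOAL)
from mtnav.maxent_irl import (DataError, IrlRewardModel, IrlTrainConfig,
                              as_side_models, demo_feature_trajectories, fit_irl,
                              irl_objective, irl_reward, observation_features,
                              train_side_models)
from mtnav.demonstrations import run_oracle_episode, demo_observations
from mtnav.nn import Tensor
from mtnav.rewards import RewardContext, reward_irl
from mtnav.vasculature import target_by_index

CFG = IrlTrainConfig(iterations=300, seed=0)


def chain_trajectories(horizon=4):
    """All action sequences of a 3-state deterministic chain, as one-hot
    state-feature trajectories (exhaustive enumeration)."""
    trajs = []
    for mask in range(2 ** horizon):
        s, states = 0, [0]
        for bit in range(horizon):
            s = min(s + 1, 2) if (mask >> bit) & 1 else max(s - 1, 0)
            states.append(s)
        trajs.append(np.eye(3)[states])
    return trajs


class TestGradientIdentity:
    def test_gradient_is_feature_expectation_difference(self):
        """With the partition term enumerated exhaustively, the objective
        gradient w.r.t. the output layer equals the background-softmax
        expectation minus the demonstration expectation of the penultimate
        activations (and of the step counts, for the bias)."""
        cfg = replace(CFG, entropy_reg=0.7, length_penalty=0.01)
        model = IrlRewardModel(3, hidden=(8, 8, 8), seed=3)
        background = chain_trajectories()
        demos = [np.eye(3)[[0, 1, 2, 2, 2]]]

        loss = irl_objective(model, demos, background, cfg)
        model.net.zero_grad()
        loss.backward()
        W4 = model.net.layers[-1]

        def penultimate(feats):
            x = Tensor(feats)
            for layer in model.net.layers[:-1]:
                x = layer(x).relu()
            return x.data

        def score(feats):
            return (model.score_batch(feats).sum()
                    - cfg.length_penalty * len(feats))

        s = np.array([score(t) for t in background])
        p = np.exp(s / cfg.entropy_reg - np.max(s / cfg.entropy_reg))
        p /= p.sum()
        fe_back_W = sum(pi * penultimate(t).sum(axis=0) for pi, t in zip(p, background))
        fe_demo_W = np.mean([penultimate(t).sum(axis=0) for t in demos], axis=0)
        np.testing.assert_allclose(W4.W.grad.ravel(), fe_back_W - fe_demo_W,
                                   rtol=1e-8, atol=1e-10)
        fe_back_b = sum(pi * len(t) for pi, t in zip(p, background))
        fe_demo_b = np.mean([len(t) for t in demos])
        np.testing.assert_allclose(W4.b.grad, fe_back_b - fe_demo_b,
                                   rtol=1e-8, atol=1e-10)

    def test_sampled_gradient_converges_to_exact(self):
        """The sample-based partition estimate yields gradients that approach
        the exhaustive-enumeration gradient as the sample count grows."""
        cfg = replace(CFG, entropy_reg=0.5)
        model = IrlRewardModel(3, hidden=(8, 8, 8), seed=1)
        all_trajs = chain_trajectories()
        demos = [np.eye(3)[[0, 1, 2]]]

        def grad_vector(background):
            model.net.zero_grad()
            irl_objective(model, demos, background, cfg).backward()
            return np.concatenate([p.grad.ravel() for p in model.net.parameters()])

        exact = grad_vector(all_trajs)
        rng = np.random.default_rng(0)
        errs = []
        for m in (8, 64, 512):
            reps = []
            for _ in range(10):
                idx = rng.integers(len(all_trajs), size=m)
                reps.append(np.linalg.norm(grad_vector([all_trajs[i] for i in idx])
                                           - exact))
            errs.append(np.mean(reps))
        assert errs[0] > errs[1] > errs[2]


@pytest.fixture(scope="module")
def trained_model():
    rng = np.random.default_rng(0)
    return fit_irl(expert_demos(rng), replace(CFG, iterations=400),
                   random_trajectory_sampler())


@pytest.fixture(scope="module")
def side_demos(right_tree, left_tree):
    demos = []
    for tree in (right_tree, left_tree):
        for idx in (3, 7):
            demos.append(run_oracle_episode(tree, target_by_index(tree, idx),
                                            seed=idx))
    return demos


class TestGridworldRecovery:
    def test_soft_optimal_policy_matches_expert(self, trained_model):
        from _mdp_oracles import expert_actions
        r = trained_model.score_batch(np.eye(GRID_N * GRID_N))
        Q = soft_value_iteration(r)
        matches = [int(np.argmax(Q[s])) in expert_actions(s)
                   for s in range(GRID_N * GRID_N) if s != GOAL]
        assert np.mean(matches) >= 0.95

    def test_expert_states_outscore_unvisited_states(self, trained_model):
        r = trained_model.score_batch(np.eye(GRID_N * GRID_N))
        # expert shortest paths never move down-left from the start corner
        visited = [GOAL] + [s for s in range(GRID_N * GRID_N)
                            if s % GRID_N >= GRID_N - 2 or s // GRID_N >= GRID_N - 2]
        unvisited = [1, 2, 5, 6]  # near the start, off all shortest paths
        assert r[GOAL] > np.mean(r[unvisited])


class TestModelBasics:
    def test_single_one_step_demo_trains_with_finite_loss(self):
        losses = []
        fit_irl([np.eye(3)[[0]]], replace(CFG, iterations=5),
                lambda rng: [np.eye(3)[[s]] for s in range(3)],
                callback=lambda it, l: losses.append(l))
        assert len(losses) == 5 and np.all(np.isfinite(losses))

    def test_reward_is_pure_function(self):
        model = IrlRewardModel(5, seed=2)
        x = np.arange(5.0)
        assert model.score(x) == model.score(x)

    def test_zero_weight_model_outputs_zero(self):
        model = IrlRewardModel(4, seed=0)
        model.net.load_state_list([np.zeros_like(p.data).tolist()
                                   for p in model.net.parameters()])
        assert model.score(np.ones(4)) == 0.0

    def test_architecture_is_exactly_four_layers(self):
        model = IrlRewardModel(6, seed=0)
        assert len(model.net.layers) == 4
        with pytest.raises(ValueError):
            IrlRewardModel(6, hidden=(8, 8), seed=0)

    def test_feature_dimension_mismatch_raises(self):
        model = IrlRewardModel(6, seed=0)
        with pytest.raises(ValueError):
            model.score(np.ones(5))

    def test_checkpoint_round_trip(self, tmp_path):
        model = IrlRewardModel(6, side="left", seed=4)
        x = np.linspace(-1, 1, 6)
        model.save(tmp_path / "m.json")
        back = IrlRewardModel.load(tmp_path / "m.json")
        assert back.side == "left"
        assert back.score(x) == model.score(x)


class TestSideModels:
    def test_each_model_sees_only_its_side(self, side_demos):
        seen: dict[str, list] = {}

        def factory_for(trajs):
            key = f"call{len(seen)}"
            seen[key] = trajs
            from mtnav.maxent_irl import make_shuffle_sampler
            return make_shuffle_sampler(trajs, 8)

        cfg = replace(CFG, iterations=10)
        models = train_side_models(side_demos, cfg, sampler_factory=factory_for)
        assert models["left"].side == "left" and models["right"].side == "right"
        # the trajectories shown to each fit are exactly that side's demos
        by_side = {"left": [], "right": []}
        for d in side_demos:
            by_side[d.target.branch_side].append(d)
        for key, side in zip(seen, ("left", "right")):
            expected = demo_feature_trajectories(by_side[side])
            assert len(seen[key]) == len(expected)
            for a, b in zip(seen[key], expected):
                np.testing.assert_array_equal(a, b)

    def test_missing_side_raises(self, side_demos):
        right_only = [d for d in side_demos if d.target.branch_side == "right"]
        with pytest.raises(DataError):
            train_side_models(right_only, replace(CFG, iterations=2))

    def test_models_dispatch_through_reward_irl(self, side_demos):
        cfg = replace(CFG, iterations=20)
        models = as_side_models(train_side_models(side_demos, cfg))
        obs = demo_observations(side_demos[0])[0]
        for side in ("left", "right"):
            ctx = RewardContext(delta_pathlength=0.0, reached=False,
                                force_magnitude=0.0, observation=obs,
                                target_side=side)
            assert np.isfinite(reward_irl(ctx, models))

    def test_reward_recovery_prefers_demonstrated_branch(self, right_tree):
        """The trained model scores observations along the demonstrated
        (target-branch) route above a distractor-branch route on average."""
        from mtnav.navigation_env import NavigationEnv
        demos = [run_oracle_episode(right_tree, target_by_index(right_tree, i),
                                    seed=i) for i in (2, 5, 8)]
        trajs = demo_feature_trajectories(demos)
        from mtnav.maxent_irl import make_shuffle_sampler
        model = fit_irl(trajs, replace(CFG, iterations=200),
                        make_shuffle_sampler(trajs, 16))
        # wrong-branch rollout: advance with a neutral tip into the distractor
        env = NavigationEnv()
        obs = env.reset(right_tree, target_by_index(right_tree, 5), seed=0)
        wrong = []
        for _ in range(40):
            if env.done:
                break
            res = env.step(np.array([0.0, 1.0, 0.0, 0.0]))
            wrong.append(observation_features(res.observation))
        demo_scores = np.concatenate([model.score_batch(t) for t in trajs])
        wrong_scores = model.score_batch(np.array(wrong))
        assert demo_scores.mean() > wrong_scores.mean()
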