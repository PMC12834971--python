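"""REINFORCE machinery: entropy, baseline, gradients, learning dynamics."""

import numpy as np
import pytest

from bidirmol.codecs import Scheme
from bidirmol.generation import SeedConstraint
from bidirmol.fixtures import get_seed
from bidirmol.models import ModelConfig, build_model
from bidirmol.nn import AdamW, Tensor
from bidirmol.rl_finetune import (RLConfig, batch_baseline, finetune,
                                  policy_entropy, reinforce_step,
                                  reinforce_update, rollout_batch)

from conftest import TOY_WINDOW


class TestEntropyAndBaseline:
    def test_uniform_entropy_is_log_n(self):
        for n in (2, 5, 17):
            assert policy_entropy(np.full(n, 1 / n)) == \
                pytest.approx(np.log(n))

    def test_one_hot_entropy_zero(self):
        assert policy_entropy([0.0, 1.0, 0.0]) == 0.0

    def test_two_point_entropy(self):
        assert policy_entropy([0.5, 0.5]) == pytest.approx(0.69314718, abs=1e-7)

    def test_negative_probabilities_rejected(self):
        with pytest.raises(ValueError):
            policy_entropy([-0.1, 1.1])

    def test_baseline_is_mean_and_centres(self):
        assert batch_baseline([1, 1, 1]) == 1.0
        assert batch_baseline([0, 1]) == 0.5
        r = np.array([0.2, 0.9, 0.4])
        assert abs((r - batch_baseline(r)).sum()) < 1e-12
        with pytest.raises(ValueError):
            batch_baseline([])


def _toy_reward(core, valid):
    return (core.count("[N]") * 0.1 if valid else 0.0), {}


class TestRollouts:
    @pytest.mark.parametrize("variant", ["forward", "fbrnn", "bimodal"])
    def test_batch_size_and_bookkeeping(self, trained_models, selfies_vocab,
                                        variant):
        cfg = RLConfig(batch_size=6, m_total=TOY_WINDOW, seed=1)
        batch = rollout_batch(trained_models[variant], selfies_vocab, cfg,
                              _toy_reward, np.random.default_rng(1))
        assert len(batch.trajectories) == 6
        for t in batch.trajectories:
            assert len(t.actions) == len(t.log_probs) == len(t.entropies)
            assert (t.log_probs <= 1e-12).all()
            assert (t.entropies >= -1e-12).all()
        assert np.allclose(batch.logprob_sums.data,
                           [t.log_probs.sum() for t in batch.trajectories])

    def test_log_probs_match_recomputed_policy(self, trained_models,
                                               selfies_vocab):
        """Each recorded log-probability equals the log softmax probability
        of the sampled token under a fresh forward pass."""
        from bidirmol.models import temperature_softmax

        model = trained_models["forward"]
        cfg = RLConfig(batch_size=4, m_total=TOY_WINDOW, seed=2)
        batch = rollout_batch(model, selfies_vocab, cfg, _toy_reward,
                              np.random.default_rng(2))
        model.set_train(False)
        for i, traj in enumerate(batch.trajectories):
            # rebuild the window prefix: start token then the actions
            prefix = [selfies_vocab.start_id] + list(traj.actions)
            state = model.zero_state(1)
            for t, action in enumerate(traj.actions):
                logits, state = model.step(
                    np.array([prefix[t]]), state)
                p = temperature_softmax(logits.data[0], cfg.temperature)
                assert np.log(p[action]) == pytest.approx(
                    traj.log_probs[t], abs=1e-10)
                if t > 6:
                    break

    def test_seed_constraint_honoured(self, trained_models, selfies_vocab):
        seed = get_seed("amide").constraint(Scheme.SELFIES)
        cfg = RLConfig(batch_size=8, m_total=TOY_WINDOW, seed=3)
        batch = rollout_batch(trained_models["fbrnn"], selfies_vocab, cfg,
                              _toy_reward, np.random.default_rng(3),
                              seed=seed)
        for t in batch.trajectories:
            assert get_seed("amide").selfies in t.core


class TestUpdateRule:
    def test_equal_rewards_give_exactly_zero_gradient(self, trained_models,
                                                      selfies_vocab):
        model = trained_models["fbrnn"]
        cfg = RLConfig(batch_size=4, m_total=TOY_WINDOW, seed=4)
        batch = rollout_batch(model, selfies_vocab, cfg, _toy_reward,
                              np.random.default_rng(4))
        opt = AdamW(model.parameters(), lr=1e-3, weight_decay=0.0)
        before = [p.data.copy() for p in model.parameters()]
        reinforce_step(opt, batch.logprob_sums, np.ones(4),
                       batch.entropy_sums, entropy_coef=0.0)
        moved = max(np.abs(p.data - b).max()
                    for p, b in zip(model.parameters(), before))
        assert moved == 0.0
        # restore
        for p, b in zip(model.parameters(), before):
            p.data[:] = b

    def test_positive_advantage_raises_trajectory_log_prob(self):
        """An update in which one trajectory carries the positive advantage
        strictly increases that trajectory's total log-probability (small
        step, no entropy bonus, no weight decay)."""
        from bidirmol.nn import stack

        rng = np.random.default_rng(0)
        theta = Tensor(rng.normal(size=(3,)) * 0.1, requires_grad=True)
        opt = AdamW([theta], lr=1e-3, weight_decay=0.0)
        traj_actions = [np.array([2, 2]), np.array([0, 1])]

        def traj_logprob_sums() -> Tensor:
            logp = theta.log_softmax(-1)
            return stack([logp[a].sum() for a in traj_actions], axis=0)

        before = traj_logprob_sums().data.copy()
        rewards = np.array([1.0, 0.0])  # trajectory 0 has advantage +0.5
        per_traj = traj_logprob_sums()
        reinforce_step(opt, per_traj, rewards, per_traj * 0.0, 0.0)
        after = traj_logprob_sums().data
        assert after[0] > before[0]

    def test_bandit_recovers_optimal_arm(self):
        """Two-armed bandit (rewards 1 and 0): the rewarded arm's
        probability exceeds 0.95 within 200 updates."""
        rng = np.random.default_rng(0)
        K = 16
        theta = Tensor(np.zeros(2), requires_grad=True)
        opt = AdamW([theta], lr=0.1, weight_decay=0.0)
        for _ in range(200):
            logits = theta.reshape(1, 2) * np.ones((K, 1))
            logp = logits.log_softmax(-1)
            probs = np.exp(logp.data[0])
            acts = rng.choice(2, size=K, p=probs)
            lp = logp.gather(acts, axis=-1)
            ent = -(logp.exp() * logp).sum(axis=-1)
            rewards = (acts == 0).astype(float)
            reinforce_step(opt, lp, rewards, ent, 0.0)
        p = np.exp(theta.log_softmax(-1).data)
        assert p[0] > 0.95

    def test_entropy_bonus_raises_entropy_without_rewards(self):
        """With zero rewards and a large entropy coefficient the policy
        moves toward the uniform distribution."""
        rng = np.random.default_rng(1)
        theta = Tensor(np.array([2.0, -1.0, 0.0]), requires_grad=True)
        opt = AdamW([theta], lr=0.05, weight_decay=0.0)
        K = 8

        def entropy():
            p = np.exp(theta.log_softmax(-1).data)
            return -(p * np.log(p)).sum()

        h0 = entropy()
        for _ in range(100):
            logits = theta.reshape(1, 3) * np.ones((K, 1))
            logp = logits.log_softmax(-1)
            acts = rng.choice(3, size=K, p=np.exp(logp.data[0]))
            lp = logp.gather(acts, axis=-1)
            ent = -(logp.exp() * logp).sum(axis=-1)
            reinforce_step(opt, lp, np.zeros(K), ent, entropy_coef=5.0)
        assert entropy() > h0

    def test_baseline_unbiased_and_variance_reducing(self):
        """On a fixed stateless softmax policy the baseline-subtracted
        estimator has the same mean (within 3 standard errors) and strictly
        smaller variance than the raw estimator, over 10,000 batches."""
        rng = np.random.default_rng(7)
        theta = np.array([0.4, -0.2])
        p = np.exp(theta - theta.max())
        p /= p.sum()
        K = 8
        n_batches = 10_000
        acts = rng.choice(2, size=(n_batches, K), p=p)
        # arm 0 pays one unit more, on top of a large action-independent
        # offset — the component a baseline exists to remove
        rewards = 5.0 + (acts == 0).astype(float)
        # grad log pi(a) wrt theta_0 = 1{a=0} - p_0
        g = (acts == 0) - p[0]
        plain = (g * rewards).mean(axis=1)
        # leave-one-out batch baseline, as used by the update rule
        base = (rewards.sum(axis=1, keepdims=True) - rewards) / (K - 1)
        centred = (g * (rewards - base)).mean(axis=1)
        se = plain.std(ddof=1) / np.sqrt(n_batches)
        assert abs(plain.mean() - centred.mean()) < 3 * se
        assert centred.var(ddof=1) < plain.var(ddof=1)

    def test_zero_entropy_coef_is_plain_reinforce(self, trained_models,
                                                  selfies_vocab):
        model = trained_models["forward"]
        cfg = RLConfig(batch_size=4, m_total=TOY_WINDOW, seed=6)
        batch = rollout_batch(model, selfies_vocab, cfg, _toy_reward,
                              np.random.default_rng(6))
        rewards = np.arange(4, dtype=float)
        # gradient with beta=0 equals gradient of the pure policy term
        # (leave-one-out advantages = plain-mean advantages times K/(K-1))
        for p in model.parameters():
            p.grad = None
        k = 4
        adv = (rewards - rewards.mean()) * (k / (k - 1))
        (-(batch.logprob_sums * adv).sum() * (1 / k)).backward()
        ref = {id(p): (p.grad.copy() if p.grad is not None else None)
               for p in model.parameters()}
        opt = AdamW(model.parameters(), lr=0.0, weight_decay=0.0)
        before = [p.data.copy() for p in model.parameters()]
        reinforce_step(opt, batch.logprob_sums, rewards,
                       batch.entropy_sums, entropy_coef=0.0)
        for p in model.parameters():
            expected = ref[id(p)]
            if expected is None:
                assert p.grad is None or np.allclose(p.grad, 0)
            else:
                assert np.allclose(p.grad, expected)
        for p, b in zip(model.parameters(), before):
            p.data[:] = b


class TestFinetuneLoop:
    def test_trace_length_and_improvement(self, trained_models,
                                          selfies_vocab):
        import copy
        model = build_model(trained_models["fbrnn"].config)
        model.load_state_dict(trained_models["fbrnn"].state_dict())
        cfg = RLConfig(batch_size=16, m_total=TOY_WINDOW, seed=8,
                       episodes=40, learning_rate=3e-3, entropy_coef=1e-4)
        trace = finetune(model, selfies_vocab, cfg, _toy_reward)
        assert len(trace) == 40
        first = np.mean([s.mean_reward for s in trace[:5]])
        last = np.mean([s.mean_reward for s in trace[-5:]])
        assert last > first

    def test_reward_concentrates_without_collapse(self, trained_models,
                                                  selfies_vocab):
        """Directional check: the reward spread narrows while training on
        the toy objective (concentration), yet stays nonzero."""
        model = build_model(trained_models["fbrnn"].config)
        model.load_state_dict(trained_models["fbrnn"].state_dict())
        cfg = RLConfig(batch_size=24, m_total=TOY_WINDOW, seed=9,
                       episodes=60, learning_rate=3e-3, entropy_coef=1e-4)
        trace = finetune(model, selfies_vocab, cfg, _toy_reward)
        early = np.mean([s.reward_std / max(s.mean_reward, 1e-9)
                         for s in trace[:5]])
        late = np.mean([s.reward_std / max(s.mean_reward, 1e-9)
                        for s in trace[-5:]])
        assert late < early
        assert trace[-1].reward_std > 0
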