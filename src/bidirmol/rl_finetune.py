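"""Variance-reduced REINFORCE fine-tuning of a pre-trained generator.

Each episode draws a batch of K rollouts from the current policy (the
generator sampling at temperature T), scores the finished molecules with
a terminal reward, and ascends the surrogate objective

    (1/K) sum_i  log pi(a^i) * (R^i - Rbar)   +   beta * (1/K) sum_i sum_t H_t^i

where ``log pi(a^i)`` is the summed log-probability of trajectory i's
sampled tokens, ``Rbar`` is the batch-mean terminal reward (an unbiased,
state-independent baseline), and H is the policy entropy at each emission
step (the bonus that delays premature mode collapse).  The step is taken
with a decoupled-weight-decay Adam optimiser, which coincides with the
plain update rule for the stated objective.  Batch-normalisation layers
stay frozen in eval mode throughout: rollouts must not mutate the
normalisation statistics.

Seed constraints are honoured during rollouts; tokens inside the seed are
forced, not sampled, and contribute neither log-probability nor entropy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .codecs import Scheme, TokenVocabulary
from .generation import SeedConstraint, _initial_window, _finish
from .models import temperature_softmax
from .nn import AdamW, Tensor, concat, stack
from .rewards import RewardWeights, score_molecule

__all__ = [
    "RLConfig",
    "Trajectory",
    "RolloutBatch",
    "EpisodeStats",
    "policy_entropy",
    "batch_baseline",
    "rollout_batch",
    "reinforce_step",
    "reinforce_update",
    "finetune",
    "qed_sa_reward_fn",
]


@dataclass(frozen=True)
class RLConfig:
    batch_size: int = 32
    temperature: float = 1.0
    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    entropy_coef: float = 1e-4
    episodes: int = 120
    m_total: int = 40
    placement: str = "fixed"
    seed: int = 0
    patience: int | None = None
    patience_tol: float = 1e-3

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("baseline needs a batch of at least 2")
        if self.entropy_coef < 0 or self.learning_rate <= 0:
            raise ValueError("bad RL hyperparameters")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class Trajectory:
    """One rollout: sampled actions with their statistics."""

    actions: np.ndarray
    log_probs: np.ndarray
    entropies: np.ndarray
    reward: float = 0.0
    core: str = ""
    valid: bool = False
    props: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.actions) == len(self.log_probs)
                == len(self.entropies)):
            raise ValueError("per-step arrays must align")


@dataclass
class RolloutBatch:
    trajectories: list[Trajectory]
    logprob_sums: Tensor     # (K,) graph-bearing
    entropy_sums: Tensor     # (K,) graph-bearing
    rewards: np.ndarray      # (K,)


def policy_entropy(probs: np.ndarray) -> float:
    """Shannon entropy (natural log) with the 0 log 0 := 0 convention."""
    p = np.asarray(probs, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("negative probabilities")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def batch_baseline(rewards) -> float:
    rewards = np.asarray(rewards, dtype=np.float64)
    if rewards.size == 0:
        raise ValueError("empty batch")
    return float(rewards.mean())


def _entropy_tensor(logp: Tensor, axis=-1) -> Tensor:
    """-sum p log p with a full graph (gradient flows through p = exp(logp))."""
    return -(logp.exp() * logp).sum(axis=axis)


class _Recorder:
    """Accumulates masked per-step log-probs and entropies for a batch."""

    def __init__(self, k: int, vocab_size: int):
        self.k, self.v = k, vocab_size
        self.lp_terms: list[Tensor] = []
        self.ent_terms: list[Tensor] = []
        self.step_actions: list[np.ndarray] = []
        self.step_masks: list[np.ndarray] = []
        self.step_lp: list[np.ndarray] = []
        self.step_ent: list[np.ndarray] = []

    def record(self, logits: Tensor, sampled: np.ndarray,
               mask: np.ndarray, inv_temp: float) -> None:
        logp = (logits * inv_temp).log_softmax(axis=-1)
        lp = logp.gather(sampled, axis=-1)
        ent = _entropy_tensor(logp, axis=-1)
        m = mask.astype(np.float64)
        self.lp_terms.append(lp * m)
        self.ent_terms.append(ent * m)
        self.step_actions.append(sampled.copy())
        self.step_masks.append(mask.copy())
        self.step_lp.append(lp.data.copy())
        self.step_ent.append(ent.data.copy())

    def sums(self) -> tuple[Tensor, Tensor]:
        if not self.lp_terms:
            z = Tensor(np.zeros(self.k))
            return z, z
        return (stack(self.lp_terms, axis=0).sum(axis=0),
                stack(self.ent_terms, axis=0).sum(axis=0))

    def trajectories(self) -> list[Trajectory]:
        out = []
        for i in range(self.k):
            steps = [t for t in range(len(self.step_actions))
                     if self.step_masks[t][i]]
            out.append(Trajectory(
                actions=np.array([self.step_actions[t][i] for t in steps]),
                log_probs=np.array([self.step_lp[t][i] for t in steps]),
                entropies=np.array([self.step_ent[t][i] for t in steps]),
            ))
        return out


def rollout_batch(model, vocab: TokenVocabulary, rlcfg: RLConfig,
                  reward_fn, rng: np.random.Generator,
                  seed: SeedConstraint | None = None) -> RolloutBatch:
    """K graph-bearing rollouts at temperature T, scored terminally.

    ``reward_fn(core, valid) -> (reward, props_dict)`` is evaluated on the
    stripped core of each finished window.
    """
    model.set_train(False)
    k = rlcfg.batch_size
    m_total = rlcfg.m_total
    inv_t = 1.0 / rlcfg.temperature
    rec = _Recorder(k, len(vocab))
    variant = model.config.variant

    ids, spans = _initial_window(
        vocab, seed, m_total, k,
        rlcfg.placement if seed is not None else
        ("left" if variant == "forward" else
         "right" if variant == "backward" else rlcfg.placement),
        rng)

    def sample(logits: Tensor, frozen: np.ndarray, mask: np.ndarray
               ) -> np.ndarray:
        probs = temperature_softmax(logits, rlcfg.temperature)
        cum = probs.cumsum(axis=-1)
        cum[:, -1] = 1.0 + 1e-12
        tok = (rng.random((k, 1)) > cum).sum(axis=-1).astype(np.int64)
        rec.record(logits, tok, mask & ~frozen, inv_t)
        tok[frozen] = vocab.pad_id
        return tok

    if variant in ("forward", "backward"):
        work = ids if variant == "forward" else ids[:, ::-1].copy()
        wspans = spans if variant == "forward" else np.stack(
            [m_total - 1 - spans[:, 1], m_total - 1 - spans[:, 0]], axis=1)
        kpref = int(wspans[0, 1]) + 1
        state = model.zero_state(k)
        logits = None
        for pos in range(kpref):
            logits, state = model.step(work[:, pos], state)
        frozen = np.zeros(k, dtype=bool)
        for pos in range(kpref, m_total):
            tok = sample(logits, frozen, np.ones(k, dtype=bool))
            frozen |= tok == vocab.pad_id
            work[:, pos] = tok
            logits, state = model.step(tok, state)
        if variant == "backward":
            ids = work[:, ::-1]
            spans = np.stack([m_total - 1 - wspans[:, 1],
                              m_total - 1 - wspans[:, 0]], axis=1)
        else:
            ids = work
    elif variant == "fbrnn":
        rows = np.arange(k)
        state = model.zero_state(k)
        centres = (spans[:, 0] + spans[:, 1]) // 2
        frozen_l = np.zeros(k, dtype=bool)
        frozen_r = np.zeros(k, dtype=bool)
        t_max = int(max(centres.max(), (m_total - 1 - centres).max()))
        for t in range(t_max + 1):
            lpos, rpos = centres - t, centres + t
            left_read = np.where(
                lpos >= 0, ids[rows, np.clip(lpos, 0, m_total - 1)],
                vocab.pad_id)
            right_read = np.where(
                rpos <= m_total - 1,
                ids[rows, np.clip(rpos, 0, m_total - 1)], vocab.pad_id)
            y_minus, y_plus, state = model.step(left_read, right_read, state)
            tgt = centres + t + 1
            write = (tgt <= m_total - 1) & (tgt > spans[:, 1])
            if write.any():
                tok = sample(y_plus, frozen_r, write)
                frozen_r |= write & (tok == vocab.pad_id)
                ids[rows[write], tgt[write]] = tok[write]
            tgt = centres - t - 1
            write = (tgt >= 0) & (tgt < spans[:, 0])
            if write.any():
                tok = sample(y_minus, frozen_l, write)
                frozen_l |= write & (tok == vocab.pad_id)
                ids[rows[write], tgt[write]] = tok[write]
    elif variant == "bimodal":
        left = spans[:, 0].copy()
        right = spans[:, 1].copy()
        frozen_l = np.zeros(k, dtype=bool)
        frozen_r = np.zeros(k, dtype=bool)
        step = 1
        while True:
            can_r = (right + 1 <= m_total - 1) & ~frozen_r
            can_l = (left - 1 >= 0) & ~frozen_l
            if not (can_r.any() or can_l.any()):
                break
            forward = step % 2 == 1
            step += 1
            sel_all = can_r if forward else can_l
            if not sel_all.any():
                continue
            pos_all = (right + 1) if forward else (left - 1)
            for pos in np.unique(pos_all[sel_all]):
                sel = sel_all & (pos_all == pos)
                logits_sel = model.next_token_logits(ids[sel], int(pos))
                # scatter back to full batch width for uniform recording
                full = np.zeros((k, len(vocab)))
                full[sel] = logits_sel.data

                def back(g, sel=sel):
                    return (g[sel],)

                logits = Tensor._make(full, (logits_sel,), back)
                tok = sample(logits, ~sel, sel)
                ids[sel, int(pos)] = tok[sel]
                if forward:
                    frozen_r[sel] |= tok[sel] == vocab.pad_id
                    right[sel] += 1
                else:
                    frozen_l[sel] |= tok[sel] == vocab.pad_id
                    left[sel] -= 1
    else:  # pragma: no cover
        raise ValueError(f"unknown variant {variant!r}")

    lp_sums, ent_sums = rec.sums()
    trajs = rec.trajectories()
    results = _finish(ids, spans, vocab, seed, vocab.scheme)
    rewards = np.zeros(k)
    for i, (traj, res) in enumerate(zip(trajs, results)):
        reward, props = reward_fn(res.core, res.valid)
        traj.reward = reward
        traj.core = res.core
        traj.valid = res.valid
        traj.props = props
        rewards[i] = reward
    return RolloutBatch(trajectories=trajs, logprob_sums=lp_sums,
                        entropy_sums=ent_sums, rewards=rewards)


def reinforce_step(opt, logprob_sums: Tensor, rewards: np.ndarray,
                   entropy_sums: Tensor, entropy_coef: float) -> float:
    """One surrogate-gradient ascent step; returns the batch-mean reward.

    The baseline subtracted from trajectory i is the mean reward of the
    *other* trajectories in the batch (leave-one-out), the form in which
    batch-mean subtraction is exactly unbiased: a baseline must not depend
    on the trajectory's own actions, and R^i does.  Algebraically this is
    the plain-mean advantage scaled by K/(K-1), so it changes nothing but
    that constant.
    """
    rewards = np.asarray(rewards, dtype=np.float64)
    baseline = batch_baseline(rewards)
    k = rewards.size
    advantages = (rewards - baseline) * (k / (k - 1))
    k = rewards.size
    surrogate = -(logprob_sums * advantages).sum() * (1.0 / k)
    if entropy_coef:
        surrogate = surrogate - entropy_coef * entropy_sums.mean()
    opt.zero_grad()
    surrogate.backward()
    opt.step()
    return baseline


@dataclass
class EpisodeStats:
    episode: int
    mean_reward: float
    reward_std: float
    qed_mean: float = float("nan")
    qed_std: float = float("nan")
    sa_mean: float = float("nan")
    sa_std: float = float("nan")

    def row(self) -> dict:
        return {
            "episode": self.episode,
            "mean_reward": self.mean_reward,
            "reward_std": self.reward_std,
            "qed_mean": self.qed_mean, "qed_std": self.qed_std,
            "sa_mean": self.sa_mean, "sa_std": self.sa_std,
        }


def _episode_stats(episode: int, batch: RolloutBatch) -> EpisodeStats:
    rewards = batch.rewards
    qed = [t.props.get("qed_raw") for t in batch.trajectories
           if getattr(t, "props", None) and "qed_raw" in t.props]
    sa = [t.props.get("sa_raw") for t in batch.trajectories
          if getattr(t, "props", None) and "sa_raw" in t.props]
    return EpisodeStats(
        episode=episode,
        mean_reward=float(rewards.mean()),
        reward_std=float(rewards.std(ddof=1)),
        qed_mean=float(np.mean(qed)) if qed else float("nan"),
        qed_std=float(np.std(qed, ddof=1)) if len(qed) > 1 else float("nan"),
        sa_mean=float(np.mean(sa)) if sa else float("nan"),
        sa_std=float(np.std(sa, ddof=1)) if len(sa) > 1 else float("nan"),
    )


def reinforce_update(model, opt, batch: RolloutBatch, rlcfg: RLConfig,
                     episode: int = 0) -> EpisodeStats:
    reinforce_step(opt, batch.logprob_sums, batch.rewards,
                   batch.entropy_sums, rlcfg.entropy_coef)
    for p in model.parameters():
        if p.grad is not None and not np.isfinite(p.grad).all():
            raise RuntimeError("non-finite policy gradient")
    return _episode_stats(episode, batch)


def qed_sa_reward_fn(scheme: Scheme, weights: RewardWeights):
    """Terminal QED/SA reward on the stripped core (invalid -> 0)."""
    from .rewards import qed_term, sa_score
    from rdkit import Chem
    from .codecs import canonical_smiles

    def fn(core: str, valid: bool):
        if not valid:
            return 0.0, {}
        value, p = score_molecule(core, scheme, weights)
        props = dict(p.values)
        smiles = canonical_smiles(core, scheme)
        if smiles is not None:
            mol = Chem.MolFromSmiles(smiles)
            props["qed_raw"] = qed_term(mol)
            props["sa_raw"] = sa_score(mol)
        return value.terminal, props

    return fn


def finetune(model, vocab: TokenVocabulary, rlcfg: RLConfig, reward_fn,
             seed: SeedConstraint | None = None, log_path=None,
             checkpoint_every: int | None = None, run_dir=None,
             callback=None) -> list[EpisodeStats]:
    """The episode loop: rollout, update, record; optional early stop when
    the moving average of the batch reward stalls."""
    from .models import save_checkpoint

    rng = np.random.default_rng(rlcfg.seed)
    opt = AdamW(model.parameters(), lr=rlcfg.learning_rate,
                weight_decay=rlcfg.weight_decay)
    trace: list[EpisodeStats] = []
    best_ma = -np.inf
    stale = 0
    for episode in range(rlcfg.episodes):
        batch = rollout_batch(model, vocab, rlcfg, reward_fn, rng, seed=seed)
        stats = reinforce_update(model, opt, batch, rlcfg, episode=episode)
        trace.append(stats)
        if callback is not None:
            callback(episode, model, batch, stats)
        if checkpoint_every and run_dir is not None \
                and (episode + 1) % checkpoint_every == 0:
            save_checkpoint(model, f"{run_dir}/rl_ep{episode + 1}.npz",
                            vocab_json=vocab.to_json(),
                            meta={"episode": episode + 1})
        if rlcfg.patience is not None:
            window = min(10, len(trace))
            ma = float(np.mean([s.mean_reward for s in trace[-window:]]))
            if ma > best_ma + rlcfg.patience_tol:
                best_ma = ma
                stale = 0
            else:
                stale += 1
                if stale >= rlcfg.patience:
                    break
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(trace[0].row()))
            writer.writeheader()
            writer.writerows(s.row() for s in trace)
    return trace
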