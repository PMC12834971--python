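"""Teacher-forced maximum-likelihood pre-training with k-fold CV.

Each variant is trained the same way it generates: the forward model
predicts the next token left-to-right (start token at the left end of the
core), the backward model the previous token on the reversed window, the
two-sided grower both frontier tokens per step reading outward from its
start position, and the bidirectional reader every window position from
its two-sided context.  The loss is the mean cross-entropy over the
variant's emission schedule (temperature-1 softmax), averaged over the
batch.  Pad emissions are supervised like any other token — that is how
the models learn to stop.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .codecs import Scheme, TokenVocabulary, encode_window
from .models import (BimodalModel, FBRNNModel, ModelConfig,
                     UnidirectionalModel, build_model, save_checkpoint)
from .nn import Adam, AdamW, Tensor, no_grad

__all__ = [
    "TrainingConfig",
    "FoldSplit",
    "make_cv_folds",
    "encode_batch",
    "training_placement",
    "teacher_forced_loss",
    "evaluate_loss",
    "train",
]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 10
    folds: int = 5
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    weight_decay: float = 0.0
    seed: int = 0
    placement: str = "fixed"
    m_total: int = 40
    hidden_size: int = 1024

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.optimizer_name not in ("adam", "adamw"):
            raise ValueError("optimizer must be adam or adamw")


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_indices: np.ndarray
    held_out_indices: np.ndarray


def make_cv_folds(n_items: int, k: int, seed: int) -> list[FoldSplit]:
    """Near-equal disjoint partition, deterministic under the seed."""
    if n_items < k:
        raise ValueError("fewer items than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    parts = np.array_split(perm, k)
    return [
        FoldSplit(
            fold_id=i,
            train_indices=np.sort(np.concatenate(
                [parts[j] for j in range(k) if j != i])),
            held_out_indices=np.sort(parts[i]),
        )
        for i in range(k)
    ]


def training_placement(variant: str, placement: str) -> str:
    """Forward/backward cores carry the start token at an end."""
    if variant == "forward":
        return "left"
    if variant == "backward":
        return "right"
    return placement


def encode_batch(token_lists: list[list[str]], vocab: TokenVocabulary,
                 m_total: int, placement: str, rng) -> tuple[np.ndarray,
                                                             np.ndarray]:
    """(B, M) window ids and (B,) start offsets."""
    ids = np.empty((len(token_lists), m_total), dtype=np.int64)
    starts = np.empty(len(token_lists), dtype=np.int64)
    for i, toks in enumerate(token_lists):
        w = encode_window(toks, vocab, m_total, placement, rng)
        ids[i] = w.token_ids
        starts[i] = w.start_offset
    return ids, starts


def _cross_entropy(logits: Tensor, targets: np.ndarray,
                   weights: np.ndarray | None = None) -> Tensor:
    logp = logits.log_softmax(axis=-1)
    nll = -logp.gather(targets, axis=-1)
    if weights is None:
        return nll.mean()
    w = np.asarray(weights, dtype=np.float64)
    return (nll * w).sum() / w.sum()


def teacher_forced_loss(model, ids: np.ndarray, starts: np.ndarray,
                        vocab: TokenVocabulary) -> Tensor:
    """Mean cross-entropy over the variant's emission schedule."""
    ids = np.asarray(ids, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    b, m = ids.shape
    variant = model.config.variant
    if variant in ("forward", "backward"):
        seq = ids if variant == "forward" else ids[:, ::-1]
        logits = model.sequence_logits(seq[:, :-1])
        return _cross_entropy(logits, seq[:, 1:])
    if variant == "fbrnn":
        t_max = int(max(starts.max(), (m - 1 - starts).max()))
        rows = np.arange(b)[:, None]
        steps = np.arange(t_max + 1)[None, :]
        pad = vocab.pad_id

        def at(pos):
            inside = (pos >= 0) & (pos <= m - 1)
            return np.where(inside, ids[rows, np.clip(pos, 0, m - 1)], pad)

        left_read = at(starts[:, None] - steps)
        right_read = at(starts[:, None] + steps)
        left_tgt = at(starts[:, None] - steps - 1)
        right_tgt = at(starts[:, None] + steps + 1)
        y_minus, y_plus = model.pair_logits(left_read, right_read)
        return 0.5 * (_cross_entropy(y_plus, right_tgt)
                      + _cross_entropy(y_minus, left_tgt))
    # bimodal: every position except the start token's
    logits = model.position_logits(ids)
    weights = np.ones((b, m))
    weights[np.arange(b), starts] = 0.0
    return _cross_entropy(logits, ids, weights)


def evaluate_loss(model, ids, starts, vocab, batch_size: int = 256) -> float:
    """Teacher-forced loss under frozen normalisation statistics."""
    model.set_train(False)
    total, count = 0.0, 0
    with no_grad():
        for i in range(0, len(ids), batch_size):
            chunk = slice(i, i + batch_size)
            loss = teacher_forced_loss(model, ids[chunk], starts[chunk],
                                       vocab)
            total += loss.item() * (min(i + batch_size, len(ids)) - i)
            count += min(i + batch_size, len(ids)) - i
    return total / count


def train(corpus_tokens: list[list[str]], vocab: TokenVocabulary,
          variant: str, config: TrainingConfig,
          run_dir=None, log_path=None):
    """k-fold CV training; returns {fold: model}, the loss trace, and folds.

    One checkpoint per (fold, epoch) is written when ``run_dir`` is given;
    the loss trace rows are {fold, epoch, step, loss}.
    """
    placement = training_placement(variant, config.placement)
    folds = make_cv_folds(len(corpus_tokens), config.folds, config.seed)
    trace: list[dict] = []
    models = {}
    for split in folds:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, split.fold_id]))
        model = build_model(ModelConfig(
            variant=variant, vocab_size=len(vocab),
            hidden_size=config.hidden_size,
            init_seed=int(rng.integers(2**31))))
        opt_cls = Adam if config.optimizer_name == "adam" else AdamW
        opt = opt_cls(model.parameters(), lr=config.learning_rate,
                      weight_decay=config.weight_decay)
        train_toks = [corpus_tokens[i] for i in split.train_indices]
        static = None
        if placement != "random":
            static = encode_batch(train_toks, vocab, config.m_total,
                                  placement, rng)
        for epoch in range(config.epochs):
            if static is None:
                ids, starts = encode_batch(train_toks, vocab, config.m_total,
                                           placement, rng)
            else:
                ids, starts = static
            order = rng.permutation(len(train_toks))
            model.set_train(True)
            for step, lo in enumerate(range(0, len(order),
                                            config.batch_size)):
                sel = order[lo:lo + config.batch_size]
                opt.zero_grad()
                loss = teacher_forced_loss(model, ids[sel], starts[sel],
                                           vocab)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"non-finite loss at fold {split.fold_id} "
                        f"epoch {epoch} step {step}")
                loss.backward()
                opt.step()
                trace.append({"fold": split.fold_id, "epoch": epoch,
                              "step": step, "loss": loss.item()})
            if run_dir is not None:
                save_checkpoint(
                    model,
                    f"{run_dir}/ckpt_fold{split.fold_id}_epoch{epoch}.npz",
                    vocab_json=vocab.to_json(),
                    meta={"fold": split.fold_id, "epoch": epoch,
                          "variant": variant, "m_total": config.m_total,
                          "placement": placement})
        model.set_train(False)
        models[split.fold_id] = model
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh,
                                    fieldnames=["fold", "epoch", "step",
                                                "loss"])
            writer.writeheader()
            writer.writerows(trace)
    return models, trace, folds
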