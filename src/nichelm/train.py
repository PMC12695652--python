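"""Masked-language-model pretraining loop and the AdamW optimizer.

Single-process, single-precision and fully deterministic for a fixed
schedule seed: data order, masking draws and parameter updates are all
driven by one seeded generator.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .masking import apply_mlm_masking, mlm_loss_and_grad
from .model import EncoderModel
from .schedule import TrainSchedule, lr_at_step
from .tokenizer import TokenizedBatch

__all__ = ["AdamW", "clip_by_global_norm", "pretrain"]


class AdamW:
    """AdamW with decoupled weight decay.

    Decay applies to weight matrices only: biases, layer-norm parameters and
    the embedding tables are not decayed (decaying the lookup tables drains
    token identity from the residual stream, since most rows receive sparse
    gradient signal).
    """

    def __init__(self, params: dict, betas=(0.9, 0.999), weight_decay: float = 0.1):
        self.params = params
        self.b1, self.b2 = betas
        self.weight_decay = weight_decay
        self.eps = 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.decay_keys = {
            k for k, v in params.items() if v.ndim >= 2 and not k.endswith("_emb")
        }

    def step(self, grads: dict, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            if self.weight_decay and k in self.decay_keys:
                update = update + self.weight_decay * p
            p -= lr * update


def clip_by_global_norm(grads: dict, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``;
    returns the pre-clip norm."""
    total = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


def pretrain(
    model: EncoderModel,
    batch: TokenizedBatch,
    schedule: TrainSchedule,
    checkpoint_dir: str | Path | None = None,
    p_select: float = 0.15,
) -> pd.DataFrame:
    """Pretrain ``model`` in place on a tokenized corpus.

    Cells are shuffled each epoch; ``grad_accumulation`` micro-batches of
    ``batch_size`` cells are accumulated per optimizer step; the learning
    rate follows the warmup+cosine schedule and gradients are clipped by
    global norm. Returns the loss trajectory as a DataFrame
    (step, lr, loss) with one row per optimizer step.
    """
    if batch.n_cells == 0:
        raise ValueError("empty corpus")
    c = model.config
    rng = np.random.default_rng(schedule.seed)
    opt = AdamW(model.params, betas=schedule.betas, weight_decay=schedule.weight_decay)
    cells_per_step = schedule.batch_size * schedule.grad_accumulation
    steps_per_epoch = max(1, batch.n_cells // cells_per_step)
    clip_switch = (
        schedule.clip_switch_step if schedule.clip_switch_step is not None else steps_per_epoch
    )

    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    records = []
    order = rng.permutation(batch.n_cells)
    cursor = 0
    for step in range(schedule.total_steps):
        grads = model.zero_grads()
        losses = []
        for _ in range(schedule.grad_accumulation):
            if cursor + schedule.batch_size > batch.n_cells:
                order = rng.permutation(batch.n_cells)
                cursor = 0
            idx = order[cursor : cursor + schedule.batch_size]
            cursor += schedule.batch_size
            tokens = batch.tokens[idx]
            corrupted, plan = apply_mlm_masking(
                tokens, c.pad_id, 1, c.vocab_size, p_select=p_select, seed=rng
            )
            _, logits, _, cache = model.forward(corrupted, need_cache=True)
            loss, d_logits = mlm_loss_and_grad(logits, plan)
            g = model.backward(cache, d_logits=d_logits)
            for k in grads:
                grads[k] += g[k]
            losses.append(loss)
        for k in grads:
            grads[k] /= schedule.grad_accumulation
        clip = schedule.clip_later if step >= clip_switch else schedule.clip_first_epoch
        clip_by_global_norm(grads, clip)
        lr = lr_at_step(schedule, step)
        opt.step(grads, lr)
        records.append((step, lr, float(np.mean(losses))))
        if checkpoint_dir is not None and (step + 1) % schedule.checkpoint_every == 0:
            model.save(checkpoint_dir / f"checkpoint_{step + 1:08d}.npz")
    return pd.DataFrame(records, columns=["step", "lr", "loss"])
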