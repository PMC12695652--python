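"""Pretraining hyperparameter schedule: linear warmup then cosine decay.

Full-scale defaults: AdamW betas (0.9, 0.999), weight decay 0.1, batch size
9 with gradients accumulated over 10 micro-batches, learning rate warming up
linearly from 1e-5 to 1e-3 over 100,000 steps then cosine-decaying back to
1e-5, gradient clipping 1.0 during the first epoch and 0.5 afterwards,
checkpoints every 10,000 optimizer steps. ``tiny()`` returns a desk-scale
preset with the step counts shrunk proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["TrainSchedule", "lr_at_step"]


@dataclass(frozen=True)
class TrainSchedule:
    total_steps: int = 1_000_000
    warmup_steps: int = 100_000
    lr_min: float = 1e-5
    lr_max: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.1
    batch_size: int = 9
    grad_accumulation: int = 10
    clip_first_epoch: float = 1.0
    clip_later: float = 0.5
    clip_switch_step: int | None = None  # optimizer step at which clip drops; None = never
    checkpoint_every: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_min <= self.lr_max:
            raise ValueError("require 0 < lr_min <= lr_max")
        if self.warmup_steps > self.total_steps:
            raise ValueError("warmup_steps must not exceed total_steps")
        if min(self.batch_size, self.grad_accumulation, self.total_steps) < 1:
            raise ValueError("batch_size, grad_accumulation, total_steps must be >= 1")

    def clip_at(self, step: int) -> float:
        if self.clip_switch_step is not None and step >= self.clip_switch_step:
            return self.clip_later
        return self.clip_first_epoch

    @classmethod
    def tiny(cls, total_steps: int = 500, seed: int = 0, **kw) -> "TrainSchedule":
        """Desk-scale preset: warmup shrunk to 10% of the run, no gradient
        accumulation, checkpointing off by default."""
        defaults = dict(
            total_steps=total_steps,
            warmup_steps=max(1, total_steps // 10),
            grad_accumulation=1,
            checkpoint_every=total_steps + 1,
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)

    def with_(self, **kw) -> "TrainSchedule":
        return replace(self, **kw)


def lr_at_step(schedule: TrainSchedule, step: int) -> float:
    """Learning rate at an optimizer step: linear from ``lr_min`` (step 0)
    to ``lr_max`` (warmup end), then cosine back down to ``lr_min``."""
    if not 0 <= step <= schedule.total_steps:
        raise ValueError(f"step {step} outside [0, {schedule.total_steps}]")
    w, t = schedule.warmup_steps, schedule.total_steps
    lo, hi = schedule.lr_min, schedule.lr_max
    if step <= w:
        if w == 0:
            return hi
        return lo + (hi - lo) * step / w
    frac = (step - w) / max(t - w, 1)
    return lo + 0.5 * (hi - lo) * (1.0 + math.cos(math.pi * frac))
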