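"""BERT-style masked-language-model corruption of token batches.

15% of non-PAD positions (context and gene tokens alike) are selected
independently; a selected token is replaced by <MASK> 80% of the time, by a
random non-special token 10% of the time, and kept unchanged 10% of the
time. The plan records the selection, the action taken and the original
tokens, and is the support of the MLM loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskingPlan", "apply_mlm_masking", "mlm_loss", "mlm_loss_and_grad"]

# action codes in MaskingPlan.actions
NOT_SELECTED, ACTION_MASK, ACTION_RANDOM, ACTION_KEEP = 0, 1, 2, 3


@dataclass(frozen=True)
class MaskingPlan:
    """Which positions were corrupted, how, and what the originals were."""

    selected: np.ndarray  # bool (B, N)
    actions: np.ndarray  # int8 (B, N), codes above
    originals: np.ndarray  # int32 (B, N), original uncorrupted tokens

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def apply_mlm_masking(
    tokens: np.ndarray,
    pad_id: int,
    mask_id: int,
    vocab_size: int,
    p_select: float = 0.15,
    p_mask: float = 0.8,
    p_random: float = 0.1,
    p_keep: float = 0.1,
    seed: int | np.random.Generator = 0,
):
    """Corrupt a (B, N) token batch; returns ``(corrupted, plan)``.

    Random replacements are drawn uniformly from the gene and context tokens,
    i.e. ids in ``[2, vocab_size)`` excluding PAD and MASK.
    """
    if not np.isclose(p_mask + p_random + p_keep, 1.0):
        raise ValueError("p_mask + p_random + p_keep must equal 1")
    if not 0.0 <= p_select <= 1.0:
        raise ValueError("p_select must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tokens = np.asarray(tokens)
    non_pad = tokens != pad_id

    selected = non_pad & (rng.random(tokens.shape) < p_select)
    u = rng.random(tokens.shape)
    actions = np.zeros(tokens.shape, dtype=np.int8)
    actions[selected & (u < p_mask)] = ACTION_MASK
    actions[selected & (u >= p_mask) & (u < p_mask + p_random)] = ACTION_RANDOM
    actions[selected & (u >= p_mask + p_random)] = ACTION_KEEP

    corrupted = tokens.copy()
    corrupted[actions == ACTION_MASK] = mask_id
    n_rand = int((actions == ACTION_RANDOM).sum())
    if n_rand:
        lo = 2  # first id after PAD and MASK
        corrupted[actions == ACTION_RANDOM] = rng.integers(lo, vocab_size, size=n_rand)
    return corrupted, MaskingPlan(selected, actions, tokens.copy())


def mlm_loss(logits: np.ndarray, plan: MaskingPlan) -> float:
    """Mean over selected positions of -log softmax-probability of the
    original token; positions outside the plan contribute nothing."""
    loss, _ = mlm_loss_and_grad(logits, plan, need_grad=False)
    return loss


def mlm_loss_and_grad(logits: np.ndarray, plan: MaskingPlan, need_grad: bool = True):
    """Loss plus its gradient w.r.t. the logits (zero outside the plan)."""
    if plan.n_selected == 0:
        raise ValueError("masking plan selects no positions")
    b, n = np.nonzero(plan.selected)
    sel_logits = logits[b, n]  # (M, V)
    targets = plan.originals[b, n]
    m = sel_logits.max(axis=1, keepdims=True)
    logsumexp = m[:, 0] + np.log(np.exp(sel_logits - m).sum(axis=1))
    logp = sel_logits[np.arange(len(b)), targets] - logsumexp
    loss = float(-logp.mean())
    if not need_grad:
        return loss, None
    probs = np.exp(sel_logits - logsumexp[:, None])
    probs[np.arange(len(b)), targets] -= 1.0
    d_logits = np.zeros_like(logits)
    d_logits[b, n] = probs / len(b)
    return loss, d_logits
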