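"""Embedding stability under rank shuffling and gene dropout.

Tokenized cells are perturbed — either by permuting the tokens within a
random subset of gene positions (rank shuffling) or by removing a random
subset of gene tokens and re-padding (gene dropout) — and the perturbed
batches are embedded and scored with the silhouette coefficient over
cell-type labels. Context tokens and sequence length are never altered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .embedding import extract_embeddings
from .model import EncoderModel
from .tokenizer import N_CONTEXT, TokenizedBatch, TokenizedCell

__all__ = [
    "StabilityCurve",
    "shuffle_ranks",
    "drop_genes",
    "silhouette_stability",
    "stability_curve",
]


@dataclass(frozen=True)
class StabilityCurve:
    kind: str  # "shuffle" or "dropout"
    fractions: tuple[float, ...]
    scores: tuple[float, ...]  # silhouette per fraction, same order

    def to_frame(self, seed: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"kind": self.kind, "fraction": self.fractions, "silhouette": self.scores})
        if seed is not None:
            df["seed"] = seed
        return df


def _as_arrays(cell: TokenizedCell | tuple) -> tuple[np.ndarray, int]:
    if isinstance(cell, TokenizedCell):
        return cell.tokens, cell.n_real
    tokens, n_real = cell
    return np.asarray(tokens), int(n_real)


def shuffle_ranks(cell, fraction: float, seed: int | np.random.Generator = 0):
    """Permute tokens within ceil(fraction * n_gene_tokens) randomly chosen
    gene positions; context and PAD positions are untouched."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    tokens, n_real = _as_arrays(cell)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = tokens.copy()
    n_genes = n_real - N_CONTEXT
    k = math.ceil(fraction * n_genes)
    if k >= 2:
        pos = rng.choice(np.arange(N_CONTEXT, n_real), size=k, replace=False)
        out[pos] = out[rng.permutation(pos)]
    if isinstance(cell, TokenizedCell):
        return TokenizedCell(out, n_real, cell.metadata)
    return out, n_real


def drop_genes(cell, fraction: float, seed: int | np.random.Generator = 0, pad_id: int = 0):
    """Remove ceil(fraction * n_gene_tokens) randomly chosen gene tokens,
    keeping the survivors' relative order, and re-pad to the full length."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    tokens, n_real = _as_arrays(cell)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = tokens.copy()
    n_genes = n_real - N_CONTEXT
    k = math.ceil(fraction * n_genes)
    new_n_real = n_real
    if k >= 1 and n_genes > 0:
        drop = rng.choice(np.arange(N_CONTEXT, n_real), size=k, replace=False)
        keep = np.setdiff1d(np.arange(N_CONTEXT, n_real), drop)  # sorted: order kept
        survivors = tokens[keep]
        out[N_CONTEXT : N_CONTEXT + survivors.size] = survivors
        out[N_CONTEXT + survivors.size :] = pad_id
        new_n_real = N_CONTEXT + survivors.size
    if isinstance(cell, TokenizedCell):
        return TokenizedCell(out, new_n_real, cell.metadata)
    return out, new_n_real


def _perturb_batch(batch: TokenizedBatch, kind: str, fraction: float, rng) -> TokenizedBatch:
    tokens = batch.tokens.copy()
    n_real = batch.n_real.copy()
    fn = shuffle_ranks if kind == "shuffle" else drop_genes
    for i in range(batch.n_cells):
        kw = {} if kind == "shuffle" else {"pad_id": batch.pad_id}
        tokens[i], n_real[i] = fn((batch.tokens[i], batch.n_real[i]), fraction, rng, **kw)
    return TokenizedBatch(tokens, n_real, batch.obs, batch.pad_id, batch.spatial)


def silhouette_stability(embeddings: np.ndarray, labels) -> float:
    """Mean silhouette coefficient (Euclidean) of embeddings grouped by
    ground-truth labels."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 labels with >= 2 cells each")
    return float(silhouette_score(embeddings, labels, metric="euclidean"))


def stability_curve(
    model: EncoderModel,
    batch: TokenizedBatch,
    kind: str,
    fractions,
    labels,
    seed: int = 0,
) -> StabilityCurve:
    """Silhouette score of embeddings after perturbing each cell at every
    fraction. Fraction 0 is required and scores the unperturbed batch."""
    fractions = tuple(float(f) for f in fractions)
    if 0.0 not in fractions:
        raise ValueError("fractions must include 0 (the unperturbed baseline)")
    if kind not in ("shuffle", "dropout"):
        raise ValueError(f"unknown perturbation kind {kind!r}")
    scores = []
    for f in fractions:
        if f == 0.0:
            perturbed = batch
        else:
            rng = np.random.default_rng(seed)
            perturbed = _perturb_batch(batch, kind, f, rng)
        emb = extract_embeddings(model, perturbed)
        scores.append(silhouette_stability(emb, labels))
    return StabilityCurve(kind, fractions, tuple(scores))
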