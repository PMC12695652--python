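"""Cell embeddings from the encoder, plus the PCA baseline.

A cell's embedding is the arithmetic mean of the last-layer outputs at its
gene-token positions; the three context tokens and all PAD positions are
excluded. Excluding the context tokens matters because the modality token
output tends to carry the largest norm and would otherwise dominate the
representation; :func:`token_output_norms` exposes that diagnostic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import EncoderModel
from .tokenizer import N_CONTEXT, TokenizedBatch

__all__ = ["extract_embeddings", "token_output_norms", "pca_baseline"]


def _auto_chunk(model: EncoderModel, seq_len: int, cap: int = 256) -> int:
    """Cells per forward chunk, bounded so the attention temporaries
    (heads x N x N doubles) stay within a few hundred MB."""
    budget = 2**25  # doubles
    return max(1, min(cap, budget // (model.config.n_heads * seq_len * seq_len)))


def extract_embeddings(
    model: EncoderModel, batch: TokenizedBatch, chunk_size: int | None = None
) -> np.ndarray:
    """Mean of last-layer outputs over gene-token positions, per cell.

    Rejects cells carrying zero gene tokens (nothing to aggregate),
    identifying the first offending cell.
    """
    bad = np.flatnonzero(batch.n_real <= N_CONTEXT)
    if bad.size:
        raise ValueError(f"cell at row {int(bad[0])} has zero gene tokens")
    if chunk_size is None:
        chunk_size = _auto_chunk(model, batch.seq_len)
    out = np.empty((batch.n_cells, model.config.d_model))
    for lo in range(0, batch.n_cells, chunk_size):
        hi = min(lo + chunk_size, batch.n_cells)
        hidden, _, _, _ = model.forward(batch.tokens[lo:hi])
        for i in range(lo, hi):
            out[i] = hidden[i - lo, N_CONTEXT : batch.n_real[i]].mean(axis=0)
    return out


def token_output_norms(
    model: EncoderModel, batch: TokenizedBatch, chunk_size: int | None = None
) -> pd.DataFrame:
    """Euclidean norm of every last-layer token output, labelled by token
    category (context / gene / PAD). Long format: (cell, position, category,
    norm)."""
    if chunk_size is None:
        chunk_size = _auto_chunk(model, batch.seq_len)
    frames = []
    for lo in range(0, batch.n_cells, chunk_size):
        hi = min(lo + chunk_size, batch.n_cells)
        hidden, _, _, _ = model.forward(batch.tokens[lo:hi])
        norms = np.linalg.norm(hidden, axis=-1)
        for i in range(lo, hi):
            cat = np.where(
                np.arange(batch.seq_len) < N_CONTEXT,
                "context",
                np.where(np.arange(batch.seq_len) < batch.n_real[i], "gene", "PAD"),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "cell": i,
                        "position": np.arange(batch.seq_len),
                        "category": cat,
                        "norm": norms[i - lo],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def pca_baseline(train, test, n_components: int = 50):
    """PCA baseline embedding.

    Raw counts are normalized so every cell totals the *train-set* median
    depth (no test leakage), log1p-transformed, and projected onto principal
    components fitted on the train split only. Returns
    ``(train_embedding, test_embedding)``.
    """
    import scanpy as sc
    from sklearn.decomposition import PCA

    if n_components > min(train.n_obs, train.n_vars):
        raise ValueError("n_components exceeds min(n_train, n_genes)")
    if list(train.var_names) != list(test.var_names):
        raise ValueError("train and test must share gene columns")

    tr, te = train.copy(), test.copy()
    median = float(np.median(np.ravel(tr.X.sum(axis=1))))
    sc.pp.normalize_total(tr, target_sum=median)
    sc.pp.normalize_total(te, target_sum=median)
    sc.pp.log1p(tr)
    sc.pp.log1p(te)
    Xtr = tr.X.toarray() if hasattr(tr.X, "toarray") else np.asarray(tr.X)
    Xte = te.X.toarray() if hasattr(te.X, "toarray") else np.asarray(te.X)
    pca = PCA(n_components=n_components, svd_solver="full")
    emb_tr = pca.fit_transform(Xtr)
    emb_te = pca.transform(Xte)
    return emb_tr, emb_te
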