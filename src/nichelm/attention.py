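"""Layer-wise attention aggregation toward target tokens, group contrasts,
and ortholog gene-embedding similarity.

For a target token m in a cell's sequence, two per-layer statistics summarise
how much attention it receives: the maximum of A[i, m] over all query tokens
i and heads, and the mean over queries and heads. Queries at PAD positions
and at the target position itself are excluded. Statistics are averaged over
cells; cells whose sequence lacks the target token are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .model import EncoderModel
from .tokenizer import TokenizedBatch

__all__ = [
    "TokenAttentionProfile",
    "sample_cells",
    "attention_to_tokens",
    "group_attention_difference",
    "compare_attention_distributions",
    "bh_adjust",
    "gene_embedding_similarity",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]

#: combined sample size below which the U test uses exact enumeration
_EXACT_N = 25


@dataclass(frozen=True)
class TokenAttentionProfile:
    """Per-layer average/max attention toward each target token.

    ``average`` and ``maximum`` are (layers, targets) arrays averaged over
    the profiled cells; ``per_cell_average``/``per_cell_max`` keep the
    per-cell values (cells, layers, targets) for distributional tests.
    """

    targets: tuple[int, ...]
    average: np.ndarray
    maximum: np.ndarray
    per_cell_average: np.ndarray
    per_cell_max: np.ndarray
    n_cells: int
    n_skipped: dict[int, int]

    def to_frame(self, group: str = "") -> pd.DataFrame:
        rows = []
        L = self.average.shape[0]
        for li in range(L):
            for tj, tok in enumerate(self.targets):
                rows.append((li, tok, "average", group, self.average[li, tj]))
                rows.append((li, tok, "max", group, self.maximum[li, tj]))
        return pd.DataFrame(rows, columns=["layer", "token", "statistic", "group", "value"])


def sample_cells(
    obs: pd.DataFrame, groups: dict, n: int = 2000, seed: int = 0
) -> dict[str, np.ndarray]:
    """Uniform without-replacement sample of up to ``n`` cells per group.

    ``groups`` maps a group name to a boolean mask or an ``(obs column,
    value)`` pair. Groups smaller than ``n`` are returned whole with a
    warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    out = {}
    for name, spec in groups.items():
        if isinstance(spec, tuple):
            col, value = spec
            mask = (obs[col] == value).to_numpy()
        else:
            mask = np.asarray(spec, dtype=bool)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"group {name!r} is empty")
        if idx.size < n:
            warnings.warn(f"group {name!r} has only {idx.size} < {n} cells; using all")
            out[name] = idx
        else:
            out[name] = np.sort(rng.choice(idx, size=n, replace=False))
    return out


def attention_to_tokens(
    model: EncoderModel,
    batch: TokenizedBatch,
    targets,
    chunk_size: int | None = None,
) -> TokenAttentionProfile:
    """Aggregate attention received by each target token, per layer.

    A target must be a non-PAD token id; asking for PAD is rejected since
    PAD receives zero attention by construction.
    """
    targets = tuple(int(t) for t in targets)
    if any(t == batch.pad_id for t in targets):
        raise ValueError("PAD cannot be a target token (it receives no attention)")
    L = model.config.n_layers
    if chunk_size is None:  # keep the stacked (B, L, H, N, N) tensor bounded
        n2 = batch.seq_len * batch.seq_len
        chunk_size = max(1, min(64, 2**25 // (L * model.config.n_heads * n2)))
    per_avg: list[np.ndarray] = []
    per_max: list[np.ndarray] = []
    skipped = {t: 0 for t in targets}

    for lo in range(0, batch.n_cells, chunk_size):
        hi = min(lo + chunk_size, batch.n_cells)
        _, _, attn, _ = model.forward(batch.tokens[lo:hi], return_attention=True)
        # attn: (B, L, H, N, N)
        for bi in range(hi - lo):
            seq = batch.tokens[lo + bi]
            nr = int(batch.n_real[lo + bi])
            cell_avg = np.full((L, len(targets)), np.nan)
            cell_max = np.full((L, len(targets)), np.nan)
            for tj, tok in enumerate(targets):
                pos = np.flatnonzero(seq[:nr] == tok)
                if pos.size == 0:
                    skipped[tok] += 1
                    continue
                m = int(pos[0])
                queries = np.setdiff1d(np.arange(nr), [m])
                a = attn[bi, :, :, queries, m]  # (queries, L, H) after fancy indexing
                cell_avg[:, tj] = a.mean(axis=(0, 2))
                cell_max[:, tj] = a.max(axis=(0, 2))
            per_avg.append(cell_avg)
            per_max.append(cell_max)

    pa = np.stack(per_avg)
    pm = np.stack(per_max)
    if np.all(np.isnan(pa)):
        raise ValueError("no profiled cell contains any target token")
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(pa, axis=0)
        mx = np.nanmean(pm, axis=0)
    return TokenAttentionProfile(targets, avg, mx, pa, pm, batch.n_cells, skipped)


def group_attention_difference(
    profile_a: TokenAttentionProfile, profile_b: TokenAttentionProfile
) -> dict[str, np.ndarray]:
    """Elementwise |A - B| of the layer-wise statistics of two groups."""
    if profile_a.targets != profile_b.targets or profile_a.average.shape != profile_b.average.shape:
        raise ValueError("profiles must share layers and target tokens")
    return {
        "average": np.abs(profile_a.average - profile_b.average),
        "max": np.abs(profile_a.maximum - profile_b.maximum),
    }


def compare_attention_distributions(
    samples_a: np.ndarray, samples_b: np.ndarray
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per (layer, target), BH-adjusted.

    Inputs are per-cell statistic arrays of shape (cells, layers, targets)
    as stored in :class:`TokenAttentionProfile`; NaNs (cells lacking the
    target) are dropped per test. Exact enumeration is used for small
    tie-free samples, the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None, None]
        b = b[:, None, None]
    _, L, T = a.shape
    rows = []
    for li in range(L):
        for tj in range(T):
            xa = a[:, li, tj]
            xb = b[:, li, tj]
            xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
            if len(xa) < 2 or len(xb) < 2:
                raise ValueError("need >= 2 observations per group")
            ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
            method = "exact" if (len(xa) + len(xb) < _EXACT_N and not ties) else "asymptotic"
            res = mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            rows.append((li, tj, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["layer", "target", "U", "pvalue"])
    df["pvalue_adj"] = bh_adjust(df["pvalue"])
    return df


def gene_embedding_similarity(model: EncoderModel, pairs) -> np.ndarray:
    """Cosine similarity of input gene-embedding rows for each token pair."""
    emb = model.params["tok_emb"]
    out = np.empty(len(pairs))
    for i, (ta, tb) in enumerate(pairs):
        va, vb = emb[int(ta)], emb[int(tb)]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            raise ValueError("zero-norm gene embedding")
        out[i] = float(va @ vb / (na * nb))
    return out
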