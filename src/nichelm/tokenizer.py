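"""Rank tokenization of expression vectors into fixed-length token sequences.

A cell is encoded as three context tokens (assay, organism, modality) followed
by its expressed genes ordered from most to least expressed, where expression
is depth-normalized to 10,000 counts and divided by a technology-specific
nonzero-mean vector; the sequence is truncated/padded to a fixed length N
(default 1,500, context tokens included). Ties in the normalized value are
broken by ascending token id so tokenization is fully deterministic.

Technology groups: all dissociated assays form one group; each spatial
technology (MERFISH, Xenium, CosMx, ISS) is its own group.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .vocab import GeneIndexMap, GeneVocabulary, map_dataset_genes

__all__ = [
    "SEQ_LEN",
    "N_CONTEXT",
    "TechnologyNormalizer",
    "TokenizedCell",
    "TokenizedBatch",
    "depth_normalize",
    "technology_group",
    "fit_nonzero_means",
    "tokenize_cell",
    "tokenize_dataset",
]

SEQ_LEN = 1500
N_CONTEXT = 3  # (assay, organism, modality) prepended to every cell
TARGET_DEPTH = 10_000.0

#: obs columns echoed into the tokenized batch when present
_ECHO_COLS = [
    "organism", "modality", "assay", "cell_type",
    "niche_label", "region_label", "fov_id", "split",
]


def technology_group(modality: str, assay: str) -> str:
    """Normalization group of a cell: 'dissociated' or the spatial assay."""
    return "dissociated" if modality == "dissociated" else assay


def depth_normalize(counts: np.ndarray) -> np.ndarray:
    """Scale a count vector so it sums to 10,000."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot depth-normalize an all-zero cell")
    return counts * (TARGET_DEPTH / total)


@dataclass(frozen=True)
class TechnologyNormalizer:
    """Per-technology-group nonzero means over vocabulary gene tokens.

    ``means[group]`` is a dense vector over the full vocabulary id range;
    entries for genes never observed nonzero in the group (and all non-gene
    slots) carry the fallback value 1.0, i.e. identity scaling.
    """

    means: dict[str, np.ndarray]
    vocab_size: int

    def group_means(self, group: str) -> np.ndarray:
        try:
            return self.means[group]
        except KeyError:
            raise KeyError(f"unknown technology group {group!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, vec in sorted(self.means.items()):
            nz = np.flatnonzero(vec != 1.0)
            rows.append(pd.DataFrame({"technology": group, "token_id": nz, "mean": vec[nz]}))
        if not rows:
            return pd.DataFrame(columns=["technology", "token_id", "mean"])
        return pd.concat(rows, ignore_index=True)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, vocab_size: int, groups=None) -> "TechnologyNormalizer":
        means = {}
        for group in groups or df["technology"].unique():
            vec = np.ones(vocab_size)
            sub = df[df["technology"] == group]
            vec[sub["token_id"].to_numpy()] = sub["mean"].to_numpy()
            means[group] = vec
        return cls(means, vocab_size)


def _dense_chunk(X, lo: int, hi: int) -> np.ndarray:
    chunk = X[lo:hi]
    if sp.issparse(chunk):
        chunk = chunk.toarray()
    return np.asarray(chunk, dtype=np.float64)


def fit_nonzero_means(
    datasets: list, vocab: GeneVocabulary, chunk_size: int = 1024
) -> TechnologyNormalizer:
    """Fit per-group nonzero means of depth-normalized expression.

    For each technology group and gene token: the mean over all cells in the
    group of the depth-normalized value, counting only cells where the value
    is nonzero. Groups/genes with zero nonzero observations get fallback 1.0.
    """
    sums: dict[str, np.ndarray] = {}
    nnz: dict[str, np.ndarray] = {}
    for adata in datasets:
        index_map = map_dataset_genes(adata, vocab)
        cols = np.flatnonzero(index_map.mapped_mask)
        tok = index_map.col_to_token[cols]
        groups = np.array(
            [technology_group(m, a) for m, a in zip(adata.obs["modality"], adata.obs["assay"])]
        )
        for lo in range(0, adata.n_obs, chunk_size):
            hi = min(lo + chunk_size, adata.n_obs)
            dense = _dense_chunk(adata.X, lo, hi)
            totals = dense.sum(axis=1)
            if np.any(totals <= 0):
                bad = lo + int(np.flatnonzero(totals <= 0)[0])
                raise ValueError(f"all-zero cell at index {bad} ({adata.obs_names[bad]})")
            normed = dense * (TARGET_DEPTH / totals[:, None])
            for group in np.unique(groups[lo:hi]):
                if group not in sums:
                    sums[group] = np.zeros(vocab.size)
                    nnz[group] = np.zeros(vocab.size, dtype=np.int64)
                sub = normed[groups[lo:hi] == group][:, cols]
                np.add.at(sums[group], tok, sub.sum(axis=0))
                np.add.at(nnz[group], tok, (sub > 0).sum(axis=0))
    means = {}
    for group in sums:
        vec = np.ones(vocab.size)
        obs = nnz[group] > 0
        vec[obs] = sums[group][obs] / nnz[group][obs]
        means[group] = vec
    return TechnologyNormalizer(means, vocab.size)


@dataclass(frozen=True)
class TokenizedCell:
    """A single fixed-length token sequence with its metadata echo."""

    tokens: np.ndarray  # int32, shape (N,)
    n_real: int  # number of non-PAD tokens (context included)
    metadata: dict

    def gene_tokens(self) -> np.ndarray:
        return self.tokens[N_CONTEXT : self.n_real]


@dataclass
class TokenizedBatch:
    """Stacked token sequences plus padding mask and metadata echo."""

    tokens: np.ndarray  # int32, shape (cells, N)
    n_real: np.ndarray  # int64, shape (cells,)
    obs: pd.DataFrame
    pad_id: int = 0
    spatial: np.ndarray | None = None  # (cells, 2) coordinates when present

    @property
    def n_cells(self) -> int:
        return self.tokens.shape[0]

    @property
    def seq_len(self) -> int:
        return self.tokens.shape[1]

    @property
    def pad_mask(self) -> np.ndarray:
        """Boolean mask, True at PAD positions."""
        return self.tokens == self.pad_id

    def subset(self, idx) -> "TokenizedBatch":
        idx = np.asarray(idx)
        return TokenizedBatch(
            self.tokens[idx],
            self.n_real[idx],
            self.obs.iloc[idx].reset_index(drop=True),
            self.pad_id,
            None if self.spatial is None else self.spatial[idx],
        )

    def save(self, path) -> None:
        """Chunked int32 HDF5 store plus a metadata table."""
        with h5py.File(path, "w") as f:
            f.create_dataset(
                "tokens", data=self.tokens,
                chunks=(min(256, self.n_cells), self.seq_len), track_times=False,
            )
            f.create_dataset("n_real", data=self.n_real, track_times=False)
            if self.spatial is not None:
                f.create_dataset("spatial", data=self.spatial, track_times=False)
            g = f.create_group("obs")
            for col in self.obs.columns:
                g.create_dataset(
                    col, data=self.obs[col].astype(str).to_numpy(dtype="S"),
                    track_times=False,
                )

    @classmethod
    def load(cls, path) -> "TokenizedBatch":
        with h5py.File(path, "r") as f:
            tokens = f["tokens"][:]
            n_real = f["n_real"][:]
            spatial = f["spatial"][:] if "spatial" in f else None
            obs = pd.DataFrame(
                {col: f["obs"][col][:].astype(str) for col in f["obs"]}
            )
        return cls(tokens, n_real, obs, spatial=spatial)


def _context_ids(metadata: dict, vocab: GeneVocabulary) -> list[int]:
    return [
        vocab.context_id("assay", metadata["assay"]),
        vocab.context_id("organism", metadata["organism"]),
        vocab.context_id("modality", metadata["modality"]),
    ]


def _rank_genes(
    values: np.ndarray, token_ids: np.ndarray
) -> np.ndarray:
    """Token ids of strictly-positive genes, descending value, ties by id."""
    pos = values > 0
    v, t = values[pos], token_ids[pos]
    order = np.lexsort((t, -v))
    return t[order]


def tokenize_cell(
    counts: np.ndarray,
    metadata: dict,
    vocab: GeneVocabulary,
    normalizer: TechnologyNormalizer,
    index_map: GeneIndexMap,
    seq_len: int = SEQ_LEN,
) -> TokenizedCell:
    """Tokenize one expression vector.

    A cell with no expressed vocabulary genes yields just the three context
    tokens followed by PAD.
    """
    group = technology_group(metadata["modality"], metadata["assay"])
    means = normalizer.group_means(group)
    ctx = _context_ids(metadata, vocab)

    counts = np.asarray(counts).ravel()
    cols = np.flatnonzero(index_map.mapped_mask)
    tok = index_map.col_to_token[cols]
    if counts.sum() > 0:
        normed = depth_normalize(counts)[cols]
        rel = normed / means[tok]
        genes = _rank_genes(rel, tok)
    else:
        genes = np.empty(0, dtype=np.int64)

    seq = np.full(seq_len, vocab.pad_id, dtype=np.int32)
    full = np.concatenate([np.asarray(ctx, dtype=np.int64), genes])[:seq_len]
    seq[: len(full)] = full
    return TokenizedCell(seq, int(len(full)), dict(metadata))


def tokenize_dataset(
    dataset,
    vocab: GeneVocabulary,
    normalizer: TechnologyNormalizer,
    index_map: GeneIndexMap | None = None,
    seq_len: int = SEQ_LEN,
    chunk_size: int = 512,
) -> TokenizedBatch:
    """Tokenize every cell of an AnnData dataset, preserving row order.

    Cells are processed in fixed-size chunks so peak working memory is
    independent of the number of cells. Per-cell failures are re-raised with
    the offending cell's name.
    """
    if index_map is None:
        index_map = map_dataset_genes(dataset, vocab)
    cols = np.flatnonzero(index_map.mapped_mask)
    tok = index_map.col_to_token[cols]

    n = dataset.n_obs
    tokens = np.zeros((n, seq_len), dtype=np.int32)
    n_real = np.zeros(n, dtype=np.int64)
    obs = dataset.obs
    ctx_per_cell = np.empty((n, N_CONTEXT), dtype=np.int64)
    for i in range(n):
        meta = {k: obs[k].iloc[i] for k in ("assay", "organism", "modality")}
        try:
            ctx_per_cell[i] = _context_ids(meta, vocab)
        except KeyError as e:
            raise ValueError(f"cell {dataset.obs_names[i]!r}: {e}") from e
    groups = np.array(
        [technology_group(m, a) for m, a in zip(obs["modality"], obs["assay"])]
    )

    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        dense = _dense_chunk(dataset.X, lo, hi)
        totals = dense.sum(axis=1)
        for i in range(lo, hi):
            row = dense[i - lo]
            if totals[i - lo] > 0:
                try:
                    means = normalizer.group_means(groups[i])
                except KeyError as e:
                    raise ValueError(f"cell {dataset.obs_names[i]!r}: {e}") from e
                rel = row[cols] * (TARGET_DEPTH / totals[i - lo]) / means[tok]
                genes = _rank_genes(rel, tok)
            else:
                genes = np.empty(0, dtype=np.int64)
            full = np.concatenate([ctx_per_cell[i], genes])[:seq_len]
            tokens[i, : len(full)] = full
            n_real[i] = len(full)

    echo_cols = [c for c in _ECHO_COLS if c in obs.columns]
    spatial = np.asarray(dataset.obsm["spatial"]) if "spatial" in dataset.obsm else None
    return TokenizedBatch(
        tokens, n_real, obs[echo_cols].reset_index(drop=True), vocab.pad_id, spatial
    )
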