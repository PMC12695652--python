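"""Deterministic joint human–mouse token registry.

Token-id layout is fixed so that registries, token files and checkpoints are
reproducible across runs: ``<PAD>`` = 0, ``<MASK>`` = 1, then context tokens
(grouped by category in the order assay, organism, modality, values in
registration order), then gene tokens sorted lexicographically by canonical
key. An ortholog pair collapses to a single gene token keyed by the human
identifier; species-specific genes are keyed by their own identifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import OrthologMap

__all__ = ["GeneVocabulary", "GeneIndexMap", "build_vocabulary", "map_dataset_genes"]

PAD, MASK = "<PAD>", "<MASK>"
CONTEXT_CATEGORIES = ("assay", "organism", "modality")


@dataclass(frozen=True)
class GeneVocabulary:
    """Immutable token registry mapping token strings to contiguous ids."""

    tokens: tuple[str, ...]
    context_ids: dict[tuple[str, str], int]
    gene_ids: dict[str, int]
    alias: dict[str, str]  # any species gene id -> canonical gene key

    pad_id: int = 0
    mask_id: int = 1

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def n_gene_tokens(self) -> int:
        return len(self.gene_ids)

    @property
    def first_gene_id(self) -> int:
        return 2 + len(self.context_ids)

    def context_id(self, category: str, value: str) -> int:
        try:
            return self.context_ids[(category, str(value))]
        except KeyError:
            raise KeyError(f"unknown context value {value!r} for category {category!r}")

    def gene_token_id(self, gene: str) -> int | None:
        """Token id for a gene identifier of either species, or None."""
        key = self.alias.get(gene, gene)
        return self.gene_ids.get(key)

    def is_gene_token(self, token_id: int) -> bool:
        return token_id >= self.first_gene_id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"token": self.tokens, "id": np.arange(self.size)})

    def save(self, path) -> None:
        """Serialize as a two-column plain-text table (token, id)."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_vocabulary(
    omap: OrthologMap,
    assays: list[str],
    organisms: list[str] = ("human", "mouse"),
    modalities: list[str] = ("dissociated", "spatial"),
) -> GeneVocabulary:
    """Build the joint registry: one gene token per ortholog pair plus one per
    species-specific gene, after the special and context tokens.
    """
    values_by_cat = {"assay": list(assays), "organism": list(organisms), "modality": list(modalities)}
    for cat, values in values_by_cat.items():
        if not values:
            raise ValueError(f"context category {cat!r} has no values")
        if len(set(values)) != len(values):
            raise ValueError(f"duplicate context values in category {cat!r}")

    tokens = [PAD, MASK]
    context_ids: dict[tuple[str, str], int] = {}
    for cat in CONTEXT_CATEGORIES:
        for value in values_by_cat[cat]:
            context_ids[(cat, value)] = len(tokens)
            tokens.append(f"<{cat}:{value}>")

    alias: dict[str, str] = {}
    keys = []
    for h, m in omap.pairs:
        alias[h] = h
        alias[m] = h
        keys.append(h)
    for g in list(omap.human_only) + list(omap.mouse_only):
        alias[g] = g
        keys.append(g)

    gene_ids: dict[str, int] = {}
    for key in sorted(keys):
        gene_ids[key] = len(tokens)
        tokens.append(key)
    return GeneVocabulary(tuple(tokens), context_ids, gene_ids, alias)


@dataclass(frozen=True)
class GeneIndexMap:
    """Dataset gene columns resolved to vocabulary token ids.

    ``col_to_token[j]`` is the token id of column ``j`` or -1 for columns with
    no vocabulary entry; unmapped columns are reported, never silently
    dropped.
    """

    col_to_token: np.ndarray
    unmapped: tuple[str, ...]

    @property
    def mapped_mask(self) -> np.ndarray:
        return self.col_to_token >= 0


def map_dataset_genes(dataset, vocab: GeneVocabulary) -> GeneIndexMap:
    """Resolve each gene column of ``dataset`` (AnnData) to its token id.

    Mouse columns participating in an ortholog pair map to the pair's shared
    token (keyed by the human id). Two columns resolving to the same token —
    e.g. a dataset carrying both members of a pair — are rejected as
    ambiguous.
    """
    gene_ids = list(dataset.var_names)
    col_to_token = np.full(len(gene_ids), -1, dtype=np.int64)
    unmapped = []
    for j, g in enumerate(gene_ids):
        tid = vocab.gene_token_id(g)
        if tid is None:
            unmapped.append(g)
        else:
            col_to_token[j] = tid
    mapped = col_to_token[col_to_token >= 0]
    if len(np.unique(mapped)) != len(mapped):
        dup = pd.Series(mapped).value_counts()
        bad = dup[dup > 1].index.tolist()
        raise ValueError(f"ambiguous mapping: multiple columns resolve to token ids {bad}")
    return GeneIndexMap(col_to_token, tuple(unmapped))
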