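"""Synthetic single-cell and spatial transcriptomics corpora with known truth.

Two generators emulate the two halves of a joint pretraining corpus:

* :func:`generate_dissociated` — negative-binomial scRNA-seq counts with
  cell-type marker programs and lognormal library sizes.
* :func:`generate_spatial` — targeted-panel data (MERFISH/Xenium/CosMx/ISS
  style): cells placed in rectangular fields of view, spatially contiguous
  niche domains (noisy Voronoi partitions), niche-driven cell-type mixing and
  niche marker programs, and a reduced gene panel.

Ground truth (cell type, niche, region, spatial coordinates) is carried in
``AnnData.obs`` so every downstream stage can be evaluated against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "OrthologMap",
    "SimulationConfig",
    "SPATIAL_TECHNOLOGIES",
    "generate_ortholog_map",
    "generate_dissociated",
    "generate_spatial",
]

#: spatial assays carried as distinct normalization groups
SPATIAL_TECHNOLOGIES = ("MERFISH", "Xenium", "CosMx", "ISS")

#: side length of one simulated field of view, micrometres
FOV_SIZE_UM = 500.0

#: default lognormal depth parameters; dissociated libraries are much deeper
#: than targeted spatial panels, mirroring the technology bias between
#: sequencing- and imaging-based assays.
DISSOCIATED_DEPTH_LOG_MEAN = math.log(2500.0)
SPATIAL_DEPTH_LOG_MEAN = math.log(250.0)


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one human/mouse ortholog pairs plus species-specific genes."""

    pairs: tuple[tuple[str, str], ...]
    human_only: tuple[str, ...]
    mouse_only: tuple[str, ...]

    def __post_init__(self) -> None:
        humans = [h for h, _ in self.pairs] + list(self.human_only)
        mice = [m for _, m in self.pairs] + list(self.mouse_only)
        all_ids = humans + mice
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("gene ids must be unique across pairs and species-specific lists")

    def genes_for(self, organism: str) -> list[str]:
        """Gene universe of one organism (its pair members + specific genes)."""
        if organism == "human":
            return [h for h, _ in self.pairs] + list(self.human_only)
        if organism == "mouse":
            return [m for _, m in self.pairs] + list(self.mouse_only)
        raise ValueError(f"unknown organism {organism!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (human_id, mouse_id); missing side empty."""
        rows = [(h, m) for h, m in self.pairs]
        rows += [(h, "") for h in self.human_only]
        rows += [("", m) for m in self.mouse_only]
        return pd.DataFrame(rows, columns=["human_id", "mouse_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologMap":
        pairs, h_only, m_only = [], [], []
        for h, m in zip(df["human_id"].fillna(""), df["mouse_id"].fillna("")):
            if h and m:
                pairs.append((str(h), str(m)))
            elif h:
                h_only.append(str(h))
            elif m:
                m_only.append(str(m))
        return cls(tuple(pairs), tuple(h_only), tuple(m_only))

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "OrthologMap":
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


def generate_ortholog_map(
    n_pairs: int, n_human_only: int, n_mouse_only: int, seed: int = 0
) -> OrthologMap:
    """Deterministic synthetic ortholog table with the requested cardinalities.

    Gene identifiers are synthetic (``HG``/``MG`` prefixes); the seed controls
    which human/mouse ids are paired with each other.
    """
    if min(n_pairs, n_human_only, n_mouse_only) < 0:
        raise ValueError("cardinalities must be non-negative")
    rng = np.random.default_rng(seed)
    humans = [f"HG{i:06d}" for i in range(n_pairs + n_human_only)]
    mice = [f"MG{i:06d}" for i in range(n_pairs + n_mouse_only)]
    h_paired = sorted(rng.choice(len(humans), size=n_pairs, replace=False).tolist())
    m_paired = rng.permutation(
        sorted(rng.choice(len(mice), size=n_pairs, replace=False).tolist())
    ).tolist()
    pairs = tuple((humans[i], mice[j]) for i, j in zip(h_paired, m_paired))
    human_only = tuple(humans[i] for i in range(len(humans)) if i not in set(h_paired))
    mouse_only = tuple(mice[j] for j in range(len(mice)) if j not in set(m_paired))
    return OrthologMap(pairs, human_only, mouse_only)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic corpus.

    ``depth_log_mean=None`` selects the per-modality default (deep dissociated
    libraries, shallow spatial panels). ``nb_dispersion`` is the
    negative-binomial shape ``theta`` (variance ``mu + mu**2/theta``).
    ``program_effect`` is the fold-change of marker blocks; ``niche_smoothness``
    in [0, 1] controls spatial domain coherence (1 = clean Voronoi domains).
    """

    n_cells: int = 2000
    n_genes: int = 500
    n_cell_types: int = 5
    n_niches: int = 4
    n_fovs: int = 4
    panel_size: int = 250
    depth_log_mean: float | None = None
    depth_log_sd: float = 0.35
    nb_dispersion: float = 2.0
    program_effect: float = 8.0
    niche_smoothness: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_cell_types", "n_niches", "n_fovs", "panel_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.panel_size > self.n_genes:
            raise ValueError("panel_size must not exceed n_genes")
        if self.program_effect < 1:
            raise ValueError("program_effect must be >= 1")
        if not 0.0 <= self.niche_smoothness <= 1.0:
            raise ValueError("niche_smoothness must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _select_genes(universe: list[str], n_genes: int, rng: np.random.Generator) -> list[str]:
    if n_genes > len(universe):
        raise ValueError(
            f"n_genes={n_genes} exceeds the organism gene universe ({len(universe)})"
        )
    chosen = rng.choice(len(universe), size=n_genes, replace=False)
    return [universe[i] for i in sorted(chosen.tolist())]


def _marker_blocks(n_genes: int, n_programs: int, offset: int = 0) -> list[np.ndarray]:
    """Disjoint contiguous marker blocks, >= 5 genes each where possible."""
    per = max(5, n_genes // (5 * max(n_programs, 1)))
    blocks = []
    for p in range(n_programs):
        lo = offset + p * per
        hi = min(lo + per, n_genes)
        blocks.append(np.arange(lo, hi))
    return blocks


def _nb_counts(
    mu: np.ndarray, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma–Poisson draw: NB with mean ``mu`` and dispersion ``theta``."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam).astype(np.int32)


def _ensure_nonempty(counts: np.ndarray, rng: np.random.Generator) -> None:
    """Guarantee per-cell totals > 0 (a shallow cell may draw all zeros)."""
    empty = np.flatnonzero(counts.sum(axis=1) == 0)
    for i in empty:
        counts[i, rng.integers(counts.shape[1])] = 1


def _base_rates(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    return base / base.sum()


def generate_dissociated(
    config: SimulationConfig, omap: OrthologMap, organism: str = "human"
) -> ad.AnnData:
    """Simulate a dissociated scRNA-seq dataset with cell-type programs.

    Each cell type overexpresses a disjoint marker block by
    ``config.program_effect``; counts are negative-binomial around
    depth-scaled expected proportions; library sizes are lognormal.
    """
    rng = np.random.default_rng(config.seed)
    genes = _select_genes(omap.genes_for(organism), config.n_genes, rng)
    base = _base_rates(config.n_genes, rng)
    type_blocks = _marker_blocks(config.n_genes, config.n_cell_types)

    cell_type = rng.integers(config.n_cell_types, size=config.n_cells)
    depth_log_mean = (
        DISSOCIATED_DEPTH_LOG_MEAN if config.depth_log_mean is None else config.depth_log_mean
    )
    depth = rng.lognormal(depth_log_mean, config.depth_log_sd, size=config.n_cells)

    props = np.tile(base, (config.n_cells, 1))
    for t, block in enumerate(type_blocks):
        props[np.ix_(cell_type == t, block)] *= config.program_effect
    props /= props.sum(axis=1, keepdims=True)
    counts = _nb_counts(props * depth[:, None], config.nb_dispersion, rng)
    _ensure_nonempty(counts, rng)

    obs = pd.DataFrame(
        {
            "organism": organism,
            "modality": "dissociated",
            "assay": "dissociated",
            "cell_type": pd.Categorical([f"CT{t}" for t in cell_type]),
            "split": pd.Categorical(
                np.where(rng.random(config.n_cells) < 0.8, "train", "test")
            ),
        },
        index=[f"{organism}_diss_{i}" for i in range(config.n_cells)],
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs)
    adata.var_names = genes
    adata.uns["simulation"] = {"kind": "dissociated", "seed": config.seed}
    return adata


def _voronoi_niches(
    xy: np.ndarray,
    n_niches: int,
    smoothness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noisy Voronoi niche assignment within one field of view.

    Distances to ``n_niches`` random seed points are perturbed with Gaussian
    noise of scale ``(1 - smoothness) * FOV_SIZE_UM / 2``; the argmin gives
    contiguous domains when smoothness is high and salt-and-pepper labels
    when it is low.
    """
    seeds = rng.uniform(0, FOV_SIZE_UM, size=(n_niches, 2))
    dist = np.linalg.norm(xy[:, None, :] - seeds[None, :, :], axis=2)
    noise_sd = (1.0 - smoothness) * FOV_SIZE_UM / 2.0
    if noise_sd > 0:
        dist = dist + rng.normal(0.0, noise_sd, size=dist.shape)
    return dist.argmin(axis=1)


def generate_spatial(
    config: SimulationConfig,
    omap: OrthologMap,
    organism: str = "mouse",
    technology: str = "MERFISH",
) -> ad.AnnData:
    """Simulate a targeted spatial panel with coherent niche domains.

    Cells are placed uniformly in ``n_fovs`` square fields of view; each FOV
    is partitioned into niche domains (noisy Voronoi). The niche drives both
    the cell-type mixing proportions and a niche marker program, so niche
    labels are recoverable from expression alone. Only ``panel_size`` genes
    are kept: all marker genes plus random fillers. Regions group pairs of
    niches. The train/test split holds out whole fields of view.
    """
    if technology not in SPATIAL_TECHNOLOGIES:
        raise ValueError(f"technology must be one of {SPATIAL_TECHNOLOGIES}")
    rng = np.random.default_rng(config.seed)
    genes = _select_genes(omap.genes_for(organism), config.n_genes, rng)
    base = _base_rates(config.n_genes, rng)
    type_blocks = _marker_blocks(config.n_genes, config.n_cell_types)
    niche_offset = max(b[-1] for b in type_blocks) + 1
    niche_blocks = _marker_blocks(
        config.n_genes - niche_offset, config.n_niches, offset=niche_offset
    )

    # cells per FOV, coordinates and niche domains
    per_fov = np.full(config.n_fovs, config.n_cells // config.n_fovs)
    per_fov[: config.n_cells % config.n_fovs] += 1
    fov_id = np.repeat(np.arange(config.n_fovs), per_fov)
    xy = rng.uniform(0, FOV_SIZE_UM, size=(config.n_cells, 2))
    niche = np.empty(config.n_cells, dtype=np.int64)
    for f in range(config.n_fovs):
        m = fov_id == f
        niche[m] = _voronoi_niches(xy[m], config.n_niches, config.niche_smoothness, rng)

    # niche -> cell-type mixing (one dominant type per niche)
    mix = np.ones((config.n_niches, config.n_cell_types))
    mix[np.arange(config.n_niches), np.arange(config.n_niches) % config.n_cell_types] = 6.0
    mix /= mix.sum(axis=1, keepdims=True)
    u = rng.random(config.n_cells)
    cell_type = (mix[niche].cumsum(axis=1) < u[:, None]).sum(axis=1)

    depth_log_mean = (
        SPATIAL_DEPTH_LOG_MEAN if config.depth_log_mean is None else config.depth_log_mean
    )
    depth = rng.lognormal(depth_log_mean, config.depth_log_sd, size=config.n_cells)
    props = np.tile(base, (config.n_cells, 1))
    for t, block in enumerate(type_blocks):
        props[np.ix_(cell_type == t, block)] *= config.program_effect
    for k, block in enumerate(niche_blocks):
        props[np.ix_(niche == k, block)] *= config.program_effect
    props /= props.sum(axis=1, keepdims=True)

    # targeted panel: all marker genes plus random fillers
    markers = np.concatenate(type_blocks + niche_blocks)
    markers = np.unique(markers)
    if markers.size > config.panel_size:
        raise ValueError(
            "panel_size too small to hold all marker genes; "
            f"need >= {markers.size}, got {config.panel_size}"
        )
    fillers = np.setdiff1d(np.arange(config.n_genes), markers)
    extra = rng.choice(fillers, size=config.panel_size - markers.size, replace=False)
    panel = np.sort(np.concatenate([markers, extra]))

    counts = _nb_counts(props * depth[:, None], config.nb_dispersion, rng)
    counts = counts[:, panel]
    _ensure_nonempty(counts, rng)

    n_test_fovs = max(1, math.ceil(config.n_fovs * 0.25)) if config.n_fovs > 1 else 0
    test_fovs = set(
        rng.choice(config.n_fovs, size=n_test_fovs, replace=False).tolist()
    )
    obs = pd.DataFrame(
        {
            "organism": organism,
            "modality": "spatial",
            "assay": technology,
            "cell_type": pd.Categorical([f"CT{t}" for t in cell_type]),
            "niche_label": pd.Categorical([f"niche_{k}" for k in niche]),
            "region_label": pd.Categorical([f"region_{k // 2}" for k in niche]),
            "fov_id": pd.Categorical([f"fov_{f}" for f in fov_id]),
            "split": pd.Categorical(
                ["test" if f in test_fovs else "train" for f in fov_id]
            ),
        },
        index=[f"{organism}_{technology}_{i}" for i in range(config.n_cells)],
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs)
    adata.var_names = [genes[j] for j in panel]
    adata.obsm["spatial"] = xy
    adata.uns["simulation"] = {"kind": "spatial", "seed": config.seed}
    return adata
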