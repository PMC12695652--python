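# Methods

This note documents the models and procedures implemented in `nichelm`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic benchmarks can and cannot show.

## Problem setting

Image-based spatial transcriptomics (MERFISH, Xenium, CosMx, ISS) measures
targeted panels of hundreds of genes per cell together with 2-D positions,
while dissociated scRNA-seq measures genome-wide expression without tissue
context. `nichelm` implements a joint representation-learning pipeline over
both: cells from either modality are encoded as rank-ordered gene-token
sequences, a transformer encoder is pretrained with masked language
modelling (MLM) on the mixed corpus, and the resulting cell embeddings are
probed or fine-tuned for spatially defined targets — niche/region labels,
neighborhood cell-type composition, and neighborhood density.

## Gene vocabulary

Human and mouse data share one token space. Each one-to-one ortholog pair
collapses to a single gene token keyed by the human identifier;
species-specific genes keep their own key. Token ids are deterministic:
`<PAD>`=0, `<MASK>`=1, then context tokens (assay, organism, modality, each
category's values in registration order), then gene keys in lexicographic
order. Rebuilding the vocabulary from the same ortholog table is bit-exact,
so token files and checkpoints are reproducible. Many-to-many ortholog
resolution is out of scope: the input table must already be one-to-one.

## Rank tokenization

Per cell: (1) counts are depth-normalized to 10,000; (2) each gene is
divided by its *technology-specific nonzero mean* — the mean of its
depth-normalized value over the cells of that technology group in which it
was detected (dissociated assays form one group; each spatial technology is
its own group; genes never detected in a group fall back to 1.0, i.e.
identity scaling). This removes the systematic detection bias of targeted
panels relative to sequencing; (3) expressed genes are sorted by the
normalized value, highest first, ties broken by ascending token id so the
sequence is a pure function of the input; (4) the three context tokens
(assay, organism, modality — in that order) are prepended; (5) the sequence
is truncated to N tokens and padded with `<PAD>` to exactly N. The default
N = 1,500 *includes* the context tokens, so at most 1,497 gene tokens
survive. Consequences: tokenization is invariant to rescaling a cell's
counts and equivariant to gene-column permutations; a cell with no expressed
vocabulary genes reduces to its three context tokens.

## Encoder

A NumPy transformer encoder with explicit forward and backward passes
(gradients are verified against central finite differences in the test
suite). Layout per block, pre-norm:

    x <- x + W_o · MultiHeadAttention(LayerNorm(x))
    x <- x + W_2 · GELU(W_1 · LayerNorm(x))

followed by a final LayerNorm and an untied linear decoder over the full
vocabulary (tying to the input embedding is available behind a flag). PAD
keys are masked to −inf before the attention softmax, so attention rows are
probability vectors over the non-PAD keys and PAD columns are exactly zero.
Positions are encoded with a learnable embedding table added to the token
embeddings.

The pre-norm layout is a deliberate design choice. A cell embedding is the
*mean of the last-layer gene-token outputs*; with pre-norm the token and
positional embeddings remain additively present in the residual stream, so
the pooled embedding always retains a linear "bag of expressed genes"
component. At desk scale (2 blocks, a few hundred optimizer steps) this is
what makes embeddings informative; a post-norm stack renormalizes the
stream twice per block and the same budget leaves mean-pooled embeddings
close to uninformative.

Initialization: linear weights are Xavier-uniform with zero biases;
embedding tables are N(0, 1/√D) (fan-based scaling is not meaningful for
lookup tables); the residual output projections (`W_o`, `W_2`) are scaled
by 0.1 at initialization so the embedding stream dominates early training.
At initialization the MLM loss is within a few percent of ln(vocabulary
size), the uniform-predictor entropy.

Full-scale defaults are 12 blocks, 16 heads, D=512, FFN 1,024 and
N=1,500; tests and the acceptance runs use a tiny
configuration (2 blocks, 4 heads, D=64, FFN 128, N=256 matched to the
simulated panel). Computation is single-precision and deterministic
(float64 available via `EncoderConfig.dtype`).

## Pretraining

BERT-style MLM: each non-PAD position (context tokens included) is selected
independently with probability 0.15; a selected token is replaced by
`<MASK>` with probability 0.8, by a random non-special token with 0.1, and
kept with 0.1. The loss is the mean negative log-likelihood of the original
tokens at the selected positions only — perturbing logits elsewhere leaves
it unchanged.

Optimizer: AdamW, β = (0.9, 0.999), weight decay 0.1 on weight matrices
(not on biases, LayerNorm parameters or the embedding tables — decaying the
lookup tables drains token identity from rarely updated rows). Learning
rate: linear warmup from 1e-5 to 1e-3, then cosine decay back to 1e-5.
Gradients are accumulated over micro-batches (full-scale: batch 9 × 10
accumulation) and clipped by global norm, 1.0 during the first epoch and
0.5 afterwards (the epoch boundary is a configurable step threshold).
Checkpoints every 10,000 optimizer steps at full scale. The `tiny()`
schedule preset shrinks warmup to 10% of the run and disables accumulation;
a 500-step run on a 5,000-cell corpus takes on the order of a minute on one
CPU and reduces the MLM loss to well under 0.8× its initial value.

All randomness (data order, masking, initialization) flows from explicit
seeds; identical seeds reproduce identical loss trajectories and
parameters.

## Cell embeddings and baselines

The cell embedding is the arithmetic mean of last-layer outputs at
gene-token positions; context tokens and PAD are excluded. Context tokens
are excluded because the modality token's output norm tends to dominate,
biasing the representation toward modality; `token_output_norms` exposes
per-position norms by category as a diagnostic. Embeddings are invariant to
trailing PAD.

The PCA baseline normalizes raw counts to the *train-set* median depth
(both splits, avoiding test leakage), log1p-transforms, and projects onto
components fitted on the train split only.

## Spatial neighborhoods

The neighborhood graph is binary, symmetric and self-loop-free: an edge
joins cells at Euclidean distance ≤ δ_r (inclusive) within the same field
of view; edges never cross FOV boundaries. Derived targets:

* **Density** — the per-cell degree (row sum of the adjacency).
* **Composition** — per cell, the proportions of cell types among its
  neighbors. The default is the row-normalized count vector; a literal
  softmax of the integer counts is retained behind a flag, because a
  softmax of counts is not a proportion and saturates at high degree.
  Zero-degree cells, for which composition is undefined, are excluded and
  reported.
* **Radius calibration** — bisection on the mean degree, bracketed by the
  smallest nearest-neighbor distance and the window diagonal, targeting a
  mean neighbor count (10/20/50/100 in typical use) within a 2% tolerance.
  Because the mean degree is a step function of the radius, the search
  returns the within-tolerance radius when one exists and otherwise the
  evaluated radius whose mean degree came closest. On a unit-intensity
  Poisson process the calibrated radius for a target of 10 neighbors agrees
  with the closed form √(10/π) to within edge effects.

## Downstream heads

Linear probing trains a single linear map on frozen embeddings (AdamW,
lr 1e-3, batch 256; the epoch count is configurable and desk-scale runs use
more than one pass since few optimizer steps fit in a small dataset).
Heads standardize their input features with train-split statistics and are
zero-initialized, so the probe starts at the uniform predictor and its
outcome does not depend on a random initial hyperplane. Classification uses
cross-entropy with no class-imbalance handling; predictions are the argmax
(ties to the lowest class index) with the softmax probability as certainty.
Composition regression is a linear layer + softmax under MSE (predictions
row-stochastic by construction); density regression is scalar linear under
MSE. The multitask MLP shares one GELU hidden layer (default width 256)
with a softmax head per neighborhood size and minimizes the unweighted mean
of per-size MSEs. Fine-tuning jointly updates encoder and head for one
epoch with a cosine decay from 1e-4 to 1e-5 (batch 9, accumulation 10);
macro-F1 averages per-class F1 over classes present in truth or
predictions.

## Attention analysis

For a target token m in a cell's sequence, the per-layer statistics are the
maximum and the mean of A[i, m] over heads and query positions i, excluding
PAD queries and the target position itself ("all other tokens"). Statistics
are averaged over the profiled cells; cells whose panel lacks the target
are skipped and counted. Group contrasts are elementwise absolute
differences of these profiles. Distributional differences are tested with
a two-sided Mann–Whitney U per (layer, token) — exact enumeration for
tie-free samples below a combined n of 25, tie-corrected normal
approximation otherwise — with Benjamini–Hochberg FDR correction across the
family. Ortholog analysis compares input gene-embedding rows by cosine
similarity.

## Stability analysis

Perturbations operate on tokenized cells and never touch context tokens or
sequence length: *rank shuffling* permutes the tokens within a random
fraction of gene positions; *gene dropout* removes a random fraction of
gene tokens, preserving the survivors' order and re-padding. Fractional
counts are rounded up so any nonzero fraction perturbs at least one token.
Stability is the mean silhouette coefficient (Euclidean) of the perturbed
embeddings under ground-truth cell-type labels, reported per fraction with
the unperturbed batch as the exact fraction-0 baseline.

## Synthetic corpus

The simulator provides ground truth for every downstream stage.

* **Dissociated data**: negative-binomial counts (gamma–Poisson, dispersion
  θ = 2) around expected proportions; each cell type overexpresses a
  disjoint marker block (~n_genes/5/n_types genes, ≥5) by the
  `program_effect` fold change (default 8); library sizes lognormal with
  mean depth ≈ 2,500.
* **Spatial data**: cells uniform in 500 µm square fields of view; each FOV
  is partitioned into niche domains by a noisy Voronoi rule (distances to
  random seeds perturbed with Gaussian noise of scale
  (1 − smoothness)·250 µm; default smoothness 0.95 gives contiguous
  domains). The niche drives both the cell-type mixing proportions (one
  dominant type per niche) and a disjoint niche marker program, so niche
  labels are recoverable from expression alone. Only a targeted panel is
  retained — all marker genes plus random fillers, 250 genes of a 500-gene
  universe by default — with lognormal depth around 250 counts per cell,
  giving ~70% zero entries, matching the sparse detection regime of real
  targeted panels. Regions group niche pairs; the train/test split holds
  out whole fields of view.

Identical configurations (including the seed) reproduce byte-identical
datasets. Under the defaults a linear model on log1p counts separates
niches essentially perfectly, which is the substrate on which the
representation-level checks stand.

What the simulator does **not** emulate: segmentation errors, doublets,
ambient RNA, spatially varying detection efficiency, realistic gene–gene
correlation structure beyond block programs, or inter-sample batch
effects. Passing the synthetic benchmarks therefore demonstrates that the
pipeline is internally correct and that the representation preserves the
programmed signal at desk scale — not that the model attains
publication-level transfer performance on real tissue atlases, which
requires corpus sizes and compute far outside this package's scope.

## Desk-scale benchmark sizes

The packaged benchmark pretrains the tiny encoder for 500 steps on a
5,000-cell simulated MERFISH corpus (vocabulary ≈ 1,100 tokens, sequences
of 256), probes niche labels on held-out fields of view (three seeds), and
scores silhouette stability on 1,200 cells. These sizes were chosen so the
full suite runs on a single CPU in minutes while every qualitative claim —
loss near ln|V| at initialization, >20% loss reduction, macro-F1 ≥ 0.8
niche recovery, monotone stability degradation — is still exercised
end-to-end.

## Known limitations

* The encoder is NumPy-based and single-threaded per operation; it is meant
  for desk-scale experiments, not multi-GPU pretraining. bfloat16 and
  distributed training are out of scope.
* Eq.-level ambiguities resolved as documented above: context-token order
  (assay, organism, modality); N includes the context tokens; composition
  defaults to proportions rather than a literal softmax of counts.
* k-nearest-neighbor and anisotropic neighborhoods are not implemented.
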