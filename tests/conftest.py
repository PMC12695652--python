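"""Shared fixtures: small synthetic datasets, a tiny vocabulary/normalizer,
tokenized batches and encoder models reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from nichelm.model import EncoderConfig, build_model
from nichelm.synthetic import SimulationConfig, generate_ortholog_map, generate_spatial
from nichelm.tokenizer import fit_nonzero_means, tokenize_dataset
from nichelm.vocab import build_vocabulary

ALL_ASSAYS = ["dissociated", "MERFISH", "Xenium", "CosMx", "ISS"]


@pytest.fixture(scope="session")
def omap_small():
    return generate_ortholog_map(n_pairs=250, n_human_only=80, n_mouse_only=80, seed=7)


@pytest.fixture(scope="session")
def vocab_small(omap_small):
    return build_vocabulary(omap_small, ALL_ASSAYS)


@pytest.fixture(scope="session")
def spatial_small(omap_small):
    cfg = SimulationConfig(
        n_cells=600, n_genes=250, panel_size=120, n_fovs=3, seed=11
    )
    return generate_spatial(cfg, omap_small, organism="mouse", technology="MERFISH")


@pytest.fixture(scope="session")
def normalizer_small(spatial_small, vocab_small):
    return fit_nonzero_means([spatial_small], vocab_small)


@pytest.fixture(scope="session")
def batch_small(spatial_small, vocab_small, normalizer_small):
    return tokenize_dataset(spatial_small, vocab_small, normalizer_small, seq_len=128)


@pytest.fixture(scope="session")
def model_small(vocab_small):
    cfg = EncoderConfig(
        vocab_size=vocab_small.size, n_layers=2, n_heads=4,
        d_model=32, d_ffn=64, max_len=128,
    )
    return build_model(cfg, seed=3)


# ---------------------------------------------------------------------------
# desk-scale pretraining runs shared by the acceptance tests: a 5,000-cell
# spatial corpus, a tiny encoder (2 layers, 4 heads, d=64) pretrained for
# 500 MLM steps, its embeddings and the niche linear probe; one run per seed,
# computed lazily and cached for the session.
# ---------------------------------------------------------------------------

PRETRAIN_SEEDS = (0, 1, 2)


def run_desk_scale_pipeline(seed: int) -> dict:
    from nichelm.embedding import extract_embeddings
    from nichelm.heads import ProbeConfig, evaluate, predict_labels, train_linear_classifier
    from nichelm.schedule import TrainSchedule
    from nichelm.train import pretrain

    omap = generate_ortholog_map(700, 200, 200, seed=100 + seed)
    cfg = SimulationConfig(n_cells=5000, seed=100 + seed)
    corpus = generate_spatial(cfg, omap, organism="mouse", technology="MERFISH")
    vocab = build_vocabulary(omap, ALL_ASSAYS)
    normalizer = fit_nonzero_means([corpus], vocab)
    batch = tokenize_dataset(corpus, vocab, normalizer, seq_len=256)

    enc_cfg = EncoderConfig(
        vocab_size=vocab.size, n_layers=2, n_heads=4, d_model=64, d_ffn=128, max_len=256
    )
    model = build_model(enc_cfg, seed=seed)
    schedule = TrainSchedule.tiny(total_steps=500, seed=seed)
    trajectory = pretrain(model, batch, schedule)

    embeddings = extract_embeddings(model, batch)
    labels = batch.obs["niche_label"].to_numpy()
    split = batch.obs["split"].to_numpy()
    train_mask, test_mask = split == "train", split == "test"
    clf = train_linear_classifier(
        embeddings[train_mask], labels[train_mask], ProbeConfig(epochs=100, seed=seed)
    )
    pred = predict_labels(clf, embeddings[test_mask])
    macro_f1 = evaluate(pred.labels, labels[test_mask], task="label")
    return dict(
        vocab=vocab, batch=batch, model=model, trajectory=trajectory,
        embeddings=embeddings, labels=labels, split=split,
        classifier=clf, niche_macro_f1=macro_f1,
    )


@pytest.fixture(scope="session")
def desk_runs():
    cache: dict[int, dict] = {}

    def get(seed: int) -> dict:
        if seed not in cache:
            cache[seed] = run_desk_scale_pipeline(seed)
        return cache[seed]

    return get
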