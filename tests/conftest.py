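"""Shared fixtures: simulated corpora and the trained toy models they feed.

Heavy artifacts (pretrained CLMs, the conditional generator, the
reconstructor) are session-scoped so every suite shares one training run.
All randomness is seeded; the suite is deterministic end to end.
"""

from __future__ import annotations

import numpy as np
import pytest

import microformer as mf
from microformer.generation import _genus_axis

MAX_LEN = 64


def _bundle(cfg: mf.SimConfig) -> dict:
    table, labels = mf.simulate_corpus(cfg)
    ft = mf.filter_corpus(table)
    vocab = mf.build_vocab(ft)
    stats = mf.fit_normalization(ft)
    seqs = mf.encode_table(ft, stats, vocab, MAX_LEN)
    return {"cfg": cfg, "table": table, "labels": labels, "filtered": ft,
            "vocab": vocab, "stats": stats, "seqs": seqs}


@pytest.fixture(scope="session")
def cls_bundle():
    """Two-class corpus with strong disjoint markers + a pretrained CLM.

    700 samples, 60 genera, 8 markers/class at effect 8; the CLM is
    pretrained on the first 500 samples, leaving 200 for supervised tasks.
    """
    cfg = mf.SimConfig(n_samples=700, n_genera=60, n_classes=2,
                       markers_per_class=8, marker_effect=8.0, sparsity=0.8,
                       min_present=10, seed=21)
    b = _bundle(cfg)
    model = mf.build_model(mf.toy_config(b["vocab"].size, seed=0, max_len=MAX_LEN),
                           vocab=b["vocab"])
    b["fresh_model"] = model
    b["pretrained"], b["pretrain_history"] = mf.pretrain_clm(
        model, b["seqs"][:500],
        mf.TrainConfig(batch_size=50, warmup_steps=100, max_epochs=100,
                       patience=6, seed=0))
    return b


@pytest.fixture(scope="session")
def keystone_bundle():
    """One-class corpus with a planted keystone (30% coupled taxa) + CLM."""
    cfg = mf.SimConfig(n_samples=700, n_genera=60, n_classes=1,
                       markers_per_class=0, marker_effect=1.0,
                       keystone_genera=1, keystone_coupling=0.3,
                       keystone_boost=8.0, sparsity=0.8, min_present=10, seed=31)
    b = _bundle(cfg)
    model = mf.build_model(mf.toy_config(b["vocab"].size, seed=0, max_len=MAX_LEN),
                           vocab=b["vocab"])
    b["pretrained"], _ = mf.pretrain_clm(
        model, b["seqs"][:500],
        mf.TrainConfig(batch_size=50, warmup_steps=100, max_epochs=120,
                       patience=8, seed=0))
    b["screen_seqs"] = b["seqs"][500:700]  # 200 held-out samples
    return b


@pytest.fixture(scope="session")
def null_bundle():
    """Exchangeable-genera corpus (no markers, no keystone) + CLM."""
    cfg = mf.SimConfig(n_samples=500, n_genera=60, n_classes=1,
                       markers_per_class=0, marker_effect=1.0,
                       keystone_genera=0, keystone_coupling=0.0,
                       sparsity=0.8, min_present=10, seed=51)
    b = _bundle(cfg)
    model = mf.build_model(mf.toy_config(b["vocab"].size, seed=0, max_len=MAX_LEN),
                           vocab=b["vocab"])
    b["pretrained"], _ = mf.pretrain_clm(
        model, b["seqs"][:300],
        mf.TrainConfig(batch_size=50, warmup_steps=100, max_epochs=60,
                       patience=5, seed=0))
    b["screen_seqs"] = b["seqs"][300:500]
    return b


@pytest.fixture(scope="session")
def turing_bundle(tmp_path_factory):
    """Conditional generator, reconstructor, and real/generated/random tables.

    1200 samples (1000 generator-training, 200 held-out real test); 100
    samples generated per label at temperature 0.9; the reconstructor is
    trained on the real training pairs.
    """
    cfg = mf.SimConfig(n_samples=1200, n_genera=60, n_classes=2,
                       markers_per_class=8, marker_effect=8.0, sparsity=0.8,
                       min_present=10, seed=41)
    b = _bundle(cfg)
    ft, vocab, stats, seqs, labels = (b["filtered"], b["vocab"], b["stats"],
                                      b["seqs"], b["labels"])
    model = mf.build_model(mf.toy_config(vocab.size, seed=0, max_len=MAX_LEN),
                           vocab=vocab)
    gen_model, gh = mf.finetune_generator(
        model, seqs[:1000],
        mf.TrainConfig(batch_size=50, warmup_steps=200, max_epochs=60,
                       patience=5, seed=0))
    b["gen_model"] = gen_model
    b["gen_history"] = gh
    gens = []
    for lab in ("class0", "class1"):
        gens += mf.generate(gen_model, lab,
                            mf.GenerationParams(n_samples=100, seed=7,
                                                max_new_tokens=40,
                                                min_new_tokens=5,
                                                temperature=0.9))
    b["gen_seqs"] = gens
    X, Y = mf.pairs_from_table(ft, vocab, stats, MAX_LEN)
    rec, _ = mf.train_reconstructor(
        X[:1000], Y[:1000],
        mf.ReconstructorConfig(max_epochs=300, patience=15, seed=0),
        genus_axis=_genus_axis(vocab))
    b["reconstructor"] = rec
    Yg = mf.reconstruct(rec, gens, vocab)
    b["gen_table"] = mf.AbundanceTable(
        [s.sample_id for s in gens], _genus_axis(vocab), Yg,
        {s.sample_id: s.label for s in gens})
    b["real_train"] = mf.AbundanceTable(
        ft.sample_ids[:1000], ft.genus_names, ft.values[:1000],
        {s: labels[s] for s in ft.sample_ids[:1000]})
    b["real_test"] = mf.AbundanceTable(
        ft.sample_ids[1000:], ft.genus_names, ft.values[1000:],
        {s: labels[s] for s in ft.sample_ids[1000:]})
    rng = np.random.default_rng(9)
    rnd_ids = [f"rnd{i:04d}" for i in range(200)]
    b["random_table"] = mf.AbundanceTable(
        rnd_ids, list(ft.genus_names),
        rng.dirichlet(np.ones(ft.n_genera), 200),
        {sid: ("class0" if i < 100 else "class1")
         for i, sid in enumerate(rnd_ids)})
    return b


@pytest.fixture(scope="session")
def tiny_bundle():
    """A minimal corpus/vocab/model for cheap structural tests."""
    cfg = mf.SimConfig(n_samples=30, n_genera=30, sparsity=0.6,
                       min_present=10, seed=3)
    b = _bundle(cfg)
    b["model"] = mf.build_model(
        mf.toy_config(b["vocab"].size, seed=0, max_len=MAX_LEN),
        vocab=b["vocab"])
    return b
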