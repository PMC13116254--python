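"""Label-conditioned generation, perplexity, and the abundance reconstructor."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import microformer as mf
from microformer.generation import (
    GenerationError, insert_label_token, rank_positions_to_input, _genus_axis,
    _softmax,
)


class TestVocabExtension:
    def test_seventeen_labels_grow_size_by_seventeen(self, tiny_bundle):
        vocab = tiny_bundle["vocab"]
        labels = [f"disease{i:02d}" for i in range(17)]
        ext = mf.extend_vocab_with_labels(vocab, labels)
        assert ext.size == vocab.size + 17

    def test_zero_labels_is_identity(self, tiny_bundle):
        vocab = tiny_bundle["vocab"]
        ext = mf.extend_vocab_with_labels(vocab, [])
        assert ext.genus_to_id == vocab.genus_to_id
        assert ext.size == vocab.size

    def test_existing_ids_never_reindexed(self, tiny_bundle):
        vocab = tiny_bundle["vocab"]
        ext = mf.extend_vocab_with_labels(vocab, ["gut", "soil"])
        assert ext.genus_to_id == vocab.genus_to_id
        assert ext.special == vocab.special
        assert min(ext.label_tokens.values()) == vocab.size

    def test_collision_with_genus_rejected(self, tiny_bundle):
        vocab = tiny_bundle["vocab"]
        genus = next(iter(vocab.genus_to_id))
        with pytest.raises(GenerationError, match="collide"):
            mf.extend_vocab_with_labels(vocab, [genus])

    def test_label_token_placed_after_bos(self, tiny_bundle):
        vocab = mf.extend_vocab_with_labels(tiny_bundle["vocab"], ["gut"])
        src = tiny_bundle["seqs"][0]
        seq = mf.TokenSequence(list(src.token_ids), list(src.genus_order),
                               src.sample_id, "gut")
        out = insert_label_token(seq, vocab)
        assert out.token_ids[0] == vocab.bos_id
        assert out.token_ids[1] == vocab.label_tokens["gut"]
        assert out.token_ids[2:] == seq.token_ids[1:]

    def test_label_counts_toward_max_len(self, tiny_bundle):
        vocab = mf.extend_vocab_with_labels(tiny_bundle["vocab"], ["gut"])
        src = tiny_bundle["seqs"][0]
        seq = mf.TokenSequence(list(src.token_ids), list(src.genus_order),
                               src.sample_id, "gut")
        out = insert_label_token(seq, vocab, max_len=len(seq.token_ids))
        assert len(out.token_ids) == len(seq.token_ids)
        assert len(out.genus_order) == len(seq.genus_order) - 1
        assert out.token_ids[-1] == vocab.eos_id


class TestGenerate:
    def test_sequences_start_with_label_and_end_with_eos(self, turing_bundle):
        vocab = turing_bundle["gen_model"].vocab
        for seq in turing_bundle["gen_seqs"][:20]:
            assert seq.token_ids[0] == vocab.bos_id
            assert vocab.label_for(seq.token_ids[1]) == seq.label
            assert seq.token_ids[-1] == vocab.eos_id

    def test_forbid_repeats_holds_in_every_sequence(self, turing_bundle):
        for seq in turing_bundle["gen_seqs"]:
            assert len(set(seq.genus_order)) == len(seq.genus_order)

    def test_same_seed_reproduces_sequences(self, turing_bundle):
        params = mf.GenerationParams(n_samples=3, seed=13, max_new_tokens=20)
        a = mf.generate(turing_bundle["gen_model"], "class0", params)
        b = mf.generate(turing_bundle["gen_model"], "class0", params)
        assert [s.token_ids for s in a] == [s.token_ids for s in b]

    def test_temperature_zero_is_greedy_argmax(self, turing_bundle):
        model = turing_bundle["gen_model"]
        vocab = model.vocab
        out = mf.generate(model, "class0",
                          mf.GenerationParams(n_samples=1, seed=0,
                                              temperature=0.0,
                                              max_new_tokens=10))[0]
        # replay the greedy rollout by hand
        ids = [vocab.bos_id, vocab.label_tokens["class0"]]
        never = (set(vocab.special.values()) - {vocab.eos_id}) \
            | set(vocab.label_tokens.values())
        emitted = set()
        while len(ids) < len(out.token_ids):
            logits = model.logits(ids)[-1].copy()
            logits[list(never)] = -np.inf
            if not emitted:
                logits[vocab.eos_id] = -np.inf
            if emitted:
                logits[list(emitted)] = -np.inf
            if len(emitted) >= 10:
                nxt = vocab.eos_id
            else:
                nxt = int(np.argmax(logits))
            ids.append(nxt)
            if nxt == vocab.eos_id:
                break
            emitted.add(nxt)
        assert ids == out.token_ids

    def test_unknown_label_rejected(self, turing_bundle):
        with pytest.raises(GenerationError, match="unknown label"):
            mf.generate(turing_bundle["gen_model"], "nonexistent",
                        mf.GenerationParams(n_samples=1))

    def test_label_conditioning_prefers_own_markers(self, turing_bundle):
        # P(class-0 marker | bos, label_0) > P(class-1 marker | bos, label_0)
        model = turing_bundle["gen_model"]
        vocab = model.vocab
        markers = mf.marker_genera(turing_bundle["cfg"])
        for lab, other in (("class0", "class1"), ("class1", "class0")):
            ids = [vocab.bos_id, vocab.label_tokens[lab]]
            probs = np.asarray(_softmax(model.logits(ids)[-1]))
            own = sum(probs[vocab.genus_to_id[g]] for g in markers[lab]
                      if g in vocab.genus_to_id)
            foreign = sum(probs[vocab.genus_to_id[g]] for g in markers[other]
                          if g in vocab.genus_to_id)
            assert own > foreign


class TestPerplexity:
    def test_uniform_model_scores_vocab_size(self, tiny_bundle):
        model, vocab = tiny_bundle["model"], tiny_bundle["vocab"]
        for seq in tiny_bundle["seqs"][:3]:
            assert mf.perplexity(model, seq) == pytest.approx(vocab.size)

    def test_short_sequence_rejected(self, tiny_bundle):
        with pytest.raises(GenerationError, match="length"):
            mf.perplexity(tiny_bundle["model"],
                          mf.TokenSequence([tiny_bundle["vocab"].bos_id], []))

    def test_generated_not_less_plausible_than_held_out(self, turing_bundle):
        # the generator samples from its own distribution, so its output
        # should score at most the held-out real perplexity on average
        model = turing_bundle["gen_model"]
        vocab = model.vocab
        real = [insert_label_token(s, vocab) for s in turing_bundle["seqs"][1000:1100]]
        ppl_gen = np.mean([mf.perplexity(model, s)
                           for s in turing_bundle["gen_seqs"][:100]])
        ppl_real = np.mean([mf.perplexity(model, s) for s in real])
        assert ppl_gen <= ppl_real


class TestReconstructorEncoding:
    def test_rank_one_is_sin_one_plus_one(self):
        x = rank_positions_to_input([4], 10)
        assert x[4] == pytest.approx(np.sin(1) + 1, abs=1e-12)
        assert x[4] == pytest.approx(1.8415, abs=1e-4)

    def test_absent_exactly_zero_and_range_bounded(self):
        x = rank_positions_to_input([2, 0, 7], 10)
        assert set(np.flatnonzero(x)) == {0, 2, 7}
        assert x.min() >= 0.0 and x.max() <= 2.0

    def test_sequence_encoding_matches_rank_positions(self, tiny_bundle):
        vocab = tiny_bundle["vocab"]
        seq = tiny_bundle["seqs"][0]
        x = mf.build_reconstructor_input(seq, vocab)
        axis = {g: j for j, g in enumerate(_genus_axis(vocab))}
        for pos, genus in enumerate(seq.genus_order, start=1):
            assert x[axis[genus]] == pytest.approx(np.sin(pos) + 1)


class TestReconstructor:
    def test_outputs_live_on_the_simplex(self, turing_bundle):
        rec = turing_bundle["reconstructor"]
        rng = np.random.default_rng(0)
        X = np.zeros((5, rec.n_genera))
        for i in range(5):
            sel = rng.choice(rec.n_genera, 8, replace=False)
            X[i] = rank_positions_to_input(sel, rec.n_genera)
        Y = mf.reconstruct(rec, X, mask_absent=False)
        np.testing.assert_allclose(Y.sum(axis=1), 1.0, atol=1e-6)
        assert (Y > 0).all()

    def test_masking_zeroes_absent_and_renormalizes(self, turing_bundle):
        rec = turing_bundle["reconstructor"]
        x = rank_positions_to_input([1, 5, 9], rec.n_genera)
        y = mf.reconstruct(rec, x[None, :], mask_absent=True)[0]
        assert set(np.flatnonzero(y)) == {1, 5, 9}
        assert y.sum() == pytest.approx(1.0)

    def test_deterministic(self, turing_bundle):
        rec = turing_bundle["reconstructor"]
        x = rank_positions_to_input([0, 3], rec.n_genera)[None, :]
        np.testing.assert_array_equal(mf.reconstruct(rec, x),
                                      mf.reconstruct(rec, x))

    def test_untrained_rejected(self):
        from microformer.generation import Reconstructor
        rec = Reconstructor.init(8, seed=0)
        with pytest.raises(GenerationError, match="trained"):
            mf.reconstruct(rec, np.zeros((1, 8)))

    def test_mismatched_width_rejected(self, turing_bundle):
        rec = turing_bundle["reconstructor"]
        with pytest.raises(GenerationError, match="width"):
            mf.reconstruct(rec, np.zeros((1, rec.n_genera + 3)))

    def test_training_pairs_must_match_shape(self):
        with pytest.raises(GenerationError, match="must match"):
            mf.train_reconstructor(np.zeros((4, 6)), np.zeros((4, 5)))

    def test_save_load_round_trip(self, tmp_path, turing_bundle):
        rec = turing_bundle["reconstructor"]
        rec.save(tmp_path / "rec")
        from microformer.generation import Reconstructor
        back = Reconstructor.load(tmp_path / "rec")
        x = rank_positions_to_input([0, 2, 4], rec.n_genera)[None, :]
        np.testing.assert_allclose(mf.reconstruct(back, x),
                                   mf.reconstruct(rec, x), atol=1e-12)


class TestFinetuneGenerator:
    def test_unlabeled_sample_rejected(self, tiny_bundle):
        seqs = [mf.TokenSequence(list(s.token_ids), list(s.genus_order),
                                 s.sample_id, None)
                for s in tiny_bundle["seqs"][:10]]
        with pytest.raises(GenerationError, match="unlabeled"):
            mf.finetune_generator(tiny_bundle["model"], seqs,
                                  mf.TrainConfig(batch_size=4, seed=0))

    def test_generator_memorizes_single_sequence(self, tiny_bundle):
        src = tiny_bundle["seqs"][0]
        seq = mf.TokenSequence(list(src.token_ids), list(src.genus_order),
                               src.sample_id, "only")
        corpus = [seq] * 150
        model, hist = mf.finetune_generator(
            tiny_bundle["model"], corpus,
            mf.TrainConfig(batch_size=16, warmup_steps=20, max_epochs=30,
                           patience=5, seed=0))
        assert hist.best_val_loss < 0.1
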