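"""Rank-value encoding: normalization stats, ordering, truncation, decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microformer as mf
from microformer.encoding import EncodingError

from test_corpus_io import make_table


def identity_stats(genera):
    return mf.NormalizationStats(list(genera), np.zeros(len(genera)),
                                 np.ones(len(genera)), 1)


@pytest.fixture()
def abc_vocab():
    return mf.build_vocab(make_table([[0.4, 0.3, 0.3]], genera=["A", "B", "C"]))


class TestFitNormalization:
    def test_hand_computed_mean_and_population_sd(self):
        # genus values (0.2, 0.4): mu = 0.3, population SD = 0.1
        table = make_table([[0.2, 0.8], [0.4, 0.6]])
        stats = mf.fit_normalization(table)
        assert stats.mu[0] == pytest.approx(0.3)
        assert stats.sigma[0] == pytest.approx(0.1)

    def test_constant_genus_normalizes_to_zero(self):
        table = make_table([[0.5, 0.5], [0.5, 0.5]])
        stats = mf.fit_normalization(table)
        assert stats.sigma[0] == 0.0
        assert stats.zscore("g0", 0.5) == 0.0

    def test_refit_is_identical(self, tiny_bundle):
        s1 = mf.fit_normalization(tiny_bundle["filtered"])
        s2 = mf.fit_normalization(tiny_bundle["filtered"])
        np.testing.assert_array_equal(s1.mu, s2.mu)
        np.testing.assert_array_equal(s1.sigma, s2.sigma)

    def test_empty_table_rejected(self):
        with pytest.raises(EncodingError):
            mf.fit_normalization(mf.AbundanceTable([], ["g0"], np.zeros((0, 1))))

    def test_json_round_trip(self, tmp_path, tiny_bundle):
        stats = tiny_bundle["stats"]
        stats.save(tmp_path / "stats.json")
        back = mf.NormalizationStats.load(tmp_path / "stats.json")
        np.testing.assert_allclose(back.mu, stats.mu, rtol=1e-12)
        np.testing.assert_allclose(back.sigma, stats.sigma, rtol=1e-12)


class TestRankEncode:
    def test_identity_stats_order_by_value(self, abc_vocab):
        stats = identity_stats(["A", "B", "C"])
        seq = mf.rank_encode(np.array([0.5, 0.3, 0.2]), stats, abc_vocab,
                             genus_names=["A", "B", "C"])
        assert seq.genus_order == ["A", "B", "C"]
        assert seq.token_ids[0] == abc_vocab.bos_id
        assert seq.token_ids[-1] == abc_vocab.eos_id

    def test_tie_break_larger_raw_then_lexicographic(self, abc_vocab):
        stats = identity_stats(["A", "B", "C"])
        seq = mf.rank_encode(np.array([0.4, 0.4, 0.2]), stats, abc_vocab,
                             genus_names=["A", "B", "C"])
        assert seq.genus_order == ["A", "B", "C"]  # tie A/B -> lexicographic
        again = mf.rank_encode(np.array([0.4, 0.4, 0.2]), stats, abc_vocab,
                               genus_names=["A", "B", "C"])
        assert again.token_ids == seq.token_ids

    def test_truncation_keeps_highest_ranked(self):
        n = 600
        genera = [f"g{j:03d}" for j in range(n)]
        vals = np.linspace(1.0, 2.0, n)
        vals = vals / vals.sum()
        table = make_table(vals[None, :], genera=genera)
        vocab = mf.build_vocab(table)
        stats = identity_stats(genera)
        seq = mf.rank_encode(vals, stats, vocab, max_len=512, genus_names=genera)
        assert len(seq) == 512
        assert len(seq.genus_order) == 510
        # oracle: sort descending, slice the top 510
        expected = [genera[j] for j in np.argsort(-vals, kind="stable")][:510]
        assert seq.genus_order == expected

    def test_zscore_can_reorder_raw_abundances(self):
        # per-genus affine map: a smaller raw value can outrank a larger one
        genera = ["A", "B"]
        stats = mf.NormalizationStats(genera, np.array([0.5, 0.0]),
                                      np.array([0.01, 10.0]), 2)
        vocab = mf.build_vocab(make_table([[0.5, 0.5]], genera=genera))
        seq = mf.rank_encode(np.array([0.4, 0.6]), stats, vocab,
                             genus_names=genera)
        # z(A) = -10, z(B) = 0.06 -> B first despite both being comparable
        assert seq.genus_order == ["B", "A"]

    def test_all_zero_row_rejected(self, abc_vocab):
        stats = identity_stats(["A", "B", "C"])
        with pytest.raises(EncodingError, match="nonzero"):
            mf.rank_encode(np.zeros(3), stats, abc_vocab,
                           genus_names=["A", "B", "C"])

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_column_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((3, 12)) * (rng.random((3, 12)) < 0.6)
        vals[:, 0] = 0.5  # ensure at least one nonzero per row
        vals = vals / vals.sum(1, keepdims=True)
        table = make_table(vals)
        vocab = mf.build_vocab(table)
        stats = mf.fit_normalization(table)
        base = [s.genus_order for s in mf.encode_table(table, stats, vocab)]
        perm = rng.permutation(12)
        shuffled = mf.AbundanceTable(
            table.sample_ids, [table.genus_names[j] for j in perm],
            vals[:, perm])
        other = [s.genus_order
                 for s in mf.encode_table(shuffled, stats, vocab)]
        assert base == other

    def test_raising_abundance_never_lowers_rank(self, tiny_bundle):
        ft, stats, vocab = (tiny_bundle["filtered"], tiny_bundle["stats"],
                            tiny_bundle["vocab"])
        row = ft.values[0].copy()
        target = int(np.flatnonzero(row)[-1])
        name = ft.genus_names[target]
        before = mf.rank_encode(row, stats, vocab, genus_names=ft.genus_names)
        row2 = row.copy()
        row2[target] *= 3.0
        after = mf.rank_encode(row2, stats, vocab, genus_names=ft.genus_names)
        assert after.genus_order.index(name) <= before.genus_order.index(name)

    def test_no_truncation_when_within_context(self, cls_bundle):
        # sparse corpus: every sample fits the 512-token context untruncated
        ft, stats, vocab = (cls_bundle["filtered"], cls_bundle["stats"],
                            cls_bundle["vocab"])
        for i in range(ft.n_samples):
            n_present = int((ft.values[i] > 0).sum())
            seq = mf.rank_encode(ft.values[i], stats, vocab, max_len=512,
                                 genus_names=ft.genus_names)
            assert len(seq.genus_order) == n_present


class TestDecode:
    def test_encode_decode_round_trip(self, tiny_bundle):
        for seq in tiny_bundle["seqs"][:10]:
            assert mf.decode_tokens(seq, tiny_bundle["vocab"]) == seq.genus_order

    def test_bos_eos_only_is_empty(self, tiny_bundle):
        vocab = tiny_bundle["vocab"]
        seq = mf.TokenSequence([vocab.bos_id, vocab.eos_id], [])
        assert mf.decode_tokens(seq, vocab) == []

    def test_label_token_excluded(self, tiny_bundle):
        vocab = mf.extend_vocab_with_labels(tiny_bundle["vocab"], ["gut"])
        gid = next(iter(vocab.genus_to_id.values()))
        genus = vocab.genus_for(gid)
        seq = mf.TokenSequence(
            [vocab.bos_id, vocab.label_tokens["gut"], gid, vocab.eos_id],
            [genus], label="gut")
        assert mf.decode_tokens(seq, vocab) == [genus]

    def test_unknown_id_names_position(self, tiny_bundle):
        vocab = tiny_bundle["vocab"]
        seq = mf.TokenSequence([vocab.bos_id, vocab.size + 50, vocab.eos_id], [])
        with pytest.raises(EncodingError, match="position 1"):
            mf.decode_tokens(seq, vocab)

    def test_corpus_jsonl_round_trip(self, tmp_path, tiny_bundle):
        path = tmp_path / "corpus.jsonl"
        mf.write_corpus_jsonl(tiny_bundle["seqs"], path)
        back = mf.read_corpus_jsonl(path)
        assert len(back) == len(tiny_bundle["seqs"])
        for a, b in zip(back, tiny_bundle["seqs"]):
            assert a.token_ids == b.token_ids
            assert a.genus_order == b.genus_order
            assert a.sample_id == b.sample_id
            assert a.label == b.label
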