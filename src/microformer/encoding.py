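"""Rank-value encoding: abundance rows -> ordered genus-token sequences.

A sample is represented by its genera sorted by z-normalized abundance
(largest first, rank 1), wrapped in ``bos``/``eos``. Magnitudes are
discarded; the reconstructor module recovers them. Normalization statistics
(per-genus mean and standard deviation over the training corpus, zeros
included, population convention) are fitted once on training data and
frozen.

Because z-scoring is a per-genus affine map, the within-sample rank order
can legitimately differ from the raw-abundance order whenever genera have
different mu/sigma.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import AbundanceTable, Vocabulary

__all__ = [
    "NormalizationStats",
    "TokenSequence",
    "fit_normalization",
    "rank_encode",
    "encode_table",
    "decode_tokens",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
]

logger = logging.getLogger(__name__)

MAX_LEN = 512  # transformer context length, specials included


class EncodingError(ValueError):
    pass


@dataclass
class TokenSequence:
    """One sample as an ordered token-id list: [bos, rank-1 genus, ..., eos].

    ``genus_order`` parallels the non-special, non-label tokens; rank 1
    (largest normalized abundance) comes first. A label token, when present,
    sits immediately after bos and is not part of ``genus_order``.
    """

    token_ids: list[int]
    genus_order: list[str]
    sample_id: str = ""
    label: str | None = None

    def __len__(self) -> int:
        return len(self.token_ids)


@dataclass
class NormalizationStats:
    """Frozen per-genus mean/SD of relative abundance over a training table.

    Population (divide-by-n) standard deviation; zeros are included, i.e.
    the statistics run over every training sample, not only those where the
    genus occurs.
    """

    genus_names: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    n_samples: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (np.isfinite(self.mu).all() and np.isfinite(self.sigma).all()):
            raise EncodingError("non-finite normalization statistics")
        if (self.sigma < 0).any():
            raise EncodingError("negative sigma")
        self._index = {g: j for j, g in enumerate(self.genus_names)}

    def zscore(self, genus: str, value: float) -> float:
        """(x - mu)/sigma; genera with sigma = 0 normalize to 0 by convention."""
        j = self._index[genus]
        if self.sigma[j] == 0.0:
            return 0.0
        return (value - self.mu[j]) / self.sigma[j]

    def to_json(self) -> str:
        return json.dumps(
            {"n_samples": self.n_samples,
             "genera": {g: [self.mu[j], self.sigma[j]]
                        for j, g in enumerate(self.genus_names)}},
            indent=1, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        obj = json.loads(text)
        genera = list(obj["genera"])
        mu = np.array([obj["genera"][g][0] for g in genera])
        sigma = np.array([obj["genera"][g][1] for g in genera])
        return cls(genera, mu, sigma, int(obj["n_samples"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationStats":
        return cls.from_json(Path(path).read_text())


def fit_normalization(table: AbundanceTable) -> NormalizationStats:
    """Per-genus mean and population SD over all samples of a training table."""
    if table.n_samples == 0:
        raise EncodingError("cannot fit normalization on an empty table")
    mu = table.values.mean(axis=0)
    sigma = table.values.std(axis=0)  # population convention (ddof=0)
    return NormalizationStats(list(table.genus_names), mu, sigma, table.n_samples)


def rank_encode(row: np.ndarray, stats: NormalizationStats, vocab: Vocabulary,
                max_len: int = MAX_LEN, sample_id: str = "",
                genus_names: list[str] | None = None) -> TokenSequence:
    """Encode one abundance row as [bos, rank-1 genus, ..., rank-n genus, eos].

    Nonzero entries are z-scored with the frozen ``stats`` and sorted
    descending; ties break toward the larger raw abundance, then
    lexicographic genus name, so sequences are deterministic. If more genera
    are present than fit in ``max_len`` (which counts bos and eos), the
    lowest-ranked ones are truncated. Genera missing from the vocabulary map
    to unk and are dropped (logged).
    """
    genus_names = genus_names if genus_names is not None else stats.genus_names
    row = np.asarray(row, dtype=float)
    if row.shape != (len(genus_names),):
        raise EncodingError(
            f"row length {row.shape} does not match {len(genus_names)} genera"
        )
    present = np.flatnonzero(row > 0)
    if present.size == 0:
        raise EncodingError(f"sample {sample_id!r} has no nonzero genera")
    keyed = []
    n_unk = 0
    for j in present:
        g = genus_names[j]
        if g not in vocab.genus_to_id:
            n_unk += 1
            continue
        z = stats.zscore(g, row[j]) if g in stats._index else 0.0
        keyed.append((-z, -row[j], g))
    if n_unk:
        logger.info("sample %s: dropped %d genera absent from vocabulary",
                    sample_id, n_unk)
    if not keyed:
        raise EncodingError(f"sample {sample_id!r} has no in-vocabulary genera")
    keyed.sort()
    room = max_len - 2
    keyed = keyed[:room]
    order = [g for _, _, g in keyed]
    ids = [vocab.bos_id] + [vocab.genus_to_id[g] for g in order] + [vocab.eos_id]
    return TokenSequence(ids, order, sample_id=sample_id)


def encode_table(table: AbundanceTable, stats: NormalizationStats,
                 vocab: Vocabulary, max_len: int = MAX_LEN) -> list[TokenSequence]:
    """Rank-encode every row of a table; labels travel with the sequences."""
    seqs = []
    for i, sid in enumerate(table.sample_ids):
        seq = rank_encode(table.values[i], stats, vocab, max_len,
                          sample_id=sid, genus_names=table.genus_names)
        if table.labels and sid in table.labels:
            seq.label = table.labels[sid]
        seqs.append(seq)
    return seqs


def decode_tokens(seq: TokenSequence, vocab: Vocabulary) -> list[str]:
    """Genus names of the non-special, non-label tokens in sequence order."""
    out = []
    for pos, tid in enumerate(seq.token_ids):
        if vocab.is_special(tid) or vocab.label_for(tid) is not None:
            continue
        g = vocab.genus_for(tid)
        if g is None:
            raise EncodingError(f"unknown token id {tid} at position {pos}")
        out.append(g)
    return out


def write_corpus_jsonl(seqs: list[TokenSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            rec = {"sample_id": s.sample_id, "tokens": list(map(int, s.token_ids)),
                   "genera": s.genus_order}
            if s.label is not None:
                rec["label"] = s.label
            fh.write(json.dumps(rec) + "\n")


def read_corpus_jsonl(path: str | Path) -> list[TokenSequence]:
    seqs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            seqs.append(TokenSequence(list(rec["tokens"]), list(rec["genera"]),
                                      rec.get("sample_id", ""), rec.get("label")))
    return seqs
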