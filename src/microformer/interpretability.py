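"""Attention-based genus importance and leave-one-genus-out perturbation.

Attention importance follows the one-hot value trick: with V replaced by
one-hot position indicators, row q of softmax(QK^T/sqrt(d_k)) V^0 is exactly
the attention probability row, so the analysis exports the probability
matrices directly, averages them elementwise over all layers and heads, and
sums each genus column to get the total attention that genus receives from
the rest of the community.

Leave-one-genus-out perturbation deletes a single genus token from a
sample's rank sequence (remaining order preserved), recomputes the sample
embedding, and reports 1 - cosine similarity as the deleterious score:
taxa whose removal most disrupts the learned community context — keystone
candidates — score highest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import cosine_similarity
from .encoding import TokenSequence
from .model_core import Model, sample_embedding

__all__ = [
    "AttentionSummary",
    "PerturbationResult",
    "aggregate_attention",
    "group_attention_profile",
    "perturb_genus",
    "perturbation_screen",
]


@dataclass
class AttentionSummary:
    """Layer/head-averaged attention matrix and per-genus received attention.

    ``matrix`` is (T, T); rows are probability distributions over the
    causally visible positions. ``genus_scores[g]`` is the column sum at
    g's position (special-token columns are excluded from the scores).
    """

    matrix: np.ndarray
    genus_scores: dict[str, float]
    sample_id: str = ""


def aggregate_attention(model: Model, seq: TokenSequence,
                        include_specials: bool = False) -> AttentionSummary:
    """Elementwise mean of all layers x heads attention, plus column sums."""
    if model.head != "lm" and model.head != "classifier":
        raise ValueError("model exposes no attention")
    mats = model.attention_matrices(list(seq.token_ids))  # (L, H, T, T)
    mean_mat = mats.mean(axis=(0, 1))
    vocab = model.vocab
    scores: dict[str, float] = {}
    col_sums = mean_mat.sum(axis=0)
    for pos, tid in enumerate(seq.token_ids):
        genus = vocab.genus_for(tid) if vocab is not None else None
        if genus is None:
            if not include_specials:
                continue
            genus = f"<token {tid}>"
        scores[genus] = float(col_sums[pos])
    return AttentionSummary(mean_mat, scores, seq.sample_id)


def group_attention_profile(model: Model, corpus: Sequence[TokenSequence],
                            groups: Sequence[str] | dict[str, str]) -> pd.DataFrame:
    """Per-genus mean attention per group plus a two-group KS comparison.

    Scores are averaged over the samples that contain the genus; a genus
    absent from every sample of a group gets NaN there. With exactly two
    groups, a two-sided Kolmogorov-Smirnov test compares the per-sample
    attention-score distributions genus by genus.
    """
    if isinstance(groups, dict):
        groups = [groups[s.sample_id] for s in corpus]
    if len(groups) != len(corpus):
        raise ValueError("one group label per sample required")
    names = sorted(set(groups))
    if any(sum(1 for g in groups if g == name) < 2 for name in names):
        raise ValueError("need >= 2 samples per group")
    per_group: dict[str, dict[str, list[float]]] = {n: {} for n in names}
    for seq, grp in zip(corpus, groups):
        summary = aggregate_attention(model, seq)
        for genus, score in summary.genus_scores.items():
            per_group[grp].setdefault(genus, []).append(score)
    all_genera = sorted({g for d in per_group.values() for g in d})
    rows = []
    for genus in all_genera:
        row: dict[str, object] = {"genus": genus}
        for name in names:
            vals = per_group[name].get(genus)
            row[f"mean_{name}"] = float(np.mean(vals)) if vals else np.nan
            row[f"n_{name}"] = len(vals) if vals else 0
        if len(names) == 2:
            a = per_group[names[0]].get(genus)
            b = per_group[names[1]].get(genus)
            if a and b:
                if a == b:
                    row["ks_stat"], row["ks_p"] = 0.0, 1.0
                else:
                    ks = sps.ks_2samp(a, b)
                    row["ks_stat"], row["ks_p"] = float(ks.statistic), float(ks.pvalue)
            else:
                row["ks_stat"], row["ks_p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("genus")


@dataclass
class PerturbationResult:
    """Embedding shift caused by deleting one genus from one sample."""

    genus: str
    cosine_similarity: float
    deleterious_score: float
    sample_id: str = ""


def _default_mode(model: Model) -> str:
    # pretrained models pool genus tokens; fine-tuned classifiers read eos
    return "eos_token" if model.head == "classifier" else "mean_pool"


def perturb_genus(model: Model, seq: TokenSequence, genus: str,
                  mode: str | None = None) -> PerturbationResult:
    """Delete ``genus`` from the sequence and measure the embedding shift.

    A genus absent from the sample leaves the input unchanged, so the
    cosine similarity is exactly 1 and the deleterious score exactly 0.
    """
    mode = mode or _default_mode(model)
    if genus not in seq.genus_order:
        return PerturbationResult(genus, 1.0, 0.0, seq.sample_id)
    if len(seq.genus_order) < 2:
        raise ValueError("cannot remove the only genus in a sample")
    vocab = model.vocab
    gid = vocab.genus_to_id[genus] if vocab is not None else None
    if gid is None:
        raise ValueError("model has no vocabulary attached")
    kept_ids = [t for t in seq.token_ids if t != gid]
    kept_order = [g for g in seq.genus_order if g != genus]
    reduced = TokenSequence(kept_ids, kept_order, seq.sample_id, seq.label)
    before = sample_embedding(model, seq, mode).vector
    after = sample_embedding(model, reduced, mode).vector
    cos = cosine_similarity(before, after)
    return PerturbationResult(genus, cos, 1.0 - cos, seq.sample_id)


def perturbation_screen(model: Model, corpus: Sequence[TokenSequence],
                        genera: Sequence[str] | None = None,
                        mode: str | None = None) -> pd.DataFrame:
    """Mean +/- SD deleterious score per genus over the samples containing it.

    Returns a DataFrame sorted by descending mean score with columns
    ``mean_score``, ``sd_score``, ``n_samples``. Samples that lack a genus
    contribute nothing to its statistics.
    """
    mode = mode or _default_mode(model)
    if genera is None:
        genera = sorted({g for s in corpus for g in s.genus_order})
    vocab = model.vocab
    collected: dict[str, list[float]] = {g: [] for g in genera}
    wanted = set(genera)
    for seq in corpus:
        present = [g for g in seq.genus_order if g in wanted]
        if not present or len(seq.genus_order) < 2:
            continue
        before = sample_embedding(model, seq, mode).vector
        for genus in present:
            gid = vocab.genus_to_id[genus]
            reduced = TokenSequence([t for t in seq.token_ids if t != gid],
                                    [g for g in seq.genus_order if g != genus],
                                    seq.sample_id, seq.label)
            after = sample_embedding(model, reduced, mode).vector
            collected[genus].append(1.0 - cosine_similarity(before, after))
    rows = []
    for genus in genera:
        vals = collected[genus]
        rows.append({
            "genus": genus,
            "mean_score": float(np.mean(vals)) if vals else np.nan,
            "sd_score": float(np.std(vals)) if vals else np.nan,
            "n_samples": len(vals),
        })
    df = pd.DataFrame(rows).set_index("genus")
    return df.sort_values("mean_score", ascending=False)
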