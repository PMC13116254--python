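"""Prompt-guided generation of communities and rank->abundance reconstruction.

Conditioning works through label tokens: the vocabulary is extended with one
token per class label, each training sequence becomes
[bos, label, rank-1 genus, ..., eos], and the model is fine-tuned with the
same next-token objective. At generation time the prompt [bos, label] steers
sampling toward communities of that class.

Generated sequences carry rank order only. The reconstructor — a small
feed-forward network N x 2N x N x N with ReLU in the first two layers,
softmax output, and residual connections around the two same-shape layers —
maps a rank-position-encoded presence vector X in [0,2]^N back onto the
abundance simplex. X_i is 0 when genus i is absent and sin(p_i) + 1 when it
occupies rank position p_i (the single-channel sinusoidal position embedding,
d_model = 1, shifted to be nonnegative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from ._utils import rng_for
from .corpus_io import AbundanceTable, Vocabulary
from .encoding import TokenSequence, encode_table, fit_normalization
from .model_core import Model, ModelConfig, _softmax
from .synthetic_data import RankAbundancePair
from .training import AdamW, TrainConfig, TrainHistory, pretrain_clm

__all__ = [
    "GenerationParams",
    "extend_vocab_with_labels",
    "extend_model_vocab",
    "insert_label_token",
    "finetune_generator",
    "generate",
    "perplexity",
    "build_reconstructor_input",
    "rank_positions_to_input",
    "pairs_to_arrays",
    "pairs_from_table",
    "Reconstructor",
    "ReconstructorConfig",
    "train_reconstructor",
    "reconstruct",
]


class GenerationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# label-token plumbing

def extend_vocab_with_labels(vocab: Vocabulary, labels: Sequence[str]) -> Vocabulary:
    """Append one token per label; existing ids are never reindexed."""
    labels = list(dict.fromkeys(labels))  # stable order, dedup
    if not labels:
        return Vocabulary(dict(vocab.genus_to_id), dict(vocab.special),
                          dict(vocab.label_tokens))
    taken = set(vocab.genus_to_id) | set(vocab.special) | set(vocab.label_tokens)
    clash = [l for l in labels if l in taken]
    if clash:
        raise GenerationError(f"label tokens collide with existing tokens: {clash}")
    label_tokens = dict(vocab.label_tokens)
    next_id = vocab.size
    for l in labels:
        label_tokens[l] = next_id
        next_id += 1
    return Vocabulary(dict(vocab.genus_to_id), dict(vocab.special), label_tokens)


def extend_model_vocab(model: Model, new_vocab: Vocabulary,
                       init_std: float = 0.02) -> Model:
    """Grow embeddings and LM head for appended tokens; old rows untouched."""
    old_v = model.config.vocab_size
    new_v = new_vocab.size
    if new_v < old_v:
        raise GenerationError("new vocabulary is smaller than the model's")
    out = model.copy()
    out.vocab = new_vocab
    if new_v == old_v:
        return out
    rng = np.random.default_rng(model.config.seed + 104729)
    extra = new_v - old_v
    out.params["tok_emb"] = np.vstack(
        [out.params["tok_emb"], rng.normal(0, init_std, (extra, model.config.d_model))])
    if "lm.w" in out.params:
        out.params["lm.w"] = np.hstack(
            [out.params["lm.w"], np.zeros((model.config.d_model, extra))])
        out.params["lm.b"] = np.concatenate([out.params["lm.b"], np.zeros(extra)])
    out.config = replace(model.config, vocab_size=new_v)
    return out


def insert_label_token(seq: TokenSequence, vocab: Vocabulary,
                       max_len: int | None = None) -> TokenSequence:
    """Place the sample's label token immediately after bos.

    The label token counts toward the context length, so the lowest-ranked
    genus is truncated if the sequence would overflow ``max_len``.
    """
    if seq.label is None:
        raise GenerationError(f"sample {seq.sample_id!r} has no label")
    if seq.label not in vocab.label_tokens:
        raise GenerationError(f"no token for label {seq.label!r}")
    lid = vocab.label_tokens[seq.label]
    ids = [seq.token_ids[0], lid] + list(seq.token_ids[1:])
    order = list(seq.genus_order)
    if max_len is not None and len(ids) > max_len:
        drop = len(ids) - max_len
        ids = ids[:-(drop + 1)] + [vocab.eos_id]
        order = order[:-drop]
    return TokenSequence(ids, order, seq.sample_id, seq.label)


def finetune_generator(model: Model, corpus: Sequence[TokenSequence],
                       cfg: TrainConfig) -> tuple[Model, TrainHistory]:
    """Next-token fine-tuning on label-prefixed sequences.

    Every sequence must carry a label with a token in the model's
    vocabulary; the vocabulary is extended (and embeddings grown) on the fly
    for labels it has not seen.
    """
    if model.head != "lm":
        raise GenerationError("generator fine-tuning needs the LM head")
    if model.vocab is None:
        raise GenerationError("model has no vocabulary attached")
    unlabeled = [s.sample_id for s in corpus if s.label is None]
    if unlabeled:
        raise GenerationError(f"unlabeled samples: {unlabeled[:5]}")
    labels = sorted({s.label for s in corpus})
    new_labels = [l for l in labels if l not in model.vocab.label_tokens]
    vocab = extend_vocab_with_labels(model.vocab, new_labels)
    model = extend_model_vocab(model, vocab)
    prefixed = [insert_label_token(s, vocab, model.config.max_len) for s in corpus]
    return pretrain_clm(model, prefixed, cfg)


# ---------------------------------------------------------------------------
# decoding

@dataclass(frozen=True)
class GenerationParams:
    """Decoding controls. temperature=0 means greedy argmax decoding."""

    max_new_tokens: int | None = None
    min_new_tokens: int = 1
    temperature: float = 1.0
    top_k: int | None = None
    forbid_repeats: bool = True
    seed: int = 0
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise GenerationError("temperature must be >= 0")
        if self.n_samples < 1:
            raise GenerationError("n_samples must be >= 1")
        if self.min_new_tokens < 1:
            raise GenerationError("min_new_tokens must be >= 1")


def generate(model: Model, label: str, params: GenerationParams) -> list[TokenSequence]:
    """Sample communities conditioned on a label token.

    Each sequence starts [bos, label], grows by temperature sampling (with
    optional top-k and repeat forbidding) and stops at eos or after
    ``max_new_tokens`` genera, in which case eos is appended. Reproducible
    from ``params.seed``.
    """
    vocab = model.vocab
    if vocab is None:
        raise GenerationError("model has no vocabulary attached")
    if label not in vocab.label_tokens:
        raise GenerationError(f"unknown label {label!r}")
    if model.head != "lm":
        raise GenerationError("generation needs the LM head")
    lid = vocab.label_tokens[label]
    budget = params.max_new_tokens
    if budget is None:
        budget = model.config.max_len - 3  # bos + label + eos
    budget = min(budget, model.config.max_len - 3)
    rng = rng_for(params.seed, f"generate:{label}")

    never = set(vocab.special.values()) - {vocab.eos_id}
    never |= set(vocab.label_tokens.values())

    out = []
    for _ in range(params.n_samples):
        ids = [vocab.bos_id, lid]
        emitted: set[int] = set()
        for _step in range(budget + 1):
            logits = model.logits(ids)[-1].astype(float).copy()
            logits[list(never)] = -np.inf
            if len(emitted) < params.min_new_tokens:
                logits[vocab.eos_id] = -np.inf
            if params.forbid_repeats and emitted:
                logits[list(emitted)] = -np.inf
            if len(ids) - 2 >= budget:
                nxt = vocab.eos_id
            elif params.temperature == 0.0:
                nxt = int(np.argmax(logits))
            else:
                z = logits / params.temperature
                if params.top_k is not None:
                    kth = np.sort(z[np.isfinite(z)])[::-1][
                        min(params.top_k, np.isfinite(z).sum()) - 1]
                    z = np.where(z >= kth, z, -np.inf)
                p = np.exp(z - np.max(z[np.isfinite(z)]))
                p[~np.isfinite(z)] = 0.0
                p = p / p.sum()
                nxt = int(rng.choice(len(p), p=p))
            ids.append(nxt)
            if nxt == vocab.eos_id:
                break
            emitted.add(nxt)
        if ids[-1] != vocab.eos_id:
            ids.append(vocab.eos_id)
        order = [vocab.genus_for(t) for t in ids
                 if vocab.genus_for(t) is not None]
        out.append(TokenSequence(ids, order, label=label))
    for i, s in enumerate(out):
        s.sample_id = f"gen_{label}_{i:04d}"
    return out


def perplexity(model: Model, seq: TokenSequence) -> float:
    """exp(mean next-token cross-entropy, nats) over the predicted positions."""
    ids = list(seq.token_ids)
    if len(ids) < 2:
        raise GenerationError("perplexity needs a sequence of length >= 2")
    logits = model.logits(ids)
    probs = np.asarray(_softmax(logits, axis=-1))
    targets = np.array(ids[1:])
    nll = -np.log(probs[np.arange(len(targets)), targets] + 1e-300)
    return float(np.exp(nll.mean()))


# ---------------------------------------------------------------------------
# reconstructor

def rank_positions_to_input(genus_indices: Sequence[int], n_genera: int) -> np.ndarray:
    """X in [0,2]^N from an ordered list of present genus indices.

    The genus at 1-based rank position p gets sin(p) + 1; absent genera stay
    exactly 0.
    """
    x = np.zeros(n_genera)
    for pos, g in enumerate(genus_indices, start=1):
        x[g] = np.sin(float(pos)) + 1.0
    return x


def _genus_axis(vocab: Vocabulary) -> list[str]:
    """Dense genus order for reconstructor vectors: ascending token id."""
    return [g for g, _ in sorted(vocab.genus_to_id.items(), key=lambda kv: kv[1])]


def build_reconstructor_input(seq: TokenSequence, vocab: Vocabulary) -> np.ndarray:
    """Encode a token sequence's rank order over the vocabulary's genus axis."""
    if not seq.genus_order:
        raise GenerationError("sequence has no genus tokens")
    axis = {g: j for j, g in enumerate(_genus_axis(vocab))}
    return rank_positions_to_input([axis[g] for g in seq.genus_order], len(axis))


def pairs_to_arrays(pairs: Sequence[RankAbundancePair],
                    n_genera: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack simulated rank/abundance pairs into training matrices (X, Y)."""
    X = np.stack([rank_positions_to_input(p.genus_indices, n_genera) for p in pairs])
    Y = np.stack([p.abundances for p in pairs])
    return X, Y


def pairs_from_table(table: AbundanceTable, vocab: Vocabulary,
                     stats=None, max_len: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Rank-encode a real table and pair each sequence with its composition.

    Targets are the sample's abundances over the vocabulary's genus axis,
    renormalized over in-vocabulary genera.
    """
    stats = stats if stats is not None else fit_normalization(table)
    seqs = encode_table(table, stats, vocab, max_len)
    axis = _genus_axis(vocab)
    col = {g: j for j, g in enumerate(table.genus_names)}
    Y = np.zeros((table.n_samples, len(axis)))
    for j, g in enumerate(axis):
        if g in col:
            Y[:, j] = table.values[:, col[g]]
    sums = Y.sum(axis=1, keepdims=True)
    Y = Y / np.where(sums > 0, sums, 1.0)
    X = np.stack([build_reconstructor_input(s, vocab) for s in seqs])
    return X, Y


@dataclass(frozen=True)
class ReconstructorConfig:
    """Training recipe for the reconstructor: Adam, lr 2e-4, batch 64,
    20% validation split, early stopping with patience 10."""

    lr: float = 2e-4
    batch_size: int = 64
    val_split: float = 0.2
    patience: int = 10
    max_epochs: int = 300
    loss: str = "ce"  # "ce" (cross-entropy vs softmax output) or "mse"
    seed: int = 0


@dataclass
class Reconstructor:
    """N x 2N x N x N network mapping rank encodings onto the simplex."""

    n_genera: int
    params: dict[str, np.ndarray]
    genus_axis: list[str] | None = None
    trained: bool = False

    @classmethod
    def init(cls, n_genera: int, seed: int = 0,
             genus_axis: list[str] | None = None) -> "Reconstructor":
        rng = np.random.default_rng(seed)
        N = n_genera
        p = {
            "w1": rng.normal(0, np.sqrt(2.0 / N), (N, 2 * N)), "b1": np.zeros(2 * N),
            "w2": rng.normal(0, np.sqrt(1.0 / N), (2 * N, N)), "b2": np.zeros(N),
            "w3": rng.normal(0, 0.02, (N, N)), "b3": np.zeros(N),
        }
        return cls(N, p, genus_axis)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "reconstructor.npz", **self.params)
        meta = {"n_genera": self.n_genera, "trained": self.trained,
                "genus_axis": self.genus_axis}
        import json
        (path / "reconstructor.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Reconstructor":
        import json
        path = Path(path)
        meta = json.loads((path / "reconstructor.json").read_text())
        with np.load(path / "reconstructor.npz") as z:
            params = {k: z[k] for k in z.files}
        return cls(meta["n_genera"], params, meta.get("genus_axis"),
                   meta.get("trained", False))


def _reconstructor_forward(p: dict, X):
    h1 = anp.maximum(anp.matmul(X, p["w1"]) + p["b1"], 0.0)
    h2 = anp.maximum(anp.matmul(h1, p["w2"]) + p["b2"], 0.0) + X  # residual
    logits = anp.matmul(h2, p["w3"]) + p["b3"] + h2                # residual
    return _softmax(logits, axis=-1)


def _reconstructor_loss(p: dict, X, Y, kind: str):
    Yh = _reconstructor_forward(p, X)
    if kind == "mse":
        return anp.mean((Yh - Y) ** 2)
    return -anp.mean(anp.sum(Y * anp.log(Yh + 1e-12), axis=-1))


def train_reconstructor(X: np.ndarray, Y: np.ndarray,
                        cfg: ReconstructorConfig = ReconstructorConfig(),
                        genus_axis: list[str] | None = None,
                        ) -> tuple[Reconstructor, TrainHistory]:
    """Fit the reconstructor on paired (rank encoding, composition) data."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.ndim != 2 or X.shape != Y.shape:
        raise GenerationError(f"X {X.shape} and Y {Y.shape} must match (n, N)")
    if len(X) < 2:
        raise GenerationError("need at least two training pairs")
    rec = Reconstructor.init(X.shape[1], cfg.seed, genus_axis)
    rng = rng_for(cfg.seed, "train_reconstructor")
    order = rng.permutation(len(X))
    n_val = max(1, int(round(cfg.val_split * len(X))))
    va, tr = order[:n_val], order[n_val:]
    if len(tr) == 0:
        raise GenerationError("validation split leaves no training pairs")
    Xtr, Ytr, Xva, Yva = X[tr], Y[tr], X[va], Y[va]

    hist = TrainHistory()
    opt = AdamW(rec.params, cfg.lr, weight_decay=0.0, warmup_steps=0)
    grad_fn = value_and_grad(lambda p, xb, yb: _reconstructor_loss(p, xb, yb, cfg.loss))
    best = {k: v.copy() for k, v in rec.params.items()}
    bad, step = 0, 0

    def evaluate() -> float:
        return float(_reconstructor_loss(rec.params, Xva, Yva, cfg.loss))

    vl = evaluate()
    hist.val_steps.append(0)
    hist.val_loss.append(vl)
    hist.best_val_loss, hist.best_step = vl, 0
    for _epoch in range(cfg.max_epochs):
        idx = rng.permutation(len(Xtr))
        for b in range(0, len(Xtr), cfg.batch_size):
            sel = idx[b:b + cfg.batch_size]
            loss, grads = grad_fn(rec.params, Xtr[sel], Ytr[sel])
            opt.step(rec.params, grads)
            step += 1
            hist.steps.append(step)
            hist.train_loss.append(float(loss))
        vl = evaluate()
        hist.val_steps.append(step)
        hist.val_loss.append(vl)
        if vl < hist.best_val_loss:
            hist.best_val_loss, hist.best_step = vl, step
            best = {k: v.copy() for k, v in rec.params.items()}
            bad = 0
        else:
            bad += 1
            if bad >= cfg.patience:
                hist.stopped_early = True
                break
    rec.params = best
    rec.trained = True
    return rec, hist


def reconstruct(rec: Reconstructor, inputs, vocab: Vocabulary | None = None,
                mask_absent: bool = True) -> np.ndarray:
    """Map rank encodings (or token sequences) to simplex abundance vectors.

    With ``mask_absent`` (default) the softmax output is zeroed wherever the
    input marks a genus absent and renormalized over the present ones.
    """
    if not rec.trained:
        raise GenerationError("reconstructor has not been trained")
    if isinstance(inputs, (list, tuple)) and inputs and isinstance(inputs[0], TokenSequence):
        if vocab is None:
            raise GenerationError("vocab required to encode token sequences")
        X = np.stack([build_reconstructor_input(s, vocab) for s in inputs])
    else:
        X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != rec.n_genera:
        raise GenerationError(
            f"input width {X.shape[1]} != reconstructor N={rec.n_genera}")
    Y = np.asarray(_reconstructor_forward(rec.params, X))
    if mask_absent:
        Y = np.where(X > 0, Y, 0.0)
        sums = Y.sum(axis=1, keepdims=True)
        Y = Y / np.where(sums > 0, sums, 1.0)
    return Y
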