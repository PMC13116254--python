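"""Decoder-only transformer over genus tokens, written in numpy.

The backbone is a GPT-style causal transformer: learned token and absolute
position embeddings, pre-layer-norm blocks of multi-head scaled dot-product
attention softmax(QK^T / sqrt(d_k)) V with a causal mask, GELU feed-forward
layers, and a final layer norm. Gradients for training come from autograd,
so every forward function here is written against ``autograd.numpy`` and
works identically on plain arrays.

Two interchangeable heads share the backbone: a language-modeling head
(linear to vocabulary logits, zero-initialized so an untrained model is
exactly uniform) and a sequence-classification head reading the hidden
state at the eos position. Swapping heads preserves all backbone weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd.scipy.special import erf

from .corpus_io import Vocabulary
from .encoding import TokenSequence

__all__ = [
    "ModelConfig",
    "Model",
    "SampleEmbedding",
    "build_model",
    "next_token_logits",
    "sample_embedding",
    "toy_config",
    "full_scale_config",
]

NEG_INF = -1e9


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``full_scale_config`` gives the full-size settings (8 layers, 8 heads,
    feed-forward 1024, context 512); ``toy_config`` gives a configuration
    that trains in seconds on one CPU core and is used throughout the tests.
    """

    vocab_size: int
    n_layers: int = 8
    n_heads: int = 8
    d_model: int = 512
    d_ff: int = 1024
    max_len: int = 512
    activation: str = "gelu"
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ConfigError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if min(self.vocab_size, self.n_layers, self.n_heads, self.d_model,
               self.d_ff) < 1 or self.max_len < 3:
            raise ConfigError("counts must be >= 1 and max_len >= 3")
        if self.activation not in ("gelu", "relu"):
            raise ConfigError(f"unknown activation {self.activation!r}")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


def toy_config(vocab_size: int, seed: int = 0, max_len: int = 512) -> ModelConfig:
    """2 layers x 2 heads, d_model 32, d_ff 64 — the CPU test configuration."""
    return ModelConfig(vocab_size=vocab_size, n_layers=2, n_heads=2, d_model=32,
                       d_ff=64, max_len=max_len, seed=seed)


def full_scale_config(vocab_size: int, seed: int = 0) -> ModelConfig:
    """Full-scale configuration: 8 layers, 8 heads, d_ff 1024, context 512."""
    return ModelConfig(vocab_size=vocab_size, n_layers=8, n_heads=8, d_model=512,
                       d_ff=1024, max_len=512, seed=seed)


# ---------------------------------------------------------------------------
# parameters

INIT_STD = 0.02


def init_params(cfg: ModelConfig, head: str = "lm", n_classes: int | None = None,
                rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Reproducibly initialize all weights from ``cfg.seed``.

    Projections and embeddings are N(0, 0.02); layer-norm gains are 1; all
    biases and both output heads start at zero, so a fresh LM predicts the
    uniform distribution (per-token cross-entropy ln(vocab_size)).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    d, dff, V = cfg.d_model, cfg.d_ff, cfg.vocab_size
    p: dict[str, np.ndarray] = {
        "tok_emb": rng.normal(0, INIT_STD, (V, d)),
        "pos_emb": rng.normal(0, INIT_STD, (cfg.max_len, d)),
        "ln_f.g": np.ones(d), "ln_f.b": np.zeros(d),
    }
    for i in range(cfg.n_layers):
        p[f"h{i}.ln1.g"] = np.ones(d)
        p[f"h{i}.ln1.b"] = np.zeros(d)
        p[f"h{i}.attn.qkv_w"] = rng.normal(0, INIT_STD, (d, 3 * d))
        p[f"h{i}.attn.qkv_b"] = np.zeros(3 * d)
        p[f"h{i}.attn.out_w"] = rng.normal(0, INIT_STD, (d, d))
        p[f"h{i}.attn.out_b"] = np.zeros(d)
        p[f"h{i}.ln2.g"] = np.ones(d)
        p[f"h{i}.ln2.b"] = np.zeros(d)
        p[f"h{i}.ff.w1"] = rng.normal(0, INIT_STD, (d, dff))
        p[f"h{i}.ff.b1"] = np.zeros(dff)
        p[f"h{i}.ff.w2"] = rng.normal(0, INIT_STD, (dff, d))
        p[f"h{i}.ff.b2"] = np.zeros(d)
    add_head_params(p, cfg, head, n_classes)
    return p


def add_head_params(p: dict, cfg: ModelConfig, head: str,
                    n_classes: int | None = None) -> None:
    if head == "lm":
        p["lm.w"] = np.zeros((cfg.d_model, cfg.vocab_size))
        p["lm.b"] = np.zeros(cfg.vocab_size)
    elif head == "classifier":
        if not n_classes or n_classes < 2:
            raise ConfigError("classifier head needs n_classes >= 2")
        p["cls.w"] = np.zeros((cfg.d_model, n_classes))
        p["cls.b"] = np.zeros(n_classes)
    else:
        raise ConfigError(f"unknown head {head!r}")


BACKBONE_PREFIXES = ("tok_emb", "pos_emb", "ln_f", "h")


def backbone_keys(p: dict) -> list[str]:
    return [k for k in p if not (k.startswith("lm.") or k.startswith("cls."))]


def n_params(p: dict) -> int:
    return int(sum(v.size for v in p.values()))


# ---------------------------------------------------------------------------
# forward pass (autograd-traceable)

def _layer_norm(x, g, b, eps: float = 1e-5):
    m = anp.mean(x, axis=-1, keepdims=True)
    v = anp.var(x, axis=-1, keepdims=True)
    return (x - m) / anp.sqrt(v + eps) * g + b


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / anp.sqrt(2.0)))


def _softmax(x, axis=-1):
    m = anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x - m)
    return e / anp.sum(e, axis=axis, keepdims=True)


def _attention(p, prefix, x, cfg: ModelConfig, mask, capture: list | None,
               dropout_masks=None):
    B, T, d = x.shape[0], x.shape[1], cfg.d_model
    H, dk = cfg.n_heads, cfg.d_k
    qkv = anp.matmul(x, p[f"{prefix}.qkv_w"]) + p[f"{prefix}.qkv_b"]
    q, k, v = qkv[..., :d], qkv[..., d:2 * d], qkv[..., 2 * d:]
    q = anp.transpose(anp.reshape(q, (B, T, H, dk)), (0, 2, 1, 3))
    k = anp.transpose(anp.reshape(k, (B, T, H, dk)), (0, 2, 1, 3))
    v = anp.transpose(anp.reshape(v, (B, T, H, dk)), (0, 2, 1, 3))
    scores = anp.matmul(q, anp.transpose(k, (0, 1, 3, 2))) / anp.sqrt(float(dk))
    attn = _softmax(scores + mask, axis=-1)  # (B, H, T, T) probability rows
    if capture is not None:
        capture.append(np.asarray(attn))
    out = anp.matmul(attn, v)
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (B, T, d))
    out = anp.matmul(out, p[f"{prefix}.out_w"]) + p[f"{prefix}.out_b"]
    if dropout_masks is not None:
        out = out * dropout_masks
    return out


def forward_hidden(p: dict, ids: np.ndarray, cfg: ModelConfig,
                   capture_attention: list | None = None,
                   dropout_rng: np.random.Generator | None = None):
    """Final-layer hidden states (after the closing layer norm), shape (B,T,d).

    ``ids`` is a (B, T) int array, T <= cfg.max_len. With
    ``capture_attention`` a list, the per-layer (B, H, T, T) attention
    probability matrices are appended to it. ``dropout_rng`` enables
    inverted dropout on the attention and feed-forward outputs at rate
    ``cfg.dropout`` (training only).
    """
    ids = np.asarray(ids)
    if ids.ndim == 1:
        ids = ids[None, :]
    B, T = ids.shape
    if T > cfg.max_len:
        raise ConfigError(f"sequence length {T} exceeds max_len {cfg.max_len}")
    mask = np.triu(np.full((T, T), NEG_INF), k=1)
    act = _gelu if cfg.activation == "gelu" else lambda x: anp.maximum(x, 0.0)

    def drop_mask(shape):
        if dropout_rng is None or cfg.dropout <= 0.0:
            return None
        keep = (dropout_rng.random(shape) >= cfg.dropout).astype(float)
        return keep / (1.0 - cfg.dropout)

    h = p["tok_emb"][ids] + p["pos_emb"][:T]
    for i in range(cfg.n_layers):
        x = _layer_norm(h, p[f"h{i}.ln1.g"], p[f"h{i}.ln1.b"])
        h = h + _attention(p, f"h{i}.attn", x, cfg, mask, capture_attention,
                           drop_mask((B, T, cfg.d_model)))
        x = _layer_norm(h, p[f"h{i}.ln2.g"], p[f"h{i}.ln2.b"])
        ff = anp.matmul(act(anp.matmul(x, p[f"h{i}.ff.w1"]) + p[f"h{i}.ff.b1"]),
                        p[f"h{i}.ff.w2"]) + p[f"h{i}.ff.b2"]
        dm = drop_mask((B, T, cfg.d_model))
        if dm is not None:
            ff = ff * dm
        h = h + ff
    return _layer_norm(h, p["ln_f.g"], p["ln_f.b"])


def lm_logits(p: dict, ids: np.ndarray, cfg: ModelConfig,
              dropout_rng: np.random.Generator | None = None):
    h = forward_hidden(p, ids, cfg, dropout_rng=dropout_rng)
    return anp.matmul(h, p["lm.w"]) + p["lm.b"]


def classifier_logits(p: dict, ids: np.ndarray, eos_positions: np.ndarray,
                      cfg: ModelConfig,
                      dropout_rng: np.random.Generator | None = None):
    """Class logits read from the hidden state at each sequence's eos token."""
    h = forward_hidden(p, ids, cfg, dropout_rng=dropout_rng)
    B = h.shape[0]
    at_eos = h[np.arange(B), np.asarray(eos_positions)]
    return anp.matmul(at_eos, p["cls.w"]) + p["cls.b"]


# ---------------------------------------------------------------------------
# model wrapper

@dataclass
class SampleEmbedding:
    """A d_model sample representation plus the pooling mode that made it.

    Embeddings produced under different modes are never comparable.
    """

    vector: np.ndarray
    mode: str
    sample_id: str = ""


@dataclass
class Model:
    """Config + parameters + head type, with convenience inference methods."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    head: str = "lm"
    n_classes: int | None = None
    vocab: Vocabulary | None = None
    class_names: list[str] | None = None

    def copy(self) -> "Model":
        return Model(self.config, {k: v.copy() for k, v in self.params.items()},
                     self.head, self.n_classes, self.vocab, self.class_names)

    def with_head(self, head: str, n_classes: int | None = None) -> "Model":
        """Swap the output head, preserving every backbone weight."""
        p = {k: self.params[k].copy() for k in backbone_keys(self.params)}
        add_head_params(p, self.config, head, n_classes)
        return Model(self.config, p, head, n_classes if head == "classifier" else None,
                     self.vocab)

    # -- inference ----------------------------------------------------------
    def hidden_states(self, token_ids: list[int]) -> np.ndarray:
        return np.asarray(forward_hidden(self.params, np.array([token_ids]),
                                         self.config))[0]

    def logits(self, token_ids: list[int]) -> np.ndarray:
        if self.head != "lm":
            raise ConfigError("language-modeling head required")
        return np.asarray(lm_logits(self.params, np.array([token_ids]), self.config))[0]

    def class_logits(self, token_ids: list[int], eos_position: int | None = None) -> np.ndarray:
        if self.head != "classifier":
            raise ConfigError("classifier head required")
        pos = len(token_ids) - 1 if eos_position is None else eos_position
        return np.asarray(classifier_logits(self.params, np.array([token_ids]),
                                            np.array([pos]), self.config))[0]

    def attention_matrices(self, token_ids: list[int]) -> np.ndarray:
        """Per-layer, per-head attention probabilities, shape (L, H, T, T)."""
        capture: list = []
        forward_hidden(self.params, np.array([token_ids]), self.config,
                       capture_attention=capture)
        return np.stack([layer[0] for layer in capture])  # (L, H, T, T)

    # -- persistence ---------------------------------------------------------
    def save(self, ckpt_dir: str | Path) -> None:
        ckpt = Path(ckpt_dir)
        ckpt.mkdir(parents=True, exist_ok=True)
        meta = {"config": asdict(self.config), "head": self.head,
                "n_classes": self.n_classes, "class_names": self.class_names,
                "format_version": 1}
        if self.vocab is not None:
            vocab_json = self.vocab.to_json()
            (ckpt / "vocab.json").write_text(vocab_json)
            meta["vocab_sha256"] = hashlib.sha256(vocab_json.encode()).hexdigest()
        (ckpt / "config.json").write_text(json.dumps(meta, indent=1))
        np.savez(ckpt / "weights.npz", **self.params)

    @classmethod
    def load(cls, ckpt_dir: str | Path) -> "Model":
        ckpt = Path(ckpt_dir)
        meta = json.loads((ckpt / "config.json").read_text())
        cfg = ModelConfig(**meta["config"])
        with np.load(ckpt / "weights.npz") as z:
            params = {k: z[k] for k in z.files}
        vocab = None
        if (ckpt / "vocab.json").exists():
            vocab_json = (ckpt / "vocab.json").read_text()
            digest = hashlib.sha256(vocab_json.encode()).hexdigest()
            if meta.get("vocab_sha256") and digest != meta["vocab_sha256"]:
                raise ConfigError("vocabulary hash mismatch in checkpoint")
            vocab = Vocabulary.from_json(vocab_json)
        return cls(cfg, params, meta["head"], meta.get("n_classes"), vocab,
                   meta.get("class_names"))


def build_model(config: ModelConfig, head: str = "lm",
                n_classes: int | None = None,
                vocab: Vocabulary | None = None) -> Model:
    """Construct a freshly initialized model (weights seeded by config.seed)."""
    if vocab is not None and vocab.size != config.vocab_size:
        raise ConfigError(
            f"vocab size {vocab.size} != config.vocab_size {config.vocab_size}"
        )
    return Model(config, init_params(config, head, n_classes), head,
                 n_classes if head == "classifier" else None, vocab)


def next_token_logits(model: Model, seq: TokenSequence) -> np.ndarray:
    """Per-position next-token probability distributions, shape (T, vocab).

    Row t conditions only on tokens at positions <= t (causal mask); each
    row sums to one.
    """
    logits = model.logits(list(seq.token_ids))
    return np.asarray(_softmax(logits, axis=-1))


def sample_embedding(model: Model, seq: TokenSequence,
                     mode: str = "mean_pool",
                     include_specials: bool = False) -> SampleEmbedding:
    """Pool final-layer hidden states into one vector per sample.

    ``mean_pool`` averages over genus-token positions (specials and label
    tokens excluded unless ``include_specials``); ``eos_token`` takes the
    hidden state at the last (eos) position. Pretrained models conventionally
    use mean pooling, fine-tuned classifiers the eos state.
    """
    if mode not in ("mean_pool", "eos_token"):
        raise ConfigError(f"unknown embedding mode {mode!r}")
    h = model.hidden_states(list(seq.token_ids))
    if mode == "eos_token":
        vec = h[len(seq.token_ids) - 1]
    else:
        if include_specials:
            vec = h.mean(axis=0)
        else:
            if model.vocab is not None:
                keep = [i for i, t in enumerate(seq.token_ids)
                        if model.vocab.genus_for(t) is not None]
            else:  # fall back to positional convention: strip bos/eos (+label)
                start = 2 if seq.label is not None else 1
                keep = list(range(start, len(seq.token_ids) - 1))
            if not keep:
                raise ConfigError("no genus tokens to pool over")
            vec = h[keep].mean(axis=0)
    return SampleEmbedding(np.asarray(vec, dtype=float), mode, seq.sample_id)
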