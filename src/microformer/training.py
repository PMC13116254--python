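"""Causal-LM pretraining, classifier fine-tuning, and cross-validation.

Training minimizes the next-token negative log-likelihood
L(theta) = -sum_k log P(t_{k+1} | t_1..t_k; theta) with an AdamW-style
optimizer (decoupled weight decay), linear warmup, and early stopping on
validation loss. Fine-tuning replaces the LM head with a classification
head read at the eos position and updates the whole backbone.

Defaults follow the pretraining recipe: learning rate 1e-3, batch size 50,
1000 warmup steps, weight decay 0.001, 10% validation split, patience 3.
Toy tasks in the tests override batch size and warmup to fit their scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._utils import rng_for
from .corpus_io import AbundanceTable, build_vocab
from .encoding import TokenSequence, encode_table, fit_normalization
from .model_core import (
    Model, ModelConfig, build_model, classifier_logits, lm_logits, _softmax,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "pretrain_clm",
    "finetune_classifier",
    "predict_proba",
    "crossvalidate",
    "fmax",
]


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults are the full-scale recipe."""

    lr: float = 1e-3
    batch_size: int = 50
    warmup_steps: int = 1000
    weight_decay: float = 0.001
    val_split: float = 0.10
    eval_every: int | str = "epoch"  # steps, or "epoch"
    patience: int = 3
    max_steps: int | None = None
    max_epochs: int = 50
    min_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_split < 1.0:
            raise TrainingError("val_split must lie in (0, 1)")
        if self.patience < 1:
            raise TrainingError("patience must be >= 1")


@dataclass
class TrainHistory:
    """Loss trajectory (cross-entropy, nats) and early-stopping outcome."""

    steps: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_steps: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_early: bool = False
    best_step: int = 0
    best_val_loss: float = float("inf")


# ---------------------------------------------------------------------------
# optimizer

DECAY_SUFFIXES = ("_w", ".w1", ".w2", "emb", "lm.w", "cls.w")


def _decays(key: str) -> bool:
    # weight decay on matrices/embeddings, not on biases or layer-norm params
    return key.endswith(("qkv_w", "out_w", "w1", "w2")) or key in (
        "tok_emb", "pos_emb", "lm.w", "cls.w")


class AdamW:
    """Adam with decoupled weight decay and linear warmup(/decay) schedule."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 warmup_steps: int = 0, max_steps: int | None = None,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.warmup, self.max_steps = warmup_steps, max_steps
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def lr_at(self, t: int) -> float:
        scale = 1.0
        if self.warmup > 0 and t < self.warmup:
            scale = (t + 1) / self.warmup
        elif self.max_steps is not None and self.max_steps > self.warmup:
            scale = max(0.0, (self.max_steps - t) / (self.max_steps - self.warmup))
        return self.lr * scale

    def step(self, params: dict, grads: dict) -> None:
        lr = self.lr_at(self.t)
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] = params[k] - lr * mh / (np.sqrt(vh) + self.eps)
            if self.wd and _decays(k):
                params[k] = params[k] - lr * self.wd * params[k]


# ---------------------------------------------------------------------------
# batching and losses

def pad_batch(seqs: Sequence[TokenSequence], pad_id: int) -> np.ndarray:
    T = max(len(s) for s in seqs)
    ids = np.full((len(seqs), T), pad_id, dtype=int)
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = s.token_ids
    return ids


def clm_batch_loss(params: dict, ids: np.ndarray, cfg: ModelConfig, pad_id: int,
                   dropout_rng=None):
    """Mean next-token cross-entropy (nats) over non-pad target positions."""
    logits = lm_logits(params, ids[:, :-1], cfg, dropout_rng=dropout_rng)
    targets = ids[:, 1:]
    mask = (targets != pad_id).astype(float)
    m = anp.max(logits, axis=-1, keepdims=True)
    lse = anp.log(anp.sum(anp.exp(logits - m), axis=-1)) + m[..., 0]
    B, T = targets.shape
    tok_ll = logits[np.arange(B)[:, None], np.arange(T)[None, :], targets] - lse
    return -anp.sum(tok_ll * mask) / anp.sum(mask)


def clm_corpus_loss(model: Model, corpus: Sequence[TokenSequence],
                    batch_size: int = 64) -> float:
    """Token-weighted mean CLM loss over a corpus (no dropout)."""
    pad = _pad_id(model)
    tot, n = 0.0, 0
    for i in range(0, len(corpus), batch_size):
        chunk = corpus[i:i + batch_size]
        ids = pad_batch(chunk, pad)
        ntok = int((ids[:, 1:] != pad).sum())
        tot += float(clm_batch_loss(model.params, ids, model.config, pad)) * ntok
        n += ntok
    return tot / max(n, 1)


def cls_batch_loss(params: dict, ids: np.ndarray, eos_pos: np.ndarray,
                   y: np.ndarray, cfg: ModelConfig, dropout_rng=None):
    logits = classifier_logits(params, ids, eos_pos, cfg, dropout_rng=dropout_rng)
    m = anp.max(logits, axis=-1, keepdims=True)
    lse = anp.log(anp.sum(anp.exp(logits - m), axis=-1)) + m[:, 0]
    ll = logits[np.arange(len(y)), y] - lse
    return -anp.mean(ll)


def _pad_id(model: Model) -> int:
    return model.vocab.pad_id if model.vocab is not None else 0


# ---------------------------------------------------------------------------
# training loops

def _early_stop_loop(train_step, evaluate, n_train: int, cfg: TrainConfig,
                     params: dict) -> tuple[dict, TrainHistory]:
    """Shared loop: batched epochs, periodic evaluation, patience-based stop."""
    hist = TrainHistory()
    opt = AdamW(params, cfg.lr, cfg.weight_decay, cfg.warmup_steps, cfg.max_steps)
    best_params = {k: v.copy() for k, v in params.items()}
    bad, step, done = 0, 0, False

    def do_eval() -> bool:
        nonlocal bad
        vl = evaluate(params)
        hist.val_steps.append(step)
        hist.val_loss.append(vl)
        if vl < hist.best_val_loss - cfg.min_delta:
            hist.best_val_loss = vl
            hist.best_step = step
            for k in params:
                best_params[k] = params[k].copy()
            bad = 0
        else:
            bad += 1
        return bad >= cfg.patience

    do_eval()  # baseline at step 0
    steps_per_epoch = max(1, -(-n_train // cfg.batch_size))
    for _epoch in range(cfg.max_epochs):
        for b in range(steps_per_epoch):
            loss, grads = train_step(params, _epoch, b)
            opt.step(params, grads)
            step += 1
            hist.steps.append(step)
            hist.train_loss.append(float(loss))
            if isinstance(cfg.eval_every, int) and step % cfg.eval_every == 0:
                if do_eval():
                    hist.stopped_early = True
                    done = True
                    break
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        if not done and cfg.eval_every == "epoch":
            if do_eval():
                hist.stopped_early = True
                done = True
        if done:
            break
    return best_params, hist


def pretrain_clm(model: Model, corpus: Sequence[TokenSequence],
                 cfg: TrainConfig) -> tuple[Model, TrainHistory]:
    """Pretrain with the causal language-modeling objective.

    A random ``cfg.val_split`` fraction is held out for validation; the
    returned model carries the parameters of the best validation loss.
    """
    if model.head != "lm":
        raise TrainingError("pretraining requires the language-modeling head")
    if len(corpus) == 0:
        raise TrainingError("empty corpus")
    rng = rng_for(cfg.seed, "pretrain_clm")
    order = rng.permutation(len(corpus))
    n_val = max(1, int(round(cfg.val_split * len(corpus))))
    val = [corpus[i] for i in order[:n_val]]
    train = [corpus[i] for i in order[n_val:]]
    if len(train) < cfg.batch_size:
        raise TrainingError(
            f"training split ({len(train)} sequences) is smaller than one batch "
            f"({cfg.batch_size}); use a smaller batch_size"
        )
    model = model.copy()
    pad = _pad_id(model)
    dropout_rng = (rng_for(cfg.seed, "dropout")
                   if model.config.dropout > 0 else None)
    grad_fn = value_and_grad(
        lambda p, ids: clm_batch_loss(p, ids, model.config, pad, dropout_rng))

    epoch_orders: dict[int, np.ndarray] = {}

    def train_step(params, epoch, b):
        if epoch not in epoch_orders:
            epoch_orders[epoch] = rng.permutation(len(train))
        idx = epoch_orders[epoch][b * cfg.batch_size:(b + 1) * cfg.batch_size]
        ids = pad_batch([train[i] for i in idx], pad)
        return grad_fn(params, ids)

    def evaluate(params):
        return clm_corpus_loss(Model(model.config, params, "lm", None, model.vocab),
                               val, batch_size=max(cfg.batch_size, 16))

    best, hist = _early_stop_loop(train_step, evaluate, len(train), cfg, model.params)
    return Model(model.config, best, "lm", None, model.vocab), hist


def _stratified_split(y: np.ndarray, val_split: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        n_val = int(round(val_split * idx.size))
        n_val = min(n_val, idx.size - 1)  # keep at least one in train
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def finetune_classifier(model: Model, corpus: Sequence[TokenSequence],
                        labels: Sequence[str] | dict[str, str],
                        cfg: TrainConfig) -> tuple[Model, TrainHistory]:
    """Fine-tune for classification: eos-state head, whole backbone unfrozen.

    ``labels`` is either a list parallel to ``corpus`` or a map from sample
    id to class label. Validation is a stratified split.
    """
    if isinstance(labels, dict):
        missing = [s.sample_id for s in corpus if s.sample_id not in labels]
        if missing:
            raise TrainingError(f"samples without label: {missing[:5]}")
        labels = [labels[s.sample_id] for s in corpus]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise TrainingError("need at least two classes")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_to_idx[l] for l in labels])

    if model.head != "classifier" or model.n_classes != len(classes):
        model = model.with_head("classifier", len(classes))
    else:
        model = model.copy()
    model.class_names = classes

    rng = rng_for(cfg.seed, "finetune_classifier")
    tr_idx, va_idx = _stratified_split(y, cfg.val_split, rng)
    if len(set(y[tr_idx])) < len(classes):
        raise TrainingError("a class is absent from the training split")
    train = [corpus[i] for i in tr_idx]
    y_train = y[tr_idx]
    val = [corpus[i] for i in va_idx]
    y_val = y[va_idx]
    pad = _pad_id(model)
    dropout_rng = (rng_for(cfg.seed, "dropout")
                   if model.config.dropout > 0 else None)
    grad_fn = value_and_grad(
        lambda p, ids, pos, yy: cls_batch_loss(p, ids, pos, yy, model.config,
                                               dropout_rng))

    epoch_orders: dict[int, np.ndarray] = {}

    def make_batch(seqs, yy):
        ids = pad_batch(seqs, pad)
        pos = np.array([len(s) - 1 for s in seqs])
        return ids, pos, yy

    def train_step(params, epoch, b):
        if epoch not in epoch_orders:
            epoch_orders[epoch] = rng.permutation(len(train))
        idx = epoch_orders[epoch][b * cfg.batch_size:(b + 1) * cfg.batch_size]
        ids, pos, yy = make_batch([train[i] for i in idx], y_train[idx])
        return grad_fn(params, ids, pos, yy)

    def evaluate(params):
        if len(val) == 0:
            ids, pos, yy = make_batch(train, y_train)
            return float(cls_batch_loss(params, ids, pos, yy, model.config))
        tot, n = 0.0, 0
        for i in range(0, len(val), 64):
            chunk = val[i:i + 64]
            ids, pos, yy = make_batch(chunk, y_val[i:i + 64])
            tot += float(cls_batch_loss(params, ids, pos, yy, model.config)) * len(chunk)
            n += len(chunk)
        return tot / n

    best, hist = _early_stop_loop(train_step, evaluate, len(train), cfg, model.params)
    out = Model(model.config, best, "classifier", len(classes), model.vocab, classes)
    return out, hist


def predict_proba(model: Model, corpus: Sequence[TokenSequence],
                  batch_size: int = 64) -> np.ndarray:
    """Class probabilities (n, k) from the eos-position classifier head."""
    if model.head != "classifier":
        raise TrainingError("classifier head required")
    pad = _pad_id(model)
    out = []
    for i in range(0, len(corpus), batch_size):
        chunk = corpus[i:i + batch_size]
        ids = pad_batch(chunk, pad)
        pos = np.array([len(s) - 1 for s in chunk])
        logits = np.asarray(classifier_logits(model.params, ids, pos, model.config))
        out.append(np.asarray(_softmax(logits, axis=-1)))
    return np.vstack(out)


# ---------------------------------------------------------------------------
# metrics and cross-validation

def fmax(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Maximum micro-averaged F1 over all observed decision thresholds.

    ``scores`` is (n,) for binary (positive-class score, y in {0,1}) or
    (n, k) with integer ``y_true`` class indices for multiclass, treated
    one-vs-rest at a shared threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.ndim == 1:
        onehot = (y_true == 1).astype(int)[:, None]
        scores = scores[:, None]
    else:
        onehot = np.zeros_like(scores, dtype=int)
        onehot[np.arange(len(y_true)), y_true] = 1
    best = 0.0
    for t in np.unique(scores):
        pred = scores >= t
        tp = int((pred & (onehot == 1)).sum())
        fp = int((pred & (onehot == 0)).sum())
        fn = int((~pred & (onehot == 1)).sum())
        if tp:
            best = max(best, 2 * tp / (2 * tp + fp + fn))
    return best


def _roc_auc(y: np.ndarray, proba: np.ndarray) -> float:
    if proba.shape[1] == 2:
        return float(roc_auc_score(y, proba[:, 1]))
    return float(roc_auc_score(y, proba, multi_class="ovr", average="macro"))


def crossvalidate(table: AbundanceTable, labels: dict[str, str] | Sequence[str],
                  k: int = 5, cfg: TrainConfig | None = None,
                  model_config: ModelConfig | None = None,
                  pretrained: Model | None = None,
                  max_len: int = 512) -> dict:
    """Stratified k-fold fine-tuning evaluation: macro ROC-AUC and F-max.

    Starts each fold from ``pretrained`` when given (the with-pretraining
    arm) or from a fresh random initialization of ``model_config`` (the
    from-scratch baseline). Fold assignment depends only on the seed, the
    labels, and the sample order.
    """
    cfg = cfg or TrainConfig()
    if isinstance(labels, dict):
        y_names = [labels[s] for s in table.sample_ids]
    else:
        y_names = list(labels)
    classes = sorted(set(y_names))
    y = np.array([classes.index(c) for c in y_names])
    counts = np.bincount(y)
    if counts.min() < k:
        raise TrainingError(
            f"smallest class has {counts.min()} members; needs >= k={k}")
    if pretrained is None and model_config is None:
        raise TrainingError("provide model_config or a pretrained model")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    folds = []
    for f, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        tr_table = AbundanceTable([table.sample_ids[i] for i in tr],
                                  list(table.genus_names), table.values[tr])
        te_table = AbundanceTable([table.sample_ids[i] for i in te],
                                  list(table.genus_names), table.values[te])
        stats = fit_normalization(tr_table)
        if pretrained is not None:
            base = pretrained.copy()
            vocab = base.vocab
            if vocab is None:
                raise TrainingError("pretrained model has no vocabulary")
        else:
            vocab = build_vocab(tr_table)
            from dataclasses import replace as _replace
            mc = _replace(model_config, vocab_size=vocab.size,
                          seed=model_config.seed + f)
            base = build_model(mc, head="lm", vocab=vocab)
        seqs_tr = encode_table(tr_table, stats, vocab, max_len)
        seqs_te = encode_table(te_table, stats, vocab, max_len)
        fold_cfg = replace(cfg, seed=cfg.seed + f)
        clf, hist = finetune_classifier(base, seqs_tr,
                                        [y_names[i] for i in tr], fold_cfg)
        proba = predict_proba(clf, seqs_te)
        y_te = y[te]
        folds.append({
            "fold": f,
            "roc_auc": _roc_auc(y_te, proba),
            "fmax": fmax(y_te, proba[:, 1] if len(classes) == 2 else proba),
            "n_test": len(te),
            "best_val_loss": hist.best_val_loss,
        })
    aucs = [f["roc_auc"] for f in folds]
    fms = [f["fmax"] for f in folds]
    return {
        "folds": folds,
        "roc_auc_mean": float(np.mean(aucs)), "roc_auc_sd": float(np.std(aucs)),
        "fmax_mean": float(np.mean(fms)), "fmax_sd": float(np.std(fms)),
        "classes": classes,
    }
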