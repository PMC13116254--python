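# microformer

Transformer language models for microbial communities, at desk scale.

Genus-level relative-abundance tables (samples × genera, the standard output
of amplicon or shotgun profiling) are sparse compositional data: most genera
are absent from most samples, and magnitudes span orders of magnitude.
`microformer` treats each sample as a *sentence*: its genera are sorted by
z-normalized abundance and emitted as a token sequence (rank 1 first,
wrapped in `bos`/`eos`), so that a causal transformer can learn community
structure the way language models learn text. On top of that backbone the
package provides:

- **Corpus preparation** — TSV I/O, the standard corpus filters (zero
  abundances below 0.01%, drop samples with fewer than 10 retained genera),
  and a prevalence-ordered genus vocabulary.
- **Pretraining and fine-tuning** — causal language modeling
  (L(θ) = −Σₖ log P(t₍ₖ₊₁₎ | t₁..tₖ; θ)) with AdamW, linear warmup and
  early stopping; a swappable eos-position classification head; stratified
  k-fold cross-validation reporting macro ROC-AUC and F-max.
- **Interpretability** — per-genus attention received, computed from the
  attention probability matrices softmax(QKᵀ/√d_k) averaged elementwise over
  all layers and heads and summed per column (equivalent to replacing V with
  one-hot position indicators); and leave-one-genus-out perturbation, where
  deleting a genus token and measuring 1 − cosine similarity of the sample
  embedding scores keystone candidates.
- **Conditional generation** — label tokens inserted after `bos` steer
  next-token sampling toward a class; a reconstructor network
  (N×2N×N×N, ReLU/ReLU/softmax with residual connections) maps
  rank-position-encoded presence vectors X ∈ [0,2]^N back onto the
  abundance simplex.
- **The Microbiome Turing Test** — a two-phase battery comparing a generated
  table with a real one: distributional fidelity (paired cosine, MAE,
  Spearman; Shannon/Simpson alpha diversity; sparsity entropy with a
  Wilcoxon comparison) and biological relevance (real-trained Random Forest
  ROC-AUC on generated data, top-feature biomarker overlap, and Pearson
  co-occurrence network density / average degree / modularity).
- **A synthetic-data module** — a seeded simulator of sparse compositional
  tables with planted class markers of tunable effect size, keystone taxa
  with dependent companion taxa, and exact rank→abundance laws, so the whole
  pipeline is testable without downloading any corpus.

The transformer is implemented in numpy with
[autograd](https://github.com/HIPS/autograd) supplying gradients; everything
runs on one CPU core. Toy configurations (2 layers, 2 heads, d_model 32)
train in seconds; the full-scale configuration (8 layers, 8 heads,
feed-forward 1024, 512-token context) is available via
`full_scale_config()` for users with the compute to match.

## Worked example

`examples/03_classify_communities.py` simulates a two-class corpus whose
classes differ by planted marker genera (8 markers per class, enriched 8×),
pretrains a toy causal LM, and runs stratified 5-fold cross-validated
fine-tuning:

```
classes: ['class0', 'class1']
  fold 0: ROC-AUC 1.000, F-max 1.000 (n=30)
  fold 1: ROC-AUC 0.911, F-max 0.867 (n=30)
  fold 2: ROC-AUC 1.000, F-max 1.000 (n=29)
  fold 3: ROC-AUC 0.976, F-max 0.929 (n=29)
  fold 4: ROC-AUC 0.948, F-max 0.923 (n=29)
mean ROC-AUC 0.967 +/- 0.034
mean F-max   0.944 +/- 0.051
```

A mean ROC-AUC near 1 means the fine-tuned transformer recovered the planted
markers from rank order alone — the abundances themselves were discarded at
encoding time. The other examples walk through encoding
(`01_encode_communities.py`), pretraining and embeddings
(`02_pretrain_and_embed.py`), keystone screening (`04_keystone_screen.py`),
conditional generation with reconstruction
(`05_conditional_generation.py`), and the Turing-test evaluation
(`06_turing_test.py`).

The same workflow is scriptable from the shell:

```bash
microformer simulate --config sim.yaml --seed 5 --out t.tsv --meta m.tsv
microformer filter --table t.tsv --out tf.tsv
microformer build-vocab --table tf.tsv --out vocab.json
microformer encode --table tf.tsv --vocab vocab.json --stats stats.json \
    --meta m.tsv --max-len 512 --out corpus.jsonl
microformer pretrain --corpus corpus.jsonl --vocab vocab.json --out ckpt/
microformer perturb --ckpt ckpt/ --corpus corpus.jsonl --genera all --out screen.tsv
microformer generate --ckpt gen_ckpt/ --label class0 --n 100 --seed 7 --out gen.jsonl
microformer turing-test --real-train a.tsv --real-test b.tsv \
    --generated g.tsv --labels m.tsv --seed 7 --out report.json
```

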