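# Methods

## Rank-value encoding

A sample is the set of its genera with nonzero relative abundance. Each
genus j has frozen training-corpus statistics μⱼ (mean) and σⱼ (population
standard deviation, zeros included — "dataset-wide" statistics are taken
over every training sample, so they are defined for every genus and do not
depend on which samples happen to contain it). A sample's nonzero entries
are z-scored, x′ = (x − μⱼ)/σⱼ, sorted descending, and emitted as
`[bos, t₍rank 1₎, …, t₍rank n₎, eos]`. Conventions:

- σⱼ = 0 (a constant genus) normalizes to 0, avoiding division by zero.
- Ties break toward the larger raw abundance, then lexicographic genus
  name, so sequences are bit-reproducible.
- The context length (default 512, specials and any label token included)
  truncates the lowest-ranked genera.
- Because z-scoring is a per-genus affine map, rank order can differ from
  raw-abundance order when genera have different μ/σ. This is intended: the
  encoding asks "how unusual is this abundance *for this genus*".
- Genera absent from the vocabulary map to `unk` and are dropped from
  sequences (logged), matching the closed vocabulary of the transformer.

Corpus filters: abundances below `min_rel_abund` (default 10⁻⁴, i.e. 0.01%)
are zeroed per sample; samples with fewer than `min_genera` (default 10)
surviving genera are dropped; surviving rows are renormalized by default so
downstream ranks reflect retained genera only (flag to disable). The filter
is idempotent. "Non-negligible abundance" is read as the same 0.01%
threshold. Vocabulary ids are assigned by descending corpus prevalence with
lexicographic tie-break: deterministic, and frequent genera get small ids.

## Model

A decoder-only transformer: learned token and absolute position embeddings
(GPT-style; the position-embedding family is a design choice here), pre-norm
blocks of multi-head scaled dot-product attention softmax(QKᵀ/√d_k)V under a
causal mask, GELU feed-forward layers, a closing layer norm. Forward and
backward passes are numpy; `autograd` supplies gradients. The
language-modeling head is zero-initialized, so an untrained model predicts
the exact uniform distribution — per-token cross-entropy ln |V| — which the
tests use as an analytic anchor. The classification head is a single linear
layer reading the hidden state at the eos position.

Full-scale defaults (`full_scale_config`): 8 layers, 8 heads, feed-forward
1024, context 512, d_model 512 (the width is this package's choice; tests
are width-agnostic). All tests and examples use the toy configuration
(2 layers, 2 heads, d_model 32, feed-forward 64), which trains in seconds
on one CPU core.

## Training

Objective: mean next-token cross-entropy (nats) over non-pad positions,
L(θ) = −Σₖ log P(t₍ₖ₊₁₎ | t₁..tₖ; θ). Optimizer: AdamW (decoupled weight
decay on matrices and embeddings, none on biases or layer norms) with linear
warmup, then linear decay when `max_steps` is set. Defaults follow the
full-scale recipe: lr 1e-3, batch 50, warmup 1000 steps, weight decay
0.001, validation split 10%, early stopping with patience 3 (evaluations
per epoch or every `eval_every` steps); the returned model carries the
best-validation parameters. Fine-tuning uses the same loop with the
classifier loss, a stratified validation split, and the whole backbone
unfrozen. At toy scale the tests fine-tune at lr 3e-4: the full-scale rate
overshoots a d_model-32 model badly enough to erase its pretrained
features, and both arms of any comparison always share one configuration.

The no-signal control for classification runs the identical pipeline on a
matched corpus whose classes are statistically exchangeable (marker effect
1, no keystone). This is the distributional equivalent of label shuffling
and is used instead of it deliberately: a single label permutation retains
chance-level agreement with the true labels (several percent at a few
hundred samples), and a classifier over strongly separable features
amplifies that residue into held-out AUROC far from 0.5 in either
direction. On the exchangeable corpus the features carry no class
information at all, and held-out AUROC concentrates tightly at chance.

Cross-validation is stratified k-fold (default 5). Metrics: macro
one-vs-rest ROC-AUC, and F-max — the maximum micro-averaged F1 over all
observed decision thresholds, computed by direct enumeration (the
definition is a convention here; the implementation is brute force and is
cross-checked against an independent enumeration in the tests). The
"without pretraining" baseline is the identical pipeline from random
initialization.

## Interpretability

With V replaced by one-hot position indicators V⁰, row q of
softmax(QKᵀ/√d_k)·V⁰ is exactly the attention probability row, so the
implementation exports the probability matrices directly instead of running
a second forward pass. They are averaged elementwise over all layers and
heads; a genus's score is its column sum — the total attention it receives
from the community. Special-token columns are excluded from rankings
(flag-controlled); with them included, the column sums of a length-T
sequence add to exactly T, a conservation law the tests assert.

Leave-one-genus-out perturbation deletes one genus token (remaining order
preserved), recomputes the sample embedding, and reports
1 − cosine similarity as the deleterious score. A genus absent from a
sample yields cosine similarity exactly 1 by contract. Sample embeddings:
mean pooling over genus-token positions for pretrained models (specials
excluded; flag to include), the eos hidden state for fine-tuned
classifiers; perturbation follows the model's head by default. The screen
reports mean ± SD per genus over the samples that contain it. Keystone
significance uses a one-sided Wilcoxon signed-rank on within-sample
differences (keystone score minus the mean background-genus score in the
same community), which controls for community size and is substantially
better powered than pooling scores across samples.

## Conditional generation and reconstruction

The vocabulary is extended with one token per class label — embedding rows
are appended, never reindexed — and each training sequence becomes
`[bos, label, rank-1 genus, …, eos]` (the label counts toward the context
length; the lowest rank is truncated if needed). Fine-tuning is ordinary
next-token prediction. Decoding starts from `[bos, label]` and samples with
temperature (default 1.0; 0 means greedy argmax), optional top-k, and
repeat-forbidding on by default, since a genus occurs at most once in a
rank encoding. `min_new_tokens` (default 1) prevents an underfit model from
emitting `eos` immediately and producing an empty community. Perplexity is
exp(mean next-token cross-entropy) over predicted positions.

The reconstructor maps X ∈ [0,2]^N to the abundance simplex, where
xᵢ = sin(pᵢ) + 1 for the genus at 1-based rank position pᵢ (the d_model = 1
sinusoidal position embedding, shifted nonnegative) and xᵢ = 0 exactly when
genus i is absent. Architecture N×2N×N×N: ReLU after the first two layers,
softmax output, residual connections around the two same-shape (N→N)
layers. Training: Adam, lr 2e-4, batch 64, 20% validation split, early
stopping with patience 10; loss is the cross-entropy between the true
composition and the softmax output (KL up to a constant; natural for
simplex targets — MSE available by flag). The default output masks genera
absent from the input and renormalizes, since the rank sequence already
determines the support exactly and only magnitudes are learned.

Reconstruction quality is measured as the per-sample Spearman correlation
between the masked reconstruction and the true profile over the full genus
axis. The decoupled control — training and evaluating against profiles
shuffled across samples — verifies that the protocol manufactures no
correlation (it sits at ≈ 0, versus ≈ 0.99 for genuinely paired data at
the simulator's settings).

## The Microbiome Turing Test

Phase 1 (per class label, averaged over labels, bootstrap 95% CIs by
resampling pairs within labels): both sides are sorted by sample id, the
larger side is down-sampled (seeded) to the smaller, and samples are paired
by index — the pairing is a documented convention; no canonical pairing
exists between real and generated samples. Per pair: cosine similarity,
mean absolute error, Spearman correlation. Per sample: Shannon (natural
log) and Simpson (1 − Σp²) alpha diversity via scikit-bio, and a sparsity
entropy defined as ln(richness) — the entropy of the uniform distribution
over present taxa. (Entropy of the renormalized nonzero abundances would be
numerically identical to alpha Shannon on a simplex row, so the richness
reading is the one that yields a distinct sparsity measure.) The real and
generated sparsity-entropy distributions are compared with a Wilcoxon
signed-rank test.

Phase 2: a Random Forest (200 trees, seeded) trained on the real training
table scores the generated table (macro one-vs-rest ROC-AUC); a second
forest is trained on the generated table and the top-500 feature
importances of the two are intersected (biomarker overlap; with fewer than
500 genera the comparison covers min(500, n_features), which saturates at
desk scale — the discriminating comparison between candidate generators
then uses a smaller `top_k`). Pearson co-occurrence networks (|r| ≥ 0.3 by
default, zero-variance genera excluded) are summarized by density
2E/(V(V−1)), average degree 2E/V, and the modularity of the greedy
modularity-community partition (0 for an edgeless graph).

## The synthetic-data generator

The simulator emulates what the analyses assume about real surveys, with
every effect planted at a known, recoverable strength:

- **Sparsity**: each genus is present with probability p = 1 − sparsity
  (default 0.8); abundances over present taxa are Dirichlet draws (or a
  geometric law over a concentration-biased random order). Rows sum to 1.
- **Markers**: marker presence is scaled by C·e/(e+C−1) in the marker's own
  class and C/(e+C−1) elsewhere (C classes, effect e), so the own/other
  presence-frequency ratio equals `marker_effect` exactly while the
  marginal presence rate — hence overall sparsity — is unchanged. Marker
  concentrations are also scaled by e when present.
- **Keystones**: a keystone is present with probability 0.7 and its
  concentration is boosted (default 8×) so it occupies top ranks; coupled
  taxa (a configurable fraction of genera) occur only when their keystone
  does, with conditional probability p/0.7 so their marginal presence stays
  at p. This gives the perturbation module a planted signal whose removal
  maximally shifts the learned context.
- **Rank-abundance pairs**: under the geometric law the rank-r taxon has
  abundance ∝ rateʳ exactly, and which taxon occupies which rank follows a
  Plackett–Luce draw with per-genus weights exp(−rank_propensity·j/N) — as
  in real communities, taxa have characteristic abundances — while presence
  stays uniform, so rank structure carries no information about occurrence.
- One global seed drives everything through named substreams (CRC-derived),
  so adding a consumer never shifts existing draws.

What it does **not** emulate: phylogenetic correlation between genera,
sequencing depth and zero-inflation mechanics, batch effects, longitudinal
autocorrelation, and the heavy-tailed prevalence distribution of real
surveys. Tests passing on this simulator therefore demonstrate that the
pipeline recovers planted structure of the stated kinds at desk scale, not
that the full-scale model reproduces any real-world benchmark.

## Problem sizes

The test suite and the acceptance script run toy models (2×2×32) on corpora
of 400–1200 samples over 40–60 genera, with 100 generated samples per label
and 1500 reconstructor training pairs — sizes chosen so the complete
pipeline, including all training runs, finishes in a few minutes on a
single CPU core while every planted effect stays statistically resolvable.
The keystone corpus in particular uses 500 pretraining samples and up to
120 epochs: with less pretraining the model underfits the keystone-coupled
co-occurrence structure on some seeds and the perturbation signal drowns in
positional variance.

## Known limitations

- The d_model = 1 sinusoidal rank encoding is nearly blind at positions
  where sin(p) ≈ −1 (p = 5, 11, …: x = sin(p)+1 ≈ 0), and the fixed
  N×2N×N×N reconstructor has ~2 hidden units per genus — not enough to
  invert the sin lookup for arbitrary permutations. Consequently mean
  reconstructed abundance decreases with rank position only as a trend
  (negative Spearman), not strictly monotonically.
- Cosine similarity discriminates weakly between sparse tables in low
  dimension: a dense Dirichlet baseline scores ≈ 0.23 against 60-genus
  profiles whose mutual ceiling under arbitrary pairing is ≈ 0.36. ROC-AUC,
  Spearman, and biomarker overlap separate generators far more sharply at
  desk scale.
- Compositional closure can cancel designed covariance: correlation-network
  properties are only meaningful relative to a same-pipeline baseline.
- The full-scale configuration is provided but untested at scale; all
  quantitative statements in the tests refer to the toy configuration on
  simulated data.
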